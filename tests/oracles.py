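"""Independent brute-force oracles used by the test suite.

Everything here enumerates exhaustively: latent state assignments for the
likelihood/posterior/expected-count oracles, labelings for the parsimony
oracles, topologies for the search oracle.  These implementations share no
code with the package's dynamic programs.
"""

from __future__ import annotations

import itertools

import numpy as np

from pmmtree.data import MISSING
from pmmtree.transitions import dropout_matrix, state_order, transition_matrix


def _site_setup(tree, params, matrix, site):
    alpha = matrix.alphabets[site]
    order = state_order(alpha)                 # [0, m..., -1]
    pos = {s: i for i, s in enumerate(order)}
    Psi = {
        n.name: transition_matrix(params.delta[n.name], params.nu, alpha)
        for n in tree.postorder() if n.parent is not None
    }
    Phi = dropout_matrix(params.phi, alpha)
    df = matrix.to_frame()
    obs_col = {}
    for leaf in tree.leaves():
        v = df.loc[leaf.name].iloc[site]
        obs_col[leaf.name] = len(order) - 1 if v == MISSING else pos[int(v)]
    return order, pos, Psi, Phi, obs_col


def enum_site_joint(tree, params, matrix, site):
    """Yield (assignment dict node->state index, joint probability)."""
    order, pos, Psi, Phi, obs_col = _site_setup(tree, params, matrix, site)
    nodes = [n for n in tree.postorder()]
    root = nodes[-1]
    free = [n for n in nodes if n is not root]
    S = len(order)
    for combo in itertools.product(range(S), repeat=len(free)):
        assign = {root.name: 0}
        assign.update({n.name: s for n, s in zip(free, combo)})
        p = 1.0
        for n in free:
            p *= Psi[n.name][assign[n.parent.name], assign[n.name]]
            if p == 0.0:
                break
        if p == 0.0:
            continue
        for leaf in tree.leaves():
            p *= Phi[assign[leaf.name], obs_col[leaf.name]]
            if p == 0.0:
                break
        if p > 0.0:
            yield assign, p


def enum_site_likelihood(tree, params, matrix, site=0) -> float:
    return sum(p for _, p in enum_site_joint(tree, params, matrix, site))


def enum_log_likelihood(tree, params, matrix) -> float:
    return float(
        sum(
            np.log(enum_site_likelihood(tree, params, matrix, k))
            for k in range(matrix.n_sites)
        )
    )


def enum_node_posteriors(tree, params, matrix, site=0):
    """dict node name -> posterior vector over [0, mutated..., -1]."""
    order = state_order(matrix.alphabets[site])
    S = len(order)
    post = {n.name: np.zeros(S) for n in tree.postorder()}
    total = 0.0
    for assign, p in enum_site_joint(tree, params, matrix, site):
        total += p
        for name, s in assign.items():
            post[name][s] += p
    return {name: v / total for name, v in post.items()}


def enum_expected_counts(tree, params, matrix):
    """Grouped per-edge expectations and per-leaf (B, Btilde) by enumeration."""
    names = [n.name for n in tree.postorder() if n.parent is not None]
    czz = {e: 0.0 for e in names}
    cza, czm, caa, cam = dict(czz), dict(czz), dict(czz), dict(czz)
    df = matrix.to_frame()
    B = {l.name: int((df.loc[l.name] != MISSING).sum()) for l in tree.leaves()}
    Btilde = {l.name: 0.0 for l in tree.leaves()}
    for k in range(matrix.n_sites):
        order = state_order(matrix.alphabets[k])
        silent = len(order) - 1
        total = 0.0
        acc = {e: np.zeros(5) for e in names}
        leaf_sil = {l.name: 0.0 for l in tree.leaves()}
        for assign, p in enum_site_joint(tree, params, matrix, k):
            total += p
            for n in tree.postorder():
                if n.parent is None:
                    continue
                a, b = assign[n.parent.name], assign[n.name]
                if a == 0 and b == 0:
                    acc[n.name][0] += p
                elif a == 0 and b not in (0, silent):
                    acc[n.name][1] += p
                elif a == 0 and b == silent:
                    acc[n.name][2] += p
                elif a not in (0, silent) and b == a:
                    acc[n.name][3] += p
                elif a not in (0, silent) and b == silent:
                    acc[n.name][4] += p
            for leaf in tree.leaves():
                if df.loc[leaf.name].iloc[k] == MISSING and assign[leaf.name] == silent:
                    leaf_sil[leaf.name] += p
        for e in names:
            czz[e] += acc[e][0] / total
            cza[e] += acc[e][1] / total
            czm[e] += acc[e][2] / total
            caa[e] += acc[e][3] / total
            cam[e] += acc[e][4] / total
        for l in tree.leaves():
            if df.loc[l.name].iloc[k] == MISSING:
                Btilde[l.name] += 1.0 - leaf_sil[l.name] / total
    return czz, cza, czm, caa, cam, B, Btilde


# ---------------------------------------------------------------------------
# Parsimony oracles
# ---------------------------------------------------------------------------

def enum_min_parsimony(tree, leaf_states, cost, root_state=None):
    """Minimum total cost over all internal labelings, by enumeration.

    ``leaf_states[name]`` is a fixed state index or a list of allowed states.
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    S = cost.shape[0]
    leaf_opts = []
    for l in leaves:
        v = leaf_states[l.name]
        leaf_opts.append(list(v) if isinstance(v, (list, tuple)) else [v])
    best = np.inf
    for leaf_combo in itertools.product(*leaf_opts):
        for combo in itertools.product(range(S), repeat=len(internal)):
            assign = {n.name: s for n, s in zip(internal, combo)}
            assign.update({l.name: s for l, s in zip(leaves, leaf_combo)})
            if root_state is not None and assign[tree.root.name] != root_state:
                continue
            c = 0.0
            for n in nodes:
                if n.parent is not None:
                    c += cost[assign[n.parent.name], assign[n.name]]
                    if c >= best:
                        break
            best = min(best, c)
    return best


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------

def all_rooted_topologies(names):
    """All distinct single-child-root topologies over ``names`` (unrooted
    shapes x root positions collapse to (2n-3)!! rooted shapes; for the
    model's fixed root-pendant convention these are the trees whose unrooted
    versions are the (2n-5)!! shapes with the root pendant on each edge).

    Implemented by recursive leaf insertion on every edge.
    """
    from pmmtree.tree import LineageTree, Node

    def clone(node):
        c = Node(name=node.name)
        for ch in node.children:
            c.add_child(clone(ch))
        return c

    def insert_on_each_edge(tree_root, leaf_name):
        out = []
        body = tree_root.children[0]
        # collect edges (as child nodes) of the body subtree, plus the top edge
        def edges(node):
            yield node
            for c in node.children:
                yield from edges(c)

        for target in edges(body):
            r = Node(name="root")
            nb = clone(body)
            r.add_child(nb)
            # find copied target by path
            path = []
            t = target
            while t is not body:
                path.append(t.parent.children.index(t))
                t = t.parent
            t = nb
            for i in reversed(path):
                t = t.children[i]
            parent = t.parent if t.parent is not None else r
            parent.remove_child(t)
            mid = Node()
            mid.add_child(t)
            mid.add_child(Node(name=leaf_name))
            parent.add_child(mid)
            out.append(LineageTree(r))
        return out

    first = Node(name="root")
    first.add_child(Node(name=names[0]))
    trees = [LineageTree(first)]
    for nm in names[1:]:
        trees = [t2 for t in trees for t2 in insert_on_each_edge(t.root, nm)]
    return trees
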