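"""Tree-comparison and parsimony-based evaluation metrics.

Includes the normalized Robinson-Foulds error between topologies, RMSE of
(phi, nu) estimates across replicates, Sankoff-parsimony branch lengths under
the irreversible editing model, the migration graph/cost for anatomical-site
labelings, triplet-based progenitor discordance, and the developmental cost
against a directed cell-type tree.  All Sankoff passes share one generic
dynamic program; ties in the top-down traceback are broken toward the
lexicographically smallest state, a deterministic convention that can affect
which optimal labeling is reported but never its cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, CharacterMatrix, ValidationError
from .tree import LineageTree

INF = np.inf


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _nontrivial_bipartitions(tree: LineageTree, ref: str) -> set[frozenset]:
    """Unrooted bipartitions, each canonicalized as the side without ``ref``."""
    leaves = set(tree.leaf_names)
    n = len(leaves)
    out = set()
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        side = frozenset(l.name for l in LineageTree(node).leaves())
        if len(side) < 2 or len(side) > n - 2:
            continue
        if ref in side:
            side = frozenset(leaves - side)
        out.add(side)
    return out


def rf_error(t1: LineageTree, t2: LineageTree) -> float:
    """(FN + FP) / (internal edges of t1 + internal edges of t2), in [0, 1]."""
    l1, l2 = set(t1.leaf_names), set(t2.leaf_names)
    if l1 != l2:
        raise ValidationError(
            f"leaf sets differ: {sorted(l1 ^ l2)[:5]} not shared"
        )
    ref = min(l1)
    b1 = _nontrivial_bipartitions(t1, ref)
    b2 = _nontrivial_bipartitions(t2, ref)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return (len(b1 - b2) + len(b2 - b1)) / denom


# ---------------------------------------------------------------------------
# Parameter RMSE
# ---------------------------------------------------------------------------

def parameter_rmse(
    estimates: list[tuple[float, float]], truth: tuple[float, float]
) -> float:
    """sqrt(mean over replicates of squared (phi, nu) deviation)."""
    if not estimates:
        raise ValidationError("need at least one estimate")
    phi_t, nu_t = truth
    d = [((p - phi_t) ** 2 + (n - nu_t) ** 2) for p, n in estimates]
    return float(np.sqrt(np.mean(d)))


# ---------------------------------------------------------------------------
# Generic Sankoff
# ---------------------------------------------------------------------------

def sankoff(
    tree: LineageTree,
    leaf_costs: dict[str, np.ndarray],
    cost: np.ndarray,
    root_state: int | None = None,
) -> tuple[dict[str, int], float]:
    """Minimum-cost ancestral labeling by dynamic programming.

    ``leaf_costs[name]`` is the cost vector of assigning each state to that
    leaf; ``cost[a, b]`` the parent-to-child transition cost.  Returns the
    per-node state assignment (lexicographic tie-break) and the total cost.
    """
    S = cost.shape[0]
    table: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            table[node.name] = np.asarray(leaf_costs[node.name], dtype=float)
        else:
            acc = np.zeros(S)
            for c in node.children:
                acc = acc + (cost + table[c.name][None, :]).min(axis=1)
            table[node.name] = acc
    root_vec = table[tree.root.name]
    if root_state is None:
        total = float(root_vec.min())
        root_state = int(np.argmin(root_vec))      # argmin -> smallest index
    else:
        total = float(root_vec[root_state])
    if not np.isfinite(total):
        raise ValidationError("no finite-cost labeling exists")
    assign = {tree.root.name: root_state}
    for node in tree.preorder():
        s = assign[node.name]
        for c in node.children:
            opts = cost[s, :] + table[c.name]
            assign[c.name] = int(np.argmin(opts))
    return assign, total


# ---------------------------------------------------------------------------
# Maximum-parsimony branch lengths
# ---------------------------------------------------------------------------

def mp_branch_lengths(
    tree: LineageTree, matrix: CharacterMatrix, lam: float | None = None
) -> dict[str, float]:
    """Per-edge parsimony mutation counts (optionally divided by lam).

    Sankoff with unit cost per edit under the irreversible state space: 0 can
    change to any observed mutated state at cost 1, mutated states can only
    persist, and "?" leaves are free.  The root is fixed to the unedited
    state.  The length of an edge is the number of sites whose reconstructed
    parent and child states differ.
    """
    leaves = tree.leaf_names
    if set(leaves) - set(matrix.cell_names):
        raise ValidationError("tree leaves missing from matrix")
    counts = {n.name: 0.0 for n in tree.postorder() if n.parent is not None}
    df = matrix.to_frame()
    for k, site in enumerate(matrix.site_names):
        states = [0] + matrix.observed_states(k)
        S = len(states)
        pos = {s: i for i, s in enumerate(states)}
        cost = np.full((S, S), INF)
        np.fill_diagonal(cost, 0.0)
        cost[0, :] = 1.0
        cost[0, 0] = 0.0
        leaf_costs = {}
        for name in leaves:
            v = df.loc[name].iloc[k]
            if v == MISSING:
                leaf_costs[name] = np.zeros(S)
            else:
                vec = np.full(S, INF)
                vec[pos[int(v)]] = 0.0
                leaf_costs[name] = vec
        assign, _ = sankoff(tree, leaf_costs, cost, root_state=0)
        for node in tree.postorder():
            if node.parent is not None and assign[node.name] != assign[node.parent.name]:
                counts[node.name] += 1.0
    if lam is not None:
        counts = {e: c / lam for e, c in counts.items()}
    return counts


# ---------------------------------------------------------------------------
# Migration cost
# ---------------------------------------------------------------------------

@dataclass
class MigrationGraph:
    """Directed multigraph of site-to-site transitions with integer weights."""

    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, src: str, dst: str) -> None:
        if src == dst:
            raise ValidationError("self-loops are collapsed before tallying")
        self.edges[(src, dst)] = self.edges.get((src, dst), 0) + 1

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for (s, d), w in self.edges.items():
            g.add_edge(s, d, weight=w)
        return g


def migration_cost(
    tree: LineageTree, leaf_sites: dict[str, str], primary: str
) -> tuple[MigrationGraph, int, int]:
    """Parsimony migration graph, migration cost, and reseeding cost.

    Ancestral anatomical sites are inferred by unit-cost Sankoff with the
    root fixed to the primary site; edges whose endpoints share a label are
    collapsed, and the remaining (parent site, child site) transitions are
    tallied.  Migration cost is the total weight; reseeding cost the weight
    of edges returning to the primary site.
    """
    for leaf in tree.leaf_names:
        if leaf not in leaf_sites:
            raise ValidationError(f"leaf {leaf!r} has no site label")
    sites = sorted(set(leaf_sites.values()) | {primary})
    pos = {s: i for i, s in enumerate(sites)}
    S = len(sites)
    cost = np.ones((S, S)) - np.eye(S)
    leaf_costs = {}
    for leaf in tree.leaf_names:
        vec = np.full(S, INF)
        vec[pos[leaf_sites[leaf]]] = 0.0
        leaf_costs[leaf] = vec
    assign, _ = sankoff(tree, leaf_costs, cost, root_state=pos[primary])
    graph = MigrationGraph()
    for node in tree.postorder():
        if node.parent is None:
            continue
        a, b = sites[assign[node.parent.name]], sites[assign[node.name]]
        if a != b:
            graph.add(a, b)
    reseed = sum(w for (s, d), w in graph.edges.items() if d == primary)
    return graph, graph.total_weight, reseed


# ---------------------------------------------------------------------------
# Progenitor discordance (normalized triplet error)
# ---------------------------------------------------------------------------

def _pairwise_lca_depth(tree: LineageTree, names: list[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    depth_of_lca = np.zeros((n, n))
    # node depth = edge count from root
    depth = {tree.root.name: 0}
    for node in tree.preorder():
        for c in node.children:
            depth[c.name] = depth[node.name] + 1
    for node in tree.postorder():
        if node.is_leaf or len(node.children) < 2:
            continue
        groups = [
            [idx[l.name] for l in LineageTree(c).leaves() if l.name in idx]
            for c in node.children
        ]
        d = depth[node.name]
        for gi, gj in itertools.combinations(range(len(groups)), 2):
            for a in groups[gi]:
                for b in groups[gj]:
                    depth_of_lca[a, b] = depth_of_lca[b, a] = d
    return depth_of_lca


def progenitor_discordance(tree: LineageTree, labels: dict[str, object]) -> float:
    """Fraction of label-resolved leaf triplets contradicted by the tree.

    A triplet (a1, a2, b) with a1, a2 sharing a label and b labeled
    differently is concordant when the tree places b as the outgroup, i.e.
    the a1-a2 join is strictly below the triplet's overall join.  With no
    resolved triplet the discordance is 0 by convention.
    """
    leaf_names = set(tree.leaf_names)
    labeled = sorted(
        c for c, v in labels.items() if v != MISSING and c in leaf_names
    )
    if len(labeled) < 3:
        return 0.0
    P = _pairwise_lca_depth(tree, labeled)
    lab = [labels[c] for c in labeled]
    n = len(labeled)
    n_resolved = 0
    n_discordant = 0
    for i, j in itertools.combinations(range(n), 2):
        if lab[i] != lab[j]:
            continue
        pij = P[i, j]
        for k in range(n):
            if k in (i, j) or lab[k] == lab[i]:
                continue
            n_resolved += 1
            if not (pij > P[i, k] and pij > P[j, k]):
                n_discordant += 1
    if n_resolved == 0:
        return 0.0
    return n_discordant / n_resolved


# ---------------------------------------------------------------------------
# Developmental cost
# ---------------------------------------------------------------------------

def developmental_cost(
    tree: LineageTree,
    leaf_types: dict[str, str],
    dev_tree,
) -> float:
    """Minimum number of cell-type transitions consistent with ``dev_tree``.

    ``dev_tree`` is a directed graph (networkx DiGraph or an iterable of
    (parent, child) edges) over cell types; the transition cost from s to t
    is the directed path length when t is reachable from s and infinite
    otherwise.  Sankoff over all ancestral labelings extending the leaves.
    """
    import networkx as nx

    if not isinstance(dev_tree, nx.DiGraph):
        g = nx.DiGraph()
        g.add_edges_from(dev_tree)
        dev_tree = g
    types = sorted(set(dev_tree.nodes) | set(leaf_types.values()))
    pos = {t: i for i, t in enumerate(types)}
    S = len(types)
    cost = np.full((S, S), INF)
    lengths = dict(nx.all_pairs_shortest_path_length(dev_tree))
    for s in types:
        cost[pos[s], pos[s]] = 0.0
        for t, d in lengths.get(s, {}).items():
            cost[pos[s], pos[t]] = float(d)
    leaf_costs = {}
    for leaf in tree.leaf_names:
        if leaf not in leaf_types:
            raise ValidationError(f"leaf {leaf!r} has no type label")
        vec = np.full(S, INF)
        vec[pos[leaf_types[leaf]]] = 0.0
        leaf_costs[leaf] = vec
    _, total = sankoff(tree, leaf_costs, cost)
    return total
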