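"""Topology search: nearest-neighbor interchange with simulated annealing.

The search walks the NNI neighborhood of the current tree, refits all
parameters by EM on each proposal, and accepts improving moves always and
worsening moves with an annealed probability

    Temp(t) = max(eps, (alpha^t - alpha^c) / (1 - alpha^c))
    p(t)    = min(1, exp(l(t) - l(t-1) - eps) / Temp(t)).

The NNI neighborhood is defined on the unrooted topology induced by the
leaves (the root pendant and its single-child convention stay fixed on their
edge), giving the standard 2 x (number of internal edges) neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import CharacterMatrix, PMMParams, ValidationError
from .em import EMConfig, em_fit
from .tree import LineageTree, Node

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    eps: float = 1e-12       # annealing constant (also the temperature floor)
    c: int = 20              # cooling horizon
    alpha: float = 0.9       # cooling base
    eta: float = 1e-3        # minimum log-likelihood improvement to continue
    t_max: int = 2000        # accepted-move cap
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


# ---------------------------------------------------------------------------
# NNI moves
# ---------------------------------------------------------------------------

def internal_edges(tree: LineageTree) -> list[tuple[str, str]]:
    """Internal edges of the unrooted leaf-induced topology.

    Each edge is a ``(parent_name, child_name)`` pair of the rooted tree,
    except the single edge that runs "through" the root's child, which is
    returned as the pair of that node's two children.
    """
    root = tree.root
    if len(root.children) != 1:
        raise ValidationError("tree must have a single-child root")
    top = root.children[0]
    edges: list[tuple[str, str]] = []
    for node in tree.postorder():
        if (
            node.parent is not None
            and not node.is_leaf
            and node.parent not in (root, top)
        ):
            edges.append((node.parent.name, node.name))
    a, b = (top.children + [None, None])[:2]
    if a is not None and b is not None and not a.is_leaf and not b.is_leaf:
        edges.append((a.name, b.name))
    return edges


def _swap(tree: LineageTree, n1: Node, n2: Node) -> None:
    p1, p2 = n1.parent, n2.parent
    i1, i2 = p1.children.index(n1), p2.children.index(n2)
    p1.children[i1], p2.children[i2] = n2, n1
    n1.parent, n2.parent = p2, p1


def nni_neighbors(
    tree: LineageTree, edge: tuple[str, str]
) -> list[LineageTree]:
    """The two NNI rearrangements across an internal edge.

    Branch lengths travel with their subtrees unchanged; callers re-optimize
    them afterwards.
    """
    u_name, v_name = edge
    out = []
    for which in (0, 1):
        t = tree.copy()
        u, v = t.find(u_name), t.find(v_name)
        if u.is_leaf or v.is_leaf:
            raise ValidationError(f"edge {edge} is not internal")
        if v.parent is u and u.parent is not None and u.parent is not t.root:
            # regular internal edge: swap v's sibling with one child of v
            sib = next(c for c in u.children if c is not v)
            _swap(t, sib, v.children[which])
        elif u.parent is v.parent and u.parent.parent is t.root:
            # the edge through the root's child: swap across the two top clades
            _swap(t, u.children[1], v.children[which])
        else:
            raise ValidationError(f"edge {edge} is not an internal edge")
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# Annealing schedule
# ---------------------------------------------------------------------------

def annealing_schedule(
    t: int, delta_loglik: float, config: SearchConfig
) -> tuple[float, float]:
    """Temperature and acceptance probability at accepted-move count ``t``."""
    if t < 1:
        raise ValueError("t must be >= 1")
    a, c, eps = config.alpha, config.c, config.eps
    temp = max(eps, (a**t - a**c) / (1.0 - a**c))
    if delta_loglik > 0:
        return temp, 1.0
    p = min(1.0, np.exp(delta_loglik - eps) / temp)
    return temp, float(p)


# ---------------------------------------------------------------------------
# The search loop
# ---------------------------------------------------------------------------

def search(
    start_tree: LineageTree,
    matrix: CharacterMatrix,
    tau: float | None = None,
    em_config: EMConfig | None = None,
    config: SearchConfig | None = None,
    labels: dict[str, object] | None = None,
) -> tuple[LineageTree, PMMParams, float]:
    """NNI + simulated-annealing maximum-likelihood search.

    ``labels``, if given, are progenitor labels: moves that would break the
    monophyly of any labeled group are skipped.  Returns the best tree seen,
    its fitted parameters, and the final log-likelihood.
    """
    config = config or SearchConfig()
    em_config = em_config or EMConfig()
    rng = np.random.default_rng(config.seed)
    tree = start_tree.copy()
    tree.validate(binary=True)
    res = em_fit(tree, matrix, tau=tau, config=em_config)
    cur_ll, cur_params = res.loglik, res.params
    best_tree, best_params, best_ll = tree.copy(), cur_params.copy(), cur_ll

    t = 1
    while t <= config.t_max:
        moves = [
            (e, w) for e in internal_edges(tree) for w in (0, 1)
        ]
        order = rng.permutation(len(moves))
        accepted = False
        for mi in order:
            edge, which = moves[mi]
            cand = nni_neighbors(tree, edge)[which]
            if labels is not None and not _labels_monophyletic(cand, labels):
                continue
            try:
                cres = em_fit(cand, matrix, tau=tau, config=em_config)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"EM failed on proposal {cand.to_newick(lengths='none')}"
                ) from exc
            dll = cres.loglik - cur_ll
            temp, p = annealing_schedule(t, dll, config)
            if dll > 0 or rng.random() < p:
                logger.info("accept t=%d dll=%+.6f loglik=%.6f", t, dll, cres.loglik)
                tree, cur_ll, cur_params = cand, cres.loglik, cres.params
                if cur_ll > best_ll:
                    best_tree, best_params, best_ll = (
                        tree.copy(), cur_params.copy(), cur_ll,
                    )
                accepted = True
                improvement = dll
                break
        if not accepted:
            break                       # NNI neighborhood exhausted
        t += 1
        if 0 < improvement < config.eta:
            break                       # converged: improving but negligibly
    best_tree.set_deltas(best_params.delta)
    if best_params.lam:
        best_tree.times_from_deltas(best_params.lam)
    return best_tree, best_params, best_ll


def _labels_monophyletic(tree: LineageTree, labels: dict[str, object]) -> bool:
    from .progenitor import check_monophyly

    try:
        check_monophyly(tree, labels)
        return True
    except ValidationError:
        return False


def neighbor_joining_start(matrix: CharacterMatrix, seed: int | None = None) -> LineageTree:
    """Starting tree: neighbor joining on normalized Hamming distances.

    Distances ignore positions where either cell is missing; ties in the NJ
    criterion are broken deterministically by leaf-name order.
    """
    import itertools

    names = matrix.cell_names
    df = matrix.to_frame().to_numpy()
    n = len(names)
    D = np.zeros((n, n))
    from .data import MISSING

    for i, j in itertools.combinations(range(n), 2):
        ok = (df[i] != MISSING) & (df[j] != MISSING)
        if ok.sum() == 0:
            d = 1.0
        else:
            d = float((df[i][ok] != df[j][ok]).sum() / ok.sum())
        D[i, j] = D[j, i] = d
    nodes = [Node(name=nm) for nm in names]
    active = list(range(n))
    Dw = D.copy()
    while len(active) > 2:
        m = len(active)
        r = Dw[np.ix_(active, active)].sum(axis=1)
        best, pair = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * Dw[active[ai], active[aj]] - r[ai] - r[aj]
                if best is None or q < best - 1e-12:
                    best, pair = q, (ai, aj)
        ai, aj = pair
        i, j = active[ai], active[aj]
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        newD = 0.5 * (Dw[i, :] + Dw[j, :] - Dw[i, j])
        Dw = np.vstack([Dw, newD[None, :]])
        Dw = np.hstack([Dw, np.append(newD, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    top = Node()
    for a in active:
        top.add_child(nodes[a])
    if len(top.children) == 1:
        top = top.children[0]
        top.parent = None
    root = Node(name="root")
    root.add_child(top)
    return LineageTree(root)
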