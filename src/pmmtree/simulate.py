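"""Ground-truthed synthetic lineage-tracing data.

The generator mirrors a standard benchmark setup for dynamic lineage
tracing: a birth-only complete binary tree of 2^g leaves hangs beneath a
single root edge; every branch duration is i.i.d. lognormal with mean 1 and
standard deviation 0.1 *on the natural scale* (so tree height is about
g + 1 time units including the root edge).  Each of K target sites evolves
down the tree under the irreversible editing + silencing chain, dropout is
applied at the leaves, and the true cause of every "?" entry (heritable vs
dropout) is recorded.  The default editing rate lambda = 0.095 with 10
generations calibrates to roughly 64% edited entries among the non-missing
observations; the five named (nu, phi) conditions each produce about 25%
missing overall while varying the heritable/dropout split from 0/100 to
100/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, SILENT, CharacterMatrix, SiteAlphabet
from .tree import LineageTree, Node

#: Named (nu, phi) pairs: hXdY = X% of missing entries heritable, Y% dropout.
CONDITIONS: dict[str, tuple[float, float]] = {
    "h0d100": (0.0, 0.25),
    "h25d75": (0.065, 0.2),
    "h50d50": (0.134, 0.143),
    "h75d25": (0.208, 0.077),
    "h100d0": (0.288, 0.0),
}


@dataclass
class SimConfig:
    generations: int = 10               # 2^g leaves
    branch_time_mean: float = 1.0       # natural-scale lognormal mean
    branch_time_sd: float = 0.1
    K: int = 30
    lam: float = 0.095
    nu: float = 0.0
    phi: float = 0.0
    subsample_n: int = 250
    replicates: int = 1
    seed: int | None = None
    min_alphabet: int = 5               # default per-site outcome counts
    max_alphabet: int = 30

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("branch_time_mean", "branch_time_sd", "lam", "nu", "phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.subsample_n > 2**self.generations:
            raise ValueError("subsample_n exceeds the number of leaves")

    @classmethod
    def condition(cls, name: str, **kw) -> "SimConfig":
        nu, phi = CONDITIONS[name]
        return cls(nu=nu, phi=phi, **kw)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given natural-scale mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None) -> LineageTree:
    """Complete binary tree of 2^g leaves beneath a single root edge.

    Every branch (including the root edge) gets an i.i.d. lognormal duration.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mu, sigma = _lognormal_params(config.branch_time_mean, config.branch_time_sd)

    def draw() -> float:
        return float(rng.lognormal(mu, sigma))

    root = Node(name="root")
    counter = [0]

    def grow(depth: int) -> Node:
        if depth == config.generations:
            counter[0] += 1
            return Node(name=f"c{counter[0]}", time=draw())
        node = Node(time=draw())
        node.add_child(grow(depth + 1))
        node.add_child(grow(depth + 1))
        # re-parent properly (add_child already set parents)
        return node

    top = Node(time=draw())
    if config.generations >= 1:
        top.children = []
        top.add_child(grow(1))
        top.add_child(grow(1))
    root.add_child(top)
    tree = LineageTree(root)
    tree.deltas_from_times(config.lam)
    return tree


def default_priors(
    config: SimConfig, rng: np.random.Generator
) -> list[SiteAlphabet]:
    """Per-site alphabets: M ~ U{min..max} outcomes, Dirichlet(1) priors."""
    alphas = []
    for k in range(config.K):
        M = int(rng.integers(config.min_alphabet, config.max_alphabet + 1))
        q = rng.dirichlet(np.ones(M))
        alphas.append(
            SiteAlphabet(k, {m + 1: float(p) for m, p in enumerate(q)}, name=f"s{k}")
        )
    return alphas


def simulate_characters(
    tree: LineageTree,
    config: SimConfig,
    priors: list[SiteAlphabet] | None = None,
    rng: np.random.Generator | None = None,
    return_node_states: bool = False,
):
    """Simulate the editing chain down the tree and the dropout layer.

    Returns ``(latent, observed, causes)``: the latent leaf matrix over
    {0, 1..M, -1}, the observed matrix over {0, 1..M, ?}, and a frame
    ``causes`` holding 'heritable' or 'dropout' for each "?" entry (None
    elsewhere).  With ``return_node_states`` the per-node latent state
    arrays are returned as a fourth value.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if priors is None:
        priors = default_priors(config, rng)
    K = config.K
    nu = config.nu
    qcum = [np.cumsum([a.priors[s] for s in a.mutated_states]) for a in priors]
    states: dict[str, np.ndarray] = {tree.root.name: np.zeros(K, dtype=int)}
    # state encoding during simulation: 0, positive mutated, SILENT
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = states[node.parent.name]
        d = node.delta if node.delta is not None else config.lam * node.time
        keep = np.exp(-nu * d)
        stay0 = np.exp(-d)
        child = parent_state.copy()
        u = rng.random(K)
        silenced = u > keep                          # silencing hits any non-silent
        active0 = (parent_state == 0) & ~silenced
        mutate = active0 & (rng.random(K) > stay0)
        for k in np.nonzero(mutate)[0]:
            r = rng.random()
            child[k] = int(np.searchsorted(qcum[k], r) + 1)
        child[silenced & (parent_state != SILENT)] = SILENT
        child[parent_state == SILENT] = SILENT
        states[node.name] = child
    leaves = tree.leaf_names
    latent = pd.DataFrame(
        [states[l] for l in leaves], index=leaves,
        columns=[a.name or f"s{a.site_index}" for a in priors],
    )
    obs = latent.astype(object).copy()
    causes = pd.DataFrame(np.full(latent.shape, None), index=latent.index,
                          columns=latent.columns)
    drop = rng.random(latent.shape) < config.phi
    for i in range(latent.shape[0]):
        for k in range(K):
            if latent.iat[i, k] == SILENT:
                obs.iat[i, k] = MISSING
                causes.iat[i, k] = "heritable"
            elif drop[i, k]:
                obs.iat[i, k] = MISSING
                causes.iat[i, k] = "dropout"
    observed = CharacterMatrix(obs, priors)
    if return_node_states:
        return latent, observed, causes, states
    return latent, observed, causes


def expected_mutation_count(delta: float, nu: float, root_distance: float) -> float:
    """Expected number of fresh edits on an edge, per site.

    An edit lands on edge e only if the site is still unedited and unsilenced
    when it reaches the top of e (probability exp(-d(r,u)(1+nu)) at
    mutation-unit root distance d) and then leaves state 0 by editing rather
    than staying or only silencing.
    """
    if delta < 0 or nu < 0 or root_distance < 0:
        raise ValueError("inputs must be nonnegative")
    return float(
        (1.0 - np.exp(-delta * (1.0 + nu))) * np.exp(-root_distance * (1.0 + nu))
    )


def subsample(
    tree: LineageTree,
    matrices: tuple[pd.DataFrame, CharacterMatrix, pd.DataFrame],
    n: int,
    replicates: int = 1,
    seed: int | None = None,
) -> list[tuple[LineageTree, pd.DataFrame, CharacterMatrix, pd.DataFrame]]:
    """Uniform cell subsampling with matched tree restriction.

    Unary nodes created by the restriction are suppressed; their two incident
    edges merge with lengths adding, so all pairwise path lengths among kept
    leaves are preserved.
    """
    rng = np.random.default_rng(seed)
    leaves = tree.leaf_names
    if n > len(leaves):
        raise ValueError(f"cannot subsample {n} of {len(leaves)} cells")
    latent, observed, causes = matrices
    out = []
    for _ in range(replicates):
        keep = sorted(rng.choice(leaves, size=n, replace=False))
        rtree = tree.restrict(keep)
        out.append(
            (
                rtree,
                latent.loc[keep],
                observed.subset(keep),
                causes.loc[keep],
            )
        )
    return out


@dataclass
class SimulatedDataset:
    """One complete replicate: tree, matrices, causes, and the truth."""

    tree: LineageTree
    latent: pd.DataFrame
    observed: CharacterMatrix
    causes: pd.DataFrame
    config: SimConfig
    priors: list[SiteAlphabet] = field(default_factory=list)

    @property
    def missing_fraction(self) -> float:
        return self.observed.missing_fraction

    @property
    def mutated_fraction_nonmissing(self) -> float:
        """Fraction of edited entries among non-missing observations."""
        arr = self.observed.to_frame().to_numpy()
        obs = arr != MISSING
        return float(((arr != 0) & obs).sum() / obs.sum())

    @property
    def mutated_fraction_all(self) -> float:
        """Fraction of all entries observed in an edited state."""
        arr = self.observed.to_frame().to_numpy()
        return float(((arr != MISSING) & (arr != 0)).sum() / arr.size)


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Tree + characters in one call (no subsampling)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    priors = default_priors(config, rng)
    latent, observed, causes = simulate_characters(tree, config, priors, rng)
    return SimulatedDataset(tree, latent, observed, causes, config, priors)
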