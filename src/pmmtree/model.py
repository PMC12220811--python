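"""Model/results interface over the estimation machinery.

``PMMModel`` bundles a character matrix (and optionally a tree, the
experiment duration tau, indel priors, and progenitor labels); ``fit``
runs EM on a fixed topology or the full NNI + simulated-annealing search and
returns a ``PMMResults`` with the estimates, the fitted time-resolved tree,
diagnostics, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CharacterMatrix, PMMParams
from .em import EMConfig, em_fit
from .likelihood import log_likelihood
from .search import SearchConfig, neighbor_joining_start, search
from .tree import LineageTree


class PMMModel:
    """Mixed-type missing model of a lineage-tracing character matrix.

    Parameters
    ----------
    matrix
        Observed cells x sites character matrix.
    tree
        Starting (or fixed) topology; when None, a neighbor-joining tree on
        normalized Hamming distances is built at fit time.
    tau
        Total experiment time.  Required for branch lengths in time units;
        without it only mutation-unit lengths are identifiable.
    labels
        Optional progenitor labels (cell -> label or "?"); labeled groups
        are kept monophyletic during topology search.
    """

    def __init__(
        self,
        matrix: CharacterMatrix,
        tree: LineageTree | str | None = None,
        tau: float | None = None,
        labels: dict[str, object] | None = None,
    ):
        self.matrix = matrix
        if isinstance(tree, str):
            tree = LineageTree.from_newick(tree)
        self.tree = tree
        self.tau = tau
        self.labels = labels

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "PMMModel":
        return cls(CharacterMatrix(df), **kw)

    @classmethod
    def from_files(cls, matrix_path, tree_path=None, priors_path=None, **kw):
        from . import io as _io

        priors = _io.read_priors(priors_path) if priors_path else None
        matrix = _io.read_character_matrix(matrix_path, priors=priors)
        tree = _io.read_tree(tree_path) if tree_path else None
        return cls(matrix, tree=tree, **kw)

    def fit(
        self,
        search_topology: bool = False,
        em_config: EMConfig | None = None,
        search_config: SearchConfig | None = None,
        init: PMMParams | None = None,
        seed: int | None = None,
    ) -> "PMMResults":
        em_config = em_config or EMConfig(seed=seed)
        tree = self.tree
        if tree is None:
            tree = neighbor_joining_start(self.matrix, seed=seed)
        if search_topology:
            search_config = search_config or SearchConfig(seed=seed)
            best_tree, params, ll = search(
                tree, self.matrix, tau=self.tau, em_config=em_config,
                config=search_config, labels=self.labels,
            )
            return PMMResults(self, best_tree, params, ll, n_iter=None,
                              converged=True)
        tree = tree.copy()
        res = em_fit(tree, self.matrix, tau=self.tau, config=em_config, init=init)
        return PMMResults(self, tree, res.params, res.loglik, res.n_iter,
                          res.converged, trace=res.trace)

    def loglike(self, tree: LineageTree, params: PMMParams) -> float:
        return log_likelihood(tree, params, self.matrix)


@dataclass
class PMMResults:
    """Fit results: parameter estimates, fitted tree, diagnostics."""

    model: PMMModel
    tree: LineageTree
    params: PMMParams
    loglik: float
    n_iter: int | None
    converged: bool
    trace: list[float] = field(default_factory=list)

    @property
    def lam(self):
        return self.params.lam

    @property
    def nu(self):
        return self.params.nu

    @property
    def phi(self):
        return self.params.phi

    def posterior_states(self):
        from .impute import posterior_states

        return posterior_states(self.tree, self.params, self.model.matrix)

    def impute(self, threshold: float = 0.5):
        from .impute import impute

        return impute(self.model.matrix, self.posterior_states(), threshold)

    def to_newick(self, lengths: str = "time") -> str:
        return self.tree.to_newick(lengths=lengths)

    def summary(self) -> str:
        m = self.model.matrix
        deltas = np.array(list(self.params.delta.values()))
        lines = [
            "Mixed-type missing lineage model",
            "=" * 48,
            f"Cells: {m.n_cells}    Sites: {m.n_sites}    "
            f"Missing: {100 * m.missing_fraction:.1f}%",
            f"Log-likelihood: {self.loglik:.4f}",
            f"EM iterations:  {self.n_iter if self.n_iter is not None else '-'}"
            f"    converged: {self.converged}",
            "-" * 48,
            f"editing rate lambda : "
            + (f"{self.lam:.6g}" if self.lam is not None else "(needs tau)"),
            f"silencing rate nu   : {self.nu:.6g}",
            f"dropout prob phi    : {self.phi:.6g}",
            f"branch delta range  : [{deltas.min():.4g}, {deltas.max():.4g}]",
        ]
        if self.params.tau is not None and self.lam:
            lines.append(
                f"tree height         : {self.lam * self.params.tau:.4g} "
                f"mutation units over tau = {self.params.tau:g}"
            )
        return "\n".join(lines)
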