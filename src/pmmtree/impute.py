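"""Posterior decoding on a fitted tree: ancestral states and imputation.

Every "?" entry of the observed matrix has two possible explanations: the
site was heritably silenced somewhere on the path from the root (latent state
-1) or it dropped out at sequencing.  Given fitted parameters, the marginal
posterior of the latent leaf state separates the two: an entry is called
heritable when P(X = -1 | D) exceeds 0.5, dropout otherwise (ties go to
dropout), and dropout entries are imputed with the most probable non-silent
state.  Internal nodes get per-site marginal MAP states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, SILENT, CharacterMatrix, PMMParams
from .likelihood import PruningContext
from .tree import LineageTree

HERITABLE = "heritable"
DROPOUT = "dropout"


@dataclass
class PosteriorTable:
    """Per-(node, site) posterior distributions over {0, 1..M, -1}."""

    node_names: list[str]
    site_names: list[str]
    _post: np.ndarray                   # (n_nodes, K, S) in slot layout
    _ctx: PruningContext

    def get(self, node: str, site: str | int) -> dict[int, float]:
        i = self.node_names.index(node)
        k = site if isinstance(site, int) else self.site_names.index(site)
        row = self._post[i, k]
        out = {0: float(row[0])}
        for slot, state in self._ctx.slot_to_state[k].items():
            out[state] = float(row[slot])
        out[SILENT] = float(row[-1])
        return out

    def silent_probability(self, node: str, site: str | int) -> float:
        i = self.node_names.index(node)
        k = site if isinstance(site, int) else self.site_names.index(site)
        return float(self._post[i, k, -1])

    def map_state(self, node: str, site: str | int, exclude_silent: bool = False) -> int:
        dist = self.get(node, site)
        if exclude_silent:
            dist = {s: p for s, p in dist.items() if s != SILENT}
        # deterministic tie-break: smallest state among maxima
        best = max(dist.values())
        return min(s for s, p in dist.items() if p >= best - 1e-15)


def posterior_states(
    tree: LineageTree, params: PMMParams, matrix: CharacterMatrix
) -> PosteriorTable:
    """Marginal posteriors for every node and site by an up/down pass."""
    ctx = PruningContext(tree, matrix)
    up, logn, msg, site_ll = ctx.up_pass(params)
    down, _ = ctx.down_pass(params, up, msg)
    post = ctx.node_posteriors(up, down)
    return PosteriorTable(
        node_names=[n.name for n in ctx.nodes],
        site_names=matrix.site_names,
        _post=post,
        _ctx=ctx,
    )


def impute(
    matrix: CharacterMatrix,
    posteriors: PosteriorTable,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Impute "?" entries and classify their cause.

    Returns ``(imputed_matrix, calls, ancestral)`` where ``calls`` has one
    row per missing entry (cell, site, call, p_heritable, imputed_state) and
    ``ancestral`` holds marginal MAP states for every internal node.
    """
    df = matrix.to_frame()
    records = []
    for cell in matrix.cell_names:
        for k, site in enumerate(matrix.site_names):
            if df.loc[cell, site] != MISSING:
                continue
            p_sil = posteriors.silent_probability(cell, k)
            if p_sil > threshold:
                call, state = HERITABLE, SILENT
            else:
                call = DROPOUT
                state = posteriors.map_state(cell, k, exclude_silent=True)
            df.loc[cell, site] = state
            records.append(
                {"cell": cell, "site": site, "call": call,
                 "p_heritable": p_sil, "imputed_state": state}
            )
    calls = pd.DataFrame(
        records, columns=["cell", "site", "call", "p_heritable", "imputed_state"]
    )
    leaves = set(n for n in matrix.cell_names)
    internal = [n for n in posteriors.node_names if n not in leaves]
    anc = pd.DataFrame(
        {
            site: [posteriors.map_state(n, k) for n in internal]
            for k, site in enumerate(matrix.site_names)
        },
        index=internal,
    )
    # imputed matrix may contain -1 entries (heritable); keep as plain frame
    return df, calls, anc
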