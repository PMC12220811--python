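"""Readers and writers for matrices, priors, labels, trees, and parameters."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .data import MISSING, CharacterMatrix, PMMParams, SiteAlphabet
from .tree import LineageTree


def read_character_matrix(
    path: str | Path,
    priors: dict[str, dict[int, float]] | None = None,
    dedup: bool = False,
    sep: str | None = None,
):
    """Load a CSV/TSV character matrix: first column cell names, rest sites.

    Missing tokens "?", "-" and blank are normalized to "?".  With ``dedup``
    the return value is ``(matrix, mapping)`` where mapping sends each
    dropped duplicate cell to the kept representative.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    alphabets = None
    if priors is not None:
        alphabets = []
        for j, site in enumerate(df.columns):
            observed = sorted(
                {int(v) for v in df.iloc[:, j]
                 if v.strip() not in ("?", "-", "") and int(v) > 0}
            )
            site_priors = priors.get(str(site))
            if site_priors is None:
                alphabets.append(SiteAlphabet.uniform(j, observed, name=str(site)))
            else:
                alphabets.append(
                    SiteAlphabet.from_priors(j, site_priors, observed, name=str(site))
                )
    matrix = CharacterMatrix(df, alphabets)
    if dedup:
        return matrix.dedup()
    return matrix


def read_priors(path: str | Path) -> dict[str, dict[int, float]]:
    """JSON priors: {site name: {state: probability}}."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        str(site): {int(s): float(p) for s, p in table.items()}
        for site, table in raw.items()
    }


def read_labels(path: str | Path, sep: str = ",") -> dict[str, object]:
    """Two-column CSV (cell, label-or-"?")."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValueError(f"expected two columns in {path}, got {df.shape[1]}")
    out = {}
    for _, (cell, label) in df.iterrows():
        label = label.strip()
        out[str(cell)] = MISSING if label in ("?", "-", "") else label
    return out


def read_tree(path: str | Path) -> LineageTree:
    return LineageTree.from_newick(Path(path).read_text())


def write_tree(
    tree: LineageTree, path: str | Path, lengths: str = "time"
) -> None:
    Path(path).write_text(tree.to_newick(lengths=lengths) + "\n")


def write_params(params: PMMParams, path: str | Path, loglik=None, iterations=None):
    out = {
        "lambda": params.lam,
        "nu": params.nu,
        "phi": params.phi,
        "tau": params.tau,
    }
    if loglik is not None:
        out["loglik"] = loglik
    if iterations is not None:
        out["iterations"] = iterations
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep)
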