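"""Core data containers: per-site alphabets and the observed character matrix.

A lineage-tracing experiment reads out, for each of N cells, the edit state of
K engineered target sites.  Each site k has its own alphabet: the unedited
state 0, a set of mutated states 1..M(k) with prior outcome probabilities
q(k)_m (the "indel priors"), a latent silent state -1 (heritable missing), and
the observed missing token "?".  Silent is never observed directly: after
sequencing it surfaces as "?", indistinguishable from dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel used internally for the observed missing state "?".
MISSING = "?"

#: Latent silent state (heritable missing before sequencing).
SILENT = -1


class ValidationError(ValueError):
    """Raised when a container violates its model invariants."""


@dataclass(frozen=True)
class SiteAlphabet:
    """Alphabet of one target site.

    Parameters
    ----------
    site_index
        Position (or name-derived index) of the site.
    priors
        Mapping mutated state (positive int) -> prior probability q_m.
        Must sum to one; all entries strictly positive.
    """

    site_index: int
    priors: Mapping[int, float]
    name: str = ""

    def __post_init__(self) -> None:
        states = list(self.priors)
        if not states:
            raise ValidationError(f"site {self.site_index}: empty alphabet")
        for s in states:
            if not isinstance(s, (int, np.integer)) or s <= 0:
                raise ValidationError(
                    f"site {self.site_index}: mutated states must be positive "
                    f"integers, got {s!r}"
                )
        probs = np.asarray([self.priors[s] for s in states], dtype=float)
        if np.any(probs <= 0):
            raise ValidationError(f"site {self.site_index}: priors must be > 0")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"site {self.site_index}: priors sum to {probs.sum():.12g}, "
                "expected 1"
            )
        object.__setattr__(self, "priors", dict(sorted(self.priors.items())))

    @property
    def mutated_states(self) -> tuple[int, ...]:
        return tuple(self.priors)

    @property
    def n_mutated(self) -> int:
        return len(self.priors)

    @classmethod
    def uniform(cls, site_index: int, states: Iterable[int], name: str = "") -> "SiteAlphabet":
        states = sorted(set(int(s) for s in states))
        if not states:
            # a column with no observed edits still needs one possible outcome
            states = [1]
        p = 1.0 / len(states)
        return cls(site_index, {s: p for s in states}, name=name)

    @classmethod
    def from_priors(
        cls,
        site_index: int,
        priors: Mapping[int, float],
        observed: Iterable[int] = (),
        name: str = "",
        pseudo_mass: float = 1e-6,
    ) -> "SiteAlphabet":
        """Build an alphabet as the union of prior-listed and observed states.

        Observed states absent from the priors share a small pseudo-mass so
        the likelihood stays finite; the listed priors are rescaled to keep
        the total at one.
        """
        observed = sorted(set(int(s) for s in observed))
        extra = [s for s in observed if s not in priors]
        if not extra:
            total = sum(priors.values())
            return cls(site_index, {s: p / total for s, p in priors.items()}, name=name)
        import warnings

        warnings.warn(
            f"site {name or site_index}: observed state(s) {extra} missing "
            f"from priors; assigning uniform share of {pseudo_mass} pseudo-mass",
            stacklevel=2,
        )
        scale = (1.0 - pseudo_mass) / sum(priors.values())
        full = {s: p * scale for s, p in priors.items()}
        for s in extra:
            full[s] = pseudo_mass / len(extra)
        return cls(site_index, full, name=name)


class CharacterMatrix:
    """Observed N x K character matrix over per-site alphabets.

    Entries are integers (0 = unedited, positive = mutated) or the missing
    token ``"?"``.  The latent silent state -1 never appears in an observed
    matrix.
    """

    def __init__(
        self,
        entries: pd.DataFrame,
        alphabets: Sequence[SiteAlphabet] | None = None,
    ) -> None:
        df = entries.copy()
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate cell names: {dupes[:5]}")
        values = np.full(df.shape, MISSING, dtype=object)
        raw = df.to_numpy()
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                v = raw[i, j]
                values[i, j] = _normalize_entry(v, df.index[i], df.columns[j])
        self._df = pd.DataFrame(values, index=df.index, columns=df.columns)
        if alphabets is None:
            alphabets = [
                SiteAlphabet.uniform(j, self.observed_states(j), name=str(c))
                for j, c in enumerate(df.columns)
            ]
        if len(alphabets) != df.shape[1]:
            raise ValidationError(
                f"{len(alphabets)} alphabets for {df.shape[1]} sites"
            )
        self.alphabets = list(alphabets)
        for j, alpha in enumerate(self.alphabets):
            bad = set(self.observed_states(j)) - set(alpha.mutated_states)
            if bad:
                raise ValidationError(
                    f"site {self._df.columns[j]}: observed state(s) {sorted(bad)} "
                    "not in alphabet"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def cell_names(self) -> list[str]:
        return list(self._df.index)

    @property
    def site_names(self) -> list[str]:
        return [str(c) for c in self._df.columns]

    @property
    def n_cells(self) -> int:
        return self._df.shape[0]

    @property
    def n_sites(self) -> int:
        return self._df.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def __getitem__(self, cell: str) -> pd.Series:
        return self._df.loc[cell]

    def entry(self, cell: str, site: str | int):
        if isinstance(site, int):
            return self._df.iloc[:, site].loc[cell]
        return self._df.loc[cell, site]

    def column(self, site: str | int) -> pd.Series:
        if isinstance(site, int):
            return self._df.iloc[:, site]
        return self._df[site]

    def observed_states(self, site: int) -> list[int]:
        col = self._df.iloc[:, site]
        return sorted({int(v) for v in col if v != MISSING and int(v) > 0})

    @property
    def n_missing(self) -> int:
        return int((self._df.to_numpy() == MISSING).sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / (self.n_cells * self.n_sites)

    def subset(self, cells: Sequence[str]) -> "CharacterMatrix":
        return CharacterMatrix(self._df.loc[list(cells)], self.alphabets)

    def single_site(self, site: str | int) -> "CharacterMatrix":
        j = site if isinstance(site, int) else self.site_names.index(site)
        return CharacterMatrix(self._df.iloc[:, [j]], [self.alphabets[j]])

    def dedup(self) -> tuple["CharacterMatrix", dict[str, str]]:
        """Drop duplicate rows; returns (matrix, dropped-cell -> kept-cell)."""
        key = self._df.astype(str).agg("|".join, axis=1)
        keep_for = {}
        keep_rows = []
        mapping: dict[str, str] = {}
        for cell, k in key.items():
            if k in keep_for:
                mapping[cell] = keep_for[k]
            else:
                keep_for[k] = cell
                keep_rows.append(cell)
        return self.subset(keep_rows), mapping

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CharacterMatrix({self.n_cells} cells x {self.n_sites} sites)"


def _normalize_entry(v, cell, site):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return MISSING
    if isinstance(v, str):
        v = v.strip()
        if v in ("?", "-", ""):
            return MISSING
        try:
            v = int(v)
        except ValueError:
            raise ValidationError(
                f"cell {cell!r}, site {site!r}: non-integer state {v!r}"
            ) from None
    if isinstance(v, (float, np.floating)):
        if v != int(v):
            raise ValidationError(
                f"cell {cell!r}, site {site!r}: non-integer state {v!r}"
            )
        v = int(v)
    v = int(v)
    if v < 0:
        raise ValidationError(
            f"cell {cell!r}, site {site!r}: negative observed state {v} "
            "(silent is latent-only)"
        )
    return v


@dataclass
class PMMParams:
    """Parameters of the mixed-type missing model.

    delta maps each edge (identified by its child-node name) to its length in
    mutation units; lam is the editing rate, nu the heritable silencing rate,
    phi the per-entry dropout probability, tau the experiment duration.
    """

    delta: dict[str, float] = field(default_factory=dict)
    lam: float | None = None
    nu: float = 0.0
    phi: float = 0.0
    tau: float | None = None

    def validate(self) -> None:
        if self.lam is not None and self.lam <= 0:
            raise ValidationError(f"lam must be > 0, got {self.lam}")
        if self.nu < 0:
            raise ValidationError(f"nu must be >= 0, got {self.nu}")
        if not (0.0 <= self.phi < 1.0):
            raise ValidationError(f"phi must be in [0, 1), got {self.phi}")
        if self.tau is not None and self.tau <= 0:
            raise ValidationError(f"tau must be > 0, got {self.tau}")
        for e, d in self.delta.items():
            if d < 0:
                raise ValidationError(f"edge {e}: delta must be >= 0, got {d}")

    def copy(self) -> "PMMParams":
        return PMMParams(dict(self.delta), self.lam, self.nu, self.phi, self.tau)
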