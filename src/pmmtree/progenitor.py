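"""Multi-progenitor extension: joint likelihood of characters and labels.

When the experiment starts from several founder cells, each sequenced cell
carries a progenitor label (or "?" when the label was not recovered).  The
label behaves like one extra character whose layer-1 chain has no editing --
labels are fixed at the start and strictly heritable -- but shares the
silencing rate nu and, in layer 2, the dropout probability phi with the
ordinary target sites.  The joint log-likelihood is therefore the character
log-likelihood plus one extra pruning pass over the label column with a
uniform root prior over the observed labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MISSING, CharacterMatrix, PMMParams, ValidationError
from .tree import LineageTree


@dataclass
class ProgenitorLabels:
    """Per-cell progenitor label; "?" marks a missing label."""

    labels: dict[str, object]

    @property
    def active(self) -> bool:
        """The extension only constrains anything once some label is known."""
        return bool(self.observed_labels())

    def observed_labels(self) -> list:
        return sorted({v for v in self.labels.values() if v != MISSING}, key=str)

    def __getitem__(self, cell: str):
        return self.labels[cell]

    def cells_with(self, label) -> list[str]:
        return [c for c, v in self.labels.items() if v == label]


def label_log_likelihood(
    tree: LineageTree, params: PMMParams, labels: ProgenitorLabels
) -> float:
    """Likelihood of the progenitor-label character.

    Labels are immutable, so each founder clade -- the minimal clade covering
    one observed label, or a maximal clade of entirely unlabeled cells -- is
    seeded with a founder label drawn uniformly from the observed labels plus
    one spare slot for never-recovered founders.  Within a clade the label
    then evolves under the shared silencing chain (it survives an edge of
    length delta with probability exp(-nu*delta)) and the shared dropout
    layer at the leaves: an observed label is read with probability 1-phi,
    "?" with probability phi, and a silenced label always reads "?".
    """
    check_monophyly(tree, labels.labels)
    obs = labels.observed_labels()
    n_slots = len(obs) + 1                        # observed labels + spare
    nu, phi = params.nu, params.phi
    clades = _founder_clades(tree, labels)
    total = 0.0
    for top_node, label in clades:
        total += np.log(1.0 / n_slots)            # founder label prior
        # two latent states within the clade: label alive, label silenced
        def up(node) -> np.ndarray:
            if node.is_leaf:
                v = labels.labels.get(node.name, MISSING)
                if v == MISSING:
                    return np.array([phi, 1.0])
                if label is not None and v != label:
                    return np.array([0.0, 0.0])   # unreachable under monophyly
                return np.array([1.0 - phi, 0.0])
            out = np.ones(2)
            for c in node.children:
                U = up(c)
                keep = np.exp(-nu * params.delta[c.name])
                out *= np.array([keep * U[0] + (1 - keep) * U[1], U[1]])
            return out

        val = up(top_node)[0]                     # founder starts alive
        if val <= 0:
            raise ValidationError(
                f"progenitor labels have zero likelihood in clade of {label!r}"
            )
        total += np.log(val)
    return float(total)


def _founder_clades(tree: LineageTree, labels: ProgenitorLabels):
    """(clade root node, founder label or None) for each founder clade."""
    by_label = {}
    for label in labels.observed_labels():
        cells = labels.cells_with(label)
        cells = [c for c in cells if c in set(tree.leaf_names)]
        by_label[label] = _lca(tree, cells) if len(cells) > 1 else tree.find(cells[0])
    covered: set[str] = set()
    clades = []
    for label, node in by_label.items():
        clades.append((node, label))
        covered |= {l.name for l in LineageTree(node).leaves()}

    def walk(node):
        names = [l.name for l in LineageTree(node).leaves()]
        if not any(n in covered for n in names):
            clades.append((node, None))           # unlabeled founder clade
            return
        if node.is_leaf:
            return
        for c in node.children:
            if {l.name for l in LineageTree(c).leaves()} <= covered:
                continue
            walk(c)

    walk(tree.root.children[0])
    return clades


def joint_log_likelihood(
    tree: LineageTree,
    params: PMMParams,
    matrix: CharacterMatrix,
    labels: ProgenitorLabels,
) -> float:
    """log P(D) + log P(s): characters plus the label pseudo-site."""
    from .likelihood import log_likelihood

    check_monophyly(tree, labels.labels)
    return log_likelihood(tree, params, matrix) + label_log_likelihood(
        tree, params, labels
    )


def check_monophyly(tree: LineageTree, labels: dict[str, object]) -> None:
    """Raise (naming a violating triplet) unless each label is monophyletic.

    Cells with "?" labels are unconstrained: a clade counts as monophyletic
    for a label if every *labeled* cell under the label's LCA has that label.
    """
    leaf_set = {l.name for l in tree.leaves()}
    by_label: dict[object, list[str]] = {}
    for cell, v in labels.items():
        if v != MISSING and cell in leaf_set:
            by_label.setdefault(v, []).append(cell)
    for label, cells in by_label.items():
        if len(cells) < 2:
            continue
        lca = _lca(tree, cells)
        under = {l.name for l in LineageTree(lca).leaves()}
        for intruder in sorted(under):
            v = labels.get(intruder, MISSING)
            if v != MISSING and v != label:
                raise ValidationError(
                    f"labels not monophyletic: cells ({cells[0]!r}, {cells[1]!r}) "
                    f"of label {label!r} bracket {intruder!r} of label {v!r}"
                )


def _lca(tree: LineageTree, cells: list[str]):
    paths = []
    for c in cells:
        node = tree.find(c)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(list(reversed(path)))
    lca = None
    for level in zip(*paths):
        if all(n is level[0] for n in level):
            lca = level[0]
        else:
            break
    return lca


def infer_progenitor_structure(
    tree: LineageTree,
    params: PMMParams,
    matrix: CharacterMatrix,
    labels: ProgenitorLabels,
) -> tuple[dict[str, object], list[list[str]]]:
    """Impute missing labels and report unlabeled founder clades.

    A "?"-labeled cell inside a labeled clade inherits that clade's label
    (its missing label is explained by dropout).  Maximal clades consisting
    solely of "?"-labeled cells that sit outside every labeled clade are
    reported as missing-label progenitors: groups descending from a founder
    whose label was never recovered.
    """
    check_monophyly(tree, labels.labels)
    imputed = dict(labels.labels)
    labeled_clades: dict[object, set[str]] = {}
    for label in labels.observed_labels():
        cells = labels.cells_with(label)
        lca = _lca(tree, cells) if len(cells) > 1 else tree.find(cells[0])
        under = {l.name for l in LineageTree(lca).leaves()}
        labeled_clades[label] = under
        for cell in under:
            if imputed.get(cell, MISSING) == MISSING:
                imputed[cell] = label
    covered = set().union(*labeled_clades.values())
    discoveries: list[list[str]] = []

    def walk(node):
        leaves_under = [l.name for l in LineageTree(node).leaves()]
        if not any(l in covered for l in leaves_under):
            discoveries.append(sorted(leaves_under))
            return
        for c in node.children:
            if not c.is_leaf:
                walk(c)
            elif c.name not in covered:
                discoveries.append([c.name])

    walk(tree.root.children[0])
    return imputed, discoveries
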