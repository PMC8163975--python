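"""Aggregate per-complex contacts into the reference-numbered interaction matrix.

Each cell relates one GTPase residue (row, reference numbering such as
HRAS "E37") to one effector residue (column, CRAF/RASSF5 numbering) and
counts the number of analyzed complex structures in which that residue
pair is in contact.  A complex contributes at most 1 to any cell no
matter how many atom pairs qualify; every crystallographically
independent copy counts as its own complex, so cell values range from 0
to the number of complexes.

A residue "hotspot" is a residue on either axis that touches the partner
chain in at least ``min_support`` complexes (support counts complexes,
not partner residues).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .alignment import ConservationLabel, ReferenceLabel
from .structure import ResidueContact, ResidueRef

__all__ = [
    "InteractionMatrix",
    "HotspotCall",
    "build_matrix",
    "hotspot_cells",
    "hotspot_residues",
    "default_min_support",
]


@dataclass(frozen=True)
class InteractionMatrix:
    """Reference-labeled GTPase x effector grid of contact support counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: pd.DataFrame                       # int cells, index/columns = labels
    support: Mapping[tuple[str, str], tuple[str, ...]]  # cell -> complex ids
    n_complexes: int
    unmapped_contacts: Mapping[str, int] = field(default_factory=dict)

    def value(self, row: str, col: str) -> int:
        return int(self.values.at[row, col])

    def total(self) -> int:
        return int(self.values.to_numpy().sum())

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        payload = {
            "n_complexes": self.n_complexes,
            "rows": list(self.row_labels),
            "columns": list(self.col_labels),
            "cells": [
                {
                    "row": r,
                    "column": c,
                    "value": self.value(r, c),
                    "complexes": list(self.support.get((r, c), ())),
                }
                for r in self.row_labels
                for c in self.col_labels
                if self.value(r, c) > 0
            ],
            "unmapped_contacts": dict(self.unmapped_contacts),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass(frozen=True)
class HotspotCall:
    """A residue in contact with the partner in >= min_support complexes."""

    axis: str                 # "gtpase" | "effector"
    label: str
    support: int
    conservation: str = "unknown"


def default_min_support(n_complexes: int) -> int:
    """Majority-of-complexes hotspot threshold: ceil(n/2)."""
    return max(1, math.ceil(0.5 * n_complexes))


def build_matrix(
    contacts_per_complex: Mapping[str, Iterable[ResidueContact]],
    gtpase_maps: Mapping[str, Mapping[ResidueRef, int]],
    effector_maps: Mapping[str, Mapping[ResidueRef, int]],
    gtpase_labels: ReferenceLabel,
    effector_labels: ReferenceLabel,
) -> InteractionMatrix:
    """Project contacts through alignment maps and count per-cell support.

    Parameters
    ----------
    contacts_per_complex :
        complex_id -> contact set from :func:`raseff.structure.extract_contacts`.
    gtpase_maps, effector_maps :
        complex_id -> (structure residue -> alignment column) for the
        GTPase and effector chains respectively.
    gtpase_labels, effector_labels :
        Column labels in reference numbering for the two alignments.

    Contacts whose residues are absent from the maps (unmapped structure
    residues) are excluded from the grid and tallied per complex in
    ``unmapped_contacts``.
    """
    row_labels = tuple(gtpase_labels.labels)
    col_labels = tuple(effector_labels.labels)
    values = pd.DataFrame(
        0, index=list(row_labels), columns=list(col_labels), dtype=int
    )
    support: dict[tuple[str, str], list[str]] = {}
    unmapped: dict[str, int] = {}

    for complex_id in sorted(contacts_per_complex):
        try:
            gmap = gtpase_maps[complex_id]
            emap = effector_maps[complex_id]
        except KeyError as exc:
            raise ValueError(
                f"no residue-column map for complex {complex_id!r}"
            ) from exc
        cells: set[tuple[str, str]] = set()
        n_unmapped = 0
        for contact in contacts_per_complex[complex_id]:
            gcol = gmap.get(contact.gtpase_residue)
            ecol = emap.get(contact.effector_residue)
            if gcol is None or ecol is None:
                n_unmapped += 1
                continue
            cells.add((row_labels[gcol], col_labels[ecol]))
        for r, c in cells:       # binarized per complex
            values.at[r, c] += 1
            support.setdefault((r, c), []).append(complex_id)
        if n_unmapped:
            unmapped[complex_id] = n_unmapped

    return InteractionMatrix(
        row_labels=row_labels,
        col_labels=col_labels,
        values=values,
        support={k: tuple(v) for k, v in support.items()},
        n_complexes=len(contacts_per_complex),
        unmapped_contacts=unmapped,
    )


def hotspot_cells(matrix: InteractionMatrix,
                  min_support: int) -> list[tuple[str, str, int]]:
    """Cells with value >= min_support, sorted by value desc then labels."""
    if not 1 <= min_support <= max(1, matrix.n_complexes):
        raise ValueError(
            f"min_support must be in [1, {matrix.n_complexes}], got {min_support}"
        )
    out = [
        (r, c, matrix.value(r, c))
        for r in matrix.row_labels
        for c in matrix.col_labels
        if matrix.value(r, c) >= min_support
    ]
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def hotspot_residues(
    matrix: InteractionMatrix,
    axis: str,
    min_support: int,
    conservation: ConservationLabel | None = None,
) -> list[HotspotCall]:
    """Residues on one axis contacting the partner in >= min_support complexes.

    A residue's support is the number of distinct complexes in which it
    has at least one contact, not the sum over its cells: a residue that
    touches three partner residues within one complex has support 1.
    """
    if axis not in ("gtpase", "effector"):
        raise ValueError(f"axis must be 'gtpase' or 'effector', got {axis!r}")
    if not 1 <= min_support <= max(1, matrix.n_complexes):
        raise ValueError(
            f"min_support must be in [1, {matrix.n_complexes}], got {min_support}"
        )
    labels = matrix.row_labels if axis == "gtpase" else matrix.col_labels
    per_residue: dict[str, set[str]] = {lab: set() for lab in labels}
    for (r, c), complexes in matrix.support.items():
        lab = r if axis == "gtpase" else c
        per_residue[lab].update(complexes)

    calls = []
    for i, lab in enumerate(labels):
        sup = len(per_residue[lab])
        if sup >= min_support:
            cons = conservation[i] if conservation is not None else "unknown"
            calls.append(
                HotspotCall(axis=axis, label=lab, support=sup, conservation=cons)
            )
    calls.sort(key=lambda h: (-h.support, h.label))
    return calls
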