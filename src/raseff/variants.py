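"""Hotspot residue-swap design between effector domains.

Given an effector-family alignment, a donor row, an acceptor row and the
set of hotspot columns, propose the substitutions that transplant the
donor's hotspot residues onto the acceptor (e.g. turning RASSF2 toward
RASSF1, or RASSF9 toward RASSF5).  Positions are reported in the
acceptor construct's own numbering via a per-construct offset, matching
the mixed numbering frames used for such variants (RASSF9 variants in
the 40s, RASSF2 variants in the 180s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import Alignment

__all__ = [
    "Substitution",
    "VariantProposal",
    "propose_swap",
    "format_variant",
    "apply_proposal",
]


@dataclass(frozen=True)
class Substitution:
    """One residue swap in acceptor construct numbering."""

    position: int
    acceptor_aa: str
    donor_aa: str

    def __post_init__(self):
        if self.acceptor_aa == self.donor_aa:
            raise ValueError(f"no-op substitution at {self.position}")

    def __str__(self) -> str:
        return f"{self.acceptor_aa}{self.position}{self.donor_aa}"


@dataclass(frozen=True)
class VariantProposal:
    """Ordered substitutions converting an acceptor toward a donor."""

    donor: str
    acceptor: str
    substitutions: tuple[Substitution, ...]
    numbering_offset: int
    unswappable_columns: tuple[int, ...] = ()

    def __post_init__(self):
        positions = [s.position for s in self.substitutions]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(
                f"substitution positions must be strictly increasing: {positions}"
            )


def propose_swap(
    alignment: Alignment,
    donor: str,
    acceptor: str,
    hotspot_columns: set[int],
    numbering_offset: int = 0,
) -> VariantProposal:
    """Substitutions at hotspot columns where donor and acceptor differ.

    Columns where the two rows agree are omitted; columns where either
    row carries a gap cannot be expressed as a point substitution and
    are reported in ``unswappable_columns``.  The construct position of
    an alignment column is the count of non-gap acceptor residues up to
    and including that column, plus ``numbering_offset``.
    """
    if donor == acceptor:
        raise ValueError("donor and acceptor rows must differ")
    donor_seq = alignment.row(donor)
    acceptor_seq = alignment.row(acceptor)
    bad = [c for c in hotspot_columns if not 0 <= c < alignment.width]
    if bad:
        raise ValueError(f"hotspot columns out of range: {sorted(bad)}")

    # acceptor construct position per column (1-based over non-gap residues)
    gap = {"-", "."}
    acc_pos = []
    n = 0
    for ch in acceptor_seq:
        if ch not in gap:
            n += 1
        acc_pos.append(n)

    subs = []
    unswappable = []
    for col in sorted(hotspot_columns):
        a, d = acceptor_seq[col], donor_seq[col]
        if a in gap or d in gap:
            unswappable.append(col)
            continue
        if a == d:
            continue
        subs.append(
            Substitution(
                position=acc_pos[col] + numbering_offset,
                acceptor_aa=a,
                donor_aa=d,
            )
        )
    positions = [s.position for s in subs]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate substitution positions: {dupes}")
    return VariantProposal(
        donor=donor,
        acceptor=acceptor,
        substitutions=tuple(subs),
        numbering_offset=numbering_offset,
        unswappable_columns=tuple(unswappable),
    )


def format_variant(proposal: VariantProposal) -> str:
    """Render as slash-joined tokens, e.g. "V40D/G42I/L43K/K45L/R46H".

    An empty proposal renders as "wild-type".
    """
    if not proposal.substitutions:
        return "wild-type"
    return "/".join(str(s) for s in proposal.substitutions)


def apply_proposal(alignment: Alignment, proposal: VariantProposal) -> str:
    """Acceptor row (gapped) with the proposed substitutions applied."""
    gap = {"-", "."}
    seq = list(alignment.row(proposal.acceptor))
    by_pos = {s.position: s for s in proposal.substitutions}
    n = 0
    for i, ch in enumerate(seq):
        if ch in gap:
            continue
        n += 1
        sub = by_pos.pop(n + proposal.numbering_offset, None)
        if sub is not None:
            if ch != sub.acceptor_aa:
                raise ValueError(
                    f"acceptor residue mismatch at {sub.position}: "
                    f"expected {sub.acceptor_aa}, found {ch}"
                )
            seq[i] = sub.donor_aa
    if by_pos:
        raise ValueError(
            f"positions beyond acceptor length: {sorted(by_pos)}"
        )
    return "".join(seq)
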