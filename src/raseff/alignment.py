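"""Map structure residues to alignment columns; reference numbering; conservation.

Curated multiple sequence alignments (one for the GTPase family, one per
effector-domain family) are consumed, never computed.  A designated
reference row (HRAS for the GTPase side; CRAF for RB domains, RASSF5 for
RA domains) provides the residue numbering used on the matrix axes, e.g.
"E37" means glutamate 37 in HRAS coordinates.

Structure chains are tied to alignment rows by pairwise global alignment
of the chain-derived sequence against the ungapped row, then composed
with the row's gap pattern.  Author residue numbers in coordinate files
are deliberately never used for this mapping.

Column conservation uses a reduced amino-acid alphabet of similarity
groups (D/E, K/R, N/Q, S/T, I/V/L/M, F/Y/W, A/G, and singletons): a
column is conserved when at least a threshold fraction (default 0.9) of
its non-gap residues fall into one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO
from Bio.Align import PairwiseAligner

from .structure import ResidueRef

__all__ = [
    "Alignment",
    "ResidueColumnMap",
    "ReferenceLabel",
    "ConservationLabel",
    "read_alignment",
    "map_chain_to_row",
    "reference_labels",
    "classify_columns",
    "DEFAULT_SIMILARITY_GROUPS",
    "DEFAULT_CONSERVATION_THRESHOLD",
    "DEFAULT_IDENTITY_GUARD",
]

GAP_CHARS = set("-.")

#: Reduced-alphabet similarity groups used for conservation calls.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in (
        "DE", "KR", "NQ", "ST", "IVLM", "FYW", "AG", "C", "H", "P",
    )
)

DEFAULT_CONSERVATION_THRESHOLD = 0.9

#: Minimum sequence identity between a chain and its assigned row.
DEFAULT_IDENTITY_GUARD = 0.8


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment with a designated reference row."""

    rows: tuple[tuple[str, str], ...]
    reference_row: str

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        names = [n for n, _ in self.rows]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate row names: {sorted(dupes)}")
        widths = {len(s) for _, s in self.rows}
        if len(widths) > 1:
            ragged = [n for n, s in self.rows if len(s) != len(self.rows[0][1])]
            raise ValueError(f"rows of unequal length: {ragged}")
        if self.reference_row not in names:
            raise ValueError(f"reference row {self.reference_row!r} not present")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.rows)

    def row(self, name: str) -> str:
        for n, s in self.rows:
            if n == name:
                return s
        raise KeyError(name)

    def ungapped(self, name: str) -> str:
        return "".join(c for c in self.row(name) if c not in GAP_CHARS)


@dataclass(frozen=True)
class ResidueColumnMap:
    """Structure residues of one chain mapped to 0-based alignment columns."""

    complex_id: str
    chain: str
    entries: tuple[tuple[ResidueRef, int], ...]
    unmapped: tuple[ResidueRef, ...] = ()

    def __post_init__(self):
        cols = [c for _, c in self.entries]
        if len(set(cols)) != len(cols):
            raise ValueError("column mapping is not injective")

    def column_of(self, ref: ResidueRef) -> int | None:
        for r, c in self.entries:
            if r == ref:
                return c
        return None

    def as_dict(self) -> dict[ResidueRef, int]:
        return dict(self.entries)


@dataclass(frozen=True)
class ReferenceLabel:
    """Reference-numbering labels for every alignment column.

    Non-gap reference columns get "<aa><number>" (e.g. "E37"); columns
    gapped in the reference get an insertion label "ins<number><letter>"
    anchored to the preceding reference number.
    """

    labels: tuple[str, ...]

    def __getitem__(self, col: int) -> str:
        return self.labels[col]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ConservationLabel:
    """Per-column conserved/variable calls with the witness group."""

    calls: tuple[str, ...]                  # "conserved" | "variable"
    witness: tuple[frozenset[str] | None, ...]

    def conserved_columns(self) -> set[int]:
        return {i for i, c in enumerate(self.calls) if c == "conserved"}

    def __getitem__(self, col: int) -> str:
        return self.calls[col]


def read_alignment(path, fmt: str = "fasta",
                   reference_row: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment file.

    The reference row defaults to the first row when not given.
    """
    if fmt not in {"fasta", "clustal"}:
        raise ValueError(f"unknown alignment format {fmt!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"failed to read {path} as {fmt}: {exc}") from exc
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in msa)
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    ref = reference_row if reference_row is not None else rows[0][0]
    return Alignment(rows=rows, reference_row=ref)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # do not penalize terminal gaps: constructs are domain fragments
    aligner.end_gap_score = 0.0
    return aligner


def map_chain_to_row(
    chain_residues: list[ResidueRef],
    row: str,
    complex_id: str = "",
    row_name: str = "",
    identity_guard: float = DEFAULT_IDENTITY_GUARD,
) -> ResidueColumnMap:
    """Map ordered chain residues onto the columns of one gapped row.

    The chain-derived one-letter sequence is globally aligned to the
    ungapped row; matched positions are composed with the row's gap
    pattern to produce residue -> column assignments.  Residues aligned
    to a gap in the pairwise step stay unmapped.  A minimum identity over
    the aligned span guards against assigning a chain to the wrong row.
    """
    if not chain_residues:
        raise ValueError(f"{complex_id}: empty chain residue list")
    chain_seq = "".join(r.aa for r in chain_residues)
    ungapped = "".join(c for c in row if c not in GAP_CHARS)
    if not ungapped:
        raise ValueError(f"{complex_id}: row {row_name!r} is all gaps")

    aligner = _make_aligner()
    aln = aligner.align(chain_seq, ungapped)[0]
    chain_to_rowpos: dict[int, int] = {}
    matches = 0
    aligned_len = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for off in range(ea - sa):
            ci, ri = sa + off, sb + off
            chain_to_rowpos[ci] = ri
            aligned_len += 1
            if chain_seq[ci] == ungapped[ri]:
                matches += 1
    if aligned_len == 0 or matches / aligned_len < identity_guard:
        ident = matches / aligned_len if aligned_len else 0.0
        raise ValueError(
            f"{complex_id}: chain does not match row {row_name!r} "
            f"(identity {ident:.0%} < guard {identity_guard:.0%})"
        )

    # row position (ungapped index) -> alignment column
    rowpos_to_col = [i for i, c in enumerate(row) if c not in GAP_CHARS]

    entries = []
    unmapped = []
    for ci, ref in enumerate(chain_residues):
        ri = chain_to_rowpos.get(ci)
        if ri is None:
            unmapped.append(ref)
        else:
            entries.append((ref, rowpos_to_col[ri]))
    return ResidueColumnMap(
        complex_id=complex_id,
        chain=chain_residues[0].chain,
        entries=tuple(entries),
        unmapped=tuple(unmapped),
    )


def reference_labels(alignment: Alignment,
                     reference_start_number: int = 1) -> ReferenceLabel:
    """Label every column in reference-row numbering.

    The k-th non-gap reference column is labeled
    ``<ref aa><start + k - 1>``; reference-gap columns become insertion
    labels ``ins<anchor><a,b,...>`` anchored to the preceding number.
    """
    ref = alignment.row(alignment.reference_row)
    labels = []
    number = reference_start_number - 1
    ins_count = 0
    for c in ref:
        if c in GAP_CHARS:
            ins_count += 1
            suffix = _insertion_suffix(ins_count)
            labels.append(f"ins{number}{suffix}")
        else:
            number += 1
            ins_count = 0
            labels.append(f"{c}{number}")
    return ReferenceLabel(labels=tuple(labels))


def _insertion_suffix(k: int) -> str:
    """1 -> 'a', 2 -> 'b', ..., 27 -> 'aa' (spreadsheet-style)."""
    s = ""
    while k > 0:
        k, rem = divmod(k - 1, 26)
        s = chr(ord("a") + rem) + s
    return s


def classify_columns(
    alignment: Alignment,
    groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS,
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> ConservationLabel:
    """Conserved/variable call per column under the reduced alphabet.

    A column is conserved iff at least ``threshold`` of its non-gap
    residues belong to a single similarity group; residues outside all
    groups count as their own singleton group.  All-gap columns are
    variable.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    group_of: dict[str, frozenset[str]] = {}
    for g in groups:
        for aa in g:
            group_of[aa] = g
    calls = []
    witness = []
    for col in range(alignment.width):
        residues = [
            s[col] for _, s in alignment.rows if s[col] not in GAP_CHARS
        ]
        if not residues:
            calls.append("variable")
            witness.append(None)
            continue
        counts: dict[frozenset[str], int] = {}
        for aa in residues:
            g = group_of.get(aa, frozenset(aa))
            counts[g] = counts.get(g, 0) + 1
        best_group = max(counts, key=lambda g: (counts[g], sorted(g)))
        if counts[best_group] / len(residues) >= threshold:
            calls.append("conserved")
            witness.append(best_group)
        else:
            calls.append("variable")
            witness.append(None)
    return ConservationLabel(calls=tuple(calls), witness=tuple(witness))
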