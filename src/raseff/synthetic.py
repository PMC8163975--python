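"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the three kinds of real input:

* toy two-chain complex structures with planted sub-cutoff residue
  contacts (stands in for crystal structures of GTPase-effector
  complexes);
* gap-free alignments with planted conserved/variable columns;
* fluorescence-polarization titration curves drawn from the quadratic
  ligand-depletion binding model with Gaussian noise.

Toy-structure geometry: each residue is a rigid planar five-atom
fragment (N, CA, C, O, CB) of radius < 2.5 Angstrom.  GTPase fragments
sit on a 16-Angstrom 2-D lattice in the z=0 plane; effector fragments
sit on a parallel lattice 300 Angstrom away.  A planted contact
(i, j, d) translates effector fragment j to directly above GTPase
fragment i at height d: the CA-CA pair then realizes the minimum
heavy-atom distance exactly d, every other atom pair of that residue
pair is >= d, and all other intermolecular residue pairs are > 11
Angstrom apart — far beyond cutoff + 2.  No physical realism is
attempted or needed; only the contact topology matters.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .affinity import TitrationDataset, titration_signal
from .alignment import Alignment, DEFAULT_SIMILARITY_GROUPS

__all__ = [
    "PlantedComplexSpec",
    "TitrationSpec",
    "SyntheticEnsemble",
    "synth_complex",
    "synth_ensemble",
    "synth_alignment",
    "simulate_titration",
    "default_concentrations",
    "DEFAULT_CUTOFF",
    "LATTICE_SPACING",
]

DEFAULT_CUTOFF = 4.0
LATTICE_SPACING = 16.0
_EFFECTOR_Z = 300.0

# planar heavy-atom fragment, CA at the origin
_FRAGMENT = (
    ("N", (1.46, 0.0, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (-1.52, 0.0, 0.0)),
    ("O", (-2.10, 1.05, 0.0)),
    ("CB", (0.0, -1.53, 0.0)),
)
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class PlantedComplexSpec:
    """A toy two-chain complex with an exact, known contact set."""

    n_gtpase_residues: int
    n_effector_residues: int
    planted_contacts: tuple[tuple[int, int, float], ...]
    seed: int = 0
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if self.n_gtpase_residues < 1 or self.n_effector_residues < 1:
            raise ValueError("chains need at least one residue")
        pairs = [(g, e) for g, e, _ in self.planted_contacts]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate planted pairs")
        effectors = [e for _, e in pairs]
        if len(set(effectors)) != len(effectors):
            raise ValueError(
                "infeasible geometry: an effector residue can realize at "
                "most one planted contact"
            )
        for g, e, d in self.planted_contacts:
            if not 0 <= g < self.n_gtpase_residues:
                raise ValueError(f"GTPase index {g} out of range")
            if not 0 <= e < self.n_effector_residues:
                raise ValueError(f"effector index {e} out of range")
            if not 0 < d < self.cutoff:
                raise ValueError(
                    f"target distance {d} must be in (0, {self.cutoff})"
                )

    @property
    def contact_pairs(self) -> set[tuple[int, int]]:
        """Planted (gtpase index, effector index) pairs, 0-based."""
        return {(g, e) for g, e, _ in self.planted_contacts}


@dataclass(frozen=True)
class TitrationSpec:
    """Ground truth for one simulated titration series."""

    kd_true: float
    receptor_total: float = 1.0
    concentrations: tuple[float, ...] = ()
    p_free: float = 60.0
    p_bound: float = 160.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.kd_true <= 0:
            raise ValueError("kd_true must be > 0")
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be > 0")
        if self.p_bound == self.p_free:
            raise ValueError("p_bound must differ from p_free")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        conc = np.asarray(self.concentrations or default_concentrations())
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and increasing")

    @property
    def conc(self) -> np.ndarray:
        return np.asarray(self.concentrations or default_concentrations())


def default_concentrations(n: int = 20, low: float = 0.002,
                           high: float = 300.0) -> tuple[float, ...]:
    """Log-spaced titrant series over the standard 0.002-300 uM range."""
    return tuple(np.geomspace(low, high, n))


def _lattice(index: int, n_total: int) -> tuple[float, float]:
    k = max(1, math.ceil(math.sqrt(n_total)))
    return (LATTICE_SPACING * (index % k), LATTICE_SPACING * (index // k))


def _build_structure(spec: PlantedComplexSpec) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synthetic complex"
    model = gemmi.Model(1)

    planted_by_effector = {e: (g, d) for g, e, d in spec.planted_contacts}

    chain_a = gemmi.Chain("A")
    for i in range(spec.n_gtpase_residues):
        x, y = _lattice(i, spec.n_gtpase_residues)
        chain_a.add_residue(_make_residue(i + 1, (x, y, 0.0), rotation=0.0))
    chain_b = gemmi.Chain("B")
    for j in range(spec.n_effector_residues):
        if j in planted_by_effector:
            g, d = planted_by_effector[j]
            gx, gy = _lattice(g, spec.n_gtpase_residues)
            center = (gx, gy, d)
        else:
            x, y = _lattice(j, spec.n_effector_residues)
            center = (x, y, _EFFECTOR_Z)
        # rotate each effector fragment in-plane so coincident plants of one
        # GTPase residue do not overlap atom-for-atom; CA stays at the
        # center, keeping the CA-CA distance the exact pair minimum
        chain_b.add_residue(
            _make_residue(j + 1, center, rotation=(j + 1) * _GOLDEN_ANGLE)
        )
    model.add_chain(chain_a)
    model.add_chain(chain_b)
    st.add_model(model)
    st.setup_entities()
    return st


def _make_residue(seqnum: int, center, rotation: float) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = "ALA"
    res.seqid = gemmi.SeqId(seqnum, " ")
    cos_r, sin_r = math.cos(rotation), math.sin(rotation)
    for name, (lx, ly, lz) in _FRAGMENT:
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element(name[0])
        rx = lx * cos_r - ly * sin_r
        ry = lx * sin_r + ly * cos_r
        atom.pos = gemmi.Position(center[0] + rx, center[1] + ry, center[2] + lz)
        atom.occ = 1.0
        atom.b_iso = 20.0
        res.add_atom(atom)
    return res


def synth_complex(spec: PlantedComplexSpec, fmt: str = "pdb") -> str:
    """Render a toy complex as PDB (or mmCIF) text.

    Chain A is the GTPase, chain B the effector; residues are numbered
    from 1.  Contact extraction at ``spec.cutoff`` recovers exactly
    ``spec.contact_pairs``.  Output is byte-identical for equal specs.
    """
    st = _build_structure(spec)
    if fmt == "pdb":
        return st.make_pdb_string()
    if fmt == "mmcif":
        return st.make_mmcif_document().as_string()
    raise ValueError(f"unknown structure format {fmt!r}")


@dataclass(frozen=True)
class SyntheticEnsemble:
    """A set of toy complexes with per-complex planted truth."""

    specs: tuple[PlantedComplexSpec, ...]
    complex_ids: tuple[str, ...]
    #: complex_id -> set of planted (gtpase idx, effector idx) pairs
    truth: dict[str, set[tuple[int, int]]]

    def pair_counts(self) -> dict[tuple[int, int], int]:
        """Planted occurrence count per residue pair across the ensemble."""
        counts: dict[tuple[int, int], int] = {}
        for pairs in self.truth.values():
            for p in pairs:
                counts[p] = counts.get(p, 0) + 1
        return counts

    def write(self, out_dir, fmt: str = "pdb") -> Path:
        """Write structures plus a YAML manifest; returns the manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = "pdb" if fmt == "pdb" else "cif"
        entries = []
        for spec, cid in zip(self.specs, self.complex_ids):
            path = out_dir / f"{cid}.{ext}"
            path.write_text(synth_complex(spec, fmt=fmt))
            entries.append(
                {
                    "complex_id": cid,
                    "path": path.name,
                    "gtpase_chain": "A",
                    "effector_chain": "B",
                    "effector_family": "RA",
                }
            )
        manifest = out_dir / "manifest.yaml"
        manifest.write_text(yaml.safe_dump({"complexes": entries}, sort_keys=False))
        return manifest


def synth_ensemble(
    core_contacts: set[tuple[int, int]],
    peripheral_rate: float,
    n_complexes: int,
    seed: int = 0,
    n_gtpase_residues: int = 20,
    n_effector_residues: int = 20,
    cutoff: float = DEFAULT_CUTOFF,
) -> SyntheticEnsemble:
    """Generate an ensemble sharing a core contact set.

    Every core pair is planted in all complexes.  Residues not used by
    the core are paired off one-to-one (i-th spare GTPase residue with
    i-th spare effector residue) to form peripheral candidate pairs,
    each planted independently per complex with probability
    ``peripheral_rate``.  Candidates are disjoint from the core and from
    each other so that any subset is geometrically realizable.
    """
    if not 0 <= peripheral_rate <= 1:
        raise ValueError("peripheral_rate must be in [0, 1]")
    if n_complexes < 1:
        raise ValueError("need at least one complex")
    core = sorted(core_contacts)
    used_g = {g for g, _ in core}
    used_e = {e for _, e in core}
    if len(used_e) != len(core):
        raise ValueError(
            "infeasible geometry: core contacts reuse an effector residue"
        )
    spare_g = [i for i in range(n_gtpase_residues) if i not in used_g]
    spare_e = [j for j in range(n_effector_residues) if j not in used_e]
    candidates = list(zip(spare_g, spare_e))

    rng = np.random.default_rng(seed)
    specs = []
    ids = []
    truth: dict[str, set[tuple[int, int]]] = {}
    for k in range(n_complexes):
        pairs = list(core)
        if peripheral_rate > 0:
            mask = rng.random(len(candidates)) < peripheral_rate
            pairs.extend(c for c, m in zip(candidates, mask) if m)
        else:
            rng.random(len(candidates))  # keep the stream position stable
        distances = rng.uniform(3.0, min(3.9, cutoff - 0.05), size=len(pairs))
        planted = tuple(
            (g, e, float(d)) for (g, e), d in zip(pairs, distances)
        )
        spec = PlantedComplexSpec(
            n_gtpase_residues=n_gtpase_residues,
            n_effector_residues=n_effector_residues,
            planted_contacts=planted,
            seed=seed,
            cutoff=cutoff,
        )
        cid = f"synth{k:03d}"
        specs.append(spec)
        ids.append(cid)
        truth[cid] = {(g, e) for g, e, _ in planted}
    return SyntheticEnsemble(
        specs=tuple(specs), complex_ids=tuple(ids), truth=truth
    )


def synth_alignment(
    n_rows: int,
    n_cols: int,
    conserved_cols: set[int],
    group_palette: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS,
    seed: int = 0,
    reference_name: str = "ref",
) -> Alignment:
    """Gap-free alignment with planted conserved and variable columns.

    Conserved columns draw every row from one similarity group; variable
    columns split the rows roughly half and half between two distinct
    groups, so no group can reach a 0.9 conservation threshold for
    n_rows >= 2.
    """
    if n_rows < 2:
        raise ValueError("alignment needs at least 2 rows")
    bad = [c for c in conserved_cols if not 0 <= c < n_cols]
    if bad:
        raise ValueError(f"conserved columns out of range: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    palette = [sorted(g) for g in group_palette]
    cols = []
    for c in range(n_cols):
        if c in conserved_cols:
            group = palette[rng.integers(len(palette))]
            cols.append([group[rng.integers(len(group))] for _ in range(n_rows)])
        else:
            g1, g2 = rng.choice(len(palette), size=2, replace=False)
            order = rng.permutation(n_rows)
            col = [""] * n_rows
            half = n_rows // 2
            for pos, r in enumerate(order):
                group = palette[g1] if pos < half else palette[g2]
                col[r] = group[rng.integers(len(group))]
            cols.append(col)
    names = [reference_name] + [f"seq{i}" for i in range(1, n_rows)]
    rows = tuple(
        (names[r], "".join(cols[c][r] for c in range(n_cols)))
        for r in range(n_rows)
    )
    return Alignment(rows=rows, reference_row=reference_name)


def simulate_titration(spec: TitrationSpec) -> TitrationDataset:
    """Draw one noisy titration from the quadratic binding model."""
    rng = np.random.default_rng(spec.seed)
    conc = spec.conc
    ideal = titration_signal(
        conc, spec.receptor_total, spec.kd_true, spec.p_free, spec.p_bound
    )
    noise = rng.normal(0.0, spec.noise_sd, size=conc.shape) if spec.noise_sd else 0.0
    return TitrationDataset(
        receptor_total=spec.receptor_total,
        concentrations=tuple(conc),
        signals=tuple(np.asarray(ideal + noise)),
        label=f"kd{spec.kd_true:g}_seed{spec.seed}",
    )
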