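"""Read GTPase-effector complex structures and extract interface contacts.

A residue pair (one residue from the GTPase chain, one from the effector
chain) is in contact when the minimum distance over all heavy-atom pairs
is at most a cutoff, 4.0 Angstrom by default.  Hydrogens are ignored;
waters, ions and other non-polymer heteroatoms never take part.  For
alternate conformations only the highest-occupancy altloc of each atom is
kept (ties broken by altloc identifier order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexSpec",
    "ResidueRef",
    "ResidueContact",
    "read_structure",
    "read_structure_string",
    "residue_min_distance",
    "extract_contacts",
    "chain_residue_refs",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 4.0

EFFECTOR_FAMILIES = ("RA", "RB")


@dataclass(frozen=True)
class ComplexSpec:
    """One GTPase-effector complex to analyze.

    Each crystallographically independent copy of a complex in the same
    file is its own ComplexSpec (same path, different chain pair).
    """

    complex_id: str
    source_path: str
    gtpase_chain: str
    effector_chain: str
    effector_family: str
    model_index: int = 0

    def __post_init__(self):
        if self.gtpase_chain == self.effector_chain:
            raise ValueError(
                f"{self.complex_id}: GTPase and effector chains must differ"
            )
        if self.effector_family not in EFFECTOR_FAMILIES:
            raise ValueError(
                f"{self.complex_id}: effector_family must be one of "
                f"{EFFECTOR_FAMILIES}, got {self.effector_family!r}"
            )


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A residue identified by chain, author numbering and amino-acid type."""

    chain: str
    seq_number: int
    insertion_code: str = ""
    aa: str = "X"


@dataclass(frozen=True)
class ResidueContact:
    """An intermolecular residue pair within the distance cutoff."""

    complex_id: str
    gtpase_residue: ResidueRef
    effector_residue: ResidueRef
    min_distance: float

    @property
    def pair(self) -> tuple[ResidueRef, ResidueRef]:
        return (self.gtpase_residue, self.effector_residue)


def read_structure(path, fmt: str | None = None) -> gemmi.Structure:
    """Parse a PDB or mmCIF file into a gemmi Structure.

    ``fmt`` may be "pdb" or "mmcif"; when omitted it is inferred from the
    file extension.  Files without any atoms are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown structure format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    n_atoms = sum(
        1 for model in st for chain in model for res in chain for _ in res
    )
    if n_atoms == 0:
        raise ValueError(f"{path}: no atom records found")
    return st


def read_structure_string(text: str, fmt: str = "pdb") -> gemmi.Structure:
    """Parse PDB or mmCIF text held in memory."""
    if fmt == "pdb":
        st = gemmi.read_pdb_string(text)
    elif fmt == "mmcif":
        doc = gemmi.cif.read_string(text)
        st = gemmi.make_structure_from_block(doc.sole_block())
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    st.setup_entities()
    return st


def _is_heavy(atom: gemmi.Atom) -> bool:
    return atom.element.name not in ("H", "D")


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    if res.is_water():
        return False
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        return info.is_amino_acid()
    # unknown residue names: treat ATOM records as polymer, HETATM not
    return res.het_flag != "H"


def _select_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Heavy atoms of a residue, one per atom name.

    Among alternate locations of the same atom name the highest occupancy
    wins; ties go to the lexicographically first altloc identifier.
    """
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        if not _is_heavy(atom):
            continue
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif atom.occ > prev.occ or (
            # gemmi encodes "no altloc" as '\x00', which sorts first
            atom.occ == prev.occ and atom.altloc < prev.altloc
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def _residue_ref(chain_name: str, res: gemmi.Residue) -> ResidueRef:
    info = gemmi.find_tabulated_residue(res.name)
    aa = "X"
    if info is not None and info.is_amino_acid():
        one = info.one_letter_code.upper()
        if one.isalpha():
            aa = one
    return ResidueRef(
        chain=chain_name,
        seq_number=res.seqid.num,
        insertion_code=(res.seqid.icode or "").strip(),
        aa=aa,
    )


def residue_min_distance(res_a: gemmi.Residue, res_b: gemmi.Residue) -> float:
    """Minimum heavy-atom distance between two residues (Angstrom)."""
    atoms_a = _select_altlocs(res_a)
    atoms_b = _select_altlocs(res_b)
    if not atoms_a or not atoms_b:
        raise ValueError("residue without heavy atoms")
    pos_a = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms_a])
    pos_b = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms_b])
    d2 = np.sum((pos_a[:, None, :] - pos_b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def _chain_atoms(chain: gemmi.Chain, complex_id: str):
    """Per-residue refs and stacked heavy-atom coordinates for one chain."""
    refs: list[ResidueRef] = []
    coords: list[np.ndarray] = []
    res_index: list[int] = []
    for res in chain:
        if not _is_polymer_residue(res):
            continue
        atoms = _select_altlocs(res)
        if not atoms:
            logger.warning(
                "%s: residue %s %d%s in chain %s has no heavy atoms; skipped",
                complex_id, res.name, res.seqid.num, res.seqid.icode or "",
                chain.name,
            )
            continue
        idx = len(refs)
        refs.append(_residue_ref(chain.name, res))
        for a in atoms:
            coords.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
            res_index.append(idx)
    if not refs:
        raise ValueError(f"{complex_id}: chain {chain.name} has no usable residues")
    return refs, np.vstack(coords), np.asarray(res_index)


def chain_residue_refs(structure: gemmi.Structure, chain_name: str,
                       model_index: int = 0) -> list[ResidueRef]:
    """Ordered polymer residues of one chain as ResidueRefs."""
    model = structure[model_index]
    chain = model.find_chain(chain_name)
    if chain is None:
        raise ValueError(f"chain {chain_name!r} not found")
    refs = []
    for res in chain:
        if _is_polymer_residue(res) and _select_altlocs(res):
            refs.append(_residue_ref(chain_name, res))
    return refs


def extract_contacts(
    spec: ComplexSpec,
    structure: gemmi.Structure | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> set[ResidueContact]:
    """All GTPase-effector residue pairs with min heavy-atom distance <= cutoff.

    Each qualifying residue pair is reported exactly once with its minimum
    distance, however many atom pairs fall under the cutoff.  Intra-chain
    pairs are never reported.  Uses a KD-tree over the smaller chain's
    atoms; equivalent to the brute-force all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if structure is None:
        structure = read_structure(spec.source_path)
    model = structure[spec.model_index]
    chains = {}
    for role, name in (("gtpase", spec.gtpase_chain),
                       ("effector", spec.effector_chain)):
        chain = model.find_chain(name)
        if chain is None:
            raise ValueError(
                f"{spec.complex_id}: chain {name!r} ({role}) not in model "
                f"{spec.model_index} of {spec.source_path}"
            )
        chains[role] = chain

    g_refs, g_xyz, g_idx = _chain_atoms(chains["gtpase"], spec.complex_id)
    e_refs, e_xyz, e_idx = _chain_atoms(chains["effector"], spec.complex_id)

    tree = cKDTree(e_xyz)
    pairs = tree.query_ball_point(g_xyz, r=cutoff)
    best: dict[tuple[int, int], float] = {}
    for ai, neighbors in enumerate(pairs):
        if not neighbors:
            continue
        gi = g_idx[ai]
        d = np.linalg.norm(e_xyz[neighbors] - g_xyz[ai], axis=1)
        for nb, dist in zip(neighbors, d):
            key = (int(gi), int(e_idx[nb]))
            if dist <= cutoff and dist < best.get(key, np.inf):
                best[key] = float(dist)
    return {
        ResidueContact(
            complex_id=spec.complex_id,
            gtpase_residue=g_refs[gi],
            effector_residue=e_refs[ei],
            min_distance=d,
        )
        for (gi, ei), d in best.items()
    }
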