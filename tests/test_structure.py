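"""Contact extraction: distances, cutoffs, formats, altlocs, invariances."""

import numpy as np
import pytest

from conftest import brute_force_contacts, random_planted_spec
from raseff.structure import (ComplexSpec, ResidueRef, extract_contacts,
                              read_structure, read_structure_string,
                              residue_min_distance)
from raseff.synthetic import PlantedComplexSpec, synth_complex

import gemmi


def _residue(name, atoms):
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(1, " ")
    for aname, elem, (x, y, z), occ, altloc in atoms:
        a = gemmi.Atom()
        a.name = aname
        a.element = gemmi.Element(elem)
        a.pos = gemmi.Position(x, y, z)
        a.occ = occ
        if altloc:
            a.altloc = altloc
        res.add_atom(a)
    return res


class TestReadStructure:
    def test_roundtrip_counts(self, tmp_path):
        spec = PlantedComplexSpec(7, 9, ((2, 3, 3.0),))
        path = tmp_path / "toy.pdb"
        path.write_text(synth_complex(spec))
        st = read_structure(path)
        model = st[0]
        assert len(model) == 2
        assert len(model.find_chain("A")) == 7
        assert len(model.find_chain("B")) == 9

    def test_zero_atom_file_fails(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(ValueError, match="no atom"):
            read_structure(path)

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(synth_complex(PlantedComplexSpec(3, 3, ())))
        with pytest.raises(ValueError, match="format"):
            read_structure(path, fmt="xyz")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_structure("/nonexistent/file.pdb")

    def test_pdb_and_mmcif_give_identical_contacts(self):
        spec = PlantedComplexSpec(15, 15, ((1, 2, 3.2), (5, 9, 3.8)))
        cs = ComplexSpec("c", "mem", "A", "B", "RA")
        sets = []
        for fmt in ("pdb", "mmcif"):
            st = read_structure_string(synth_complex(spec, fmt=fmt), fmt=fmt)
            contacts = extract_contacts(cs, structure=st)
            sets.append({
                (c.gtpase_residue.seq_number, c.effector_residue.seq_number,
                 round(c.min_distance, 6))
                for c in contacts
            })
        assert sets[0] == sets[1]


class TestResidueMinDistance:
    def test_three_four_five_triangle(self):
        ra = _residue("GLY", [("CA", "C", (0, 0, 0), 1.0, "")])
        rb = _residue("GLY", [("CA", "C", (3, 4, 0), 1.0, "")])
        assert residue_min_distance(ra, rb) == pytest.approx(5.0)

    def test_identical_residues_zero(self):
        ra = _residue("GLY", [("CA", "C", (1, 2, 3), 1.0, "")])
        assert residue_min_distance(ra, ra) == 0.0

    def test_symmetric(self):
        ra = _residue("ALA", [("CA", "C", (0, 0, 0), 1.0, ""),
                              ("CB", "C", (1.5, 0, 0), 1.0, "")])
        rb = _residue("ALA", [("CA", "C", (5, 1, 0), 1.0, ""),
                              ("CB", "C", (4, 0, 0), 1.0, "")])
        assert residue_min_distance(ra, rb) == residue_min_distance(rb, ra)

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(0)
        pa = rng.normal(size=(6, 3))
        pb = rng.normal(size=(4, 3)) + 5.0
        ra = _residue("XXX", [(f"C{i}", "C", tuple(p), 1.0, "")
                              for i, p in enumerate(pa)])
        rb = _residue("YYY", [(f"C{i}", "C", tuple(p), 1.0, "")
                              for i, p in enumerate(pb)])
        expected = min(
            float(np.linalg.norm(a - b)) for a in pa for b in pb
        )
        assert residue_min_distance(ra, rb) == pytest.approx(expected)

    def test_hydrogens_excluded(self):
        ra = _residue("GLY", [("CA", "C", (0, 0, 0), 1.0, "")])
        rb = _residue("GLY", [("CA", "C", (0, 0, 6.0), 1.0, ""),
                              ("H", "H", (0, 0, 1.0), 1.0, "")])
        assert residue_min_distance(ra, rb) == pytest.approx(6.0)

    def test_only_hydrogens_fails(self):
        ra = _residue("GLY", [("CA", "C", (0, 0, 0), 1.0, "")])
        rb = _residue("GLY", [("H", "H", (0, 0, 1), 1.0, "")])
        with pytest.raises(ValueError, match="heavy"):
            residue_min_distance(ra, rb)

    def test_altloc_highest_occupancy_wins(self):
        # B altloc at 2 A has higher occupancy than A altloc at 1 A
        ra = _residue("SER", [("CA", "C", (0, 0, 1.0), 0.3, "A"),
                              ("CA", "C", (0, 0, 2.0), 0.7, "B")])
        rb = _residue("GLY", [("CA", "C", (0, 0, 0), 1.0, "")])
        assert residue_min_distance(ra, rb) == pytest.approx(2.0)

    def test_altloc_tie_broken_by_identifier(self):
        ra = _residue("SER", [("CA", "C", (0, 0, 2.0), 0.5, "B"),
                              ("CA", "C", (0, 0, 1.0), 0.5, "A")])
        rb = _residue("GLY", [("CA", "C", (0, 0, 0), 1.0, "")])
        assert residue_min_distance(ra, rb) == pytest.approx(1.0)


class TestExtractContacts:
    def test_planted_single_contact(self):
        spec = PlantedComplexSpec(10, 10, ((3, 7, 3.5),))
        st = read_structure_string(synth_complex(spec))
        cs = ComplexSpec("c", "mem", "A", "B", "RA")
        contacts = extract_contacts(cs, structure=st)
        assert len(contacts) == 1
        c = next(iter(contacts))
        assert (c.gtpase_residue.seq_number, c.effector_residue.seq_number) == (4, 8)
        assert c.min_distance == pytest.approx(3.5)

    def test_tighter_cutoff_drops_contact(self):
        spec = PlantedComplexSpec(10, 10, ((3, 7, 3.5),))
        st = read_structure_string(synth_complex(spec))
        cs = ComplexSpec("c", "mem", "A", "B", "RA")
        assert extract_contacts(cs, structure=st, cutoff=3.0) == set()

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(4)
        spec = random_planted_spec(rng, max_residues=25)
        st = read_structure_string(synth_complex(spec))
        cs = ComplexSpec("c", "mem", "A", "B", "RA")
        previous = set()
        for cutoff in (1.0, 2.0, 3.0, 4.0):
            pairs = {
                (c.gtpase_residue.seq_number, c.effector_residue.seq_number)
                for c in extract_contacts(cs, structure=st, cutoff=cutoff)
            }
            assert previous <= pairs
            previous = pairs

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        spec = random_planted_spec(rng, max_residues=50)
        st = read_structure_string(synth_complex(spec))
        cs = ComplexSpec("c", "mem", "A", "B", "RA")
        got = {
            (c.gtpase_residue.seq_number, c.effector_residue.seq_number):
                c.min_distance
            for c in extract_contacts(cs, structure=st)
        }
        brute = brute_force_contacts(st, "A", "B", cutoff=4.0)
        assert set(got) == set(brute)
        for k in got:
            assert got[k] == pytest.approx(brute[k], abs=1e-9)

    def test_atom_order_permutation_invariant(self, toy_structure):
        spec, st = toy_structure
        cs = ComplexSpec("c", "mem", "A", "B", "RA")
        before = {
            (c.gtpase_residue.seq_number, c.effector_residue.seq_number)
            for c in extract_contacts(cs, structure=st)
        }
        st2 = read_structure_string(synth_complex(spec))
        for chain in st2[0]:
            for res in chain:
                atoms = [a.clone() for a in reversed(list(res))]
                while len(res) > 0:
                    del res[0]
                for a in atoms:
                    res.add_atom(a)
        after = {
            (c.gtpase_residue.seq_number, c.effector_residue.seq_number)
            for c in extract_contacts(cs, structure=st2)
        }
        assert before == after

    def test_missing_chain_named_in_error(self, toy_structure):
        _, st = toy_structure
        cs = ComplexSpec("c", "mem", "A", "Z", "RA")
        with pytest.raises(ValueError, match="'Z'"):
            extract_contacts(cs, structure=st)

    def test_waters_excluded(self):
        spec = PlantedComplexSpec(5, 5, ())
        st = read_structure_string(synth_complex(spec))
        # drop a water into chain B right next to a chain A residue
        water = _residue("HOH", [("O", "O", (0.0, 0.0, 2.0), 1.0, "")])
        water.seqid = gemmi.SeqId(100, " ")
        water.het_flag = "H"
        st[0].find_chain("B").add_residue(water)
        cs = ComplexSpec("c", "mem", "A", "B", "RA")
        assert extract_contacts(cs, structure=st) == set()

    def test_same_chain_rejected_in_spec(self):
        with pytest.raises(ValueError, match="differ"):
            ComplexSpec("c", "mem", "A", "A", "RA")

    def test_bad_family_rejected(self):
        with pytest.raises(ValueError, match="effector_family"):
            ComplexSpec("c", "mem", "A", "B", "XX")
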