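import numpy as np
import pytest

from torsionqa.structure import (ContentError, FormatError, PairingError,
                                 pair_residues, read_structure, write_mmcif,
                                 write_pdb)
from torsionqa.synth import PeptideSpec, build_peptide

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00 11.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00 11.00           C
ATOM      8  O   GLY A   2       6.030   1.580   0.000  1.00 11.00           O
ATOM      9  N   SER A   3       6.230   3.800   0.000  1.00 12.00           N
ATOM     10  CA  SER A   3       7.684   3.800   0.000  1.00 12.00           C
ATOM     11  C   SER A   3       8.262   5.210   0.000  1.00 12.00           C
ATOM     12  O   SER A   3       7.520   6.190   0.000  1.00 12.00           O
ATOM     13  CB  SER A   3       8.200   3.020   1.200  1.00 12.00           C
ATOM     14  OG  SER A   3       9.610   3.010   1.150  1.00 12.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB ASER A   1       2.000  -0.800   1.200  0.60 10.00           C
ATOM      6  CB BSER A   1       2.000  -0.900   1.100  0.40 10.00           C
ATOM      7  OG ASER A   1       3.400  -0.810   1.190  0.60 10.00           O
ATOM      8  OG BSER A   1       3.400  -0.950   1.050  0.40 10.00           O
ATOM      9  N   ALA A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM     10  CA  ALA A   2       3.988   2.839   0.000  1.00 11.00           C
ATOM     11  C   ALA A   2       5.504   2.693   0.000  1.00 11.00           C
ATOM     12  O   ALA A   2       6.030   1.580   0.000  1.00 11.00           O
ATOM     13  CB  ALA A   2       3.500   3.650   1.200  1.00 11.00           C
END
"""


@pytest.fixture()
def minimal_path(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


class TestReadStructure:
    def test_minimal_roundtrip(self, minimal_path):
        record = read_structure(minimal_path)
        assert record.source_format == "pdb"
        assert list(record.chains) == ["A"]
        assert len(record.chains["A"]) == 3
        assert [r.res_type for r in record.chains["A"]] == ["ALA", "GLY", "SER"]

    def test_atom_metadata(self, minimal_path):
        record = read_structure(minimal_path)
        atom = record.chains["A"][0].get_atom("N")
        assert atom.occupancy == 1.0
        assert atom.b_factor == 10.0
        np.testing.assert_allclose(atom.position, [0.0, 0.0, 0.0])

    def test_altloc_max_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        record = read_structure(path)
        ser = record.chains["A"][0]
        cb = [a for a in ser.atoms if a.name == "CB"]
        assert len(cb) == 1
        assert cb[0].occupancy == 0.6
        assert cb[0].altloc == "A"

    def test_altloc_tie_breaks_lexicographically(self, tmp_path):
        text = ALTLOC_PDB.replace("0.60", "0.40")
        path = tmp_path / "tie.pdb"
        path.write_text(text)
        record = read_structure(path)
        cb = record.chains["A"][0].get_atom("CB")
        assert cb.altloc == "A"

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_structure(tmp_path / "nope.pdb")

    def test_empty_polymer(self, tmp_path):
        path = tmp_path / "water.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00 10.00           O\nEND\n")
        with pytest.raises(ContentError):
            read_structure(path)

    def test_waters_flagged_nonpolymer(self, tmp_path):
        path = tmp_path / "mix.pdb"
        path.write_text(MINIMAL_PDB.replace("END\n", "") +
                        "HETATM   15  O   HOH A 101      12.000   0.000   "
                        "0.000  1.00 30.00           O\nEND\n")
        record = read_structure(path)
        waters = [r for r in record.residues() if r.res_type == "HOH"]
        assert len(waters) == 1 and not waters[0].is_polymer
        assert record.n_polymer_residues() == 3

    def test_mse_maps_to_met(self, tmp_path):
        text = MINIMAL_PDB.replace("ALA A   1", "MSE A   1")
        path = tmp_path / "mse.pdb"
        path.write_text(text)
        record = read_structure(path)
        res = record.chains["A"][0]
        assert res.res_type == "MSE"
        assert res.is_polymer
        assert res.standard_type == "MET"


class TestWriteRead:
    def test_pdb_roundtrip_exact(self, mixed, tmp_path):
        path = tmp_path / "out.pdb"
        write_pdb(mixed, path)
        back = read_structure(path)
        assert back.n_polymer_residues() == mixed.n_polymer_residues()
        for orig, re_read in zip(mixed.residues(), back.residues()):
            assert orig.res_type == re_read.res_type
            assert [a.name for a in orig.atoms] == [a.name for a in re_read.atoms]
            for a, b in zip(orig.atoms, re_read.atoms):
                np.testing.assert_allclose(a.position, b.position, atol=5e-4)
                assert a.occupancy == pytest.approx(b.occupancy, abs=5e-3)
                assert a.b_factor == pytest.approx(b.b_factor, abs=5e-3)

    def test_cross_format_equality(self, mixed, tmp_path):
        pdb_path = tmp_path / "s.pdb"
        cif_path = tmp_path / "s.cif"
        write_pdb(mixed, pdb_path)
        write_mmcif(mixed, cif_path)
        from_pdb = read_structure(pdb_path)
        from_cif = read_structure(cif_path)
        assert from_pdb.source_format == "pdb"
        assert from_cif.source_format == "mmcif"
        pdb_res = list(from_pdb.residues())
        cif_res = list(from_cif.residues())
        assert len(pdb_res) == len(cif_res)
        for a, b in zip(pdb_res, cif_res):
            assert (a.res_type, a.seq_number) == (b.res_type, b.seq_number)
            assert [x.name for x in a.atoms] == [x.name for x in b.atoms]
            for x, y in zip(a.atoms, b.atoms):
                np.testing.assert_allclose(x.position, y.position, atol=1e-9)


class TestPairResidues:
    def test_identity_all_matched(self, mixed):
        pairs = pair_residues(mixed, mixed)
        assert len(pairs) == mixed.n_polymer_residues()
        assert all(p.model_residue is not None for p in pairs)
        assert not any(p.mutated for p in pairs)

    def test_missing_residues_bookkeeping(self, mixed):
        partial = mixed.copy()
        partial.chains["A"] = [r for r in partial.chains["A"]
                               if not 5 <= r.seq_number <= 8]
        pairs = pair_residues(mixed, partial)
        assert len(pairs) == 20
        absent = [p for p in pairs if p.model_residue is None]
        assert len(absent) == 4
        assert sorted(p.target_residue.seq_number for p in absent) == [5, 6, 7, 8]

    def test_numbering_offset_alignment(self, mixed_spec):
        target = build_peptide(mixed_spec)
        offset_spec = PeptideSpec(
            mixed_spec.sequence, mixed_spec.backbone_torsions,
            mixed_spec.chi_torsions, first_seq_number=101)
        shifted = build_peptide(offset_spec)
        with pytest.raises(PairingError):
            # by numbering nothing matches
            pair_residues(target, shifted, mode="numbering")
        pairs = pair_residues(target, shifted, mode="alignment")
        assert all(p.model_residue is not None for p in pairs)
        for p in pairs:
            assert p.model_residue.seq_number == p.target_residue.seq_number + 100

    def test_alignment_matches_offset_free_pairing(self, mixed_spec):
        target = build_peptide(mixed_spec)
        pairs_offset_free = pair_residues(target, target, mode="alignment")
        shifted = build_peptide(PeptideSpec(
            mixed_spec.sequence, mixed_spec.backbone_torsions,
            mixed_spec.chi_torsions, first_seq_number=101))
        pairs_shifted = pair_residues(target, shifted, mode="alignment")
        for a, b in zip(pairs_offset_free, pairs_shifted):
            assert a.target_residue.key == b.target_residue.key
            assert (a.model_residue is None) == (b.model_residue is None)

    def test_mutation_flag(self, mixed):
        mutant = mixed.copy()
        mutant.chains["A"][1].res_type = "ALA"  # LEU -> ALA
        pairs = pair_residues(mixed, mutant)
        assert pairs[1].mutated
        assert sum(p.mutated for p in pairs) == 1

    def test_pairing_error_on_disjoint(self, mixed):
        other = build_peptide(PeptideSpec("GG", first_seq_number=500))
        with pytest.raises(PairingError):
            pair_residues(mixed, other, mode="numbering")
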