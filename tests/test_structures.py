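import numpy as np
import pytest

from tifpscreen.structures import (
    ComplexStructure,
    Mol2FormatError,
    RmsdTable,
    extract_binding_site,
    pose_rmsd,
    read_complex,
    read_mol2,
    select_receptor,
    write_mol2,
)

from conftest import atom, random_rotation, transform_complex


class TestMol2:
    def test_minimal_parse(self, minimal_mol2):
        cx = read_mol2(minimal_mol2)
        assert len(cx.atoms) == 3
        np.testing.assert_allclose(cx.atoms[0].position, (0, 0, 0))
        np.testing.assert_allclose(cx.atoms[2].position, (3, 1, 0))
        assert [a.role for a in cx.atoms] == ["protein", "protein", "ligand"]
        assert cx.atoms[1].element == "O"

    def test_round_trip_preserves_atoms(self, mixed_complex, tmp_path):
        cx, _ = mixed_complex
        out = tmp_path / "cx.mol2"
        write_mol2(cx, out)
        cx2 = read_mol2(out)
        assert len(cx2.atoms) == len(cx.atoms)
        key = lambda a: (a.role, a.element, a.formal_charge, a.is_aromatic)
        assert sorted(map(key, cx.atoms)) == sorted(map(key, cx2.atoms))
        # coordinates identical to mol2 precision (4 decimals written)
        c1 = np.sort(cx.coords(), axis=0)
        c2 = np.sort(cx2.coords(), axis=0)
        np.testing.assert_allclose(c1, c2, atol=1e-3)

    def test_missing_atom_section_is_format_error(self, tmp_path):
        p = tmp_path / "bad.mol2"
        p.write_text("@<TRIPOS>MOLECULE\nempty\n0 0 0 0 0\n")
        with pytest.raises(Mol2FormatError):
            read_mol2(p)

    def test_malformed_atom_line_names_line(self, tmp_path):
        p = tmp_path / "bad.mol2"
        p.write_text("@<TRIPOS>MOLECULE\nx\n1 0\nSMALL\n\n@<TRIPOS>ATOM\n1 C notanumber 0 0 C\n")
        with pytest.raises(Mol2FormatError, match=r":7"):
            read_mol2(p)

    def test_pdb_roles_and_coordinates(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  O1  LIG A  10       3.000   1.000   0.000  1.00  0.00           O\n"
            "HETATM    4 ZN    ZN A  20       5.000   0.000   0.000  1.00  0.00          ZN\n"
            "HETATM    5  O   HOH A  30       8.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        cx = read_complex(pdb)
        assert [a.role for a in cx.atoms] == ["protein", "protein", "ligand", "metal", "water"]
        np.testing.assert_allclose(cx.atoms[2].position, (3.0, 1.0, 0.0))
        assert cx.atoms[3].element.upper() == "ZN"

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x.sdf"
        p.write_text("")
        with pytest.raises(ValueError, match="format"):
            read_complex(p)


class TestBindingSite:
    def _complex(self, residue_dists):
        atoms = [atom(1, "C", (0, 0, 0), role="ligand", residue_name="LIG")]
        nid = 2
        for rid, d in enumerate(residue_dists, start=10):
            atoms.append(atom(nid, "C", (d, 0, 0), residue_name="ALA", residue_id=rid))
            nid += 1
        return ComplexStructure("t", atoms)

    def test_inclusion_at_5p9_exclusion_at_6p1(self):
        site = extract_binding_site(self._complex([5.9, 6.1]), cutoff=6.0)
        dists = sorted(np.linalg.norm(a.xyz) for a in site.atoms)
        assert dists == [5.9]

    def test_whole_residue_retained(self):
        atoms = [
            atom(1, "C", (0, 0, 0), role="ligand", residue_name="LIG"),
            atom(2, "C", (5.9, 0, 0), residue_name="ALA", residue_id=10),
            atom(3, "O", (9.0, 0, 0), residue_name="ALA", residue_id=10),
            atom(4, "C", (9.0, 5, 0), residue_name="GLY", residue_id=11),
        ]
        site = extract_binding_site(ComplexStructure("t", atoms), cutoff=6.0)
        assert {a.atom_id for a in site.atoms} == {2, 3}

    def test_zero_cutoff_empty_site(self):
        site = extract_binding_site(self._complex([3.0]), cutoff=0.0)
        assert site.atoms == [] and site.residue_keys == frozenset()

    def test_no_ligand_errors(self):
        cx = ComplexStructure("t", [atom(1, "C", (0, 0, 0))])
        with pytest.raises(ValueError, match="ligand"):
            extract_binding_site(cx)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        atoms = [atom(1, "C", (0, 0, 0), role="ligand", residue_name="LIG")]
        for i in range(30):
            atoms.append(atom(i + 2, "C", rng.uniform(-10, 10, 3),
                              residue_name="ALA", residue_id=i + 10))
        cx = ComplexStructure("t", atoms)
        keys = [extract_binding_site(cx, c).residue_keys for c in (2.0, 4.0, 6.0, 9.0)]
        for small, big in zip(keys, keys[1:]):
            assert small <= big


class TestPoseRmsd:
    def test_identity_is_zero(self):
        a = np.arange(15.0).reshape(5, 3)
        assert pose_rmsd(a, a) == 0.0

    def test_uniform_translation(self):
        a = np.arange(15.0).reshape(5, 3)
        assert pose_rmsd(a, a + [3, 0, 0]) == pytest.approx(3.0)

    def test_matches_per_atom_summation_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        expected = np.sqrt(sum(
            sum((a[i, k] - b[i, k]) ** 2 for k in range(3)) for i in range(5)
        ) / 5)
        assert pose_rmsd(a, b) == pytest.approx(expected, abs=1e-12)
        assert pose_rmsd(b, a) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        rot, t = random_rotation(rng), rng.normal(size=3)
        moved = pose_rmsd(a @ rot.T + t, b @ rot.T + t)
        assert moved == pytest.approx(pose_rmsd(a, b), abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            pose_rmsd(np.zeros((2, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pose_rmsd(np.zeros((0, 3)), np.zeros((0, 3)))


class TestSelectReceptor:
    def _table(self, data):
        t = RmsdTable()
        for (s, l), v in data.items():
            t.add(s, l, v)
        return t

    def test_smallest_mean_wins(self):
        t = self._table({("A", "l1"): 1.0, ("A", "l2"): 2.0,
                         ("B", "l1"): 3.0, ("B", "l2"): 0.5})
        assert select_receptor(t) == "A"

    def test_single_candidate(self):
        assert select_receptor(self._table({("only", "l1"): 4.2})) == "only"

    def test_exact_tie_breaks_lexicographically(self):
        t = self._table({("5mvs", "l1"): 1.0, ("1nw3", "l1"): 1.0})
        assert select_receptor(t) == "1nw3"

    def test_missing_entries_skipped_or_penalized(self):
        t = self._table({("A", "l1"): 1.0, ("A", "l2"): None, ("B", "l1"): 1.5, ("B", "l2"): 1.5})
        assert select_receptor(t) == "A"            # skip: mean(A)=1.0
        assert select_receptor(t, on_missing=10.0) == "B"  # penalty: mean(A)=5.5

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            select_receptor(RmsdTable())

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_bruteforce_argmin(self, seed):
        rng = np.random.default_rng(seed)
        t = RmsdTable()
        cands = [f"s{i}" for i in range(rng.integers(2, 6))]
        for c in cands:
            for l in range(rng.integers(1, 5)):
                t.add(c, f"l{l}", float(rng.uniform(0, 8)))
        means = {c: np.mean([v for (s, _), v in t.entries.items() if s == c]) for c in cands}
        best = min(cands, key=lambda c: (means[c], c))
        assert select_receptor(t) == best
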