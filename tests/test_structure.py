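import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import grid_min_rmsd
from petmine.seqio import AMINO_ACIDS
from petmine.structure import (StructureModel, SuperpositionResult,
                               aromatic_contacts, kabsch, rank_by_structure,
                               read_ca_coordinates, structural_align, tm_d0,
                               tm_score, triage_table, write_ca_pdb)
from petmine.synthetic import generate_helix_structure


def random_chain(rng, n, step=3.8):
    """A random walk with CA-like step length (a crude unfolded chain)."""
    steps = rng.normal(size=(n - 1, 3))
    steps = step * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    return StructureModel(id="chain", residues=residues, ca_coordinates=coords)


def rigid_motion(rng, coords):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31)))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return coords @ R.T + t


class TestPdbIO:
    def test_three_residue_round_trip(self, tmp_path):
        model = StructureModel(
            id="m", residues="AFW",
            ca_coordinates=np.array([[0.0, 0.0, 0.0], [3.8, 0.1, -0.2], [7.1, 1.0, 0.5]]),
        )
        path = write_ca_pdb(model, tmp_path / "m.pdb")
        back = read_ca_coordinates(path)
        assert back.residues == "AFW"
        assert np.allclose(back.ca_coordinates, model.ca_coordinates, atol=1e-3)

    def test_round_trip_at_pdb_precision(self, tmp_path, rng):
        model = random_chain(rng, 30)
        back = read_ca_coordinates(write_ca_pdb(model, tmp_path / "c.pdb"))
        assert np.abs(back.ca_coordinates - model.ca_coordinates).max() < 5.1e-4

    def test_altloc_keeps_one_ca_per_residue(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C\n"
            "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  CA  TRP A   3       7.600   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "altloc.pdb"
        p.write_text(text)
        model = read_ca_coordinates(p)
        assert model.residues == "AGW"
        assert model.ca_coordinates.shape == (3, 3)

    def test_no_ca_atoms_rejected(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\nEND\n"
        )
        with pytest.raises(ValueError, match="no CA"):
            read_ca_coordinates(p)


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        p = rng.normal(size=(10, 3))
        res = kabsch(p, p)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self, rng):
        p = rng.normal(size=(20, 3)) * 5
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        q = p @ Rz.T + np.array([5.0, 0.0, 0.0])
        res = kabsch(p, q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transform(p), q, atol=1e-9)

    def test_mirror_image_matches_grid_oracle(self, rng):
        # chiral 4-point set: a proper rotation cannot reach the mirror image
        p = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [0.5, 0.5, 2.5]])
        q = p.copy()
        q[:, 2] *= -1
        res = kabsch(p, q)
        assert res.rmsd > 0.5
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd == pytest.approx(grid_min_rmsd(p, q), abs=1e-3)

    def test_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            kabsch(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestTmScore:
    def test_d0_formula_and_floor(self):
        assert tm_d0(21) == pytest.approx(0.5)  # raw value ~0.453, floored
        assert tm_d0(150) == pytest.approx(1.24 * 135 ** (1 / 3) - 1.8)

    def test_identical_structures_score_one(self, rng):
        m = random_chain(rng, 60)
        corr = [(i, i) for i in range(1, 61)]
        assert tm_score(m, m, corr) == pytest.approx(1.0, abs=1e-6)

    def test_unrelated_coils_score_low(self, rng):
        low = 0
        n_pairs = 40
        for _ in range(n_pairs):
            a = random_chain(rng, 100)
            b = random_chain(rng, 100)
            corr = [(i, i) for i in range(1, 101)]
            if tm_score(a, b, corr) < 0.30:
                low += 1
        assert low >= 0.95 * n_pairs

    def test_monotone_degradation_under_noise(self, rng):
        base = generate_helix_structure("A" * 80, noise_sd=0.0)
        corr = [(i, i) for i in range(1, 81)]
        tms = []
        for noise in (0.0, 0.5, 2.0):
            noisy = generate_helix_structure("A" * 80, noise_sd=noise, seed=5)
            tms.append(tm_score(noisy, base, corr))
        assert tms[0] == pytest.approx(1.0, abs=1e-6)
        assert tms[0] > tms[1] > tms[2]

    def test_correspondence_validation(self, rng):
        m = random_chain(rng, 20)
        with pytest.raises(ValueError):
            tm_score(m, m, [])
        with pytest.raises(ValueError):
            tm_score(m, m, [(2, 2), (1, 1)])


class TestStructuralAlign:
    def test_self_alignment(self, rng):
        m = random_chain(rng, 50)
        res = structural_align(m, m)
        assert res.tm_score == pytest.approx(1.0, abs=1e-6)
        assert res.correspondence == [(i, i) for i in range(1, 51)]

    def test_n_terminal_deletion(self, rng):
        ref = generate_helix_structure("ACDEFGHIKL" * 6, noise_sd=0.3, seed=8)
        query = StructureModel(
            id="trunc", residues=ref.residues[10:],
            ca_coordinates=ref.ca_coordinates[10:],
        )
        res = structural_align(query, ref)
        assert res.tm_score >= 0.8
        ref_positions = {b for _, b in res.correspondence}
        assert not (ref_positions & set(range(1, 9)))

    def test_rigid_motion_invariance(self, rng):
        ref = random_chain(rng, 60)
        query = random_chain(rng, 60)
        base = structural_align(query, ref).tm_score
        moved = StructureModel(
            id="mv", residues=query.residues,
            ca_coordinates=rigid_motion(rng, query.ca_coordinates),
        )
        assert structural_align(moved, ref).tm_score == pytest.approx(base, abs=1e-6)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            structural_align(random_chain(rng, 5), random_chain(rng, 50))


class TestAromaticContacts:
    def test_pair_within_cutoff(self):
        m = StructureModel(
            id="m", residues="FAAF",
            ca_coordinates=np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0]], dtype=float),
        )
        assert aromatic_contacts(m, cutoff=7.0, min_separation=3) == 1

    def test_pair_beyond_cutoff(self):
        m = StructureModel(
            id="m", residues="FAAF",
            ca_coordinates=np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0], [8, 0, 0]], dtype=float),
        )
        assert aromatic_contacts(m, cutoff=7.0, min_separation=3) == 0

    def test_matches_brute_force(self, rng):
        m = random_chain(rng, 50)
        for cutoff, sep in ((7.0, 2), (5.0, 1), (10.0, 4)):
            expected = 0
            for i in range(50):
                for j in range(i + 1, 50):
                    if (
                        m.residues[i] in "FYWH"
                        and m.residues[j] in "FYWH"
                        and j - i >= sep
                        and np.linalg.norm(m.ca_coordinates[i] - m.ca_coordinates[j]) <= cutoff
                    ):
                        expected += 1
            assert aromatic_contacts(m, cutoff, sep) == expected


class TestRanking:
    def test_reference_copies_rank_by_id(self, rng):
        ref = generate_helix_structure("ACDEFGHIKLMNPQRSTVWY" * 2, noise_sd=0.2, seed=3)
        cands = [
            StructureModel(id=f"c{i}", residues=ref.residues,
                           ca_coordinates=ref.ca_coordinates.copy())
            for i in range(3)
        ]
        ranking = rank_by_structure(cands, [ref])
        assert [r[0] for r in ranking] == ["c0", "c1", "c2"]
        assert all(tm == pytest.approx(1.0, abs=1e-6) for _, _, tm in ranking)

    def test_homolog_outranks_coils(self, rng):
        ref = generate_helix_structure("ACDEFGHIKLMNPQRSTVWY" * 3, noise_sd=0.2, seed=3)
        derived = StructureModel(
            id="derived", residues=ref.residues,
            ca_coordinates=rigid_motion(rng, ref.ca_coordinates + rng.normal(scale=0.3, size=ref.ca_coordinates.shape)),
        )
        coils = [random_chain(rng, 60) for _ in range(3)]
        for i, c in enumerate(coils):
            c.id = f"coil{i}"
        ranking = rank_by_structure([derived] + coils, [ref])
        assert ranking[0][0] == "derived"
        assert all(0.0 < tm <= 1.0 for _, _, tm in ranking)

    def test_empty_references(self, rng):
        with pytest.raises(ValueError):
            rank_by_structure([random_chain(rng, 20)], [])

    def test_triage_table_columns(self, rng):
        ref = generate_helix_structure("ACDEFGHIKLMNPQRSTVWY", noise_sd=0.1, seed=1)
        ref.id = "ref"
        table = triage_table([ref], [ref])
        assert list(table.columns) == [
            "candidate", "best_reference", "tm_score", "rmsd",
            "aligned_length", "aromatic_contacts",
        ]


class TestSuperpositionResult:
    def test_improper_rotation_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            SuperpositionResult(rotation=R, translation=np.zeros(3), rmsd=0.0)
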