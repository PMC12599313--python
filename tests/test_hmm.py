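import math

import numpy as np
import pytest

from oracles import enumerate_forward_bits, random_profile_hmm
from petmine.hmm import (CalibrationParams, HmmHit, ProfileHMM, build_profile,
                         calibrate, evalue, fit_exponential_tail, forward_score,
                         load_hmm, read_hits_tsv, save_hmm, score_database, search,
                         write_hits_tsv)
from petmine.msa import MSA
from petmine.seqio import ProteinSequence, ResidueComposition, shuffle_sequence


class TestBuildProfile:
    def test_single_column_laplace_counts(self):
        msa = MSA([("r1", "A"), ("r2", "A")])
        hmm = build_profile(msa, mask=np.array([True]))
        assert hmm.length == 1
        assert hmm.match_emissions[0, 0] == pytest.approx(3 / 22)  # (2+1)/(2+20)
        assert hmm.match_emissions[0, 5] == pytest.approx(1 / 22)

    def test_pseudocount_only_limit_is_uniform(self):
        # X rows contribute no emission counts: pure-pseudocount emissions
        msa = MSA([("r1", "XX"), ("r2", "XX")])
        hmm = build_profile(msa, mask=np.array([True, True]))
        assert np.allclose(hmm.match_emissions, 1 / 20)

    def test_gap_free_paths_dominated_by_match_transitions(self, rng):
        rows = [
            (f"r{i}", "".join(rng.choice(list("ACDEFGHIKL"), size=12)))
            for i in range(6)
        ]
        hmm = build_profile(MSA(rows))
        tr = hmm.transitions[1:-1]
        assert (tr[:, 0] >= tr[:, 1]).all()  # MM >= MI
        assert (tr[:, 0] >= tr[:, 2]).all()  # MM >= MD

    def test_no_match_columns_rejected(self):
        msa = MSA([("r1", "AC"), ("r2", "AC")])
        with pytest.raises(ValueError):
            build_profile(msa, mask=np.array([False, False]))


class TestForward:
    def test_single_state_peaked_model(self):
        # M=1 model strongly favoring A, scored on "A": the enumeration
        # oracle is exact for such tiny models
        rng = np.random.default_rng(5)
        me = np.full((1, 20), 1e-4)
        me[0, 0] = 1 - 19e-4
        tr = np.tile([0.8, 0.1, 0.1, 0.7, 0.3, 0.6, 0.4], (2, 1))
        bg = np.full(20, 0.05)
        hmm = ProfileHMM(me, tr, bg)
        got = forward_score(hmm, "A")
        assert got == pytest.approx(enumerate_forward_bits(hmm, "A"), abs=1e-9)
        # dominated by log2(P(A)/bg(A)) = log2(~1.0/0.05)
        assert got == pytest.approx(math.log2((1 - 19e-4) / 0.05), abs=0.01)

    def test_matches_enumeration_on_small_models(self, rng):
        for _ in range(25):
            M = int(rng.integers(1, 4))
            hmm = random_profile_hmm(rng, M)
            s = "".join(rng.choice(list("ACDE"), size=int(rng.integers(1, 5))))
            assert forward_score(hmm, s) == pytest.approx(
                enumerate_forward_bits(hmm, s), abs=1.5e-9
            )

    def test_consensus_beats_its_shuffles(self, tiny_profile):
        consensus = ProteinSequence(id="cons", residues=tiny_profile.consensus())
        ref = forward_score(tiny_profile, consensus)
        for s in range(100):
            assert forward_score(tiny_profile, shuffle_sequence(consensus, s)) < ref


class TestCalibration:
    def test_tail_fit_recovers_known_lambda(self, rng):
        # the diagnostic exceedance estimator on truly exponential scores
        true_lam = 0.7
        scores = 5.0 + rng.exponential(1.0 / true_lam, size=500)
        lam, tau = fit_exponential_tail(scores)
        assert lam == pytest.approx(true_lam, rel=0.15)
        assert tau < np.median(scores)  # anchored below the median by ln2/lambda

    def test_fit_survival_anchor(self, rng):
        scores = rng.normal(0.0, 3.0, size=1000)
        lam, tau = fit_exponential_tail(scores)
        m = float(np.median(scores))
        assert math.exp(-lam * (m - tau)) == pytest.approx(0.5, rel=1e-9)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_tail(np.ones(100))

    def test_deep_tail_fit_matches_shallow_on_exponential_scores(self, rng):
        # on a genuinely exponential tail, the fitted rate is threshold-free
        scores = rng.exponential(2.0, size=20_000)
        lam_shallow, _ = fit_exponential_tail(scores, tail_mass=0.5)
        lam_deep, _ = fit_exponential_tail(scores, tail_mass=0.01)
        assert lam_deep == pytest.approx(lam_shallow, rel=0.2)
        assert lam_deep == pytest.approx(0.5, rel=0.2)

    def test_calibrate_anchor_property(self, tiny_profile):
        # E at the fitted location tau equals the database size
        comp = ResidueComposition.swissprot()
        calib = calibrate(tiny_profile, comp, decoy_count=100, seed=4)
        assert calib.lam > 0
        assert evalue(calib.tau, calib, 777) == pytest.approx(777.0)

    def test_calibrate_deterministic(self, tiny_profile):
        comp = ResidueComposition.swissprot()
        c1 = calibrate(tiny_profile, comp, decoy_count=60, seed=4)
        c2 = calibrate(tiny_profile, comp, decoy_count=60, seed=4)
        assert (c1.lam, c1.tau) == (c2.lam, c2.tau)

    def test_decoy_count_floor(self, tiny_profile):
        with pytest.raises(ValueError):
            calibrate(tiny_profile, ResidueComposition.swissprot(), decoy_count=10)


class TestEvalue:
    @pytest.fixture()
    def calib(self):
        return CalibrationParams(lam=0.7, tau=5.0, decoy_count=200, decoy_seed=0)

    def test_at_location_point_equals_db_size(self, calib):
        assert evalue(5.0, calib, 100) == pytest.approx(100.0)

    def test_vanishes_at_high_score(self, calib):
        assert evalue(500.0, calib, 10**7) == pytest.approx(0.0, abs=1e-100)

    def test_halves_every_ln2_over_lambda_bits(self, calib):
        step = math.log(2) / calib.lam
        for s in (6.0, 9.0, 20.0):
            assert evalue(s + step, calib, 1000) == pytest.approx(
                evalue(s, calib, 1000) / 2
            )

    def test_strictly_decreasing(self, calib):
        scores = np.linspace(5.0, 40.0, 50)
        es = [evalue(s, calib, 100) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_capped_at_db_size(self, calib):
        assert evalue(-100.0, calib, 42) == 42


class TestSearch:
    def test_seed_self_recovery(self, tiny_world, tiny_profile):
        comp = ResidueComposition.swissprot()
        calib = calibrate(tiny_profile, comp, decoy_count=100,
                          length_sampler=[len(s) for s in tiny_world.seed_family],
                          seed=1)
        hits = search(tiny_profile, tiny_world.seed_family, calib, 1e-5)
        assert {h.target_id for h in hits} == {s.id for s in tiny_world.seed_family}

    def test_sorted_by_evalue_then_id(self, tiny_world, tiny_profile):
        comp = ResidueComposition.swissprot()
        calib = calibrate(tiny_profile, comp, decoy_count=100, seed=1)
        hits = search(tiny_profile, tiny_world.database, calib, 10.0)
        keys = [(h.evalue, h.target_id) for h in hits]
        assert keys == sorted(keys)

    def test_empty_db(self, tiny_profile):
        calib = CalibrationParams(lam=0.7, tau=5.0, decoy_count=200, decoy_seed=0)
        assert search(tiny_profile, [], calib) == []

    def test_hit_invariants(self):
        with pytest.raises(ValueError):
            HmmHit("t", float("nan"), 1e-6, 1, 10)
        with pytest.raises(ValueError):
            HmmHit("t", 10.0, -1e-6, 1, 10)
        with pytest.raises(ValueError):
            HmmHit("t", 10.0, 1e-6, 5, 4)


class TestSerialization:
    def test_model_round_trip_scores(self, tiny_profile, tmp_path, rng):
        path = save_hmm(tiny_profile, tmp_path / "m.hmm")
        back = load_hmm(path)
        assert back.length == tiny_profile.length
        assert back.name == tiny_profile.name
        s = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        assert forward_score(back, s) == pytest.approx(
            forward_score(tiny_profile, s), abs=1e-3
        )

    def test_hits_tsv_round_trip(self, tmp_path):
        hits = [HmmHit("t1", 50.0, 1e-8, 1, 100), HmmHit("t2", 20.0, 1e-6, 1, 80)]
        path = write_hits_tsv(hits, tmp_path / "h.tsv")
        back = read_hits_tsv(path)
        assert [h.target_id for h in back] == ["t1", "t2"]
        assert back[0].evalue == pytest.approx(1e-8)

    def test_bad_file_rejected(self, tmp_path):
        p = tmp_path / "bad.hmm"
        p.write_text("not a model\n")
        with pytest.raises(ValueError):
            load_hmm(p)
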