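import pytest

from petmine.cluster import Cluster
from petmine.hmm import HmmHit
from petmine.selection import (CandidateRecord, PipelineConfig, aggregate_hits,
                               annotate, candidates_table, final_select,
                               select_representatives)
from petmine.seqio import AMINO_ACIDS, ProteinSequence, SiteMetadata


def seq(residues, sid):
    return ProteinSequence(id=sid, residues=residues)


def hit(tid, e, bits=50.0, length=100):
    return HmmHit(tid, bits, e, 1, length)


class TestAggregateHits:
    def test_identical_residues_merge_keep_min_evalue(self):
        seqs = {"a": seq("ACDEFGHIKL", "a"), "b": seq("ACDEFGHIKL", "b")}
        out = aggregate_hits(
            [("S1", [hit("a", 1e-8, 60.0, 10)]), ("S2", [hit("b", 1e-6, 40.0, 10)])],
            seqs,
        )
        assert len(out) == 1
        assert out[0].best_evalue == 1e-8
        assert out[0].bit_score == 60.0
        assert out[0].sample_ids == ["S1", "S2"]

    def test_no_duplicates_size_preserved(self):
        seqs = {f"s{i}": seq("ACDEFGHIKL"[: 5 + i] + "WY" * i, f"s{i}") for i in range(4)}
        out = aggregate_hits([("S1", [hit(f"s{i}", 10 ** -(6 + i)) for i in range(4)])], seqs)
        assert len(out) == 4
        assert [r.best_evalue for r in out] == sorted(r.best_evalue for r in out)

    def test_synthetic_batch_matches_hash_oracle(self, rng):
        pool = ["".join(rng.choice(list(AMINO_ACIDS), size=30)) for _ in range(40)]
        seqs, batches = {}, []
        hits = []
        for i in range(120):
            residues = pool[int(rng.integers(40))]
            sid = f"t{i}"
            seqs[sid] = seq(residues, sid)
            hits.append(hit(sid, float(10 ** -rng.uniform(5, 12))))
        batches = [("S1", hits[:60]), ("S2", hits[60:])]
        out = aggregate_hits(batches, seqs)
        assert len(out) == len({seqs[h.target_id].residues for h in hits})

    def test_unknown_sequence_rejected(self):
        with pytest.raises(KeyError):
            aggregate_hits([("S1", [hit("ghost", 1e-7)])], {})

    def test_idempotent(self):
        seqs = {"a": seq("ACDEFGHIKL", "a")}
        batches = [("S1", [hit("a", 1e-8)])]
        once = aggregate_hits(batches, seqs)
        assert len(once) == len(aggregate_hits(batches, seqs))


class TestSelectRepresentatives:
    def _candidates(self):
        return [
            CandidateRecord("a", "ACDEFGHIKL", 1e-10, 50.0),
            CandidateRecord("b", "ACDEFGHIKW", 1e-7, 40.0),
            CandidateRecord("c", "WWWWYYYYFF", 1e-6, 30.0),
        ]

    def test_min_evalue_flagged(self):
        cands = self._candidates()
        clusters = [
            Cluster("a", ["a", "b"], 0.4),
            Cluster("c", ["c"], 0.4),
        ]
        select_representatives(cands, clusters)
        flags = {c.sequence_id: c.is_representative for c in cands}
        assert flags == {"a": True, "b": False, "c": True}

    def test_singletons_all_flagged(self):
        cands = self._candidates()
        clusters = [Cluster(c.sequence_id, [c.sequence_id], 0.4) for c in cands]
        select_representatives(cands, clusters)
        assert all(c.is_representative for c in cands)

    def test_tie_broken_by_length_then_id(self):
        cands = [
            CandidateRecord("short", "ACDEFGHIKL", 1e-8, 50.0),
            CandidateRecord("longer", "ACDEFGHIKLMN", 1e-8, 50.0),
        ]
        select_representatives(cands, [Cluster("short", ["short", "longer"], 0.4)])
        assert {c.sequence_id: c.is_representative for c in cands} == {
            "short": False, "longer": True,
        }

    def test_unclustered_candidate_rejected(self):
        cands = self._candidates()
        with pytest.raises(KeyError):
            select_representatives(cands, [Cluster("a", ["a"], 0.4)])


class TestAnnotate:
    def test_identical_to_reference(self):
        cands = [CandidateRecord("a", "ACDEFGHIKL", 1e-8, 50.0, sample_ids=["S1"])]
        refs = [seq("ACDEFGHIKL", "ref1")]
        meta = [SiteMetadata("S1", 20.0, 38.0, 15.0, 20.0)]
        annotate(cands, refs, meta)
        assert cands[0].novelty_identity == pytest.approx(1.0)
        assert cands[0].nearest_reference == "ref1"
        assert cands[0].site_temperature_max_c == 38.0

    def test_hottest_site_wins(self):
        cands = [CandidateRecord("a", "ACDEFGHIKL", 1e-8, 50.0, sample_ids=["S1", "S2"])]
        meta = [
            SiteMetadata("S1", 20.0, 38.0, 15.0, 20.0),
            SiteMetadata("S2", 74.1, 115.0, 20.0, 30.0),
        ]
        annotate(cands, [seq("WWWWYYYYFF", "r")], meta)
        assert cands[0].site_temperature_max_c == 115.0

    def test_missing_metadata_leaves_temperature_absent(self):
        cands = [CandidateRecord("a", "ACDEFGHIKL", 1e-8, 50.0, sample_ids=["S9"])]
        annotate(cands, [seq("ACDEFGHIKL", "r")], [])
        assert cands[0].site_temperature_max_c is None

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            annotate([], [], [])


class TestFinalSelect:
    def _reps(self, n, novelty=0.3):
        out = []
        for i in range(n):
            rec = CandidateRecord(f"r{i:02d}", "ACDEFGHIKL", 10 ** -(6 + i), 50.0)
            rec.is_representative = True
            rec.novelty_identity = novelty
            out.append(rec)
        return out

    def test_exactly_top_n_selected(self):
        records = self._reps(32)
        ranking = [(f"r{i:02d}", "ref", 0.9 - 0.01 * i) for i in range(32)]
        final_select(records, ranking, PipelineConfig(top_n=22))
        assert sum(r.selected for r in records) == 22

    def test_novelty_ceiling_excludes_before_ranking(self):
        records = self._reps(3)
        records[0].novelty_identity = 0.70  # best TM but too close to known enzymes
        ranking = [("r00", "ref", 0.99), ("r01", "ref", 0.5), ("r02", "ref", 0.4)]
        final_select(records, ranking, PipelineConfig(top_n=2, novelty_max_identity=0.65))
        assert [r.sequence_id for r in records if r.selected] == ["r01", "r02"]

    def test_all_tm_absent_falls_back_to_evalue(self):
        records = self._reps(5)
        final_select(records, None, PipelineConfig(top_n=2))
        selected = {r.sequence_id for r in records if r.selected}
        by_e = sorted(records, key=lambda r: r.best_evalue)[:2]
        assert selected == {r.sequence_id for r in by_e}

    def test_clamp_when_top_n_exceeds_reps(self):
        records = self._reps(5)
        final_select(records, None, PipelineConfig(top_n=22))
        assert sum(r.selected for r in records) == 5

    def test_non_representatives_never_selected(self):
        records = self._reps(3)
        records[1].is_representative = False
        final_select(records, None, PipelineConfig(top_n=3))
        assert not records[1].selected


class TestConfig:
    def test_defaults_round_trip(self, tmp_path):
        cfg = PipelineConfig()
        path = cfg.to_file(tmp_path / "run.cfg")
        assert PipelineConfig.from_file(path) == cfg

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(seed_cluster_identity=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(top_n=0)
        with pytest.raises(ValueError):
            PipelineConfig(evalue_cutoff=0.0)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("nonsense: 1\n")
        with pytest.raises(ValueError):
            PipelineConfig.from_file(p)


def test_candidates_table_columns():
    rec = CandidateRecord("a", "ACDEFGHIKL", 1e-8, 50.0)
    table = candidates_table([rec])
    assert list(table.columns)[:5] == [
        "id", "best_evalue", "bit_score", "cluster_id", "is_representative",
    ]
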