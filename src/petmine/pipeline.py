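"""Config-driven orchestration of the full mining pipeline.

Stages (seed clustering -> seed MSA -> profile build -> decoy calibration
-> database search -> hit aggregation -> candidate clustering ->
representative picking -> annotation -> optional structural triage ->
final selection) are independent functions that communicate only through
files in the run directory, so composing the stage commands reproduces a
monolithic :func:`run_pipeline` exactly.  Every stage is deterministic
given the config's random seed.

Sample-of-origin is carried in FASTA descriptions as a ``sample=<id>``
token and resolved against the site metadata table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import cluster as _cluster
from . import hmm as _hmm
from . import msa as _msa
from . import physchem as _physchem
from . import selection as _selection
from . import seqio as _seqio
from . import structure as _structure
from .selection import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing upstream artifact {path}")
    return path


def _sample_of(seq: _seqio.ProteinSequence) -> str | None:
    if seq.sample_id:
        return seq.sample_id
    for token in seq.description.split():
        if token.startswith("sample="):
            return token[len("sample="):] or None
    return None


@dataclass
class RunManifest:
    """Machine-readable run summary: config, input checksums, stage counts."""

    config: dict
    input_checksums: dict[str, str]
    counts: dict[str, int | list[int]]
    log_file: str = "run.log"

    def validate(self) -> None:
        c = self.counts
        if not (
            c["selected"] <= c["representatives"] <= c["unique_candidates"]
            <= c["hit_targets"]
        ):
            raise ValueError("manifest count invariants violated")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_cluster_seeds(config: PipelineConfig, seed_fasta: str | Path,
                        outdir: str | Path) -> list[_cluster.Cluster]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _seqio.read_fasta(_require("cluster-seeds", Path(seed_fasta)))
    logger.info("[cluster-seeds] %d seed sequences", len(seeds))
    clusters = _cluster.greedy_cluster(
        seeds, config.seed_cluster_identity, config.cluster_identity_mode
    )
    _cluster.write_clusters_tsv(clusters, outdir / "seed_clusters.tsv")
    _cluster.write_clstr(clusters, {s.id: len(s) for s in seeds},
                         outdir / "seed_clusters.clstr")
    logger.info("[cluster-seeds] %d clusters at %.0f%% identity",
                len(clusters), 100 * config.seed_cluster_identity)
    return clusters


def _profile_cluster_ids(config: PipelineConfig,
                         clusters: list[_cluster.Cluster]) -> list[int]:
    if config.profile_scope == "largest":
        return [clusters.index(_cluster.largest_cluster(clusters))]
    ids = [i for i, cl in enumerate(clusters) if len(cl) >= 2]
    if not ids:
        ids = [clusters.index(_cluster.largest_cluster(clusters))]
    return ids


def stage_build_profiles(config: PipelineConfig, seed_fasta: str | Path,
                         outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    seeds = {s.id: s for s in _seqio.read_fasta(Path(seed_fasta))}
    clusters = _cluster.read_clusters_tsv(
        _require("build-profile", outdir / "seed_clusters.tsv"),
        config.seed_cluster_identity,
    )
    paths = []
    for cid in _profile_cluster_ids(config, clusters):
        members = [seeds[m] for m in clusters[cid].members]
        if len(members) == 1:
            msa = _msa.MSA([(members[0].id, members[0].residues)])
            msa.match_mask = np.ones(msa.columns, dtype=bool)
        else:
            msa = _msa.progressive_align(members)
            msa.match_mask = _msa.assign_match_columns(
                msa, config.gap_fraction_threshold
            )
        _msa.write_aligned_fasta(msa, outdir / f"seed_msa_{cid:03d}.afa")
        _msa.write_stockholm(msa, outdir / f"seed_msa_{cid:03d}.sto")
        profile = _hmm.build_profile(
            msa,
            pseudocount_weight=config.pseudocount_weight,
            name=f"seed_cluster_{cid:03d}",
        )
        path = _hmm.save_hmm(profile, outdir / f"profile_{cid:03d}.hmm")
        logger.info("[build-profile] cluster %d: %d sequences -> M=%d",
                    cid, len(members), profile.length)
        paths.append(path)
    return paths


def _profiles_in(outdir: Path, stage: str) -> list[Path]:
    paths = sorted(outdir.glob("profile_*.hmm"))
    if not paths:
        raise StageError(stage, f"no profile_*.hmm found in {outdir}")
    return paths


def stage_calibrate(config: PipelineConfig, database_fasta: str | Path,
                    outdir: str | Path) -> None:
    outdir = Path(outdir)
    db = _seqio.read_fasta(_require("calibrate", Path(database_fasta)))
    composition = _seqio.residue_composition(db)
    lengths = [len(s) for s in db]
    for path in _profiles_in(outdir, "calibrate"):
        profile = _hmm.load_hmm(path)
        calib = _hmm.calibrate(
            profile, composition, decoy_count=config.decoy_count,
            length_sampler=lengths, seed=config.random_seed,
        )
        calib.to_json(outdir / (path.stem.replace("profile", "calibration") + ".json"))
        logger.info("[calibrate] %s: lambda=%.3f tau=%.2f bits",
                    path.stem, calib.lam, calib.tau)


def stage_search(config: PipelineConfig, database_fasta: str | Path,
                 outdir: str | Path) -> list[_hmm.HmmHit]:
    outdir = Path(outdir)
    db = _seqio.read_fasta(_require("search", Path(database_fasta)))
    merged: dict[str, _hmm.HmmHit] = {}
    for path in _profiles_in(outdir, "search"):
        profile = _hmm.load_hmm(path)
        calib_path = _require(
            "search", outdir / (path.stem.replace("profile", "calibration") + ".json")
        )
        calib = _hmm.CalibrationParams.from_json(calib_path)
        hits = _hmm.search(profile, db, calib, config.evalue_cutoff)
        _hmm.write_hits_tsv(hits, outdir / (path.stem.replace("profile", "hits") + ".tsv"))
        _hmm.write_domtbl(hits, profile,
                          outdir / (path.stem.replace("profile", "domtbl") + ".txt"))
        logger.info("[search] %s: %d hits at E<=%g", path.stem, len(hits),
                    config.evalue_cutoff)
        for h in hits:
            old = merged.get(h.target_id)
            if old is None or (h.evalue, -h.bit_score) < (old.evalue, -old.bit_score):
                merged[h.target_id] = h
    hits = sorted(merged.values(), key=lambda h: (h.evalue, h.target_id))
    _hmm.write_hits_tsv(hits, outdir / "hits.tsv")
    logger.info("[search] %d unique hit targets", len(hits))
    return hits


def stage_diversify(config: PipelineConfig, database_fasta: str | Path,
                    outdir: str | Path) -> list[_selection.CandidateRecord]:
    outdir = Path(outdir)
    db = {s.id: s for s in _seqio.read_fasta(Path(database_fasta))}
    hits = _hmm.read_hits_tsv(_require("diversify", outdir / "hits.tsv"))
    batches: dict[str, list[_hmm.HmmHit]] = {}
    for h in hits:
        sample = _sample_of(db[h.target_id]) or ""
        batches.setdefault(sample, []).append(h)
    candidates = _selection.aggregate_hits(
        sorted(batches.items()), db
    )
    logger.info("[diversify] %d unique candidates from %d hits",
                len(candidates), len(hits))
    cand_seqs = [
        _seqio.ProteinSequence(id=c.sequence_id, residues=c.residues)
        for c in candidates
    ]
    if cand_seqs:
        clusters = _cluster.greedy_cluster(
            cand_seqs, config.candidate_cluster_identity, config.cluster_identity_mode
        )
        _selection.select_representatives(candidates, clusters)
    else:
        clusters = []
    _cluster.write_clusters_tsv(clusters, outdir / "candidate_clusters.tsv")
    _seqio.write_fasta(cand_seqs, outdir / "candidates.fasta")
    _selection.write_candidates_tsv(candidates, outdir / "candidates.tsv")
    logger.info("[diversify] %d clusters at %.0f%% identity", len(clusters),
                100 * config.candidate_cluster_identity)
    return candidates


def _load_candidates(config: PipelineConfig, outdir: Path, stage: str
                     ) -> list[_selection.CandidateRecord]:
    import pandas as pd

    df = pd.read_csv(_require(stage, outdir / "candidates.tsv"), sep="\t")
    seqs = {s.id: s for s in _seqio.read_fasta(
        _require(stage, outdir / "candidates.fasta"))}
    records = []
    for r in df.itertuples(index=False):
        records.append(
            _selection.CandidateRecord(
                sequence_id=r.id,
                residues=seqs[r.id].residues,
                best_evalue=float(r.best_evalue),
                bit_score=float(r.bit_score),
                sample_ids=[] if pd.isna(r.sample_ids) else str(r.sample_ids).split(","),
                cluster_id=None if pd.isna(r.cluster_id) else int(r.cluster_id),
                is_representative=bool(r.is_representative),
                novelty_identity=None if pd.isna(r.novelty_identity)
                else float(r.novelty_identity),
                nearest_reference=None if pd.isna(r.nearest_reference)
                else str(r.nearest_reference),
                site_temperature_max_c=None if pd.isna(r.site_temp_max_c)
                else float(r.site_temp_max_c),
                structure_tm=None if pd.isna(r.structure_tm)
                else float(r.structure_tm),
                selected=bool(r.selected),
            )
        )
    return records


def stage_annotate(config: PipelineConfig, seed_fasta: str | Path,
                   metadata_tsv: str | Path | None,
                   outdir: str | Path) -> list[_selection.CandidateRecord]:
    outdir = Path(outdir)
    candidates = _load_candidates(config, outdir, "annotate")
    references = _seqio.read_fasta(Path(seed_fasta))
    metadata = (
        _seqio.read_site_metadata(metadata_tsv) if metadata_tsv is not None else []
    )
    _selection.annotate(candidates, references, metadata,
                        mode=config.novelty_identity_mode)
    _selection.write_candidates_tsv(candidates, outdir / "candidates.tsv")
    logger.info("[annotate] %d candidates annotated against %d references",
                len(candidates), len(references))
    return candidates


def stage_triage(config: PipelineConfig, structures_dir: str | Path,
                 reference_structures_dir: str | Path,
                 outdir: str | Path) -> None:
    outdir = Path(outdir)
    candidates = _load_candidates(config, outdir, "triage")
    structures_dir = Path(structures_dir)
    reps = [c for c in candidates if c.is_representative]
    models = []
    for c in reps:
        pdb = structures_dir / f"{c.sequence_id}.pdb"
        if pdb.exists():
            models.append(_structure.read_ca_coordinates(pdb))
        else:
            logger.warning("[triage] no structure for representative %s",
                           c.sequence_id)
    refs = [
        _structure.read_ca_coordinates(p)
        for p in sorted(Path(reference_structures_dir).glob("*.pdb"))
    ]
    if not refs:
        raise StageError("triage", "no reference structures (*.pdb) found")
    table = _structure.triage_table(models, refs)
    table.to_csv(outdir / "triage.tsv", sep="\t", index=False, float_format="%.6g")
    logger.info("[triage] %d candidate structures against %d references",
                len(models), len(refs))


def stage_select(config: PipelineConfig, outdir: str | Path
                 ) -> list[_selection.CandidateRecord]:
    import pandas as pd

    outdir = Path(outdir)
    candidates = _load_candidates(config, outdir, "select")
    ranking = None
    triage_path = outdir / "triage.tsv"
    if triage_path.exists():
        df = pd.read_csv(triage_path, sep="\t")
        ranking = [
            (str(r.candidate), str(r.best_reference), float(r.tm_score))
            for r in df.itertuples(index=False)
        ]
    _selection.final_select(candidates, ranking, config)
    _selection.write_candidates_tsv(candidates, outdir / "candidates.tsv")
    _selection.write_candidates_tsv(
        [c for c in candidates], outdir / "final_candidates.tsv"
    )
    n_sel = sum(c.selected for c in candidates)
    logger.info("[select] %d of %d representatives selected (top_n=%d)",
                n_sel, sum(c.is_representative for c in candidates), config.top_n)
    return candidates


def stage_properties(config: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    candidates = _load_candidates(config, outdir, "properties")
    pka = _physchem.PKA_SETS[config.pka_set]
    selected = [
        _seqio.ProteinSequence(id=c.sequence_id, residues=c.residues)
        for c in candidates
        if c.selected
    ]
    table = _physchem.properties_table(selected, pka)
    table.to_csv(outdir / "properties.tsv", sep="\t", index=False,
                 float_format="%.4f")
    logger.info("[properties] %d selected candidates", len(selected))


# ---------------------------------------------------------------------------
# monolithic run


def run_pipeline(
    config: PipelineConfig,
    seed_fasta: str | Path,
    database_fasta: str | Path,
    metadata_tsv: str | Path | None = None,
    structures_dir: str | Path | None = None,
    reference_structures_dir: str | Path | None = None,
    outdir: str | Path = "petmine_run",
) -> RunManifest:
    """Run every stage in order; returns the validated run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clusters = stage_cluster_seeds(config, seed_fasta, outdir)
    profile_paths = stage_build_profiles(config, seed_fasta, outdir)
    stage_calibrate(config, database_fasta, outdir)
    hits = stage_search(config, database_fasta, outdir)
    candidates = stage_diversify(config, database_fasta, outdir)
    stage_annotate(config, seed_fasta, metadata_tsv, outdir)
    if structures_dir is not None and reference_structures_dir is not None:
        stage_triage(config, structures_dir, reference_structures_dir, outdir)
    records = stage_select(config, outdir)
    stage_properties(config, outdir)

    seeds = _seqio.read_fasta(seed_fasta)
    db_n = len(_seqio.read_fasta(database_fasta))
    profile_lengths = [_hmm.load_hmm(p).length for p in profile_paths]
    checksums = {"seed_fasta": _sha256(seed_fasta),
                 "database_fasta": _sha256(database_fasta)}
    if metadata_tsv is not None:
        checksums["metadata_tsv"] = _sha256(metadata_tsv)
    n_clusters = len(
        _cluster.read_clusters_tsv(outdir / "candidate_clusters.tsv",
                                   config.candidate_cluster_identity)
    )
    manifest = RunManifest(
        config={k: v for k, v in asdict(config).items()},
        input_checksums=checksums,
        counts={
            "seed_sequences": len(seeds),
            "seed_clusters": len(clusters),
            "profiles": len(profile_paths),
            "profile_lengths": profile_lengths,
            "database_size": db_n,
            "hit_targets": len(hits),
            "unique_candidates": len(candidates),
            "candidate_clusters": n_clusters,
            "representatives": sum(r.is_representative for r in records),
            "selected": sum(r.selected for r in records),
        },
    )
    manifest.validate()
    manifest.to_json(outdir / "manifest.json")
    return manifest
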