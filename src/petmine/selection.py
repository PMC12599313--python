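"""Candidate aggregation, representative picking, annotation, final selection.

This codifies the down-selection logic of the bioprospecting pipeline:
hits from per-sample searches are deduplicated on exact residue-string
equality (keeping the best E-value and all source samples), diversified
by identity clustering, reduced to the lowest-E representative per
cluster, annotated with novelty (max identity to the reference enzymes)
and the hottest linked sampling-site temperature, and finally ranked.
The default final ranking applies a hard novelty ceiling, then orders by
structural similarity (TM-score) with E-value as tie-break; temperature
is carried as annotation rather than a filter.  All thresholds live in
:class:`PipelineConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import ScoringScheme, max_identity_to_references
from .cluster import Cluster
from .hmm import HmmHit
from .seqio import ProteinSequence, SiteMetadata

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, with its default."""

    seed_cluster_identity: float = 0.30
    candidate_cluster_identity: float = 0.40
    evalue_cutoff: float = 1e-5
    top_n: int = 22
    novelty_max_identity: float = 0.65
    gap_fraction_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    decoy_count: int = 50_000
    random_seed: int = 0
    cluster_identity_mode: str = "shorter"
    novelty_identity_mode: str = "alignment"
    pka_set: str = "bjellqvist"
    profile_scope: str = "ge2"  # "ge2": one profile per seed cluster of size >= 2

    def __post_init__(self) -> None:
        for name in ("seed_cluster_identity", "candidate_cluster_identity",
                     "novelty_max_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0.0 < self.gap_fraction_threshold <= 1.0):
            raise ValueError("gap_fraction_threshold must be in (0, 1]")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.decoy_count < 50:
            raise ValueError("decoy_count must be >= 50")
        if self.profile_scope not in ("ge2", "largest"):
            raise ValueError("profile_scope must be 'ge2' or 'largest'")

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in fields(self)]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value.strip())
        return cls(**kwargs)


@dataclass
class CandidateRecord:
    """An annotated pipeline candidate."""

    sequence_id: str
    residues: str
    best_evalue: float
    bit_score: float
    sample_ids: list[str] = field(default_factory=list)
    cluster_id: int | None = None
    is_representative: bool = False
    novelty_identity: float | None = None
    nearest_reference: str | None = None
    site_temperature_max_c: float | None = None
    structure_tm: float | None = None
    selected: bool = False

    def __post_init__(self) -> None:
        if self.best_evalue < 0:
            raise ValueError("best_evalue must be non-negative")
        if self.selected and not self.is_representative:
            raise ValueError("only representatives can be selected")


def aggregate_hits(
    hit_batches: Sequence[tuple[str, Sequence[HmmHit]]],
    sequences: dict[str, ProteinSequence],
) -> list[CandidateRecord]:
    """Merge per-sample hit lists into unique candidates.

    Candidates with identical residue strings are merged, keeping the
    minimum E-value (and its bit score) and recording every source
    sample.  Output is sorted by ascending E-value then id.
    """
    by_residues: dict[str, CandidateRecord] = {}
    for sample_id, hits in hit_batches:
        for h in hits:
            seq = sequences.get(h.target_id)
            if seq is None:
                raise KeyError(f"hit references unknown sequence {h.target_id!r}")
            rec = by_residues.get(seq.residues)
            if rec is None:
                rec = CandidateRecord(
                    sequence_id=seq.id,
                    residues=seq.residues,
                    best_evalue=h.evalue,
                    bit_score=h.bit_score,
                )
                by_residues[seq.residues] = rec
            if h.evalue < rec.best_evalue or (
                h.evalue == rec.best_evalue and h.bit_score > rec.bit_score
            ):
                rec.best_evalue = h.evalue
                rec.bit_score = h.bit_score
            if sample_id not in rec.sample_ids:
                rec.sample_ids.append(sample_id)
    out = sorted(by_residues.values(), key=lambda r: (r.best_evalue, r.sequence_id))
    return out


def select_representatives(
    candidates: list[CandidateRecord], clusters: Sequence[Cluster]
) -> list[CandidateRecord]:
    """Flag the minimum-E candidate in each cluster as its representative.

    Ties on E-value break toward the longer sequence, then lexicographic id.
    """
    by_id = {c.sequence_id: c for c in candidates}
    clustered: set[str] = set()
    for cid, cl in enumerate(clusters):
        members = []
        for mid in cl.members:
            rec = by_id.get(mid)
            if rec is None:
                raise KeyError(f"cluster member {mid!r} is not a candidate")
            rec.cluster_id = cid
            rec.is_representative = False
            clustered.add(mid)
            members.append(rec)
        rep = min(
            members,
            key=lambda r: (r.best_evalue, -len(r.residues), r.sequence_id),
        )
        rep.is_representative = True
    missing = set(by_id) - clustered
    if missing:
        raise KeyError(f"candidates missing from all clusters: {sorted(missing)[:5]}")
    return candidates


def annotate(
    candidates: list[CandidateRecord],
    references: Sequence[ProteinSequence],
    metadata: Sequence[SiteMetadata],
    mode: str = "alignment",
    scheme: ScoringScheme | None = None,
) -> list[CandidateRecord]:
    """Attach novelty identity and hottest linked site temperature."""
    if not references:
        raise ValueError("reference set is empty")
    sites = {m.sample_id: m for m in metadata}
    refs = list(references)
    for rec in candidates:
        query = ProteinSequence(id=rec.sequence_id, residues=rec.residues)
        ref_id, pid = max_identity_to_references(query, refs, mode, scheme)
        rec.nearest_reference = ref_id
        rec.novelty_identity = pid
        temps = [
            sites[s].temperature_max_c for s in rec.sample_ids if s in sites
        ]
        if temps:
            rec.site_temperature_max_c = max(temps)
        else:
            rec.site_temperature_max_c = None
            if rec.sample_ids:
                logger.warning(
                    "candidate %s: no metadata for samples %s",
                    rec.sequence_id, rec.sample_ids,
                )
    return candidates


def final_select(
    records: list[CandidateRecord],
    structure_ranking: Sequence[tuple[str, str, float]] | None,
    config: PipelineConfig,
) -> list[CandidateRecord]:
    """Flag the final top-N candidates.

    Representatives above the novelty ceiling are dropped; the rest are
    ordered by TM-score descending (candidates without structures last),
    with ascending E-value then id as tie-breaks.
    """
    tm_by_id = {}
    for cand_id, _, tm in structure_ranking or []:
        tm_by_id[cand_id] = tm
    for rec in records:
        rec.selected = False
        if rec.sequence_id in tm_by_id:
            rec.structure_tm = tm_by_id[rec.sequence_id]
    eligible = [
        r
        for r in records
        if r.is_representative
        and (r.novelty_identity is None
             or r.novelty_identity <= config.novelty_max_identity)
    ]
    eligible.sort(
        key=lambda r: (
            -(r.structure_tm if r.structure_tm is not None else -1.0),
            r.best_evalue,
            r.sequence_id,
        )
    )
    n_rep = len(eligible)
    if config.top_n > n_rep:
        logger.warning(
            "top_n=%d exceeds eligible representatives (%d); selecting all",
            config.top_n, n_rep,
        )
    for rec in eligible[: config.top_n]:
        rec.selected = True
    return records


def candidates_table(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    rows = [
        (
            r.sequence_id, r.best_evalue, r.bit_score, r.cluster_id,
            r.is_representative,
            r.novelty_identity, r.nearest_reference,
            r.site_temperature_max_c, r.structure_tm, r.selected,
            ",".join(r.sample_ids),
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "best_evalue", "bit_score", "cluster_id", "is_representative",
            "novelty_identity", "nearest_reference", "site_temp_max_c",
            "structure_tm", "selected", "sample_ids",
        ],
    )


def write_candidates_tsv(records: Sequence[CandidateRecord], path: str | Path) -> Path:
    path = Path(path)
    candidates_table(records).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
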