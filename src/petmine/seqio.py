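"""Protein sequence domain types, FASTA I/O and composition utilities.

The toolkit operates on predicted proteins from metagenomic scaffolds, so
ingestion is deliberately permissive: ambiguous one-letter codes (B, Z, J)
and the rare translated residues (U, O) are mapped to ``X`` with a warning,
and a single trailing ``*`` (translated stop) is stripped.  Anything else
non-standard fails loudly — internal stops usually flag frameshifted ORFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The canonical 20 amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Alphabet accepted in :class:`ProteinSequence` residues.
ALPHABET = AMINO_ACIDS + "X"
#: Codes silently (well, loudly-logged) converted to X on ingestion.
_AMBIGUOUS = set("BZUOJ")

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Average Swiss-Prot residue frequencies (UniProtKB release statistics),
#: used as the default background for null models and simulation.
BACKGROUND_FREQUENCIES = {
    "A": 0.0826, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


class FastaFormatError(ValueError):
    """Raised when a FASTA record violates the protein-sequence contract."""


@dataclass
class ProteinSequence:
    """A protein sequence with optional sample-of-origin link.

    ``residues`` must be uppercase over the 20 standard amino acids plus X.
    """

    id: str
    residues: str
    description: str = ""
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if not self.residues.isupper():
            raise ValueError(f"sequence {self.id!r} residues must be uppercase")
        for pos, c in enumerate(self.residues, start=1):
            if c not in ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: illegal residue {c!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteMetadata:
    """Per-sample site description: temperature range and sediment depth."""

    sample_id: str
    temperature_min_c: float
    temperature_max_c: float
    depth_cm_min: float
    depth_cm_max: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.temperature_min_c > self.temperature_max_c:
            raise ValueError(f"{self.sample_id}: temperature_min_c > temperature_max_c")
        if self.depth_cm_min < 0 or self.depth_cm_max < 0:
            raise ValueError(f"{self.sample_id}: depths must be non-negative")


@dataclass(frozen=True)
class ResidueComposition:
    """Frequencies over the 20 standard residues; sums to one."""

    frequencies: tuple[float, ...]  # indexed by AA_INDEX

    def __post_init__(self) -> None:
        arr = np.asarray(self.frequencies, dtype=float)
        if arr.shape != (20,):
            raise ValueError("composition needs exactly 20 frequencies")
        if (arr < 0).any():
            raise ValueError("negative frequency")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {arr.sum()!r}, not 1")

    @classmethod
    def from_dict(cls, freqs: dict[str, float]) -> "ResidueComposition":
        total = sum(freqs.values())
        return cls(tuple(freqs.get(aa, 0.0) / total for aa in AMINO_ACIDS))

    @classmethod
    def uniform(cls) -> "ResidueComposition":
        return cls(tuple([0.05] * 20))

    @classmethod
    def swissprot(cls) -> "ResidueComposition":
        return cls.from_dict(BACKGROUND_FREQUENCIES)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)

    def frequency(self, residue: str) -> float:
        return self.frequencies[AA_INDEX[residue]]


def _clean_residues(record_id: str, raw: str) -> str:
    seq = "".join(raw.split()).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise FastaFormatError(f"record {record_id!r} has an empty sequence")
    cleaned = []
    n_ambiguous = 0
    for pos, c in enumerate(seq, start=1):
        if c in ALPHABET:
            cleaned.append(c)
        elif c in _AMBIGUOUS:
            cleaned.append("X")
            n_ambiguous += 1
        elif c == "*":
            raise FastaFormatError(
                f"record {record_id!r}: internal stop '*' at position {pos}"
            )
        else:
            raise FastaFormatError(
                f"record {record_id!r}: illegal character {c!r} at position {pos}"
            )
    if n_ambiguous:
        logger.warning(
            "record %r: %d non-standard residue(s) (B/Z/U/O/J) mapped to X",
            record_id, n_ambiguous,
        )
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file into validated :class:`ProteinSequence` records."""
    path = Path(path)
    seqs: list[ProteinSequence] = []
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            desc = record.description
            if desc.startswith(record.id):
                desc = desc[len(record.id):].strip()
            seqs.append(
                ProteinSequence(
                    id=record.id,
                    residues=_clean_residues(record.id, str(record.seq)),
                    description=desc,
                )
            )
    return seqs


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path, wrap: int = 60) -> Path:
    """Write sequences to ``path`` in FASTA, wrapping at ``wrap`` columns."""
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    path = Path(path)
    with open(path, "w") as out:
        for s in seqs:
            header = s.id if not s.description else f"{s.id} {s.description}"
            out.write(f">{header}\n")
            for i in range(0, len(s.residues), wrap):
                out.write(s.residues[i:i + wrap] + "\n")
    return path


def residue_composition(seqs: Iterable[ProteinSequence]) -> ResidueComposition:
    """Empirical residue frequencies over all sequences, X excluded."""
    counts = np.zeros(20, dtype=float)
    for s in seqs:
        for c in s.residues:
            if c != "X":
                counts[AA_INDEX[c]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable residues (input is empty or all-X)")
    return ResidueComposition(tuple(counts / total))


def shuffle_sequence(seq: ProteinSequence, seed: int) -> ProteinSequence:
    """Return a residue-shuffled copy (null-model decoy); deterministic per seed."""
    rng = np.random.default_rng(seed)
    residues = "".join(rng.permutation(list(seq.residues)))
    return replace(seq, id=f"{seq.id}|shuf{seed}", residues=residues)


METADATA_COLUMNS = [
    "sample_id", "temp_min_c", "temp_max_c", "depth_min_cm", "depth_max_cm", "label",
]


def read_site_metadata(path: str | Path) -> list[SiteMetadata]:
    """Read the tab-separated site metadata table (see :data:`METADATA_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "label": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SiteMetadata(
                sample_id=row.sample_id,
                temperature_min_c=float(row.temp_min_c),
                temperature_max_c=float(row.temp_max_c),
                depth_cm_min=float(row.depth_min_cm),
                depth_cm_max=float(row.depth_max_cm),
                label="" if pd.isna(row.label) else str(row.label),
            )
        )
    return out


def write_site_metadata(sites: Sequence[SiteMetadata], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            (s.sample_id, s.temperature_min_c, s.temperature_max_c,
             s.depth_cm_min, s.depth_cm_max, s.label)
            for s in sites
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return path
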