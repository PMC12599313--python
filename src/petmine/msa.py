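"""Progressive multiple sequence alignment for seed-family profiles.

The seed cluster is aligned by UPGMA-guided progressive profile–profile
alignment: pairwise identity distances -> average-linkage guide tree ->
post-order merge of sub-alignments, scoring profile columns by the
sum-of-pairs expected substitution score with affine gaps.  This is a
deterministic stand-in for the usual iterative aligners, adequate for a
seed family sharing >= 30% identity.  Match columns for profile
construction follow the standard rule: a column is a match column when
its gap fraction is below a threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .align import (ScoringScheme, align_score_matrix, blosum62_scheme,
                    global_align, percent_identity)
from .seqio import ProteinSequence

#: Index of the gap channel in profile frequency matrices (after 20 aa + X).
GAP_CHANNEL = 21


@dataclass
class MSA:
    """A multiple sequence alignment: rows of (sequence id, aligned string)."""

    rows: list[tuple[str, str]]
    match_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA has no rows")
        ncols = len(self.rows[0][1])
        for rid, aligned in self.rows:
            if len(aligned) != ncols:
                raise ValueError(f"row {rid!r} length differs from first row")
        for j in range(ncols):
            if all(aligned[j] == "-" for _, aligned in self.rows):
                raise ValueError(f"column {j + 1} is all-gap")

    @property
    def columns(self) -> int:
        return len(self.rows[0][1])

    def degapped(self, row_id: str) -> str:
        for rid, aligned in self.rows:
            if rid == row_id:
                return aligned.replace("-", "")
        raise KeyError(row_id)

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]


@dataclass
class GuideTree:
    """Rooted binary guide tree; leaves carry sequence ids, internal nodes heights."""

    label: str | None = None
    height: float = 0.0
    children: tuple["GuideTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def identity_distance_matrix(
    seqs: Sequence[ProteinSequence], scheme: ScoringScheme | None = None
) -> np.ndarray:
    """d(i, j) = 1 - alignment-mode identity of the optimal global alignment."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(global_align(seqs[i], seqs[j], scheme), "alignment")
            d[i, j] = d[j, i] = 1.0 - pid
    return d


def upgma_tree(dist: np.ndarray, labels: Sequence[str]) -> GuideTree:
    """Average-linkage (UPGMA) guide tree; node height = merge distance / 2."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label mismatch")
    if n == 1:
        return GuideTree(label=labels[0])
    Z = linkage(squareform(dist, checks=False), method="average")
    nodes = [GuideTree(label=lab) for lab in labels]
    for a, b, d, _ in Z:
        nodes.append(
            GuideTree(height=d / 2.0, children=(nodes[int(a)], nodes[int(b)]))
        )
    return nodes[-1]


def _profile_weight_matrix(scheme: ScoringScheme) -> np.ndarray:
    """22x22 column-pair score table: residues/X per the scheme, gaps at -gap_extend."""
    W = np.zeros((22, 22))
    W[:21, :21] = scheme.matrix
    W[GAP_CHANNEL, :21] = -scheme.gap_extend
    W[:21, GAP_CHANNEL] = -scheme.gap_extend
    W[GAP_CHANNEL, GAP_CHANNEL] = 0.0
    return W


def _profile_frequencies(rows: list[tuple[str, str]]) -> np.ndarray:
    from .align import _sym_index

    ncols = len(rows[0][1])
    F = np.zeros((ncols, 22))
    for _, aligned in rows:
        for j, c in enumerate(aligned):
            F[j, GAP_CHANNEL if c == "-" else _sym_index(c)] += 1.0
    return F / len(rows)


def _merge(rows_a: list[tuple[str, str]], rows_b: list[tuple[str, str]],
           scheme: ScoringScheme) -> list[tuple[str, str]]:
    W = _profile_weight_matrix(scheme)
    FA = _profile_frequencies(rows_a)
    FB = _profile_frequencies(rows_b)
    S = FA @ W @ FB.T
    _, moves = align_score_matrix(S, scheme.gap_open, scheme.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for di, dj in moves:
        for k, (_, aligned) in enumerate(rows_a):
            out_a[k] += aligned[i] if di else "-"
        for k, (_, aligned) in enumerate(rows_b):
            out_b[k] += aligned[j] if dj else "-"
        i += di
        j += dj
    merged = [(rid, out_a[k]) for k, (rid, _) in enumerate(rows_a)]
    merged += [(rid, out_b[k]) for k, (rid, _) in enumerate(rows_b)]
    return merged


def progressive_align(
    seqs: Sequence[ProteinSequence],
    tree: GuideTree | None = None,
    scheme: ScoringScheme | None = None,
) -> MSA:
    """Align ``seqs`` progressively along ``tree`` (computed by UPGMA if absent)."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    scheme = scheme or blosum62_scheme()
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate sequence ids")
    if tree is None:
        tree = upgma_tree(identity_distance_matrix(seqs, scheme), [s.id for s in seqs])
    if sorted(tree.leaves()) != sorted(by_id):
        raise ValueError("guide tree leaves do not match input sequences")

    def rec(node: GuideTree) -> list[tuple[str, str]]:
        if node.is_leaf:
            return [(node.label, by_id[node.label].residues)]
        left = rec(node.children[0])
        for child in node.children[1:]:
            left = _merge(left, rec(child), scheme)
        return left

    rows = rec(tree)
    # restore input order
    order = {s.id: k for k, s in enumerate(seqs)}
    rows.sort(key=lambda r: order[r[0]])
    msa = MSA(rows)
    msa.match_mask = assign_match_columns(msa)
    return msa


def assign_match_columns(msa: MSA, gap_fraction_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask: True where the column's gap fraction is below threshold."""
    if not (0.0 < gap_fraction_threshold <= 1.0):
        raise ValueError("gap_fraction_threshold must be in (0, 1]")
    nrows = len(msa.rows)
    mask = np.empty(msa.columns, dtype=bool)
    for j in range(msa.columns):
        gaps = sum(1 for _, aligned in msa.rows if aligned[j] == "-")
        mask[j] = gaps / nrows < gap_fraction_threshold
    return mask


def write_aligned_fasta(msa: MSA, path: str | Path, wrap: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for rid, aligned in msa.rows:
            out.write(f">{rid}\n")
            for i in range(0, len(aligned), wrap):
                out.write(aligned[i:i + wrap] + "\n")
    return path


def read_aligned_fasta(path: str | Path) -> MSA:
    rows: list[tuple[str, str]] = []
    rid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if rid is not None:
                    rows.append((rid, "".join(chunks)))
                rid, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if rid is not None:
        rows.append((rid, "".join(chunks)))
    msa = MSA(rows)
    msa.match_mask = assign_match_columns(msa)
    return msa


def write_stockholm(msa: MSA, path: str | Path) -> Path:
    """Stockholm with the match mask as a #=GC RF reference-annotation line."""
    path = Path(path)
    mask = msa.match_mask if msa.match_mask is not None else assign_match_columns(msa)
    width = max(len(rid) for rid, _ in msa.rows)
    width = max(width, len("#=GC RF"))
    with open(path, "w") as out:
        out.write("# STOCKHOLM 1.0\n\n")
        for rid, aligned in msa.rows:
            out.write(f"{rid:<{width}}  {aligned}\n")
        rf = "".join("x" if m else "." for m in mask)
        out.write(f"{'#=GC RF':<{width}}  {rf}\n")
        out.write("//\n")
    return path


def read_stockholm(path: str | Path) -> MSA:
    rows: list[tuple[str, str]] = []
    order: dict[str, int] = {}
    mask_str = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("# ") or line == "//":
                continue
            if line.startswith("#=GC RF"):
                mask_str += line.split()[-1]
                continue
            if line.startswith("#"):
                continue
            rid, chunk = line.split()
            chunk = chunk.replace(".", "-")
            if rid in order:
                prev_id, prev = rows[order[rid]]
                rows[order[rid]] = (prev_id, prev + chunk)
            else:
                order[rid] = len(rows)
                rows.append((rid, chunk))
    msa = MSA(rows)
    if mask_str:
        msa.match_mask = np.array([c == "x" for c in mask_str], dtype=bool)
    else:
        msa.match_mask = assign_match_columns(msa)
    return msa
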