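"""Structure-based candidate triage on CA traces.

Candidates surviving sequence-level selection are compared against
reference enzyme structures by TM-score: Kabsch least-squares
superposition, iterated with a distance-weighted dynamic program to
refine the residue correspondence (a compact TM-align-style procedure).
The TM-score is normalized by the reference length, matching the
direction of comparison (candidates against canonical enzymes).  Geometry
is CA-only: predicted models' side chains are their least reliable part.

Aromatic contact counting (F/Y/W/H pairs within a CA-distance cutoff) is
a coarse surrogate for ring-interaction analyses; counts are comparable
within this toolkit only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .align import ScoringScheme, align_score_matrix, global_align
from .seqio import ALPHABET, ProteinSequence

AROMATIC = set("FYWH")


@dataclass
class StructureModel:
    """CA-trace model: one coordinate triple per residue, in Angstroms."""

    id: str
    residues: str
    ca_coordinates: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("ca_coordinates must be (N, 3)")
        if coords.shape[0] != len(self.residues):
            raise ValueError(f"{self.id}: coordinate count != residue count")
        if coords.shape[0] < 3:
            raise ValueError(f"{self.id}: need at least 3 residues")
        if not np.isfinite(coords).all():
            raise ValueError(f"{self.id}: non-finite coordinates")
        self.ca_coordinates = coords

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SuperpositionResult:
    """Rigid superposition of a query onto a reference."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    tm_score: float | None = None
    correspondence: list[tuple[int, int]] | None = None  # 1-based, increasing

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def read_ca_coordinates(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read one CA per residue from a PDB file (first model, first altloc).

    ``chain`` selects a chain id; default is the first chain in the file.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    if len(model) == 0:
        raise ValueError(f"{path}: no chains in file")
    if chain is None:
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"{path}: no chain {chain!r}")
    residues: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for res in ch:
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom
                break  # first altloc wins
        if ca is None:
            continue
        info = gemmi.find_tabulated_residue(res.name)
        one = info.one_letter_code.upper() if info else "X"
        residues.append(one if one in ALPHABET else "X")
        coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
    if not coords:
        raise ValueError(f"{path}: no CA atoms found")
    return StructureModel(path.stem, "".join(residues), np.array(coords))


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_ca_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write a CA-trace PDB (ATOM records, chain A, 3-decimal coordinates)."""
    path = Path(path)
    with open(path, "w") as out:
        for i, (aa, (x, y, z)) in enumerate(zip(model.residues, model.ca_coordinates), 1):
            out.write(
                f"ATOM  {i:>5}  CA  {_THREE[aa]} A{i:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        out.write("END\n")
    return path


def kabsch(p: np.ndarray, q: np.ndarray) -> SuperpositionResult:
    """Least-RMSD proper rotation + translation taking ``p`` onto ``q``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 points")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    rot, _ = Rotation.align_vectors(q - qc, p - pc)
    R = rot.as_matrix()
    t = qc - R @ pc
    moved = p @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def tm_d0(l_ref: int) -> float:
    """TM-score normalization distance, floored at 0.5 A for short references."""
    if l_ref <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_superposition(query: np.ndarray, reference: np.ndarray,
                           pairs: np.ndarray, sup: SuperpositionResult,
                           l_ref: int) -> float:
    d0 = tm_d0(l_ref)
    moved = sup.transform(query[pairs[:, 0]])
    d2 = np.sum((moved - reference[pairs[:, 1]]) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / d0**2)) / l_ref)


def tm_score(
    query: StructureModel,
    reference: StructureModel,
    correspondence: Sequence[tuple[int, int]],
) -> float:
    """TM-score of ``query`` against ``reference`` over ``correspondence``.

    TM = (1/L_ref) sum_i 1/(1 + (d_i/d0)^2), maximized over superpositions
    seeded from fragments of the correspondence and refined on the pairs
    closer than d0 (the standard TM-score search).  Indices are 1-based.
    """
    if len(reference) < 3:
        raise ValueError("reference too short")
    pairs = np.asarray(correspondence, dtype=int)
    if pairs.size == 0:
        raise ValueError("empty correspondence")
    if (np.diff(pairs, axis=0) <= 0).any():
        raise ValueError("correspondence must be strictly increasing in both columns")
    pairs = pairs - 1
    qc = query.ca_coordinates
    rc = reference.ca_coordinates
    l_ref = len(reference)
    d0 = tm_d0(l_ref)
    n = pairs.shape[0]
    best = 0.0
    seeds = []
    for frag in (n, n // 2, n // 4):
        if frag < 4:
            continue
        step = max(1, frag // 2)
        for start in range(0, n - frag + 1, step):
            seeds.append(slice(start, start + frag))
    if not seeds:
        seeds = [slice(0, n)]
    for sl in seeds:
        sub = pairs[sl]
        if sub.shape[0] < 3:
            continue
        sup = kabsch(qc[sub[:, 0]], rc[sub[:, 1]])
        for _ in range(20):
            tm = _tm_from_superposition(qc, rc, pairs, sup, l_ref)
            if tm > best:
                best = tm
            moved = sup.transform(qc[pairs[:, 0]])
            d = np.linalg.norm(moved - rc[pairs[:, 1]], axis=1)
            keep = d < max(d0, 3.0)
            if keep.sum() < 3 or keep.all():
                break
            new_sub = pairs[keep]
            if new_sub.shape[0] == sub.shape[0] and (new_sub == sub).all():
                break
            sub = new_sub
            sup = kabsch(qc[sub[:, 0]], rc[sub[:, 1]])
    return best


def structural_align(
    query: StructureModel,
    reference: StructureModel,
    scheme: ScoringScheme | None = None,
    max_iters: int = 20,
) -> SuperpositionResult:
    """Iterative structure alignment of ``query`` onto ``reference``.

    Starts from the sequence-alignment correspondence, then alternates
    Kabsch superposition with a dynamic program on the TM-style distance
    weights 1/(1 + (d/d0)^2) (gap penalty 0.6) until the correspondence is
    stable.  Returns the superposition on the final correspondence with
    the best TM-score found.
    """
    if len(query) < 10 or len(reference) < 10:
        raise ValueError("structures must have at least 10 residues")
    aln = global_align(
        ProteinSequence(id="q", residues=query.residues),
        ProteinSequence(id="r", residues=reference.residues),
        scheme,
    )
    pairs = []
    i = j = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            pairs.append((i, j))
        i += ca != "-"
        j += cb != "-"
    if not pairs:
        raise ValueError("no alignable residues")
    pairs = np.asarray(pairs, dtype=int)
    qc = query.ca_coordinates
    rc = reference.ca_coordinates
    l_ref = len(reference)
    d0 = tm_d0(l_ref)
    best_tm = -1.0
    best_pairs = pairs
    for _ in range(max_iters):
        sup = kabsch(qc[pairs[:, 0]], rc[pairs[:, 1]])
        tm = _tm_from_superposition(qc, rc, pairs, sup, l_ref)
        if tm > best_tm:
            best_tm = tm
            best_pairs = pairs
        moved = sup.transform(qc)
        d2 = ((moved[:, None, :] - rc[None, :, :]) ** 2).sum(axis=2)
        S = 1.0 / (1.0 + d2 / d0**2)
        _, moves = align_score_matrix(S, gap_open=0.6, gap_extend=0.0)
        new_pairs = []
        i = j = 0
        for di, dj in moves:
            if di and dj:
                new_pairs.append((i, j))
            i += di
            j += dj
        new_pairs = np.asarray(new_pairs, dtype=int)
        if new_pairs.shape == pairs.shape and (new_pairs == pairs).all():
            break
        pairs = new_pairs
    corr = [(int(a) + 1, int(b) + 1) for a, b in best_pairs]
    final_tm = tm_score(query, reference, corr)
    sup = kabsch(qc[best_pairs[:, 0]], rc[best_pairs[:, 1]])
    return SuperpositionResult(
        rotation=sup.rotation,
        translation=sup.translation,
        rmsd=sup.rmsd,
        tm_score=max(final_tm, best_tm),
        correspondence=corr,
    )


def aromatic_contacts(
    structure: StructureModel, cutoff: float = 7.0, min_separation: int = 2
) -> int:
    """Count aromatic (F/Y/W/H) residue pairs with CA distance <= cutoff
    and sequence separation >= min_separation."""
    idx = [i for i, aa in enumerate(structure.residues) if aa in AROMATIC]
    if len(idx) < 2:
        return 0
    coords = structure.ca_coordinates[idx]
    dmat = squareform(pdist(coords))
    count = 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if idx[b] - idx[a] >= min_separation and dmat[a, b] <= cutoff:
                count += 1
    return count


def rank_by_structure(
    candidates: Sequence[StructureModel],
    references: Sequence[StructureModel],
    scheme: ScoringScheme | None = None,
) -> list[tuple[str, str, float]]:
    """Rank candidates by their best TM-score against any reference."""
    if not references:
        raise ValueError("reference set is empty")
    rows = []
    for cand in candidates:
        best_ref, best_tm = references[0].id, -1.0
        for ref in references:
            tm = structural_align(cand, ref, scheme).tm_score
            if tm > best_tm:
                best_ref, best_tm = ref.id, tm
        rows.append((cand.id, best_ref, best_tm))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows


def triage_table(
    candidates: Sequence[StructureModel],
    references: Sequence[StructureModel],
    scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Full triage report: best reference, TM, RMSD, aligned length, contacts."""
    if not references:
        raise ValueError("reference set is empty")
    by_id = {r.id: r for r in references}
    rows = []
    for cand in candidates:
        results = {ref.id: structural_align(cand, ref, scheme) for ref in references}
        best_ref = max(results, key=lambda rid: results[rid].tm_score)
        res = results[best_ref]
        rows.append(
            (cand.id, best_ref, res.tm_score, res.rmsd,
             len(res.correspondence or []), aromatic_contacts(cand))
        )
    df = pd.DataFrame(
        rows,
        columns=["candidate", "best_reference", "tm_score", "rmsd",
                 "aligned_length", "aromatic_contacts"],
    )
    return df.sort_values(
        ["tm_score", "candidate"], ascending=[False, True], ignore_index=True
    )
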