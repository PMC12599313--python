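"""Profile hidden Markov models: build, score, calibrate, search.

The architecture is "Plan7-lite": match/insert/delete nodes with the usual
seven transitions, scored in fully local mode.  Entry is uniform over the
L x M (position, match state) pairs; exit from match state k has
probability 1/(M - k + 1), which makes the exit point uniform over the
remaining states and — crucially — conserves total path probability, so
the bit score is a proper log-likelihood ratio.  Flanking residues are
emitted by the background and cancel in the ratio.  There is no
multi-domain loop: one envelope per target, which is all the ranking and
thresholding stages need.  Scores are full forward (sum over all
alignments) log-odds in bits, matching the semantics of full-sequence
scores from standard homology-search tools.

E-values come from explicit decoy calibration: background-composition
decoys are scored and an exponential tail P(S >= s) = exp(-lambda (s -
tau)) is fitted by maximum likelihood to the exceedances over an upper
quantile.  The null decays faster near its bulk than in its far tail, so
the fit must sit deep enough that the E-value thresholds of interest lie
inside (not beyond) the fitted stretch; the default budget of 50000
decoys with a top-1% fit covers survival down to ~2e-5, bracketing the
E ~ 1 regime of databases up to ~5e4 sequences.  Scoring decoys is
seconds of work, and E(s) = db_size * min(1, exp(-lambda (s - tau))).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .msa import MSA, assign_match_columns
from .seqio import AA_INDEX, AMINO_ACIDS, ProteinSequence, ResidueComposition

TRANS_COLS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
_T = {name: i for i, name in enumerate(TRANS_COLS)}


@dataclass
class ProfileHMM:
    """A profile HMM over the 20-residue alphabet.

    ``match_emissions[k-1]`` is the emission distribution of match state k
    (k = 1..M); ``transitions[k]`` holds the seven transition probabilities
    out of node k (node 0 is Begin), columns ordered as
    (MM, MI, MD, IM, II, DM, DD), each of the three bundles summing to 1.
    Insert emissions are tied to the background (score-neutral inserts).
    """

    match_emissions: np.ndarray  # (M, 20)
    transitions: np.ndarray  # (M+1, 7)
    background: np.ndarray  # (20,)
    insert_emissions: np.ndarray | None = None  # (20,), defaults to background
    name: str = "profile"

    def __post_init__(self) -> None:
        me = np.asarray(self.match_emissions, dtype=float)
        tr = np.asarray(self.transitions, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if me.ndim != 2 or me.shape[1] != 20 or me.shape[0] < 1:
            raise ValueError("match_emissions must be (M, 20) with M >= 1")
        if tr.shape != (me.shape[0] + 1, 7):
            raise ValueError("transitions must be (M+1, 7)")
        if self.insert_emissions is None:
            self.insert_emissions = bg.copy()
        ie = np.asarray(self.insert_emissions, dtype=float)
        for arr, what in ((me, "match emissions"), (bg[None, :], "background"),
                          (ie[None, :], "insert emissions")):
            if (arr <= 0).any():
                raise ValueError(f"{what} must be strictly positive (pseudocounts)")
            if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-6:
                raise ValueError(f"{what} rows must sum to 1")
        for cols, what in (((0, 1, 2), "M->"), ((3, 4), "I->"), ((5, 6), "D->")):
            if (tr[:, cols] <= 0).any():
                raise ValueError(f"{what} transitions must be strictly positive")
            if np.abs(tr[:, cols].sum(axis=1) - 1.0).max() > 1e-6:
                raise ValueError(f"{what} transition bundles must sum to 1")
        # exact renormalization (serialization may carry rounding)
        me /= me.sum(axis=1, keepdims=True)
        ie /= ie.sum()
        bg /= bg.sum()
        for cols in ((0, 1, 2), (3, 4), (5, 6)):
            tr[:, cols] /= tr[:, cols].sum(axis=1, keepdims=True)
        self.match_emissions = me
        self.transitions = tr
        self.background = bg
        self.insert_emissions = ie

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


@dataclass(frozen=True)
class CalibrationParams:
    """Exponential-tail score calibration: P(S >= s) = exp(-lambda (s - tau))."""

    lam: float  # inverse bits
    tau: float  # bits
    decoy_count: int
    decoy_seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.decoy_count < 50:
            raise ValueError("decoy_count must be >= 50")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationParams":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass(frozen=True)
class HmmHit:
    """A database match above threshold."""

    target_id: str
    bit_score: float
    evalue: float
    envelope_start: int
    envelope_end: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")
        if not (1 <= self.envelope_start <= self.envelope_end):
            raise ValueError("invalid envelope coordinates")


def build_profile(
    msa: MSA,
    mask: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
    background: ResidueComposition | None = None,
    name: str = "profile",
) -> ProfileHMM:
    """Estimate a profile HMM from an MSA with Laplace-style pseudocounts.

    Match-state emission for residue x in match column k is
    (count_kx + w) / (n_k + 20 w); transitions are counted from each row's
    state path against the match mask (the I->D and D->I adjacencies the
    architecture forbids are dropped) and smoothed the same way.
    """
    if mask is None:
        mask = msa.match_mask if msa.match_mask is not None else assign_match_columns(msa)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (msa.columns,):
        raise ValueError("mask length must equal MSA columns")
    M = int(mask.sum())
    if M == 0:
        raise ValueError("mask designates no match columns")
    w = float(pseudocount_weight)
    if w <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = (background or ResidueComposition.swissprot()).as_array()

    # match-column index per column (1-based node number)
    node_of_col = np.cumsum(mask)

    em_counts = np.zeros((M, 20))
    tr_counts = np.zeros((M + 1, 7))
    for _, aligned in msa.rows:
        path: list[tuple[str, int]] = [("M", 0)]  # Begin acts as M_0
        for j, c in enumerate(aligned):
            k = int(node_of_col[j])
            if mask[j]:
                path.append(("M", k) if c != "-" else ("D", k))
                if c not in ("-", "X"):
                    em_counts[k - 1, AA_INDEX[c]] += 1
            elif c != "-":
                path.append(("I", k))
        path.append(("M", M + 1))  # End counted as a match transition
        for (s1, k1), (s2, _) in zip(path, path[1:]):
            key = s1 + ("M" if s2 == "M" else s2)
            if key in ("ID", "DI"):
                continue  # forbidden in Plan7-lite; dropped
            row = min(k1, M)
            tr_counts[row, _T[key]] += 1

    match_em = (em_counts + w) / (em_counts.sum(axis=1, keepdims=True) + 20 * w)
    tr = np.empty((M + 1, 7))
    for cols in ((0, 1, 2), (3, 4), (5, 6)):
        c = tr_counts[:, cols] + w
        tr[:, cols] = c / c.sum(axis=1, keepdims=True)
    return ProfileHMM(match_em, tr, bg, name=name)


# ---------------------------------------------------------------------------
# forward scoring


@njit(cache=True)
def _forward_kernel(R, tMM, tMI, tMD, tIM, tII, tDM, tDD, entry_w):  # pragma: no cover
    L, M = R.shape
    # exit probability from match state k: 1/(M - k + 1) gives a uniform
    # exit distribution over l >= k and conserves path mass (proper model)
    eps = np.empty(M + 1)
    cont = np.empty(M + 1)
    for k in range(1, M + 1):
        eps[k] = 1.0 / (M - k + 1)
        cont[k] = 1.0 - eps[k]
    eps[0] = 0.0
    cont[0] = 1.0
    Mprev = np.zeros(M + 1)
    Iprev = np.zeros(M + 1)
    Dprev = np.zeros(M + 1)
    Mcur = np.zeros(M + 1)
    Icur = np.zeros(M + 1)
    Dcur = np.zeros(M + 1)
    total_log = -np.inf
    logscale = 0.0
    ew = entry_w
    for i in range(L):
        for k in range(1, M + 1):
            Mcur[k] = R[i, k - 1] * (
                ew
                + Mprev[k - 1] * tMM[k - 1] * cont[k - 1]
                + Iprev[k - 1] * tIM[k - 1]
                + Dprev[k - 1] * tDM[k - 1]
            )
        for k in range(1, M + 1):
            Icur[k] = Mprev[k] * tMI[k] * cont[k] + Iprev[k] * tII[k]
        Dcur[1] = 0.0
        for k in range(2, M + 1):
            Dcur[k] = Mcur[k - 1] * tMD[k - 1] * cont[k - 1] + Dcur[k - 1] * tDD[k - 1]
        rowsum = 0.0
        for k in range(1, M + 1):
            rowsum += Mcur[k] * eps[k]
        if rowsum > 0.0:
            c = math.log(rowsum) + logscale
            if total_log == -np.inf:
                total_log = c
            elif c > total_log:
                total_log = c + math.log1p(math.exp(total_log - c))
            else:
                total_log = total_log + math.log1p(math.exp(c - total_log))
        mx = 0.0
        for k in range(1, M + 1):
            if Mcur[k] > mx:
                mx = Mcur[k]
            if Icur[k] > mx:
                mx = Icur[k]
            if Dcur[k] > mx:
                mx = Dcur[k]
        if mx > 1e120:
            inv = 1.0 / mx
            for k in range(M + 1):
                Mcur[k] *= inv
                Icur[k] *= inv
                Dcur[k] *= inv
            ew *= inv
            logscale += math.log(mx)
        Mprev, Mcur = Mcur, Mprev
        Iprev, Icur = Icur, Iprev
        Dprev, Dcur = Dcur, Dprev
    return total_log


def _emission_ratio_table(hmm: ProfileHMM) -> np.ndarray:
    """(M, 21) table of emission/background ratios; X (index 20) is neutral."""
    ratio = np.empty((hmm.length, 21))
    ratio[:, :20] = hmm.match_emissions / hmm.background[None, :]
    ratio[:, 20] = 1.0
    return ratio


def _encode21(residues: str) -> np.ndarray:
    return np.array(
        [20 if c == "X" else AA_INDEX[c] for c in residues], dtype=np.int64
    )


def _forward_bits_codes(hmm: ProfileHMM, ratio: np.ndarray, codes: np.ndarray) -> float:
    M = hmm.length
    L = codes.shape[0]
    R = np.ascontiguousarray(ratio[:, codes].T)
    tr = hmm.transitions
    # uniform prior over the L entry positions and M entry states; the
    # 1/L factor length-normalizes the null (otherwise longer random
    # sequences score higher just by offering more alignment starts)
    entry_w = 1.0 / (L * M)
    ln_total = _forward_kernel(
        R,
        np.ascontiguousarray(tr[:, 0]), np.ascontiguousarray(tr[:, 1]),
        np.ascontiguousarray(tr[:, 2]), np.ascontiguousarray(tr[:, 3]),
        np.ascontiguousarray(tr[:, 4]), np.ascontiguousarray(tr[:, 5]),
        np.ascontiguousarray(tr[:, 6]), entry_w,
    )
    return ln_total / math.log(2.0)


def forward_score(hmm: ProfileHMM, seq: ProteinSequence | str) -> float:
    """Local forward log-odds score of ``seq`` under ``hmm``, in bits."""
    residues = seq if isinstance(seq, str) else seq.residues
    return _forward_bits_codes(hmm, _emission_ratio_table(hmm), _encode21(residues))


def score_database(hmm: ProfileHMM, db: Sequence[ProteinSequence]) -> np.ndarray:
    """Forward bit scores for every sequence in ``db``."""
    ratio = _emission_ratio_table(hmm)
    return np.array(
        [_forward_bits_codes(hmm, ratio, _encode21(s.residues)) for s in db]
    )


# ---------------------------------------------------------------------------
# calibration and search


#: Fraction of the decoy score distribution the exponential tail is
#: fitted to.  The fit interpolates rather than extrapolates across the
#: E-value regime of interest when decoy_count * tail_mass is a few
#: hundred points reaching survival below ~1/db_size.
DEFAULT_TAIL_MASS = 0.01

#: Default decoy budget.  Generous on purpose: the null decays faster
#: near its bulk than in its far tail, so a slope fitted from shallow
#: exceedances and extrapolated into the far tail mis-states extreme
#: E-values severalfold.  50000 scored decoys cost seconds and place the
#: fitted stretch on top of the thresholds that matter.
DEFAULT_DECOY_COUNT = 50_000

#: Minimum number of exceedances used for the tail fit; when the decoy
#: sample is small, the threshold is lowered to keep this many points.
MIN_TAIL_POINTS = 20


def fit_exponential_tail(scores: np.ndarray,
                         tail_mass: float = 0.5) -> tuple[float, float]:
    """Fit P(S >= s) = exp(-lambda (s - tau)) to the right tail of ``scores``.

    lambda is the maximum-likelihood exponential rate of the exceedances
    over the upper ``tail_mass`` quantile; tau anchors the fitted
    survival to ``tail_mass`` at that threshold (so with the default
    tail_mass 0.5, tau = median - ln2/lambda).
    """
    if not (0.0 < tail_mass < 1.0):
        raise ValueError("tail_mass must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    thr = float(np.quantile(scores, 1.0 - tail_mass))
    tail = scores[scores > thr]
    if tail.size < 2 or np.ptp(scores) == 0:
        raise ValueError("degenerate scores; cannot fit tail")
    lam = 1.0 / float(np.mean(tail - thr))
    tau = thr + math.log(tail_mass) / lam
    return lam, tau


def calibrate(
    hmm: ProfileHMM,
    db_composition: ResidueComposition,
    decoy_count: int = DEFAULT_DECOY_COUNT,
    length_sampler: Callable[[np.random.Generator], int] | Sequence[int] | None = None,
    seed: int = 0,
    tail_mass: float = DEFAULT_TAIL_MASS,
) -> CalibrationParams:
    """Calibrate the E-value exponential tail from background decoy scores.

    Scores ``decoy_count`` background-sampled sequences and fits the
    exponential survival by maximum likelihood to the exceedances over
    the upper ``tail_mass`` quantile (threshold lowered if needed to keep
    at least :data:`MIN_TAIL_POINTS` exceedances).  Deterministic per
    ``seed``.

    ``length_sampler`` may be a callable drawing one length from a
    Generator, a pool of lengths to resample, or None for the default
    log-normal (median ~230 residues, sigma 0.35).
    """
    if not (0.0 < tail_mass < 0.5):
        raise ValueError("tail_mass must be in (0, 0.5)")
    if decoy_count < 50:
        raise ValueError("decoy_count must be >= 50")
    # salt the stream so a raw-seed collision with a sequence generator
    # elsewhere cannot replay its draws as "decoys"
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDEC0]))
    if length_sampler is None:
        draw = lambda r: max(30, int(round(r.lognormal(math.log(230.0), 0.35))))
    elif callable(length_sampler):
        draw = length_sampler
    else:
        pool = np.asarray(length_sampler, dtype=np.int64)
        draw = lambda r: int(pool[r.integers(len(pool))])
    comp = db_composition.as_array()
    ratio = _emission_ratio_table(hmm)
    scores = np.empty(decoy_count)
    for i in range(decoy_count):
        codes = rng.choice(20, size=draw(rng), p=comp).astype(np.int64)
        scores[i] = _forward_bits_codes(hmm, ratio, codes)
    if np.ptp(scores) == 0:
        raise ValueError("degenerate decoy scores; cannot calibrate")
    effective_mass = max(tail_mass, min(0.5, MIN_TAIL_POINTS / decoy_count))
    lam, tau = fit_exponential_tail(scores, tail_mass=effective_mass)
    return CalibrationParams(lam=lam, tau=tau, decoy_count=decoy_count, decoy_seed=seed)


def evalue(score: float, calib: CalibrationParams, db_size: int) -> float:
    """Expected false positives at ``score`` in a database of ``db_size``."""
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    return db_size * min(1.0, math.exp(-calib.lam * (score - calib.tau)))


def search(
    hmm: ProfileHMM,
    db: Sequence[ProteinSequence],
    calib: CalibrationParams,
    evalue_cutoff: float = 1e-5,
    db_size: int | None = None,
) -> list[HmmHit]:
    """Score every database sequence; report hits with E <= cutoff.

    Hits are sorted by ascending E-value then target id.  Envelopes span
    the full target (posterior decoding is not enabled in this toolkit).
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    if not db:
        return []
    n = db_size if db_size is not None else len(db)
    scores = score_database(hmm, db)
    hits = []
    for s, score in zip(db, scores):
        e = evalue(float(score), calib, n)
        if e <= evalue_cutoff:
            hits.append(
                HmmHit(
                    target_id=s.id,
                    bit_score=float(score),
                    evalue=e,
                    envelope_start=1,
                    envelope_end=len(s),
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


def hits_table(hits: Sequence[HmmHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.target_id, h.bit_score, h.evalue, h.envelope_start, h.envelope_end)
         for h in hits],
        columns=["target", "bit_score", "evalue", "env_start", "env_end"],
    )


def write_hits_tsv(hits: Sequence[HmmHit], path: str | Path) -> Path:
    path = Path(path)
    hits_table(hits).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_hits_tsv(path: str | Path) -> list[HmmHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        HmmHit(str(r.target), float(r.bit_score), float(r.evalue),
               int(r.env_start), int(r.env_end))
        for r in df.itertuples(index=False)
    ]


def write_domtbl(hits: Sequence[HmmHit], hmm: ProfileHMM, path: str | Path) -> Path:
    """Human-readable per-target report in the spirit of domain-table output."""
    path = Path(path)
    with open(path, "w") as out:
        out.write(f"# query: {hmm.name} (M={hmm.length})\n")
        out.write(f"# {'target':<28} {'bits':>10} {'E-value':>12} {'env':>12}\n")
        for h in hits:
            out.write(
                f"{h.target_id:<30} {h.bit_score:>10.2f} {h.evalue:>12.3g} "
                f"{h.envelope_start:>5}-{h.envelope_end}\n"
            )
    return path


# ---------------------------------------------------------------------------
# plain-text model serialization (HMMER3-like field layout)


def save_hmm(hmm: ProfileHMM, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write("PETMINE-HMM 1\n")
        out.write(f"NAME  {hmm.name}\n")
        out.write(f"LENG  {hmm.length}\n")
        out.write("ALPH  amino\n")
        out.write("ORDER " + " ".join(AMINO_ACIDS) + "\n")
        out.write("COMPO " + " ".join(f"{p:.6e}" for p in hmm.background) + "\n")
        out.write("INSE  " + " ".join(f"{p:.6e}" for p in hmm.insert_emissions) + "\n")
        out.write("# per-node match emissions (M k e_A..e_Y) and transitions\n")
        out.write("# (T k " + " ".join(TRANS_COLS) + ")\n")
        for k in range(1, hmm.length + 1):
            probs = " ".join(f"{p:.6e}" for p in hmm.match_emissions[k - 1])
            out.write(f"M {k} {probs}\n")
        for k in range(hmm.length + 1):
            probs = " ".join(f"{p:.6e}" for p in hmm.transitions[k])
            out.write(f"T {k} {probs}\n")
        out.write("//\n")
    return path


def load_hmm(path: str | Path) -> ProfileHMM:
    name, length = "profile", None
    bg = ins = None
    match_rows: dict[int, list[float]] = {}
    trans_rows: dict[int, list[float]] = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("PETMINE-HMM"):
            raise ValueError(f"{path}: not a petmine HMM file")
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0] == "//":
                continue
            tag = parts[0]
            if tag == "NAME":
                name = parts[1]
            elif tag == "LENG":
                length = int(parts[1])
            elif tag == "COMPO":
                bg = [float(x) for x in parts[1:]]
            elif tag == "INSE":
                ins = [float(x) for x in parts[1:]]
            elif tag == "M":
                match_rows[int(parts[1])] = [float(x) for x in parts[2:]]
            elif tag == "T":
                trans_rows[int(parts[1])] = [float(x) for x in parts[2:]]
    if length is None or bg is None or len(match_rows) != length:
        raise ValueError(f"{path}: incomplete model")
    me = np.array([match_rows[k] for k in range(1, length + 1)])
    tr = np.array([trans_rows[k] for k in range(length + 1)])
    return ProfileHMM(me, tr, np.array(bg),
                      insert_emissions=None if ins is None else np.array(ins),
                      name=name)
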