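"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration or dense
grid search — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

from petmine.align import ScoringScheme
from petmine.hmm import ProfileHMM
from petmine.seqio import AMINO_ACIDS


def brute_force_global_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Optimal global affine-gap score by exhaustive alignment enumeration.

    A gap run of length L costs gap_open + L * gap_extend.  Enumerates all
    alignments recursively; exponential, fine for len <= 6.
    """

    def sub(x: str, y: str) -> float:
        return scheme.score(x, y)

    best = [-math.inf]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(a[i], b[j]), "M")
        if i < len(a):
            cost = scheme.gap_extend + (scheme.gap_open if prev != "A" else 0.0)
            rec(i + 1, j, score - cost, "A")
        if j < len(b):
            cost = scheme.gap_extend + (scheme.gap_open if prev != "B" else 0.0)
            rec(i, j + 1, score - cost, "B")

    rec(0, 0, 0.0, "start")
    return best[0]


def enumerate_forward_bits(hmm: ProfileHMM, seq: str) -> float:
    """Forward log-odds score by explicit enumeration of every local path.

    Entry at any residue position (uniform 1/L prior) into any match state
    (uniform 1/M prior); exit from match state k with probability
    1/(M - k + 1) (uniform over remaining states, mass-conserving);
    flanking residues free.  Exponential in M and len(seq).
    """
    M = hmm.length
    codes = [AMINO_ACIDS.index(c) for c in seq]
    bg = hmm.background
    tr = hmm.transitions
    em = hmm.match_emissions
    L = len(seq)
    entry_w = 1.0 / (L * M)
    total = 0.0

    def extend(state: str, k: int, p: int, prob: float) -> None:
        nonlocal total
        if state == "M":
            eps = 1.0 / (M - k + 1)
            total += prob * eps  # exit here
            prob = prob * (1.0 - eps)  # or continue
        if state == "M":
            trans = [("M", k + 1, tr[k, 0]), ("I", k, tr[k, 1]), ("D", k + 1, tr[k, 2])]
        elif state == "I":
            trans = [("M", k + 1, tr[k, 3]), ("I", k, tr[k, 4])]
        else:
            trans = [("M", k + 1, tr[k, 5]), ("D", k + 1, tr[k, 6])]
        for s2, k2, t in trans:
            if s2 in ("M", "D") and k2 > M:
                continue
            if s2 == "M":
                if p >= L:
                    continue
                ratio = em[k2 - 1, codes[p]] / bg[codes[p]]
                extend("M", k2, p + 1, prob * t * ratio)
            elif s2 == "I":
                if p >= L:
                    continue
                extend("I", k2, p + 1, prob * t)  # insert emits background
            else:
                extend("D", k2, p, prob * t)

    for i in range(L):
        for k in range(1, M + 1):
            ratio = em[k - 1, codes[i]] / bg[codes[i]]
            extend("M", k, i + 1, entry_w * ratio)
    return math.log2(total)


def random_profile_hmm(rng: np.random.Generator, M: int) -> ProfileHMM:
    """A random, valid profile HMM with emissions concentrated on A/C/D/E."""
    conc = np.full(20, 0.02)
    conc[:4] = 1.0  # A, C, D, E carry the mass
    me = rng.dirichlet(conc, size=M) + 1e-9
    me /= me.sum(axis=1, keepdims=True)
    tr = np.empty((M + 1, 7))
    for k in range(M + 1):
        tr[k, :3] = rng.dirichlet([8.0, 1.0, 1.0])
        tr[k, 3:5] = rng.dirichlet([3.0, 1.0])
        tr[k, 5:7] = rng.dirichlet([3.0, 1.0])
    bg = rng.dirichlet(np.full(20, 5.0)) + 1e-9
    bg /= bg.sum()
    return ProfileHMM(me, tr, bg)


def _euler_matrix(ax: float, ay: float, az: float) -> np.ndarray:
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def grid_min_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum superposition RMSD by dense rotation-grid search.

    Proper rotations only: a dense Euler-angle sweep followed by nested
    refinement from the best starting cells (multi-start, to dodge the
    local minima of the Euler parametrization).  Accurate to well under
    1e-3 A on small point sets.
    """
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def rmsd_at(ang: np.ndarray) -> float:
        R = _euler_matrix(*ang)
        return math.sqrt(np.mean(np.sum((pc @ R.T - qc) ** 2, axis=1)))

    coarse = np.linspace(-math.pi, math.pi, 21)
    cells = []
    for ax in coarse:
        for ay in coarse:
            for az in coarse:
                ang = np.array([ax, ay, az])
                cells.append((rmsd_at(ang), tuple(ang)))
    cells.sort(key=lambda c: c[0])
    best = cells[0][0]
    for _, start in cells[:10]:
        center = np.array(start)
        span = coarse[1] - coarse[0]
        for _ in range(8):
            grid = np.linspace(-span, span, 9)
            best_angles = center
            for dx in grid:
                for dy in grid:
                    for dz in grid:
                        ang = center + np.array([dx, dy, dz])
                        r = rmsd_at(ang)
                        if r < best:
                            best = r
                            best_angles = ang
            center = best_angles
            span /= 4.0
    return best


def grid_scan_pi(net_charge_fn, step: float = 1e-4) -> float:
    """pI by dense pH grid scan: first pH where the net charge goes negative."""
    grid = np.arange(0.5, 13.5 + step, step)
    for ph in grid:
        if net_charge_fn(float(ph)) <= 0.0:
            return float(ph)
    return 13.5
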