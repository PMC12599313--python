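"""Sequence-level physicochemical annotation.

Net charge follows the Henderson–Hasselbalch treatment of each ionizable
group; the isoelectric point is the pH at which the net charge crosses
zero, located by bisection.  Hydrophobicity is the Kyte–Doolittle GRAVY.
Cleavage-site consensus and trimming implement the arithmetic used when
reconciling several signal-peptide predictors; the predictors themselves
are external and out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .seqio import ProteinSequence


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa values (pH units)."""

    asp: float
    glu: float
    cys: float
    tyr: float
    his: float
    lys: float
    arg: float
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa {name}={v} outside (0, 14)")


#: Bjellqvist pKa values (ExPASy-compatible), the de-facto standard for
#: theoretical pI. A single N-terminal pKa is used for all residues.
BJELLQVIST = PkaSet(
    asp=4.05, glu=4.45, cys=9.0, tyr=10.0, his=5.98,
    lys=10.0, arg=12.0, n_term=7.5, c_term=3.55,
)

#: EMBOSS pKa values, an alternative convention.
EMBOSS = PkaSet(
    asp=3.9, glu=4.1, cys=8.5, tyr=10.1, his=6.5,
    lys=10.8, arg=12.5, n_term=8.6, c_term=3.6,
)

PKA_SETS = {"bjellqvist": BJELLQVIST, "emboss": EMBOSS}

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def net_charge(seq: ProteinSequence, ph: float, pka: PkaSet = BJELLQVIST) -> float:
    """Net charge (elementary charges) at ``ph``.

    charge = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH)) with
    basic groups {N-terminus, K, R, H} and acidic {C-terminus, D, E, C, Y}.
    Strictly decreasing in pH.
    """
    if not (0.0 < ph < 14.0):
        raise ValueError("ph must be in (0, 14)")
    r = seq.residues
    basics = [pka.n_term]
    basics += [pka.lys] * r.count("K")
    basics += [pka.arg] * r.count("R")
    basics += [pka.his] * r.count("H")
    acidics = [pka.c_term]
    acidics += [pka.asp] * r.count("D")
    acidics += [pka.glu] * r.count("E")
    acidics += [pka.cys] * r.count("C")
    acidics += [pka.tyr] * r.count("Y")
    pos = sum(1.0 / (1.0 + 10.0 ** (ph - k)) for k in basics)
    neg = sum(1.0 / (1.0 + 10.0 ** (k - ph)) for k in acidics)
    return pos - neg


def isoelectric_point(
    seq: ProteinSequence, pka: PkaSet = BJELLQVIST, tol: float = 1e-3
) -> float:
    """pH of zero net charge, by bisection on [0.5, 13.5] to within ``tol``."""
    lo, hi = 0.5, 13.5
    # net_charge is strictly decreasing: positive at lo, negative at hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(seq: ProteinSequence) -> float:
    """Grand average of hydropathy (Kyte–Doolittle) over non-X residues."""
    values = [KYTE_DOOLITTLE[c] for c in seq.residues if c != "X"]
    if not values:
        raise ValueError(f"sequence {seq.id!r} has no non-X residues")
    return sum(values) / len(values)


def consensus_cleavage(predictions: list[tuple[str, int]]) -> int | None:
    """Consensus signal-peptide cleavage position from several predictors.

    A position held by a strict majority of predictors wins; otherwise the
    median (lower of the two middles for even counts). Empty input → None.
    """
    if not predictions:
        return None
    if len(predictions) > 10:
        raise ValueError("at most 10 predictions supported")
    positions = [p for _, p in predictions]
    if any(p < 1 for p in positions):
        raise ValueError("cleavage positions are 1-based and must be >= 1")
    n = len(positions)
    for p in set(positions):
        if positions.count(p) * 2 > n:
            return p
    return sorted(positions)[(n - 1) // 2]


def trim_signal_peptide(seq: ProteinSequence, cleavage: int) -> ProteinSequence:
    """Remove the first ``cleavage`` residues (the predicted signal peptide)."""
    if not (1 <= cleavage < len(seq.residues)):
        raise ValueError(
            f"cleavage {cleavage} outside [1, {len(seq.residues) - 1}] for {seq.id!r}"
        )
    return replace(
        seq,
        id=f"{seq.id}|mature",
        residues=seq.residues[cleavage:],
        description=(seq.description + f" signal_peptide_removed={cleavage}").strip(),
    )


def properties_table(
    seqs: list[ProteinSequence], pka: PkaSet = BJELLQVIST
) -> pd.DataFrame:
    """Per-sequence report: id, length, net_charge_ph7, pI, gravy."""
    rows = [
        (s.id, len(s), net_charge(s, 7.0, pka), isoelectric_point(s, pka), gravy(s))
        for s in seqs
    ]
    return pd.DataFrame(
        rows, columns=["id", "length", "net_charge_ph7", "pI", "gravy"]
    )
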