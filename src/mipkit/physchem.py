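"""Physicochemical profiling: length, molecular weight, isoelectric point,
and a hydropathy-based count of candidate membrane-spanning segments.

Molecular weights use average (not monoisotopic) residue masses so values
are on the scale of the common web calculators.  The isoelectric point is
the root of the Henderson--Hasselbalch net-charge function, found by
bisection; the charge function is strictly decreasing in pH so the root is
unique.  Membrane-segment counting uses a Kyte--Doolittle sliding window
and is an approximation -- it is *not* expected to reproduce HMM-based
transmembrane-domain predictions, which are carried as annotations instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import AA20, ProteinRecord

logger = logging.getLogger(__name__)

#: mass of one water molecule (Da), added once per peptide chain
WATER_MASS = 18.01524

#: average residue (amino acid minus water) masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Kyte-Doolittle hydropathy scale
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


@dataclass(frozen=True)
class PkaTable:
    """Dissociation constants for the ionizable groups of a protein.

    ``side_chain`` maps the seven ionizable residues (D, E, C, Y acidic;
    H, K, R basic) to their pKa; ``n_term``/``c_term`` are the terminal
    group pKas.  All values must lie in (0, 14).
    """

    side_chain: dict
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        vals = list(self.side_chain.values()) + [self.n_term, self.c_term]
        if not all(0 < v < 14 for v in vals):
            raise ValueError("all pKa values must lie in (0, 14)")
        missing = set("DECYHKR") - set(self.side_chain)
        if missing:
            raise ValueError(f"pKa table missing side chains: {sorted(missing)}")


#: Bjellqvist-style pKa set (the scale of the common web pI calculators)
BJELLQVIST = PkaTable(
    side_chain={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
                "H": 5.98, "K": 10.0, "R": 12.0},
    n_term=7.5,
    c_term=3.55,
)

#: classic EMBOSS pKa set, selectable alternative
EMBOSS = PkaTable(
    side_chain={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
                "H": 6.5, "K": 10.8, "R": 12.5},
    n_term=8.6,
    c_term=3.6,
)

PKA_TABLES = {"bjellqvist": BJELLQVIST, "emboss": EMBOSS}

ACIDIC = "DECY"
BASIC = "HKR"


def molecular_weight(record: ProteinRecord) -> float:
    """Average molecular weight in Da: residue masses plus one water.

    ``X`` residues carry no defined mass and are excluded from the sum
    (logged); a sequence of only ``X`` is rejected.
    """
    seq = record.sequence
    n_x = seq.count("X")
    if n_x:
        logger.warning("record %s: %d 'X' residue(s) excluded from MW", record.id, n_x)
    if n_x == len(seq):
        raise ValueError(f"record {record.id}: no residues with defined mass")
    return sum(AVERAGE_RESIDUE_MASS[a] for a in seq if a != "X") + WATER_MASS


def _group_counts(sequence: str) -> dict:
    return {aa: sequence.count(aa) for aa in ACIDIC + BASIC}


def net_charge(sequence: str, ph, pka: PkaTable = BJELLQVIST):
    """Henderson--Hasselbalch net charge of the chain at pH ``ph``.

    Accepts a scalar or an array of pH values.  Strictly decreasing in pH.
    """
    ph = np.asarray(ph, dtype=float)
    counts = _group_counts(sequence)
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka.n_term))
    neg = -1.0 / (1.0 + 10.0 ** (pka.c_term - ph))
    for aa in BASIC:
        if counts[aa]:
            pos = pos + counts[aa] / (1.0 + 10.0 ** (ph - pka.side_chain[aa]))
    for aa in ACIDIC:
        if counts[aa]:
            neg = neg - counts[aa] / (1.0 + 10.0 ** (pka.side_chain[aa] - ph))
    total = pos + neg
    return float(total) if total.ndim == 0 else total


def isoelectric_point(
    record: ProteinRecord,
    pka: PkaTable = BJELLQVIST,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Bisection runs until ``|charge| < tol``; the charge function is a sum
    of strictly decreasing terms, so a unique root always exists.
    """
    if not record.sequence:
        raise ValueError("empty sequence")
    seq = record.sequence
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def hydropathy_profile(sequence: str, window: int = 19) -> np.ndarray:
    """Sliding-window mean Kyte--Doolittle hydropathy.

    Returns one value per window placement (length ``len(seq) - window + 1``).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > len(sequence):
        raise ValueError(
            f"window {window} exceeds sequence length {len(sequence)}"
        )
    scores = np.array([KD_SCALE[a] for a in sequence], dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(scores, kernel, mode="valid")


def hydropathy_segments(
    record: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 5,
) -> int:
    """Count maximal runs of window positions with mean hydropathy >= threshold.

    Runs separated by fewer than ``merge_gap`` positions are merged into one
    segment, approximating contiguous membrane-spanning stretches.
    """
    prof = hydropathy_profile(record.sequence, window)
    above = prof >= threshold
    segments = 0
    last_end = None  # index just past the previous run
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            start = i
            while i < n and above[i]:
                i += 1
            if last_end is not None and start - last_end < merge_gap:
                pass  # merged into the previous segment
            else:
                segments += 1
            last_end = i
        else:
            i += 1
    return segments


@dataclass
class PhyschemSummary:
    """Per-protein physicochemical profile (one row of the family table)."""

    id: str
    length: int
    mw: float
    pi: float
    tm_segments: int
    tmd_annotation: Optional[int] = None
    loc_annotation: Optional[str] = None


def summarize(
    record: ProteinRecord,
    pka: PkaTable = BJELLQVIST,
    kd_window: int = 19,
    kd_threshold: float = 1.6,
    merge_gap: int = 5,
) -> PhyschemSummary:
    """Compute the full physicochemical profile for one record."""
    return PhyschemSummary(
        id=record.id,
        length=len(record.sequence),
        mw=molecular_weight(record),
        pi=isoelectric_point(record, pka),
        tm_segments=hydropathy_segments(
            record, window=kd_window, threshold=kd_threshold, merge_gap=merge_gap
        )
        if kd_window <= len(record.sequence)
        else 0,
        tmd_annotation=record.tmd_annotation,
        loc_annotation=record.loc_annotation,
    )
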