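"""Global pairwise alignment, percent identity/similarity, and detection of
near-duplicate paralog pairs above a similarity threshold.

"Similarity" is deliberately exposed as two operational definitions:

* ``identity`` -- identical residues in aligned columns;
* ``positives`` -- aligned residue pairs with a positive substitution-matrix
  score (the sense in which most sequence tools report "similarity").

Both are percentages of the full alignment length including gap columns, so
length differences count against a pair; gap columns never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from . import _dp
from .seqio import GAP, ProteinRecord


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62"):
    """Load a named substitution matrix as (alphabet, numpy array)."""
    try:
        m = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {name!r}") from exc
    return str(m.alphabet), np.asarray(m, dtype=float)


@dataclass(frozen=True)
class PairingConfig:
    """Alignment and pair-detection parameters.

    The 90% default threshold is the conventional cutoff for calling two
    family members a recently duplicated (near-duplicate) paralog pair.
    """

    threshold: float = 90.0
    mode: str = "positives"  # or "identity"
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 100):
            raise ValueError("threshold must lie in (0, 100]")
        if self.mode not in ("identity", "positives"):
            raise ValueError(f"unknown similarity mode {self.mode!r}")


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with its score and percentages."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float
    pid: float
    psim: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")


def _encode(seq: str, alphabet: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(alphabet)}
    return np.array([idx[c] for c in seq], dtype=np.intp)


def global_align(
    a: ProteinRecord, b: ProteinRecord, config: PairingConfig = PairingConfig()
) -> PairwiseAlignment:
    """Needleman--Wunsch global alignment with affine gap penalties.

    The optimum is unique up to ties, which the DP kernel breaks
    deterministically (diagonal > up > left), so the returned alignment is
    reproducible.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("both sequences must be non-empty")
    alphabet, mat = load_matrix(config.matrix)
    ca = _encode(a.sequence, alphabet)
    cb = _encode(b.sequence, alphabet)
    S = mat[np.ix_(ca, cb)]
    score, ops = _dp.align_matrix(S, config.gap_open, config.gap_extend)
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            ra.append(a.sequence[i]); rb.append(b.sequence[j]); i += 1; j += 1
        elif op == 1:
            ra.append(a.sequence[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(b.sequence[j]); j += 1
    aln = PairwiseAlignment(
        id_a=a.id, id_b=b.id, row_a="".join(ra), row_b="".join(rb),
        score=float(score), pid=0.0, psim=0.0,
    )
    aln.pid = percent_similarity(aln, "identity", config.matrix)
    aln.psim = percent_similarity(aln, "positives", config.matrix)
    return aln


def percent_similarity(
    aln: PairwiseAlignment, mode: str = "positives", matrix: str = "BLOSUM62"
) -> float:
    """Percentage of alignment columns that match under the given mode.

    ``identity``: both residues present and equal.  ``positives``: both
    residues present and their substitution score is positive.  The
    denominator is the full alignment length including gap columns.
    """
    n = len(aln.row_a)
    if n == 0:
        raise ValueError("zero-length alignment")
    if mode == "identity":
        hits = sum(
            1 for x, y in zip(aln.row_a, aln.row_b) if x != GAP and x == y
        )
    elif mode == "positives":
        alphabet, mat = load_matrix(matrix)
        idx = {c: i for i, c in enumerate(alphabet)}
        hits = sum(
            1
            for x, y in zip(aln.row_a, aln.row_b)
            if x != GAP and y != GAP and mat[idx[x], idx[y]] > 0
        )
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    return 100.0 * hits / n


def find_paralog_pairs(
    records: list[ProteinRecord], config: PairingConfig = PairingConfig()
) -> list[tuple[str, str, float]]:
    """All unordered pairs whose percent similarity exceeds the threshold.

    Returns ``(id_a, id_b, psim)`` triples sorted by descending similarity
    (ties by id pair); a record may participate in several pairs.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    hits = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            aln = global_align(records[i], records[j], config)
            sim = aln.pid if config.mode == "identity" else aln.psim
            if sim > config.threshold:
                a, b = sorted((records[i].id, records[j].id))
                hits.append((a, b, sim))
    hits.sort(key=lambda t: (-t[2], t[0], t[1]))
    return hits


def all_pairs_table(records: list[ProteinRecord], config: PairingConfig = PairingConfig()):
    """Percent identity and similarity for every unordered pair (DataFrame)."""
    import pandas as pd

    rows = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            aln = global_align(records[i], records[j], config)
            rows.append(
                {"id_a": records[i].id, "id_b": records[j].id,
                 "pid": aln.pid, "psim": aln.psim, "score": aln.score}
            )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "pid", "psim", "score"])
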