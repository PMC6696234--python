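"""Progressive multiple sequence alignment.

The aligner is the classic progressive scheme: a k-mer dissimilarity
prefilter feeds a UPGMA guide tree, and profiles are merged bottom-up with
affine-gap Needleman--Wunsch under sum-of-pairs column scoring.  Once a gap
column is introduced into a profile it is never removed ("once a gap,
always a gap").  There is no iterative refinement; users who prefer an
external aligner can import any aligned FASTA and continue the pipeline,
since every downstream stage consumes only the ``MultipleAlignment``
container defined here.

All ties (guide-tree merges, DP traceback, child ordering) are broken by
sorted sequence ids, so the alignment is deterministic and permuting the
input order changes only the row order of the result.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from . import _dp
from .pairwise import load_matrix
from .seqio import AA20, GAP, ProteinRecord

# internal residue codes: 0..19 = AA20, 20 = X, 21 = gap
_CODE = {c: i for i, c in enumerate(AA20)}
_CODE["X"] = 20
_GAP_CODE = 21
_DECODE = AA20 + "X" + GAP


class MultipleAlignment:
    """Gapped, equal-length rows with a residue <-> column coordinate map.

    Coordinates are 1-based on both sides: residue index r of a row maps to
    the alignment column where that residue sits.
    """

    def __init__(self, ids: list[str], rows: list[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")
        if rows and len(set(map(len, rows))) != 1:
            raise ValueError("all rows must have equal length")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self._index[rid]]
        except KeyError:
            raise KeyError(f"no row with id {rid!r}") from None

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def colmap(self, rid: str) -> dict[int, int]:
        """1-based residue index -> 1-based alignment column for one row."""
        out = {}
        r = 0
        for c, ch in enumerate(self.row(rid), start=1):
            if ch != GAP:
                r += 1
                out[r] = c
        return out

    def column(self, c: int) -> str:
        """Alignment column ``c`` (1-based) across all rows."""
        if not (1 <= c <= self.n_columns):
            raise IndexError(f"column {c} out of range")
        return "".join(row[c - 1] for row in self.rows)


def write_alignment(msa: MultipleAlignment, path=None, width: int = 60) -> str:
    """Serialize an alignment as aligned (gapped) FASTA."""
    out = []
    for rid, row in zip(msa.ids, msa.rows):
        out.append(f">{rid}")
        for i in range(0, len(row), width):
            out.append(row[i : i + width])
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_alignment(path) -> MultipleAlignment:
    """Read an aligned FASTA file (from this package or any external aligner)."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no alignment rows in {path}")
    return MultipleAlignment(ids, rows)


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - (shared k-mers / min total k-mers); a fast guide-tree prefilter."""
    if len(a) < k or len(b) < k:
        raise ValueError(f"sequences must be at least k={k} long")
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum(min(ca[w], cb[w]) for w in ca.keys() & cb.keys())
    return 1.0 - shared / min(sum(ca.values()), sum(cb.values()))


@dataclass
class GuideNode:
    """A node of the rooted binary UPGMA merge tree."""

    members: tuple[int, ...]        # input indices under this node
    height: float
    left: Optional["GuideNode"] = None
    right: Optional["GuideNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def build_guide_tree(dm: np.ndarray, ids: list[str]) -> GuideNode:
    """UPGMA merge order from a symmetric dissimilarity matrix.

    Ties are broken by the lexicographically smallest (representative id)
    pair, where a cluster is represented by its smallest member id; the
    merge order is therefore a pure function of (distances, ids).
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n) or n != len(ids):
        raise ValueError("distance matrix shape must match ids")
    if np.isnan(dm).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if n == 1:
        return GuideNode(members=(0,), height=0.0)
    clusters: dict[int, GuideNode] = {
        i: GuideNode(members=(i,), height=0.0) for i in range(n)
    }
    reprs = {i: ids[i] for i in range(n)}  # smallest member id per cluster
    d = {frozenset((i, j)): dm[i, j] for i in range(n) for j in range(i + 1, n)}
    next_key = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                i, j = keys[ai], keys[bi]
                dist = d[frozenset((i, j))]
                tag = tuple(sorted((reprs[i], reprs[j])))
                cand = (dist, tag, i, j)
                if best is None or cand < best:
                    best = cand
        dist, _, i, j = best
        node = GuideNode(
            members=tuple(sorted(clusters[i].members + clusters[j].members)),
            height=dist / 2.0,
            left=clusters[i],
            right=clusters[j],
        )
        ni, nj = len(clusters[i].members), len(clusters[j].members)
        for k in clusters:
            if k in (i, j):
                continue
            dk = (ni * d[frozenset((i, k))] + nj * d[frozenset((j, k))]) / (ni + nj)
            d[frozenset((next_key, k))] = dk
        reprs[next_key] = min(reprs[i], reprs[j])
        del clusters[i], clusters[j]
        clusters[next_key] = node
        next_key += 1
    return clusters.popitem()[1]


@dataclass(frozen=True)
class MsaConfig:
    """Progressive-alignment parameters."""

    k: int = 3
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@lru_cache(maxsize=None)
def _submatrix(name: str) -> np.ndarray:
    """Substitution scores reindexed to the internal 21-letter code."""
    alphabet, mat = load_matrix(name)
    idx = [alphabet.index(c) for c in AA20 + "X"]
    return mat[np.ix_(idx, idx)].copy()


def _profile(rows: list[np.ndarray], n_letters: int = 21) -> np.ndarray:
    """Per-column residue frequencies (gaps carry no mass)."""
    L = len(rows[0])
    counts = np.zeros((L, n_letters))
    for r in rows:
        mask = r != _GAP_CODE
        np.add.at(counts, np.nonzero(mask)[0], np.eye(n_letters)[r[mask]])
    return counts / len(rows)


def _merge(rows_a, rows_b, cfg: MsaConfig) -> tuple[list[np.ndarray], list[np.ndarray]]:
    S21 = _submatrix(cfg.matrix)
    fa = _profile(rows_a)
    fb = _profile(rows_b)
    S = fa @ S21 @ fb.T
    _, ops = _dp.align_matrix(S, cfg.gap_open, cfg.gap_extend)
    ops = np.asarray(ops)
    take_a = ops != 2  # columns consuming profile a
    take_b = ops != 1
    L = len(ops)

    def expand(rows, take):
        out = []
        src = np.nonzero(take)[0]
        for r in rows:
            new = np.full(L, _GAP_CODE, dtype=np.int8)
            new[src] = r
            out.append(new)
        return out

    return expand(rows_a, take_a), expand(rows_b, take_b)


def progressive_align(
    records: list[ProteinRecord], config: MsaConfig = MsaConfig()
) -> MultipleAlignment:
    """Align a family progressively along a UPGMA guide tree.

    Rows of the result are in input order; ungapping any row recovers the
    corresponding input sequence exactly.
    """
    if not records:
        raise ValueError("empty record set")
    if len(records) < 2:
        raise ValueError("need at least two records to align")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = kmer_distance(
                records[i].sequence, records[j].sequence, config.k
            )
    guide = build_guide_tree(dm, ids)

    coded = [
        np.array([_CODE[c] for c in r.sequence], dtype=np.int8) for r in records
    ]

    def align_node(node: GuideNode) -> tuple[list[int], list[np.ndarray]]:
        if node.is_leaf:
            i = node.members[0]
            return [i], [coded[i]]
        mi, ra = align_node(node.left)
        mj, rb = align_node(node.right)
        # deterministic child order: block with the smallest id goes first
        if min(ids[k] for k in mj) < min(ids[k] for k in mi):
            mi, mj = mj, mi
            ra, rb = rb, ra
        ra, rb = _merge(ra, rb, config)
        return mi + mj, ra + rb

    members, rows = align_node(guide)
    by_input = {m: r for m, r in zip(members, rows)}
    decoded = [
        "".join(_DECODE[c] for c in by_input[i]) for i in range(n)
    ]
    out = MultipleAlignment(ids, decoded)
    for rec in records:  # ungapping invariant, cheap insurance
        assert out.ungapped(rec.id) == rec.sequence
    return out
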