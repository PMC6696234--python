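"""Distance-based phylogeny and labeled-clade subfamily classification.

The tree builder is Saitou--Nei Neighbor-Joining, which recovers the true
tree exactly whenever the input distances are additive.  Support values
come from the standard column-resampling bootstrap: replicate alignments
are drawn by sampling columns with replacement, a replicate NJ tree is
built from each, and each internal edge of the original tree is annotated
with the percentage of replicates containing its bipartition.

Subfamily calls are clade-based: a query takes the label of the smallest
edge-induced split that contains it together with at least one labeled
reference, provided every reference inside that split agrees; when no such
pure split exists the query falls back to its nearest reference by path
distance.  Evidence ("clade" vs "nearest-neighbor") is reported with every
call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .msa import MultipleAlignment
from .seqio import GAP

DISTANCE_MODELS = ("p", "poisson")


def _coded(msa: MultipleAlignment) -> np.ndarray:
    arr = np.frombuffer(
        "".join(msa.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(msa), msa.n_columns)
    return arr


def _distances_from_codes(
    arr: np.ndarray, ids: list[str], model: str
) -> np.ndarray:
    gap = ord(GAP)
    valid = arr != gap
    both = valid[:, None, :] & valid[None, :, :]
    shared = both.sum(axis=2)
    diff = ((arr[:, None, :] != arr[None, :, :]) & both).sum(axis=2)
    n = len(ids)
    iu = np.triu_indices(n, 1)
    if (shared[iu] == 0).any():
        i, j = next(zip(*[x[shared[iu] == 0] for x in iu]))
        raise ValueError(
            f"rows {ids[int(i)]!r} and {ids[int(j)]!r} share no aligned columns"
        )
    with np.errstate(invalid="ignore"):
        p = diff / np.where(shared == 0, 1, shared)
    np.fill_diagonal(p, 0.0)
    if model == "p":
        return p
    if model == "poisson":
        if (p[iu] >= 1.0).any():
            bad = np.argwhere((p >= 1.0) & np.triu(np.ones_like(p, bool), 1))[0]
            raise ValueError(
                f"p-distance >= 1 between {ids[bad[0]]!r} and {ids[bad[1]]!r}; "
                "Poisson correction undefined"
            )
        return -np.log(1.0 - p)
    raise ValueError(f"unknown distance model {model!r}")


def msa_distance(msa: MultipleAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise evolutionary distances from an alignment.

    ``p`` is the proportion of mismatches over columns where both rows have
    a residue; ``poisson`` applies the multiple-hit correction -ln(1 - p).
    """
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    if model not in DISTANCE_MODELS:
        raise ValueError(f"unknown distance model {model!r}")
    d = _distances_from_codes(_coded(msa), msa.ids, model)
    return DistanceMatrix(d, ids=msa.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou--Nei Neighbor-Joining with deterministic tie-breaking.

    Joins the pair minimizing the Q criterion; exact Q ties are broken by
    the lexicographically smallest pair of subtree labels (each subtree is
    labeled by its smallest leaf name).  Negative branch lengths are
    clamped to zero with the deficit moved to the sibling edge, the usual
    presentation convention.  The result is unrooted, represented with a
    trifurcating root.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes = [TreeNode(name=i) for i in ids]
    keys = list(ids)  # smallest leaf label under each working node

    def clamp_pair(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        i, j = min(
            (tuple(sorted((keys[a], keys[b]))), a, b)
            for a, b in cand
            if a < b
        )[1:]
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = D[i, j] - vi
        vi, vj = clamp_pair(vi, vj)
        a, b = nodes[i], nodes[j]
        a.length, b.length = vi, vj
        if keys[j] < keys[i]:
            a, b = b, a
        parent = TreeNode(children=[a, b])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    order = sorted(range(3), key=lambda k: keys[k])
    children = []
    for k in order:
        nodes[k].length = max(lens[k], 0.0)
        children.append(nodes[k])
    return TreeNode(children=children)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the tree as canonical tip-name sets.

    Each internal edge splits the tips in two; the side not containing the
    lexicographically smallest tip represents the split.  Trivial splits
    (single tip on one side) are excluded.
    """
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if anchor in side:
            side = frozenset(tips - side)
        out.add(side)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: size of the symmetric bipartition difference."""
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def bootstrap_support(
    msa: MultipleAlignment,
    model: str = "poisson",
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> TreeNode:
    """NJ tree from the full alignment, with bootstrap supports on its edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    node of the original tree is annotated (``node.support``, and
    ``node.name`` for Newick output) with the percentage of replicate trees
    containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(msa_distance(msa, model))
    arr = _coded(msa)
    L = arr.shape[1]
    counts: dict[frozenset, int] = {b: 0 for b in bipartitions(tree)}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        sub = arr[:, cols]
        try:
            d = _distances_from_codes(sub, msa.ids, model)
        except ValueError:
            continue  # degenerate resample (no shared columns / saturated)
        rep = neighbor_joining(DistanceMatrix(d, ids=msa.ids))
        for b in bipartitions(rep):
            if b in counts:
                counts[b] += 1
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        canon = side if anchor not in side else frozenset(tips - side)
        support = 100.0 * counts[canon] / n_reps
        node.support = support
        node.name = f"{support:.0f}"
    return tree


@dataclass
class SubfamilyAssignment:
    """One query's subfamily/subgroup call and the evidence behind it."""

    id: str
    subfamily: str
    subgroup: Optional[str]
    evidence: str  # "clade" or "nearest-neighbor"


def _pure_label_side(
    tree: TreeNode, query_id: str, labels: dict[str, str]
) -> Optional[str]:
    """Label of the smallest edge-induced split holding query + pure references."""
    tips = {t.name for t in tree.tips()}
    candidates = []
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset((node.name,))
        for side in (clade, frozenset(tips - clade)):
            if query_id not in side:
                continue
            ref_labels = {labels[t] for t in side if t in labels}
            if len(ref_labels) == 1:
                candidates.append((len(side), tuple(sorted(side)), ref_labels.pop()))
    if not candidates:
        return None
    return min(candidates)[2]


def _nearest_reference(tree: TreeNode, query_id: str, ref_ids) -> str:
    q = tree.find(query_id)
    best = min((q.distance(tree.find(r)), r) for r in sorted(ref_ids))
    return best[1]


def classify_subfamily(
    tree: TreeNode,
    reference_subfamilies: dict[str, str],
    query_id: str,
    reference_subgroups: Optional[dict[str, str]] = None,
) -> SubfamilyAssignment:
    """Assign a query to a subfamily from its placement among references.

    ``reference_subfamilies`` maps reference tip ids to subfamily labels;
    ``reference_subgroups`` optionally maps them to subgroup labels (e.g.
    "PIP2"), resolved the same way but restricted to references of the
    assigned subfamily so the subgroup is always consistent with it.
    """
    tip_names = {t.name for t in tree.tips()}
    refs = {r: l for r, l in reference_subfamilies.items() if r in tip_names}
    if not refs:
        raise ValueError("no labeled references present in the tree")
    if query_id not in tip_names:
        raise ValueError(f"query {query_id!r} not in the tree")

    label = _pure_label_side(tree, query_id, refs)
    if label is not None:
        evidence = "clade"
    else:
        nearest = _nearest_reference(tree, query_id, refs)
        label = refs[nearest]
        evidence = "nearest-neighbor"

    subgroup = None
    if reference_subgroups:
        sub_refs = {
            r: g
            for r, g in reference_subgroups.items()
            if r in tip_names and refs.get(r) == label
        }
        if sub_refs:
            subgroup = _pure_label_side(tree, query_id, sub_refs)
            if subgroup is None:
                subgroup = sub_refs[_nearest_reference(tree, query_id, sub_refs)]
    return SubfamilyAssignment(
        id=query_id, subfamily=label, subgroup=subgroup, evidence=evidence
    )


def classify_all(
    tree: TreeNode,
    reference_subfamilies: dict[str, str],
    query_ids: Optional[list[str]] = None,
    reference_subgroups: Optional[dict[str, str]] = None,
) -> list[SubfamilyAssignment]:
    """Classify every query tip (default: every unlabeled tip) in the tree."""
    if query_ids is None:
        query_ids = sorted(
            t.name for t in tree.tips() if t.name not in reference_subfamilies
        )
    return [
        classify_subfamily(tree, reference_subfamilies, q, reference_subgroups)
        for q in query_ids
    ]
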