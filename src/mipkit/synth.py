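"""Synthetic MIP-family generator with planted ground truth.

The generator emulates the statistical structure of a plant aquaporin
family so that every pipeline stage can be validated without downloads:

* five subfamilies (PIP/TIP/NIP/SIP/XIP) descending from a common master
  sequence, each carrying a subfamily signature at the anchored diagnostic
  slots (two NPA boxes, four ar/R filter residues, five Froger positions);
  default signatures follow the consensus patterns observed in plant
  families (e.g. PIP ar/R = F-H-T-R with Froger Q-S-A-F-W);
* conserved cores around every anchored site (substitution slowed by
  ``core_conservation`` within ``anchor_buffer`` columns), emulating the
  strong conservation of the NPA loops and transmembrane helix cores that
  makes anchored extraction well-posed in real families -- with fully
  random flanks the placement of small indels would be unidentifiable for
  any aligner;
* subfamily-specific deletion blocks confined to inter-anchor regions
  (variable termini and loops), so member lengths fall in realistic
  per-subfamily ranges while anchored sites and cores are never deleted --
  the truth alignment is simply the master coordinate system;
* members evolved along simulated trees by an i.i.d. per-site Poisson
  substitution process (uniform replacement, no rate heterogeneity -- a
  documented non-biological simplification);
* near-duplicate paralog pairs appended last: copies of random members
  re-mutated at a low rate, emulating recent duplicates;
* gene models with subfamily-typical intron counts, two genes left on an
  unanchored scaffold.

Anchored slots are frozen by default, so a failed motif recovery indicates
a pipeline bug, not simulation noise.  All outputs are deterministic under
``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from .motifs import MotifProfile, ReferenceAnchor
from .msa import MultipleAlignment
from .seqio import AA20, GAP, GffFeature, ProteinRecord, SUBFAMILIES, write_gff3


@dataclass(frozen=True)
class SubfamilySignature:
    """Planted diagnostic residues for one subfamily."""

    npa_lb: str
    npa_le: str
    arr: tuple[str, str, str, str]
    froger: tuple[str, str, str, str, str]


#: consensus-style signatures per subfamily (NPA boxes, ar/R, Froger P1-P5)
DEFAULT_SIGNATURES = {
    "PIP": SubfamilySignature("NPA", "NPA", ("F", "H", "T", "R"), ("Q", "S", "A", "F", "W")),
    "TIP": SubfamilySignature("NPA", "NPA", ("H", "I", "A", "V"), ("T", "S", "A", "Y", "W")),
    "NIP": SubfamilySignature("NPA", "NPA", ("W", "V", "A", "R"), ("F", "S", "A", "Y", "I")),
    "SIP": SubfamilySignature("NPT", "NPA", ("V", "L", "P", "N"), ("M", "A", "A", "Y", "W")),
    "XIP": SubfamilySignature("SPV", "NPA", ("V", "V", "V", "R"), ("M", "C", "A", "F", "W")),
}

#: typical intron counts per subfamily for synthetic gene models
DEFAULT_INTRON_COUNTS = {"PIP": 3, "TIP": 2, "NIP": 4, "SIP": 2, "XIP": 1}

#: per-subfamily mature-protein length ranges (aa)
DEFAULT_LENGTH_RANGES = {
    "PIP": (281, 289), "TIP": (239, 256), "NIP": (260, 306),
    "SIP": (236, 242), "XIP": (304, 309),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic family.

    ``per_site_rate`` is the substitution-event rate per site per unit
    branch length; pendant branches get ``pendant_branch_min`` added so
    sibling leaves never collapse onto each other, keeping background
    similarity well below the near-duplicate band.
    """

    n_subfamilies: int = 5
    members_per_subfamily: int = 10
    refs_per_subfamily: int = 2
    seq_length_range: tuple[int, int] = (236, 309)
    length_ranges: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_RANGES))
    signatures: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURES))
    intron_counts: dict = field(default_factory=lambda: dict(DEFAULT_INTRON_COUNTS))
    per_site_rate: float = 0.05
    subfamily_divergence: float = 0.4
    internal_branch_mean: float = 0.75
    pendant_branch_min: float = 3.0
    near_duplicate_count: int = 5
    near_duplicate_rate: float = 0.02
    anchor_site_mutation_rate: float = 0.0
    anchor_buffer: int = 8
    core_conservation: float = 0.25
    unplaced_count: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.per_site_rate, self.subfamily_divergence,
                  self.near_duplicate_rate, self.anchor_site_mutation_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.seq_length_range[0] < 50:
            raise ValueError("sequence lengths must be >= 50")
        if not (1 <= self.n_subfamilies <= len(SUBFAMILIES)):
            raise ValueError("n_subfamilies must be between 1 and 5")

    @property
    def subfamilies(self) -> tuple[str, ...]:
        return SUBFAMILIES[: self.n_subfamilies]


def paperlike_config(seed: int = 0) -> SynthConfig:
    """The default study conditions: a 5-subfamily family of ~50 queries."""
    return SynthConfig(rng_seed=seed)


# ---------------------------------------------------------------------------
# tree simulation

def simulate_tree(n_leaves: int, seed: Optional[int] = None,
                  branch_mean: float = 1.0) -> TreeNode:
    """Random birth (Yule-style) topology with exponential branch lengths.

    Leaves are named T1..Tn in creation order; deterministic under seed.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    leaves = []
    for _ in range(2):
        c = TreeNode()
        root.append(c)
        leaves.append(c)
    while len(leaves) < n_leaves:
        k = int(rng.integers(0, len(leaves)))
        node = leaves.pop(k)
        for _ in range(2):
            c = TreeNode()
            node.append(c)
            leaves.append(c)
    for i, leaf in enumerate(root.tips(), start=1):
        leaf.name = f"T{i}"
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(branch_mean))
    return root


def n_edges_unrooted(tree: TreeNode) -> int:
    """Edge count of the unrooted tree (a rooted-binary root merges two)."""
    edges = sum(1 for _ in tree.traverse(include_self=False))
    return edges - 1 if len(tree.children) == 2 else edges


# ---------------------------------------------------------------------------
# sequence evolution

_A2C = {c: i for i, c in enumerate(AA20)}


def _mutate(codes: np.ndarray, t: float, rate: float, rng,
            site_multipliers: Optional[np.ndarray] = None) -> np.ndarray:
    """Poisson substitution process: each event jumps to one of the 19
    other residues uniformly.  Per-site rates are ``rate * multiplier``."""
    out = codes.copy()
    lam = np.full(codes.shape, rate * t)
    if site_multipliers is not None:
        lam = lam * site_multipliers
    k = rng.poisson(lam)
    for step in range(1, int(k.max()) + 1 if k.size else 0):
        mask = k >= step
        n = int(mask.sum())
        if n:
            out[mask] = (out[mask] + rng.integers(1, 20, size=n)) % 20
    return out


def expected_p_distance(rate: float, path_length: float, n_states: int = 20) -> float:
    """Exact P(two sites differ) for the uniform-replacement Poisson process
    along a total path of the given length."""
    f = 1.0 - 1.0 / n_states
    return f * (1.0 - np.exp(-rate * path_length * n_states / (n_states - 1.0)))


# ---------------------------------------------------------------------------
# anchored-site layout on the master coordinate system

def _anchor_layout(master_len: int) -> dict[str, int]:
    """Deterministic anchored-site columns (1-based) on the master sequence,
    at AQP-like fractional positions; strictly increasing within each group."""
    M = master_len
    pos = {
        "H2": round(0.21 * M),
        "LB": round(0.28 * M),          # 3-column NPA box
        "P1": round(0.43 * M),
        "H5": round(0.67 * M),
        "LE1": round(0.71 * M),
        "LE": round(0.735 * M),         # 3-column NPA box
        "LE2": round(0.76 * M),
        "P2": round(0.775 * M),
        "P3": round(0.79 * M),
        "P4": round(0.81 * M),
    }
    pos["P5"] = pos["P4"] + 1
    return pos


def _anchored_columns(layout: dict[str, int]) -> set[int]:
    cols = set()
    for key, p in layout.items():
        if key in ("LB", "LE"):
            cols.update(range(p, p + 3))
        else:
            cols.add(p)
    return cols


@dataclass
class TruthTable:
    """Planted truth for every generated record."""

    sequences: pd.DataFrame          # id, subfamily, subgroup, duplicate_of
    profiles: dict[str, MotifProfile]
    pairs: list[tuple[str, str]]     # planted near-duplicate pairs (sorted ids)


@dataclass
class SynthFamily:
    """A generated family: records, references, truth, and coordinates."""

    records: list[ProteinRecord]          # query members + near-duplicates
    references: list[ProteinRecord]       # labeled panel (subfamily/subgroup)
    anchor_record: ProteinRecord          # annotated anchor sequence
    anchor: ReferenceAnchor
    alignment: MultipleAlignment          # truth alignment (master coords)
    truth: TruthTable
    trees: dict[str, TreeNode]            # per-subfamily simulated trees
    anchored_columns: dict[str, int]      # slot -> truth alignment column
    site_rate_multipliers: np.ndarray     # per master column, in [0, 1]
    config: SynthConfig

    @property
    def all_records(self) -> list[ProteinRecord]:
        return self.records + self.references + [self.anchor_record]


def _apply_signature(codes: np.ndarray, sig: SubfamilySignature,
                     layout: dict[str, int]) -> None:
    for k, ch in enumerate(sig.npa_lb):
        codes[layout["LB"] - 1 + k] = _A2C[ch]
    for k, ch in enumerate(sig.npa_le):
        codes[layout["LE"] - 1 + k] = _A2C[ch]
    for slot, ch in zip(("H2", "H5", "LE1", "LE2"), sig.arr):
        codes[layout[slot] - 1] = _A2C[ch]
    for slot, ch in zip(("P1", "P2", "P3", "P4", "P5"), sig.froger):
        codes[layout[slot] - 1] = _A2C[ch]


def _deletion_columns(total: int, layout: dict[str, int], master_len: int,
                      buffer: int, rng) -> set[int]:
    """Contiguous deletion blocks inside the three inter-anchor regions."""
    anchored = _anchored_columns(layout)
    lo_a, hi_a = min(anchored), max(anchored)
    regions = [
        (buffer + 1, layout["H2"] - buffer - 1),
        (layout["P1"] + buffer + 1, layout["H5"] - buffer - 1),
        (layout["P5"] + buffer + 1, master_len - buffer),
    ]
    caps = [max(0, b - a + 1) for a, b in regions]
    if total > sum(caps):
        raise ValueError("requested deletion exceeds deletable capacity")
    # largest-remainder proportional split
    alloc = [int(total * c / sum(caps)) for c in caps]
    while sum(alloc) < total:
        k = int(np.argmax([c - a for c, a in zip(caps, alloc)]))
        alloc[k] += 1
    cols: set[int] = set()
    for (a, b), take in zip(regions, alloc):
        if take == 0:
            continue
        start = a + int(rng.integers(0, b - a + 1 - take + 1))
        cols.update(range(start, start + take))
    assert not cols & anchored
    return cols


def _truth_profile(rid: str, sig: SubfamilySignature) -> MotifProfile:
    return MotifProfile(
        id=rid, npa_lb=sig.npa_lb, npa_le=sig.npa_le,
        arr=tuple(sig.arr), froger=tuple(sig.froger),
    )


def evolve_family(config: SynthConfig = SynthConfig()) -> SynthFamily:
    """Generate the family, its labeled reference panel, and all truth."""
    rng = np.random.default_rng(config.rng_seed)
    M = config.seq_length_range[1]
    layout = _anchor_layout(M)
    anchored = np.zeros(M, dtype=bool)
    for c in _anchored_columns(layout):
        anchored[c - 1] = True
    # conserved cores: slowed substitution within the buffer of any anchor
    core = np.zeros(M, dtype=bool)
    for c in _anchored_columns(layout):
        lo = max(0, c - 1 - config.anchor_buffer)
        hi = min(M, c + config.anchor_buffer)
        core[lo:hi] = True
    mult = np.ones(M)
    mult[core] = config.core_conservation
    mult[anchored] = config.anchor_site_mutation_rate

    family_anc = rng.integers(0, 20, size=M).astype(np.int64)

    records: list[ProteinRecord] = []
    references: list[ProteinRecord] = []
    rows: dict[str, str] = {}
    seq_rows = []
    profiles: dict[str, MotifProfile] = {}
    trees: dict[str, TreeNode] = {}
    member_master: dict[str, np.ndarray] = {}   # master-coordinate codes
    member_deleted: dict[str, set[int]] = {}
    pip_anc = None

    for sf in config.subfamilies:
        sig = config.signatures[sf]
        anc = family_anc.copy()
        # subfamily background divergence, slowed inside conserved cores
        hit = rng.random(M) < config.subfamily_divergence * mult
        n_div = int(hit.sum())
        anc[hit] = (anc[hit] + rng.integers(1, 20, size=n_div)) % 20
        _apply_signature(anc, sig, layout)
        if sf == config.subfamilies[0]:
            pip_anc = anc.copy()

        lo, hi = config.length_ranges.get(sf, config.seq_length_range)
        target_len = int(rng.integers(lo, hi + 1))
        deleted = _deletion_columns(M - target_len, layout, M,
                                    config.anchor_buffer, rng)
        keep = np.array([c not in deleted for c in range(1, M + 1)])

        n_leaves = config.members_per_subfamily + config.refs_per_subfamily
        tree = simulate_tree(max(n_leaves, 3),
                             seed=int(rng.integers(0, 2**31)),
                             branch_mean=config.internal_branch_mean)
        for tip in tree.tips():
            tip.length += config.pendant_branch_min

        leaf_names = [t.name for t in tree.tips()][:n_leaves]
        new_names = (
            [f"{sf}_{k + 1:02d}" for k in range(config.members_per_subfamily)]
            + [f"REF_{sf}_{r + 1}" for r in range(config.refs_per_subfamily)]
        )
        rename = dict(zip(leaf_names, new_names))

        leaf_codes: dict[str, np.ndarray] = {}

        def _walk(node, codes):
            for child in node.children:
                cc = _mutate(codes, child.length, config.per_site_rate, rng,
                             site_multipliers=mult)
                if child.is_tip():
                    leaf_codes[child.name] = cc
                else:
                    _walk(child, cc)

        _walk(tree, anc)

        for old, new in rename.items():
            tree.find(old).name = new
        trees[sf] = tree

        for k, new in enumerate(new_names):
            old = leaf_names[k]
            codes = leaf_codes[old]
            seq = "".join(AA20[c] for c in codes[keep])
            row = "".join(
                AA20[c] if keep[i] else GAP for i, c in enumerate(codes)
            )
            is_ref = new.startswith("REF_")
            rec = ProteinRecord(
                id=new, sequence=seq,
                subfamily_label=sf if is_ref else None,
                subgroup_label=f"{sf}1" if is_ref else None,
            )
            (references if is_ref else records).append(rec)
            rows[new] = row
            member_master[new] = codes
            member_deleted[new] = deleted
            profiles[new] = _truth_profile(new, sig)
            seq_rows.append(
                {"id": new, "subfamily": sf, "subgroup": f"{sf}1",
                 "is_reference": is_ref, "duplicate_of": ""}
            )

    # near-duplicate pairs: mutated copies of random members, appended last
    pairs: list[tuple[str, str]] = []
    member_ids = [r.id for r in records]
    dup_sources = rng.choice(member_ids, size=config.near_duplicate_count,
                             replace=False)
    for src in dup_sources:
        src = str(src)
        sf = src.split("_")[0]
        codes = member_master[src].copy()
        deleted = member_deleted[src]
        keep = np.array([c not in deleted for c in range(1, M + 1)])
        hit = (rng.random(M) < config.near_duplicate_rate * mult) & keep
        n = int(hit.sum())
        codes[hit] = (codes[hit] + rng.integers(1, 20, size=n)) % 20
        dup_id = f"{src}d"
        rec = ProteinRecord(id=dup_id, sequence="".join(AA20[c] for c in codes[keep]))
        records.append(rec)
        rows[dup_id] = "".join(
            AA20[c] if keep[i] else GAP for i, c in enumerate(codes)
        )
        profiles[dup_id] = _truth_profile(dup_id, config.signatures[sf])
        pairs.append(tuple(sorted((src, dup_id))))
        seq_rows.append(
            {"id": dup_id, "subfamily": sf, "subgroup": f"{sf}1",
             "is_reference": False, "duplicate_of": src}
        )

    # annotated anchor sequence: undeleted first-subfamily background
    anchor_mult = mult.copy()
    anchor_mult[anchored] = 0.0  # the annotated anchor keeps its signature
    anchor_codes = _mutate(pip_anc, 1.0, config.per_site_rate, rng,
                           site_multipliers=anchor_mult)
    anchor_rec = ProteinRecord(
        id="AQP_REF", sequence="".join(AA20[c] for c in anchor_codes)
    )
    rows["AQP_REF"] = anchor_rec.sequence  # full master length, gap-free
    anchor = ReferenceAnchor(
        ref_id="AQP_REF",
        arr_positions=tuple(layout[s] for s in ("H2", "H5", "LE1", "LE2")),
        froger_positions=tuple(layout[s] for s in ("P1", "P2", "P3", "P4", "P5")),
        npa_lb_start=layout["LB"],
        npa_le_start=layout["LE"],
    )
    sig0 = config.signatures[config.subfamilies[0]]
    profiles["AQP_REF"] = _truth_profile("AQP_REF", sig0)

    all_ids = [r.id for r in records] + [r.id for r in references] + ["AQP_REF"]
    alignment = MultipleAlignment(all_ids, [rows[i] for i in all_ids])
    truth = TruthTable(
        sequences=pd.DataFrame(seq_rows),
        profiles=profiles,
        pairs=sorted(pairs),
    )
    slot_cols = {}
    for key, p in layout.items():
        if key == "LB":
            for k in range(3):
                slot_cols[f"LB{k + 1}"] = p + k
        elif key == "LE":
            for k in range(3):
                slot_cols[f"LE{k + 1}box"] = p + k
        else:
            slot_cols[key] = p
    return SynthFamily(
        records=records, references=references, anchor_record=anchor_rec,
        anchor=anchor, alignment=alignment, truth=truth, trees=trees,
        anchored_columns=slot_cols, site_rate_multipliers=mult, config=config,
    )


# ---------------------------------------------------------------------------
# synthetic gene models

def synthetic_gff(config: SynthConfig = SynthConfig(),
                  seed: Optional[int] = None) -> tuple[str, pd.DataFrame]:
    """GFF3 text for the family's gene models plus the planted truth table.

    Exon counts follow the per-subfamily intron patterns; ``unplaced_count``
    genes are placed on unanchored scaffolds so they cannot be assigned to
    a chromosome.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    fam_ids = []
    for sf in config.subfamilies:
        fam_ids += [f"{sf}_{k + 1:02d}" for k in range(config.members_per_subfamily)]
    n_chrom = 17
    cursors: dict[str, int] = {}
    features: list[GffFeature] = []
    truth_rows = []
    unplaced = set(
        str(g) for g in rng.choice(fam_ids, size=config.unplaced_count, replace=False)
    )
    for k, gid in enumerate(fam_ids):
        sf = gid.split("_")[0]
        n_exons = config.intron_counts[sf] + 1
        if gid in unplaced:
            seqid = f"Scaffold{1000 + len([g for g in truth_rows if g['chromosome'] == 'UNPLACED'])}"
            chrom_truth = "UNPLACED"
        else:
            seqid = f"Chr{(k % n_chrom) + 1:02d}"
            chrom_truth = seqid
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors.get(seqid, 0) + int(rng.integers(500, 5000))
        exons = []
        pos = start
        for e in range(n_exons):
            ex_len = int(rng.integers(80, 400))
            exons.append((pos, pos + ex_len - 1))
            pos += ex_len + int(rng.integers(85, 800))
        end = exons[-1][1]
        cursors[seqid] = end
        features.append(GffFeature(seqid, "gene", start, end, strand, id=gid))
        mid = f"{gid}.t1"
        features.append(GffFeature(seqid, "mRNA", start, end, strand,
                                   id=mid, parent=gid))
        for e, (s, t) in enumerate(exons, start=1):
            features.append(GffFeature(seqid, "exon", s, t, strand,
                                       id=f"{mid}.e{e}", parent=mid))
        truth_rows.append(
            {"gene_id": gid, "chromosome": chrom_truth, "strand": strand,
             "start": start, "end": end, "n_exons": n_exons,
             "n_introns": n_exons - 1}
        )
    return write_gff3(features), pd.DataFrame(truth_rows)
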