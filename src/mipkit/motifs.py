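"""Reference-anchored extraction of aquaporin diagnostic residues.

Aquaporin substrate selectivity is read from a handful of positions: the
two NPA tripeptide boxes in loops B and E, the four-residue aromatic/
arginine (ar/R) selectivity filter (helix 2, helix 5, and loop E positions
1 and 2), and the five Froger positions P1--P5.  On human AQP1 the ar/R
filter is F58-H182-C191-R197 and the Froger positions are
T116-S196-A200-F212-W213; those coordinates are the default anchor.

Extraction is anchored: the positions are defined once on an annotated
reference sequence, mapped through the reference's row of a multiple
alignment to alignment columns, and each query's residues are read off at
those columns.  Reading mapped columns (rather than regex-matching the
query) is what lets variant boxes -- NPS, NPV, NPL, NPT, NPE, NPI, SPV,
SPA -- be reported faithfully.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .msa import MultipleAlignment
from .seqio import GAP, ProteinRecord

#: ar/R filter coordinates on human AQP1 (H2, H5, LE1, LE2)
AQP1_ARR_POSITIONS = (58, 182, 191, 197)
#: Froger position coordinates on human AQP1 (P1..P5)
AQP1_FROGER_POSITIONS = (116, 196, 200, 212, 213)

ARR_SLOTS = ("H2", "H5", "LE1", "LE2")
FROGER_SLOTS = ("P1", "P2", "P3", "P4", "P5")


@dataclass(frozen=True)
class ReferenceAnchor:
    """Diagnostic-site coordinates on an annotated reference sequence.

    All coordinates are 1-based residue indices on the ungapped reference
    ("F58" means the 58th residue).  ``npa_lb_start``/``npa_le_start`` are
    the first residues of the loop-B and loop-E tripeptide boxes.
    """

    ref_id: str
    arr_positions: tuple[int, int, int, int] = AQP1_ARR_POSITIONS
    froger_positions: tuple[int, int, int, int, int] = AQP1_FROGER_POSITIONS
    npa_lb_start: int = 0
    npa_le_start: int = 0

    def __post_init__(self) -> None:
        for group, name in ((self.arr_positions, "ar/R"),
                            (self.froger_positions, "Froger")):
            if list(group) != sorted(group) or len(set(group)) != len(group):
                raise ValueError(f"{name} positions must be strictly increasing")
        if len(self.arr_positions) != 4 or len(self.froger_positions) != 5:
            raise ValueError("anchor needs 4 ar/R and 5 Froger positions")
        if self.npa_lb_start and self.npa_le_start:
            if self.npa_le_start <= self.npa_lb_start:
                raise ValueError("loop-E NPA must follow loop-B NPA")

    def all_positions(self) -> dict[str, int]:
        """Slot name -> 1-based reference residue index (boxes expanded)."""
        out = {}
        for k in range(3):
            out[f"LB{k + 1}"] = self.npa_lb_start + k
            out[f"LE{k + 1}box"] = self.npa_le_start + k
        for slot, pos in zip(ARR_SLOTS, self.arr_positions):
            out[slot] = pos
        for slot, pos in zip(FROGER_SLOTS, self.froger_positions):
            out[slot] = pos
        return out


def locate_npa_on_reference(ref: ProteinRecord) -> tuple[int, int]:
    """1-based start positions of the loop-B and loop-E NPA boxes.

    The loop-B box is the first exact "NPA" in the N-terminal half of the
    sequence, the loop-E box the first in the C-terminal half.  References
    with variant boxes (fewer than two exact NPA matches, or none in one
    half) are rejected so the anchor can be entered manually.
    """
    seq = ref.sequence
    starts = []
    pos = seq.find("NPA")
    while pos != -1:
        starts.append(pos + 1)
        pos = seq.find("NPA", pos + 1)
    half = len(seq) / 2
    n_half = [s for s in starts if s <= half]
    c_half = [s for s in starts if s > half]
    if len(starts) < 2 or not n_half or not c_half:
        raise ValueError(
            f"reference {ref.id!r}: need one NPA box in each half of the "
            f"sequence (found starts {starts}); enter anchor positions manually"
        )
    return n_half[0], c_half[0]


def anchor_from_reference(
    ref: ProteinRecord,
    arr_positions: tuple = AQP1_ARR_POSITIONS,
    froger_positions: tuple = AQP1_FROGER_POSITIONS,
) -> ReferenceAnchor:
    """Build an anchor for ``ref``, locating its NPA boxes automatically."""
    lb, le = locate_npa_on_reference(ref)
    anchor = ReferenceAnchor(
        ref_id=ref.id,
        arr_positions=tuple(arr_positions),
        froger_positions=tuple(froger_positions),
        npa_lb_start=lb,
        npa_le_start=le,
    )
    top = max(anchor.all_positions().values())
    if top + 0 > len(ref.sequence):
        raise ValueError(
            f"anchor position {top} beyond reference length {len(ref.sequence)}"
        )
    return anchor


@dataclass
class MotifProfile:
    """Per-protein diagnostic residues; '-' marks a gap at a mapped column."""

    id: str
    npa_lb: str
    npa_le: str
    arr: tuple[str, str, str, str]
    froger: tuple[str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.npa_lb) != 3 or len(self.npa_le) != 3:
            raise ValueError("NPA boxes must be 3 characters")
        if len(self.arr) != 4 or len(self.froger) != 5:
            raise ValueError("need 4 ar/R and 5 Froger residues")

    def slots(self) -> dict[str, str]:
        """Flat slot-name -> value view (boxes as whole tripeptides)."""
        out = {"NPA_LB": self.npa_lb, "NPA_LE": self.npa_le}
        out.update(zip(ARR_SLOTS, self.arr))
        out.update(zip(FROGER_SLOTS, self.froger))
        return out


def map_reference_positions(
    msa: MultipleAlignment, anchor: ReferenceAnchor
) -> dict[str, int]:
    """Map each anchored reference residue to its alignment column (1-based)."""
    colmap = msa.colmap(anchor.ref_id)
    ref_len = len(msa.ungapped(anchor.ref_id))
    out = {}
    for slot, pos in anchor.all_positions().items():
        if not (1 <= pos <= ref_len):
            raise ValueError(
                f"anchor position {pos} ({slot}) beyond reference length {ref_len}"
            )
        out[slot] = colmap[pos]
    return out


def extract_profile(
    msa: MultipleAlignment, anchor: ReferenceAnchor, query_id: str
) -> MotifProfile:
    """Read a query's diagnostic residues at the anchor-mapped columns."""
    if query_id not in msa.ids:
        raise ValueError(f"query {query_id!r} not in the alignment")
    cols = map_reference_positions(msa, anchor)
    row = msa.row(query_id)

    def at(slot: str) -> str:
        return row[cols[slot] - 1]

    return MotifProfile(
        id=query_id,
        npa_lb="".join(at(f"LB{k}") for k in (1, 2, 3)),
        npa_le="".join(at(f"LE{k}box") for k in (1, 2, 3)),
        arr=tuple(at(s) for s in ARR_SLOTS),
        froger=tuple(at(s) for s in FROGER_SLOTS),
    )


def summarize_conservation(
    profiles: Iterable[MotifProfile], assignments: dict[str, str]
) -> pd.DataFrame:
    """Per-subfamily consensus of every diagnostic slot.

    For each (subfamily, slot): the modal value, the percent of members
    carrying it, and the ids deviating from it.  NPA boxes are summarized
    as whole tripeptides; the remaining nine slots as single residues.
    """
    by_subfam: dict[str, list[MotifProfile]] = {}
    for p in profiles:
        sf = assignments.get(p.id)
        if sf is None:
            continue
        by_subfam.setdefault(sf, []).append(p)
    if not by_subfam:
        raise ValueError("no profile has a subfamily assignment")
    rows = []
    for sf in sorted(by_subfam):
        members = by_subfam[sf]
        for slot in ("NPA_LB", "NPA_LE", *ARR_SLOTS, *FROGER_SLOTS):
            values = [(p.id, p.slots()[slot]) for p in members]
            counts = Counter(v for _, v in values)
            consensus, n_mode = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            deviants = sorted(i for i, v in values if v != consensus)
            rows.append(
                {"subfamily": sf, "slot": slot, "consensus": consensus,
                 "agreement_pct": 100.0 * n_mode / len(values),
                 "n": len(values), "deviants": ",".join(deviants)}
            )
    return pd.DataFrame(
        rows, columns=["subfamily", "slot", "consensus", "agreement_pct",
                       "n", "deviants"]
    )


def read_anchor_tsv(path) -> ReferenceAnchor:
    """Read an anchor file: TSV with columns ref_id, site_class, ref_position.

    Site classes: arr_H2, arr_H5, arr_LE1, arr_LE2, froger_P1..P5, npa_lb,
    npa_le (box starts).
    """
    df = pd.read_csv(path, sep="\t")
    need = {"ref_id", "site_class", "ref_position"}
    if not need.issubset(df.columns):
        raise ValueError(f"anchor file must have columns {sorted(need)}")
    ref_ids = df["ref_id"].unique()
    if len(ref_ids) != 1:
        raise ValueError("anchor file must describe exactly one reference")
    sites = dict(zip(df["site_class"], df["ref_position"].astype(int)))
    try:
        return ReferenceAnchor(
            ref_id=str(ref_ids[0]),
            arr_positions=tuple(sites[f"arr_{s}"] for s in ARR_SLOTS),
            froger_positions=tuple(sites[f"froger_{s}"] for s in FROGER_SLOTS),
            npa_lb_start=sites["npa_lb"],
            npa_le_start=sites["npa_le"],
        )
    except KeyError as exc:
        raise ValueError(f"anchor file missing site class {exc}") from None


def write_anchor_tsv(anchor: ReferenceAnchor, path=None) -> str:
    """Serialize an anchor as the TSV format read by :func:`read_anchor_tsv`."""
    rows = [("npa_lb", anchor.npa_lb_start), ("npa_le", anchor.npa_le_start)]
    rows += [(f"arr_{s}", p) for s, p in zip(ARR_SLOTS, anchor.arr_positions)]
    rows += [
        (f"froger_{s}", p) for s, p in zip(FROGER_SLOTS, anchor.froger_positions)
    ]
    lines = ["ref_id\tsite_class\tref_position"]
    lines += [f"{anchor.ref_id}\t{c}\t{p}" for c, p in rows]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
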