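"""Input/output for the formats the pipeline touches: FASTA, GFF3, Newick, TSV.

Conventions
-----------
* Protein sequences are uppercase strings over the 20 standard amino acids
  plus ``X`` (unknown residue).  A single *terminal* stop ``*`` is stripped
  on input; an internal stop is an error.
* FASTA deflines are NCBI-style: the token before the first whitespace is
  the record id.
* GFF3 coordinates are 1-based inclusive and stay that way through every
  transformation in this package.
* Newick trees carry branch lengths; internal-node labels hold bootstrap
  support values when present.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, alphabetical one-letter codes
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet accepted in input sequences
ALPHABET = frozenset(AA20) | {"X"}
#: gap character used in alignments
GAP = "-"
#: the five higher-plant aquaporin subfamilies
SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")


@dataclass
class ProteinRecord:
    """One protein sequence plus annotation slots carried from external tools.

    ``tmd_annotation`` (transmembrane-domain count) and ``loc_annotation``
    (subcellular localization) are pass-through annotations from upstream
    predictors; this package never computes them.
    """

    id: str
    sequence: str
    accession: Optional[str] = None
    subfamily_label: Optional[str] = None
    subgroup_label: Optional[str] = None
    tmd_annotation: Optional[int] = None
    loc_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record must have a non-empty id")
        seq = self.sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(seq) - ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue character(s) {''.join(bad)!r}"
            )
        self.sequence = seq
        if self.subfamily_label is not None and self.subfamily_label not in SUBFAMILIES:
            raise ValueError(
                f"record {self.id!r}: unknown subfamily {self.subfamily_label!r}"
            )
        if self.tmd_annotation is not None and self.tmd_annotation < 0:
            raise ValueError(f"record {self.id!r}: negative TMD count")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    The id is the defline token before the first whitespace.  Duplicate ids
    and illegal residue characters raise ``ValueError``.  An empty file
    yields an empty list (with a logged warning).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path=None, width: int = 60) -> str:
    """Serialize records as FASTA; write to ``path`` when given."""
    out = []
    for rec in records:
        out.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), width):
            out.append(rec.sequence[i : i + width])
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


GFF_TYPES = ("gene", "mRNA", "exon", "CDS")


@dataclass
class GffFeature:
    """A single GFF3 feature (1-based inclusive coordinates)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    id: Optional[str] = None
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in GFF_TYPES:
            raise ValueError(f"unsupported feature type {self.type!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.id or self.type}: invalid interval "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.type in ("gene", "mRNA") and self.strand not in ("+", "-"):
            raise ValueError(
                f"feature {self.id or self.type}: {self.type} requires strand +/-, "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gff3(source) -> list[GffFeature]:
    """Parse GFF3 (path or text) into validated :class:`GffFeature` objects.

    Only gene/mRNA/exon/CDS features are kept; others are skipped with a log
    message.  Parent links come from the ``Parent`` attribute.  Invalid
    intervals (end < start) and genes with undefined strand raise
    ``ValueError``.
    """
    import gffutils

    text = source if "\n" in str(source) else open(source).read()
    # gffutils swaps start/end silently for malformed intervals; validate first
    for ln in text.splitlines():
        if ln.startswith("#") or not ln.strip():
            continue
        cols = ln.split("\t")
        if len(cols) >= 5:
            try:
                s, e = int(cols[3]), int(cols[4])
            except ValueError:
                continue
            if e < s:
                raise ValueError(f"GFF3 feature with end < start: {ln!r}")
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[GffFeature] = []
    for f in db.all_features():
        if f.featuretype not in GFF_TYPES:
            logger.info("skipping unsupported feature type %r", f.featuretype)
            continue
        parent = f.attributes.get("Parent", [None])[0]
        fid = f.attributes.get("ID", [None])[0] or f.id
        feats.append(
            GffFeature(
                seqid=f.seqid, type=f.featuretype, start=f.start, end=f.end,
                strand=f.strand, id=fid, parent=parent,
            )
        )
    return feats


def write_gff3(features: Iterable[GffFeature], path=None) -> str:
    """Serialize features as GFF3 text; write to ``path`` when given."""
    lines = ["##gff-version 3"]
    for f in features:
        attrs = []
        if f.id:
            attrs.append(f"ID={f.id}")
        if f.parent:
            attrs.append(f"Parent={f.parent}")
        lines.append(
            "\t".join(
                [f.seqid, "mipkit", f.type, str(f.start), str(f.end), ".",
                 f.strand, ".", ";".join(attrs) or "."]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    """Read a Newick tree (path, file handle, or string) into a TreeNode."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(source))
    return TreeNode.read(source)


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize a tree to Newick with branch lengths and support labels.

    Every leaf must be labeled and labels must be unique; internal-node
    names (bootstrap supports) are written as internal labels.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 leaves")
    names = [t.name for t in tips]
    if any(n is None or n == "" for n in names):
        raise ValueError("every leaf must be labeled")
    if len(set(names)) != len(names):
        raise ValueError("leaf labels must be unique")
    buf = io.StringIO()
    tree.write(buf)
    text = buf.getvalue().strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
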