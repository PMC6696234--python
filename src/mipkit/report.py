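"""Pipeline driver: compose all stages and emit the family-characterization
tables (physicochemical profile, subfamily assignments, paralog pairs,
diagnostic-residue table, gene structure) plus the bootstrap-annotated tree.

The pipeline is a pure function of (inputs, config, seed): rerunning with
identical inputs produces byte-identical TSVs.  The hydropathy-based
``TM_segments`` column and the pass-through ``TMD_annot`` column are both
printed, clearly labeled, because the sliding-window count is an
approximation and is not expected to match HMM-based predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from skbio import TreeNode

from . import genestruct, motifs, pairwise, physchem, phylo
from .msa import MsaConfig, MultipleAlignment, progressive_align, write_alignment
from .pairwise import PairingConfig
from .seqio import GffFeature, ProteinRecord, write_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters in one bundle."""

    pairing: PairingConfig = field(default_factory=PairingConfig)
    msa: MsaConfig = field(default_factory=MsaConfig)
    distance_model: str = "poisson"
    bootstrap_reps: int = 100
    pka_table: str = "bjellqvist"
    kd_window: int = 19
    kd_threshold: float = 1.6
    merge_gap: int = 5
    chromosome_pattern: str = genestruct.CHROMOSOME_PATTERN


@dataclass
class FamilyReport:
    """All pipeline outputs, one table per analysis stage."""

    family: pd.DataFrame
    motif_profiles: pd.DataFrame
    pairs: pd.DataFrame
    assignments: pd.DataFrame
    tree: TreeNode
    newick: str
    alignment: MultipleAlignment
    genes: Optional[pd.DataFrame] = None
    chromosomes: Optional[genestruct.ChromosomeTable] = None


def family_table(
    summaries: list[physchem.PhyschemSummary],
    assignments: dict[str, phylo.SubfamilyAssignment],
    accessions: Optional[dict[str, str]] = None,
) -> str:
    """Family-profile TSV: one row per protein, input order preserved.

    MW and pI are printed to two decimals; missing annotation cells are
    empty.  Every summary id must have an assignment.
    """
    missing = [s.id for s in summaries if s.id not in assignments]
    if missing:
        raise ValueError(f"no subfamily assignment for: {missing}")
    header = ["Name", "Accession", "Size(aa)", "MW(Da)", "pI",
              "TM_segments", "TMD_annot", "Loc", "Subfamily", "Subgroup",
              "Evidence"]
    lines = ["\t".join(header)]
    for s in summaries:
        a = assignments[s.id]
        acc = (accessions or {}).get(s.id, "") or ""
        lines.append("\t".join([
            s.id, acc, str(s.length), f"{s.mw:.2f}", f"{s.pi:.2f}",
            str(s.tm_segments),
            "" if s.tmd_annotation is None else str(s.tmd_annotation),
            s.loc_annotation or "", a.subfamily, a.subgroup or "",
            a.evidence,
        ]))
    return "\n".join(lines) + "\n"


def motif_table(profiles: list[motifs.MotifProfile]) -> str:
    """Diagnostic-residue TSV: NPA boxes, ar/R filter, Froger P1-P5.

    Gaps at mapped columns are rendered as '-'.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    header = ["Name", "NPA_LB", "NPA_LE", "H2", "H5", "LE1", "LE2",
              "P1", "P2", "P3", "P4", "P5"]
    lines = ["\t".join(header)]
    for p in profiles:
        lines.append("\t".join([p.id, p.npa_lb, p.npa_le, *p.arr, *p.froger]))
    return "\n".join(lines) + "\n"


def run_pipeline(
    records: list[ProteinRecord],
    references: list[ProteinRecord],
    anchor: motifs.ReferenceAnchor,
    anchor_record: Optional[ProteinRecord] = None,
    gff_features: Optional[list[GffFeature]] = None,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    outdir=None,
) -> FamilyReport:
    """Run every stage on a query family against a labeled reference panel.

    ``references`` must carry ``subfamily_label`` (and optionally
    ``subgroup_label``); the anchor's reference sequence must be among the
    inputs or supplied as ``anchor_record``.  Stage failures abort with the
    stage name and offending id in the exception message.
    """
    if not records:
        raise ValueError("no query records")
    ref_labels = {r.id: r.subfamily_label for r in references if r.subfamily_label}
    if not ref_labels:
        raise ValueError("references must carry subfamily labels")
    subgroups = {r.id: r.subgroup_label for r in references if r.subgroup_label}

    pka = physchem.PKA_TABLES[config.pka_table]
    summaries = []
    for rec in records:
        try:
            summaries.append(physchem.summarize(
                rec, pka=pka, kd_window=config.kd_window,
                kd_threshold=config.kd_threshold, merge_gap=config.merge_gap,
            ))
        except Exception as exc:
            raise RuntimeError(f"physchem stage failed on {rec.id!r}: {exc}") from exc

    msa_input = list(records) + list(references)
    ids_present = {r.id for r in msa_input}
    if anchor.ref_id not in ids_present:
        if anchor_record is None or anchor_record.id != anchor.ref_id:
            raise ValueError(
                f"anchor reference {anchor.ref_id!r} not among inputs"
            )
        msa_input.append(anchor_record)
    logger.info("aligning %d sequences", len(msa_input))
    alignment = progressive_align(msa_input, config.msa)

    logger.info("building NJ tree with %d bootstrap replicates (seed=%d)",
                config.bootstrap_reps, seed)
    tree = phylo.bootstrap_support(
        alignment, model=config.distance_model,
        n_reps=config.bootstrap_reps, seed=seed,
    )
    query_ids = [r.id for r in records]
    try:
        calls = phylo.classify_all(tree, ref_labels, query_ids, subgroups)
    except Exception as exc:
        raise RuntimeError(f"classification stage failed: {exc}") from exc
    assignments = {c.id: c for c in calls}
    assign_df = pd.DataFrame(
        [{"id": c.id, "subfamily": c.subfamily, "subgroup": c.subgroup or "",
          "evidence": c.evidence} for c in calls]
    )

    logger.info("scanning %d query sequences for paralog pairs", len(records))
    pair_hits = pairwise.find_paralog_pairs(records, config.pairing) \
        if len(records) > 1 else []
    pairs_df = pd.DataFrame(pair_hits, columns=["id_a", "id_b", "similarity"])

    profs = []
    for rid in query_ids:
        try:
            profs.append(motifs.extract_profile(alignment, anchor, rid))
        except Exception as exc:
            raise RuntimeError(f"motif stage failed on {rid!r}: {exc}") from exc
    motif_df = pd.DataFrame(
        [{"id": p.id, **p.slots()} for p in profs]
    )

    genes_df = None
    chrom_table = None
    if gff_features is not None:
        try:
            models = genestruct.gene_models_from_gff(
                gff_features, config.chromosome_pattern
            )
            genes_df = genestruct.structure_table(models)
            chrom_table = genestruct.chromosome_table(models)
        except Exception as exc:
            raise RuntimeError(f"gene-structure stage failed: {exc}") from exc

    fam_df = pd.read_csv(
        __import__("io").StringIO(
            family_table(summaries, assignments,
                         {r.id: r.accession for r in records})
        ), sep="\t", keep_default_na=False,
    )
    report = FamilyReport(
        family=fam_df, motif_profiles=motif_df, pairs=pairs_df,
        assignments=assign_df, tree=tree, newick=write_newick(tree),
        alignment=alignment, genes=genes_df, chromosomes=chrom_table,
    )
    if outdir is not None:
        write_report(report, summaries, profs, assignments, records, outdir)
    return report


def write_report(report: FamilyReport, summaries, profs, assignments,
                 records, outdir) -> None:
    """Write every report table (TSV), the alignment, and the tree."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "family.tsv").write_text(
        family_table(summaries, assignments, {r.id: r.accession for r in records})
    )
    (out / "motifs.tsv").write_text(motif_table(profs))
    report.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    report.assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    (out / "tree.nwk").write_text(report.newick + "\n")
    write_alignment(report.alignment, out / "alignment.afa")
    if report.genes is not None:
        report.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        rows = [
            {"chromosome": c, "genes": ",".join(g)}
            for c, g in report.chromosomes.by_chromosome.items()
        ]
        rows.append({"chromosome": "UNPLACED",
                     "genes": ",".join(report.chromosomes.unplaced)})
        pd.DataFrame(rows).to_csv(out / "chromosomes.tsv", sep="\t", index=False)
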