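# mipkit

A toolkit for characterizing MIP/aquaporin (AQP) gene families from protein
sequences and genome annotation. Plant genomes encode dozens of aquaporins
falling into five subfamilies — PIP, TIP, NIP, SIP and XIP — and a standard
family paper characterizes the set the same way every time: physicochemical
profile per protein, a Neighbor-Joining phylogeny against labeled reference
AQPs to assign subfamilies, detection of recently duplicated paralog pairs,
extraction of the pore-determining residues (the two NPA boxes, the ar/R
selectivity filter, Froger's positions P1–P5), and intron/exon structure
per gene. `mipkit` implements that whole workflow as a reusable, testable
pipeline.

## What it computes

* **Physicochemical profile** — length, average molecular weight
  (Σ residue masses + H₂O), isoelectric point (bisection on the
  Henderson–Hasselbalch net charge, Bjellqvist pKa set by default), and a
  Kyte–Doolittle sliding-window count of candidate membrane segments
  (window 19, threshold 1.6). HMM-based TMD counts and subcellular
  localizations from external predictors are carried as annotations, never
  recomputed.
* **Phylogeny and classification** — progressive multiple alignment (UPGMA
  guide tree, profile–profile Needleman–Wunsch, BLOSUM62), Poisson-corrected
  distances d = −ln(1 − p), Saitou–Nei Neighbor-Joining, and column-resampling
  bootstrap supports. A query takes the subfamily of the smallest clade that
  contains it together with exclusively same-label references (falling back
  to the nearest reference by path distance).
* **Paralog pairs** — affine-gap global alignment of every pair; pairs above
  a similarity threshold (default >90%, "positives" or strict-identity mode)
  are reported as candidate recent duplicates.
* **Diagnostic residues** — NPA(LB), NPA(LE), ar/R (H2, H5, LE1, LE2) and
  Froger P1–P5, read off at alignment columns mapped from an annotated
  anchor sequence (human AQP1 coordinates F58-H182-C191-R197 and
  T116-S196-A200-F212-W213 are the built-in default). Reading anchored
  columns rather than regex-matching the query is what reports variant
  boxes (NPS, NPV, SPA, …) faithfully.
* **Gene structure** — exon/intron counts from GFF3 (longest isoform) and a
  per-chromosome table with unplaced scaffolds listed separately.
* **Synthetic families** — a generator that plants subfamily signatures,
  near-duplicate pairs, deletion blocks and gene models with full truth
  tables, so the entire pipeline is validated end-to-end with no downloads.

## Worked example

Generate a synthetic family at the default study conditions (5 subfamilies
× 10 members, 2 labeled references each, 5 planted near-duplicate pairs at
2% divergence) and run the full pipeline on it:

```bash
mipkit synth --seed 3 --out fam/
mipkit run --fasta fam/queries.fasta --refs-fasta fam/refs.fasta \
           --refs fam/refs.tsv --anchor fam/anchor.tsv \
           --anchor-fasta fam/anchor.fasta --gff fam/family.gff3 \
           --out out/ --seed 3
head -3 out/family.tsv
head -4 out/motifs.tsv
mipkit pairs --fasta fam/queries.fasta | head -4
```

prints

```
Name    Accession  Size(aa)  MW(Da)    pI    TM_segments  TMD_annot  Loc  Subfamily  Subgroup  Evidence
PIP_01             282       33597.36  6.03  0                            PIP        PIP1      clade
PIP_02             282       33448.38  8.17  0                            PIP        PIP1      clade

Name    NPA_LB  NPA_LE  H2  H5  LE1  LE2  P1  P2  P3  P4  P5
PIP_01  NPA     NPA     F   H   T    R    Q   S   A   F   W
PIP_02  NPA     NPA     F   H   T    R    Q   S   A   F   W
PIP_03  NPA     NPA     F   H   T    R    Q   S   A   F   W

id_a    id_b      similarity
NIP_01  NIP_01d   99.65
NIP_10  NIP_10d   99.31
PIP_03  PIP_03d   98.58
```

Each `family.tsv` row is one protein: its length, molecular weight (Da) and
pI as computed here, the hydropathy segment count, and the subfamily call
with its evidence. The `motifs.tsv` rows show that every PIP member carries
the canonical F-H-T-R filter and twin NPA boxes — exactly the planted
signatures. The pair table recovers the five planted near-duplicates and
nothing else. `out/tree.nwk` holds the bootstrap-annotated NJ tree and
`out/genes.tsv` the intron counts (3 per PIP-like gene, 2 per TIP-like,
and so on), with the two scaffold-bound genes listed as UNPLACED in
`out/chromosomes.tsv`.

The same commands run on a real family: supply the family FASTA, a labeled
reference panel (e.g. the *Arabidopsis* AQPs), an anchor TSV with the AQP1
coordinates, and the genome's GFF3.

## Layout

| module | role |
|---|---|
| `mipkit.seqio` | FASTA / GFF3 / Newick / TSV I/O with validation |
| `mipkit.physchem` | MW, pI, hydropathy segments |
| `mipkit.pairwise` | affine-gap global alignment, % identity/similarity, pair detection |
| `mipkit.msa` | k-mer distances, UPGMA guide tree, progressive alignment |
| `mipkit.phylo` | distances, Neighbor-Joining, bootstrap, clade classification |
| `mipkit.motifs` | anchored NPA / ar/R / Froger extraction and conservation summary |
| `mipkit.genestruct` | gene models, intron counts, chromosome table |
| `mipkit.synth` | synthetic families with planted truth |
| `mipkit.report` | pipeline driver and table assembly |

See `docs/methods.md` for the models, parameter choices and limitations.
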