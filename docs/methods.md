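# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Physicochemical profile

**Molecular weight** is the sum of average (not monoisotopic) residue
masses plus one water (18.01524 Da), the scale used by the common web
calculators. `X` residues have no defined mass and are excluded with a
logged warning.

**Isoelectric point.** The net charge at pH x is the Henderson–Hasselbalch
sum over ionizable groups: positive terms for the N-terminus, H, K, R
(`1/(1+10^(x−pKa))`) and negative for the C-terminus, D, E, C, Y
(`−1/(1+10^(pKa−x))`). Every term is strictly decreasing in pH, so the
root is unique; it is found by bisection on [0, 14] until |charge| < 1e-4
(≈0.002 pH units of positional error in the flattest realistic curves).
The default pKa set is Bjellqvist-style (D 4.05, E 4.45, C 9.0, Y 10.0,
H 5.98, K 10.0, R 12.0; termini 7.5/3.55), matching the scale of the
standard web tool; an EMBOSS set is selectable. Whether published values
were computed on precursor or processed chains is usually unstated; the
full input sequence is always used here.

**Membrane segments** are counted as maximal runs of 19-residue windows
with mean Kyte–Doolittle hydropathy ≥ 1.6, merging runs separated by
fewer than 5 positions. This is a transparent approximation, *not* a
reimplementation of HMM topology predictors: the report prints this count
(`TM_segments`) and any externally supplied TMD annotation side by side
and makes no claim that they agree.

## Pairwise alignment and paralog pairs

Global alignment is Gotoh's three-state affine-gap DP under BLOSUM62 with
gap open 10 and extend 0.5 (conventional protein defaults); a length-L gap
costs `open + (L−1)·extend`, terminal gaps included. Ties are broken
diagonal > up > left so the traceback is unique and reproducible.

"Similarity" between two proteins is reported under two operational
definitions, because the term is ambiguous in the literature: strict
identity, and *positives* (aligned pairs with positive substitution
score — the default, since that is what alignment viewers label
"similarity"). Both use the full alignment length, gap columns included,
in the denominator, so length differences count against a pair; the
denominator convention is switchable. Pairs above the threshold (default
90%) are reported as candidate recent duplicates; a protein may occur in
several pairs.

## Multiple alignment

The aligner is classic progressive alignment: 3-mer dissimilarity
(`1 − shared/min-total`) feeds a UPGMA guide tree; profiles are merged
bottom-up by profile–profile Needleman–Wunsch with sum-of-pairs scoring
(column frequency vectors over residues; gaps carry no mass, so a gap
scores 0 against anything) and the same affine penalties as above. Once a
gap column enters a profile it is never removed. There is no iterative
refinement — a documented limitation — and no attempt to reproduce any
particular external aligner column-for-column. Every downstream stage
consumes the `MultipleAlignment` container, so an externally computed
aligned FASTA can be imported in place of the built-in aligner.

All ties (guide-tree merges, child ordering) resolve through sorted
sequence ids: the alignment is a pure function of the input *set*, and
permuting input order permutes only the row order.

## Distances, tree, bootstrap

p-distance is the mismatch fraction over columns where both rows have
residues; the Poisson correction −ln(1−p) is the default model (standard
for proteins; p-distance is selectable). Pairs sharing no columns, or
saturated pairs (p ≥ 1) under the correction, raise errors naming the pair.

Neighbor-Joining follows Saitou–Nei with the Q criterion. Exact Q ties are
broken by the lexicographically smallest pair of subtree labels, so the
tree is reproducible; negative branch lengths are clamped to zero with the
deficit moved to the sibling edge (presentation convention; path lengths
are preserved). On additive matrices NJ is exact, which the tests exploit
as an oracle: distances generated from a known tree must return that tree
to machine precision.

Bootstrap supports resample alignment columns with replacement, rebuild
the NJ tree per replicate, and annotate each internal edge of the
*original* tree with the percentage of replicates containing its
bipartition — the standard "support on the best tree" presentation, not a
consensus tree. Degenerate replicates (a pair left with no shared columns
or saturated) are skipped and count against support. 1000 replicates is
the conventional choice; the pipeline default is 100, which bounds support
resolution at 1% and keeps the end-to-end run in seconds at family sizes
of ~50–100.

## Subfamily classification

References are tips with known subfamily (and optionally subgroup)
labels. A query is assigned by the smallest edge-induced split containing
the query and at least one reference in which *all* references share one
label (`evidence=clade`); if no pure split exists, the nearest reference
by path distance decides (`evidence=nearest-neighbor`). Subgroups are
resolved the same way, restricted to references of the assigned subfamily
so the subgroup is always consistent with it. The procedure is invariant
to leaf order and needs no rooting.

## Anchored motif extraction

The diagnostic positions are defined once on an annotated anchor sequence
— human AQP1 coordinates (ar/R F58-H182-C191-R197; Froger
T116-S196-A200-F212-W213) are the built-in default — with the two NPA
boxes located by scanning the anchor for exact `NPA` tripeptides, one
expected in each half of the sequence (references with variant boxes must
be annotated manually via the anchor TSV). Each anchored residue index
maps through the anchor's alignment row to a column; the query's residues
are read at those columns, with `-` reported where the query is gapped.
Per-subfamily anchor overrides are supported for families whose divergent
loops align poorly to a single anchor.

## Gene structure

Intron count is exons − 1 on the exon intervals of the longest annotated
isoform (total exon length; ties by mRNA id) — whether published counts
use CDS or mRNA exons is often unstated; exon-based counting is used and
stated. Genes whose seqid does not match the chromosome naming pattern
(default `Chr\d+`) are reported UNPLACED. Genes lacking exon features are
treated as single-exon over their own interval, logged.

## Synthetic families

The generator exists to make every stage testable against planted truth
with zero downloads. Its default parameters *are* the study conditions the
tests and the acceptance script run at:

* 5 subfamilies × 10 members, 2 labeled references each; member lengths
  drawn per subfamily (PIP 281–289, TIP 239–256, NIP 260–306, SIP 236–242,
  XIP 304–309 aa) inside a 236–309 master range.
* A 309-column master coordinate system with 15 anchored columns (two
  3-column NPA boxes + 4 ar/R + 5 Froger) laid out at AQP-like fractional
  positions. Subfamily ancestors carry consensus-style signatures at those
  columns (PIP: NPA/NPA, F-H-T-R, Q-S-A-F-W; TIP: H-I-A-V; NIP: W-V-A-R;
  SIP: NPT box, V-L-P-N; XIP: SPV box, V-V-V-R). Anchored columns are
  frozen by default (`anchor_site_mutation_rate=0`), so motif-recovery
  failures indicate pipeline bugs, not simulation noise.
* Substitution is an i.i.d. per-site Poisson process (rate 0.05 events per
  site per unit branch, uniform replacement over the other 19 residues, no
  rate heterogeneity) along simulated birth trees (exponential internal
  branches, mean 0.75; pendant branches get +3.0 so sibling leaves never
  collapse into the near-duplicate similarity band). Within-subfamily
  divergence lands around 25–40%, between subfamilies 55–70%.
* Conserved cores: within 8 columns of any anchored site the substitution
  rate (and the 40% between-subfamily background divergence) is scaled by
  0.25. This emulates the strong conservation of the NPA loops and
  transmembrane helix cores in real aquaporins, and it is what makes
  anchored extraction well-posed: with fully random flanks the position of
  a small deletion is unidentifiable for *any* aligner, and the planted
  "truth" would not be a meaningful target.
* Length variation comes from subfamily-level contiguous deletion blocks
  confined to three inter-anchor regions (variable termini and a loop),
  never touching anchors or cores — so the truth alignment is simply the
  master coordinate system and contains no insertions.
* Near-duplicate pairs: 5 members are copied and re-mutated at 2% per
  site, emulating recent duplicates; planted pairs sit at ≥97% similarity
  versus ≤~80% background, so the 90% threshold separates them cleanly.
* Gene models: subfamily-typical intron counts (PIP-like 3, TIP-like 2,
  NIP-like 4, SIP-like 2, XIP-like 1), 17 chromosomes, and 2 genes on
  unanchored scaffolds.

What the generator does **not** emulate: insertion evolution and
within-subfamily indels, substitution-rate heterogeneity beyond the
core/non-core distinction, compositional bias (synthetic sequences are
uniform-random, so hydropathy segment counts are near zero and MW/pI have
no familial structure), codon-level effects, and EST/expression data.
Passing the synthetic suite therefore demonstrates the *pipeline logic*
(coordinate bookkeeping, tree correctness, threshold behavior, recovery of
planted structure), not the field realism of any particular biological
inference.

## Numerical conventions

1-based inclusive coordinates for GFF3 intervals and for residue positions
("F58" is the 58th residue); alignment columns are 1-based. All RNG flows
through `numpy.random.default_rng` seeds exposed at every API; reruns with
identical inputs and seeds are byte-identical. Q-criterion and guide-tree
ties break lexicographically; DP ties break diagonal > up > left.
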