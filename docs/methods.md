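# Methods

`protoscan` implements a pipeline for detecting **proto-genes** — ancestrally
silent genomic regions that gain stable transcription (and occasionally
translation) downstream of new mutations — in an evolving bacterial lineage,
together with a synthetic-study generator that provides planted ground truth
for every stage. This note documents the models, the numerical choices, and
what the synthetic data does and does not establish.

## Coordinate engineering

Evolved clone genomes are reconstructed by applying GenomeDiff-style
mutation records (SNP, DEL, INS, MOB) to the ancestral sequence. Instead of
re-aligning sequences to recover evolved coordinates, the package builds an
exact ancestral↔evolved coordinate map during application, so interval
liftover is deterministic and lossless. Conventions:

- GenomeDiff positions are 1-based (breseq dialect); everything in memory is
  0-based half-open; BED output is 0-based half-open.
- INS inserts *after* its position. MOB inserts the element plus a
  target-site duplication (default 3 bp, typical for IS150-class elements,
  overridable per record); a − strand insertion carries the reverse
  complement of the element.
- Mutations must be mutually non-overlapping; overlapping records are
  rejected rather than resolved, because reconciled clone mutation lists
  satisfy this and any resolution rule would be arbitrary. AMP/INV records
  are rejected loudly — no supported analysis needs them.
- Lift statuses: `clean` (no mutation intersects), `contains-indel(size)`
  (largest net inserted/deleted span among intersecting events; a SNP gives
  size 0), `partial` (some bases deleted), `deleted` (all bases deleted).
  The genome is treated as linear; no interval wraps the origin.

## Window survey

The ancestral genome is tiled into fixed-width windows (default 400 bp) on
both strands; the terminal partial window is dropped. "Sliding" is
implemented as non-overlapping tiling (step = window size, configurable),
the only reading consistent with ~18.7k windows of 400 bp over a 4.6-Mb
genome on two strands. Windows are dropped if, in any clone, they are
deleted or carry a net indel > 10 bp (strict), or if they overlap an
annotated repeat/IS element by ≥ 1 bp on either strand. The multi-mapping
filter of aligner-based workflows is a deliberate no-op under exact
liftover: without duplications a window's sequence cannot legitimately map
twice, and imitating an aligner artifact would add noise, not fidelity.

Categorization: a window is `annotated` when its same-strand overlap with
any annotated gene (coding, RNA, pseudogene; extents = coding sequence)
exceeds 10 bp — strictly, so a tie at exactly 10 bp stays non-genic;
otherwise `antisense` when a protein-coding gene overlaps it by ≥ 1 bp on
the opposite strand (RNA genes do not create antisense status); otherwise
`intergenic`. Non-genic windows touching (≥ 1 bp, inclusive) the 300-bp
upstream or 100-bp downstream flank of a same-strand gene are flagged
`gene_adjacent` to account for transcription initiation before the start
codon and readthrough past the stop.

## Quantification

Read intervals are counted with **nonunique-all** semantics: a read
increments every same-strand feature it overlaps by ≥ 1 bp. Expression
units: NRC = count / feature length (bp) and TPM = NRC / ΣNRC × 10⁶, where
the denominator runs over the feature universe of the current analysis only
(windows for the genome-wide survey; candidate regions + annotated genes
for detection). The two universes are never mixed. TPM cutoff comparisons
(> 1, > 5) are strict; exact-boundary values are excluded. Paired-end
evidence is counted as fragments (union of mate intervals); ribosome
profiling uses the identical counting path with no P-site offsetting.

## Differential expression

Counts are modelled NB2 (Var = μ + αμ²) with a log-link GLM
log μ = log s + x'β, where s are median-of-ratios size factors (fallback to
column-sum ratios when no feature has all-positive counts; scaled to
geometric mean 1). The two-group test uses an intercept plus group
indicator; the Wald statistic is β₁/SE with a two-sided normal p-value and
Benjamini–Hochberg adjustment over the tested family (one family per run).
Features with total count < 2 are skipped, not tested. Significant gain of
transcription additionally requires log₂FC > 0. Thresholds default to
p_adj < 0.05 (transcription) and q < 0.01 (translation).

Numerical choices that matter:

- **Dispersion**: per-feature method of moments on normalized counts using
  within-group moments — E[pooled within-group variance] = mean(μ_g) +
  α·mean(μ_g²) — so genuine between-group signal does not inflate α. A
  hyperbolic trend α(m) = a₀ + a₁/m is fitted by least squares on the
  *unfloored* moment estimates (Poisson-like data pulls the trend to zero
  rather than inheriting the flooring bias), and each feature's estimate is
  pulled 0.9 of the way toward the trend (weight configurable). At 2 vs 2
  replicates the raw per-feature estimate has ~2 degrees of freedom and is
  nearly uninformative; the strong trend weight is what keeps the null
  type-I error at α = 0.05 in the 0.05–0.06 range (weights ≤ 0.5 leave the
  test visibly anti-conservative, ~0.07–0.09).
- **Pseudocount**: the GLM is fitted on counts + 0.25. When one group is
  all-zero the NB MLE is degenerate (the coefficient diverges and the Wald
  statistic collapses); the pseudocount keeps estimates finite and is
  negligible at the counts where p-values matter. Fold changes are the raw
  GLM coefficients — no posterior shrinkage.
- **IRLS**: vectorized across features; convergence when the relative
  deviance change is < 10⁻⁸, at most 100 iterations; non-converged features
  are flagged and carry no p-value.
- DESeq2-style apeglm shrinkage, Cook's-distance outlier handling and
  independent filtering are deliberately not reproduced: they affect
  effect-size display more than the p < 0.05 calls this pipeline consumes.

**Differential translation** stacks RNA and Ribo counts and fits covariates
assay, group, and assay×group; the BH-adjusted interaction Wald p-value is
the q-value. A transcription-only change moves both assays equally and
leaves the interaction at zero — the confound control this design exists
for. At 2 replicates per cell, an 8-fold translation-only gain at mean 100
yields an interaction z of ≈ 4.4, so per-feature power at q < 0.01 is
roughly 0.8, an intrinsic limit of the design rather than of the
implementation.

## Detection cascade

For every mutation, 100- and 200-bp regions immediately downstream are
extracted in evolved coordinates — on both strands, except MOB insertions,
which anchor only on the strand read outward from the element's
promoter-bearing end (after the target-site duplication for + orientation,
into the left flank for −). "Immediately downstream" means the first base
after the mutation's footprint in the evolved genome: after the junction
for DEL, after the inserted bases for INS, after the variant base for SNP.
Regions running off a genome end are truncated and flagged.

Stages, each recorded in a per-region filter trail (an excluded region
names exactly one deciding filter):

1. **Overlap filter** — strict > 10-bp same-strand overlap with any
   annotated gene, RNA gene, pseudogene or repeat excludes the region.
2. **DE test** — on the combined regions+genes transcriptome; a mutation ×
   strand unit carries forward if *either* length variant is significant
   (a strict mode requiring both is available; observation suggests some
   real events are visible only in the shorter region).
3. **Dedup** — identical evolved-coordinate regions from adjacent mutations
   keep the first in genome order; regions overlapping a repeat on the
   opposite strand are removed.
4. **Ancestral silence** — a quantitative stand-in for visual inspection of
   coverage plots: `silent` iff in ALL ancestral replicates the region's
   mean per-base coverage is below max(0.1 × genome-wide median, 1 read)
   AND no contiguous ≥ 25-bp run reaches 3 reads; `expressed` iff the mean
   reaches max(median, 1 read) in any replicate; otherwise `ambiguous`
   (the three-way verdict preserves the ambiguous class of the original
   procedure). The exact rule the original visual inspection implied is
   unrecoverable; every threshold here is config-exposed.
5. **Condition screen** — `seen` iff the region draws ≥ 3 reads in at least
   one external condition (per-condition rule, no pooling; the 3-read floor
   follows the display floor of the source data, which never states its
   cutoff numerically). Seen candidates are excluded.
6. **Cause classification** — MOB → "promoter in insertion sequence";
   DEL ≥ 1,000 bp with a same-strand gene ending within 500 bp upstream of
   the new junction → "translocation to existing promoter" (otherwise
   labelled as a large deletion with no identified promoter); SNP/small
   indel → promoter status unknown.
7. **ORF scan** — from 200 bp upstream of the mutation anchor to 500 bp
   downstream on the transcribed strand: maximal ORFs (ATG/GTG/TTG start to
   in-frame stop, stop included in the length) in all three frames,
   strictly > 30 bp; ORFs entirely upstream of the anchor are discarded.

The same cascade runs on Ribo-seq counts for novel translation. The
cross-check against an external transcript catalogue is out of scope; the
report carries a placeholder column for a user-supplied verdict. An IS
survey utility reports, for every insertion of a named element, the
downstream DE and silence verdicts with summary counts.

## Synthetic study design

The generator emulates the data structure of a long-term evolution
experiment at desk scale. Defaults: 50-kb linear genome; 40 genes of
300–900 bp with 50–400-bp intergenic gaps on both strands plus two repeat
annotations; 100 mutually non-overlapping mutations with class weights
SNP 0.80, small indel 0.157, MOB 0.03, large deletion 0.013 (95.7%
SNP+small-indel mass); IS element of 1,443 bp; 5 planted proto-genes at
50-fold gain (IS insertions planted preferentially, then large deletions,
mirroring the observed dominance of promoter recruitment); 2 replicates per
group; NB2 dispersion 0.1; a 34-condition ancestor expression library with
one planted region made condition-expressed at ~30 reads. Random streams
are split per stage from the master seed, so changing one stage's
parameters does not perturb another's draws.

Depth and noise parameters are not fixed by the emulated study and were set
by an a priori design analysis so the generated truth is self-consistent:

- RNA/Ribo library size 1.2 × 10⁶ reads: a silent 200-bp region at the
  non-genic baseline draws ~1.8 reads per replicate and its planted
  counterpart ~90, giving the Wald test a z ≈ 6 while keeping ancestral
  evidence below the silence floor.
- Read length 28 bp (ribosome-footprint scale): per-base coverage of a
  silent region stays near 0.25×, well under the 1 read/base floor.
- Non-genic baseline 0.01 TPM: low-but-nonzero stochastic transcription.
  At 0.02 TPM roughly 5% of truly silent regions exceeded the silence floor
  by chance — the ground truth contradicted itself — so the baseline is the
  value at which "planted silent" is actually silent.
- External condition library 7.5 × 10⁴ reads per condition: a silent region
  draws ~0.05 reads per condition, far below the 3-read visibility floor
  even across 34 conditions, while the planted condition-expressed region
  (30 reads) is unambiguously seen.

Ancestral coverage tracks are built from one read population: gene reads
follow the simulated ancestor count columns; non-genic background is placed
once per merged (interval-union) region locus, since candidate regions
overlap and nest and per-feature placement would double-count coverage.

**What the synthetic data does not emulate**: sequencing error, mapping
bias and multi-mapping, rRNA contamination, fragment-length variation,
operonic structure and correlated expression, condition-to-condition
correlation in the external library, duplications/inversions, and circular
chromosome topology. Passing the planted-truth tests therefore shows that
the pipeline's logic and statistics behave as specified under the assumed
noise model — not that real-data artifacts (chimeric alignments, repeat
family cross-mapping, coverage unevenness) are handled.

## Problem sizes in the tests

The test suite and the acceptance script use 10⁴ null features for
calibration checks, 10³ embedded signal features for power, 5 independent
50-kb scenarios (500 mutations, 25 planted events) for end-to-end recovery,
and 10-seed brute-force oracle sweeps for counting, categorization and
liftover; the whole suite runs in a few seconds on one CPU.

## Known limitations

- The Wald normal approximation at 2 vs 2 replicates is only as good as the
  trend-stabilized dispersion; single-feature analyses without a trend
  (few features) fall back to a median-based trend and will be less
  calibrated.
- Size factors absorb genuine global shifts: if a large fraction of
  features change in one direction, null features acquire a compensating
  apparent change (a known property of median-of-ratios normalization).
- `lift_back` reports `clean` for evolved intervals that map 1:1 even when
  they contain a substituted base; only forward lifting distinguishes SNPs.
- The cause classifier checks for an upstream gene, not an upstream
  promoter; a deletion fusing a region to a promoterless gene end is still
  labelled a translocation.
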