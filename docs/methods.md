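# Methods

This note documents the models and conventions behind each stage, the
defaults and why they were chosen, the design decisions made where the
underlying procedure is underdetermined, and the limits of what the
synthetic benchmark demonstrates.

## Input model and conventions

All scores operate on a log-normalized gene × cell matrix (non-negative;
`log1p` of library-size-normalized counts).  When raw counts are supplied,
a single normalization is applied at load: counts are scaled to the median
cell depth and `log1p`-transformed.  Where a fold change on the natural
scale is needed, `expm1` undoes the log.  Gene symbols are matched exactly
and case-sensitively — alias resolution is deliberately absent, as silent
symbol mapping is a reproducibility hazard.  MatrixMarket files are 1-based
on disk per the standard; all in-memory indices are 0-based, converted only
at the I/O boundary.  Readers validate and fail naming the offending
identifier; the only silent repair anywhere is whitespace trimming in
annotation values, which is logged.

## Marker specificity (CESG)

A cell "detects" a gene when its normalized value is strictly above a
threshold (default 0; configurable).  CESG = pct.1 / pct.2 with CESG = ∞
for exclusive detection and 0 for an undetected gene.  Decisions where the
procedure is underdetermined:

* *Reference aggregation*: "CESG greater than the known markers" is read as
  greater than the **maximum** CESG among the type's known markers — the
  conservative choice among max/mean/min.
* *Infinite references*: if any known marker is itself exclusively
  detected, the reference is infinite and a candidate can only be called
  when it is also infinite with a larger pct.1.
* Types without a known-marker set yield candidates flagged
  `no_reference`, never called novel.  The downstream literature check that
  separates a "candidate" from a genuinely novel marker is manual curation
  and out of scope.

## Cell-type abundance (ACT)

ACT(c, k) = (n_ck / n_k) / (n_c / n_total), the observed/expected
(Ro/e-style) ratio.  This form was adopted because it satisfies the
"enriched iff ACT > 1" semantics and, importantly, reproduces the published
fold differences (2.7, 8.5 and 1.56) from the published ACT values — an
interpretive choice, since abundance ratios appear in the literature in
several variants.  Cells are pooled across donors; per-donor behaviour can
be inspected by stratifying on the donor field.  No shrinkage, continuity
correction or significance test is applied: raw ratios are reported with
the contingency table so small-count instability is visible.  The ratio
satisfies an exact conservation law (Σ_k ACT(c,k)·n_k = n_total for every
type) used as an internal consistency check.

## Differential expression

Wilcoxon rank-sum, two-sided.  For pooled sizes above 12 the tie-corrected
normal approximation with a 0.5 continuity correction is used (the
`wilcox.test` convention); at or below 12 cells the null distribution is
enumerated exactly over all group assignments, conditioning on observed
ties, with two-sided p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.  The fold
change is `log2((mean(expm1 x_a)+1)/(mean(expm1 x_b)+1))` — group means on
the de-logged scale with pseudocount 1, which keeps it finite.  Adjustment
is Bonferroni by default (the convention the 0.05/0.25 thresholds are
calibrated against in the upstream tooling); Benjamini–Hochberg is
available.  All genes detected in at least one cell of either group are
tested; a `min_pct` prefilter exists for speed but defaults to off.  DEG
calling keeps |avg_log2FC| ≥ 0.25 (inclusive, two-sided) and p_adj < 0.05
(strict).  Null simulations hold the raw-p rejection rate at 4.8–5.0% at
the 5% level.

## Expression patterns

Multiplicative-update NMF on the Frobenius objective from a seeded uniform
random initialization; the objective is non-increasing at every update and
a fixed seed yields bitwise-identical factors.  Convergence: relative
Frobenius error change < 1e-5 or 200 iterations (the pipeline default uses
100 — adequate for the rank-based AUC downstream, which stabilizes long
before the objective's tail).  A full Bayesian sparse factorization would
offer uncertainty quantification; the decomposition is used here purely as
a source of cell-associated gene sets, for which seeded NMF is a
reproducible, well-understood stand-in.  The rank k is a plain
configuration parameter (no automatic selection); 10 is the default at
synthetic scale.

Predictive power is the midrank Mann–Whitney AUROC of a pattern's cell
weights for one type versus the rest, optionally stratified by condition;
the ≥ 0.7 selection threshold is boundary-inclusive.  Pattern gene
membership — needed to use a pattern in the overlap test — is the top 50
genes by amplitude weight (ties broken by gene id), configurable to a
weight quantile; the choice is a declared guess, as no canonical membership
rule exists for NMF amplitudes.

## Regulon activity and specificity

Regulon target sets are inputs; inferring them (co-expression modules plus
motif pruning against a cisTarget-style database) is upstream and out of
scope.  RAS ranks each cell's genes by descending expression — ties broken
by a fixed permutation seeded from the cell index, so the score is
reproducible without a global RNG — and takes the area under the target
recovery step curve within the top 5% of ranks (the customary AUCell
cutoff), normalized by the maximal achievable area.

RSS(R, C) = 1 − JSD(P^R, P^C) exactly as printed in the originating
formula, although some implementations use 1 − √JSD; the divergence uses
log base 2 so RSS ∈ [0, 1].  The Z-score gate standardizes a regulon's
per-type mean RAS across cell types (population SD).  Two consequences
worth knowing: (a) with T cell types a single-type spike attains z =
√(T−1), so the z ≥ 2 gate needs at least 6 types to be attainable by a
clean one-type regulon — with fewer types, lower the gate or rely on RSS;
(b) the "z ≥ 2" phrase is ambiguous in its source ("in all cell types");
it is evaluated here for the focal type against the distribution across
all types.  Condition-wise RSS log2 fold changes recompute RAS and RSS
within each condition and are clipped to ±10, with ±10 sentinels for
zero denominators/numerators and 0 when both conditions are silent.

## Loop construction

The printed overlap formula is the hypergeometric point mass; a point mass
cannot coherently gate "P < 0.05" (it vanishes for any large sets), so
P_loop is the upper tail P(X ≥ k), computed as a log-space sum of log point
masses.  The exact point mass is exposed separately (`hypergeom_pmf`,
integer-combinatorics arithmetic) for comparison against the printed
formula.  The universe N defaults to the genes of the analyzed matrix.  No
multiple-testing correction is applied to P_loop (the raw 0.05 gate is the
documented procedure); a BH option exists, off by default.  Only
cross-kind pairs are tested, and a ternary loop requires all three pairwise
edges — the strictest reading of "ternary".  Pathway annotation is pure
set membership (≥ 1 shared gene by default) of loop nodes against
user-supplied pathway gene sets; communication inference itself is out of
scope.

## Synthetic data

Counts are negative-binomial (gamma–Poisson) with gene-specific log-normal
baselines (log-mean 0, log-sd 0.6, i.e. mean ≈ 1.2 counts) and common
dispersion θ = 2, then library-size normalized and log1p-transformed.
Default shape: 8 cell types × 2 conditions × 100 cells, 2,000 genes.
Planted per type: one exclusive novel marker (mean e² ≈ 7.4 in-type, zero
elsewhere), two known markers (in-type mean × e²), a 50-gene program
(× e^1.5 in-type), a 20-target regulon (× e² in-type), and 20 condition
DEGs (× e^1.4 in disease cells of the type), with 15 genes deliberately
shared among program, regulon targets and DEG set to form a ternary loop.
Two extra regulons are active only in the disease stratum of their type.
Effect sizes were fixed once so that every planted structure is
comfortably recoverable under the default sampling noise (the DEG shift is
e^1.4 ≈ 4× because weakly expressed genes at ~3× sit on the Bonferroni
boundary at 100 + 100 cells); they are frozen and not revisited per test.
An effect of zero disables the corresponding plant, giving exact null
configurations (`SimulationConfig.null()`).

Region and donor labels are generated but carry no signal by default;
`region_bias` plants an uneven macula:periphery odds for one type to
exercise regional abundance analysis.

*What passing tests show*: that the scoring machinery is correct and
well-calibrated under its own model (NB noise, discrete plants, no
batch/doublet/ambient artefacts, discrete cell types).  They do not show
robustness to the failure modes of real dissociation data, nor that any
particular biological marker or loop would replicate.

## Problem sizes

Defaults were chosen so a full pipeline run (2,000 × 1,600, k = 10, 10
regulons) takes a few seconds: the recovery suite runs 10 seeded
replicates and the acceptance script 3, each a complete end-to-end run.
The exact rank-sum branch is limited to 12 pooled cells (C(12,6) = 924
enumerations per gene); the hypergeometric oracle sweep enumerates all
draws for universes up to 12 genes.

## Known limitations

* The NMF stand-in means pattern gene sets depend on the seed and rank;
  factors can share residual variance, so a type's factor occasionally
  shows mild (AUC ≈ 0.7) association with a second type.
* RAS tie-breaking by a per-cell-index permutation is reproducible but
  arbitrary for heavily tied (sparse) cells with few detected genes.
* ACT has no uncertainty quantification by design; judge stability from
  the counts table.
* The novel-marker caller emits candidates; distinguishing genuinely novel
  markers requires literature curation outside the package.
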