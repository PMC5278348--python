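# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `hapblocks`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A `GenotypePanel` is a lines × SNPs matrix of biallelic calls over fully
homozygous inbred lines, with a genetic map in cM. Because the material is
inbred, each line contributes one haploid-equivalent gamete per locus:
**all frequencies count each line once**. Diploid counting would only double
every count and leave all the ratios unchanged.

Heterozygous calls — rare array artefacts on selfing-crop material — are
**treated as missing by default** wherever a phase-free haplotype is needed
(LD, block haplotypes, painting, GWAS dosages). How such calls were handled
upstream of block construction in array studies of this kind is generally
unstated; treating them as missing is the conservative choice and is exposed
as a `het_as_missing` flag throughout.

cM positions are real-valued and ties are allowed (co-located markers give
legitimate zero-span blocks); within a tie, SNPs order by id so every run is
deterministic. A SNP mapping to more than one chromosome is rejected at
load time. Missing-data symbols per dialect: `NA`/`-` in TSV, `NN` in
HapMap genotypes, `./.` in VCF.

## LD statistics

Two-locus haplotype frequencies are counted directly from lines homozygous
at both SNPs (no EM). From the counts, `D = p_AB − p_A p_B`,
`D′ = |D|/D_max`, `r² = D²/(p_A p_a p_B p_b)`, with
`D_max = min(p_A p_b, p_a p_B)` for `D > 0` and `min(p_A p_B, p_a p_b)`
otherwise. Unsigned |D′| is used throughout — the spine rule is sign-free.
Missing data are handled by pairwise-complete deletion and the informative
line count is recorded. Pairs with fewer than 5 informative lines (a
configurable floor) are flagged uninformative because D′ is wildly unstable
at tiny counts; uninformative pairs count as *failing* the spine threshold.
The pair statistics are verified against an exhaustive contingency-count
oracle in the acceptance suite.

## Solid-spine block detection

The interval `[i..j]` is valid iff `D′(i,j) > t` and, for every interior
`k`, `D′(i,k) > t` and `D′(k,j) > t` (strict inequality at the default
`t = 0.8`; interior-interior pairs are unconstrained). Blocks come from a
greedy left-to-right scan: start at the leftmost unblocked SNP, grow the
right edge while validity holds, emit if at least two SNPs, continue after
the block. This is a fixed, symmetric reading of the "solid spine of LD"
family of rules; the original GUI implementation's exact code path
(pairwise-deletion details, rare-genotype handling, version-specific
minimum-count settings) is not reproducible from its description, so the
scan here is pinned by a brute-force oracle instead: enumerate every valid
interval by definition and replay the same greedy selection. The two agree
on a seeded suite of random D′ matrices up to 10 SNPs (acceptance criterion)
and on whole simulated chromosomes. Minimum block size is 2 SNPs; there is
no span cap; zero-span blocks are allowed.

Haplotype enumeration keeps only lines with complete calls across the block
members (an incomplete line is unassigned — it neither founds nor joins a
class) and numbers haplotypes 1, 2, … by descending frequency with
lexicographic tie-break, giving labels like `HapB-1A-29-2` (haplotype 2 of
block 29 on chromosome 1A).

Tag SNPs: greedy set cover over the pairs of common haplotypes
(frequency ≥ 0.05), adding at each step the member SNP that separates the
most still-confounded pairs, leftmost on ties. The greedy set size is
checked against exhaustive minimal set cover on small constructed blocks.
With fewer than two common haplotypes the tag set is empty (real summary
tables show tag counts of zero for some blocks).

Summary tables report, per chromosome, SNP totals and coverage, tag counts,
block counts, span statistics and haplotype counts. Genome aggregates are
emitted **both** block-count-weighted (pooling all blocks) and as the
unweighted mean of per-chromosome means — published tables mix the two
conventions without saying so, and the two disagree (e.g. a weighted mean
span can be 1.23 cM where the unweighted total-row mean is 1.16 cM), so both
are computed and clearly labelled.

## Diversity and differentiation

Gene diversity `1 − Σ pᵢ²` and Botstein PIC
`1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²` apply to any frequency simplex — SNP alleles
or block haplotypes. Differentiation is Nei's Gst with populations weighted
by informative-line counts in both `H_S` and the pooled frequencies (the
convention of the classic population-genetics packages); this guarantees
`H_T ≥ H_S` by convexity. Within-population haplotype frequencies are always
recomputed from that population's lines, never from global assignments.

The sliding-window profile averages the haplotype gene diversities of three
consecutive blocks, stepping one block at a time from the short arm; the
window midpoint is the mean of the three block midpoints. Whether the
original index was a mean of block diversities or a pooled diversity over
the window is not documented; mean-of-blocks is the default and a pooled
variant is offered (`pooled=True`).

**Gst as an estimator of Balding–Nichols F.** With k equal populations,
`E[Gst] ≈ F(1 − 1/k)/(1 − F/k)`: at k = 2 and F = 0.15 the expectation is
only ≈ 0.081, an intrinsic property of Gst, not an estimation error. The
parameter-recovery experiment therefore uses k = 10 populations, where the
expectation (≈ 0.137) is within the stated ±0.03 band of F; the 2-population
bias is worth remembering when reading absolute Gst values off real panels.

## Kinship, structure covariates, BLUP

Loiselle kinship is the moment estimator averaged over polymorphic SNPs,
pairwise-complete, with the small-sample correction `p(1−p)/(n−1)` per
locus. Negative pair estimates are set to 0 (a pair less related than two
random lines carries no usable signal for the mixed model) and the diagonal
is set to 1 by convention — the estimator is defined for pairs; the
convention is recorded on the object. Zero-clipping routinely makes the
matrix indefinite; before use in the mixed model it is bent to the nearest
PSD matrix by clipping negative eigenvalues to zero (with a warning). The
10,000-permutation significance test that sometimes accompanies this
estimator is omitted: it feeds nothing downstream.

Structure covariates are the top-q principal-component scores of the
centred dosage matrix (missing dosages mean-imputed for the decomposition
only, columns exactly centred). They stand in for model-based ancestry
proportions (STRUCTURE-style Q): the mixed model consumes Q only as fixed
covariates, which PCA axes supply deterministically at desk scale.
User-supplied Q matrices are accepted everywhere a Q is accepted. Axes are
unconstrained (no k vs k−1 column convention is imposed).

Across-environment genotypic values come from the REML fit of
`value = mean + environment (fixed) + line (random) + error` via
statsmodels' MixedLM, with `h² = σ²ₐ/(σ²ₐ + σ²ₑ)`. The degenerate design —
one observation per line in a single environment — is not REML-identifiable;
the package returns the no-shrinkage limit (centred observations, σ²ₑ → 0)
with a warning rather than failing.

## Mixed-model association (Q + K, P3D)

The null model `y = μ + Qγ + u + e` with `cov(u) = σ²ₐK` is fitted once by
REML over `δ = σ²ₑ/σ²ₐ`, using the eigendecomposition `K = U D Uᵀ`: after
rotating by `Uᵀ` the model is weighted least squares with weights
`1/(dᵢ + δ)`, and the REML criterion is optimised over `log δ` on a coarse
grid (61 points in [−10, 10]) followed by bounded Brent refinement
(tolerance 1e−10). The fitted `δ` is then **reused for every marker**
(population parameters previously determined): each marker test is a GLS
F-test of its design columns at fixed δ. No "compression" (line clustering)
is applied — the no-compression path is the default model here; the
P3D-vs-full-REML discrepancy is bounded in the tests
(|Δlog₁₀ p| ≤ 0.2 on structured fixtures).

Markers with missing lines are handled exactly: the affected lines are
dropped for that marker and the GLS is solved on the subset with δ held
fixed. SNPs are 0/1 dosages; monomorphic and sub-MAF markers are excluded
and `n` in the `P < 1/n` rule counts markers actually tested. Blocks are
coded as indicator columns for each haplotype class against the most common
class; classes rarer than 0.05 among the phenotyped, assigned lines are
pooled into an `other` class (the upstream description filters blocks by MAF
but is silent on within-block rare classes); a block's MAF is the frequency
of its second-most-common class. Marker `R²` is deliberately the plain
one-way ANOVA `SSA/SST` on the raw phenotype — computed outside the mixed
model, as in the original analysis chain. The favorable allele or haplotype
is the class with the largest trait-increasing fitted effect; whether larger
is favorable is a per-trait orientation switch (`higher_is_favorable`),
since per-trait orientations are not printed anywhere authoritative.

Significance thresholds: `1/n` rounded to two significant digits for
display, and `−log₁₀(1/n)` rounded to two decimals (computed from the exact
`1/n`, which is what reproduces the printed pairs 2.3 × 10⁻⁴ / 3.65 and
1.2 × 10⁻³ / 2.93; rounding the threshold first would give 3.64).

## Synthetic panels: what they emulate and what they do not

Founder-haplotype pools are built on random perfect phylogenies: every SNP
marks one clade of the pool, so at most three of the four two-locus gametes
occur and within-block |D′| = 1 — the structure the spine detector assumes.
One SNP is dedicated to each of the tree's splits (when the block is wide
enough), making pool haplotypes pairwise distinct. Population structure
follows Balding–Nichols: per-population haplotype frequencies are Dirichlet
with concentration `p(1−F)/F` around the ancestral frequencies (Beta for
loose biallelic SNPs). Lines are independent haplotype mosaics: free
recombination between blocks, none within unless a breakpoint rate is set.
Selection plans overwrite one block's haplotype in one population
(frequency-1 fixation). Phenotypes are
`grand mean + environment + QTL effects + polygenic + residual`; the
polygenic term is a genome-wide random SNP-weight combination (so it
covaries with kinship, which is exactly what the Q+K model corrects),
scaled so total genetic variance hits the target h²; SNPs inside
QTL-carrying blocks are excluded from the polygenic basis so the planted
effect is the only genetic signal in those blocks. A single seed fans out
to per-stage substreams (panel, phenotypes); identical seeds reproduce
byte-identical output.

Default study conditions mirror the motivating panel: landrace/modern
subpopulations of 157/88 lines, differentiation F = 0.06 (the scale of the
published landrace-vs-modern differentiation), four environments
(02LY/05LY/06LY/10SY), TKW-like trait scale (grand mean 35, residual
variance 16) and target h² = 0.6.

What the generator does **not** emulate: wheat's allopolyploid homoeology
(panels are analysed as diploid-inbred, as array genotypes are), realistic
demography or LD decay within blocks, genotyping error, and map error.
Passing tests on generator output therefore validate the estimators and the
pipeline logic under the stated statistical structure, not array-specific
artefacts of real data.

## The block-beats-SNP experiment

The qualitative phenomenon — a causal haplotype found by the block test
while no member SNP reaches the single-SNP threshold — is reproduced with a
planted 3-haplotype causal block (`haplotype_power_scenario`) on a panel
with study-scale marker counts (four chromosomes of 1100 SNPs tiled with
6-SNP blocks: ~3900 testable SNPs and ~660 blocks, so the two `P < 1/n`
thresholds fall near 2.6 × 10⁻⁴ and 1.5 × 10⁻³ — the scale of the
motivating 4434-SNP / 847-block scan). The causal block's six member SNPs
carry haplotypes `000000 / 111000 / 000111`; each SNP's derived allele
marks one of the two non-causal haplotypes, so no single SNP separates the
all-zeros causal haplotype and the best marginal single-SNP contrast
carries only a fraction `f₁ p_C / ((1−p_C)(1−f₁))` (≈ 0.2) of the block
test's noncentrality.

The carrier frequency and effect size were chosen by a design-stage power
analysis to centre the block statistic inside the success window (block
significant, no member SNP significant). Because the two statistics share
the same realised phenotype noise, their p-values are strongly correlated
(log–log correlation ≈ 0.9) and the per-replicate success probability
plateaus near 0.70–0.75 at study scale — the success window is only about
two orders of magnitude wide in p while the realised block p fluctuates
with comparable spread. A 20-replicate run therefore shows the phenomenon
in roughly 70 % of replicates in expectation, sitting right at that bar,
and individual 20-replicate draws scatter binomially a few replicates
either side of it; this variance is intrinsic to the phenomenon at these
thresholds, not a tuning artefact. Deeper significance tails (more markers)
widen the window in χ² units, which is why the study-scale panel is used
rather than a miniature (a 240-SNP desk panel caps the per-replicate rate
near 0.60).

## Painting

Identity-in-state only: a line's call equal to the founder's is green,
different yellow, missing (or heterozygous, or at a SNP where the founder
itself is missing) white, over the MAF-filtered SNP subset. Per block, the
founder fraction excludes white members; the 0.9 founder-type cutoff is this
package's operationalisation of a classification done visually in the
original analyses, and is configurable. Multi-founder comparisons are
composed by the caller from single-founder paintings.

## Numerical and degenerate-input choices

- D′/r² are clipped into [0, 1] against floating-point overshoot; `r² ≤ D′`
  is *not* assumed (false in general).
- Frequency simplexes are validated to 1e−9.
- Kinship bending: negative eigenvalues clipped to 0, warning emitted;
  non-finite kinship is an error.
- Zero-variance phenotypes and markers with too few informative lines are
  errors, not NaNs.
- All greedy tie-breaks (tag SNPs, haplotype numbering, within-tie SNP
  order) are deterministic and documented above.

## Problem sizes used by the acceptance run

Oracle suites: 200 random 2-SNP fixtures (LD), 360 random D′ matrices of
2–10 SNPs (blocks). Parameter recovery: 500 loci × 10 populations × 100
lines (Gst); 200 lines × 4 environments (h²). GWAS: 200 lines × 2000
independent markers for the null calibration; 20 replicates of the
300-line, ~4400-SNP power scenario (the dominant cost, a few seconds per
replicate). These sizes keep the whole run to a few minutes while leaving
Monte-Carlo error well inside the stated tolerances.
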