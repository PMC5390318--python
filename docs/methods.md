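# Methods

This note documents the statistical procedures, the generative model
behind the bundled simulator, the numerical conventions, and the design
choices made where common practice leaves the details open.

## Data model and scales

Methylation is carried as beta values β ∈ [0, 1] (methylated signal
proportion per CpG probe). Rank-based statistics (Spearman correlation,
quantile ranges) and the class thresholds operate on β directly; linear
modelling and PCA use M-values, M = log2(β/(1 − β)), which are closer to
homoscedastic across the β range. Betas are clipped to
[clip_eps, 1 − clip_eps] before the transform (default clip_eps = 0.001)
so boundary values map to finite M while interior values are untouched;
the transform is strictly monotone on the clipped range and exactly
inverted by β = 2^M/(1 + 2^M). Missing values are NaN in memory and the
token `NA` on disk; no operation imputes — correlations and means are
pairwise-complete, and PCA / moderated-F drop incomplete probes with a
logged count.

## Probe QC

A probe is removed when it fails background detection (detection
p-value strictly greater than 0.01 in **any** sample), is flagged
cross-reactive, or overlaps a common SNP. The any-sample detection rule
is the strictest reading of standard practice and is configurable.
Sex-chromosome probes are retained by default, which is appropriate for
single-sex cohorts; `retain_sex=False` drops chrX/chrY. A probe failing
several rules appears in every applicable reason list but is counted
once in the retention arithmetic.

## Methylation classes and overlaps

Per tissue, each probe's mean β across donors is classed with closed
boundaries: hypo iff β ≤ 0.2, hyper iff β ≥ 0.8, otherwise intermediate.
Cross-tissue overlap is reported as the full 2^T − 1 table of disjoint
exclusive-subset counts (the tabular form of an UpSet plot): a probe
hypomethylated in all four tissues is counted only in the
all-tissues cell. The joint blood × eye class tables report, within each
genomic feature class and each CpG-island relation, the percentage of
probes in every combination of blood class (B1–B3) and eye class
(E1–E3); percentages sum to 100 per panel.

Probes carrying several manifest feature annotations must be collapsed
to one class before entering the package; the provided collapser uses
the fixed priority TSS200 > TSS1500 > 5′UTR > first exon > body > 3′UTR >
intergenic, i.e. the most promoter-proximal annotation wins.

## Sample-level concordance

All unordered sample pairs get a Spearman correlation (Pearson on
mid-ranks, average-rank ties) over the full probe set, pairwise-complete
over missing cells. Tissue-pair summaries report median/min/max over the
cross-tissue pairs of each tissue pair and the within-tissue pairs of
each tissue, with the midpoint convention for even counts. Clustering is
agglomerative with average linkage on d = 1 − ρ; the distance and
linkage are not uniquely dictated by field practice, so they are fixed
here for determinism and recorded in the output. Samples are sorted
lexicographically before linkage so exact ties resolve deterministically
toward lexicographically earlier samples. The dendrogram is emitted as
Newick under an ultrametric convention (a node merged at distance h sits
at height h/2).

## Surrogate covariation

**Blood-variable probes.** Per probe, the 10th and 90th percentiles of
blood β across donors are computed with linear interpolation between
order statistics (h = (n − 1)p, the default of mainstream statistical
environments); a probe is blood-variable iff q90 − q10 > 0.05, strictly.
A range of exactly 0.05 is excluded.

**Matched correlation.** For each blood-variable probe and each eye
tissue, Spearman's ρ between the donor-ordered blood vector and the same
donors' eye vector (n = matched donors; donors lacking either sample are
dropped with a warning, minimum 4). Two-sided p-values use
t = ρ√((n − 2)/(1 − ρ²)) with df = n − 2. At n = 8 the Spearman null is
discrete (ρ on a grid of width 6/504); full enumeration of the 8!
orderings shows the t-approximation's realised level at nominal
p < 0.05 is 0.0576, not 0.05 — the calibration tests therefore accept
the selection fraction in a band of 0.04–0.075 around the nominal level.
An exact-permutation p (enumerating all n! orderings, n ≤ 9) is
available via `exact_p=True` and recorded in the output metadata.
A probe is *selected* when |ρ| > 0.5 **and** p < 0.05.

**Permutation null.** The null distribution of matched correlations is
built by drawing `n_null_permutations` (default 100) random non-identity
permutations of the donor labels of the eye samples, recomputing every
per-probe correlation, and pooling all values into one distribution —
pooling is required to obtain a single null to compare against. The
draw is seeded and reproducible; partial matches (permutations fixing
some donors) are allowed, only the full identity is excluded. Matched
vs null distributions are compared with a two-sided Mann–Whitney
rank-sum test (normal approximation with tie correction, no continuity
correction).

**Cross-tissue intersection.** Probes selected in *every* eye tissue
form the commonly-correlated set. This intersection is the package's
headline recovery metric: with three eye tissues the per-tissue false
positive rate (~0.058 under the null) compounds to ~2 × 10⁻⁴, so the
intersection is nearly free of null probes while probes with genuine
donor-shared effects survive all three screens.

**Paired similarity.** Donor-paired t-tests on β differences between
two tissues, BH-adjusted across probes. Because non-significance alone
cannot certify similarity (it conflates "no difference" with "no
power"), the `similar` flag is the conjunction of adjusted p ≥ 0.05 and
|mean difference| < 0.05 (the equivalence bound, configurable). Probes
with zero-variance differences have no t-statistic and are judged on
the mean difference alone. Both components of the flag are emitted so
either definition can be reconstructed.

## Variation structure

**PCA.** Probes are centred across samples and the centred
samples × probes matrix decomposed by SVD; scores are US, loadings V,
and the percent variance explained is s²/Σs². The sign convention
(largest-magnitude loading positive per component) makes results
reproducible across SVD implementations.

**Trait association.** Component scores are screened against sample
traits: one-way ANOVA for categorical traits, a simple-regression F-test
for continuous ones. Traits constant within donor (age at death, cause
of death, preservation interval, chip) are tested on **donor-mean
scores** with the donor as the unit of replication. This is a deliberate
design choice: with four samples per donor, testing a donor-level trait
at sample level pseudo-replicates — any donor-structured component then
"associates" with age or preservation essentially by construction, and
no component can ever be exclusively individual-associated. Tissue
(varying within donor) and donor identity itself are tested at sample
level. A component is *individual-exclusive* when its donor-identity
p < α while every other tested trait has p ≥ α; α defaults to 0.05 with
0.10 available as the looser screen.

**Probes behind a component.** Selection is by Pearson correlation of
each probe's M-values with the component's score vector, |r| > 0.5,
matching the "probes that correlate with the PC" notion; thresholding
loading magnitudes is offered as an option. Zero-variance probes are
excluded with a logged count.

**Tissue-specific probes (moderated F).** Per probe, a one-way layout
of M-values on tissue gives the between-tissue mean square and a
residual variance s² on d degrees of freedom. An empirical-Bayes prior
(d0, s0²) is estimated across probes by moment matching on log s²: with
e = log s² − ψ(d/2) + log(d/2), the mean of e estimates log s0² (bias-
corrected by ψ(d0/2) − log(d0/2) once d0 is known) and the excess of the
sample variance of e over ψ′(d/2) equals ψ′(d0/2), inverted by Newton
iteration on the trigamma function. Infinite d0 (no excess spread) pools
all variances at s0². The moderated statistic is
F = MS_between / s̃² with s̃² = (d0·s0² + d·s²)/(d0 + d), referred to
F(k − 1, d0 + d) (χ² when d0 = ∞), then BH-adjusted. Setting the prior
df to 0 recovers the ordinary ANOVA F exactly; ∞ gives full shrinkage —
both limits are exposed for verification via the `prior_df` argument.

## Enrichment

For each genomic feature class and CpG-island relation, the 2×2 table
(subset vs rest-of-background) × (in category vs not) is tested with a
two-sided Fisher exact test — exact at the small counts a selected probe
set can produce — with a chi-square alternative for large tables.
Odds ratios are sample cross-product ratios with ∞ reported for zero
denominators. BH adjustment is applied within each annotation scheme.
The background defaults to all post-QC probes.

## The simulator

The generator draws study-shaped datasets with known truth so every
stage can be tested without external data. The default design matches
the emulated study: 8 donors × {blood, retina, RPE/choroid, optic
nerve}, donors assigned to chips round-robin.

Per probe, a baseline class is drawn with weights (0.4, 0.2, 0.4) for
(hypo, intermediate, hyper); baseline β is Beta(1.5, 30) for hypo
(mass below 0.15), its mirror for hyper, and 0.2 + 0.6·Beta(2, 2) for
intermediate — a bimodal marginal like real array data. All effects act
on the logit scale, which keeps β in (0, 1) without truncation and,
because the inverse logit is monotone, leaves rank statistics unchanged.

* **Tissue effects** (fraction f_tissue = 0.2 of probes, exact count):
  per-tissue offsets g·Xᵗ where X is the classical-MDS embedding of the
  configured tissue-distance matrix and g a standard normal vector per
  probe, so expected squared offset separations reproduce the squared
  configured distances. The default distances (logit units) are
  blood–retina 3.4, blood–optic nerve 3.0, blood–RPE/choroid 2.6,
  retina–RPE/choroid 2.0, retina–optic nerve 1.8, RPE/choroid–optic
  nerve 0.8: blood is the most distinct tissue, blood is closest to
  RPE/choroid among its pairs, and RPE/choroid–optic nerve is the most
  similar pair. The matrix embeds exactly (its Gram form is PSD).
* **Donor-shared effects** (f_individual = 0.05, exact count, disjoint
  from tissue probes): one offset per donor, identical across that
  donor's tissues — the cleanest recoverable mQTL-like signal. Gaussian
  with sd 1.5 by default; `trimodal_genotype=True` instead draws levels
  {−δ, 0, +δ} with weights (0.25, 0.5, 0.25), like the three genotypes
  of a biallelic variant at allele frequency one half.
* **Noise**: independent Gaussian, sd 0.3, per cell on the logit scale.
* **QC artefacts**: exact counts of cross-reactive (5%) and
  SNP-overlapping (2%) probes, drawn disjointly; detection p-values are
  0 except a configurable fraction of cells drawn uniform (0.01, 1].
* **Annotation**: feature classes and island relations drawn from fixed
  HM450K-like marginals; `individual_opensea_bias` optionally seeds
  donor-effect probes preferentially into open-sea/intergenic context
  for enrichment testing.

Effect-class counts are `round(f·n)` rather than binomial so truth-based
tests are deterministic. Everything is reproducible from the seed.

**What the simulator does not model**: probe-type (I/II) chemistry and
normalisation artefacts, cell-composition heterogeneity within tissues,
chip/batch effects on β (chip is a label only), spatially correlated
probes, age-related drift, and partially shared donor effects (donor
offsets are perfectly conserved across tissues before noise). Passing
tests therefore demonstrate correctness of the procedures and their
calibration under this generative model, not performance on real arrays,
where effect sizes are smaller and correlated structure richer.

## Problem sizes and tolerances

The test suite and the acceptance script use 2,000–4,000-probe draws for
structure/recovery checks and 20,000-probe draws for calibration
(null level of the matched-correlation screen, moderated-F FDR), with
10–50 null permutations — sizes at which Monte-Carlo error is well below
the asserted margins while a full run stays in seconds. Oracle
equivalence checks (Spearman, paired t, ANOVA F, rank-sum, Fisher, BH
against brute-force implementations) are asserted at 1e-10; file
round-trips at 1e-12; the permutation-null mean at ±0.02; the
matched-screen level within ±0.01 of the enumerated exact level 0.0576.

## Known limitations

With 8 donors the matched-correlation screen has coarse p-value
granularity; single-tissue selections at |ρ| > 0.5, p < 0.05 carry a
~6% false-positive rate among blood-variable null probes, which is why
conclusions rest on the cross-tissue intersection. The donor-level
trait testing assumes donor traits are exactly constant within donor.
The enrichment test treats probes as exchangeable units, ignoring the
genomic clustering of CpGs. The pipeline assumes inputs are already
normalised; background correction, normalisation and batch adjustment
are out of scope.
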