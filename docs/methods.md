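# Methods

## Study design and contrasts

The pipeline targets a fully crossed paired design: each cell line is
cultured under a solvent control (MOCK) and under one or more cytokine arms,
and profiled at T1 (end of stimulation) and T2 (after a withdrawal period).
Every contrast is *treated vs MOCK at the same timepoint*, pairing by cell
line: the design matrix carries an intercept, cell-line indicator columns,
and a treatment indicator, so any per-line offset (genetic background,
culture history) is absorbed before the treatment coefficient is tested.
The T2 contrast uses the parallel-cultured T2 controls rather than carrying
T1 significance forward; persistence is therefore "independently significant
at both timepoints with the same direction". Features significant at both
timepoints with opposite directions are reported separately as *flipped*
and never counted stable — the direction-consistent intersection is the
only defensible reading when the two timepoints are tested independently.

## Statistical core

**Feature-wise linear models.** Weighted least squares per feature against
the shared design, solved by batched normal equations. Observation weights
are normalized to mean 1 per feature, which leaves coefficients and t
statistics untouched while keeping residual variances on a common scale for
the moderation step (and makes an all-equal weight matrix exactly
equivalent to the unweighted fit).

**Empirical-Bayes moderation.** The prior (d₀, s₀²) is estimated by
moment-matching the distribution of log s²_g, which under the hierarchical
model is a log scaled-F: after removing the known digamma/trigamma
contribution of the residual df, a positive excess variance yields d₀ via
the inverse trigamma (Newton iteration); a non-positive excess yields
d₀ = ∞ and a fully pooled variance, in which case the test is normal rather
than t. Residual variances below 1e−20 are treated as exactly zero
(numerically exact fits); if *all* variances are zero the input is
degenerate and the fit refuses to moderate rather than emit p-values of 0.
The implementation is cross-checked against limma's `lmFit`/`eBayes` (prior
df, prior variance, t and p to 0.1% relative) in the test suite.

**Calling thresholds.** Raw p < 0.01 with |logFC| ≥ log2(1.5), on the
modeled scale: log2-CPM for expression, M values for methylation. The fold
threshold is applied to the M-scale contrast (not to β differences); this
is a documented choice — the alternative is switchable by thresholding the
DiffTable differently — because the linear model operates on M and its
logFC is the quantity with a sampling theory. Boundary convention: p
strictly below, |logFC| at or above. BH-adjusted q values are carried in
every table but are not used for DEG/DMC calling; they control FDR in the
enrichment tables.

**Exact tests.** Enrichment p is the upper hypergeometric tail summed in
rational arithmetic (`fractions.Fraction`), immune to cancellation for any
table the pipeline produces. The rank-sum test enumerates all C(n, n_x)
rank assignments when n_x + n_y ≤ 12 and the pooled sample is tie-free,
counting assignments with |U − μ| at least as extreme; otherwise it uses
the tie-corrected normal approximation with continuity correction and
reports which path was taken.

**Quantile normalization.** Each column is mapped onto the vector of
rank-wise means of the sorted columns; within-column ties receive the mean
of the quantiles they span (linear interpolation at average ranks). The
operation is idempotent to 1e−12.

## Methylome stage

Probe QC is sequential and bookkept: stage 1 removes probes whose detection
p fails the threshold (default 1e−10) in *any* sample (strict rule; a
mean-across-samples variant is available via `detection_rule="mean"`);
stage 2 removes remaining probes that are user-blacklisted (SNP-associated,
cross-hybridizing) or on chrX/chrY. Because the stages apply in order, the
removal counts are disjoint and final = initial − Σ removed always holds —
the report validates this identity. Normalization defaults to quantile
normalization of β followed by the logit2 transform (β clamped to
[ε, 1−ε], ε = 1e−6); normalizing on the M scale instead is a config switch.
Background/dye-bias correction is out of scope — the generator produces
background-free data. DMC distribution summaries count probe–annotation
assignments for region classes (a probe annotated to two genes contributes
to both) and one category per probe for island relations, with half-up
rounding at one decimal.

## Transcriptome stage

Genes are kept when CPM > 1 in at least (smallest group size) samples. TMM
follows the original trimmed-mean construction: reference sample by the
upper-quartile-closest-to-mean rule, gene-wise M and A over genes positive
in both samples, 30%/5% two-sided trims on M/A ranks, factor =
2^(inverse-variance-weighted mean of surviving M) with delta-method
binomial variances, factors rescaled to geometric mean 1; verified against
edgeR's `calcNormFactors` to 1e−6. Log-CPM is log2(CPM + prior) with
prior 0.5 — finite at zero and exactly invariant to rescaling counts and
libraries together. Precision weights are a deliberately single-pass voom:
one unweighted fit, lowess (span 0.5) of √(residual sd) against mean
log2-count, weights = inverse fourth power of the trend evaluated at each
observation's fitted log2-count, clamped at the trend ends; below 50 genes
the trend is unreliable and unit weights are used with a warning. PCA
selects the top-variance features (ties by feature id), centers each
feature, and decomposes by SVD; scores are exactly centered and orthogonal.

## Integration

Called DMCs are restricted to promoter annotations (TSS200, TSS1500,
5′UTR, 1st exon) and grouped by gene; each called probe contributes one
entry per promoter annotation. Classification: up + ≥1 hypo → diametral_up;
down + ≥1 hyper → diametral_down; both promoter directions present →
conflicting (excluded from diametral counts — the conservative reading when
no rule is otherwise forced); anything else non-diametral. Gene identity is
by case-sensitive symbol; the pipeline emits a manifest-to-counts symbol
reconciliation report so silent vocabulary mismatches surface. Stable
diametral genes are those with the same diametral class at both timepoints;
by construction they are a subset of the stable DEGs, and the pipeline
asserts this on every run.

## Synthetic data: what it emulates, and what it does not

Baseline β values come from the canonical bimodal mixture
0.45·Beta(2,10) + 0.45·Beta(10,2) + 0.1·Beta(5,5) (hypo/hyper/intermediate
modes). All perturbations act additively on the M scale — per-(probe, line)
random effects (sd 0.1), observation noise (sd 0.3), and planted shifts
(δ = ±2) — so planted effects compose exactly with the linear model and a
noiseless run recovers every planted effect to machine precision. Counts
are NB with variance μ + αμ² (default α = 0.1, a typical bulk RNA-seq
magnitude), lognormal baselines (median 200), per-(gene, line) lognormal
effects (sd 0.1), and uniform library factors in [0.5, 2]; at α = 0 the
Poisson limit is used. One sample per design cell, matching an n = 3
biological-replicate study. Planted effects go to genes with baseline mean
above a floor (default 50) so the truth is in the detectable regime, and
the study driver never plants an independent methylation effect on a
promoter probe of a gene carrying an expression effect — otherwise untagged
diametral pairs would arise by coincidence and recovery scoring against the
registry would be ill-defined. Detection-p failures are planted on a fixed
fraction of effect-free probes, failing in every sample.

Not emulated: array background/dye chemistry, SNP-affected probes (the
blacklist is user input), batch structure, technical replicates,
transcript-level quantification, and any coupling between methylation and
expression beyond the planted diametral pairs. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not robustness to real-array artefacts.

## The validation benchmark and its power analysis

The planted-truth benchmark (`persistome.config.benchmark_config`) uses the
study-shaped design with 50 transient DEGs and DMCs per arm plus three
diametral-persistent genes (fold 2 up, promoter δ = −2; two on one arm, one
on the other). For exact recovery the planted effects must be identifiable
at n = 3 pairs and p < 0.01: the delta-method standard error of a log2 fold
change is √(2/3 · (1/μ + α))/ln 2, so at the package's realistic default
α = 0.1 a fold-2 effect sits near t ≈ 2.7 and cannot be recovered reliably
— that regime is characterized by the null-calibration tests instead. The
benchmark therefore fixes α = 0.01 and a planted-baseline floor of 100
(t ≈ 7), chosen from this power calculation, and at that operating point
recovery of the three planted genes is exact across seeds with sensitivity
and precision ≥ 0.9 over repeated runs. The methylation side (δ = 2, noise
0.3, se ≈ 0.25) is comfortably powered at either setting.

## Reporting conventions

Printed percentages use half-up rounding at the precision of the figure
they feed (integer or one decimal, selectable per call); direction percents
are complementary to within one rounding unit. ΔΔCq: per group,
ΔCq = mean Cq(target) − mean Cq(reference); ΔΔCq = ΔCq(treated) −
ΔCq(control); fold = 2^(−ΔΔCq); significance by a paired t-test on
replicate-level ΔCq values paired by replicate id. The tissue comparison
applies the exact rank-sum test per gene on a user-supplied normalized
table and appends a BH column; the package never fetches external data.

## Numerical and reproducibility choices

Every generator draws from one `numpy.random.default_rng` seeded per
operation; the pipeline derives independent child seeds from the single
configured seed via `SeedSequence`, keeps them below 2³¹, and stamps a
SHA-256 configuration hash into every bundle. Reruns with the same
configuration and seed are byte-identical, which the test suite checks
file by file. Enrichment universes are the features that survived the
layer's filtering (standard over-representation practice; a whole-genome
universe would overstate enrichment). The curated-pathway fixture used by
the overlap report has realistic set sizes but synthetic membership — the
real lists are versioned external resources — so its percentages exercise
the arithmetic, not biology.

## Limitations

No robust/trended empirical Bayes, no duplicate-correlation or surrogate
variable modeling, no multi-CpG region calling, no enhancer annotation, no
rank-based enrichment scores (the Fisher component only), and gene-level
expression only. The persistence rule is one of several the two-timepoint
design admits; the flipped and transient partitions are reported so
alternative readings can be reconstructed from the outputs.
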