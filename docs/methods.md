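# Methods

## Per-gene methylation measures

A 450K-style beta matrix gives methylation levels β ∈ [0, 1] per probe and
sample. For a gene region (TSS200 promoter or gene body, as annotated in the
probe manifest) the package computes, per sample:

* **region mean** — arithmetic mean over the region's probes (any probe
  count);
* **IGV** — sample variance over the region's probes, denominator n − 1,
  requiring ≥ 3 probes. IGV is invariant to adding a constant to all probes
  of the gene in a sample, which makes it robust to global methylation
  shifts and sample-level offsets ("self-calibrating");
* **mean derivative** — mean |β(i+1) − β(i)| over genomically adjacent probe
  pairs (≥ 2 probes), a CpG-to-CpG roughness measure. Adjacency is defined
  purely by coordinate order; inter-CpG distances are not weighted;
* **cross-sample variance** — mean over the region's probes of each probe's
  across-sample variance (n − 1), a proxy for intra-tumour heterogeneity
  when the samples come from one tumour.

The variance denominator (n − 1 versus n) is exposed as `ddof`; the default
is the unbiased n − 1, used consistently for IGV and cross-sample variance.
"Gene body" means the manifest label `Body` only; UTR/exon categories are
not folded in.

## Preprocessing

Probes are removed in a fixed order — blacklist (non-unique mapping or SNP
overlap), sex chromosome, unannotated, then < 95% non-missing coverage — and
each probe is counted once under the first rule that removed it, so the
filter report is deterministic. Cells with detection p > 0.05 (strict
inequality) are then masked, and remaining holes are imputed by k-nearest
neighbours over probe rows (k = 5): distance is Euclidean over jointly
observed samples scaled by the shared-sample count, and the imputed value is
the unweighted mean of the neighbours' values at that sample (scikit-learn's
`KNNImputer`, whose nan-Euclidean convention matches this definition).
Filtering precedes masking precedes imputation.

## Survival primitives

The Cox partial likelihood uses the Breslow risk-set convention: tied event
times each contribute the full risk-set denominator. The implementation is
a single vectorised pass over times sorted in decreasing order with a
running log-sum-exp.

The elastic-net Cox model maximises

    φ(θ, λ, α) = (2/N)·ℓ(θ) − λ·[ α‖θ‖₁ + (1 − α)/2·‖θ‖₂² ]

via scikit-survival's coordinate-descent path solver (a glmnet port) with
internal predictor standardisation; coefficients are reported on the
original scale. λ is selected by ten-fold cross-validation using the
Verweij–van Houwelingen deviance, D = −2[ℓ_all(θ̂₋f) − ℓ₋f(θ̂₋f)], with
event-stratified folds from a seeded RNG. Two selection rules are offered:
`"1se"` (default) takes the largest λ within one standard error of the
deviance minimum — the canonical sparse cross-validation choice, which
keeps the per-split models small and the downstream consensus specific —
and `"min"` takes the minimiser. The blend α is chosen once per analysis by
evaluating the grid 0, 0.1, …, 1 and taking the cross-validated-deviance
argmin (ties to the smaller α). The solver requires a strictly positive L1
share, so the α = 0 grid point is evaluated at an L1 ratio of 0.01; λ = 0
(unpenalised) is delegated to lifelines' Newton fit.

Unpenalised univariate and multivariate Cox fits use lifelines'
`CoxPHFitter` (Newton precision tightened to 1e-9). Hazard-ratio CIs use
the normal approximation exp(θ̂ ± 1.96·SE). Standardized coefficients are
θ̂ scaled by the predictor's standard deviation. Collinear predictor sets
are rejected with the offending columns named.

The stratified Mantel–Haenszel test is the stratified log-rank test:
observed-minus-expected counts and hypergeometric variances accumulate over
event times within each stratum; the chi-square statistic uses 1 df.
Stratum labels combine the binarized covariates age ≥ 60, stage 3–4 and
residual disease; grade is excluded from stratification (it enters only the
multivariate prognostic model). Strata containing one group contribute
nothing, with a warning. FDR adjustment is Benjamini–Hochberg throughout.

## Signature discovery

Each split partitions the samples with training size ⌊2n/3⌋ (145/73 at
n = 218). The elastic net is fitted on the training portion only; the
linear predictor θ̂ᵀx defines training tertiles (linear-interpolation 1/3
and 2/3 quantiles; low: score ≤ lower cutoff, high: score > upper cutoff)
whose cutoffs classify test samples one at a time. Top vs bottom test
tertiles are compared with the stratified test above. Clinical covariates
never enter the predictor set; they act only through stratification.

Split p-values are BH-adjusted over the family of all informative splits in
the run; splits with q < 0.1 form the consensus family of size k. Per gene,
the inclusion count y out of k is scored by the tail probability

    P(Y ≥ y) = Σ_{r=y}^{k} C(k, r) p_b^r (1 − p_b)^{k−r},

with the per-fit inclusion probability p_b = f/m (f = model size, m = gene
universe) treated as a random draw from its empirical distribution over the
significant fits — the tail becomes a frequency-weighted mixture of
binomial tails. Gene-level p-values are BH-adjusted; q < 0.05 defines the
signature. Ranking is by y descending, ties broken by the gene's mean share
of each selecting model's absolute-coefficient total. Direction (hyper:
higher IGV → worse outcome; hypo: reverse) is the sign of the gene's
univariate Cox coefficient on the full cohort — the minimal reading of
"individually associated" with outcome.

The number of repeats is a parameter; desk-scale analyses and this
package's own acceptance runs use 200 splits (recorded in model metadata),
with the machinery unchanged at larger repeat counts.

## Cluster scores and the prognostic score

Hyper and hypo signature genes are consensus-clustered separately: in each
of the (default 1000) resamplings, 80% of samples are drawn, genes are
hierarchically clustered with average linkage on 1 − Spearman ρ, and the
tree is cut at every k in 2..20; the consensus matrix per k records
co-clustering frequencies. The cluster count is chosen from the relative
change Δ(k) of the area under the consensus CDF: the largest k whose gain
is still appreciable (Δ ≥ 0.1), i.e. where the Δ curve levels off.
Overcutting is deliberately preferred to undercutting — stable clusters
survive a finer cut intact while loose genes fragment, and the next stage's
filters (≥ 10 genes, mean-IGV survival association at p < 0.05) remove the
fragments; an undercut irreversibly merges distinct IGV patterns. Final
labels come from average-linkage clustering of 1 − consensus. Surviving
clusters are named hyper1/hyper2/… by decreasing size within direction.

Cluster scores are unweighted per-sample means of the cluster's gene IGVs.
The prognostic model is a multivariate Cox fit on the cluster scores plus
binarized covariates (age ≥ 60, stage 3–4, grade 3, residual). The IGV
prognostic score of any sample is Σ_c θ̂_c · score_c — cluster terms only —
and the training-cohort median of this score is the fixed cutoff that
dichotomises every cohort, so external samples are classified one by one
with no re-normalisation against other external samples. Up to 10% of a
cluster's genes may be missing externally (cluster mean renormalised, with
a warning); more is an error. Validation reports univariate and
multivariate (covariate-adjusted) Cox fits for worse vs better, plus
Kaplan–Meier step functions.

## Heterogeneity analyses

For each gene with ≥ 3 gene-body probes and each sample set (one per
patient for multi-region designs, or the whole cohort), the package pairs
the set's mean IGV with its cross-sample variance. E(cross-var | IGV) is
summarised by a least-squares cubic B-spline regression with df = 4 basis
functions (interior knots at quantiles); this reproduces straight lines
exactly and is the fixed-df analogue of a smoothing spline. Quadrant
enrichment splits genes at the *signature-gene* median IGV (not the
genome-wide median) and applies two-sided Fisher tests per cluster, BH
across clusters. The mean-derivative dispersion analysis reports, per gene,
the across-sample variance of the mean derivative, summarised per cluster
by median and IQR: consistent cell-mixing regimes give low dispersion,
heterogeneous ones high dispersion.

## TF and CGI/enhancer enrichment

TF-binding enrichment is a two-sided Fisher test of bound × cluster
membership over the gene universe, BH across all (TF, cluster) pairs, with
direction over/under at q < 0.05. Expression–IGV correlations are Spearman
by default (matching the rank-based clustering distance; Pearson is a
switch) across the shared samples (≥ 5), computed per gene and partitioned
by binding; constant-IGV genes are excluded with a warning. The
bound-vs-unbound comparison is a one-sided two-sample Kolmogorov–Smirnov
test per orientation ("greater": bound correlations shifted positive), BH
across TFs within orientation. CGI (island/shore/shelf) and enhancer
enrichment uses all array probes as background for the all-gene-body test
and all gene-body probes as background for signature- and cluster-level
tests, BH within category.

## Synthetic data

The generator emits what an array measures: per probe and sample, the
average methylation over `cells_per_sample` (default 50) latent single-cell
profiles, truncated to [0, 1], plus N(0, 0.02) technical noise. Two
cell-mixing mechanics are planted:

* **consistent** (clusters hyper2, hypo2): all cells share one
  high-amplitude alternating probe pattern (half-range 0.30); a per-sample
  amplitude 1 + 0.08·z_c modulates it. Result: high IGV, low cross-sample
  variance, low mean-derivative dispersion.
* **heterogeneous** (clusters hyper1, hypo1): each cell draws its own ±0.50
  pattern; averaging flattens the measured profile. A per-sample coherent
  fraction κ = 0.35 + 0.25·z_c (clipped to [0.02, 0.98]) of the cells share
  a sample-level random phase, and a per-sample global shift N(0, 0.10)
  adds tumour-level offset. Result: low IGV, high cross-sample variance,
  high mean-derivative dispersion.

Each planted cluster c has a latent per-sample factor z_c ~ N(0, 1) that
modulates its genes' IGV and enters the proportional-hazards linear
predictor with coefficient β_c (defaults ±0.9; positive for hyper,
negative for hypo). Survival times are exponential with hazard
∝ exp(Σ β_c z_c + covariate terms); censoring is an independent exponential
whose rate is solved numerically so the expected censored fraction equals
`censoring_rate` (default 0.28, matching a ~72% event fraction typical of
advanced serous ovarian cohorts). Covariate prevalences default to
stage 3–4: 0.83, grade 3: 0.65, age ≥ 60: 0.43, residual disease: 0.42,
with log-hazard weights 0.5/0.2/0.3/0.4. Default scale is 200 samples ×
500 genes × 8 gene-body probes (+3 TSS200 probes), 4 planted clusters of 20
genes; decoy blacklisted and sex-chromosome probes exercise the filters.
Effect sizes are the package's own choices — picked once so that the
regime contrasts and planted-signal recovery are realised at desk scale —
not values reported for any real cohort.

Multi-region cohorts share each patient's latent factors across regions
(within-patient perturbation SD 0.3 versus 1.0 between patients), give the
heterogeneous regime a patient-level phase with a 15% per-region probe-flip
rate, and add a patient-level baseline offset (SD 0.08), so within-patient
cross-sample variance sits below the between-patient value. TF tables plant
positive/negative expression–IGV correlations by binding a planted TF to
one cluster's genes (rate 0.9, off-cluster 0.01) and building its
expression from the bound genes' mean IGV profile, scaled so the realised
mean per-gene correlation lands near the target (default ρ = 0.6).

What the generator does **not** emulate: Type I/II probe chemistry and
probe-type bias, batch effects, copy-number confounding, cell-composition
mixtures beyond the two planted regimes, and realistic genomic probe
spacing. Passing tests therefore demonstrate the statistical machinery and
its calibration, not performance on real 450K data.

## Numerical choices and limitations

* Seeds: one master seed per run; per-stage and per-split seeds derive from
  it by SHA-256, all below 2³¹.
* Neighbour and linkage ties resolve by input order (stable sorts
  throughout); consensus clustering skips a resampling whose subsample
  renders a gene constant.
* Fisher odds ratios of ∞ are reported as such and excluded from direction
  calls only when binding is empty.
* The pipeline applies the prognostic model to external betas as given; no
  cross-cohort renormalisation is attempted.
* Desk-scale defaults (200 splits, 1000 consensus resamplings) trade
  resolution of the consensus matrix and of the empirical model-size
  distribution for runtime; both are parameters and their values are
  recorded in the run metadata.
* Efron/exact tie corrections for the Cox fits are not implemented; the
  partial-likelihood primitive is Breslow, and generated survival times are
  continuous so ties do not arise in synthetic cohorts.
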