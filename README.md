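# igvprog

Prognostic-signature discovery from **intra-gene DNA-methylation variability
(IGV)** on Illumina 450K-style beta matrices, with downstream intra-tumour
heterogeneity and transcription-factor analyses.

## The problem

Most methylation biomarkers summarise a gene by its *mean* beta value over a
region. In high-grade serous ovarian carcinoma and related Müllerian-tract
cancers, the *variability* of methylation across the CpGs of a gene body —
the within-sample variance of the probes annotated to one gene,

&nbsp;&nbsp;&nbsp;&nbsp;IGV<sub>g,s</sub> = Var<sub>p ∈ probes(g)</sub>( β<sub>p,s</sub> )

— carries prognostic information that the mean does not, and is
*self-calibrating*: adding a constant to every probe of a gene (a global
methylation shift, a batch offset) leaves it unchanged. `igvprog` implements
the full analysis around this statistic:

1. **Preprocessing** — blacklist/sex-chromosome/coverage probe filters,
   detection-p masking, KNN imputation (k = 5 over probe rows).
2. **Per-gene measures** — region mean, IGV (≥ 3 probes), the
   *mean derivative* (mean |Δβ| between adjacent CpGs), and cross-sample
   variance, for promoter (TSS200) and gene-body regions.
3. **Signature discovery** — repeated 2/3–1/3 splits; on each training set an
   elastic-net Cox model (maximising
   φ(θ, λ, α) = (2/N)·ℓ(θ) − λ[α‖θ‖₁ + (1−α)/2·‖θ‖₂²], λ by ten-fold CV)
   selects genes; training-score tertiles classify the test set and the
   extreme tertiles are compared by a stratified Mantel–Haenszel (log-rank)
   test. Across the FDR-significant splits (q < 0.1), each gene's inclusion
   count y out of k fits is scored against a binomial null whose inclusion
   probability p_b = f/m is mixed over the empirical distribution of the
   observed model sizes f; genes at q < 0.05 form the signature, labelled
   *hyper*/*hypo* by the sign of their univariate Cox association.
4. **Cluster scores and the prognostic score** — Monti consensus clustering
   (hierarchical inner loop, 1 − Spearman ρ distance, 0.8 sample resampling)
   of hyper and hypo genes separately; clusters with ≥ 10 genes and
   survival-associated mean IGV survive; a multivariate Cox model on the
   cluster scores (+ binarized clinical covariates) yields the IGV prognostic
   score, dichotomised at the training-cohort median. External cohorts are
   scored from the cluster-score coefficients only, one sample at a time.
5. **Heterogeneity and TF analyses** — cross-sample variance vs IGV spline
   curves (per patient for multi-region cohorts), quadrant enrichment,
   mean-derivative dispersion contrasts, Fisher TF-binding enrichment,
   bound-vs-unbound expression–IGV KS tests, CGI/enhancer probe enrichment.

A first-class synthetic-data module generates 450K-like cohorts in which
every one of these effects is planted — including the two cell-mixing
regimes (consistent vs heterogeneous single-cell variability averaged over
cells) that explain how high single-cell variability can yield either high
or low measured IGV.

## Worked example

```python
from igvprog import SimConfig, gen_cohort, gen_manifest
from igvprog.cli import run_pipeline

cfg = SimConfig(seed=1)                 # 200 samples, 500 genes, 4 planted clusters
beta, clinical, truth = gen_cohort(cfg)
result = run_pipeline(beta, gen_manifest(cfg), clinical,
                      seed=7, n_repeats=200, resamplings=1000)
print(len(result["signature"]), result["model"].cluster_coefficients_standardized)
```

prints (elastic-net blend α = 0.4 selected by cross-validation; 200 of 200
splits significant):

```
98 {'hyper1': 0.802, 'hyper2': 0.735, 'hypo1': -0.648, 'hypo2': -0.722}
```

i.e. a 98-gene signature covering 77 of the 80 planted genes (precision
0.79, recall 0.96) whose four consensus clusters match the planted
clusters, with positive standardized Cox coefficients for the hyper
clusters (higher IGV → worse outcome) and negative for the hypo clusters.
Applying the model to an independently simulated 300-sample cohort
(`SimConfig(seed=99, n_samples=300)`) and splitting at the *training*
median gives a worse-vs-better univariate hazard ratio of 4.25
(p ≈ 1×10⁻¹⁹).

The same pipeline is available from the shell:

```bash
igvprog simulate --seed 1 --outdir sim/
igvprog run --beta sim/beta.tsv --manifest sim/manifest.tsv \
            --clinical sim/clinical.tsv --seed 7 --outdir out/
```

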