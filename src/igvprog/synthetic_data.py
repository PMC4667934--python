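"""Synthetic 450K-like data with the statistical structure the pipeline assumes.

The generator emulates what a methylation array measures: each emitted beta
value is the average methylation of a probe over a latent mixture of
single-cell profiles, truncated to [0, 1].  Two cell-mixing regimes are
planted:

* **consistent** — every cell in the sample carries the same high-amplitude
  probe pattern.  Averaging preserves it, so the gene shows high IGV, low
  cross-sample variance, and a CpG-to-CpG roughness (mean derivative) that
  varies little across samples.
* **heterogeneous** — every cell carries its own random high-amplitude
  pattern.  Averaging over many cells flattens the profile (low IGV), while
  a sample-level random phase (the partially coherent fraction of cells,
  plus a per-sample global shift) makes the measured profile differ strongly
  between samples: high cross-sample variance and a mean-derivative
  roughness whose across-sample dispersion is high.

Four planted prognostic clusters use these mechanics: "hyper" clusters gain
hazard as their IGV rises, "hypo" clusters as it falls.  Per cluster, a
latent per-sample factor z_c ~ N(0,1) modulates the genes' IGV and enters
the proportional-hazards linear predictor with the planted coefficient.
Survival times are exponential under that hazard; censoring is an
independent exponential whose rate is tuned to the target censoring
fraction.  Clinical covariate prevalences and the event fraction default to
values typical of an advanced serous ovarian carcinoma cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_io import BetaMatrix, ClinicalTable, ExpressionMatrix, ProbeManifest, TFBindingTable

REGIMES = ("hyper1", "hyper2", "hypo1", "hypo2", "null")

#: Cell-mixing mechanics per regime: consistent patterns for the clusters
#: that sit in the high-IGV / low-heterogeneity corner, heterogeneous
#: (cell-variable) patterns for the low-IGV / high-heterogeneity corner.
REGIME_MECHANICS = {
    "hyper1": "heterogeneous",
    "hyper2": "consistent",
    "hypo1": "heterogeneous",
    "hypo2": "consistent",
    "null": "null",
}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort."""

    n_samples: int = 200
    n_genes: int = 500
    probes_per_gene: int = 8
    n_signature_genes: int = 20  # per planted cluster
    cluster_regimes: Tuple[str, ...] = ("hyper1", "hyper2", "hypo1", "hypo2")
    #: Planted log-hazard weight of each cluster's latent factor.
    cluster_betas: Tuple[float, ...] = (0.9, 0.9, -0.9, -0.9)
    cells_per_sample: int = 50
    censoring_rate: float = 0.28
    #: Prevalence of the binarized clinical covariates.
    covariate_prevalence: Dict[str, float] = field(default_factory=lambda: {
        "age_ge60": 0.43, "stage_34": 0.83, "grade_3": 0.65, "residual": 0.42,
    })
    #: Log-hazard weight of each clinical covariate.
    covariate_betas: Dict[str, float] = field(default_factory=lambda: {
        "age_ge60": 0.3, "stage_34": 0.5, "grade_3": 0.2, "residual": 0.4,
    })
    # --- regime amplitudes (methylation-scale) -------------------------
    consistent_amplitude: float = 0.30   # probe-pattern half-range, consistent
    consistent_modulation: float = 0.08  # relative IGV modulation by z
    consistent_gene_noise: float = 0.05  # per-gene-sample amplitude noise
    hetero_cell_amplitude: float = 0.50  # per-cell pattern half-range
    hetero_coherence_base: float = 0.35  # mean coherent cell fraction
    hetero_coherence_slope: float = 0.25 # coherence modulation by z
    hetero_sample_shift_sd: float = 0.10 # per-sample global shift (phase)
    array_noise_sd: float = 0.02         # technical noise after cell averaging
    # --- manifest annotation rates per regime --------------------------
    cgi_island_rate: Dict[str, float] = field(default_factory=lambda: {
        "hyper2": 0.7, "hypo2": 0.5, "default": 0.3,
    })
    enhancer_rate: Dict[str, float] = field(default_factory=lambda: {
        "hypo1": 0.5, "hypo2": 0.5, "default": 0.2,
    })
    n_tss200_probes: int = 3
    n_blacklisted: int = 10
    n_sex_probes: int = 10
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.probes_per_gene < 3:
            raise ValueError("probes_per_gene must be >= 3")
        if len(self.cluster_regimes) != len(self.cluster_betas):
            raise ValueError("one planted beta per cluster regime required")
        for r in self.cluster_regimes:
            if r not in REGIMES:
                raise ValueError(f"unknown regime {r!r}")
        if not np.all(np.isfinite(self.cluster_betas)):
            raise ValueError("planted coefficients must be finite")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    cluster_genes: Dict[str, List[str]]
    gene_regimes: Dict[str, str]
    cluster_factors: pd.DataFrame   # sample × cluster latent z
    linear_predictor: np.ndarray
    covariates: pd.DataFrame

    @property
    def signature_genes(self) -> List[str]:
        return sorted(g for genes in self.cluster_genes.values() for g in genes)


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

def _gene_regimes(config: SimConfig) -> Dict[str, str]:
    regimes = {}
    i = 0
    for regime in config.cluster_regimes:
        for _ in range(config.n_signature_genes):
            regimes[f"G{i:04d}"] = regime
            i += 1
    while i < config.n_genes:
        regimes[f"G{i:04d}"] = "null"
        i += 1
    if i > config.n_genes:
        raise ValueError("n_genes too small for the planted clusters")
    return regimes


def gen_manifest(config: SimConfig) -> ProbeManifest:
    """Synthetic probe manifest: per gene, a gene-body block of
    ``probes_per_gene`` probes plus a TSS200 block, on autosomes with
    strictly increasing positions; plus blacklisted and sex-chromosome
    decoy probes to exercise filtering."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    regimes = _gene_regimes(config)
    rows = []
    pos = {f"chr{c}": 10_000 for c in range(1, 23)}
    for gi, (gene, regime) in enumerate(regimes.items()):
        chrom = f"chr{gi % 22 + 1}"
        island_rate = config.cgi_island_rate.get(
            regime, config.cgi_island_rate["default"])
        enh_rate = config.enhancer_rate.get(
            regime, config.enhancer_rate["default"])
        for t in range(config.n_tss200_probes):
            pos[chrom] += int(rng.integers(20, 80))
            rows.append({
                "probe_id": f"cg_{gene}_tss{t}", "chromosome": chrom,
                "position": pos[chrom], "gene": gene, "region": "TSS200",
                "cgi_relation": "island" if rng.random() < 0.6 else "shore",
                "enhancer": False, "blacklisted": False,
            })
        pos[chrom] += 500
        for p in range(config.probes_per_gene):
            pos[chrom] += int(rng.integers(50, 400))
            cgi = ("island" if rng.random() < island_rate else
                   rng.choice(["shore", "shelf", "open_sea"], p=[0.3, 0.2, 0.5]))
            rows.append({
                "probe_id": f"cg_{gene}_b{p}", "chromosome": chrom,
                "position": pos[chrom], "gene": gene, "region": "Body",
                "cgi_relation": cgi,
                "enhancer": bool(rng.random() < enh_rate),
                "blacklisted": False,
            })
        pos[chrom] += 2000
    for b in range(config.n_blacklisted):
        rows.append({
            "probe_id": f"cg_bl{b}", "chromosome": "chr1",
            "position": 1_000_000 + b * 100, "gene": "", "region": "other",
            "cgi_relation": "open_sea", "enhancer": False, "blacklisted": True,
        })
    for s in range(config.n_sex_probes):
        rows.append({
            "probe_id": f"cg_sex{s}", "chromosome": "X",
            "position": 10_000 + s * 100, "gene": "", "region": "other",
            "cgi_relation": "open_sea", "enhancer": False, "blacklisted": False,
        })
    df = pd.DataFrame(rows).set_index("probe_id")
    return ProbeManifest(df)


# ---------------------------------------------------------------------------
# Beta-matrix emission
# ---------------------------------------------------------------------------

def _emit_gene_body(
    regime: str,
    z: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    patient_of: Optional[np.ndarray] = None,
    flip_rate: float = 0.15,
    patient_offset_sd: float = 0.08,
) -> np.ndarray:
    """Probe × sample beta block for one gene given its cluster factor z.

    When ``patient_of`` groups samples into tumours (multi-region designs),
    the heterogeneous regime's per-sample phase becomes a patient-level
    pattern with a small per-region flip rate, and every gene gains a
    patient-level baseline offset — regions of one tumour then resemble
    each other more than regions of different tumours.
    """
    P, n, C = config.probes_per_gene, len(z), config.cells_per_sample
    noise = rng.normal(0.0, config.array_noise_sd, size=(P, n))
    jitter = rng.uniform(0.9, 1.1)  # mild per-gene amplitude variation
    mechanics = REGIME_MECHANICS[regime]
    if mechanics == "null":
        baseline = rng.uniform(0.3, 0.7)
        probe_fx = rng.normal(0.0, 0.03, size=(P, 1))
        cell_avg = rng.normal(0.0, 0.08 / np.sqrt(C), size=(P, n))
        block = baseline + probe_fx + cell_avg + noise
    elif mechanics == "consistent":
        # one shared high-amplitude alternating pattern across all cells;
        # per-sample amplitude modulated by the cluster factor
        A = config.consistent_amplitude * jitter
        pattern = (np.where(np.arange(P) % 2 == 0, 1.0, -1.0)
                   * rng.uniform(0.8, 1.2, size=P))[:, None]
        amp = 1.0 + config.consistent_modulation * z \
            + rng.normal(0.0, config.consistent_gene_noise, size=n)
        amp = np.clip(amp, 0.1, None)[None, :]
        block = 0.5 + A * pattern * amp + noise
    elif mechanics == "heterogeneous":
        # independent high-amplitude patterns per cell; averaging flattens
        # the profile, leaving a coherent per-sample phase whose strength
        # kappa is modulated by the cluster factor, plus a per-sample shift
        A = config.hetero_cell_amplitude * jitter
        kappa = np.clip(
            config.hetero_coherence_base + config.hetero_coherence_slope * z
            + rng.normal(0.0, 0.05, size=n), 0.02, 0.98)
        if patient_of is None:
            sample_pattern = rng.choice([-1.0, 1.0], size=(P, n))
        else:
            n_pat = int(patient_of.max()) + 1
            base = rng.choice([-1.0, 1.0], size=(P, n_pat))[:, patient_of]
            flips = np.where(rng.random((P, n)) < flip_rate, -1.0, 1.0)
            sample_pattern = base * flips
        shift = rng.normal(0.0, config.hetero_sample_shift_sd, size=(1, n))
        incoherent = rng.normal(0.0, A / np.sqrt(C), size=(P, n))
        block = 0.5 + shift + A * kappa[None, :] * sample_pattern \
            + incoherent + noise
    else:  # pragma: no cover
        raise ValueError(f"unknown mechanics {mechanics!r}")
    if patient_of is not None:
        n_pat = int(patient_of.max()) + 1
        offsets = rng.normal(0.0, patient_offset_sd, size=n_pat)
        block = block + offsets[patient_of][None, :]
    return np.clip(block, 0.0, 1.0)


def _emit_decoys(config: SimConfig, n: int,
                 rng: np.random.Generator) -> Tuple[List[str], np.ndarray]:
    """Blacklisted and sex-chromosome decoy probes (flat noisy betas)."""
    ids = [f"cg_bl{b}" for b in range(config.n_blacklisted)]
    ids += [f"cg_sex{s}" for s in range(config.n_sex_probes)]
    vals = np.clip(rng.uniform(0.2, 0.8, size=(len(ids), 1))
                   + rng.normal(0.0, 0.05, size=(len(ids), n)), 0.0, 1.0)
    return ids, vals


def _emit_tss200(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Promoter probes carry no planted signal: low, weakly noisy betas."""
    P = config.n_tss200_probes
    baseline = rng.uniform(0.05, 0.25)
    probe_fx = rng.normal(0.0, 0.02, size=(P, 1))
    noise = rng.normal(0.0, 0.03, size=(P, n))
    return np.clip(baseline + probe_fx + noise, 0.0, 1.0)


def _censoring_rate_for(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate r with mean P(C < T) equal to ``target``."""
    if target <= 0:
        return 0.0

    def frac(r):
        return float(np.mean(r / (r + hazards))) - target

    hi = float(hazards.max()) * 1e3 + 1.0
    return brentq(frac, 1e-12, hi)


def gen_cohort(
    config: SimConfig,
    manifest: Optional[ProbeManifest] = None,
    sample_prefix: str = "S",
) -> Tuple[BetaMatrix, ClinicalTable, SimTruth]:
    """Generate a beta matrix, clinical table and ground truth.

    Deterministic in (config, seed): identical configs reproduce the output
    bit for bit.
    """
    if manifest is None:
        manifest = gen_manifest(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_samples
    regimes = _gene_regimes(config)
    clusters = list(config.cluster_regimes)
    z = pd.DataFrame(
        rng.normal(size=(n, len(clusters))),
        index=[f"{sample_prefix}{i:04d}" for i in range(n)],
        columns=clusters,
    )
    cluster_of = {}
    cluster_genes: Dict[str, List[str]] = {c: [] for c in clusters}
    for gene, regime in regimes.items():
        if regime != "null" and len(cluster_genes[regime]) < config.n_signature_genes:
            cluster_genes[regime].append(gene)
            cluster_of[gene] = regime

    probe_ids: List[str] = []
    blocks: List[np.ndarray] = []
    for gene, regime in regimes.items():
        zg = (z[cluster_of[gene]].to_numpy() if gene in cluster_of
              else np.zeros(n))
        blocks.append(_emit_tss200(config, n, rng))
        probe_ids.extend(f"cg_{gene}_tss{t}" for t in range(config.n_tss200_probes))
        blocks.append(_emit_gene_body(regime, zg, config, rng))
        probe_ids.extend(f"cg_{gene}_b{p}" for p in range(config.probes_per_gene))
    decoy_ids, decoy_vals = _emit_decoys(config, n, rng)
    probe_ids.extend(decoy_ids)
    blocks.append(decoy_vals)
    values = np.vstack(blocks)
    mask = np.zeros_like(values, dtype=bool)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan
    beta = BetaMatrix(np.asarray(probe_ids, dtype=object), z.index.to_numpy(),
                      values, mask)

    # clinical covariates and proportional-hazards survival
    cov = pd.DataFrame({
        name: (rng.random(n) < prev).astype(float)
        for name, prev in config.covariate_prevalence.items()
    }, index=z.index)
    betas = np.asarray(config.cluster_betas, dtype=float)
    lp = z.to_numpy() @ betas
    for name, b in config.covariate_betas.items():
        if name in cov.columns:
            lp = lp + b * cov[name].to_numpy()
    hazards = np.exp(lp - lp.mean())
    event_times = rng.exponential(1.0 / hazards) * 1000.0
    if config.censoring_rate > 0:
        r = _censoring_rate_for(hazards / 1000.0, config.censoring_rate)
        censor_times = rng.exponential(1.0 / r, size=n)
        times = np.minimum(event_times, censor_times)
        events = event_times <= censor_times
    else:
        times, events = event_times, np.ones(n, dtype=bool)
    clinical = ClinicalTable(pd.DataFrame({
        "time": np.maximum(times, 1e-3),
        "event": events,
        "age": np.where(cov["age_ge60"] > 0, 60, 50) + rng.integers(0, 10, n),
        "stage": np.where(cov["stage_34"] > 0, 3, 2),
        "grade": np.where(cov["grade_3"] > 0, 3, 2),
        "residual": cov["residual"].astype(int),
    }, index=pd.Index(z.index, name="sample_id")))
    truth = SimTruth(
        cluster_genes=cluster_genes,
        gene_regimes=regimes,
        cluster_factors=z,
        linear_predictor=lp,
        covariates=cov,
    )
    return beta, clinical, truth


# ---------------------------------------------------------------------------
# Multi-region tumours
# ---------------------------------------------------------------------------

def gen_multiregion(
    config: SimConfig,
    patients: int,
    samples_per_patient: int,
    within_patient_sd: float = 0.3,
) -> Tuple[BetaMatrix, pd.DataFrame]:
    """Multi-region sampling: several samples per tumour.

    Regions of one patient share the patient's latent cluster factors with a
    within-patient perturbation smaller than the between-patient spread, so
    within-patient cross-sample variance sits below the between-patient one.
    """
    if samples_per_patient < 2:
        raise ValueError("samples_per_patient must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_total = patients * samples_per_patient
    sub = replace(config, n_samples=n_total)
    manifest = gen_manifest(sub)
    regimes = _gene_regimes(sub)
    clusters = list(sub.cluster_regimes)
    z_patient = rng.normal(size=(patients, len(clusters)))
    z = np.repeat(z_patient, samples_per_patient, axis=0) \
        + rng.normal(0.0, within_patient_sd, size=(n_total, len(clusters)))
    sample_ids = [f"P{p:02d}_R{r}" for p in range(patients)
                  for r in range(samples_per_patient)]
    patient_idx = np.repeat(np.arange(patients), samples_per_patient)
    zdf = pd.DataFrame(z, index=sample_ids, columns=clusters)
    cluster_of = {}
    seen = {c: 0 for c in clusters}
    for gene, regime in regimes.items():
        if regime != "null" and seen[regime] < sub.n_signature_genes:
            cluster_of[gene] = regime
            seen[regime] += 1
    probe_ids: List[str] = []
    blocks: List[np.ndarray] = []
    for gene, regime in regimes.items():
        zg = (zdf[cluster_of[gene]].to_numpy() if gene in cluster_of
              else np.zeros(n_total))
        blocks.append(_emit_tss200(sub, n_total, rng))
        probe_ids.extend(f"cg_{gene}_tss{t}" for t in range(sub.n_tss200_probes))
        blocks.append(_emit_gene_body(regime, zg, sub, rng,
                                      patient_of=patient_idx))
        probe_ids.extend(f"cg_{gene}_b{p}" for p in range(sub.probes_per_gene))
    beta = BetaMatrix(np.asarray(probe_ids, dtype=object),
                      np.asarray(sample_ids, dtype=object),
                      np.vstack(blocks), np.zeros((len(probe_ids), n_total), bool))
    grouping = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": [s.split("_")[0] for s in sample_ids],
    })
    return beta, grouping


# ---------------------------------------------------------------------------
# TF binding and expression
# ---------------------------------------------------------------------------

def gen_tf_data(
    config: SimConfig,
    igv_values: pd.DataFrame,
    cluster_genes: Dict[str, List[str]],
    n_tfs: int = 55,
    planted_positive: Sequence[str] = ("TF01",),
    planted_negative: Sequence[str] = ("TF02",),
    target_rho: float = 0.6,
    base_binding_rate: float = 0.3,
    enriched_binding_rate: float = 0.9,
) -> Tuple[TFBindingTable, ExpressionMatrix]:
    """TF binding and expression with planted bound-vs-unbound contrasts.

    Planted TFs bind one planted cluster's genes at a high rate; their
    expression is built from the bound genes' mean IGV profile so the
    per-gene IGV correlation over bound genes targets ±``target_rho``.
    ``igv_values`` is a gene × sample IGV table from the same cohort.
    """
    overlap = set(planted_positive) & set(planted_negative)
    if overlap:
        raise ValueError(f"TFs planted in both directions: {sorted(overlap)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    tf_names = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    for tf in list(planted_positive) + list(planted_negative):
        if tf not in tf_names:
            raise ValueError(f"planted TF {tf!r} outside the emitted TF names")
    genes = list(igv_values.index)
    samples = list(igv_values.columns)
    cluster_cycle = [c for c in cluster_genes if cluster_genes[c]]
    rows = []
    expr = np.empty((n_tfs, len(samples)))
    planted = {tf: +1 for tf in planted_positive}
    planted.update({tf: -1 for tf in planted_negative})
    for i, tf in enumerate(tf_names):
        if tf in planted and cluster_cycle:
            target_cluster = cluster_cycle[i % len(cluster_cycle)]
            in_cluster = set(cluster_genes[target_cluster]) & set(genes)
            bound = {g for g in genes
                     if (g in in_cluster and rng.random() < enriched_binding_rate)
                     or (g not in in_cluster and rng.random() < 0.01)}
            sign = planted[tf]
            bound_profile = igv_values.loc[sorted(bound)].mean(axis=0).to_numpy()
            zs = (bound_profile - bound_profile.mean())
            sd = zs.std()
            zs = zs / sd if sd > 0 else zs
            # scale the coherent part so the realized mean per-gene
            # correlation over bound genes lands near the target
            per_gene = igv_values.loc[sorted(bound)].to_numpy()
            cors = []
            for row in per_gene:
                if row.std() > 0:
                    cors.append(np.corrcoef(row, bound_profile)[0, 1])
            attenuation = float(np.clip(np.mean(cors), 0.1, 1.0)) if cors else 1.0
            w = min(target_rho / attenuation, 0.99)
            expr[i] = sign * (w * zs
                              + np.sqrt(max(1 - w ** 2, 0.0))
                              * rng.normal(size=len(samples)))
        else:
            bound = {g for g in genes if rng.random() < base_binding_rate}
            expr[i] = rng.normal(size=len(samples))
        for g in genes:
            rows.append({"tf": tf, "gene": g, "bound": g in bound})
    binding = TFBindingTable(pd.DataFrame(rows))
    expression = ExpressionMatrix(
        np.asarray(tf_names, dtype=object),
        np.asarray(samples, dtype=object),
        expr,
    )
    return binding, expression


# ---------------------------------------------------------------------------
# Direct cluster-score cohorts (for coefficient-recovery studies)
# ---------------------------------------------------------------------------

def gen_score_cohort(
    coefficients: Dict[str, float],
    n_samples: int,
    seed: int,
    censoring_rate: float = 0.28,
    covariate_prevalence: Optional[Dict[str, float]] = None,
    covariate_betas: Optional[Dict[str, float]] = None,
) -> Tuple[pd.DataFrame, ClinicalTable]:
    """Cohort with cluster scores drawn as unit-variance normals and survival
    from a Cox model with the given (standardized-scale) coefficients.

    Because the scores have unit variance, the planted values are directly
    the SD-standardized coefficients a Cox fit should recover.
    """
    rng = np.random.default_rng(seed)
    names = list(coefficients)
    sample_ids = [f"V{i:04d}" for i in range(n_samples)]
    scores = pd.DataFrame(rng.normal(size=(n_samples, len(names))),
                          index=pd.Index(sample_ids, name="sample_id"),
                          columns=names)
    lp = scores.to_numpy() @ np.array([coefficients[c] for c in names])
    prev = covariate_prevalence or {
        "age_ge60": 0.43, "stage_34": 0.83, "grade_3": 0.65, "residual": 0.42}
    cbetas = covariate_betas or {
        "age_ge60": 0.3, "stage_34": 0.5, "grade_3": 0.2, "residual": 0.4}
    cov = pd.DataFrame({k: (rng.random(n_samples) < p).astype(float)
                        for k, p in prev.items()}, index=scores.index)
    for k, b in cbetas.items():
        lp = lp + b * cov[k].to_numpy()
    hazards = np.exp(lp - lp.mean())
    t_event = rng.exponential(1.0 / hazards) * 1000.0
    if censoring_rate > 0:
        r = _censoring_rate_for(hazards / 1000.0, censoring_rate)
        t_cens = rng.exponential(1.0 / r, size=n_samples)
        times = np.minimum(t_event, t_cens)
        events = t_event <= t_cens
    else:
        times, events = t_event, np.ones(n_samples, dtype=bool)
    clinical = ClinicalTable(pd.DataFrame({
        "time": np.maximum(times, 1e-3),
        "event": events,
        "age": np.where(cov["age_ge60"] > 0, 65, 52),
        "stage": np.where(cov["stage_34"] > 0, 3, 2),
        "grade": np.where(cov["grade_3"] > 0, 3, 2),
        "residual": cov["residual"].astype(int),
    }, index=scores.index))
    return scores, clinical
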