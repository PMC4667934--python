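"""Consensus clustering of signature genes and the IGV prognostic score.

Signature genes are consensus-clustered (separately for hyper and hypo
genes) by repeated hierarchical clustering of sample subsamples with
1 − Spearman correlation distance.  Clusters surviving the size and
survival-association filters yield per-sample cluster scores (mean IGV over
the cluster's genes).  A multivariate Cox model on the cluster scores plus
binarized clinical covariates defines the IGV prognostic score; its
training-cohort median dichotomizes any cohort — external cohorts are
scored from the cluster-score coefficients only, never the covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .core_io import ClinicalTable
from .gene_measures import GeneMeasureMatrix
from .survival_stats import CoxFit, binarize_covariates, multivariate_cox, univariate_cox


# ---------------------------------------------------------------------------
# Consensus clustering (Monti resampling scheme)
# ---------------------------------------------------------------------------

@dataclass
class ConsensusClustering:
    gene_ids: np.ndarray
    consensus_matrix: np.ndarray  # for chosen_k
    k_grid: np.ndarray
    chosen_k: int
    labels: Dict[str, int]
    cdf_areas: Dict[int, float] = field(default_factory=dict)


def _spearman_distance(values: np.ndarray) -> np.ndarray:
    """1 − Spearman rho between rows, clipped to [0, 2]."""
    ranks = np.apply_along_axis(rankdata, 1, values)
    sd = ranks.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant gene rows at indices {bad.tolist()}")
    rho = np.corrcoef(ranks)
    return np.clip(1.0 - rho, 0.0, 2.0)


def _cut_tree(dist: np.ndarray, k: int) -> np.ndarray:
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    igv: GeneMeasureMatrix,
    resamplings: int = 1000,
    sample_frac: float = 0.8,
    feature_frac: float = 1.0,
    max_k: int = 20,
    seed: int = 0,
    delta_min: float = 0.1,
) -> ConsensusClustering:
    """Consensus-cluster genes by their IGV profiles across samples.

    Each resampling subsamples samples at ``sample_frac`` (and genes at
    ``feature_frac`` if below 1), hierarchically clusters the genes with
    average linkage on 1 − Spearman rho, and cuts at every k in the grid.
    Per k, the consensus matrix entry for a gene pair is the fraction of
    co-resamplings in which they co-clustered.  The cluster count is chosen
    from the relative change Δ(k) in the area under the consensus CDF: the
    largest k whose area gain is still appreciable (Δ(k) >= ``delta_min``),
    i.e. the point where the Δ curve levels off.  Cutting finer than the
    true structure is benign here — stable clusters stay intact and loose
    genes split into fragments that the downstream size/survival filter
    removes — whereas undercutting irreversibly merges distinct IGV
    patterns.  The final labels come from hierarchical clustering of
    1 − consensus at the chosen k.
    """
    if resamplings < 10:
        raise ValueError("need at least 10 resamplings")
    G = len(igv.gene_ids)
    if G < 2:
        raise ValueError("need at least 2 genes to cluster")
    n = len(igv.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    _spearman_distance(igv.values)  # fail fast on constant rows
    rng = np.random.default_rng(seed)
    ks = np.arange(2, min(max_k, G - 1) + 1)
    co = {k: np.zeros((G, G)) for k in ks}
    both = np.zeros((G, G))
    n_sub = max(3, int(round(sample_frac * n)))
    g_sub = G if feature_frac >= 1.0 else max(2, int(round(feature_frac * G)))
    for _ in range(resamplings):
        cols = rng.choice(n, size=n_sub, replace=False)
        gidx = (np.arange(G) if g_sub == G
                else np.sort(rng.choice(G, size=g_sub, replace=False)))
        vals = igv.values[np.ix_(gidx, cols)]
        try:
            dist = _spearman_distance(vals)
        except ValueError:
            continue  # a subsample can render a row constant; skip it
        both[np.ix_(gidx, gidx)] += 1.0
        for k in ks:
            if k >= len(gidx):
                continue
            labels = _cut_tree(dist.copy(), k)
            same = labels[:, None] == labels[None, :]
            co[k][np.ix_(gidx, gidx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {k: np.where(both > 0, co[k] / both, 0.0) for k in ks}
    for k in ks:
        np.fill_diagonal(consensus[k], 1.0)

    areas = {int(k): _cdf_area(consensus[k]) for k in ks}
    deltas = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[int(k)] = areas[int(k)]
        else:
            prev = areas[int(ks[i - 1])]
            deltas[int(k)] = (areas[int(k)] - prev) / prev if prev > 0 else 0.0
    appreciable = [k for k, d in deltas.items() if d >= delta_min]
    if appreciable:
        chosen_k = max(appreciable)
    else:  # no appreciable gain anywhere: take the largest single change
        chosen_k = max(deltas, key=lambda k: (deltas[k], -k))

    final = _cut_tree(1.0 - consensus[chosen_k], chosen_k)
    labels = {g: int(c) for g, c in zip(igv.gene_ids, final)}
    return ConsensusClustering(
        gene_ids=np.asarray(igv.gene_ids, dtype=object),
        consensus_matrix=consensus[chosen_k],
        k_grid=ks,
        chosen_k=int(chosen_k),
        labels=labels,
        cdf_areas=areas,
    )


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus values."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    if vals.size == 0:
        return 0.0
    # A = sum_i (x_i - x_{i-1}) * CDF(x_{i-1}) over the sorted support
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.searchsorted(vals, xs, side="right") / vals.size
    return float(np.sum(np.diff(xs) * cdf[:-1]))


# ---------------------------------------------------------------------------
# Cluster filtering and scores
# ---------------------------------------------------------------------------

def filter_clusters(
    clustering: ConsensusClustering,
    igv: GeneMeasureMatrix,
    clinical: ClinicalTable,
    min_genes: int = 10,
    p_max: float = 0.05,
    name_prefix: str = "cluster",
) -> Dict[str, List[str]]:
    """Keep clusters with >= ``min_genes`` genes whose mean IGV is
    survival-associated (univariate Cox p < ``p_max``).

    Survivors are named ``<prefix>1``, ``<prefix>2``, ... by decreasing size.
    """
    by_cluster: Dict[int, List[str]] = {}
    for g, c in clustering.labels.items():
        by_cluster.setdefault(c, []).append(g)
    common = [s for s in igv.sample_ids if s in set(clinical.sample_ids)]
    clin = clinical.subset(common).table
    t = clin["time"].to_numpy(dtype=float)
    e = clin["event"].to_numpy(dtype=bool)
    meas = igv.to_frame()[common]
    survivors: List[Tuple[int, List[str]]] = []
    for c, genes in by_cluster.items():
        if len(genes) < min_genes:
            continue
        mean_igv = meas.loc[genes].mean(axis=0).to_numpy()
        try:
            fit = univariate_cox(mean_igv, t, e)
        except ValueError:
            continue
        if fit.p_values[0] < p_max:
            survivors.append((c, sorted(genes)))
    if not survivors:
        raise ValueError("no clusters survive the size and survival filters")
    survivors.sort(key=lambda cg: (-len(cg[1]), cg[0]))
    return {f"{name_prefix}{i + 1}": genes
            for i, (_, genes) in enumerate(survivors)}


def cluster_scores(
    igv: GeneMeasureMatrix,
    clusters: Dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-sample mean IGV over each cluster's genes (sample × cluster)."""
    meas = igv.to_frame()
    present = set(igv.gene_ids)
    out = {}
    for name, genes in clusters.items():
        missing = [g for g in genes if g not in present]
        if missing:
            raise KeyError(f"cluster {name!r} genes missing from matrix: {missing}")
        out[name] = meas.loc[list(genes)].mean(axis=0)
    df = pd.DataFrame(out)
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# Prognostic model
# ---------------------------------------------------------------------------

@dataclass
class PrognosticModel:
    """Fitted IGV prognostic score: cluster gene sets, Cox coefficients and
    the training-cohort median cutoff."""

    clusters: Dict[str, List[str]]
    cluster_coefficients: Dict[str, float]
    cluster_coefficients_standardized: Dict[str, float]
    covariate_coefficients: Dict[str, float]
    training_median: float
    fit: Optional[CoxFit] = None
    metadata: Dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "clusters": self.clusters,
            "cluster_coefficients": self.cluster_coefficients,
            "cluster_coefficients_standardized":
                self.cluster_coefficients_standardized,
            "covariate_coefficients": self.covariate_coefficients,
            "training_median": self.training_median,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PrognosticModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            clusters=payload["clusters"],
            cluster_coefficients=payload["cluster_coefficients"],
            cluster_coefficients_standardized=
                payload["cluster_coefficients_standardized"],
            covariate_coefficients=payload["covariate_coefficients"],
            training_median=payload["training_median"],
            metadata=payload.get("metadata", {}),
        )


def fit_prognostic_model(
    scores: pd.DataFrame,
    clinical: ClinicalTable,
    clusters: Optional[Dict[str, List[str]]] = None,
    metadata: Optional[Dict] = None,
) -> PrognosticModel:
    """Multivariate Cox on cluster scores plus binarized clinical covariates.

    The training median is the median over training samples of the
    cluster-score-only linear predictor (covariate terms excluded), and is
    the cutoff later reused to dichotomize external cohorts.
    """
    common = [s for s in scores.index if s in set(clinical.sample_ids)]
    sc = scores.loc[common]
    clin = clinical.subset(common).table
    cov = binarize_covariates(clin)
    cov = cov.loc[:, cov.std(ddof=1) > 0]
    design = pd.concat([sc, cov], axis=1)
    fit = multivariate_cox(
        design.to_numpy(), clin["time"].to_numpy(dtype=float),
        clin["event"].to_numpy(dtype=bool), names=list(design.columns),
    )
    cluster_names = list(sc.columns)
    coefs = dict(zip(fit.names, fit.coefficients))
    std = dict(zip(fit.names, fit.standardized_coefficients))
    cluster_coef = {c: float(coefs[c]) for c in cluster_names}
    lin_pred = sc.to_numpy() @ np.array([cluster_coef[c] for c in cluster_names])
    return PrognosticModel(
        clusters={c: list(map(str, g)) for c, g in (clusters or {}).items()}
                 or {c: [] for c in cluster_names},
        cluster_coefficients=cluster_coef,
        cluster_coefficients_standardized={c: float(std[c]) for c in cluster_names},
        covariate_coefficients={c: float(coefs[c]) for c in cov.columns},
        training_median=float(np.median(lin_pred)),
        fit=fit,
        metadata=metadata or {},
    )


def apply_prognostic_score(
    model: PrognosticModel,
    igv_external: GeneMeasureMatrix,
) -> pd.DataFrame:
    """IGV prognostic score and risk group for an external cohort.

    Uses cluster-score coefficients only (no covariates); every sample is
    classified independently against the training-cohort median.  Up to 10%
    of a cluster's genes may be absent, in which case the cluster mean is
    renormalized over the present genes.
    """
    present = set(igv_external.gene_ids)
    meas = igv_external.to_frame()
    scores = {}
    for name, genes in model.clusters.items():
        if not genes:
            raise ValueError(f"model cluster {name!r} carries no gene list")
        have = [g for g in genes if g in present]
        missing_frac = 1.0 - len(have) / len(genes)
        if missing_frac > 0.10:
            raise KeyError(
                f"{missing_frac:.0%} of cluster {name!r} genes missing "
                "from the external matrix (limit 10%)"
            )
        if missing_frac > 0:
            warnings.warn(
                f"cluster {name!r}: {missing_frac:.0%} genes missing; "
                "renormalizing the cluster mean over present genes"
            )
        scores[name] = meas.loc[have].mean(axis=0)
    sc = pd.DataFrame(scores)
    sc.index = pd.Index(igv_external.sample_ids, name="sample_id")
    theta = np.array([model.cluster_coefficients[c] for c in sc.columns])
    score = sc.to_numpy() @ theta
    out = pd.DataFrame({
        "score": score,
        "risk_group": np.where(score > model.training_median, "worse", "better"),
    }, index=pd.Index(igv_external.sample_ids, name="sample_id"))
    return pd.concat([sc, out], axis=1)


def validate_groups(
    groups: pd.Series,
    clinical_external: ClinicalTable,
) -> Tuple[CoxFit, CoxFit, pd.DataFrame]:
    """Univariate and multivariate Cox for worse-vs-better risk groups, plus
    Kaplan–Meier step functions per group."""
    common = [s for s in groups.index if s in set(clinical_external.sample_ids)]
    grp = groups.loc[common]
    if grp.nunique() < 2:
        raise ValueError("both risk groups must be non-empty for validation")
    clin = clinical_external.subset(common).table
    t = clin["time"].to_numpy(dtype=float)
    e = clin["event"].to_numpy(dtype=bool)
    worse = (grp == "worse").astype(float).to_numpy()
    uni = univariate_cox(worse, t, e, name="worse_group")
    cov = binarize_covariates(clin)
    cov = cov.loc[:, cov.std(ddof=1) > 0]
    design = np.column_stack([worse, cov.to_numpy()]) if len(cov.columns) else \
        worse[:, None]
    multi = multivariate_cox(design, t, e,
                             names=["worse_group"] + list(cov.columns))
    km_rows = []
    for label in ("better", "worse"):
        m = (grp == label).to_numpy()
        if not m.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=label)
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"]
        for time, surv in sf.itertuples():
            km_rows.append({
                "group": label, "time": float(time), "survival": float(surv),
                "at_risk": int(at_risk.get(time, 0)),
            })
    return uni, multi, pd.DataFrame(km_rows)
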