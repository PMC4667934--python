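"""Intra-tumour-heterogeneity analyses relating IGV to cross-sample variance.

For each gene (gene-body region, >= 3 probes) and each sample set — one set
per patient for multi-region cohorts, or the whole cohort — two statistics
are computed: the mean IGV across the set's samples, and the cross-sample
variance (mean over probes of the per-probe across-sample variance).  Their
relationship E(cross_var | IGV) is summarised by a spline fit per set, and
gene clusters are tested for enrichment on either side of the signature
median IGV.  The dispersion of the mean-derivative measure across samples
separates consistently-variable methylation patterns (low dispersion) from
cell-heterogeneous ones (high dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .core_io import BetaMatrix, ProbeManifest
from .gene_measures import (
    build_region_index,
    cross_sample_variance,
    mean_derivative,
    region_igv,
)
from .survival_stats import bh_fdr


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def ith_profile(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    sample_sets: Dict[str, Sequence[str]],
    region: str = "Body",
) -> pd.DataFrame:
    """Per (gene, sample set): mean IGV and cross-sample variance.

    ``sample_sets`` maps a set label (patient id, or a single label for the
    whole cohort) to its sample ids; every set needs >= 2 samples.
    """
    for label, samples in sample_sets.items():
        if len(samples) < 2:
            raise ValueError(f"sample set {label!r} has fewer than 2 samples")
    present = set(beta.probe_ids)
    indices = [ix for ix in build_region_index(manifest, region, min_probes=3)
               if all(p in present for p in ix.probe_ids)]
    lookup = {s: j for j, s in enumerate(beta.sample_ids)}
    rows = []
    for label, samples in sample_sets.items():
        cols = [lookup[s] for s in samples]
        for ix in indices:
            igv = region_igv(beta, ix)[cols]
            cv = cross_sample_variance(beta, ix, sample_subset=samples)
            rows.append({
                "gene": ix.gene, "set": label,
                "mean_igv": float(igv.mean()), "cross_var": cv,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spline curve for E(cross_var | IGV)
# ---------------------------------------------------------------------------

@dataclass
class FittedCurve:
    """Least-squares cubic B-spline regression curve with fixed df."""

    knots: np.ndarray
    coefficients: np.ndarray
    degree: int
    x_range: Tuple[float, float]
    df: int

    def __call__(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        return BSpline(self.knots, self.coefficients, self.degree)(x)


def fit_ith_curve(profile: pd.DataFrame, df: int = 4) -> FittedCurve:
    """Fit cross_var as a smooth function of mean_igv (cubic spline, df=4).

    The basis has ``df`` B-spline functions with interior knots at x
    quantiles, estimated by ordinary least squares; a straight-line
    relationship is reproduced exactly.
    """
    if len(profile) < 10:
        raise ValueError("need at least 10 genes to fit a curve")
    x = profile["mean_igv"].to_numpy(dtype=float)
    y = profile["cross_var"].to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    degree = 3
    n_interior = max(df - degree - 1, 0)
    lo, hi = float(x[0]), float(x[-1])
    if hi == lo:
        hi = lo + 1e-12
    interior = (np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
                if n_interior else np.array([]))
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    n_basis = len(knots) - degree - 1
    design = np.column_stack([
        BSpline.basis_element(knots[i:i + degree + 2], extrapolate=False)(x)
        for i in range(n_basis)
    ])
    design = np.nan_to_num(design)
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    return FittedCurve(knots, coefs, degree, (lo, hi), df)


# ---------------------------------------------------------------------------
# Enrichment either side of the signature median IGV
# ---------------------------------------------------------------------------

def quadrant_enrichment(
    profile: pd.DataFrame,
    clusters: Dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Fisher enrichment of each cluster on either side of the median IGV.

    Genes are split at the median mean_igv of all signature (cluster) genes;
    each cluster's membership × side table is tested two-sided and BH-adjusted
    across clusters.
    """
    for name, genes in clusters.items():
        if len(genes) == 0:
            raise ValueError(f"cluster {name!r} is empty")
    prof = profile.set_index("gene")
    sig_genes = sorted({g for genes in clusters.values() for g in genes})
    median_igv = prof.loc[sig_genes, "mean_igv"].median()
    high_side = prof.loc[sig_genes, "mean_igv"] > median_igv
    rows = []
    for name, genes in clusters.items():
        in_cluster = high_side.index.isin(list(genes))
        a = int((in_cluster & high_side).sum())
        b = int((in_cluster & ~high_side).sum())
        c = int((~in_cluster & high_side).sum())
        d = int((~in_cluster & ~high_side).sum())
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"cluster": name, "n_high": a, "n_low": b,
                     "odds_ratio": orr, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def overlap_test(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    universe: int,
) -> Tuple[float, float]:
    """Fisher's exact test of the overlap between two gene sets."""
    a_set, b_set = set(genes_a), set(genes_b)
    if not a_set or not b_set:
        raise ValueError("both gene sets must be non-empty")
    if universe < len(a_set | b_set):
        raise ValueError("universe smaller than the union of the sets")
    both = len(a_set & b_set)
    only_a = len(a_set) - both
    only_b = len(b_set) - both
    neither = universe - both - only_a - only_b
    orr, p = stats.fisher_exact([[both, only_a], [only_b, neither]],
                                alternative="two-sided")
    return float(orr), float(p)


# ---------------------------------------------------------------------------
# Mean-derivative dispersion
# ---------------------------------------------------------------------------

def mean_derivative_dispersion(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    clusters: Dict[str, Sequence[str]],
    region: str = "Body",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Across-sample variance of the mean derivative, per gene and cluster.

    Returns the gene-level table and a per-cluster summary (median, IQR) of
    the dispersion distribution.
    """
    present = set(beta.probe_ids)
    wanted = {g for genes in clusters.values() for g in genes}
    indices = {ix.gene: ix
               for ix in build_region_index(manifest, region, min_probes=2)
               if ix.gene in wanted and all(p in present for p in ix.probe_ids)}
    rows = []
    for name, genes in clusters.items():
        for g in genes:
            if g not in indices:
                continue
            md = mean_derivative(beta, indices[g])
            rows.append({"cluster": name, "gene": g,
                         "dispersion": float(np.var(md, ddof=1))})
    gene_table = pd.DataFrame(rows)
    summaries = []
    for name, grp in gene_table.groupby("cluster"):
        q1, med, q3 = np.percentile(grp["dispersion"], [25, 50, 75])
        summaries.append({"cluster": name, "median": med, "iqr": q3 - q1,
                          "n_genes": len(grp)})
    return gene_table, pd.DataFrame(summaries)
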