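"""Transcription-factor binding and CGI/enhancer enrichment analyses.

Each TF is tested (Fisher's exact, two-sided, BH across TF × cluster pairs)
for over- or under-enriched binding to the genes of each prognostic-
signature cluster.  Separately, the correlation of each TF's expression
with the IGV of the genes it binds versus the genes it does not bind is
compared with a one-sided two-sample Kolmogorov–Smirnov test.  Probe-level
enrichment of CGI categories (island/shore/shelf) and enhancer annotation
is tested for gene-body probe sets against their stated backgrounds.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, ProbeManifest, TFBindingTable
from .gene_measures import GeneMeasureMatrix
from .survival_stats import bh_fdr

#: Sentinel reported in place of an infinite odds ratio.
OR_INF = float("inf")


def _fisher(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


def tf_binding_enrichment(
    binding: TFBindingTable,
    clusters: Dict[str, Sequence[str]],
    universe: Sequence[str],
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of TF binding in each cluster over the universe.

    Direction is "over" / "under" (odds ratio above / below 1) where the
    BH-adjusted q across all (TF, cluster) pairs is below ``q_max``, else
    "none".
    """
    universe = list(dict.fromkeys(universe))
    uni_set = set(universe)
    for name, genes in clusters.items():
        if len(genes) == 0:
            raise ValueError(f"cluster {name!r} is empty")
        if not set(genes) <= uni_set:
            raise ValueError(f"cluster {name!r} has genes outside the universe")
    rows = []
    for tf in binding.tfs:
        bound = binding.bound_genes(tf) & uni_set
        for name, genes in clusters.items():
            gset = set(genes)
            a = len(bound & gset)
            b = len(gset) - a
            c = len(bound - gset)
            d = len(uni_set) - len(gset) - c
            if len(bound) == 0:
                rows.append({"tf": tf, "cluster": name, "odds_ratio": np.nan,
                             "p": 1.0, "undefined": True})
                continue
            orr, p = _fisher(a, b, c, d)
            rows.append({"tf": tf, "cluster": name,
                         "odds_ratio": OR_INF if np.isinf(orr) else orr,
                         "p": p, "undefined": False})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    direction = np.full(len(out), "none", dtype=object)
    sig = (out["q"] < q_max) & ~out["undefined"]
    direction[sig & (out["odds_ratio"] > 1)] = "over"
    direction[sig & (out["odds_ratio"] < 1)] = "under"
    out["direction"] = direction
    return out


def expression_igv_correlation(
    expression: ExpressionMatrix,
    igv: GeneMeasureMatrix,
    binding: TFBindingTable,
    tf: str,
    method: str = "spearman",
) -> Tuple[np.ndarray, np.ndarray]:
    """Correlation of a TF's expression with per-gene IGV, split by binding.

    Correlations run across the samples shared between the expression and
    IGV matrices (>= 5 required); genes with constant IGV are excluded with
    a warning.  Returns (bound correlations, unbound correlations).
    """
    if tf not in set(expression.gene_ids):
        raise KeyError(f"TF {tf!r} absent from the expression matrix")
    shared = [s for s in expression.sample_ids if s in set(igv.sample_ids)]
    if len(shared) < 5:
        raise ValueError("need >= 5 shared samples for correlation")
    exp_cols = {s: j for j, s in enumerate(expression.sample_ids)}
    tf_expr = expression.gene_values(tf)[[exp_cols[s] for s in shared]]
    igv_df = igv.to_frame()[shared]
    corr_func = stats.spearmanr if method == "spearman" else stats.pearsonr
    bound_set = binding.bound_genes(tf)
    bound, unbound = [], []
    skipped = 0
    for gene, row in igv_df.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            skipped += 1
            continue
        rho = corr_func(tf_expr, vals)[0]
        (bound if gene in bound_set else unbound).append(rho)
    if skipped:
        warnings.warn(f"excluded {skipped} constant-IGV genes from correlation")
    return np.asarray(bound), np.asarray(unbound)


def bound_vs_unbound_ks(
    bound_corrs,
    unbound_corrs,
    alternative: str = "greater",
) -> Tuple[float, float]:
    """One-sided two-sample KS test of bound vs unbound correlations.

    ``alternative="greater"`` tests whether the bound correlations are
    shifted toward more positive values than the unbound ones ("less" the
    reverse).
    """
    bound = np.asarray(bound_corrs, dtype=float)
    unbound = np.asarray(unbound_corrs, dtype=float)
    if bound.size == 0 or unbound.size == 0:
        raise ValueError("both correlation sets must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    # scipy's one-sided alternatives are phrased on CDFs: the bound sample
    # being stochastically larger means its CDF lies below the unbound CDF.
    scipy_alt = "less" if alternative == "greater" else "greater"
    res = stats.ks_2samp(bound, unbound, alternative=scipy_alt)
    return float(res.statistic), float(res.pvalue)


def tf_expression_screen(
    expression: ExpressionMatrix,
    igv: GeneMeasureMatrix,
    binding: TFBindingTable,
    method: str = "spearman",
) -> pd.DataFrame:
    """KS screen over all TFs for both orientations, BH within orientation."""
    rows = []
    for tf in binding.tfs:
        if tf not in set(expression.gene_ids):
            continue
        bound, unbound = expression_igv_correlation(
            expression, igv, binding, tf, method=method)
        if bound.size == 0 or unbound.size == 0:
            continue
        for orientation in ("greater", "less"):
            d, p = bound_vs_unbound_ks(bound, unbound, alternative=orientation)
            rows.append({"tf": tf, "orientation": orientation, "D": d, "p": p,
                         "n_bound": bound.size, "n_unbound": unbound.size})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = np.nan
        for orientation in ("greater", "less"):
            m = out["orientation"] == orientation
            out.loc[m, "q"] = bh_fdr(out.loc[m, "p"].to_numpy())
    return out


def cgi_enhancer_enrichment(
    manifest: ProbeManifest,
    probe_sets: Dict[str, Sequence[str]],
    background: Dict[str, Sequence[str]],
    categories: Sequence[str] = ("island", "shore", "shelf", "enhancer"),
) -> pd.DataFrame:
    """Fisher enrichment of CGI/enhancer categories in probe sets.

    ``background`` maps each set name to its background probe list (all
    array probes for the all-gene-body test; all gene-body probes for
    signature/cluster tests).  BH adjustment runs within each category
    across sets.
    """
    df = manifest.table
    rows = []
    for name, probes in probe_sets.items():
        probes = list(probes)
        if not probes:
            raise ValueError(f"probe set {name!r} is empty")
        bg = list(background[name])
        bg_set = set(bg)
        if not set(probes) <= bg_set:
            raise ValueError(f"probe set {name!r} not contained in its background")
        sub = df.loc[probes]
        bgdf = df.loc[bg]
        for cat in categories:
            if cat == "enhancer":
                in_cat = sub["enhancer"].to_numpy(dtype=bool)
                bg_cat = bgdf["enhancer"].to_numpy(dtype=bool)
            else:
                in_cat = (sub["cgi_relation"] == cat).to_numpy()
                bg_cat = (bgdf["cgi_relation"] == cat).to_numpy()
            if not bg_cat.any():
                raise ValueError(f"category {cat!r} absent from background of {name!r}")
            a = int(in_cat.sum())
            b = len(probes) - a
            c = int(bg_cat.sum()) - a
            d = (len(bg) - len(probes)) - c
            orr, p = _fisher(a, b, c, d)
            rows.append({"set": name, "category": cat, "odds_ratio": orr, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for cat in out["category"].unique():
        m = out["category"] == cat
        out.loc[m, "q"] = bh_fdr(out.loc[m, "p"].to_numpy())
    sig = out["q"] < 0.05
    out["direction"] = np.where(sig & (out["odds_ratio"] > 1), "over",
                                np.where(sig & (out["odds_ratio"] < 1),
                                         "under", "none"))
    return out
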