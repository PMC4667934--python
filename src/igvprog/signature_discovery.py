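"""Prognostic-signature discovery by repeated-split elastic-net Cox.

The cohort is repeatedly partitioned into a 2/3 training and 1/3 test set.
On each training set an elastic-net Cox model selects a group of genes and
their coefficients; training risk scores define tertile cutoffs; top- and
bottom-tertile test samples are compared by the stratified Mantel–Haenszel
test.  Splits significant after FDR adjustment (q < 0.1 by default) form
the consensus family: each gene's inclusion count y out of the k
significant fits is scored against a binomial null whose per-fit inclusion
probability p_b = f/m is either fixed (binomial tail) or drawn from the
empirical distribution of the observed model sizes f (mixture tail).
Genes significant under the mixture model (q < 0.05 by default) form the
signature, each labelled hyper or hypo by the sign of its univariate Cox
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, ClinicalTable, ProbeManifest
from .gene_measures import GeneMeasureMatrix, measure_matrix
from .survival_stats import (
    bh_fdr,
    fit_elastic_net_cox,
    select_alpha,
    strata_labels,
    stratified_mh_test,
    univariate_cox,
)


# ---------------------------------------------------------------------------
# Split machinery
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    """One train/test partition with its fitted model and test outcome."""

    split_id: int
    seed: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    alpha: float
    lam: float
    selected: Dict[str, float]  # gene -> coefficient
    test_p: Optional[float]  # None when the split was uninformative
    test_q: Optional[float] = None  # filled by the family-wise FDR pass

    @property
    def f(self) -> int:
        return len(self.selected)


def train_test_partition(
    sample_ids: Sequence[str], seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded 2/3–1/3 partition; training size floor(2n/3).

    At n = 218 this gives 145 training and 73 test samples.
    """
    ids = np.asarray(sample_ids, dtype=object)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = (2 * len(ids)) // 3
    return ids[perm[:n_train]], ids[perm[n_train:]]


def tertile_groups(scores) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Tertile labels and cutoffs (1/3 and 2/3 linear-interpolation quantiles).

    Label is "low" for score <= lower cutoff, "high" for score > upper
    cutoff, "mid" otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(scores)) < 3:
        raise ValueError("tertile grouping needs >= 3 distinct scores")
    lo, hi = np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(scores <= lo, "low", np.where(scores > hi, "high", "mid"))
    return labels.astype(object), (float(lo), float(hi))


def apply_tertile_cutoffs(scores, cutoffs: Tuple[float, float]) -> np.ndarray:
    """Classify scores against training-derived cutoffs, sample by sample."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = cutoffs
    return np.where(scores <= lo, "low",
                    np.where(scores > hi, "high", "mid")).astype(object)


def run_split(
    measure: GeneMeasureMatrix,
    clinical: ClinicalTable,
    seed: int,
    split_id: int = 0,
    alpha: Optional[float] = None,
    n_lambdas: int = 30,
) -> SplitResult:
    """One discovery split: partition, penalized fit, tertile test.

    ``alpha=None`` selects the elastic-net blend by grid search within the
    training set; a fixed value skips that search (the full-cohort pipeline
    selects alpha once and passes it to every split).
    """
    common = [s for s in measure.sample_ids if s in set(clinical.sample_ids)]
    if len(common) < 30:
        raise ValueError("need >= 30 samples shared between measure and clinical")
    clin = clinical.subset(common).table
    meas = measure.to_frame()[common]
    train_ids, test_ids = train_test_partition(common, seed)

    X = meas.T  # samples x genes
    Xtr = X.loc[train_ids].to_numpy()
    t_tr = clin.loc[train_ids, "time"].to_numpy(dtype=float)
    e_tr = clin.loc[train_ids, "event"].to_numpy(dtype=bool)
    if e_tr.sum() < 2 or clin.loc[test_ids, "event"].sum() < 2:
        raise ValueError("need >= 2 events in both the training and test portion")

    genes = list(meas.index)
    if alpha is None:
        used_alpha, fit = select_alpha(Xtr, t_tr, e_tr, names=genes, seed=seed,
                                       n_lambdas=n_lambdas)
    else:
        used_alpha = float(alpha)
        fit = fit_elastic_net_cox(Xtr, t_tr, e_tr, alpha=used_alpha, lam="cv",
                                  names=genes, seed=seed, n_lambdas=n_lambdas)
    selected = {g: float(c) for g, c in zip(genes, fit.coefficients) if c != 0.0}

    test_p: Optional[float] = None
    if selected:
        coefs = fit.coefficients
        train_scores = Xtr @ coefs
        try:
            _, cutoffs = tertile_groups(train_scores)
        except ValueError:
            cutoffs = None
        if cutoffs is not None:
            test_scores = X.loc[test_ids].to_numpy() @ coefs
            test_labels = apply_tertile_cutoffs(test_scores, cutoffs)
            extreme = np.isin(test_labels, ["low", "high"])
            if (test_labels == "low").any() and (test_labels == "high").any():
                sub = np.asarray(test_ids, dtype=object)[extreme]
                strata = strata_labels(clin.loc[sub])
                try:
                    _, test_p = stratified_mh_test(
                        test_labels[extreme], strata,
                        clin.loc[sub, "time"].to_numpy(dtype=float),
                        clin.loc[sub, "event"].to_numpy(dtype=bool),
                    )
                except ValueError:
                    test_p = None
    return SplitResult(
        split_id=split_id, seed=seed,
        train_ids=train_ids, test_ids=test_ids,
        alpha=used_alpha, lam=fit.lam, selected=selected, test_p=test_p,
    )


def run_splits(
    measure: GeneMeasureMatrix,
    clinical: ClinicalTable,
    n_repeats: int,
    seed: int,
    alpha: Optional[float] = None,
    n_lambdas: int = 30,
) -> List[SplitResult]:
    """Run ``n_repeats`` seeded splits; per-split seeds derive from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_repeats)]
    return [
        run_split(measure, clinical, child_seeds[i], split_id=i,
                  alpha=alpha, n_lambdas=n_lambdas)
        for i in range(n_repeats)
    ]


def assign_split_fdr(splits: List[SplitResult]) -> None:
    """BH-adjust test p-values across the family of informative splits."""
    idx = [i for i, s in enumerate(splits) if s.test_p is not None]
    if not idx:
        return
    q = bh_fdr([splits[i].test_p for i in idx])
    for i, qi in zip(idx, q):
        splits[i].test_q = float(qi)


# ---------------------------------------------------------------------------
# Consensus significance model
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalInclusionDist:
    """Empirical distribution of the per-fit inclusion probability p_b = f/m."""

    support: np.ndarray  # observed p_b values
    weights: np.ndarray  # relative frequencies, sum 1
    m: int

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size and not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")


@dataclass
class ConsensusTally:
    """Per-gene inclusion counts and mixture-model significance."""

    table: pd.DataFrame  # index gene; columns y, proportion_mean, p, q
    k: int  # number of significant fits
    m: int  # gene universe size


def binom_tail(y: int, k: int, p_b: float) -> float:
    """P(Y >= y) for Y ~ Binomial(k, p_b), computed stably for large k."""
    if not 0 <= y <= k:
        raise ValueError("require 0 <= y <= k")
    if y == 0:
        return 1.0
    return float(stats.binom.sf(y - 1, k, p_b))


def mixture_tail(y: int, k: int, dist: EmpiricalInclusionDist) -> float:
    """Binomial tail averaged over the empirical distribution of p_b."""
    tails = np.array([binom_tail(y, k, p) for p in dist.support])
    return float(np.dot(dist.weights, tails))


def consensus_tally(
    splits: List[SplitResult],
    m: int,
    q_max: float = 0.1,
) -> Tuple[ConsensusTally, EmpiricalInclusionDist, int]:
    """Tally gene inclusions over the significant splits and score each gene.

    ``m`` is the size of the gene universe the models selected from.  Genes
    are ranked by inclusion count y, ties broken by the mean share of the
    absolute-coefficient total that the gene carried in the models that
    selected it.
    """
    if any(s.test_q is None and s.test_p is not None for s in splits):
        assign_split_fdr(splits)
    signif = [s for s in splits if s.test_q is not None and s.test_q < q_max]
    k = len(signif)
    if k == 0:
        raise ValueError("no significant fits; cannot form a consensus")

    f_values = np.array([s.f for s in signif], dtype=float)
    support, counts = np.unique(f_values / m, return_counts=True)
    dist = EmpiricalInclusionDist(support, counts / counts.sum(), m)

    y_counts: Dict[str, int] = {}
    prop_sums: Dict[str, float] = {}
    for s in signif:
        total = sum(abs(c) for c in s.selected.values())
        for g, c in s.selected.items():
            y_counts[g] = y_counts.get(g, 0) + 1
            prop_sums[g] = prop_sums.get(g, 0.0) + abs(c) / total
    genes = sorted(y_counts)
    y = np.array([y_counts[g] for g in genes], dtype=int)
    prop = np.array([prop_sums[g] / y_counts[g] for g in genes])
    p = np.array([mixture_tail(int(yy), k, dist) for yy in y])
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"y": y, "proportion_mean": prop, "p": p, "q": q},
        index=pd.Index(genes, name="gene"),
    ).sort_values(["y", "proportion_mean"], ascending=False, kind="stable")
    return ConsensusTally(table, k, m), dist, k


def extract_signature(
    tally: ConsensusTally,
    measure: GeneMeasureMatrix,
    clinical: ClinicalTable,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Signature genes (mixture-model q < ``q_max``) with hyper/hypo labels.

    A gene is "hyper" when higher IGV associates with worse outcome
    (positive univariate Cox coefficient on the full cohort), "hypo"
    otherwise.
    """
    sig = tally.table[tally.table["q"] < q_max].copy()
    if sig.empty:
        raise ValueError("empty signature at the requested q threshold")
    common = [s for s in measure.sample_ids if s in set(clinical.sample_ids)]
    clin = clinical.subset(common).table
    t = clin["time"].to_numpy(dtype=float)
    e = clin["event"].to_numpy(dtype=bool)
    meas = measure.to_frame()[common]
    directions = []
    for g in sig.index:
        fit = univariate_cox(meas.loc[g].to_numpy(), t, e)
        directions.append("hyper" if fit.coefficients[0] > 0 else "hypo")
    sig["direction"] = directions
    sig["k"] = tally.k
    return sig


# ---------------------------------------------------------------------------
# Measure comparison
# ---------------------------------------------------------------------------

MEASURE_REGIMES = (
    ("mean", "TSS200"),
    ("igv", "TSS200"),
    ("mean", "Body"),
    ("igv", "Body"),
)


def compare_measures(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    clinical: ClinicalTable,
    n_repeats: int = 2001,
    seed: int = 0,
    alpha: Optional[float] = 0.5,
    fit_q: float = 0.1,
    n_lambdas: int = 30,
) -> pd.DataFrame:
    """Fraction of significantly predictive splits for each per-gene measure.

    For each of the four measures (promoter/body × mean/IGV) the repeated
    split procedure runs ``n_repeats`` times; test p-values are FDR-adjusted
    within measure and splits with q < ``fit_q`` counted.
    """
    rows = []
    for i, (meas_name, region) in enumerate(MEASURE_REGIMES):
        mm = measure_matrix(beta, manifest, meas_name, region)
        if mm.values.shape[0] == 0:
            rows.append({"measure": meas_name, "region": region,
                         "n_repeats": n_repeats, "n_significant": 0,
                         "fraction_significant": 0.0})
            continue
        splits = run_splits(mm, clinical, n_repeats, seed + i, alpha=alpha,
                            n_lambdas=n_lambdas)
        assign_split_fdr(splits)
        n_sig = sum(1 for s in splits if s.test_q is not None and s.test_q < fit_q)
        rows.append({"measure": meas_name, "region": region,
                     "n_repeats": n_repeats, "n_significant": n_sig,
                     "fraction_significant": n_sig / n_repeats})
    return pd.DataFrame(rows)
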