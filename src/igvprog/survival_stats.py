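"""Survival-analysis primitives.

Cox partial likelihood (Breslow risk-set convention), elastic-net-penalized
Cox regression with internal ten-fold cross-validation for the penalty
magnitude, the stratified Mantel–Haenszel (stratified log-rank) two-group
test, univariate/multivariate Cox fits, and Benjamini–Hochberg FDR.

The penalized fit maximizes

    phi(theta, lambda, alpha)
        = (2/N) l(theta)
          - lambda * [ alpha * ||theta||_1 + (1 - alpha)/2 * ||theta||_2^2 ]

where ``l`` is the log partial likelihood, ``alpha`` blends the L1 and L2
penalties and ``lambda`` scales them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.stats.multitest import multipletests

Z_95 = 1.959963984540054  # normal 97.5% quantile


# ---------------------------------------------------------------------------
# Partial likelihood (Breslow)
# ---------------------------------------------------------------------------

def cox_log_partial_likelihood(
    theta: np.ndarray,
    covariates: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
) -> float:
    """Log Breslow partial likelihood.

    l(theta) = sum_{j in S} [ theta'x_j - log sum_{j' in R_j} exp(theta'x_{j'}) ]
    with risk set R_j = {j' : Y_{j'} >= Y_j}.  Tied event times each
    contribute the full risk-set denominator (Breslow convention).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    if not events.any():
        warnings.warn("all subjects censored; partial likelihood is 1")
        return 0.0
    eta = X @ theta
    # sort by decreasing time: the risk set at time t is a prefix, and the
    # log-denominator is a running logsumexp over that prefix
    order = np.argsort(-times, kind="stable")
    eta_sorted = eta[order]
    times_sorted = times[order]
    events_sorted = events[order]
    cum_lse = np.logaddexp.accumulate(eta_sorted)
    # subjects tied at the same time all enter the risk set together: each
    # event's denominator runs to the last index of its tie block (Breslow)
    last_in_tie = np.searchsorted(-times_sorted, -times_sorted, side="right") - 1
    ev = events_sorted
    ll = np.sum(eta_sorted[ev] - cum_lse[last_in_tie[ev]])
    return float(ll)


def cox_partial_likelihood(theta, covariates, times, events) -> float:
    """Breslow partial likelihood L(theta) (product form)."""
    return float(np.exp(cox_log_partial_likelihood(theta, covariates, times, events)))


# ---------------------------------------------------------------------------
# Fit records
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Unpenalized Cox fit summary."""

    names: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    standardized_coefficients: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "coef": self.coefficients,
            "se": self.standard_errors,
            "hr": self.hazard_ratios,
            "hr_ci_lower": self.ci_lower,
            "hr_ci_upper": self.ci_upper,
            "p": self.p_values,
        }, index=pd.Index(self.names, name="predictor"))
        if self.standardized_coefficients is not None:
            df["coef_standardized"] = self.standardized_coefficients
        return df


@dataclass
class PenalizedCoxFit:
    """Elastic-net Cox fit at one (alpha, lambda)."""

    names: list
    coefficients: np.ndarray
    lam: float
    alpha: float
    cv_error: Optional[float] = None
    cv_errors_path: Optional[pd.DataFrame] = None  # lambda -> mean CV deviance

    @property
    def selected(self) -> list:
        return [n for n, c in zip(self.names, self.coefficients) if c != 0.0]


# ---------------------------------------------------------------------------
# Elastic-net Cox
# ---------------------------------------------------------------------------

def _as_surv(times, events):
    return Surv.from_arrays(
        np.asarray(events, dtype=bool), np.asarray(times, dtype=float)
    )

#: l1_ratio floor — the coordinate-descent solver requires a strictly
#: positive L1 share, so the pure-ridge grid point is evaluated just off 0.
MIN_L1_RATIO = 0.01


def _cv_folds(events: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Event-stratified fold assignment so every fold carries events."""
    events = np.asarray(events, dtype=bool)
    fold = np.empty(len(events), dtype=int)
    for mask in (events, ~events):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def fit_elastic_net_cox(
    covariates,
    times,
    events,
    alpha: float = 0.5,
    lam: Union[float, str] = "cv",
    names: Optional[Sequence[str]] = None,
    n_folds: int = 10,
    n_lambdas: int = 30,
    seed: int = 0,
    lambda_rule: str = "1se",
) -> PenalizedCoxFit:
    """Fit the elastic-net Cox model; ``lam="cv"`` selects the penalty by
    ten-fold cross-validated partial-likelihood deviance within the data.

    ``lambda_rule`` picks from the CV curve: ``"1se"`` (default) takes the
    largest penalty whose deviance is within one standard error of the
    minimum — the sparser, canonical cross-validation choice — while
    ``"min"`` takes the deviance minimizer.  Predictors are standardized
    internally; coefficients are reported on the original scale.  ``lam=0``
    is the unpenalized fit.
    """
    X = np.asarray(covariates, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)

    if isinstance(lam, (int, float)) and lam == 0:
        fit = multivariate_cox(X, times, events, names=names, allow_collinear=True)
        return PenalizedCoxFit(names, fit.coefficients, 0.0, alpha)

    l1 = max(float(alpha), MIN_L1_RATIO)

    if isinstance(lam, (int, float)):
        model = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=[float(lam)],
                                       normalize=True)
        model.fit(X, _as_surv(times, events))
        coef = model.coef_[:, 0]
        return PenalizedCoxFit(names, coef, float(lam), alpha)

    if lam != "cv":
        raise ValueError("lam must be a number or 'cv'")

    # Path on the full data defines the candidate lambda sequence.
    path = CoxnetSurvivalAnalysis(
        l1_ratio=l1, n_alphas=n_lambdas, alpha_min_ratio=0.05, normalize=True
    )
    path.fit(X, _as_surv(times, events))
    lambdas = np.asarray(path.alphas_)

    rng = np.random.default_rng(seed)
    fold = _cv_folds(events, n_folds, rng)
    # Verweij & Van Houwelingen cross-validated deviance:
    #   D_f(lambda) = -2 * [ l_all(theta_{-f}) - l_{-f}(theta_{-f}) ]
    dev = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        tr = fold != f
        try:
            m = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=list(lambdas),
                                       normalize=True)
            m.fit(X[tr], _as_surv(times[tr], events[tr]))
        except (ValueError, ArithmeticError):
            dev[f] = np.nan
            continue
        fitted = {a: i for i, a in enumerate(m.alphas_)}
        for j, lamv in enumerate(lambdas):
            if lamv in fitted:
                theta = m.coef_[:, fitted[lamv]]
            else:  # solver dropped this lambda; fall back to nearest fitted
                theta = m.coef_[:, int(np.argmin(np.abs(m.alphas_ - lamv)))]
            l_all = cox_log_partial_likelihood(theta, X, times, events)
            l_tr = cox_log_partial_likelihood(theta, X[tr], times[tr], events[tr])
            dev[f, j] = -2.0 * (l_all - l_tr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dev = np.nanmean(dev, axis=0)
        se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.nanargmin(mean_dev))
    if lambda_rule == "1se":
        # largest lambda (lambdas are descending) within 1 SE of the minimum
        within = np.flatnonzero(mean_dev <= mean_dev[best] + se_dev[best])
        best = int(within[0])
    elif lambda_rule != "min":
        raise ValueError("lambda_rule must be 'min' or '1se'")
    coef = path.coef_[:, best]
    cv_path = pd.DataFrame({"lam": lambdas, "cv_deviance": mean_dev})
    return PenalizedCoxFit(
        names, coef, float(lambdas[best]), alpha,
        cv_error=float(mean_dev[best]), cv_errors_path=cv_path,
    )


DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))


def select_alpha(
    covariates,
    times,
    events,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    names: Optional[Sequence[str]] = None,
    seed: int = 0,
    **kwargs,
) -> Tuple[float, PenalizedCoxFit]:
    """Choose the L1/L2 blend by minimum cross-validated deviance.

    Every grid value is evaluated; ties resolve to the smaller alpha.
    """
    best_alpha = None
    best_fit = None
    records = []
    for a in grid:
        fit = fit_elastic_net_cox(
            covariates, times, events, alpha=float(a), lam="cv",
            names=names, seed=seed, **kwargs,
        )
        records.append((float(a), fit.cv_error))
        if best_fit is None or fit.cv_error < best_fit.cv_error:
            best_alpha, best_fit = float(a), fit
    best_fit.alpha_grid_errors = records  # type: ignore[attr-defined]
    return best_alpha, best_fit


# ---------------------------------------------------------------------------
# Stratified Mantel–Haenszel (stratified log-rank) test
# ---------------------------------------------------------------------------

def stratified_mh_test(
    groups,
    strata,
    times,
    events,
) -> Tuple[float, float]:
    """Stratified log-rank chi-square for a binary group comparison.

    Observed-minus-expected and hypergeometric variances accumulate over
    event times within each stratum; p comes from chi-square with 1 df.
    Strata containing a single group contribute no information.
    """
    groups = np.asarray(groups)
    strata = np.asarray(strata)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("stratified_mh_test requires exactly two groups overall")
    g1 = groups == levels[1]
    U = 0.0
    V = 0.0
    informative = False
    for s in np.unique(strata):
        m = strata == s
        if len(np.unique(groups[m])) < 2:
            warnings.warn(f"stratum {s!r} contains a single group; contributes 0")
            continue
        u, v = _logrank_terms(g1[m], times[m], events[m])
        if v > 0:
            informative = True
        U += u
        V += v
    if not informative or V == 0:
        raise ValueError("all strata uninformative for the stratified test")
    chi2 = U * U / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _logrank_terms(in_group1, times, events) -> Tuple[float, float]:
    """Sum of O−E and hypergeometric variances over event times."""
    u = 0.0
    v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & in_group1).sum()
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(u), float(v)


# ---------------------------------------------------------------------------
# Unpenalized Cox fits (lifelines-backed)
# ---------------------------------------------------------------------------

def _lifelines_fit(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-09, "max_steps": 500})
    return cph


def univariate_cox(score, times, events, name: str = "score") -> CoxFit:
    """Single-predictor Cox fit with normal-approximation 95% CI on the HR."""
    score = np.asarray(score, dtype=float)
    if np.ptp(score) == 0:
        raise ValueError("constant score; univariate Cox fit is degenerate")
    return multivariate_cox(score[:, None], times, events, names=[name])


def multivariate_cox(
    predictors,
    times,
    events,
    names: Optional[Sequence[str]] = None,
    allow_collinear: bool = False,
) -> CoxFit:
    """Joint Cox fit; also reports coefficients scaled by predictor SD."""
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    sds = X.std(axis=0, ddof=1)
    nonconst = sds > 0
    if not nonconst.all():
        dropped = [n for n, ok in zip(names, nonconst) if not ok]
        raise ValueError(f"constant predictors: {dropped}")
    if not allow_collinear:
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            # name the offending columns via the null space of the Gram matrix
            _, _, vt = np.linalg.svd(X - X.mean(axis=0))
            culprit = vt[-1]
            named = [n for n, w in zip(names, culprit) if abs(w) > 1e-6]
            raise ValueError(f"collinear predictors: {named}")
    df = pd.DataFrame(X, columns=names)
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=bool)
    cph = _lifelines_fit(df)
    coef = cph.params_.loc[names].to_numpy()
    se = cph.standard_errors_.loc[names].to_numpy()
    p = cph.summary.loc[names, "p"].to_numpy()
    return CoxFit(
        names=names,
        coefficients=coef,
        standard_errors=se,
        log_likelihood=float(cph.log_likelihood_),
        hazard_ratios=np.exp(coef),
        ci_lower=np.exp(coef - Z_95 * se),
        ci_upper=np.exp(coef + Z_95 * se),
        p_values=p,
        standardized_coefficients=coef * sds,
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Clinical covariate coding
# ---------------------------------------------------------------------------

#: Binarization rules for the standard clinical covariates.
COVARIATE_CODING = {
    "age_ge60": ("age", lambda a: a >= 60),
    "stage_34": ("stage", lambda s: s >= 3),
    "grade_3": ("grade", lambda g: g >= 3),
    "residual": ("residual", lambda r: r > 0),
}


def binarize_covariates(
    clinical_df: pd.DataFrame,
    include: Sequence[str] = ("age_ge60", "stage_34", "grade_3", "residual"),
) -> pd.DataFrame:
    """Binary-coded clinical covariates (age >= 60, stage 3–4, grade 3,
    residual disease present)."""
    out = {}
    for key in include:
        col, rule = COVARIATE_CODING[key]
        if col in clinical_df.columns:
            out[key] = rule(clinical_df[col].astype(float)).astype(float)
    return pd.DataFrame(out, index=clinical_df.index)


def strata_labels(
    clinical_df: pd.DataFrame,
    include: Sequence[str] = ("age_ge60", "stage_34", "residual"),
) -> np.ndarray:
    """Combined stratum label from binarized age/stage/residual.

    Disease grade is deliberately excluded from the stratification set.
    """
    binc = binarize_covariates(clinical_df, include=include)
    if binc.empty:
        return np.zeros(len(clinical_df), dtype=object)
    return binc.astype(int).astype(str).agg("|".join, axis=1).to_numpy(dtype=object)
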