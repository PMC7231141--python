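"""Clinical validation arm: normalization, group comparison, survival.

The downstream analyses that turn a cis-gene list into clinical
evidence: quantile normalization of expression across samples, Wilcoxon
rank-sum comparison between sample groups, median dichotomization of a
gene's expression, Kaplan–Meier survival curves with the log-rank test,
and Cox proportional-hazards regression (Breslow tie handling,
Newton–Raphson on the partial likelihood).

Kaplan–Meier, log-rank and Cox are implemented here directly; the test
suite cross-checks them against independent survival implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import chdtrc

from .core_io import ExpressionMatrix, SurvivalDataset

logger = logging.getLogger("popqtl")

__all__ = [
    "KMCurve",
    "CoxFit",
    "quantile_normalize",
    "ranksum_test",
    "dichotomize_by_median",
    "km_fit",
    "logrank_test",
    "cox_fit",
]


# ---------------------------------------------------------------------------
# Expression preprocessing
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common mean order-statistic scale.

    Each sample's values are replaced by the across-sample mean of the
    order statistics at the same rank; ties within a sample receive the
    mean of the reference values they span. Afterwards every column
    shares an identical sorted value multiset (up to tie averaging).
    """
    v = matrix.values
    if v.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if v.isna().any().any():
        raise ValueError("quantile normalization requires complete data")
    data = v.to_numpy(float)
    reference = np.sort(data, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(data)
    for j in range(data.shape[1]):
        col = data[:, j]
        if np.ptp(col) == 0:
            logger.warning(
                "sample %s has constant expression; mapped to the reference mean",
                v.columns[j],
            )
            out[:, j] = reference.mean()
            continue
        # average ranks (1-based); ties -> mean of spanned reference values
        ranks = stats.rankdata(col, method="average")
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return ExpressionMatrix(pd.DataFrame(out, index=v.index, columns=v.columns))


def ranksum_test(
    x: np.ndarray, y: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``x`` (midranks for
    ties). ``mode="exact"`` enumerates the permutation null (valid for
    untied data); ``mode="normal"`` uses the tie-corrected normal
    approximation with continuity correction; ``mode="auto"`` picks exact
    when ``n_x + n_y <= 20`` and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        mode = "exact" if (combined.size <= 20 and not has_ties) else "normal"
    if mode == "exact":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_x = x.size
    w = float(res.statistic) + n_x * (n_x + 1) / 2.0  # U -> rank sum of x
    return w, float(res.pvalue)


def dichotomize_by_median(values) -> np.ndarray:
    """Split samples into ``"high"`` (> median) and ``"low"`` (<= median).

    Ties at the median go to the low group so the split is
    deterministic. All-identical values admit no split and raise.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    if np.ptp(arr) == 0:
        raise ValueError("all values identical; median split is degenerate")
    median = float(np.median(arr))
    return np.where(arr > median, "high", "low")


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``median_survival`` is the earliest event time at which the survival
    probability drops to 0.5 or below, or ``None`` when never reached.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median_survival: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function (1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(data: SurvivalDataset) -> KMCurve:
    """Kaplan–Meier product-limit estimator over distinct event times."""
    if data.n < 1:
        raise ValueError("empty survival dataset")
    times = data.times
    events = data.events
    event_times = np.unique(times[events == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size, dtype=float)
    s = 1.0
    for i, t in enumerate(event_times):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n
        at_risk[i] = n
        n_events[i] = d
        surv[i] = s
    median = None
    below = np.flatnonzero(surv <= 0.5)
    if below.size:
        median = float(event_times[below[0]])
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        median_survival=median,
    )


def logrank_test(data: SurvivalDataset, groups) -> tuple[float, float]:
    """Two-group log-rank test (1 df).

    Sums observed-minus-expected events for group 1 over the pooled
    distinct event times, with the hypergeometric variance. ``groups``
    is a label per record (exactly two distinct labels).
    """
    labels = np.asarray(groups)
    if labels.shape[0] != data.n:
        raise ValueError("group labels must align with the survival records")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {uniq.tolist()}")
    g1 = labels == uniq[0]
    times, events = data.times, data.events
    event_times = np.unique(times[events == 1])
    obs_minus_exp = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(chdtrc(1, chi2))


@dataclass
class CoxFit:
    coefficients: pd.Series  # log hazard ratios
    se: pd.Series
    hazard_ratios: pd.Series
    log_likelihood: float
    converged: bool
    iterations: int


def _cox_loglik(beta, x_sorted, t_sorted, e_sorted, risk_start):
    """Breslow partial log-likelihood with gradient and information."""
    eta = x_sorted @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * x_sorted
    wxx = wx[:, :, None] * x_sorted[:, None, :]
    # suffix sums: risk set of an event at sorted index i starts at risk_start[i]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros_like(beta)
    info = np.zeros((beta.size, beta.size))
    for i in np.flatnonzero(e_sorted == 1):
        j = risk_start[i]
        m = s1[j] / s0[j]
        ll += eta[i] - np.log(s0[j])
        grad += x_sorted[i] - m
        info += s2[j] / s0[j] - np.outer(m, m)
    return ll, grad, info


def cox_fit(
    data: SurvivalDataset,
    covariates: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton–Raphson (Breslow ties).

    Maximizes the partial likelihood; converged when the maximum
    absolute score component falls below ``tol`` (else ``converged``
    is False after ``max_iter`` iterations — e.g. under perfect
    separation, where a coefficient diverges). Standard errors come from
    the inverse observed information.
    """
    if covariates is None:
        covariates = data.covariate_names
    if not covariates:
        raise ValueError("no covariates supplied")
    if int(data.events.sum()) == 0:
        raise ValueError("no observed events; partial likelihood is undefined")
    x = data.table[list(covariates)].to_numpy(float)
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < len(covariates):
        raise ValueError("covariates are collinear")
    order = np.argsort(data.times, kind="stable")
    t_sorted = data.times[order]
    e_sorted = data.events[order]
    x_sorted = x[order]
    risk_start = np.searchsorted(t_sorted, t_sorted, side="left")

    beta = np.zeros(len(covariates))
    ll, grad, info = _cox_loglik(beta, x_sorted, t_sorted, e_sorted, risk_start)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps Newton monotone on flat likelihoods
        for _ in range(30):
            candidate = beta + step
            ll_new, grad_new, info_new = _cox_loglik(
                candidate, x_sorted, t_sorted, e_sorted, risk_start
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            break
        beta, ll, grad, info = candidate, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 50:
            logger.warning("Cox coefficient diverging (possible perfect separation)")
            break
    else:
        iterations = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(covariates), np.nan)
        converged = False
    names = list(covariates)
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        hazard_ratios=pd.Series(np.exp(beta), index=names),
        log_likelihood=float(ll),
        converged=converged,
        iterations=iterations,
    )
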