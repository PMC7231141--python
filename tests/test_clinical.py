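"""Normalization, rank-sum comparisons and survival statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from popqtl.clinical import (
    cox_fit,
    dichotomize_by_median,
    km_fit,
    logrank_test,
    quantile_normalize,
    ranksum_test,
)
from popqtl.core_io import ExpressionMatrix, SurvivalDataset


def _em(cols: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(cols, index=[f"G{i}" for i in range(len(next(iter(cols.values()))))])
    )


def _surv(times, events, **cov) -> SurvivalDataset:
    return SurvivalDataset(
        pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(times))],
             "time": times, "event": events, **cov}
        )
    )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def test_quantile_normalize_rank_mean():
    out = quantile_normalize(_em({"a": [1, 2, 3], "b": [4, 5, 6]}))
    assert np.allclose(out.values["a"], [2.5, 3.5, 4.5])
    assert np.allclose(out.values["b"], [2.5, 3.5, 4.5])


def test_quantile_normalize_identical_columns_idempotent():
    em = _em({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
    out = quantile_normalize(em)
    assert np.allclose(out.values.to_numpy(), em.values.to_numpy())


def test_quantile_normalize_common_multiset():
    rng = np.random.default_rng(8)
    em = ExpressionMatrix(
        pd.DataFrame(rng.normal(size=(50, 6)),
                     index=[f"G{i}" for i in range(50)],
                     columns=[f"S{j}" for j in range(6)])
    )
    out = quantile_normalize(em).values.to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, 6):
        assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)
    # column means (and variances) coincide after normalization
    assert np.ptp(out.mean(axis=0)) < 1e-12


def test_quantile_normalize_constant_column_warns(caplog):
    em = _em({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with caplog.at_level("WARNING", logger="popqtl"):
        out = quantile_normalize(em)
    assert "constant" in caplog.text
    assert np.allclose(out.values["b"], out.values["b"].iloc[0])


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def test_ranksum_exact_enumeration():
    """2 of the C(6,3)=20 assignments are as extreme -> p = 0.1."""
    w, p = ranksum_test([1, 2, 3], [4, 5, 6])
    assert w == 6.0  # ranks 1+2+3
    assert p == pytest.approx(0.1)
    # exact p-values are achievable tail probabilities (multiples of 1/20)
    assert (p * 20) == pytest.approx(round(p * 20))


def test_ranksum_exhaustive_oracle():
    """Exact mode reproduces full enumeration over all group assignments."""
    pooled = [0.3, 1.1, 2.2, 2.9, 4.0, 5.5]
    x, y = pooled[:3], pooled[3:]
    w_obs, p_obs = ranksum_test(x, y, mode="exact")
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    stats = []
    for combo in itertools.combinations(pooled, 3):
        stats.append(sum(ranks[v] for v in combo))
    stats = np.array(stats)
    mu = stats.mean()
    p_enum = np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12)
    assert p_obs == pytest.approx(p_enum)


def test_ranksum_identical_groups():
    _, p = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_ranksum_modes_agree():
    rng = np.random.default_rng(15)
    for _ in range(20):
        x = rng.normal(size=10)
        y = rng.normal(0.5, 1, size=10)
        _, p_exact = ranksum_test(x, y, mode="exact")
        _, p_norm = ranksum_test(x, y, mode="normal")
        assert abs(p_exact - p_norm) < 0.01


def test_ranksum_empty_group():
    with pytest.raises(ValueError):
        ranksum_test([], [1.0])


# ---------------------------------------------------------------------------
# median dichotomization
# ---------------------------------------------------------------------------


def test_dichotomize_rules():
    assert dichotomize_by_median([1, 2, 3, 4]).tolist() == ["low", "low", "high", "high"]
    # ties at the median go low
    assert dichotomize_by_median([1, 2, 2, 3]).tolist() == ["low", "low", "low", "high"]
    # odd n: the median sample itself is low
    assert dichotomize_by_median([1, 2, 3]).tolist() == ["low", "low", "high"]
    with pytest.raises(ValueError, match="identical"):
        dichotomize_by_median([5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


def test_km_product_limit_closed_form():
    km = km_fit(_surv([1.0, 2.0, 3.0], [1, 1, 1]))
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert km.at_risk.tolist() == [3, 2, 1]
    assert km.median_survival == 2.0


def test_km_all_censored():
    km = km_fit(_surv([1.0, 2.0], [0, 0]))
    assert km.event_times.size == 0
    assert km.median_survival is None
    assert km.survival_at(5.0) == 1.0


def test_km_trailing_censoring_leaves_curve():
    a = km_fit(_surv([1.0, 2.0, 3.0], [1, 1, 1]))
    b = km_fit(_surv([1.0, 2.0, 3.0, 9.0], [1, 1, 1, 0]))
    # at-risk counts change but S at the last event time only through them
    assert b.survival_at(3.0) == pytest.approx(0.25)
    assert a.survival_at(0.5) == b.survival_at(0.5) == 1.0


def test_km_equals_empirical_without_censoring():
    rng = np.random.default_rng(3)
    times = rng.exponential(10, 40)
    km = km_fit(_surv(times, np.ones(40, dtype=int)))
    for t in km.event_times:
        assert km.survival_at(t) == pytest.approx((times > t).mean())
    assert ((km.survival >= 0) & (km.survival <= 1)).all()
    assert (np.diff(km.survival) <= 1e-12).all()


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def test_logrank_identical_groups_and_symmetry():
    times = [1.0, 2.0, 3.0, 4.0]
    events = [1, 0, 1, 1]
    ds = _surv(times + times, events + events)
    groups = np.array(["a"] * 4 + ["b"] * 4)
    chi2, p = logrank_test(ds, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    ds2 = _surv(rng.exponential(5, 30), rng.binomial(1, 0.8, 30))
    g = np.array(["a"] * 15 + ["b"] * 15)
    assert logrank_test(ds2, g) == pytest.approx(
        logrank_test(ds2, np.where(g == "a", "b", "a"))
    )


def test_logrank_time_rescaling_invariance():
    rng = np.random.default_rng(2)
    times = rng.exponential(5, 40)
    events = rng.binomial(1, 0.7, 40)
    g = np.array(["a"] * 20 + ["b"] * 20)
    chi2_raw, _ = logrank_test(_surv(times, events), g)
    chi2_sq, _ = logrank_test(_surv(times**2, events), g)  # monotone map
    assert chi2_sq == pytest.approx(chi2_raw, rel=1e-9)


def test_logrank_null_calibration():
    """Type-I error at alpha=0.05 under equal survival distributions."""
    rng = np.random.default_rng(77)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        times = rng.exponential(10, 60)
        cens = rng.exponential(25, 60)
        obs = np.minimum(times, cens)
        events = (times <= cens).astype(int)
        _, p = logrank_test(_surv(obs, events), np.array(["a"] * 30 + ["b"] * 30))
        rejections += p < 0.05
    assert abs(rejections / reps - 0.05) < 0.02


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def test_cox_null_covariate_near_zero():
    rng = np.random.default_rng(9)
    n = 500
    x = rng.normal(size=n)
    times = rng.exponential(10, n)
    cens = rng.exponential(25, n)
    ds = _surv(np.minimum(times, cens), (times <= cens).astype(int), x=x)
    fit = cox_fit(ds, ["x"])
    assert fit.converged
    assert abs(fit.coefficients["x"]) < 0.15
    assert fit.hazard_ratios["x"] == pytest.approx(np.exp(fit.coefficients["x"]))


def test_cox_requires_events_and_independent_covariates():
    rng = np.random.default_rng(10)
    x = rng.normal(size=20)
    with pytest.raises(ValueError, match="events"):
        cox_fit(_surv(rng.exponential(5, 20), np.zeros(20, dtype=int), x=x), ["x"])
    ds = _surv(rng.exponential(5, 20), np.ones(20, dtype=int), x=x, y=2 * x)
    with pytest.raises(ValueError, match="collinear"):
        cox_fit(ds, ["x", "y"])


def test_cox_perfect_separation_flagged():
    """A covariate that perfectly orders the failures diverges and is
    reported as non-converged rather than returned silently."""
    n = 30
    times = np.arange(1, n + 1, dtype=float)
    x = -times  # the next failure always has the largest covariate
    fit = cox_fit(_surv(times, np.ones(n, dtype=int), x=x), ["x"])
    assert not fit.converged
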