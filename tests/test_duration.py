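"""Response construction, regression fitting, trimming, stepwise, VIF, lmg."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import lmg_by_permutations
from ldldur.duration import (
    AliasedDesignError,
    baseline_duration,
    duration_difference,
    fit_mixed,
    fit_standard,
    lmg_importance,
    log_plus_one,
    stepwise_eliminate,
    trim_refit,
    vif,
)


# ---------------------------------------------------------------- response


def test_baseline_duration_sums_segment_means():
    table = {"k": 50.0, "a": 100.0, "t": 70.0}
    assert baseline_duration("kat", table) == 220.0
    assert baseline_duration("a", table) == 100.0
    with pytest.raises(KeyError, match="z"):
        baseline_duration("kz", table)


def _token_frame(rng, n=400):
    baseline = rng.uniform(200, 500, size=n)
    return pd.DataFrame(
        {
            "observed_duration_ms": 0.8 * baseline + 40 + rng.normal(scale=20, size=n),
            "baseline_duration_ms": baseline,
        }
    )


def test_duration_difference_residual_properties(rng):
    tokens = duration_difference(_token_frame(rng))
    resid = tokens["duration_difference"]
    assert abs(resid.mean()) < 1e-9
    assert abs(np.corrcoef(resid, tokens["baseline_duration_ms"])[0, 1]) < 1e-10


def test_duration_difference_affine_and_shift_invariance(rng):
    tokens = _token_frame(rng)
    tokens["observed_duration_ms"] = 0.7 * tokens["baseline_duration_ms"] + 55
    out = duration_difference(tokens)
    np.testing.assert_allclose(out["duration_difference"], 0, atol=1e-9)
    noisy = _token_frame(rng)
    shifted = noisy.copy()
    shifted["observed_duration_ms"] += 123.0
    np.testing.assert_allclose(
        duration_difference(noisy)["duration_difference"],
        duration_difference(shifted)["duration_difference"],
        atol=1e-9,
    )


def test_duration_difference_requires_varying_baseline(rng):
    tokens = _token_frame(rng)
    tokens["baseline_duration_ms"] = 300.0
    with pytest.raises(ValueError, match="constant"):
        duration_difference(tokens)


def test_duration_difference_recovers_nonbaseline_signal(rng):
    """With vanishing noise the residuals track the generating non-baseline
    signal almost perfectly."""
    n = 500
    baseline = rng.uniform(200, 500, size=n)
    signal = rng.normal(size=n) * 15.0
    tokens = pd.DataFrame(
        {
            "observed_duration_ms": 100 + baseline + signal + rng.normal(scale=0.1, size=n),
            "baseline_duration_ms": baseline,
        }
    )
    out = duration_difference(tokens)
    assert np.corrcoef(out["duration_difference"], signal)[0, 1] > 0.9


# ---------------------------------------------------------------- standard fit


def test_fit_standard_exact_and_noise_calibration(rng):
    x = rng.normal(size=200)
    data = pd.DataFrame({"y": 2.0 * x, "x": x, "speech_rate": rng.normal(size=200)})
    fit = fit_standard(data, "y", ["x"], forced=())
    assert fit.coefficients.loc["x", "estimate"] == pytest.approx(2.0, abs=1e-10)
    assert fit.r_squared["adjusted"] == pytest.approx(1.0)


def test_fit_standard_null_predictor_p_uniform():
    """p-values of a pure-noise predictor are uniform (KS check over sims)."""
    rng = np.random.default_rng(8)
    pvals = []
    for _ in range(1000):
        data = pd.DataFrame(
            {"y": rng.normal(size=40), "x": rng.normal(size=40)}
        )
        pvals.append(fit_standard(data, "y", ["x"], forced=()).coefficients.loc["x", "p_value"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_fit_standard_rank_deficiency_lists_aliased(rng):
    x = rng.normal(size=50)
    data = pd.DataFrame({"y": rng.normal(size=50), "x1": x, "x2": x})
    with pytest.raises(AliasedDesignError, match="x2"):
        fit_standard(data, "y", ["x1", "x2"], forced=())


# ---------------------------------------------------------------- mixed fit


def _grouped_data(rng, n_types=100, per_type=5, tau=2.0, sigma=1.0, beta=1.5):
    groups = np.repeat([f"w{i}" for i in range(n_types)], per_type)
    u = dict(zip([f"w{i}" for i in range(n_types)], tau * rng.normal(size=n_types)))
    x = rng.normal(size=n_types * per_type)
    y = beta * x + np.array([u[g] for g in groups]) + sigma * rng.normal(size=len(x))
    return pd.DataFrame({"y": y, "x": x, "word_id": groups})


def test_fit_mixed_degenerate_zero_variance(rng):
    data = _grouped_data(rng, tau=0.0)
    fit = fit_mixed(data, "y", ["x"], forced=())
    assert fit.r_squared["tau2"] < 0.2
    assert fit.r_squared["marginal"] == pytest.approx(
        fit.r_squared["conditional"], abs=0.05
    )


def test_fit_mixed_recovers_variance_components():
    """Random-intercept sd tau=2 is recovered on average over replicates."""
    rng = np.random.default_rng(31)
    taus = []
    for _ in range(50):
        fit = fit_mixed(_grouped_data(rng), "y", ["x"], forced=())
        taus.append(np.sqrt(fit.r_squared["tau2"]))
    assert 1.6 <= np.mean(taus) <= 2.4


def test_fit_mixed_excludes_hapax_types(rng):
    data = _grouped_data(rng, n_types=30, per_type=3)
    hapax = pd.DataFrame(
        {"y": rng.normal(size=5), "x": rng.normal(size=5), "word_id": [f"h{i}" for i in range(5)]}
    )
    fit = fit_mixed(pd.concat([data, hapax], ignore_index=True), "y", ["x"], forced=())
    assert fit.n_hapax_types_excluded == 5
    assert fit.n_hapax_tokens_excluded == 5
    assert fit.n == len(data)


# ---------------------------------------------------------------- trimming


def test_trim_removes_expected_gaussian_fraction():
    rng = np.random.default_rng(5)
    data = pd.DataFrame({"y": rng.normal(size=1000), "x": rng.normal(size=1000)})
    fit = fit_standard(data, "y", ["x"], forced=())
    trimmed = trim_refit(fit)
    assert 0.005 <= trimmed.trim_fraction <= 0.025


def test_trim_removes_gross_outlier_only(rng):
    x = rng.normal(size=300)
    y = 2 * x + rng.normal(scale=1.0, size=300) * 0.5
    data = pd.DataFrame({"y": y, "x": x})
    data.loc[0, "y"] += 50.0  # ~10 SD outlier
    fit = fit_standard(data, "y", ["x"], forced=())
    trimmed = trim_refit(fit)
    assert trimmed.n_trimmed >= 1
    assert 0 not in trimmed.data.index


def test_trim_noop_when_no_tail(rng):
    x = rng.uniform(size=60)
    data = pd.DataFrame({"y": x * 1.5 + np.sin(np.arange(60)) * 0.01, "x": x})
    fit = fit_standard(data, "y", ["x"], forced=())
    trimmed = trim_refit(fit, threshold=10.0)
    assert trimmed.n_trimmed == 0
    assert trimmed.n == fit.n


def test_trim_refuses_to_discard_too_much(rng):
    data = pd.DataFrame({"y": rng.standard_cauchy(size=200), "x": rng.normal(size=200)})
    fit = fit_standard(data, "y", ["x"], forced=())
    with pytest.raises(ValueError, match="%"):
        trim_refit(fit, threshold=0.3)


# ---------------------------------------------------------------- stepwise


def test_stepwise_keeps_significant_model(rng):
    x1, x2 = rng.normal(size=(2, 300))
    data = pd.DataFrame(
        {"y": 3 * x1 - 2 * x2 + rng.normal(size=300), "x1": x1, "x2": x2}
    )
    fit = fit_standard(data, "y", ["x1", "x2"], forced=())
    final = stepwise_eliminate(fit)
    assert final.terms == ["x1", "x2"]
    assert final.dropped_terms == []


def test_stepwise_drops_noise_term_first():
    """A pure-noise term among strong signals is eliminated first in the
    vast majority of simulations."""
    rng = np.random.default_rng(23)
    first_out = 0
    n_sims = 200
    for _ in range(n_sims):
        x1, x2, noise = rng.normal(size=(3, 120))
        data = pd.DataFrame(
            {
                "y": 2 * x1 - 2 * x2 + 0.8 * rng.normal(size=120),
                "x1": x1,
                "x2": x2,
                "noise": noise,
            }
        )
        fit = fit_standard(data, "y", ["x1", "x2", "noise"], forced=())
        final = stepwise_eliminate(fit)
        if final.dropped_terms and final.dropped_terms[0] == "noise":
            first_out += 1
    assert first_out / n_sims >= 0.9


def test_stepwise_survives_aliased_copies(rng):
    x = rng.normal(size=200)
    data = pd.DataFrame(
        {"y": 2 * x + rng.normal(size=200), "x1": x, "x2": x}
    )
    fit = fit_standard(data, "y", ["x1", "x2"], forced=(), on_aliased="drop")
    final = stepwise_eliminate(fit)
    assert final.terms == ["x1"]


def test_stepwise_never_drops_forced_term(rng):
    rate = rng.normal(size=250)
    data = pd.DataFrame({"y": rng.normal(size=250), "speech_rate": rate})
    fit = fit_standard(data, "y", ["speech_rate"])
    final = stepwise_eliminate(fit)
    assert "speech_rate" in final.terms


# ---------------------------------------------------------------- vif / lmg


def test_vif_reference_cases(rng):
    n = 500
    q, _ = np.linalg.qr(
        np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    )
    ortho = pd.DataFrame(q[:, 1:], columns=list("abc"))  # orthonormal, mean 0
    np.testing.assert_allclose(vif(ortho), 1.0, atol=1e-6)
    x1 = rng.normal(size=n)
    near = pd.DataFrame({"x1": x1, "x2": x1 + 1e-6 * rng.normal(size=n)})
    assert (vif(near) > 10).all()
    indep = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
    assert (vif(indep) < 2).all()


def test_lmg_single_and_orthogonal_closed_forms(rng):
    n = 400
    x1, x2 = rng.normal(size=(2, n))
    x1 = x1 - x1.mean()
    x2 = x2 - x2.mean()
    x2 = x2 - x1 * (x1 @ x2) / (x1 @ x1)  # orthogonal to x1 and the intercept
    y = 1.0 * x1 + 0.5 * x2 + rng.normal(size=n)
    data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    single = lmg_importance(data, "y", ["x1"])
    assert single.shares["x1"] == pytest.approx(single.total_r_squared)
    both = lmg_importance(data, "y", ["x1", "x2"])
    for col in ("x1", "x2"):
        marginal_r2 = np.corrcoef(data[col], y)[0, 1] ** 2
        assert both.shares[col] == pytest.approx(marginal_r2, abs=1e-10)


def test_lmg_matches_permutation_oracle_and_conserves_r2(rng):
    n = 200
    x = rng.normal(size=(n, 4))
    x[:, 1] += 0.5 * x[:, 0]
    y = x @ np.array([1.0, -0.5, 0.3, 0.0]) + rng.normal(size=n)
    data = pd.DataFrame(x, columns=list("abcd"))
    data["y"] = y
    result = lmg_importance(data, "y", list("abcd"))
    oracle = lmg_by_permutations(y, x)
    np.testing.assert_allclose(result.shares.to_numpy(), oracle, atol=1e-10)
    assert result.shares.sum() == pytest.approx(result.total_r_squared, abs=1e-8)
    assert (result.shares >= 0).all()


def test_lmg_rejects_too_many_predictors(rng):
    data = pd.DataFrame(rng.normal(size=(30, 12)), columns=[f"x{i}" for i in range(12)])
    data["y"] = rng.normal(size=30)
    with pytest.raises(ValueError, match="10"):
        lmg_importance(data, "y", [f"x{i}" for i in range(11)])


# ---------------------------------------------------------------- transforms


def test_log_plus_one_reference_values():
    assert log_plus_one([0.0])[0] == 0.0
    assert log_plus_one([np.e - 1])[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        log_plus_one([-0.5])


@given(
    st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=30)
)
@settings(max_examples=100, deadline=None)
def test_log_plus_one_preserves_order(values):
    arr = np.asarray(values)
    out = log_plus_one(arr)
    assert (np.argsort(out, kind="stable") == np.argsort(arr, kind="stable")).all()
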