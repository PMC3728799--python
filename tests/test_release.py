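"""Release-model evaluation, analytic rates, and fit recovery."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from gastropk.release import (
    DissolutionProfile,
    FitError,
    ReleaseModel,
    evaluate_cumulative,
    fit_release,
    release_rate,
    select_model,
)

WEIBULL = ReleaseModel(form="weibull", m_inf=100.0, tau=2.0, beta=1.0)


def profile_from(model, times, noise=None, label="x", dose=100.0):
    y = model.cumulative(np.asarray(times, dtype=float))
    if noise is not None:
        y = y * noise
    return DissolutionProfile(times=times, cumulative_released=y, label=label, dose_content_mg=dose)


# ---------------------------------------------------------------------------
# closed-form evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "model",
    [
        WEIBULL,
        ReleaseModel(form="weibull", m_inf=80.0, tau=3.0, beta=1.6),
        ReleaseModel(form="first_order", m_inf=50.0, tau=1.0),
        ReleaseModel(form="zero_order_capped", m_inf=100.0, tau=4.0),
    ],
)
def test_cumulative_zero_at_t0_without_lag(model):
    assert evaluate_cumulative(model, 0.0) == 0.0


def test_weibull_closed_form_at_tau():
    assert evaluate_cumulative(WEIBULL, 2.0) == pytest.approx(100.0 * (1 - math.exp(-1)))


def test_cumulative_reaches_asymptote():
    for model in (WEIBULL, ReleaseModel(form="weibull", m_inf=90.0, tau=1.5, beta=2.2)):
        assert evaluate_cumulative(model, 50 * model.tau) == pytest.approx(
            model.m_inf, rel=1e-6
        )


def test_lag_delays_release():
    model = ReleaseModel(form="weibull", m_inf=100.0, tau=2.0, beta=1.4, t_lag=1.0)
    assert evaluate_cumulative(model, 0.5) == 0.0
    assert evaluate_cumulative(model, 1.0) == 0.0
    assert evaluate_cumulative(model, 1.5) > 0.0


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        evaluate_cumulative(WEIBULL, -0.1)
    with pytest.raises(ValueError):
        release_rate(WEIBULL, -0.1)


# ---------------------------------------------------------------------------
# analytic rate vs cumulative (quadrature oracle)
# ---------------------------------------------------------------------------


def test_zero_order_rate_constant_before_cap():
    model = ReleaseModel(form="zero_order_capped", m_inf=100.0, tau=4.0)
    for t in (0.5, 1.0, 3.9):
        assert release_rate(model, t) == pytest.approx(25.0)
    assert release_rate(model, 4.1) == 0.0


def test_first_order_initial_rate():
    assert release_rate(WEIBULL, 0.0) == pytest.approx(50.0)  # m_inf / tau


@pytest.mark.parametrize(
    "model",
    [
        WEIBULL,
        ReleaseModel(form="weibull", m_inf=100.0, tau=3.0, beta=1.6),
        ReleaseModel(form="weibull", m_inf=60.0, tau=2.0, beta=0.5),
        ReleaseModel(form="weibull", m_inf=75.0, tau=1.0, beta=1.4, t_lag=0.8),
        ReleaseModel(form="zero_order_capped", m_inf=100.0, tau=4.0),
    ],
)
def test_rate_integrates_back_to_cumulative(model):
    """quad of the analytic rate over [0, 50 tau] recovers the cumulative to 1e-6.

    For beta >= 1 the cumulative at 50 tau is M_inf to machine precision, so
    the integral also recovers the asymptote.
    """
    upper = 50 * model.tau + model.t_lag
    total, _ = quad(
        lambda t: release_rate(model, t), 0.0, upper,
        points=[model.t_lag, model.t_lag + model.tau], limit=200,
    )
    assert total == pytest.approx(evaluate_cumulative(model, upper), rel=1e-6)
    if model.beta >= 1.0:
        assert total == pytest.approx(model.m_inf, rel=1e-6)
    # and at an interior point
    mid = model.t_lag + 1.3 * model.tau
    part, _ = quad(
        lambda t: release_rate(model, t), 0.0, mid,
        points=[model.t_lag], limit=200,
    )
    assert part == pytest.approx(evaluate_cumulative(model, mid), rel=1e-6)


def test_rate_nonnegative_and_cumulative_monotone():
    t = np.linspace(0, 30, 400)
    for model in (
        ReleaseModel(form="weibull", m_inf=100.0, tau=3.0, beta=0.7),
        ReleaseModel(form="weibull", m_inf=100.0, tau=3.0, beta=3.5),
        ReleaseModel(form="zero_order_capped", m_inf=100.0, tau=5.0, t_lag=1.0),
    ):
        assert np.all(release_rate(model, t) >= 0)
        cum = evaluate_cumulative(model, t)
        assert np.all(np.diff(cum) >= -1e-12)
        assert np.all(cum <= model.m_inf + 1e-9)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

TIMES_12 = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0])


def test_fit_recovers_noiseless_weibull():
    truth = ReleaseModel(form="weibull", m_inf=100.0, tau=3.0, beta=1.6)
    fit = fit_release(profile_from(truth, TIMES_12), "weibull")
    assert fit.m_inf == pytest.approx(truth.m_inf, rel=1e-4)
    assert fit.tau == pytest.approx(truth.tau, rel=1e-4)
    assert fit.beta == pytest.approx(truth.beta, rel=1e-4)


def test_weibull_fit_of_first_order_data_gives_beta_one():
    truth = ReleaseModel(form="first_order", m_inf=100.0, tau=2.5)
    fit = fit_release(profile_from(truth, TIMES_12), "weibull")
    assert fit.beta == pytest.approx(1.0, abs=1e-3)


def test_all_zero_profile_is_a_fit_error():
    profile = DissolutionProfile(
        times=TIMES_12, cumulative_released=np.zeros_like(TIMES_12), dose_content_mg=100.0
    )
    with pytest.raises(FitError):
        fit_release(profile, "weibull")


def test_non_monotone_profile_beyond_allowance_is_a_fit_error():
    y = np.array([0, 10, 30, 50, 40, 60, 70, 75, 80, 85, 88, 90], dtype=float)
    profile = DissolutionProfile(times=TIMES_12, cumulative_released=y, dose_content_mg=100.0)
    with pytest.raises(FitError):
        fit_release(profile, "weibull")


def test_too_few_points_is_a_fit_error():
    with pytest.raises(FitError):
        fit_release(
            profile_from(WEIBULL, np.array([1.0, 2.0, 3.0])), "weibull"
        )


def test_fit_reports_diagnostics():
    fit = fit_release(profile_from(WEIBULL, TIMES_12), "weibull")
    assert fit.rss is not None and fit.rss >= 0
    assert fit.aicc is not None and math.isfinite(fit.aicc)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def test_select_model_prefers_weibull_on_sigmoid_data():
    truth = ReleaseModel(form="weibull", m_inf=100.0, tau=3.0, beta=2.5)
    chosen = select_model(
        profile_from(truth, TIMES_12), ["weibull", "zero_order_capped"]
    )
    assert chosen.form == "weibull"


def test_select_model_prefers_ramp_on_linear_data():
    """On a noisy linear ramp the 2-parameter ramp wins by AICc parsimony."""
    truth = ReleaseModel(form="zero_order_capped", m_inf=100.0, tau=10.0)
    rng = np.random.default_rng(3)
    noise = rng.lognormal(0, 0.02, len(TIMES_12))
    chosen = select_model(
        profile_from(truth, TIMES_12, noise=noise), ["weibull", "zero_order_capped"]
    )
    assert chosen.form == "zero_order_capped"


def test_select_model_single_candidate_equals_fit_release():
    profile = profile_from(WEIBULL, TIMES_12)
    assert select_model(profile, ["weibull"]) == fit_release(profile, "weibull")


def test_select_model_needs_candidates():
    with pytest.raises(ValueError):
        select_model(profile_from(WEIBULL, TIMES_12), [])


# ---------------------------------------------------------------------------
# noisy parameter recovery benchmark
# ---------------------------------------------------------------------------


def test_parameter_recovery_under_5pct_noise():
    """Median relative error of tau and beta <= 10% over 50 noisy profiles."""
    truth = ReleaseModel(form="weibull", m_inf=100.0, tau=3.0, beta=1.6)
    rng = np.random.default_rng(42)
    tau_err, beta_err = [], []
    for _ in range(50):
        noise = rng.lognormal(0, 0.05, len(TIMES_12))
        y = np.maximum.accumulate(np.clip(truth.cumulative(TIMES_12) * noise, 0, 105))
        profile = DissolutionProfile(
            times=TIMES_12, cumulative_released=y, dose_content_mg=100.0
        )
        fit = fit_release(profile, "weibull")
        tau_err.append(abs(fit.tau - truth.tau) / truth.tau)
        beta_err.append(abs(fit.beta - truth.beta) / truth.beta)
    assert np.median(tau_err) <= 0.10
    assert np.median(beta_err) <= 0.10
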