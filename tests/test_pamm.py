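"""Penalized-spline Poisson hazard model (PAMM) fitting and inference."""

import numpy as np
import pytest

from gesthaz.cox import fit_cox
from gesthaz.pamm import (
    PammFit,
    PammSpec,
    fit_linear_interaction,
    fit_pamm,
    predict_curve,
)
from gesthaz.pamm import test_nonlinear as nonlinearity_pvalue
from gesthaz.ped import expand_cohort, shift_durations
from gesthaz.simulate import CohortConfig, EffectShape, simulate_durations


@pytest.fixture(scope="module")
def constant_ped(constant_effect_cohort):
    return expand_cohort(constant_effect_cohort, variant=0)


@pytest.fixture(scope="module")
def decay_cohort():
    cfg = CohortConfig(
        n=20000, mafs=(0.3,), effects=(EffectShape("linear_decay", 0.6),), seed=31
    )
    return simulate_durations(cfg)


def test_intercept_only_matches_closed_form_poisson_mle(null_cohort):
    """With a constant baseline and no covariates the fit reduces to the
    Poisson MLE with offset: log(total events / total exposure)."""
    ped = expand_cohort(null_cohort)
    fit = fit_pamm(ped, PammSpec(baseline_dim=0, dosage_col=None))
    expected = np.log(ped["event"].sum() / ped["exposure"].sum())
    assert fit.coef[0] == pytest.approx(expected, abs=1e-8)


def test_constant_effect_model_matches_cox(constant_effect_cohort, constant_ped):
    """The simplified (constant beta_g) PAMM and the Breslow Cox fit agree
    closely, and both recover the simulated effect."""
    fit = fit_pamm(constant_ped, PammSpec(time_varying=False))
    cox = fit_cox(
        shift_durations(constant_effect_cohort.durations),
        constant_effect_cohort.spontaneous,
        constant_effect_cohort.dosages[:, 0],
    )
    assert abs(fit.beta_g - cox.coef[0]) <= 0.02
    assert abs(fit.beta_g - 0.3) < 2 * fit.se_g
    assert fit.se_g == pytest.approx(cox.se[0], rel=0.05)


def test_large_penalty_collapses_smooth_to_linear(constant_ped):
    """Sending the effect-smooth penalty to infinity collapses the smooth
    onto the penalty null space: the fitted curve becomes a straight line
    matching the parametric linear-interaction model, with the smooth's
    effective degrees of freedom pinned at one."""
    lam = {"baseline": 10.0, "effect_smooth": 1e9}
    full = fit_pamm(constant_ped, PammSpec(), lambdas=lam)
    assert full.edf["effect_smooth"] <= 1.01
    grid = np.arange(25.0, 115.0, 5.0)
    crv = predict_curve(full, grid)
    # zero second differences -> the curve is linear in time
    d2 = np.diff(crv.estimate, 2)
    assert np.max(np.abs(d2)) < 1e-4
    lin = fit_linear_interaction(constant_ped)
    lin_curve = predict_curve(lin, grid)
    np.testing.assert_allclose(crv.estimate, lin_curve.estimate, atol=0.02)


def test_curve_recovery_linear_decay(decay_cohort):
    """The predicted hazard curve tracks a decaying true effect: higher
    early, lower late, with truth inside the CI at most grid points."""
    ped = expand_cohort(decay_cohort, variant=0)
    fit = fit_pamm(ped, PammSpec())
    grid = np.arange(fit.t_range[0], fit.t_range[1] + 1e-9, 7.0)
    crv = predict_curve(fit, grid)
    truth = EffectShape("linear_decay", 0.6).beta(grid + 169.0)
    cover = (crv.lower <= truth) & (truth <= crv.upper)
    assert cover.mean() >= 0.8
    assert crv.estimate[0] > crv.estimate[-1]


def test_nonlinear_test_detects_decay_and_not_constant(
    constant_ped, decay_cohort
):
    p_const = nonlinearity_pvalue(fit_pamm(constant_ped, PammSpec()))
    ped = expand_cohort(decay_cohort, variant=0)
    p_decay = nonlinearity_pvalue(fit_pamm(ped, PammSpec()))
    assert p_decay < 0.05
    assert p_const > p_decay


def test_nonlinear_statistic_zero_boundary():
    """Zero smooth coefficients with identity covariance give statistic 0
    and the chi-square boundary p-value of 1."""
    k = 5
    fit = PammFit(
        coef=np.zeros(k),
        cov=np.eye(k),
        names=[f"effect_{i}" for i in range(k)],
        blocks={"effect_smooth": np.arange(k)},
        lambdas={},
        edf={"effect_smooth": 3.0},
        loglik=0.0,
        deviance=0.0,
        converged=True,
        iterations=1,
        spec=PammSpec(),
        t_range=(0.0, 1.0),
    )
    assert nonlinearity_pvalue(fit) == 1.0


def test_linear_interaction_sign_and_null(constant_ped, decay_cohort):
    ped = expand_cohort(decay_cohort, variant=0)
    f_dec = fit_linear_interaction(ped)
    i = f_dec.blocks["interaction"][0]
    assert f_dec.coef[i] < 0  # decaying effect: negative time interaction
    assert f_dec.interaction_p() < 0.05
    f_const = fit_linear_interaction(constant_ped)
    assert f_const.interaction_p() > 1e-4


def test_degenerate_dosage_column_rejected(null_cohort):
    ped = expand_cohort(null_cohort)
    ped["g"] = 0.0
    with pytest.raises(ValueError, match="constant"):
        fit_pamm(ped, PammSpec())


def test_flat_curve_for_constant_spec(constant_ped):
    fit = fit_pamm(constant_ped, PammSpec(time_varying=False))
    crv = predict_curve(fit, np.array([30.0, 60.0, 90.0]))
    np.testing.assert_allclose(crv.estimate, fit.beta_g, atol=1e-12)


def test_no_extrapolation(constant_ped):
    fit = fit_pamm(constant_ped, PammSpec(time_varying=False))
    with pytest.raises(ValueError, match="range"):
        predict_curve(fit, np.array([fit.t_range[1] + 50.0]))


def test_ci_width_shrinks_with_sample_size():
    widths = []
    for n in (2000, 12000):
        cfg = CohortConfig(
            n=n, mafs=(0.3,), effects=(EffectShape("constant", 0.2),), seed=13
        )
        ped = expand_cohort(simulate_durations(cfg), variant=0)
        fit = fit_pamm(ped, PammSpec())
        crv = predict_curve(fit, np.arange(30.0, 100.0, 7.0))
        widths.append(np.median(crv.upper - crv.lower))
    assert widths[1] < widths[0]


def test_deviance_below_null_and_covariance_psd(constant_ped):
    fit = fit_pamm(constant_ped, PammSpec())
    null = fit_pamm(constant_ped, PammSpec(baseline_dim=0, dosage_col=None))
    assert fit.deviance < null.deviance
    eig = np.linalg.eigvalsh(fit.cov)
    assert eig.min() > 0
    for name, e in fit.edf.items():
        assert 0 < e <= len(fit.blocks[name]) + 1e-8


def test_aggregation_invariance(null_cohort):
    """Collapsing identical design rows must not change the fit: compare
    the aggregated default against a fit on a row-shuffled table."""
    ped = expand_cohort(null_cohort, variant=0)
    fit1 = fit_pamm(ped, PammSpec(time_varying=False))
    shuffled = ped.sample(frac=1.0, random_state=0).reset_index(drop=True)
    fit2 = fit_pamm(shuffled, PammSpec(time_varying=False))
    assert fit1.beta_g == pytest.approx(fit2.beta_g, abs=1e-10)
    assert fit1.deviance == pytest.approx(fit2.deviance, abs=1e-6)


def test_report_serializable(constant_ped):
    import json

    fit = fit_pamm(constant_ped, PammSpec())
    text = json.dumps(fit.to_report())
    assert "beta_g" in text
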