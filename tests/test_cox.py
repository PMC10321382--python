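"""Cox partial likelihood, Kaplan-Meier and the zph proportionality test."""

import numpy as np
import pytest
from scipy.stats import kstest

from gesthaz.cox import fit_cox, km_estimate, zph_test
from gesthaz.ped import shift_durations
from gesthaz.simulate import CohortConfig, EffectShape, simulate_durations


def _r_fixture():
    """Deterministic small dataset with heavy ties (mirrors the frozen R run)."""
    rng = np.random.default_rng(42)
    n = 80
    x1 = rng.binomial(2, 0.3, n).astype(float)
    x2 = rng.normal(0, 1, n)
    t = np.ceil(rng.exponential(20 * np.exp(-0.5 * x1 - 0.2 * x2)))
    c = rng.random(n) < 0.2
    return t, ~c, np.column_stack([x1, x2])


# Values computed once with R survival: coxph(..., ties="breslow"),
# survfit, and cox.zph(..., transform="km") on the exact same data.
R_COEF = [0.6111256, 0.2301504]
R_SE = [0.2153988, 0.1370480]
R_LOGLIK = -209.5022
R_KM_TAIL = [0.16335393, 0.13068314, 0.08712209, 0.04356105, 0.0]
R_ZPH = {0: (1.0555953, 0.3042219), 1: (0.1543594, 0.6944037)}


class TestCox:
    def test_matches_independent_survival_fit(self):
        t, e, X = _r_fixture()
        fit = fit_cox(t, e, X)
        np.testing.assert_allclose(fit.coef, R_COEF, atol=1e-6)
        np.testing.assert_allclose(fit.se, R_SE, atol=1e-6)
        assert fit.loglik == pytest.approx(R_LOGLIK, abs=1e-3)

    def test_matches_brute_force_grid_on_toy(self):
        """Four subjects, binary covariate: Newton-Raphson lands on the
        grid-search maximizer of the enumerated partial likelihood."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, True, True, True])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def pl(b):
            ll = 0.0
            for i in range(4):
                risk = np.exp(b * (x[i:] - x.mean()))
                ll += b * (x[i] - x.mean()) - np.log(risk.sum())
            return ll

        grid = np.linspace(-3, 3, 20001)
        b_grid = grid[np.argmax([pl(b) for b in grid])]
        fit = fit_cox(t, e, x)
        assert fit.coef[0] == pytest.approx(b_grid, abs=1e-3)

    def test_null_covariate_estimate_near_zero(self, null_cohort):
        fit = fit_cox(
            shift_durations(null_cohort.durations),
            null_cohort.spontaneous,
            null_cohort.dosages[:, 0],
        )
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            fit_cox([1.0, 2.0], [False, False], [[1.0], [0.0]])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox([1.0, 2.0, 3.0], [True, True, True], [[1.0], [1.0], [1.0]])


class TestKM:
    def test_product_limit_no_censoring(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [True] * 4)
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_survival_one(self):
        km = km_estimate([1.0, 2.0], [False, False])
        assert km.times.size == 0
        assert np.all(km.at([0.5, 1.5, 3.0]) == 1.0)

    def test_matches_frozen_survfit_tail(self):
        t, e, _ = _r_fixture()
        km = km_estimate(t, e)
        np.testing.assert_allclose(km.survival[-5:], R_KM_TAIL, atol=1e-8)

    def test_monotone_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200)
        e = rng.random(200) < 0.7
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))


class TestZph:
    def test_matches_survival_cox_zph(self):
        t, e, X = _r_fixture()
        fit = fit_cox(t, e, X)
        for j, (stat, p) in R_ZPH.items():
            got_stat, got_p = zph_test(fit, t, e, X, covariate=j)
            assert got_stat == pytest.approx(stat, abs=1e-5)
            assert got_p == pytest.approx(p, abs=1e-5)

    def test_null_pvalues_uniform(self):
        """Under proportional hazards the zph p-values are uniform."""
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(150):
            n = 250
            x = rng.binomial(2, 0.3, n).astype(float)
            t = np.ceil(rng.exponential(30 * np.exp(-0.3 * x)))
            e = np.ones(n, dtype=bool)
            fit = fit_cox(t, e, x)
            pvals.append(zph_test(fit, t, e, x)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_decaying_effect_detected_more_than_null(self):
        reject_decay = reject_null = 0
        for seed in range(8):
            for eff, counter in (
                (EffectShape("linear_decay", 0.6), "decay"),
                (EffectShape("null"), "null"),
            ):
                cfg = CohortConfig(n=6000, mafs=(0.3,), effects=(eff,), seed=100 + seed)
                coh = simulate_durations(cfg)
                fit = fit_cox(
                    shift_durations(coh.durations),
                    coh.spontaneous,
                    coh.dosages[:, 0],
                )
                p = zph_test(
                    fit,
                    shift_durations(coh.durations),
                    coh.spontaneous,
                    coh.dosages[:, 0],
                )[1]
                if p < 0.05:
                    if counter == "decay":
                        reject_decay += 1
                    else:
                        reject_null += 1
        assert reject_decay > reject_null

    def test_single_event_degenerate(self):
        with pytest.raises(ValueError):
            t = np.array([1.0, 2.0, 3.0])
            e = np.array([True, False, False])
            fit = fit_cox(t, e, np.array([1.0, 0.0, 1.0]))
            zph_test(fit, t, e, np.array([1.0, 0.0, 1.0]))
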