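"""Liability-model power calculus for continuous vs. dichotomized GWAS.

When a normally distributed outcome (here gestational duration) is
dichotomized at a threshold (preterm: < 259 days), the liability model
relates the Wald statistics of the linear and logistic analyses through a
single conversion factor

    t = phi(Phi^-1(K)) / sqrt(K (1 - K)),

where ``K`` is the case prevalence and phi / Phi^-1 are the standard-normal
pdf and quantile function.  The sample size needed for equal power in the
dichotomized analysis is ``1/t**2`` times larger, and standardized effects
convert as ``beta_d/SE_d = t * beta_c/SE_c``.

All functions here are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "conversion_factor",
    "sample_size_ratio",
    "convert_effect",
    "threshold_for_power",
    "min_detectable_continuous",
    "detectable_or_logistic",
    "detectable_beta_linear",
    "PowerReport",
    "power_report",
]


def _check_prob(x: float, name: str) -> None:
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {x!r}")


def conversion_factor(K: float) -> float:
    """Liability conversion factor ``t = phi(Phi^-1(K)) / sqrt(K(1-K))``.

    Parameters
    ----------
    K : float
        Case prevalence, strictly in (0, 1).

    Returns
    -------
    float
        The factor ``t``; symmetric in ``K <-> 1-K`` and maximal
        (``sqrt(2/pi)``) at ``K = 0.5``.
    """
    _check_prob(K, "K")
    return float(norm.pdf(norm.ppf(K)) / math.sqrt(K * (1.0 - K)))


def sample_size_ratio(K: float) -> float:
    """Fold-increase in sample size needed by the dichotomized analysis.

    ``1 / t(K)**2``: how many times larger a cohort the case/control GWAS
    needs to match the power of the continuous GWAS, under the liability
    model.  At ``K = 0.5`` this is the classic median-split efficiency loss
    ``pi/2``.
    """
    t = conversion_factor(K)
    return 1.0 / (t * t)


def convert_effect(beta_c: float, se_c: float, K: float) -> float:
    """Convert a continuous-scale Wald ratio to the dichotomized scale.

    Returns ``beta_d/SE_d = t * beta_c/SE_c``.
    """
    if se_c <= 0:
        raise ValueError(f"se_c must be positive; got {se_c!r}")
    return conversion_factor(K) * (beta_c / se_c)


def threshold_for_power(beta_d_over_se_d: float, f: float) -> float:
    """Significance level at which the dichotomized test reaches power ``f``.

    ``alpha_d = Phi(-Phi^-1(1 - f) - beta_d/SE_d)``.  With a null effect the
    threshold equals the requested power itself.
    """
    _check_prob(f, "f")
    return float(norm.cdf(-norm.ppf(1.0 - f) - beta_d_over_se_d))


def min_detectable_continuous(alpha: float, f: float) -> float:
    """Smallest standardized effect detectable in the continuous analysis.

    ``beta_c/SE_c = Phi^-1(f) - Phi^-1(alpha/2)`` (two-sided test at level
    ``alpha`` with power ``f``); ~6.29 at genome-wide ``alpha = 5e-8`` and
    80% power.
    """
    _check_prob(alpha, "alpha")
    _check_prob(f, "f")
    return float(norm.ppf(f) - norm.ppf(alpha / 2.0))


def _logistic_wald_power(
    or_: float, n: float, K: float, maf: float, alpha: float
) -> float:
    """Power of the additive-logistic Wald test at odds ratio ``or_``.

    Expected-information approximation: genotypes 0/1/2 with HWE
    frequencies at the effect-allele frequency ``maf``; the intercept is
    solved so the marginal case fraction equals ``K``; Var(log OR) comes
    from the inverse expected information.
    """
    p = maf
    freqs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    g = np.array([0.0, 1.0, 2.0])
    b1 = math.log(or_)

    def marginal(b0: float) -> float:
        return float(np.sum(freqs / (1.0 + np.exp(-(b0 + b1 * g)))) - K)

    b0 = brentq(marginal, -30.0, 10.0)
    mu = 1.0 / (1.0 + np.exp(-(b0 + b1 * g)))
    w = freqs * mu * (1.0 - mu)
    info = n * np.array(
        [[w.sum(), (w * g).sum()], [(w * g).sum(), (w * g * g).sum()]]
    )
    se = math.sqrt(np.linalg.inv(info)[1, 1])
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(b1 / se - z) + norm.cdf(-b1 / se - z))


def detectable_or_logistic(
    n: float, K: float, maf: float, alpha: float = 5e-8, f: float = 0.8
) -> float:
    """Minimum odds ratio detectable by the additive logistic Wald test.

    Inverts the expected-information power approximation (HWE genotype
    distribution, additive allele coding, two-sided test) by root-finding
    over OR > 1.

    Raises
    ------
    ValueError
        If no OR below 10 reaches the requested power.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    _check_prob(K, "K")
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must lie in (0, 0.5]; got {maf!r}")
    _check_prob(alpha, "alpha")
    _check_prob(f, "f")
    lo, hi = 1.0 + 1e-9, 10.0
    if _logistic_wald_power(lo, n, K, maf, alpha) >= f:
        return 1.0  # the requested power is below the test's size
    if _logistic_wald_power(hi, n, K, maf, alpha) < f:
        raise ValueError("no odds ratio below 10 achieves the requested power")
    return float(
        brentq(lambda o: _logistic_wald_power(o, n, K, maf, alpha) - f, lo, hi)
    )


def detectable_beta_linear(
    n: float, sd_y: float, maf: float, alpha: float = 5e-8, f: float = 0.8
) -> float:
    """Minimum per-allele effect (in outcome units) detectable by OLS.

    ``|beta| = (Phi^-1(f) - Phi^-1(alpha/2)) * sd_y / sqrt(n * 2 maf (1-maf))``,
    where ``2 maf (1 - maf)`` is the HWE genotype variance.
    """
    if sd_y <= 0:
        raise ValueError("sd_y must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must lie in (0, 0.5]; got {maf!r}")
    z = min_detectable_continuous(alpha, f)
    return float(z * sd_y / math.sqrt(n * 2.0 * maf * (1.0 - maf)))


@dataclass(frozen=True)
class PowerReport:
    """Bundle of the liability-model power quantities for one design."""

    K: float
    n: float
    maf: float
    alpha: float
    f: float
    t: float
    sample_size_ratio: float
    beta_c_over_se_c: float
    beta_d_over_se_d: float
    alpha_dichotomized: float
    detectable_or: float
    detectable_beta_days: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def power_report(
    K: float,
    n: float,
    maf: float,
    alpha: float = 5e-8,
    f: float = 0.8,
    sd_y: float | None = None,
) -> PowerReport:
    """Compute the full power comparison for one GWAS design.

    ``sd_y`` (outcome SD in days) is needed only for the detectable linear
    effect; pass None to skip it.
    """
    t = conversion_factor(K)
    bc = min_detectable_continuous(alpha, f)
    bd = t * bc
    return PowerReport(
        K=K,
        n=n,
        maf=maf,
        alpha=alpha,
        f=f,
        t=t,
        sample_size_ratio=1.0 / (t * t),
        beta_c_over_se_c=bc,
        beta_d_over_se_d=bd,
        alpha_dichotomized=threshold_for_power(bd, f),
        detectable_or=detectable_or_logistic(n, K, maf, alpha, f),
        detectable_beta_days=(
            detectable_beta_linear(n, sd_y, maf, alpha, f) if sd_y else None
        ),
    )
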