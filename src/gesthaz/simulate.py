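"""Synthetic pregnancy cohorts with known time-varying genetic effects.

The generator draws spontaneous-delivery times from the hazard model

    h(t | g, z) = h0(t) * exp( sum_v beta_v(t) g_v + z' gamma ),

with a weekly piecewise-constant baseline ``h0`` calibrated so that the
marginal distribution of durations has ~2.7% spontaneous births before 259
days, ~0.3% before 224 days and a median near 281 days.  Per-allele effects
``beta_v(t)`` come in the shapes seen for real gestational-duration loci:
constant, decaying from early pregnancy, peaking around week 34, or
confined to the term window (weeks 38-41).  Non-spontaneous deliveries
(inductions / planned cesareans) are drawn independently of the latent
spontaneous onset and act as independent right-censoring.

Every operation is reproducible from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm

from .cohort import Cohort

__all__ = [
    "EffectShape",
    "BaselineHazard",
    "StructureConfig",
    "CohortConfig",
    "simulate_genotypes",
    "simulate_durations",
    "bootstrap_phenotype",
    "default_baseline",
]

T_MIN = 169.0  # earliest live-delivery day modeled (24+1 weeks)
T_MAX = 315.0  # 45 weeks; essentially no mass remains beyond this

INDUCTION_MEAN = 277.0  # planned inductions/cesareans cluster before term
INDUCTION_SD = 9.0


@dataclass(frozen=True)
class EffectShape:
    """Per-allele log-hazard-ratio curve beta(t) over gestational days.

    kind:
        ``constant``      beta(t) = magnitude
        ``linear_decay``  magnitude at ``t_start`` declining linearly to 0
                          at ``t_end`` (clipped outside)
        ``peak``          Gaussian bump centered at ``t_peak`` (sd ``width``)
        ``window``        magnitude inside [``t_start``, ``t_end``] with
                          short sigmoid shoulders (scale ``width``) so the
                          curve stays smooth
        ``null``          identically zero
    """

    kind: str = "null"
    magnitude: float = 0.0
    t_peak: float = 238.0  # ~week 34, the preterm-range peak
    t_start: float = T_MIN
    t_end: float = 290.0
    width: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in {"constant", "linear_decay", "peak", "window", "null"}:
            raise ValueError(f"unknown effect shape kind {self.kind!r}")

    def beta(self, t) -> np.ndarray:
        """Evaluate beta(t) at gestational days ``t`` (vectorized)."""
        t = np.asarray(t, dtype=float)
        m = self.magnitude
        if self.kind == "null":
            return np.zeros_like(t)
        if self.kind == "constant":
            return np.full_like(t, m)
        if self.kind == "linear_decay":
            frac = (self.t_end - t) / (self.t_end - self.t_start)
            return m * np.clip(frac, 0.0, 1.0)
        if self.kind == "peak":
            return m * np.exp(-0.5 * ((t - self.t_peak) / self.width) ** 2)
        # window: product of two logistic shoulders, ~2-day transition
        s = min(self.width, 2.0)
        rise = 1.0 / (1.0 + np.exp(-(t - self.t_start) / s))
        fall = 1.0 / (1.0 + np.exp((t - self.t_end) / s))
        return m * rise * fall


@dataclass(frozen=True)
class BaselineHazard:
    """Piecewise-constant baseline hazard on a day grid.

    ``cuts`` are strictly increasing absolute gestational days spanning the
    support; ``hazard[i]`` applies on ``[cuts[i], cuts[i+1])``.
    """

    cuts: np.ndarray
    hazard: np.ndarray

    def __post_init__(self) -> None:
        if len(self.hazard) != len(self.cuts) - 1:
            raise ValueError("need one hazard value per interval")
        if np.any(np.asarray(self.hazard) < 0):
            raise ValueError("hazards must be non-negative")

    def at(self, t) -> np.ndarray:
        """Hazard value at days ``t``."""
        idx = np.clip(
            np.searchsorted(self.cuts, t, side="right") - 1,
            0,
            len(self.hazard) - 1,
        )
        return np.asarray(self.hazard)[idx]

    def cumulative(self, t) -> np.ndarray:
        """Integrated hazard from ``cuts[0]`` to ``t``."""
        t = np.asarray(t, dtype=float)
        widths = np.diff(self.cuts)
        cum = np.concatenate([[0.0], np.cumsum(np.asarray(self.hazard) * widths)])
        idx = np.clip(
            np.searchsorted(self.cuts, t, side="right") - 1,
            0,
            len(self.hazard) - 1,
        )
        return cum[idx] + np.asarray(self.hazard)[idx] * (
            np.clip(t, self.cuts[0], self.cuts[-1]) - self.cuts[idx]
        )

    def survival(self, t) -> np.ndarray:
        return np.exp(-self.cumulative(t))


@lru_cache(maxsize=8)
def _calibrated_mixture(
    p_preterm: float,
    p_very_preterm: float,
    median: float,
    censor_frac: float,
) -> tuple[float, float, float, float, float]:
    """Two-component normal mixture hitting the duration anchors.

    Returns (w, mu_early, sigma_early, mu_main, sigma_main): a small early
    component supplies the heavy left (preterm) tail that a single normal
    cannot produce.  The anchors are enforced on the *observed spontaneous*
    subset — deliveries preempted by a planned induction (see
    :func:`simulate_durations`) drop out of the denominator, and the
    calibration accounts for that selection.  Targets sit at half-day
    boundaries because recorded durations are rounded to whole days.
    """
    mu_early, sigma_main = 235.0, 8.5
    grid = np.arange(T_MIN, T_MAX, 0.25)
    f_c = norm.pdf(grid, INDUCTION_MEAN, INDUCTION_SD)
    F_c = norm.cdf(grid, INDUCTION_MEAN, INDUCTION_SD)

    def resid(params):
        logit_w, log_se, mm = params
        w = 1.0 / (1.0 + np.exp(-logit_w))
        se = np.exp(log_se)
        pdf_t = w * norm.pdf(grid, mu_early, se) + (1 - w) * norm.pdf(
            grid, mm, sigma_main
        )
        surv_t = 1.0 - np.cumsum(pdf_t) * 0.25
        # planned-induction probability giving the target censored share
        p_ct = float(np.sum(f_c * surv_t) * 0.25)  # P(C < T)
        p_plan = min(censor_frac / max(p_ct, 1e-6), 0.95) if censor_frac else 0.0
        dens_obs = pdf_t * (1.0 - p_plan * F_c)  # spontaneous & observed at t
        cum = np.cumsum(dens_obs) * 0.25
        total = cum[-1]
        frac = lambda x: float(np.interp(x, grid, cum)) / total
        med = float(np.interp(0.5 * total, cum, grid))
        return [
            np.log(frac(223.5) / p_very_preterm),
            np.log(frac(258.5) / p_preterm),
            (med - (median - 0.5)) / 2.0,
        ]

    sol = least_squares(resid, x0=[np.log(0.025), np.log(10.0), 281.0])
    w = 1.0 / (1.0 + np.exp(-sol.x[0]))
    return (w, mu_early, float(np.exp(sol.x[1])), float(sol.x[2]), sigma_main)


def default_baseline(
    p_preterm: float = 0.027,
    p_very_preterm: float = 0.003,
    median: float = 281.0,
    censor_frac: float = 0.15,
) -> BaselineHazard:
    """Weekly piecewise-constant baseline calibrated to the duration anchors."""
    w, mu_e, s_e, mu_m, s_m = _calibrated_mixture(
        p_preterm, p_very_preterm, median, censor_frac
    )
    cuts = np.arange(T_MIN, T_MAX + 7.0, 7.0)
    cuts[-1] = max(cuts[-1], T_MAX)

    def cdf(x):
        x = np.asarray(x, dtype=float)
        return w * norm.cdf((x - mu_e) / s_e) + (1 - w) * norm.cdf((x - mu_m) / s_m)

    surv = (1.0 - cdf(cuts)) / (1.0 - cdf(cuts[0]))
    widths = np.diff(cuts)
    with np.errstate(divide="ignore"):
        haz = -np.log(surv[1:] / surv[:-1]) / widths
    haz = np.nan_to_num(haz, nan=0.0, posinf=10.0)
    return BaselineHazard(cuts=cuts, hazard=haz)


def planned_induction_fraction(
    baseline: BaselineHazard, censor_frac: float
) -> float:
    """Planned-induction probability yielding ~``censor_frac`` censored births.

    A planned induction at C only censors when C < T (the spontaneous onset
    has not happened yet), so the planning rate must exceed the target
    censored share by the factor 1/P(C < T).
    """
    if censor_frac <= 0:
        return 0.0
    grid = np.arange(T_MIN, T_MAX, 0.25)
    p_ct = float(
        np.sum(norm.pdf(grid, INDUCTION_MEAN, INDUCTION_SD) * baseline.survival(grid))
        * 0.25
    )
    return min(censor_frac / max(p_ct, 1e-6), 0.95)


@dataclass(frozen=True)
class StructureConfig:
    """Optional planted population structure for PCA testing.

    A latent binary group shifts the allele frequency of ``block`` variants
    by ``delta_maf`` and adds ``early_log_hr`` to the log hazard before
    ``early_until`` days (raising very-preterm risk in one group).
    """

    block: tuple[int, ...]
    delta_maf: float = 0.1
    early_log_hr: float = 0.0
    early_until: float = 224.0


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the reference study conditions."""

    n: int = 20000
    mafs: tuple[float, ...] = (0.3,)
    effects: tuple[EffectShape, ...] = (EffectShape("null"),)
    baseline: BaselineHazard | None = None
    censor_frac: float = 0.15
    dosage_jitter: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    structure: StructureConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.effects) != len(self.mafs):
            raise ValueError("need one EffectShape per variant")
        for m in self.mafs:
            if not (0.0 < m <= 0.5):
                raise ValueError(f"maf must lie in (0, 0.5]; got {m!r}")
        if not (0.0 <= self.censor_frac < 1.0):
            raise ValueError("censor_frac must lie in [0, 1)")


def simulate_genotypes(
    n: int,
    mafs,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.0,
) -> np.ndarray:
    """Draw an (n, m) dosage matrix under Hardy-Weinberg equilibrium.

    Hard calls 0/1/2 with genotype frequencies (q^2, 2pq, p^2) at each
    minor-allele frequency; optional Gaussian ``jitter`` mimics imputation
    uncertainty (clipped back into [0, 2]).
    """
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("all mafs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = (rng.random((n, len(mafs))) < mafs).astype(float) + (
        rng.random((n, len(mafs))) < mafs
    )
    if jitter > 0:
        g = np.clip(g + rng.normal(0.0, jitter, g.shape), 0.0, 2.0)
    return g


# --- covariates -----------------------------------------------------------

_COVARIATE_BUILDERS = {
    "age": lambda p: p["mother_age"].to_numpy() - 30.0,
    "height": lambda p: np.nan_to_num(p["height"].to_numpy() - 167.0),
    "fetal_sex": lambda p: (p["fetal_sex"] == "female").to_numpy(float),
    "malformation": lambda p: p["malformation"].to_numpy(float),
    "parity_0": lambda p: (p["parity"] == "0").to_numpy(float),
    "parity_2": lambda p: (p["parity"] == "2").to_numpy(float),
    "parity_3": lambda p: (p["parity"] == "3+").to_numpy(float),
}


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    height = rng.normal(167.0, 6.0, n)
    height[rng.random(n) < 0.02] = np.nan  # missingness as in registry data
    return pd.DataFrame(
        {
            "mother_age": rng.normal(30.0, 4.5, n),
            "height": height,
            "fetal_sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "malformation": rng.random(n) < 0.02,
            "parity": rng.choice(
                ["0", "1", "2", "3+"], size=n, p=[0.45, 0.35, 0.15, 0.05]
            ),
            "batch": rng.choice(["harvest", "rotterdam", "norment"], size=n),
            "delivery_year": rng.integers(2000, 2009, n),
        }
    )


def _covariate_log_hr(pheno: pd.DataFrame, effects: dict) -> np.ndarray:
    out = np.zeros(len(pheno))
    for key, coef in effects.items():
        if key not in _COVARIATE_BUILDERS:
            raise KeyError(
                f"unknown covariate effect {key!r}; choose from "
                f"{sorted(_COVARIATE_BUILDERS)}"
            )
        out += coef * _COVARIATE_BUILDERS[key](pheno)
    return out


def _variant_table(m: int) -> pd.DataFrame:
    chrom = 1 + np.arange(m) % 22
    pos = 1_000_000 * (1 + np.arange(m) // 22 * 2)  # 2 Mbp apart within chrom
    return pd.DataFrame(
        {
            "id": [f"sim{i + 1}" for i in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos + chrom,  # break exact equality across chromosomes
            "effect_allele": np.tile(["A", "C", "G"], m)[:m],
            "other_allele": np.tile(["G", "T", "C"], m)[:m],
        }
    )


def simulate_durations(config: CohortConfig) -> Cohort:
    """Generate a full cohort under the configured hazard model.

    Event times are drawn by inverting the per-subject cumulative hazard on
    a one-day grid (the hazard is treated as constant within each day, with
    time-varying effects evaluated at day midpoints); recorded durations are
    rounded to whole days.  A ``censor_frac`` share of pregnancies is
    non-spontaneous: their recorded duration is an independent induction
    time, so they enter the hazard analyses as right-censored.
    """
    rng = np.random.default_rng(config.seed)
    base = config.baseline or default_baseline(censor_frac=config.censor_frac)
    n, m = config.n, len(config.mafs)

    mafs = np.asarray(config.mafs, dtype=float)
    if config.structure is not None and config.structure.delta_maf:
        group = rng.random(n) < 0.5
        maf_lo = mafs[None, :].repeat(n, axis=0)
        delta = np.zeros(m)
        delta[list(config.structure.block)] = config.structure.delta_maf
        per_subject_maf = np.clip(maf_lo + np.where(group[:, None], delta, -delta) / 2.0, 0.005, 0.995)
        g = (rng.random((n, m)) < per_subject_maf).astype(float) + (
            rng.random((n, m)) < per_subject_maf
        )
        if config.dosage_jitter > 0:
            g = np.clip(g + rng.normal(0, config.dosage_jitter, g.shape), 0, 2)
    else:
        group = np.zeros(n, dtype=bool)
        g = simulate_genotypes(n, mafs, rng, jitter=config.dosage_jitter)

    pheno = _draw_covariates(n, rng)
    log_hr = _covariate_log_hr(pheno, config.covariate_effects)

    days = np.arange(T_MIN, T_MAX)  # day interval [d, d+1)
    mid = days + 0.5
    h0 = base.at(mid)  # (D,)
    if m:
        beta_mat = np.stack([e.beta(mid) for e in config.effects])  # (m, D)
        eta = g @ beta_mat + log_hr[:, None]  # (n, D)
    else:
        eta = np.broadcast_to(log_hr[:, None], (n, len(mid))).copy()
    if config.structure is not None and config.structure.early_log_hr:
        eta += np.where(
            group[:, None] & (mid[None, :] < config.structure.early_until),
            config.structure.early_log_hr,
            0.0,
        )
    haz = h0[None, :] * np.exp(eta)
    cum = np.cumsum(haz, axis=1)
    total = cum[:, -1]

    e = rng.exponential(1.0, n)
    beyond = e >= total
    if beyond.mean() > 0.10:
        warnings.warn(
            f"{beyond.mean():.1%} of latent delivery times fall beyond "
            f"{T_MAX:.0f} days; the configured baseline looks unrealistic",
            stacklevel=2,
        )
    idx = np.minimum((cum < e[:, None]).sum(axis=1), len(days) - 1)
    prev = np.where(idx > 0, cum[np.arange(n), idx - 1], 0.0)
    frac = np.clip((e - prev) / haz[np.arange(n), idx], 0.0, 1.0)
    t = days[idx] + frac
    t[beyond] = T_MAX

    # planned inductions preempt spontaneous onset: observe min(T, C);
    # C is independent of T, so this is independent right-censoring
    p_plan = planned_induction_fraction(base, config.censor_frac)
    planned = rng.random(n) < p_plan
    c_time = np.where(
        planned,
        np.maximum(rng.normal(INDUCTION_MEAN, INDUCTION_SD, n), 170.0),
        np.inf,
    )
    spontaneous = t <= c_time
    duration = np.clip(np.round(np.where(spontaneous, t, c_time)), 170, T_MAX)

    pheno.insert(0, "duration_days", duration)
    pheno.insert(1, "spontaneous", spontaneous)
    if config.structure is not None:
        pheno["latent_group"] = group
    return Cohort(pheno=pheno, dosages=g, variants=_variant_table(m))


def bootstrap_phenotype(cohort: Cohort, seed: int = 0) -> Cohort:
    """Resample (duration, spontaneous) pairs with replacement.

    The resampled phenotype is independent of genotypes and covariates by
    construction — the null configuration used for type-I-error
    calibration of the time-varying-effect test.
    """
    if cohort.n == 0:
        raise ValueError("cannot bootstrap an empty cohort")
    rng = np.random.default_rng(seed)
    take = rng.integers(0, cohort.n, cohort.n)
    pheno = cohort.pheno.copy()
    pheno["duration_days"] = cohort.pheno["duration_days"].to_numpy()[take]
    pheno["spontaneous"] = cohort.pheno["spontaneous"].to_numpy()[take]
    return Cohort(pheno=pheno, dosages=cohort.dosages, variants=cohort.variants)


def true_effect_table(config: CohortConfig, times=None) -> pd.DataFrame:
    """Tabulate the generating beta_v(t) curves (for recovery checks)."""
    if times is None:
        times = np.arange(T_MIN, T_MAX + 1.0, 7.0)
    rows = []
    names = _variant_table(len(config.mafs))["id"]
    for name, eff in zip(names, config.effects):
        rows.append(
            pd.DataFrame(
                {"id": name, "day": times, "beta_true": eff.beta(times)}
            )
        )
    return pd.concat(rows, ignore_index=True)
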