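"""Piecewise-exponential data (PED) expansion and covariate preparation.

The Poisson approximation to the hazard model needs one row per subject per
risk interval, with the time at risk inside the interval as an exposure
offset and a 0/1 event indicator in the subject's final interval.  Durations
are first shifted to start near 1 (subtracting 169 days) so the long
event-free early period does not influence the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "SHIFT_DAYS",
    "IntervalGrid",
    "shift_durations",
    "expand",
    "expand_cohort",
    "prepare_covariates",
]

logger = logging.getLogger(__name__)

SHIFT_DAYS = 169.0


def shift_durations(durations) -> np.ndarray:
    """Shift durations to start at 1 by subtracting 169 days.

    Raises
    ------
    ValueError
        Naming the first offending record if any duration <= 169 days.
    """
    d = np.asarray(durations, dtype=float)
    bad = np.nonzero(d <= SHIFT_DAYS)[0]
    if bad.size:
        raise ValueError(
            f"duration at record {bad[0]} is {d[bad[0]]:g} days; all durations "
            f"must exceed {SHIFT_DAYS:g} days to be shifted"
        )
    return d - SHIFT_DAYS


@dataclass(frozen=True)
class IntervalGrid:
    """Strictly increasing cut points on the shifted-day scale.

    The default follows 0, 20, then every 7 days, extended to cover the
    observed maximum.  Intervals are right-closed: a duration equal to a
    cut point belongs to the interval ending there.
    """

    cut_points: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cut_points, dtype=float)
        if c[0] != 0:
            raise ValueError("first cut point must be 0")
        if np.any(np.diff(c) <= 0):
            raise ValueError("cut points must be strictly increasing")
        object.__setattr__(self, "cut_points", c)

    @classmethod
    def default(cls, max_shifted: float, first: float = 20.0, step: float = 7.0):
        """0, ``first``, then every ``step`` days up to ``max_shifted``."""
        cuts = [0.0, first]
        while cuts[-1] < max_shifted:
            cuts.append(cuts[-1] + step)
        return cls(np.asarray(cuts))

    @property
    def n_intervals(self) -> int:
        return len(self.cut_points) - 1

    def covering(self, max_shifted: float) -> "IntervalGrid":
        """Extend with the trailing spacing until ``max_shifted`` is covered."""
        c = list(self.cut_points)
        step = c[-1] - c[-2] if len(c) > 2 else 7.0
        while c[-1] < max_shifted:
            c.append(c[-1] + step)
        return IntervalGrid(np.asarray(c))


def expand(
    shifted: np.ndarray,
    event: np.ndarray,
    grid: IntervalGrid,
    subject_ids=None,
) -> pd.DataFrame:
    """Expand survival records into the interval table.

    Returns a DataFrame with one row per subject per interval entered:
    ``subject``, ``interval`` (0-based index), ``t_end`` (interval end
    time, the T at which spline terms are evaluated), ``exposure`` (> 0
    days at risk), ``offset`` (log exposure) and ``event``.
    """
    shifted = np.asarray(shifted, dtype=float)
    event = np.asarray(event, dtype=bool)
    if shifted.min() <= 0:
        raise ValueError("shifted durations must be positive")
    grid = grid.covering(shifted.max())
    cuts = grid.cut_points
    if subject_ids is None:
        subject_ids = np.arange(len(shifted))
    # right-closed intervals: duration == cut belongs to the ending interval
    last = np.searchsorted(cuts, shifted, side="left") - 1
    n_rows = last + 1
    subj = np.repeat(np.arange(len(shifted)), n_rows)
    interval = np.concatenate([np.arange(k) for k in n_rows])
    t_in = cuts[interval]
    t_out = np.minimum(cuts[interval + 1], shifted[subj])
    exposure = t_out - t_in
    ev = (interval == last[subj]) & event[subj]
    out = pd.DataFrame(
        {
            "subject": np.asarray(subject_ids)[subj],
            "interval": interval,
            "t_end": cuts[interval + 1],
            "exposure": exposure,
            "event": ev.astype(int),
        }
    )
    assert (out["exposure"] > 0).all()
    out["offset"] = np.log(out["exposure"].to_numpy())
    return out


def expand_cohort(
    cohort: Cohort,
    grid: IntervalGrid | None = None,
    variant: int | str | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Shift, expand and annotate a cohort's survival records.

    ``variant`` (index or ID) attaches that variant's dosage as column
    ``g``; ``covariates`` (one row per pregnancy, e.g. from
    :func:`prepare_covariates`) are joined by subject.
    """
    shifted = shift_durations(cohort.durations)
    if grid is None:
        grid = IntervalGrid.default(shifted.max())
    ped = expand(shifted, cohort.spontaneous, grid)
    if variant is not None:
        if isinstance(variant, str):
            pos = cohort.variants.index[cohort.variants["id"] == variant]
            if len(pos) == 0:
                raise KeyError(f"variant {variant!r} not in cohort")
            variant = int(pos[0])
        ped["g"] = cohort.dosages[:, variant][ped["subject"].to_numpy()]
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for col in cov.columns:
            ped[col] = cov[col].to_numpy()[ped["subject"].to_numpy()]
    return ped


def prepare_covariates(cohort: Cohort) -> pd.DataFrame:
    """Build the constant-effect covariate design for the hazard models.

    Maternal age enters as two orthonormal degree-2 polynomial columns;
    height has missing or extreme values (outside mean +/- 4 SD) replaced
    by the sample mean; fetal sex (reference male), malformation (reference
    no) and parity (reference 1; categories 0, 2, 3+) are reference-coded
    indicators, as are genotyping batches; delivery year is centered.
    """
    p = cohort.pheno
    out = pd.DataFrame(index=p.index)

    age = p["mother_age"].to_numpy(dtype=float)
    a1 = age - age.mean()
    a2 = age**2
    # Gram-Schmidt against [1, a1], then normalize: orthonormal poly columns
    a2 = a2 - a2.mean() - (a2 @ a1) / (a1 @ a1) * a1
    out["age_1"] = a1 / np.linalg.norm(a1)
    out["age_2"] = a2 / np.linalg.norm(a2)

    h = p["height"].to_numpy(dtype=float)
    bad = np.isnan(h)
    if not bad.all():
        mu, sd = np.nanmean(h), np.nanstd(h)
        if sd > 0:
            bad |= np.abs(h - mu) > 4 * sd
    if bad.all():
        logger.warning("all heights missing; height column is constant after imputation")
        h = np.zeros_like(h)
    else:
        if bad.any():
            logger.info("mean-imputing %d missing/outlier heights", int(bad.sum()))
        good_mean = h[~bad].mean()
        h = np.where(bad, good_mean, h)
    out["height"] = h - h.mean()

    out["fetal_sex_female"] = (p["fetal_sex"] == "female").astype(float)
    out["malformation"] = p["malformation"].astype(float)

    parity = p["parity"].astype(str)
    known = {"0", "1", "2", "3+"}
    unknown = set(parity.unique()) - known
    if unknown:
        raise ValueError(f"unknown parity categories: {sorted(unknown)}")
    for cat, col in [("0", "parity_0"), ("2", "parity_2"), ("3+", "parity_3plus")]:
        out[col] = (parity == cat).astype(float)

    batches = sorted(p["batch"].astype(str).unique())
    for b in batches[1:]:  # first batch is the reference
        out[f"batch_{b}"] = (p["batch"].astype(str) == b).astype(float)

    year = p["delivery_year"].to_numpy(dtype=float)
    out["delivery_year"] = year - year.mean()
    return out
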