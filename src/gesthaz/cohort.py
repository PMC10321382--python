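"""Cohort container shared by every analysis stage.

A cohort is one row per pregnancy: the observed gestational duration in
days, whether onset was spontaneous (non-spontaneous deliveries are
censoring events for the hazard models), maternal/fetal covariates, and a
dosage matrix (expected minor-allele counts in [0, 2]) with per-variant
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PRETERM_DAYS = 259  # < 37 completed weeks
VERY_PRETERM_DAYS = 224  # < 32 completed weeks

PHENO_COLUMNS = [
    "duration_days",
    "spontaneous",
    "mother_age",
    "height",
    "fetal_sex",
    "malformation",
    "parity",
    "batch",
    "delivery_year",
]


@dataclass
class Cohort:
    """Per-pregnancy phenotypes, covariates and genotype dosages.

    Attributes
    ----------
    pheno : DataFrame
        One row per pregnancy with at least ``duration_days`` (positive)
        and ``spontaneous`` (bool); the clinical covariates are optional
        but expected by covariate preparation.
    dosages : ndarray, shape (n, m)
        Expected allele counts in [0, 2]; column j corresponds to
        ``variants`` row j; the counted allele is ``effect_allele``.
    variants : DataFrame
        Columns ``id, chrom, pos, effect_allele, other_allele``.
    """

    pheno: pd.DataFrame
    dosages: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.pheno = self.pheno.reset_index(drop=True)
        self.dosages = np.atleast_2d(np.asarray(self.dosages, dtype=float))
        if self.dosages.size == 0:
            self.dosages = np.empty((len(self.pheno), 0))
        if self.dosages.shape[0] != len(self.pheno):
            raise ValueError(
                f"dosage rows ({self.dosages.shape[0]}) != pregnancies "
                f"({len(self.pheno)})"
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise ValueError("dosages must lie within [0, 2]")
        if (self.pheno["duration_days"] <= 0).any():
            raise ValueError("durations must be positive")

    @property
    def n(self) -> int:
        return len(self.pheno)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def durations(self) -> np.ndarray:
        return self.pheno["duration_days"].to_numpy(dtype=float)

    @property
    def spontaneous(self) -> np.ndarray:
        return self.pheno["spontaneous"].to_numpy(dtype=bool)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant (folded to <= 0.5)."""
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def hard_calls(self) -> np.ndarray:
        """Round dosages to 0/1/2; ties at .5 round half-up."""
        return np.floor(self.dosages + 0.5)

    def spontaneous_subset(self) -> "Cohort":
        """Restrict to spontaneous-onset deliveries (drops censored rows)."""
        keep = self.spontaneous
        return Cohort(
            pheno=self.pheno.loc[keep].reset_index(drop=True),
            dosages=self.dosages[keep],
            variants=self.variants,
        )

    def preterm(self, threshold: float = PRETERM_DAYS) -> np.ndarray:
        """Indicator of spontaneous delivery before ``threshold`` days."""
        return (self.durations < threshold) & self.spontaneous

    def summary(self) -> dict:
        spont = self.spontaneous
        d = self.durations[spont]
        return {
            "n": self.n,
            "n_variants": self.n_variants,
            "frac_spontaneous": float(spont.mean()) if self.n else np.nan,
            "mean_duration_spontaneous": float(d.mean()) if d.size else np.nan,
            "frac_preterm": float((d < PRETERM_DAYS).mean()) if d.size else np.nan,
            "frac_very_preterm": (
                float((d < VERY_PRETERM_DAYS).mean()) if d.size else np.nan
            ),
        }
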