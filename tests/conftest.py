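import numpy as np
import pandas as pd
import pytest

from gesthaz.cohort import Cohort
from gesthaz.simulate import CohortConfig, EffectShape, simulate_durations


@pytest.fixture(scope="session")
def null_cohort():
    """Mid-size cohort with two null variants (fast shared fixture)."""
    cfg = CohortConfig(n=4000, mafs=(0.3, 0.2), effects=(EffectShape("null"),) * 2, seed=7)
    return simulate_durations(cfg)


@pytest.fixture(scope="session")
def constant_effect_cohort():
    """Cohort with one constant log-HR 0.3 variant at MAF 0.3."""
    cfg = CohortConfig(
        n=20000, mafs=(0.3,), effects=(EffectShape("constant", 0.3),), seed=11
    )
    return simulate_durations(cfg)


def make_cohort(durations, spontaneous, dosages=None, variants=None, rng=None):
    """Assemble a Cohort with placeholder covariates for unit tests."""
    n = len(durations)
    rng = rng or np.random.default_rng(0)
    pheno = pd.DataFrame(
        {
            "duration_days": np.asarray(durations, dtype=float),
            "spontaneous": np.asarray(spontaneous, dtype=bool),
            "mother_age": rng.normal(30, 4.5, n),
            "height": rng.normal(167, 6, n),
            "fetal_sex": rng.choice(["male", "female"], n),
            "malformation": np.zeros(n, dtype=bool),
            "parity": rng.choice(["0", "1", "2", "3+"], n),
            "batch": ["b1"] * n,
            "delivery_year": np.full(n, 2004),
        }
    )
    if dosages is None:
        dosages = np.empty((n, 0))
        variants = pd.DataFrame(
            columns=["id", "chrom", "pos", "effect_allele", "other_allele"]
        )
    elif variants is None:
        m = np.atleast_2d(dosages).shape[1]
        variants = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(m)],
                "chrom": ["1"] * m,
                "pos": 1_000_000 * (np.arange(m) + 1),
                "effect_allele": ["A"] * m,
                "other_allele": ["G"] * m,
            }
        )
    return Cohort(pheno=pheno, dosages=dosages, variants=variants)
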