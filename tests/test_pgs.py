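"""Polygenic score construction and PGS-stratified analyses."""

import numpy as np
import pandas as pd
import pytest

from gesthaz.pgs import (
    compute_pgs,
    ld_prune,
    pca_and_association,
    quantile_group_pamm,
    rare_deleterious_counts,
    unadjusted_risks,
    variance_explained,
    wilson_ci,
)
from gesthaz.simulate import CohortConfig, EffectShape, StructureConfig, simulate_durations
from tests.conftest import make_cohort


def _weights(ids, eas, oas, w):
    return pd.DataFrame(
        {"id": ids, "effect_allele": eas, "other_allele": oas, "weight": w}
    )


class TestComputePgs:
    def test_hand_computed_score(self):
        coh = make_cohort(
            [280.0], [True], dosages=np.array([[2.0, 1.0]]),
            variants=pd.DataFrame(
                {
                    "id": ["v0", "v1"],
                    "chrom": ["1", "1"],
                    "pos": [1, 2],
                    "effect_allele": ["A", "C"],
                    "other_allele": ["G", "T"],
                }
            ),
        )
        w = _weights(["v0", "v1"], ["A", "C"], ["G", "T"], [0.5, -0.2])
        assert compute_pgs(coh, w)[0] == pytest.approx(0.8)

    def test_zero_weights_zero_scores(self, null_cohort):
        w = _weights(["sim1", "sim2"], ["A", "C"], ["G", "T"], [0.0, 0.0])
        assert np.all(compute_pgs(null_cohort, w) == 0)

    def test_invariant_to_ordering_and_strand_flip(self, null_cohort):
        # simulated variants: sim1 A/G, sim2 C/T (both strand-unambiguous)
        w1 = _weights(["sim1", "sim2"], ["A", "C"], ["G", "T"], [0.4, -0.3])
        w2 = w1.iloc[::-1].reset_index(drop=True)  # reorder
        w3 = _weights(["sim1", "sim2"], ["T", "G"], ["C", "A"], [0.4, -0.3])  # complement
        s1, s2, s3 = (compute_pgs(null_cohort, w) for w in (w1, w2, w3))
        np.testing.assert_allclose(s1, s2)
        np.testing.assert_allclose(s1, s3)

    def test_swapped_alleles_counted_complementarily(self):
        coh = make_cohort(
            [280.0, 280.0], [True, True],
            dosages=np.array([[2.0], [0.0]]),
        )
        direct = _weights(["v0"], ["A"], ["G"], [1.0])
        swapped = _weights(["v0"], ["G"], ["A"], [1.0])
        np.testing.assert_allclose(
            compute_pgs(coh, direct) + compute_pgs(coh, swapped), [2.0, 2.0]
        )

    def test_palindromic_only_weight_file_rejected(self):
        coh = make_cohort([280.0], [True], dosages=np.array([[1.0]]))
        coh.variants.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        w = _weights(["v0"], ["A"], ["T"], [1.0])
        with pytest.raises(ValueError, match="matched"):
            compute_pgs(coh, w)


class TestVarianceExplained:
    def test_score_equal_to_phenotype(self, null_cohort):
        pgs = null_cohort.durations.copy()
        assert variance_explained(pgs, null_cohort) == pytest.approx(1.0)

    def test_independent_score(self, null_cohort):
        rng = np.random.default_rng(0)
        pgs = rng.normal(size=null_cohort.n)
        assert variance_explained(pgs, null_cohort) < 0.005

    def test_constructed_variance_fraction_recovered(self):
        """Durations built as mean + score + noise with a known variance
        split: the reported R^2 matches the construction."""
        rng = np.random.default_rng(4)
        n = 20000
        s = rng.normal(0, 2.0, n)  # var 4
        y = 280 + s + rng.normal(0, 6.0, n)  # var 36; R2 = 4/40 = 0.1
        coh = make_cohort(y, [True] * n)
        assert variance_explained(s, coh) == pytest.approx(0.1, abs=0.01)

    def test_zero_variance_score_rejected(self, null_cohort):
        with pytest.raises(ValueError):
            variance_explained(np.zeros(null_cohort.n), null_cohort)


class TestRisks:
    def test_wilson_ci_matches_prop_test(self):
        # frozen from R prop.test(5, 100) and prop.test(17, 3900)
        np.testing.assert_allclose(
            wilson_ci(5, 100), (0.0185525637, 0.1182994639), atol=1e-9
        )
        np.testing.assert_allclose(
            wilson_ci(17, 3900), (0.0026249248, 0.0071273100), atol=1e-9
        )

    def test_boundary_cases(self):
        lo0, hi0 = wilson_ci(0, 50)
        assert lo0 == 0.0 and hi0 > 0
        lo1, hi1 = wilson_ci(50, 50)
        assert hi1 == 1.0 and lo1 < 1

    def test_quintile_risk_table(self, null_cohort):
        rng = np.random.default_rng(2)
        pgs = rng.normal(size=null_cohort.n)
        tab = unadjusted_risks(pgs, null_cohort)
        assert set(tab["group"]) == {1, 2, 3, 4, 5}
        assert ((tab["ci_low"] <= tab["risk"]) & (tab["risk"] <= tab["ci_high"])).all()
        assert (tab["events"] <= tab["n"]).all()

    def test_protective_score_gives_decreasing_preterm_risk(self):
        """When the score tracks a protective (hazard-lowering) allele
        burden, preterm risk falls across quintiles."""
        cfg = CohortConfig(
            n=30000,
            mafs=(0.3,) * 6,
            effects=(EffectShape("constant", -0.25),) * 6,
            seed=23,
        )
        coh = simulate_durations(cfg)
        pgs = coh.dosages.sum(axis=1)  # high score = many protective alleles
        tab = unadjusted_risks(pgs, coh, cutoffs=(259,))
        risks = tab.sort_values("group")["risk"].to_numpy()
        assert risks[0] > risks[-1]
        # allow one local tie/inversion from binomial noise, demand trend
        assert np.polyfit(np.arange(5), risks, 1)[0] < 0


class TestQuantilePamm:
    def test_even_group_count_rejected(self, null_cohort):
        pgs = np.random.default_rng(0).normal(size=null_cohort.n)
        with pytest.raises(ValueError, match="odd"):
            quantile_group_pamm(pgs, null_cohort, n_groups=4)

    def test_null_score_curves_near_zero(self, null_cohort):
        rng = np.random.default_rng(5)
        pgs = rng.normal(size=null_cohort.n)
        res = quantile_group_pamm(
            pgs, null_cohort, n_groups=5,
            covariates=pd.DataFrame(index=range(null_cohort.n)),
        )
        for crv in res.curves.values():
            inside = (crv.lower <= 0) & (0 <= crv.upper)
            assert inside.mean() > 0.8

    def test_protective_effect_orders_group_curves(self):
        cfg = CohortConfig(
            n=25000,
            mafs=(0.3,) * 4,
            effects=(EffectShape("constant", -0.3),) * 4,
            seed=29,
        )
        coh = simulate_durations(cfg)
        pgs = coh.dosages.sum(axis=1) + np.random.default_rng(1).normal(
            0, 0.1, coh.n
        )
        res = quantile_group_pamm(
            pgs, coh, n_groups=5, covariates=pd.DataFrame(index=range(coh.n))
        )
        means = {k: float(np.mean(c.estimate)) for k, c in res.curves.items()}
        # bottom quintile (few protective alleles): higher hazard than top
        assert means["q1"] > 0 > means["q5"]
        assert means["q1"] > means["q2"] > means["q5"]


class TestRareAlleles:
    def _toy_cohort(self):
        rng = np.random.default_rng(7)
        n = 4000
        g_common = rng.binomial(2, 0.4, n).astype(float)
        g_rare = rng.binomial(2, 0.05, n).astype(float)
        dur = rng.normal(281, 9, n) + 1.0 * g_common - 3.0 * g_rare
        coh = make_cohort(dur, [True] * n, dosages=np.column_stack([g_common, g_rare]))
        w = _weights(["v0", "v1"], ["A", "A"], ["G", "G"], [1.0, -3.0])
        return coh, w

    def test_no_qualifying_variant_zero_counts(self, null_cohort):
        w = _weights(["sim1"], ["A"], ["G"], [0.5])  # positive weight
        rep = rare_deleterious_counts(null_cohort, w)
        assert np.all(rep.allele_counts == 0)
        assert rep.n_allele_variants == 0

    def test_single_qualifying_variant_counts_equal_hardcalls(self):
        coh, w = self._toy_cohort()
        rep = rare_deleterious_counts(coh, w)
        assert rep.n_allele_variants == 1
        np.testing.assert_allclose(rep.allele_counts, coh.hard_calls()[:, 1])
        np.testing.assert_allclose(
            rep.homozygote_counts, (coh.hard_calls()[:, 1] == 2).astype(float)
        )

    def test_count_anticorrelated_with_protective_score(self):
        coh, w = self._toy_cohort()
        rep = rare_deleterious_counts(coh, w)
        assert rep.corr_alleles_pgs < 0


class TestPca:
    def test_duplicate_variant_pruned(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, 500).astype(float)
        other = rng.binomial(2, 0.3, (500, 3)).astype(float)
        kept = ld_prune(np.column_stack([g, g, other]))
        assert 1 not in kept and 0 in kept

    def test_scores_orthogonal_and_variance_ordered(self):
        rng = np.random.default_rng(13)
        n, m = 800, 40
        g = rng.binomial(2, 0.3, (n, m)).astype(float)
        coh = make_cohort(rng.normal(280, 10, n), [True] * n, dosages=g)
        res = pca_and_association(coh, pgs=np.zeros(n), n_pcs=5)
        S = res.scores
        off = S.T @ S - np.diag(np.diag(S.T @ S))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(S.T @ S))
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_planted_structure_found_by_pc_association(self):
        """A latent group shifting a variant block's frequencies and raising
        very-early delivery risk: the leading PC separates the groups,
        associates with very-preterm delivery more strongly than with all
        preterm delivery, and loads on the block."""
        block = tuple(range(10))
        cfg = CohortConfig(
            n=12000,
            mafs=(0.3,) * 30,
            effects=(EffectShape("null"),) * 30,
            structure=StructureConfig(
                block=block, delta_maf=0.35, early_log_hr=2.0
            ),
            seed=37,
        )
        coh = simulate_durations(cfg)
        pgs = np.zeros(coh.n)
        res = pca_and_association(coh, pgs, n_pcs=5)
        group = coh.pheno["latent_group"].to_numpy()
        # the PC most correlated with the latent group
        cors = [abs(np.corrcoef(res.scores[:, j], group)[0, 1]) for j in range(5)]
        j = int(np.argmax(cors))
        assert cors[j] > 0.5
        a = res.assoc.set_index(["pc", "outcome"])
        assert a.loc[(j + 1, "vptd"), "p"] < 0.01
        assert a.loc[(j + 1, "vptd"), "p"] < a.loc[(j + 1, "ptd"), "p"]
        # loadings concentrate on the block
        load = res.loadings[f"loading_{j + 1}"].to_numpy() ** 2
        ids = res.loadings["id"].str.replace("sim", "").astype(int) - 1
        in_block = np.isin(ids, block)
        assert load[in_block].sum() > 2 * in_block.mean()

    def test_region_flagging(self):
        rng = np.random.default_rng(17)
        g = rng.binomial(2, 0.3, (300, 8)).astype(float)
        coh = make_cohort(rng.normal(280, 10, 300), [True] * 300, dosages=g)
        res = pca_and_association(
            coh, np.zeros(300), n_pcs=2, region=("1", 0, 3_500_000)
        )
        assert "in_region" in res.loadings.columns
        assert res.loadings["in_region"].any()
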