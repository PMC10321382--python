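"""Interval expansion (PED) and covariate preparation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gesthaz.ped import (
    IntervalGrid,
    expand,
    expand_cohort,
    prepare_covariates,
    shift_durations,
)
from tests.conftest import make_cohort


class TestShift:
    def test_arithmetic(self):
        np.testing.assert_array_equal(shift_durations([280.0]), [111.0])

    def test_preterm_boundary(self):
        assert shift_durations([259.0])[0] == 90.0

    def test_boundary_error_names_record(self):
        with pytest.raises(ValueError, match="record 1"):
            shift_durations([280.0, 169.0])


class TestGrid:
    def test_default_spacing(self):
        g = IntervalGrid.default(40.0)
        np.testing.assert_array_equal(g.cut_points, [0, 20, 27, 34, 41])

    def test_first_cut_must_be_zero(self):
        with pytest.raises(ValueError):
            IntervalGrid(np.array([1.0, 5.0]))

    def test_covering_extends(self):
        g = IntervalGrid.default(40.0).covering(60.0)
        assert g.cut_points[-1] >= 60.0
        assert np.all(np.diff(g.cut_points) > 0)


class TestExpand:
    def test_event_row_layout(self):
        grid = IntervalGrid(np.array([0.0, 20.0, 27.0, 34.0]))
        ped = expand(np.array([30.0]), np.array([True]), grid)
        np.testing.assert_array_equal(ped["exposure"], [20.0, 7.0, 3.0])
        np.testing.assert_array_equal(ped["event"], [0, 0, 1])
        np.testing.assert_array_equal(ped["t_end"], [20.0, 27.0, 34.0])

    def test_censored_rows_have_no_event(self):
        grid = IntervalGrid(np.array([0.0, 20.0, 27.0, 34.0]))
        ped = expand(np.array([30.0]), np.array([False]), grid)
        assert ped["event"].sum() == 0

    def test_short_duration_single_row(self):
        grid = IntervalGrid(np.array([0.0, 20.0, 27.0]))
        ped = expand(np.array([15.0]), np.array([True]), grid)
        assert len(ped) == 1
        assert ped["exposure"].iloc[0] == 15.0
        assert ped["event"].iloc[0] == 1

    def test_duration_at_cut_point_closes_interval(self):
        grid = IntervalGrid(np.array([0.0, 20.0, 27.0]))
        ped = expand(np.array([20.0]), np.array([True]), grid)
        assert len(ped) == 1
        assert ped["t_end"].iloc[0] == 20.0

    @settings(deadline=None, max_examples=25)
    @given(
        durs=st.lists(
            st.floats(min_value=0.5, max_value=150.0), min_size=1, max_size=60
        ),
        events=st.data(),
    )
    def test_conservation_properties(self, durs, events):
        """Total exposure equals total follow-up, event rows equal
        uncensored subjects, and per-subject exposure rebuilds durations."""
        ev = np.array(
            events.draw(
                st.lists(st.booleans(), min_size=len(durs), max_size=len(durs))
            )
        )
        durs = np.array(durs)
        ped = expand(durs, ev, IntervalGrid.default(20.0))
        assert ped["exposure"].sum() == pytest.approx(durs.sum(), rel=1e-12)
        assert ped["event"].sum() == ev.sum()
        per_subject = ped.groupby("subject")["exposure"].sum()
        np.testing.assert_allclose(per_subject.to_numpy(), durs, rtol=1e-12)
        assert (ped["exposure"] > 0).all()

    def test_expand_cohort_attaches_dosage(self, null_cohort):
        ped = expand_cohort(null_cohort, variant=0)
        assert "g" in ped.columns
        sub = ped[ped["subject"] == 0]
        assert (sub["g"] == null_cohort.dosages[0, 0]).all()

    def test_expand_cohort_unknown_variant(self, null_cohort):
        with pytest.raises(KeyError):
            expand_cohort(null_cohort, variant="nope")


class TestCovariates:
    def test_age_polynomials_orthonormal(self, null_cohort):
        cov = prepare_covariates(null_cohort)
        a1 = cov["age_1"].to_numpy()
        a2 = cov["age_2"].to_numpy()
        assert abs(a1.sum()) < 1e-8
        assert abs(a2.sum()) < 1e-8
        assert abs(a1 @ a2) < 1e-8
        assert a1 @ a1 == pytest.approx(1.0)

    def test_parity_reference_level_one(self):
        coh = make_cohort([280.0] * 4, [True] * 4)
        coh.pheno["parity"] = ["1", "0", "2", "3+"]
        cov = prepare_covariates(coh)
        row = cov.loc[0, ["parity_0", "parity_2", "parity_3plus"]]
        assert (row == 0).all()
        assert cov.loc[1, "parity_0"] == 1

    def test_unknown_parity_rejected(self):
        coh = make_cohort([280.0] * 2, [True] * 2)
        coh.pheno["parity"] = ["1", "5"]
        with pytest.raises(ValueError, match="parity"):
            prepare_covariates(coh)

    def test_height_outliers_and_missing_imputed(self):
        coh = make_cohort([280.0] * 100, [True] * 100)
        h = coh.pheno["height"].to_numpy().copy()
        h[0] = np.nan
        h[1] = 400.0  # beyond mean + 4 SD
        coh.pheno["height"] = h
        cov = prepare_covariates(coh)
        assert np.isfinite(cov["height"]).all()
        # both records imputed to the clean mean -> equal centered values
        assert cov.loc[0, "height"] == pytest.approx(cov.loc[1, "height"])

    def test_all_heights_missing_gives_constant_column(self):
        coh = make_cohort([280.0] * 5, [True] * 5)
        coh.pheno["height"] = np.nan
        cov = prepare_covariates(coh)
        assert (cov["height"] == 0).all()
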