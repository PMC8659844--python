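"""Improvement estimation, colour coding, smoothing, and range brushing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coachcohort import (
    BASELINE,
    FINAL,
    AssessmentRecord,
    DataError,
    RangeFilter,
    categorize,
    filter_by_ranges,
    fit_standardization,
    group_trajectories,
    improvement,
    improvement_profiles,
    smooth,
)
from coachcohort.errors import ConfigError
from coachcohort.evolution import IMPROVED, SAME, WORSENED
from coachcohort.scoring import ActivityMatrix
from coachcohort.specs import AssessmentVariableSpec


def one_var_model(var, values):
    return fit_standardization({var: values})


class TestImprovement:
    specs = {
        "foot_up_and_go": AssessmentVariableSpec("foot_up_and_go", "physical", -1, 2),
        "chair_stand": AssessmentVariableSpec("chair_stand", "physical", +1, 1),
    }

    def test_no_change_is_zero(self):
        model = one_var_model("chair_stand", [10.0, 12.0, 14.0, 16.0])
        b = AssessmentRecord("p1", BASELINE, {"chair_stand": 12.0})
        f = AssessmentRecord("p1", FINAL, {"chair_stand": 12.0})
        assert improvement(b, f, model, self.specs, "physical") == 0.0

    def test_lower_is_better_flips_sign(self):
        # Foot Up and Go is timed: a drop of 0.4 fitted-sd is an improvement.
        model = one_var_model("foot_up_and_go", [5.0, 6.0, 7.0, 8.0])
        sd = model.variables["foot_up_and_go"].std
        b = AssessmentRecord("p1", BASELINE, {"foot_up_and_go": 6.5})
        f = AssessmentRecord("p1", FINAL, {"foot_up_and_go": 6.5 - 0.4 * sd})
        assert improvement(b, f, model, self.specs, "physical") == pytest.approx(0.4)

    def test_mean_over_available_variables_only(self):
        model = fit_standardization(
            {"chair_stand": [8.0, 10, 12, 14], "foot_up_and_go": [5.0, 6, 7, 8]}
        )
        sd = model.variables["chair_stand"].std
        b = AssessmentRecord("p1", BASELINE, {"chair_stand": 10.0})
        f = AssessmentRecord("p1", FINAL, {"chair_stand": 10.0 + sd})
        # foot_up_and_go missing from both records -> excluded from the mean
        assert improvement(b, f, model, self.specs, "physical") == pytest.approx(1.0)

    def test_no_usable_variables_rejected(self):
        model = one_var_model("chair_stand", [8.0, 10, 12, 14])
        b = AssessmentRecord("p1", BASELINE, {})
        f = AssessmentRecord("p1", FINAL, {})
        with pytest.raises(DataError):
            improvement(b, f, model, self.specs, "physical")


class TestCategorize:
    def test_within_band_is_same(self):
        assert categorize(0.0, 0.1, 1.0) == (SAME, 0.0)

    def test_cohort_max_gets_full_shade(self):
        cat, shade = categorize(0.4, 0.1, 0.4)
        assert cat == IMPROVED and shade == 1.0

    def test_worsened_shade_fraction(self):
        assert categorize(-0.2, 0.1, 0.4) == (WORSENED, 0.5)

    @settings(max_examples=50, deadline=None)
    @given(
        change=st.floats(-5, 5),
        eps=st.floats(0, 0.5),
        max_abs=st.floats(0.1, 10),
    )
    def test_odd_symmetry_about_the_band(self, change, eps, max_abs):
        cat1, shade1 = categorize(change, eps, max_abs)
        cat2, shade2 = categorize(-change, eps, max_abs)
        assert shade1 == shade2
        swap = {IMPROVED: WORSENED, WORSENED: IMPROVED, SAME: SAME}
        assert cat2 == swap[cat1]


class TestSmooth:
    def test_centered_mean_with_boundary_shrink(self):
        out = smooth([1, 2, 3, 4, 5], 3, "mean")
        np.testing.assert_allclose(out, [1.5, 2, 3, 4, 4.5])

    def test_window_one_is_identity(self):
        s = [3.0, 1.0, 4.0]
        for method in ("mean", "max", "min"):
            np.testing.assert_allclose(smooth(s, 1, method), s)

    def test_moving_max(self):
        np.testing.assert_allclose(smooth([1, 2, 3], 3, "max"), [2, 3, 3])

    @pytest.mark.parametrize("n", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, n):
        with pytest.raises(ConfigError):
            smooth([1, 2, 3], n)

    def test_missing_days_excluded_from_window(self):
        out = smooth([1.0, np.nan, 3.0], 3, "mean")
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_all_missing_window_stays_missing(self):
        out = smooth([np.nan, np.nan, np.nan, 1.0], 3, "mean")
        assert np.isnan(out[0])
        assert out[3] == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        series=st.lists(
            st.one_of(st.floats(-50, 50), st.just(float("nan"))),
            min_size=1, max_size=25,
        ),
        half=st.integers(0, 5),
        method=st.sampled_from(["mean", "max", "min"]),
    )
    def test_matches_bruteforce_window_oracle(self, series, half, method):
        n = 2 * half + 1
        out = smooth(series, n, method)
        agg = {"mean": np.mean, "max": np.max, "min": np.min}[method]
        for i in range(len(series)):
            window = [
                x
                for x in series[max(0, i - half) : i + half + 1]
                if not np.isnan(x)
            ]
            if not window:
                assert np.isnan(out[i])
            else:
                assert out[i] == pytest.approx(agg(window))

    @settings(max_examples=40, deadline=None)
    @given(
        series=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        half=st.integers(0, 4),
    )
    def test_max_dominates_mean_dominates_min(self, series, half):
        n = 2 * half + 1
        hi = smooth(series, n, "max")
        mid = smooth(series, n, "mean")
        lo = smooth(series, n, "min")
        assert (hi >= mid - 1e-9).all() and (mid >= lo - 1e-9).all()

    def test_mean_commutes_with_affine_maps(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=30)
        a, b = 2.5, -3.0
        np.testing.assert_allclose(
            smooth(a * s + b, 5, "mean"), a * smooth(s, 5, "mean") + b
        )


class TestRangeFilter:
    profiles = pd.DataFrame(
        {
            "participant_id": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "dimension": ["physical", "cognitive"] * 3,
            "change": [0.5, 0.2, -0.3, 0.4, 0.1, -0.1],
        }
    )

    def test_empty_filter_keeps_everyone(self):
        assert filter_by_ranges(self.profiles, RangeFilter()) == ["p1", "p2", "p3"]

    def test_nonnegative_everywhere_means_no_worsening(self):
        f = RangeFilter({"physical": (0.0, None), "cognitive": (0.0, None)})
        assert filter_by_ranges(self.profiles, f) == ["p1"]

    def test_disjoint_interval_empty_result(self):
        f = RangeFilter({"physical": (100.0, 200.0)})
        assert filter_by_ranges(self.profiles, f) == []

    def test_ill_ordered_interval_rejected(self):
        with pytest.raises(ConfigError):
            RangeFilter({"physical": (1.0, 0.0)})

    def test_matches_bruteforce_scan_on_random_filters(self):
        rng = np.random.default_rng(12)
        pids = [f"p{i}" for i in range(12)]
        rows = [
            (pid, dim, float(rng.normal()))
            for pid in pids
            for dim in ("physical", "cognitive", "nutritional")
        ]
        profiles = pd.DataFrame(rows, columns=["participant_id", "dimension", "change"])
        for _ in range(20):
            intervals = {}
            for dim in ("physical", "cognitive", "nutritional"):
                if rng.random() < 0.6:
                    lo, hi = sorted(rng.normal(0, 1, 2))
                    intervals[dim] = (float(lo), float(hi))
            got = filter_by_ranges(profiles, RangeFilter(intervals))
            expected = []
            for pid in pids:
                ok = True
                for dim, (lo, hi) in intervals.items():
                    x = profiles[
                        (profiles.participant_id == pid) & (profiles.dimension == dim)
                    ]["change"].iloc[0]
                    ok = ok and lo <= x <= hi
                if ok:
                    expected.append(pid)
            assert sorted(got) == sorted(expected)


class TestTrajectories:
    def test_singleton_group_yields_one_series(self, tiny_cohort):
        from coachcohort import fit_baseline_standardization

        matrix = ActivityMatrix.from_dataset(tiny_cohort)
        model = fit_baseline_standardization(tiny_cohort.assessments)
        profiles = improvement_profiles(tiny_cohort, model)

        class OneGroup:
            def members(self, cid):
                return ["a"]

        view = group_trajectories(
            0, OneGroup(), matrix, "physical", "physical", profiles, 3, "mean"
        )
        assert list(view.series.columns) == ["a"]
        assert len(view.series) == tiny_cohort.n_days

    def test_all_token_covers_cohort(self, tiny_cohort):
        from coachcohort import fit_baseline_standardization

        matrix = ActivityMatrix.from_dataset(tiny_cohort)
        model = fit_baseline_standardization(tiny_cohort.assessments)
        profiles = improvement_profiles(tiny_cohort, model)
        view = group_trajectories(
            "all", None, matrix, "nutritional", "physical", profiles, 1, "mean"
        )
        assert set(view.series.columns) == {"a", "b", "c", "d", "e"}
        assert set(view.colors.columns) >= {"participant_id", "category", "shade", "color"}

    def test_unknown_group_rejected(self, tiny_cohort):
        matrix = ActivityMatrix.from_dataset(tiny_cohort)
        with pytest.raises(DataError):
            group_trajectories(
                0, None, matrix, "physical", "physical", pd.DataFrame(), 3, "mean"
            )


def test_improvement_profiles_shades_in_unit_interval(tiny_cohort):
    from coachcohort import fit_baseline_standardization

    model = fit_baseline_standardization(tiny_cohort.assessments)
    profiles = improvement_profiles(tiny_cohort, model)
    assert not profiles.empty
    assert ((profiles["shade"] >= 0) & (profiles["shade"] <= 1)).all()
    for _, row in profiles.iterrows():
        if row["category"] == SAME:
            assert abs(row["change"]) <= 0.1 + 1e-12
        elif row["category"] == IMPROVED:
            assert row["change"] > 0
        else:
            assert row["change"] < 0
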