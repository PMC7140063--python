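"""Xenograft response: relative areas, trends, Dunnett contrasts, calls, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fishdose.exceptions import DomainError, InputError
from fishdose.response import (
    EmbryoTrack,
    classify_cohort,
    classify_response,
    cohort_table,
    compare_pyknotic,
    dunnett_compare,
    group_trend,
    pyknotic_fraction,
    relative_area,
    repeated_measures_anova,
)
from fishdose.synthdata import CohortSimConfig, gen_cohort
from fishdose.response import tracks_from_frame


def track(areas, group="control", pid="C001", eid="e1"):
    keys = ("2hpi", "1dpi", "2dpi")
    return EmbryoTrack(
        patient_id=pid, group=group, embryo_id=eid,
        areas={k: a for k, a in zip(keys, areas) if a is not None},
    )


class TestRelativeArea:
    def test_normalisation(self):
        assert relative_area(track([1000, 1500, 2000])) == pytest.approx(
            {"2hpi": 1.0, "1dpi": 1.5, "2dpi": 2.0}
        )

    def test_constant_areas(self):
        assert relative_area(track([7, 7, 7])) == pytest.approx(
            {"2hpi": 1.0, "1dpi": 1.0, "2dpi": 1.0}
        )

    def test_thirty_percent_decline(self):
        rel = relative_area(track([800, None, 560]))
        assert rel["2dpi"] == pytest.approx(0.7)

    def test_missing_or_zero_baseline_rejected(self):
        with pytest.raises(InputError):
            relative_area(EmbryoTrack("p", "g", {"1dpi": 5.0}))
        with pytest.raises(InputError):
            relative_area(track([0.0, 1.0, 2.0]))

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, k):
        base = relative_area(track([800, 1000, 1300]))
        scaled = relative_area(track([800 * k, 1000 * k, 1300 * k]))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestRepeatedMeasuresAnova:
    def test_matches_pingouin_on_random_data(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        y = rng.lognormal(0.0, 0.3, size=(12, 3)) * np.array([1.0, 1.6, 2.4])
        f, p = repeated_measures_anova(y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "time": np.tile(np.arange(3), 12),
                "y": y.ravel(),
            }
        )
        ref = pingouin.rm_anova(
            data=long, dv="y", within="time", subject="subject", correction=False
        )
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-9)

    def test_flat_identical_trajectories_give_p_one(self):
        y = np.ones((5, 3))
        f, p = repeated_measures_anova(y)
        assert p == 1.0

    def test_zero_residual_with_time_effect_gives_p_zero(self):
        y = np.tile([1.0, 2.0, 4.0], (4, 1))
        _, p = repeated_measures_anova(y)
        assert p == 0.0

    def test_insufficient_data_rejected(self):
        with pytest.raises(InputError):
            repeated_measures_anova(np.ones((1, 3)))


class TestGroupTrend:
    def _cohort(self, effect, seed, n=10, cv=0.10):
        config = CohortSimConfig(
            patients=1,
            regimens=("R",),
            embryos_per_group=n,
            effects={("C001", "R"): effect},
            noise_cv=cv,
            dropout_per_day=0.0,
            seed=seed,
        )
        areas, _ = gen_cohort(config)
        return tracks_from_frame(areas)

    def test_growing_control_group_detected(self):
        # doubling per day, 10 embryos, 10% noise: the time trend is significant
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            tracks = [t for t in self._cohort(0.0, seed) if t.group == "control"]
            stats_ = group_trend(tracks)
            hits += stats_.p_value < 0.05
        assert hits / n_seeds >= 0.95

    def test_fully_suppressed_group_not_significant(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            tracks = [t for t in self._cohort(1.0, seed) if t.group == "R"]
            stats_ = group_trend(tracks)
            hits += stats_.p_value > 0.05
        assert hits / n_seeds >= 0.90

    def test_baseline_mean_is_exactly_one(self):
        tracks = [t for t in self._cohort(0.5, 3) if t.group == "R"]
        stats_ = group_trend(tracks)
        assert stats_.mean["2hpi"] == pytest.approx(1.0, abs=1e-12)
        assert stats_.sem["2hpi"] == pytest.approx(0.0, abs=1e-12)

    def test_undefined_p_with_reason_for_tiny_group(self):
        stats_ = group_trend([track([100, 120, None])])
        assert stats_.p_value is None
        assert stats_.reason

    def test_mixed_groups_rejected(self):
        with pytest.raises(InputError):
            group_trend([track([1, 2, 3], group="a"), track([1, 2, 3], group="b")])


class TestDunnett:
    def test_identical_treated_group_p_near_one(self):
        rng = np.random.default_rng(0)
        control = rng.normal(2.0, 0.2, size=10)
        res = dunnett_compare(control, {"same": control.copy()})
        assert res.adjusted_p["same"] > 0.99

    def test_two_identical_groups_get_equal_p(self):
        rng = np.random.default_rng(1)
        control = rng.normal(2.0, 0.2, size=10)
        treated = rng.normal(1.5, 0.2, size=10)
        res = dunnett_compare(control, {"a": treated, "b": treated.copy()})
        assert res.adjusted_p["a"] == pytest.approx(res.adjusted_p["b"], abs=1e-9)

    def test_single_group_reduces_to_two_sample_comparison(self):
        rng = np.random.default_rng(2)
        control = rng.normal(2.0, 0.3, size=12)
        treated = rng.normal(1.6, 0.3, size=12)
        res = dunnett_compare(control, {"t": treated})
        _, p_raw = stats.ttest_ind(treated, control)
        assert res.adjusted_p["t"] >= p_raw - 1e-3
        assert res.adjusted_p["t"] == pytest.approx(p_raw, abs=5e-3)

    def test_strong_responder_detected(self):
        # 70% endpoint reduction, CV 15%, n = 8/group
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            control = 4.0 * rng.lognormal(0.0, 0.15, size=8)
            responder = 1.2 * rng.lognormal(0.0, 0.15, size=8)
            others = {
                f"g{j}": 4.0 * rng.lognormal(0.0, 0.15, size=8) for j in range(3)
            }
            res = dunnett_compare(control, {"responder": responder, **others}, seed=seed)
            hits += res.adjusted_p["responder"] < 0.05
        assert hits / n_seeds >= 0.90

    def test_small_groups_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        control = rng.normal(2.0, 0.2, size=8)
        with pytest.warns(UserWarning, match="excluded"):
            res = dunnett_compare(control, {"tiny": [1.0], "ok": rng.normal(2, 0.2, 8)})
        assert res.excluded == ("tiny",)
        assert "tiny" not in res.adjusted_p

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            dunnett_compare([1.0], {"a": [1.0, 2.0]})
        with pytest.raises(InputError):
            dunnett_compare([1.0, 2.0], {})


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "treated, control, expected_decrease, expected_call",
        [
            (1.4, 2.0, 30.0, "PR"),   # threshold inclusive
            (0.2, 2.0, 90.0, "CR"),   # threshold inclusive
            (1.5, 2.0, 25.0, "NR"),
            (2.5, 2.0, -25.0, "NR"),  # growth beyond control
        ],
    )
    def test_thresholds(self, treated, control, expected_decrease, expected_call):
        call = classify_response(treated, control)
        assert call.percent_decrease == pytest.approx(expected_decrease)
        assert call.call == expected_call

    def test_nonpositive_control_rejected(self):
        with pytest.raises(DomainError):
            classify_response(1.0, 0.0)

    @given(
        t1=st.floats(min_value=0.0, max_value=4.0),
        delta=st.floats(min_value=0.0, max_value=4.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_lower_treated_never_downgrades(self, t1, delta):
        order = {"NR": 0, "PR": 1, "CR": 2}
        hi = classify_response(t1 + delta, 2.0)
        lo = classify_response(t1, 2.0)
        assert order[lo.call] >= order[hi.call]


class TestCohortTable:
    def _calls(self, n, k, regimen="FOLFOX", cr=0):
        calls = []
        for i in range(n):
            if i < cr:
                call = "CR"
            elif i < k:
                call = "PR"
            else:
                call = "NR"
            dec = 95.0 if call == "CR" else 50.0 if call == "PR" else 5.0
            calls.append(
                classify_response(
                    (100 - dec) / 100 * 2.0, 2.0, patient_id=f"P{i}", regimen=regimen
                )
            )
        return calls

    def test_five_of_eight(self):
        table = cohort_table(self._calls(8, 5))
        assert table.rows[0]["pct_pr"] == 62.5

    def test_seven_of_twelve(self):
        table = cohort_table(self._calls(12, 7))
        assert table.rows[0]["pct_pr"] == 58.33

    def test_zero_of_n(self):
        table = cohort_table(self._calls(6, 0))
        assert table.rows[0]["pct_pr"] == 0.0

    def test_cr_nested_in_pr(self):
        table = cohort_table(self._calls(4, 4, cr=1))
        row = table.rows[0]
        assert row["pct_cr"] == 25.0
        assert row["pct_pr"] == 100.0
        assert row["pct_cr"] <= row["pct_pr"]

    def test_duplicate_patient_regimen_rejected(self):
        calls = self._calls(3, 2)
        with pytest.raises(InputError):
            cohort_table(calls + [calls[0]])


class TestClassifyCohort:
    def test_zero_noise_cohort_matches_truth(self):
        config = CohortSimConfig(patients=4, noise_cv=0.0, baseline_cv=0.0,
                                 dropout_per_day=0.0, seed=11)
        areas, truth = gen_cohort(config)
        calls = classify_cohort(tracks_from_frame(areas))
        by_key = {(c.patient_id, c.regimen): c for c in calls}
        assert len(calls) == len(truth)
        for _, row in truth.iterrows():
            call = by_key[(row["patient_id"], row["regimen"])]
            assert call.call == row["label"]
            assert call.percent_decrease == pytest.approx(row["true_decrease_pct"], abs=1e-9)

    def test_missing_control_rejected(self):
        config = CohortSimConfig(patients=1, seed=0)
        areas, _ = gen_cohort(config)
        treated_only = areas[areas["group"] != "control"]
        with pytest.raises(InputError):
            classify_cohort(tracks_from_frame(treated_only))


class TestPyknotic:
    def test_mean_and_sem(self):
        mean, sem, per = pyknotic_fraction([(8, 100), (10, 100), (12, 100)])
        assert mean == pytest.approx(10.0)
        assert sem == pytest.approx(2.0 / np.sqrt(3), rel=1e-9)

    def test_all_zero(self):
        mean, sem, _ = pyknotic_fraction([(0, 50), (0, 80)])
        assert mean == 0.0 and sem == 0.0

    def test_single_sample_sem_undefined(self):
        mean, sem, _ = pyknotic_fraction([(5, 50)])
        assert mean == pytest.approx(10.0)
        assert sem is None

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            pyknotic_fraction([(0, 0)])

    def test_two_group_comparison_is_unpaired_t(self):
        treated = [(30, 100), (35, 100), (28, 100)]
        control = [(8, 100), (10, 100), (12, 100)]
        t, p = compare_pyknotic(treated, control)
        t_ref, p_ref = stats.ttest_ind([30.0, 35.0, 28.0], [8.0, 10.0, 12.0])
        assert t == pytest.approx(float(t_ref))
        assert p == pytest.approx(float(p_ref))
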