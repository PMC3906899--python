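"""EAE clinical metrics: onset rule, cohort summaries, group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vesselquant as vq
from vesselquant.clinical import ClinicalCourse, mannwhitney_exact


def course(scores, mouse="m", group="g"):
    return ClinicalCourse(mouse, group, tuple(scores))


class TestOnset:
    def test_two_consecutive_days_rule(self):
        assert vq.onset_day(course([0, 0, 1, 1, 2])) == 3
        assert vq.onset_day(course([0, 1, 0, 1, 1])) == 4  # isolated day-2 score ignored
        assert vq.onset_day(course([0] * 30)) is None

    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_onset_matches_naive_scan(self, scores):
        expected = None
        for d in range(len(scores) - 1):
            if scores[d] >= 1 and scores[d + 1] >= 1:
                expected = d + 1
                break
        assert vq.onset_day(course(scores)) == expected

    def test_mean_onset_with_substitution(self):
        c1 = course([0, 0, 1, 1, 2] + [0] * 0)
        assert vq.mean_day_of_onset([course([0, 0, 1, 1]), course([0, 0, 0, 0, 1, 1])], 6) == pytest.approx(
            (3 + 5) / 2
        )
        # never-diseased mouse counts as T+1
        sick = course([0] * 9 + [1, 1] + [0] * 19)
        well = course([0] * 30)
        assert vq.mean_day_of_onset([sick, well], 30) == pytest.approx((10 + 31) / 2)


class TestCourseValidation:
    def test_scores_must_be_integers_on_scale(self):
        with pytest.raises(ValueError):
            course([0, 1.5, 2])
        with pytest.raises(ValueError):
            course([0, 6])

    def test_death_is_absorbing(self):
        with pytest.raises(ValueError):
            course([0, 5, 4])
        assert course([0, 3, 5, 5]).max_score == 5


class TestCohortSummary:
    def test_single_mouse_worked_example(self):
        s = vq.cohort_summary([course([0, 0, 1, 2, 2])], 5)
        assert s.incidence == 1.0
        assert s.mean_day_of_onset == 3
        assert s.mean_max_score == 2
        assert s.disease_index == pytest.approx(5 / 3 * 100, abs=0.01)  # ≈166.67

    def test_two_mouse_worked_example(self):
        cohort = [course([0, 1, 1, 2, 3, 3]), course([0, 0, 0, 1, 1, 2])]
        s = vq.cohort_summary(cohort, 6)
        assert s.mean_day_of_onset == 3.0
        assert s.mean_max_score == 2.5
        assert s.incidence == 1.0
        assert s.disease_index == pytest.approx(7.0 / 3.0 * 100, abs=0.01)  # ≈233.33

    def test_all_zero_cohort(self):
        s = vq.cohort_summary([course([0] * 30), course([0] * 30)], 30)
        assert s.incidence == 0.0
        assert s.mean_day_of_onset == 31.0
        assert s.disease_index == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            vq.cohort_summary([course([0, 1]), course([0, 1, 1])])

    def test_summary_matches_spreadsheet_oracle_on_random_cohorts(self):
        """Brute-force recomputation of every formula on 10 random cohorts."""
        rng = np.random.default_rng(99)
        for trial in range(10):
            T = int(rng.integers(6, 25))
            cohort = []
            for m in range(int(rng.integers(2, 8))):
                onset = int(rng.integers(2, T + 4))  # may exceed T: never diseased
                plateau = int(rng.integers(1, 5))
                scores = [0 if d < onset else min(plateau, d - onset + 1) for d in range(1, T + 1)]
                cohort.append(course(scores, mouse=f"m{m}"))
            s = vq.cohort_summary(cohort, T)

            # oracle: naive spreadsheet-style evaluation
            onsets = []
            for c in cohort:
                o = next(
                    (d + 1 for d in range(T - 1) if c.scores[d] >= 1 and c.scores[d + 1] >= 1),
                    None,
                )
                onsets.append(o)
            mdo = sum(o if o else T + 1 for o in onsets) / len(cohort)
            daily = [sum(c.scores[d] for c in cohort) / len(cohort) for d in range(T)]
            assert s.incidence == pytest.approx(sum(o is not None for o in onsets) / len(cohort))
            assert s.mean_day_of_onset == pytest.approx(mdo)
            assert s.mean_max_score == pytest.approx(sum(max(c.scores) for c in cohort) / len(cohort))
            assert s.disease_index == pytest.approx(100 * sum(daily) / mdo)


class TestAscendingSlope:
    def test_exact_line_through_ascending_window(self):
        assert vq.ascending_slope([0, 0, 1, 2, 3, 3, 3], 3) == pytest.approx(1.0)
        assert vq.ascending_slope([0, 0.5, 1.5, 2.5, 2.5], 2) == pytest.approx(1.0)

    def test_flat_series_after_onset_has_zero_slope(self):
        assert vq.ascending_slope([0, 2, 2, 2], 2) == pytest.approx(0.0)

    def test_too_short_window_is_undefined(self):
        assert vq.ascending_slope([0, 0, 1], 4) is None


class TestGroupComparisons:
    def make(self, maxima, onset, group, T=20):
        out = []
        for i, mx in enumerate(maxima):
            scores = [0 if d < onset else min(mx, d - onset + 1) for d in range(1, T + 1)]
            out.append(course(scores, mouse=f"{group}{i}", group=group))
        return out

    def test_identical_groups_not_significant(self):
        a = self.make([2, 3, 2, 3], onset=5, group="a")
        b = self.make([2, 3, 2, 3], onset=5, group="b")
        rep = vq.compare_clinical_groups({"a": a, "b": b})
        assert rep["incidence"]["p"] > 0.05
        assert rep["severity_mannwhitney"]["a|b"]["p"] > 0.05
        assert rep["onset_anova"]["p"] > 0.05

    def test_extreme_severity_split_exact_p(self):
        # exact two-sided permutation p for {1,1,1,1} vs {4,4,4,4} is 2/70
        assert mannwhitney_exact([1, 1, 1, 1], [4, 4, 4, 4]) == pytest.approx(2 / 70)
        a = self.make([1, 1, 1, 1], onset=5, group="a")
        b = self.make([4, 4, 4, 4], onset=5, group="b")
        rep = vq.compare_clinical_groups({"a": a, "b": b})
        assert rep["severity_mannwhitney"]["a|b"]["p"] == pytest.approx(0.0286, abs=0.0005)
        assert rep["severity_mannwhitney"]["a|b"]["significant"]

    def test_exact_mannwhitney_matches_scipy_without_ties(self):
        from scipy import stats

        a, b = [1.2, 3.4, 2.2, 5.0], [4.1, 6.3, 7.7, 2.9]
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert mannwhitney_exact(a, b) == pytest.approx(expected)

    def test_incidence_split_is_significant(self):
        sick = self.make([3, 3, 3, 3], onset=5, group="a")
        well = [course([0] * 20, mouse=f"b{i}", group="b") for i in range(4)]
        rep = vq.compare_clinical_groups({"a": sick, "b": well})
        assert rep["incidence"]["p"] < 0.05


class TestSimulation:
    def test_same_seed_is_identical(self):
        c1 = vq.simulate_cohort("wt", 10, 30, seed=4)
        c2 = vq.simulate_cohort("wt", 10, 30, seed=4)
        assert [c.scores for c in c1] == [c.scores for c in c2]

    def test_profile_orderings_at_n50(self):
        wt = vq.cohort_summary(vq.simulate_cohort("wt", 50, 30, seed=1), 30)
        ak = vq.cohort_summary(vq.simulate_cohort("astro_ko", 50, 30, seed=2), 30)
        ek = vq.cohort_summary(vq.simulate_cohort("endo_ko", 50, 30, seed=3), 30)
        assert ek.mean_day_of_onset > wt.mean_day_of_onset
        assert ak.mean_max_score < wt.mean_max_score

    def test_unknown_profile(self):
        with pytest.raises(ValueError):
            vq.simulate_cohort("ccl2_global_ko", 5, 30, 0)


def test_scores_csv_roundtrip(tmp_path):
    import pandas as pd

    rows = []
    for g, mouse, scores in (
        ("wt", "m1", [0, 1, 1, 2]),
        ("wt", "m2", [0, 0, 1, 1]),
        ("ko", "m3", [0, 0, 0, 0]),
    ):
        rows += [{"mouse_id": mouse, "group": g, "day": d + 1, "score": s} for d, s in enumerate(scores)]
    p = tmp_path / "scores.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    cohorts = vq.read_scores_csv(p)
    assert set(cohorts) == {"wt", "ko"}
    assert len(cohorts["wt"]) == 2
    assert vq.onset_day(cohorts["wt"][0]) == 2
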