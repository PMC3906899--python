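"""EAE clinical-course metrics and group statistics.

Mice are scored daily on the standard 0–5 EAE scale (0 normal, 1 limp tail,
2 hind-leg weakness, 3 hind-leg paralysis, 4 fore-leg involvement,
5 death; death is absorbing).  The cohort metrics implemented here follow
the conventional definitions:

* onset day — first day of a run of two consecutive days with score ≥ 1;
* mean day of onset — mean over mice, substituting T+1 (one day after the
  last day of the experiment) for mice that never show disease;
* mean maximum clinical score — mean of the per-mouse maxima;
* disease index — 100 × (sum over days of the cohort's daily mean score)
  divided by the mean day of onset;
* disease incidence — fraction of mice with an onset;
* ascending slope — OLS slope of the daily mean score over the window from
  ceil(mean day of onset) through the first attainment of the series
  maximum (extended along a flat plateau when the window is degenerate).

Group comparisons use a χ² test on incidence (Fisher's exact fallback for
small expected counts), Mann–Whitney U on per-mouse maximum scores (exact
permutation p for ≤8 mice per group, normal approximation with tie
correction otherwise) and ANOVA with Bonferroni post-hoc on onset days,
significance at p ≤ 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalCourse",
    "CohortSummary",
    "onset_day",
    "mean_day_of_onset",
    "cohort_summary",
    "ascending_slope",
    "compare_clinical_groups",
    "simulate_cohort",
    "read_scores_csv",
]

SCALE = (0, 1, 2, 3, 4, 5)


@dataclass
class ClinicalCourse:
    """Daily clinical scores for one mouse, days 1..T."""

    mouse_id: str
    group: str
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        scores = tuple(self.scores)
        if len(scores) < 1:
            raise ValueError("need at least one day of scores")
        for s in scores:
            if not float(s).is_integer() or int(s) not in SCALE:
                raise ValueError(f"score {s!r} not on the integer 0–5 scale")
        scores = tuple(int(s) for s in scores)
        if 5 in scores:
            d = scores.index(5)
            if any(s != 5 for s in scores[d:]):
                raise ValueError("death (score 5) is absorbing; later scores must stay 5")
        self.scores = scores

    @property
    def max_score(self) -> int:
        return max(self.scores)


@dataclass
class CohortSummary:
    incidence: float
    mean_day_of_onset: float
    mean_max_score: float
    disease_index: float
    ascending_slope: float | None
    n_mice: int


def onset_day(course: ClinicalCourse) -> int | None:
    """First day d with score ≥ 1 on both day d and day d+1 (1-based), else None."""
    s = course.scores
    for d in range(len(s) - 1):
        if s[d] >= 1 and s[d + 1] >= 1:
            return d + 1
    return None


def mean_day_of_onset(cohort: list[ClinicalCourse], last_day: int) -> float:
    """Mean onset day with the no-disease convention: onset := T+1."""
    if not cohort:
        raise ValueError("empty cohort")
    onsets = [onset_day(c) if onset_day(c) is not None else last_day + 1 for c in cohort]
    return float(np.mean(onsets))


def ascending_slope(daily_mean_scores, mean_onset: float) -> float | None:
    """OLS slope of mean score vs day over the ascending disease window.

    The window runs from day ceil(mean_onset) through the first day the
    series attains its maximum; if that window is a single day it is
    extended along the consecutive plateau of the maximum.  Returns None
    when no ≥2-day window exists.
    """
    y = np.asarray(daily_mean_scores, dtype=float)
    days = np.arange(1, len(y) + 1)
    start = int(math.ceil(mean_onset))
    if start > len(y):
        return None
    end = int(days[np.argmax(y)])  # first attainment of the maximum
    if end <= start:
        end = start
        while end < len(y) and y[end] == y[start - 1]:
            end += 1
    if end - start < 1:
        return None
    window = (days >= start) & (days <= end)
    slope = np.polyfit(days[window], y[window], 1)[0]
    return float(slope)


def cohort_summary(cohort: list[ClinicalCourse], last_day: int | None = None) -> CohortSummary:
    """All cohort metrics from equal-length score series."""
    if not cohort:
        raise ValueError("empty cohort")
    lengths = {len(c.scores) for c in cohort}
    if len(lengths) != 1:
        raise ValueError(f"unequal score series lengths: {sorted(lengths)}")
    T = lengths.pop()
    if last_day is None:
        last_day = T
    onsets = [onset_day(c) for c in cohort]
    incidence = sum(o is not None for o in onsets) / len(cohort)
    mdo = mean_day_of_onset(cohort, last_day)
    daily_means = np.mean([c.scores for c in cohort], axis=0)
    disease_index = 100.0 * float(daily_means.sum()) / mdo
    return CohortSummary(
        incidence=float(incidence),
        mean_day_of_onset=mdo,
        mean_max_score=float(np.mean([c.max_score for c in cohort])),
        disease_index=disease_index,
        ascending_slope=ascending_slope(daily_means, mdo),
        n_mice=len(cohort),
    )


def mannwhitney_exact(a, b) -> float:
    """Two-sided exact Mann–Whitney p by permutation enumeration (handles ties).

    Enumerates all assignments of the pooled observations to the two groups
    and counts those with a U statistic at least as far from its null mean
    as observed.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = np.asarray(a + b)
    n1 = len(a)
    mu = n1 * len(b) / 2.0

    def u_stat(idx_a: tuple[int, ...]) -> float:
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx_a)] = True
        # U1 = Σ ranks(a) − n1(n1+1)/2, mid-ranks for ties
        order = stats.rankdata(pooled)
        return float(order[mask].sum() - n1 * (n1 + 1) / 2.0)

    u_obs = u_stat(tuple(range(n1)))
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def _mannwhitney_p(a, b) -> float:
    if len(a) <= 8 and len(b) <= 8:
        return mannwhitney_exact(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def compare_clinical_groups(cohorts: dict[str, list[ClinicalCourse]], last_day: int | None = None) -> dict:
    """χ² incidence / Mann–Whitney severity / ANOVA-Bonferroni onset report."""
    if len(cohorts) < 2:
        raise ValueError("need at least 2 groups")
    for g, c in cohorts.items():
        if len(c) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 mice")
    names = sorted(cohorts)
    if last_day is None:
        last_day = len(cohorts[names[0]][0].scores)

    # incidence: groups × (diseased, not diseased)
    table = []
    for g in names:
        d = sum(onset_day(c) is not None for c in cohorts[g])
        table.append([d, len(cohorts[g]) - d])
    table = np.asarray(table)
    if table.shape == (2, 2) and (stats.contingency.expected_freq(table) < 5).any():
        incidence_p = float(stats.fisher_exact(table)[1])
        incidence_test = "fisher_exact"
    elif np.any(table.sum(axis=0) == 0):
        # every mouse in every group shares the same outcome: nothing to test
        incidence_p, incidence_test = 1.0, "no_variation"
    else:
        incidence_p = float(stats.chi2_contingency(table, correction=False)[1])
        incidence_test = "chi2"

    onsets = {
        g: [onset_day(c) if onset_day(c) is not None else last_day + 1 for c in cohorts[g]]
        for g in names
    }
    arrays = [np.asarray(onsets[g], dtype=float) for g in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        onset_f, onset_p = 0.0, 1.0
    else:
        onset_f, onset_p = (float(v) for v in stats.f_oneway(*arrays))

    m = len(names) * (len(names) - 1) // 2
    severity = {}
    onset_pairwise = {}
    for (ga, gb) in itertools.combinations(names, 2):
        max_a = [c.max_score for c in cohorts[ga]]
        max_b = [c.max_score for c in cohorts[gb]]
        if np.ptp(max_a + max_b) == 0:
            p_sev = 1.0
        else:
            p_sev = _mannwhitney_p(max_a, max_b)
        severity[f"{ga}|{gb}"] = {"p": p_sev, "significant": p_sev <= 0.05}
        oa, ob = onsets[ga], onsets[gb]
        if np.ptp(oa + ob) == 0:
            raw = 1.0
        else:
            raw = float(stats.ttest_ind(oa, ob).pvalue)
        adj = min(1.0, m * raw)
        onset_pairwise[f"{ga}|{gb}"] = {"p_raw": raw, "p_adj": adj, "significant": adj <= 0.05}

    return {
        "incidence": {"test": incidence_test, "p": incidence_p, "table": table.tolist()},
        "severity_mannwhitney": severity,
        "onset_anova": {"F": onset_f, "p": onset_p, "pairwise": onset_pairwise},
        "groups": {
            g: {
                "n": len(cohorts[g]),
                "incidence": float(np.mean([onset_day(c) is not None for c in cohorts[g]])),
                "mean_onset": float(np.mean(onsets[g])),
                "mean_max_score": float(np.mean([c.max_score for c in cohorts[g]])),
            }
            for g in names
        },
    }


#: Disease-course profiles for the three genotypes: wild type, astrocyte
#: CCL2 knockout (milder plateau, slower ramp) and endothelial CCL2 knockout
#: (delayed onset, otherwise WT-like course).  Onset ~ N(mean, sd) days,
#: plateau drawn per mouse, ramp in score units/day.
_PROFILES = {
    "wt": dict(onset_mean=10.0, onset_sd=1.5, plateaus=(3, 4), ramp=1.0, p_no_disease=0.0),
    "astro_ko": dict(onset_mean=11.0, onset_sd=1.5, plateaus=(2, 3), ramp=0.5, p_no_disease=0.0),
    "endo_ko": dict(onset_mean=16.0, onset_sd=1.5, plateaus=(3, 4), ramp=1.0, p_no_disease=0.0),
}


def simulate_cohort(profile: str, n_mice: int, T: int = 30, seed: int = 0) -> list[ClinicalCourse]:
    """Seeded stochastic EAE score trajectories for a genotype profile.

    Each mouse draws an onset day and a plateau score; from onset the score
    ramps at the profile rate (integer steps, capped at the plateau).
    Death is not simulated (score 5 never occurs by default).
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; known: {sorted(_PROFILES)}")
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    p = _PROFILES[profile]
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_mice):
        if rng.random() < p["p_no_disease"]:
            scores = [0] * T
        else:
            onset = int(np.clip(round(rng.normal(p["onset_mean"], p["onset_sd"])), 2, T))
            plateau = int(rng.choice(p["plateaus"]))
            scores = []
            for day in range(1, T + 1):
                if day < onset:
                    scores.append(0)
                else:
                    level = min(plateau, int(math.floor((day - onset) * p["ramp"])) + 1)
                    scores.append(max(1, level))
        cohort.append(ClinicalCourse(f"{profile}_{i:03d}", profile, tuple(scores)))
    return cohort


def read_scores_csv(path: str | Path) -> dict[str, list[ClinicalCourse]]:
    """Read long-format scores (mouse_id, group, day, score) into cohorts."""
    df = pd.read_csv(path)
    required = {"mouse_id", "group", "day", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"scores CSV must have columns {sorted(required)}")
    cohorts: dict[str, list[ClinicalCourse]] = {}
    for (group, mouse), sub in df.groupby(["group", "mouse_id"], sort=True):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise ValueError(f"mouse {mouse!r}: days must be consecutive starting at 1")
        cohorts.setdefault(str(group), []).append(
            ClinicalCourse(str(mouse), str(group), tuple(int(s) for s in sub["score"]))
        )
    return cohorts
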