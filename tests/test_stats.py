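"""Kruskal–Wallis, Bonferroni post-hoc and stepwise-regression behavior."""

import itertools

import numpy as np

import pytest

from mpmri.io import TIMEPOINTS, ValidationError
from mpmri.phantom import (
    GroupEffectProfile,
    STUDY_GROUP_SIZES,
    default_group_profiles,
    simulate_cohort,
    simulate_correlated_predictors,
)
from mpmri.stats import (
    kruskal_wallis,
    pairwise_posthoc,
    percent_change_table,
    run_study_analysis,
    stepwise_regression,
)


def brute_force_h(groups):
    """Independent tie-corrected H from the rank-sum definition."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # mid-rank for the tied block
        i = j
    offsets = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for k, g in enumerate(groups):
        r = ranks[offsets[k]: offsets[k + 1]]
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction if correction > 0 else 0.0


class TestKruskalWallis:
    def test_hand_rank_sum_value(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.h_statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_all_identical_degenerates_to_null(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert res.h_statistic == 0.0
        assert res.p_value == 1.0

    def test_two_group_h_equals_ranksum_chi_square_form(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(1.0, size=6)
        res = kruskal_wallis([a, b])
        assert res.h_statistic == pytest.approx(brute_force_h([a, b]), rel=1e-12)
        assert res.df == 1

    @pytest.mark.parametrize(
        "sizes,alphabet",
        [((2, 2, 2), (1, 2, 3)), ((2, 2, 3), (1, 2, 3)), ((3, 3, 3), (1, 2))],
    )
    def test_exhaustive_small_instances_match_brute_force(self, sizes, alphabet):
        n = sum(sizes)
        for values in itertools.product(alphabet, repeat=n):
            groups = []
            at = 0
            for s in sizes:
                groups.append(np.asarray(values[at: at + s], dtype=float))
                at += s
            res = kruskal_wallis(groups)
            assert res.h_statistic == pytest.approx(
                brute_force_h(groups), rel=1e-10, abs=1e-10
            )

    def test_permutation_invariance_within_groups(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=5), rng.normal(size=6)]
        shuffled = [rng.permutation(g) for g in groups]
        assert kruskal_wallis(groups).h_statistic == pytest.approx(
            kruskal_wallis(shuffled).h_statistic
        )

    def test_exact_permutation_p_matches_enumeration(self):
        groups = [[1.0, 4.0], [2.0, 6.0], [9.0, 3.0]]
        res = kruskal_wallis(groups, exact=True)
        # independent enumeration of all 6!/(2!2!2!) = 90 assignments
        pooled = np.concatenate(groups)
        h_obs = brute_force_h(groups)
        count = total = 0
        for perm in itertools.permutations(range(6)):
            parts = [pooled[list(perm[:2])], pooled[list(perm[2:4])],
                     pooled[list(perm[4:])]]
            total += 1
            if brute_force_h(parts) >= h_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            kruskal_wallis([[1.0], [2.0, 3.0]])


class TestPosthoc:
    def test_four_groups_give_six_comparisons(self, rng):
        groups = [rng.normal(loc=i, size=6) for i in range(4)]
        posthoc = pairwise_posthoc(groups, labels=["a", "b", "c", "d"])
        assert len(posthoc) == 6
        assert {(p[0], p[1]) for p in posthoc} == {
            ("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")
        }

    def test_bonferroni_adjustment_and_cap(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        for _, _, raw, adj in pairwise_posthoc(groups):
            assert adj == pytest.approx(min(1.0, raw * 6))

    def test_separated_groups_survive_correction(self, rng):
        groups = [rng.normal(loc=10 * i, scale=0.1, size=8) for i in range(4)]
        posthoc = pairwise_posthoc(groups)
        assert all(adj < 0.05 for _, _, _, adj in posthoc)


class TestStepwise:
    def test_dominant_predictor_selected_alone(self, rng):
        n = 40
        x1 = rng.normal(size=n)
        candidates = {
            "x1": x1,
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
        }
        y = 2.0 * x1 + 0.01 * rng.normal(size=n)
        res = stepwise_regression(y, candidates)
        assert res.selected_predictors == ["x1"]
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=0.05)

    def test_single_predictor_r_is_signed_correlation(self, rng):
        y, candidates = simulate_correlated_predictors(-0.8, 30, 2, seed=4)
        res = stepwise_regression(y, candidates)
        assert res.selected_predictors == ["radc_change"]
        expected_r = np.corrcoef(y, candidates["radc_change"])[0, 1]
        assert res.model_r == pytest.approx(expected_r)
        assert res.model_r < 0
        assert res.model_r_squared == pytest.approx(expected_r**2)

    def test_saturation_when_thresholds_disabled(self, rng):
        n = 30
        candidates = {f"x{i}": rng.normal(size=n) for i in range(3)}
        y = rng.normal(size=n)
        res = stepwise_regression(y, candidates, entry_p=1.0, exit_p=1.0)
        assert sorted(res.selected_predictors) == ["x0", "x1", "x2"]
        entries = [s for s in res.step_log if s["action"] == "enter"]
        ps = [s["p"] for s in entries]
        # forward order follows marginal partial-F at each step
        assert len(entries) == 3

    def test_constant_candidate_rejected(self, rng):
        with pytest.raises(ValidationError, match="constant"):
            stepwise_regression(
                rng.normal(size=20), {"x": np.ones(20), "y": rng.normal(size=20)}
            )

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValidationError, match="n_candidates"):
            stepwise_regression(
                rng.normal(size=6),
                {f"x{i}": rng.normal(size=6) for i in range(4)},
            )


@pytest.fixture(scope="module")
def cohort_frame():
    from mpmri.io import records_to_frame

    records, _ = simulate_cohort(
        default_group_profiles(), STUDY_GROUP_SIZES, seed=17
    )
    return records_to_frame(records)


class TestStudyAnalysis:
    def test_percent_change_table_shape(self, cohort_frame):
        changes = percent_change_table(cohort_frame)
        assert len(changes) == 44 * 4  # four post-treatment timepoints
        assert set(changes["timepoint"]) == {"4h", "2d", "6d", "12d"}

    def test_all_endpoint_timepoint_cells_present(self, cohort_frame):
        result = run_study_analysis(cohort_frame)
        assert set(result.comparisons) == {
            (ep, tp)
            for ep in ("tumor_volume", "radc", "ktrans", "ve", "rbv", "rbf")
            for tp in ("4h", "2d", "6d", "12d")
        }
        for res in result.comparisons.values():
            assert len(res.posthoc) == 6
        assert result.stepwise is not None

    def test_strong_effects_detected(self, cohort_frame):
        result = run_study_analysis(cohort_frame)
        # vascular shutdown at 4 h: rBV omnibus strongly significant
        assert result.comparisons[("rbv", "4h")].p_value < 0.001
        # growth delay under the combination at 12 d
        pairs = {
            tuple(sorted((a, b))): adj
            for a, b, _, adj in result.comparisons[("tumor_volume", "12d")].posthoc
        }
        assert pairs[("ZdTha", "control")] < 0.05

    def test_missing_group_is_reported(self, cohort_frame):
        broken = cohort_frame[cohort_frame["group"] != "Tha"]
        with pytest.raises(ValidationError, match="Tha"):
            run_study_analysis(broken)

    def test_power_monotone_in_effect_size(self):
        # separation between ZdTha and control volume factors at 12 d:
        # rejection rate never decreases along a 3-point effect grid
        rates = []
        for factor in (1.0, 1.5, 3.0):
            flat = {tp: {} for tp in TIMEPOINTS}
            eff = {tp: ({"volume": factor} if tp != "pre" else {})
                   for tp in TIMEPOINTS}
            profiles = [
                GroupEffectProfile("control", flat, cv=0.15),
                GroupEffectProfile("Zd", flat, cv=0.15),
                GroupEffectProfile("Tha", flat, cv=0.15),
                GroupEffectProfile("ZdTha", eff, cv=0.15),
            ]
            hits = 0
            n_rep = 60
            for rep in range(n_rep):
                records, _ = simulate_cohort(profiles, {"control": 10, "Zd": 2,
                                                        "Tha": 2, "ZdTha": 12},
                                             seed=1000 + rep)
                from mpmri.io import records_to_frame

                changes = percent_change_table(records_to_frame(records))
                sub = changes[changes["timepoint"] == "12d"]
                groups = [sub.loc[sub["group"] == g, "tumor_volume_change"].to_numpy()
                          for g in ("control", "ZdTha")]
                posthoc = pairwise_posthoc(groups, labels=["control", "ZdTha"])
                if posthoc[0][3] < 0.05:
                    hits += 1
            rates.append(hits / n_rep)
        assert rates[0] <= rates[1] + 0.10
        assert rates[1] <= rates[2] + 0.10
        assert rates[2] > rates[0]
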