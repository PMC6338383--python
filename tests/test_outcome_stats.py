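"""Rank correlations, group comparisons and bootstrap intervals."""

import numpy as np
import pytest
from scipy import stats

from sympnet.outcome_stats import (
    association_battery,
    battery_frame,
    bca_ci,
    bca_endpoints,
    cohen_d,
    compare_correlations,
    contingency_chi2,
    detectable_r,
    kendall_tau,
    welch_t,
)

from oracles import brute_kendall_tau_b


class TestKendallTau:
    def test_perfectly_concordant(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfectly_reversed(self):
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example_matches_pair_counting(self):
        x, y = [1, 2, 2, 3], [1, 1, 2, 3]
        assert kendall_tau(x, y) == pytest.approx(brute_kendall_tau_b(x, y), abs=1e-12)

    def test_matches_pair_counting_on_random_tied_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert kendall_tau(x, y) == pytest.approx(
                brute_kendall_tau_b(x, y), abs=1e-12
            )

    def test_symmetry_and_monotone_invariance(self, rng):
        x = rng.integers(0, 10, size=30).astype(float)
        y = rng.integers(0, 10, size=30).astype(float)
        assert kendall_tau(x, y) == pytest.approx(kendall_tau(y, x))
        assert kendall_tau(np.exp(x), y) == pytest.approx(kendall_tau(x, y))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestWelchAndCohen:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)
        assert cohen_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)

    def test_df_bounded_by_pooled_df(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 20))
            b = rng.normal(2, 3, size=rng.integers(3, 20))
            _, df, _ = welch_t(a, b)
            assert df <= len(a) + len(b) - 2 + 1e-9

    def test_one_pooled_sd_apart(self):
        a = np.array([0.0, 1.0, 2.0])
        b = a + 1.0  # pooled SD is exactly 1
        assert abs(cohen_d(a, b)) == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            cohen_d([1.0, 1.0], [2.0, 2.0])


class TestContingency:
    @pytest.mark.parametrize(
        "table, expected",
        [([[37, 109], [10, 199]], 31.625), ([[75, 71], [16, 193]], 86.165)],
    )
    def test_comorbidity_tables(self, table, expected):
        chi2, p = contingency_chi2(table)
        assert chi2 == pytest.approx(expected, abs=5e-4)
        assert p < 0.001

    def test_proportional_table_zero(self):
        chi2, p = contingency_chi2([[20, 40], [10, 20]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_transpose_invariance(self, rng):
        t = rng.integers(1, 50, size=(2, 2))
        assert contingency_chi2(t)[0] == pytest.approx(contingency_chi2(t.T)[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_chi2([[0, 0], [5, 6]])


class TestBcaCi:
    def test_constant_data_point_interval(self):
        lo, hi = bca_ci(np.full(20, 3.5), np.mean, B=200, seed=0)
        assert lo == hi == 3.5

    def test_reduces_to_percentile_when_unadjusted(self, rng):
        boot = rng.normal(size=2000)
        lo, hi = bca_endpoints(boot, z0=0.0, a_hat=0.0, level=0.95)
        expected = np.percentile(boot, [2.5, 97.5])
        assert (lo, hi) == pytest.approx(tuple(expected), abs=1e-12)

    def test_small_B_warns(self, rng):
        with pytest.warns(UserWarning, match="small"):
            bca_ci(rng.normal(size=30), np.mean, B=50, seed=0)

    def test_endpoints_within_support_and_cover_estimate(self, rng):
        data = rng.exponential(size=80)
        lo, hi = bca_ci(data, np.mean, B=2000, seed=1)
        assert data.min() <= lo < hi <= data.max()
        assert lo < data.mean() < hi

    def test_agrees_with_scipy_bca(self, rng):
        data = rng.normal(1.0, 2.0, size=60)
        lo, hi = bca_ci(data, np.mean, B=4000, seed=2)
        res = stats.bootstrap(
            (data,), np.mean, n_resamples=4000, method="BCa",
            confidence_level=0.95, random_state=np.random.default_rng(3),
        )
        se = data.std(ddof=1) / np.sqrt(len(data))
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.15 * se)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.15 * se)


class TestCompareCorrelations:
    def test_identical_scores_zero_width(self, rng):
        a = rng.integers(0, 18, size=50).astype(float)
        y = rng.normal(size=50)
        delta, (lo, hi) = compare_correlations(a, a.copy(), y, B=200, seed=0)
        assert delta == lo == hi == 0.0

    def test_monotone_transform_exactly_zero(self, rng):
        a = rng.integers(0, 18, size=60).astype(float)
        y = a + rng.normal(size=60)
        delta, (lo, hi) = compare_correlations(a, 2 * a, y, B=500, seed=1)
        assert delta == 0.0
        assert (lo, hi) == (0.0, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_correlations([1, 2, 3], [1, 2], [1, 2, 3])


class TestDetectableR:
    def test_closed_form_n_100(self):
        r = detectable_r(100)
        assert r == pytest.approx(np.tanh(2.8016 / np.sqrt(97)), abs=2e-4)
        assert r == pytest.approx(0.277, abs=5e-3)

    def test_monotone_decreasing_and_vanishing(self):
        values = [detectable_r(n) for n in (10, 50, 200, 1000, 100000)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 0.02

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            detectable_r(4)


class TestAssociationBattery:
    def build_scores_cohort(self, rng, outcome):
        import pandas as pd
        from sympnet.symptoms import SYMPTOMS
        from sympnet.data_io import CohortTable

        n = 80
        profiles = (rng.random((n, 18)) < 0.4).astype(int)
        df = pd.DataFrame(profiles, columns=list(SYMPTOMS))
        df.insert(0, "id", [f"p{i}" for i in range(n)])
        df.insert(1, "group", "ADHD")
        counts = profiles.sum(axis=1)
        df["out_baseline"] = outcome(counts)
        cohort = CohortTable(df)
        scores = pd.DataFrame(
            {
                "id": df["id"],
                "group": "ADHD",
                "unweighted": counts,
                "strength_weighted": counts * 1.7,
                "clustering_weighted": counts * 0.4,
            }
        )
        return scores, cohort

    def test_outcome_copy_of_score_gives_tau_one(self, rng):
        scores, cohort = self.build_scores_cohort(rng, lambda c: c.astype(float))
        results = association_battery(scores, cohort, B=200, seed=0)
        unweighted = [r for r in results if r.score_kind == "unweighted"][0]
        assert unweighted.statistic == "tau"
        assert unweighted.estimate == pytest.approx(1.0)

    def test_independent_outcome_small_tau(self, rng):
        scores, cohort = self.build_scores_cohort(
            rng, lambda c: rng.normal(size=len(c))
        )
        results = association_battery(scores, cohort, B=200, seed=0)
        for r in results:
            assert abs(r.estimate) < 0.2
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_binary_outcome_sign_convention(self, rng):
        scores, cohort = self.build_scores_cohort(
            rng, lambda c: (c > np.median(c)).astype(int)
        )
        results = association_battery(scores, cohort, B=200, seed=0)
        r = results[0]
        assert r.statistic == "cohen_d"
        # high scores sit in the outcome-present group, so absent-minus-present d < 0
        assert r.estimate < 0
        flipped = association_battery(
            scores, cohort, B=200, seed=0, d_sign="present_minus_absent"
        )[0]
        assert flipped.estimate == pytest.approx(-r.estimate)

    def test_sparse_outcome_skipped_with_warning(self, rng):
        scores, cohort = self.build_scores_cohort(rng, lambda c: c.astype(float))
        cohort.data.loc[2:, "out_baseline"] = np.nan
        with pytest.warns(UserWarning, match="skipped"):
            results = association_battery(scores, cohort, B=200, seed=0)
        assert results == []

    def test_frame_shape(self, rng):
        scores, cohort = self.build_scores_cohort(rng, lambda c: c.astype(float))
        results = association_battery(scores, cohort, B=200, seed=0)
        frame = battery_frame(results)
        assert len(frame) == 3  # three score kinds x one outcome
        assert set(frame["score_kind"]) == {
            "unweighted", "strength_weighted", "clustering_weighted"
        }
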