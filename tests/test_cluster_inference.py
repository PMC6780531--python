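"""Subject-resampling bootstrap, correlation, paired tests, trends."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qtdyn import (
    bonferroni,
    cluster_bootstrap,
    paired_test,
    pearson,
    rate_trend,
)


def make_trend_frame(rng, n_patients, slope_by_rate=None, sd=5.0):
    rates = list(range(50, 121, 10))
    rows = []
    for i in range(n_patients):
        offset = rng.normal(0.0, sd)
        for r in rates:
            shift = slope_by_rate.get(r, 0.0) if slope_by_rate else 0.0
            rows.append({"patient_id": f"P{i}", "rate_bpm": r,
                         "value": offset + shift + rng.normal(0.0, sd)})
    return pd.DataFrame(rows)


class TestClusterBootstrap:
    def test_identical_patients_degenerate(self):
        values = {f"P{i}": [7.5, 7.5] for i in range(5)}
        out = cluster_bootstrap(values, "mean", n_boot=200, seed=0)
        assert out.estimate == 7.5
        assert out.ci_low == out.ci_high == 7.5

    def test_same_seed_same_summary(self):
        rng = np.random.default_rng(3)
        values = {i: rng.normal(size=4) for i in range(10)}
        a = cluster_bootstrap(values, "mean", n_boot=500, seed=9)
        b = cluster_bootstrap(values, "mean", n_boot=500, seed=9)
        assert a == b

    def test_matches_brute_force_naive_bootstrap(self):
        """With one observation per patient the cluster bootstrap is the
        ordinary naive bootstrap; check CI and p against full enumeration
        of the 3-patient resample space."""
        values = {"a": [1.0], "b": [2.0], "c": [9.0]}
        flat = np.array([1.0, 2.0, 9.0])
        # all 27 equally likely resamples
        grid = np.array(np.meshgrid(flat, flat, flat)).reshape(3, -1).T
        exact_means = np.sort(grid.mean(axis=1))
        observed = flat.mean()

        def discrete_quantile(q):
            # smallest value whose cumulative probability reaches q
            cum = np.arange(1, exact_means.size + 1) / exact_means.size
            return exact_means[np.searchsorted(cum, q)]

        exact_p = (1 + 20000 * np.mean(np.abs(exact_means - observed)
                                       >= abs(observed))) / (20000 + 1)
        out = cluster_bootstrap(values, "mean", n_boot=20000, seed=4)
        assert out.estimate == pytest.approx(observed)
        assert out.ci_low == pytest.approx(discrete_quantile(0.025), abs=0.25)
        assert out.ci_high == pytest.approx(discrete_quantile(0.975), abs=0.25)
        assert out.p_value == pytest.approx(exact_p, abs=0.01)

    def test_general_path_agrees_with_fast_path(self):
        rng = np.random.default_rng(0)
        values = {i: rng.normal(size=3) for i in range(8)}
        fast = cluster_bootstrap(values, "mean", n_boot=800, seed=2)
        slow = cluster_bootstrap(values, lambda d: float(np.mean(d)),
                                 n_boot=800, seed=2)
        assert slow.estimate == pytest.approx(fast.estimate)
        assert slow.ci_low == pytest.approx(fast.ci_low, abs=1e-9)
        assert slow.p_value == pytest.approx(fast.p_value, abs=1e-12)

    def test_ci_width_scales_with_standard_error(self):
        rng = np.random.default_rng(5)
        values = {i: [v] for i, v in enumerate(rng.normal(5.0, 1.0, size=400))}
        out = cluster_bootstrap(values, "mean", n_boot=2000, seed=1)
        assert out.ci_low <= out.estimate <= out.ci_high
        width = out.ci_high - out.ci_low
        assert width == pytest.approx(2 * 1.96 / np.sqrt(400), rel=0.25)

    def test_degenerate_statistic_hits_redraw_cap(self):
        # finite on the observed (all-distinct) sample, NaN on nearly
        # every resample: the redraw budget of 10x n_boot runs out
        values = {i: [float(i)] for i in range(5)}

        def picky_mean(d):
            return float(np.mean(d)) if np.unique(d).size == 5 else float("nan")

        with pytest.raises(RuntimeError, match="degenerate"):
            cluster_bootstrap(values, picky_mean, n_boot=50, seed=0)

    def test_needs_two_patients(self):
        with pytest.raises(ValueError, match="2 patients"):
            cluster_bootstrap({"only": [1.0]}, "mean")

    def test_bca_interval_is_ordered_and_brackets_estimate(self):
        rng = np.random.default_rng(12)
        values = {i: rng.exponential(2.0, size=3) for i in range(30)}
        out = cluster_bootstrap(values, "mean", n_boot=1000, seed=3,
                                ci_method="bca")
        assert out.ci_low < out.estimate < out.ci_high


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_hand_computed_covariance_ratio(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 9.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert pearson(x, y) == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestPairedTest:
    def test_no_shift(self):
        before = {i: [float(i), float(i + 1)] for i in range(6)}
        out = paired_test(before, before, n_boot=300, seed=0)
        assert out.estimate == 0.0
        assert out.p_value == pytest.approx(1.0)

    def test_exact_constant_shift(self):
        before = {i: [float(i)] for i in range(6)}
        after = {i: [float(i) + 10.0] for i in range(6)}
        out = paired_test(before, after, n_boot=300, seed=0)
        assert out.estimate == 10.0
        assert out.ci_low == out.ci_high == 10.0
        assert out.p_value < 0.01

    def test_unmatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            paired_test({0: [1.0, 2.0]}, {0: [1.0]})

    def test_sequence_input(self):
        out = paired_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], n_boot=200, seed=1)
        assert out.estimate == pytest.approx(1.0)

    def test_ci_covers_true_shift(self):
        """Simulated widening of 32.5 ms (SD 5) in 23 patients: the CI95
        should cover the truth in roughly 95 % of repeats (percentile
        intervals undercover slightly at this n)."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            base = rng.normal(400.0, 20.0, size=23)
            shift = rng.normal(32.5, 5.0, size=23)
            out = paired_test(dict(enumerate(base)), dict(enumerate(base + shift)),
                              n_boot=500, seed=int(rng.integers(2**31)))
            hits += out.ci_low <= 32.5 <= out.ci_high
        assert 0.88 <= hits / n_rep <= 0.99


class TestRateTrend:
    def test_exact_linear_values(self):
        frame = pd.DataFrame([
            {"patient_id": f"P{i}", "rate_bpm": r, "value": 2.0 * r}
            for i in range(4) for r in (50, 60, 70, 80)])
        out = rate_trend(frame, n_boot=300, seed=0)
        assert out.slope == pytest.approx(2.0)
        assert out.ci_high - out.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_flat_profile_not_flagged(self):
        """Rate-invariant deltas (the QRS widening pattern) yield a
        near-zero slope and a non-significant trend."""
        frame = make_trend_frame(np.random.default_rng(6), n_patients=200)
        out = rate_trend(frame, n_boot=400, seed=1)
        assert abs(out.slope) < 0.05
        assert out.p_value > 0.05

    def test_high_rate_injection_detected(self):
        """A released-phase Tpeak-Tend rise confined to 100-120 bpm is
        detected as a positive rate trend."""
        frame = make_trend_frame(
            np.random.default_rng(7), n_patients=200,
            slope_by_rate={100: 6.0, 110: 10.0, 120: 14.0})
        out = rate_trend(frame, n_boot=400, seed=1)
        assert out.slope > 0.05
        assert out.p_value < 0.05

    def test_needs_three_rates(self):
        frame = pd.DataFrame([
            {"patient_id": "P0", "rate_bpm": r, "value": 1.0} for r in (50, 60)])
        with pytest.raises(ValueError, match="3 distinct rates"):
            rate_trend(frame)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], m=8) == [0.08]
        assert bonferroni([0.5], m=8) == [1.0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=12).tolist()
        assert bonferroni(p) == [min(1.0, v * 12) for v in p]

    def test_never_decreases_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20).tolist()
        adjusted = bonferroni(p, m=25)
        assert all(0.0 <= a <= 1.0 and a >= v for a, v in zip(adjusted, p))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bonferroni([1.5])
        with pytest.raises(ValueError, match="smaller"):
            bonferroni([0.1, 0.2], m=1)
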