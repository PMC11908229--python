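import numpy as np
import pytest

from lickwave import (
    BootstrapResult,
    Snip,
    SnipGrid,
    auc_epochs,
    bootstrap_mean,
    compare_groups,
    onset_offset,
    significant_runs,
)
from lickwave.errors import EmptyInputError, ExcludedSnipError, GridMismatchError
from lickwave.licking import LickBout

GRID = SnipGrid()


def result_from_ci(lo, hi, mean=None):
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    return BootstrapResult(
        mean_wave=(lo + hi) / 2 if mean is None else mean,
        ci_lower=lo,
        ci_upper=hi,
        n_boot=1000,
        alpha=0.05,
        n_snips=10,
        seed=0,
    )


def brute_force_runs(below, above, min_consecutive):
    """Exhaustive scan over all intervals for maximal qualifying runs."""
    out = []
    for sign, mask in (("below_zero", below), ("above_zero", above)):
        n = len(mask)
        for i in range(n):
            for j in range(i, n):
                if (
                    all(mask[i : j + 1])
                    and (i == 0 or not mask[i - 1])
                    and (j == n - 1 or not mask[j + 1])
                    and j - i + 1 >= min_consecutive
                ):
                    out.append((i, j, sign))
    return sorted(out)


class TestBootstrapMean:
    def test_single_snip_degenerate(self, rng):
        x = rng.normal(0, 1, 230)
        res = bootstrap_mean(x[None, :], n_boot=50, seed=0)
        np.testing.assert_allclose(res.mean_wave, x)
        np.testing.assert_allclose(res.ci_lower, x)
        np.testing.assert_allclose(res.ci_upper, x)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            bootstrap_mean(np.empty((0, 230)))

    def test_order_invariance(self, rng):
        X = rng.normal(0, 1, (40, 230))
        res1 = bootstrap_mean(X, n_boot=200, seed=5)
        res2 = bootstrap_mean(X[rng.permutation(40)], n_boot=200, seed=5)
        np.testing.assert_array_equal(res1.ci_lower, res2.ci_lower)
        np.testing.assert_array_equal(res1.ci_upper, res2.ci_upper)
        np.testing.assert_array_equal(res1.mean_wave, res2.mean_wave)

    def test_determinism_under_fixed_seed(self, rng):
        X = rng.normal(0, 1, (30, 230))
        a = bootstrap_mean(X, n_boot=300, seed=9)
        b = bootstrap_mean(X, n_boot=300, seed=9)
        np.testing.assert_array_equal(a.ci_lower, b.ci_lower)

    def test_ci_width_matches_clt(self, rng):
        # flat gaussian snips: per-bin CI width ~ 2 * 1.96 * sigma / sqrt(n)
        sigma, n = 1.0, 100
        X = rng.normal(0, sigma, (n, 230))
        res = bootstrap_mean(X, n_boot=2000, seed=1)
        width = np.mean(res.ci_upper - res.ci_lower)
        assert width == pytest.approx(2 * 1.96 * sigma / np.sqrt(n), rel=0.15)


class TestSignificantRuns:
    def test_straddling_ci_gives_no_runs(self):
        res = result_from_ci(-np.ones(230), np.ones(230))
        assert significant_runs(res) == []

    def test_consecutive_threshold_boundary(self):
        lo = -2 * np.ones(230)
        hi = -1 * np.ones(230)
        hi[:100] = 1.0
        hi[105:] = 1.0  # 5-bin excursion below zero
        assert significant_runs(result_from_ci(lo, hi)) == []
        hi[105] = -1.0  # now 6 bins
        runs = significant_runs(result_from_ci(lo, hi))
        assert len(runs) == 1
        assert (runs[0].start_bin, runs[0].end_bin, runs[0].sign) == (
            100, 105, "below_zero",
        )

    def test_touching_zero_counts_as_including_zero(self):
        hi = np.zeros(230)  # upper CI exactly 0 everywhere
        res = result_from_ci(-np.ones(230), hi)
        assert significant_runs(res) == []

    def test_matches_exhaustive_scan_on_random_cis(self, rng):
        for _ in range(100):
            lo = rng.normal(-0.1, 0.3, 40)
            hi = lo + np.abs(rng.normal(0.2, 0.2, 40))
            res = result_from_ci(lo, hi)
            mc = int(rng.integers(1, 8))
            got = sorted(
                (r.start_bin, r.end_bin, r.sign)
                for r in significant_runs(res, mc)
            )
            assert got == brute_force_runs(hi < 0, lo > 0, mc)


class TestCompareGroups:
    def test_identical_results_no_runs(self, rng):
        X = rng.normal(0, 1, (20, 230))
        res = bootstrap_mean(X, n_boot=100, seed=0)
        assert compare_groups(res, res) == []

    def test_disjoint_constant_cis_full_run(self):
        a = result_from_ci(np.full(230, 1.0), np.full(230, 2.0))
        b = result_from_ci(np.full(230, 3.0), np.full(230, 4.0))
        runs = compare_groups(a, b)
        assert len(runs) == 1
        assert (runs[0].start_bin, runs[0].end_bin) == (0, 229)
        assert runs[0].sign == "group_difference"
        # symmetric up to sign labeling
        rev = compare_groups(b, a)
        assert (rev[0].start_bin, rev[0].end_bin) == (0, 229)

    def test_grid_mismatch_raises(self):
        a = result_from_ci(np.zeros(230), np.ones(230))
        b = result_from_ci(np.zeros(100), np.ones(100))
        with pytest.raises(GridMismatchError):
            compare_groups(a, b)


class TestOnsetOffset:
    def run(self, start, end, sign):
        lo = np.zeros(230)
        hi = np.zeros(230)
        if sign == "below_zero":
            lo[start : end + 1] = -2.0
            hi[start : end + 1] = -1.0
            lo[: start] = -1; hi[:start] = 1
            lo[end + 1 :] = -1; hi[end + 1 :] = 1
        else:
            lo[start : end + 1] = 1.0
            hi[start : end + 1] = 2.0
            lo[:start] = -1; hi[:start] = 1
            lo[end + 1 :] = -1; hi[end + 1 :] = 1
        return result_from_ci(lo, hi)

    def test_onset_from_fifteenth_bin_after_start(self):
        runs = significant_runs(self.run(65, 100, "below_zero"))
        times = onset_offset(runs)
        assert times.suppression_onset_s == pytest.approx(1.5)

    def test_offset_relative_to_bout_end(self):
        # below-zero run extending to bin 157 -> suppressed 2.8 s past bout end
        runs = significant_runs(self.run(100, 157, "below_zero"))
        assert onset_offset(runs).suppression_offset_s == pytest.approx(2.8)

    def test_rebound_onset_and_missing_values(self):
        runs = significant_runs(self.run(174, 229, "above_zero"))
        times = onset_offset(runs)
        assert times.rebound_onset_s == pytest.approx(4.4)
        assert times.suppression_onset_s is None
        assert times.suppression_offset_s is None

    def test_matches_index_arithmetic_oracle(self, rng):
        for _ in range(50):
            start = int(rng.integers(0, 220))
            end = int(rng.integers(start + 6, min(start + 40, 230)) - 1)
            sign = ["below_zero", "above_zero"][int(rng.integers(2))]
            times = onset_offset(significant_runs(self.run(start, end, sign)))
            # anchor-aware left-edge arithmetic, derived independently:
            # bins before the last-2-s zone are timed from bout start,
            # later bins from bout end
            left = (start - 50) * 0.1 if start < 110 else (start - 130) * 0.1
            if sign == "below_zero":
                if start >= 50:
                    assert times.suppression_onset_s == pytest.approx(left)
                if end >= 130:
                    assert times.suppression_offset_s == pytest.approx(
                        (end + 1 - 130) * 0.1
                    )
            else:
                if start >= 130:
                    assert times.rebound_onset_s == pytest.approx(left)


class TestAucEpochs:
    def make_snip(self, values, status="included"):
        return Snip(
            values=np.asarray(values, float),
            bout=LickBout(0.0, 10.0, 60),
            status=status,
            bout_index=3,
        )

    def test_zero_snip_zero_aucs(self):
        for ea in auc_epochs(self.make_snip(np.zeros(230))):
            assert ea.auc == 0.0
            assert ea.bout_id == 3

    def test_constant_post_window(self):
        z = np.zeros(230)
        z[130:180] = 1.0
        by_epoch = {ea.epoch: ea.auc for ea in auc_epochs(self.make_snip(z))}
        # trapezoid over 50 bins of width 0.1 -> 4.9
        assert by_epoch["post_0_5"] == pytest.approx(4.9)
        assert by_epoch["post_5_10"] == pytest.approx(0.0)

    def test_piecewise_linear_matches_hand_trapezoid(self):
        z = np.zeros(230)
        z[110:130] = np.linspace(0.0, 1.9, 20)  # lick_end zone ramp
        by_epoch = {ea.epoch: ea.auc for ea in auc_epochs(self.make_snip(z))}
        ramp = np.linspace(0.0, 1.9, 20)
        hand = sum((ramp[i] + ramp[i + 1]) / 2 * 0.1 for i in range(19))
        assert by_epoch["lick_end"] == pytest.approx(hand)

    def test_excluded_snip_raises(self):
        with pytest.raises(ExcludedSnipError):
            auc_epochs(self.make_snip(np.zeros(230), status="excluded_short"))
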