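import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lickwave import (
    LickTrainParams,
    generate_lick_train,
    rm_anova_oneway,
    segment_bouts,
    session_behavior,
)
from lickwave.errors import LickwaveError


def brute_force_segment(licks, min_licks=3, gap=10.0):
    """Independent reference: explicit left-to-right cluster scan."""
    licks = list(licks)
    bouts = []
    i = 0
    while i < len(licks):
        j = i
        while j + 1 < len(licks) and licks[j + 1] - licks[j] < gap:
            j += 1
        if j - i + 1 >= min_licks:
            bouts.append((licks[i], licks[j], j - i + 1))
        i = j + 1
    return bouts


def random_train(rng, n):
    # mix of short and long gaps so clusters of every size occur
    gaps = rng.choice([0.1, 0.2, 3.0, 9.99, 10.0, 25.0], size=n, p=[0.4, 0.25, 0.1, 0.05, 0.1, 0.1])
    return np.cumsum(gaps)


class TestSegmentBouts:
    def test_three_lick_rule(self):
        bouts = segment_bouts([0.0, 0.1, 0.2, 15.0, 15.1])
        assert len(bouts) == 1
        b = bouts[0]
        assert (b.start_s, b.end_s, b.n_licks) == (0.0, 0.2, 3)

    def test_sub_threshold_gap_merges(self):
        bouts = segment_bouts([0.0, 0.1, 0.2, 9.9, 10.0])
        assert len(bouts) == 1
        assert bouts[0].n_licks == 5 and bouts[0].duration_s == pytest.approx(10.0)

    def test_exact_threshold_gap_splits(self):
        bouts = segment_bouts([0.0, 0.1, 0.2, 10.2, 10.3, 10.4])
        assert len(bouts) == 2

    def test_empty_input(self):
        assert segment_bouts([]) == []

    def test_matches_brute_force_on_random_trains(self, rng):
        for _ in range(200):
            licks = random_train(rng, int(rng.integers(0, 60)))
            got = [(b.start_s, b.end_s, b.n_licks) for b in segment_bouts(licks)]
            assert got == pytest.approx(brute_force_segment(licks))

    @given(
        gaps=st.lists(st.floats(0.05, 40.0), max_size=40),
        shift=st.floats(-1000.0, 1000.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_translation_invariance_and_conservation(self, gaps, shift):
        licks = np.cumsum(np.asarray(gaps, dtype=float))
        a = segment_bouts(licks)
        b = segment_bouts(licks + shift)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert y.start_s - x.start_s == pytest.approx(shift, abs=1e-6)
            assert x.n_licks == y.n_licks
        assert sum(x.n_licks for x in a) <= len(licks)

    @given(gaps=st.lists(st.floats(0.05, 40.0), min_size=3, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_adding_a_lick_inside_a_bout_never_splits_it(self, gaps):
        licks = np.cumsum(np.asarray(gaps, dtype=float))
        bouts = segment_bouts(licks)
        if not bouts:
            return
        b = bouts[0]
        extra = (b.start_s + b.end_s) / 2.0
        augmented = np.unique(np.append(licks, extra))
        after = segment_bouts(augmented)
        assert len(after) == len(bouts)
        match = [x for x in after if x.start_s == b.start_s]
        assert match and match[0].end_s == b.end_s

    def test_segmentation_is_idempotent_on_bout_licks(self, rng):
        licks = random_train(rng, 50)
        for b in segment_bouts(licks):
            sub = licks[(licks >= b.start_s) & (licks <= b.end_s)]
            again = segment_bouts(sub)
            assert len(again) == 1
            assert again[0].n_licks == b.n_licks


class TestSessionBehavior:
    def test_arithmetic_on_single_bout(self):
        licks = [0.0, 0.1, 0.2, 9.9, 10.0]
        beh = session_behavior(licks, segment_bouts(licks))
        assert beh.total_licks == 5
        assert beh.n_bouts == 1
        assert beh.mean_bout_length_s == pytest.approx(10.0)

    def test_empty_session(self):
        beh = session_behavior([], [])
        assert beh.total_licks == 0 and beh.n_bouts == 0
        assert math.isnan(beh.mean_bout_length_s)
        assert math.isnan(beh.lick_frequency_hz)

    def test_small_clusters_count_in_totals_not_bouts(self):
        licks = [0.0, 0.1, 50.0, 50.1, 50.2, 50.3]
        beh = session_behavior(licks, segment_bouts(licks))
        assert beh.total_licks == 6 and beh.n_bouts == 1

    def test_lick_frequency_recovers_generator_rate(self):
        params = LickTrainParams(n_bouts=20, session_length_s=1000.0)
        licks = generate_lick_train(params, seed=3)
        beh = session_behavior(licks, segment_bouts(licks))
        assert beh.lick_frequency_hz == pytest.approx(7.0, rel=0.05)


class TestRmAnova:
    def test_no_effect_gives_zero_F(self):
        table = pd.DataFrame(
            {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0], "C": [1.0, 2.0, 3.0]}
        )
        assert rm_anova_oneway(table).F == pytest.approx(0.0)

    def test_degrees_of_freedom_for_14_mice_4_conditions(self, rng):
        table = pd.DataFrame(rng.normal(size=(14, 4)), columns=list("ABCD"))
        res = rm_anova_oneway(table)
        assert (res.df1, res.df2) == (3, 39)

    def test_matches_hand_computed_sums_of_squares(self):
        X = np.array(
            [[3.0, 5.0, 4.0], [2.0, 4.0, 6.0], [5.0, 7.0, 6.0], [4.0, 8.0, 9.0]]
        )
        # textbook decomposition, written out independently
        grand = X.mean()
        ss_cond = sum(len(X) * (X[:, j].mean() - grand) ** 2 for j in range(3))
        ss_subj = sum(3 * (X[i].mean() - grand) ** 2 for i in range(4))
        ss_err = sum(
            (X[i, j] - X[i].mean() - X[:, j].mean() + grand) ** 2
            for i in range(4)
            for j in range(3)
        )
        F_ref = (ss_cond / 2) / (ss_err / 6)
        res = rm_anova_oneway(pd.DataFrame(X, columns=list("abc")))
        assert res.F == pytest.approx(F_ref, rel=1e-12)
        assert res.ss_condition == pytest.approx(ss_cond)
        assert res.ss_error == pytest.approx(ss_err)

    def test_agrees_with_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        n, k = 8, 4
        values = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "condition": np.tile(list("WXYZ"), n),
                "value": values.ravel(),
            }
        )
        res = rm_anova_oneway(long, "subject", "condition", "value")
        ref = AnovaRM(long, "value", "subject", within=["condition"]).fit()
        assert res.F == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-8
        )

    def test_missing_cell_raises(self):
        long = pd.DataFrame(
            {"subject": [0, 0, 1], "condition": ["A", "B", "A"], "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(LickwaveError):
            rm_anova_oneway(long, "subject", "condition", "value")
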