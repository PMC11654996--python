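"""Questionnaire aggregation, pain deltas, and normality-gated paired tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiosync import (MissingDataError, aggregate_ssq, aggregate_sus,
                        compute_pain_deltas, ownership_contrast,
                        paired_condition_test, signed_rank_statistic,
                        simulate_ownership, simulate_pain_measures,
                        simulate_questionnaires)


class TestQuestionnaires:
    def test_sus_composite_from_published_item_means(self):
        # item means 4.54 / 4.36 / 4.36 -> composite 4.42
        assert aggregate_sus([4.54, 4.36, 4.36]).group_mean == \
            pytest.approx(4.42, abs=5e-3)

    @pytest.mark.parametrize("value,expected", [(3, 3.0), (5, 5.0)])
    def test_sus_constant_items(self, value, expected):
        assert aggregate_sus([value] * 3).group_mean == expected

    @pytest.mark.parametrize("items,expected", [
        ([1] * 7, 1.0),
        ([1, 1, 2, 1, 1, 1, 1], 8 / 7),
        ([4] * 7, 4.0),
    ])
    def test_ssq_composites(self, items, expected):
        assert aggregate_ssq(items).group_mean == pytest.approx(expected)

    def test_out_of_range_items_rejected(self):
        with pytest.raises(ValueError):
            aggregate_sus([0, 3, 3])
        with pytest.raises(ValueError):
            aggregate_ssq([1, 1, 5, 1, 1, 1, 1])

    def test_group_mean_is_order_invariant(self):
        q = simulate_questionnaires(seed=3)
        items = q[["sus_1", "sus_2", "sus_3"]].to_numpy()
        shuffled = items[np.random.default_rng(0).permutation(len(items))]
        assert aggregate_sus(items).group_mean == \
            pytest.approx(aggregate_sus(shuffled).group_mean)


def _pain_rows(participant, condition, blocks, instrument, site, pre, post):
    """Two-block bilateral rows with per-block (pre, post) scalars."""
    rows = []
    for block, (p0, p1) in zip(blocks, zip(pre, post)):
        for phase, v in (("pre", p0), ("post", p1)):
            for side in ("left", "right"):
                rows.append({"participant": participant, "block": block,
                             "condition": condition, "phase": phase,
                             "instrument": instrument, "site": site,
                             "side": side, "value": v})
    return rows


class TestPainDeltas:
    def test_no_change_gives_zero_deltas(self):
        df = pd.DataFrame(
            _pain_rows(1, "sync", [1, 3], "algopeg", "finger",
                       pre=[3.0, 3.0], post=[3.0, 3.0])
            + _pain_rows(1, "async", [2, 4], "algopeg", "finger",
                         pre=[4.0, 4.0], post=[4.0, 4.0]))
        out = compute_pain_deltas(df)
        assert np.allclose(out["delta"], 0.0)

    def test_algopeg_condition_delta_is_block_mean(self):
        # block deltas -0.1 and +0.064 average to -0.018
        df = pd.DataFrame(
            _pain_rows(1, "sync", [1, 3], "algopeg", "finger",
                       pre=[3.0, 3.0], post=[2.9, 3.064]))
        out = compute_pain_deltas(df)
        assert out.loc[0, "delta"] == pytest.approx(-0.018)

    def test_somedic_sign_convention_threshold_drop_positive(self):
        # threshold falls 350 -> 300 kPa: MORE sensitive, delta = +50
        df = pd.DataFrame(
            _pain_rows(1, "sync", [1, 3], "somedic", "finger",
                       pre=[350.0, 350.0], post=[300.0, 300.0]))
        out = compute_pain_deltas(df)
        assert out.loc[0, "delta"] == pytest.approx(50.0)

    def test_hyperalgesia_positive_for_both_instruments(self):
        # ratings up AND thresholds down must both give positive deltas
        df = pd.DataFrame(
            _pain_rows(1, "sync", [1, 3], "algopeg", "finger",
                       pre=[3.0, 3.0], post=[3.5, 3.5])
            + _pain_rows(1, "sync", [1, 3], "somedic", "finger",
                         pre=[350.0, 350.0], post=[330.0, 330.0]))
        out = compute_pain_deltas(df)
        assert np.all(out["delta"] > 0)

    def test_missing_side_raises_with_offending_keys(self):
        df = pd.DataFrame(
            _pain_rows(1, "sync", [1, 3], "algopeg", "finger",
                       pre=[3.0, 3.0], post=[3.0, 3.0]))
        df = df[~((df["side"] == "left") & (df["phase"] == "post")
                  & (df["block"] == 3))]
        with pytest.raises(MissingDataError) as exc:
            compute_pain_deltas(df)
        assert any("post" in str(k) for k in exc.value.missing_keys)

    def test_simulated_study_table_is_complete(self):
        out = compute_pain_deltas(simulate_pain_measures(seed=0))
        # 20 participants x 2 conditions x 3 instrument-site combinations
        assert len(out) == 120
        assert set(out["condition"]) == {"sync", "async"}


class TestPairedConditionTest:
    def test_identical_vectors_degenerate(self):
        x = np.arange(10.0)
        rep = paired_condition_test(x, x)
        assert rep.branch == "degenerate"

    def test_normal_data_takes_t_branch(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        rep = paired_condition_test(x, x + rng.normal(0, 1, 20))
        assert rep.branch == "t"
        assert rep.normality_p is not None and rep.normality_p > 0.05

    def test_skewed_differences_select_wilcoxon(self):
        rng = np.random.default_rng(2)
        chosen = []
        for _ in range(100):
            y = rng.normal(0, 1, 40)
            x = y + rng.lognormal(0, 1.5, 40)  # heavily skewed shift
            chosen.append(paired_condition_test(x, y).branch)
        assert chosen.count("wilcoxon") >= 95

    def test_rejection_rate_matches_textbook_t_test(self):
        # power under a true shift of 0.5 SD, n=20, alpha 0.05 one-sided;
        # oracle: t = mean(d) / (sd(d)/sqrt(n)) against Student's t
        rng = np.random.default_rng(3)
        n, reps = 20, 2000
        mine = oracle = 0
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            x = y + rng.normal(-0.5, 1.0, n)  # sync lower by 0.5 SD
            rep = paired_condition_test(x, y, alternative="less")
            mine += rep.p_value < 0.05
            d = x - y  # oracle on the same draws the pipeline sees
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            oracle += stats.t.cdf(t, n - 1) < 0.05
        assert abs(mine - oracle) / reps <= 0.03

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_condition_test([1.0, 2.0], [2.0, 1.0])


def _enumerated_signed_rank(diffs):
    """Independent W+ via explicit sorting-based ranks (Pratt zeros)."""
    d = list(diffs)
    order = sorted(range(len(d)), key=lambda i: abs(d[i]))
    ranks = [0.0] * len(d)
    i = 0
    while i < len(order):
        j = i
        while (j + 1 < len(order)
               and abs(d[order[j + 1]]) == abs(d[order[i]])):
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return sum(r for r, v in zip(ranks, d) if v > 0)


class TestOwnershipContrast:
    def test_identical_conditions_degenerate(self):
        rep = ownership_contrast([2.0, 3.0, 0.0], [2.0, 3.0, 0.0])
        assert rep.branch == "degenerate"

    def test_statistic_matches_enumeration_oracle(self):
        sync = [3.0, 4.0, 2.0, 5.0, 0.0]
        asyn = [1.0, 2.0, 2.0, 1.0, 0.0]
        rep = ownership_contrast(sync, asyn)
        d = np.subtract(sync, asyn)
        assert rep.statistic == _enumerated_signed_rank(d)
        assert signed_rank_statistic(d) == _enumerated_signed_rank(d)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_samples_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sync = rng.integers(0, 7, 8).astype(float)
        asyn = rng.integers(0, 7, 8).astype(float)
        if np.all(sync == asyn):
            return
        rep = ownership_contrast(sync, asyn)
        assert rep.statistic == _enumerated_signed_rank(sync - asyn)

    def test_uniform_positive_shift_is_maximal(self):
        asyn = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rep = ownership_contrast(asyn + 1.0, asyn)
        n = len(asyn)
        assert rep.statistic == n * (n + 1) / 2

    def test_simulated_ownership_near_floor(self):
        own = simulate_ownership(seed=4)
        items = [c for c in own.columns if c.startswith("own_")]
        scores = own[items].mean(axis=1)
        assert np.median(scores) <= 1.0
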