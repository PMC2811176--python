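"""Scan statistics: paired tests, states, ranking, permutation null, thresholds."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from helpscan import diffscan
from helpscan.diffscan import (
    PermutationNull,
    RankingConfig,
    call_state,
    paired_t_scan,
    perm_locus_pvalues,
    permutation_null,
    rank_scores,
    select_candidates,
    significance_threshold,
)

from conftest import make_matrix, make_sample_table


def closed_form_paired_t(diffs):
    """Independent paired-t oracle: closed-form t and regularized beta p."""
    d = np.asarray(diffs, dtype=float)
    k = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(k))
    df = k - 1
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


class TestCallState:
    @pytest.mark.parametrize(
        "ratio,state",
        [
            (2.06, "hypomethylated"),   # high ratio: HpaII representation enriched
            (-1.29, "methylated"),
            (0.0, "boundary"),
            (0.51, "hypomethylated"),
            (-1e-12, "methylated"),
        ],
    )
    def test_zero_threshold_rule(self, ratio, state):
        assert call_state(ratio) == state

    def test_missing_ratio_missing_state(self):
        assert call_state(float("nan")) is None
        assert call_state(None) is None


class TestPairedTScan:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 3))
        m = make_matrix(np.hstack([vals, vals]), ["case_1", "case_2", "case_3", "ctrl_1", "ctrl_2", "ctrl_3"])
        stats = paired_t_scan(m, make_sample_table(3))
        assert (stats["t"] == 0).all()
        assert (stats["p"] == 1).all()

    def test_difference_is_case_minus_control(self):
        # group means 2.56 and 3.34 -> difference -0.78
        case = np.array([2.50, 2.60, 2.58])
        ctrl = np.array([3.30, 3.40, 3.32])
        case = case - case.mean() + 2.56
        ctrl = ctrl - ctrl.mean() + 3.34
        m = make_matrix(
            np.array([np.concatenate([case, ctrl])]),
            ["case_1", "case_2", "case_3", "ctrl_1", "ctrl_2", "ctrl_3"],
        )
        stats = paired_t_scan(m, make_sample_table(3))
        assert stats["difference"].iloc[0] == pytest.approx(-0.78, abs=1e-9)

    def test_matches_closed_form_oracle(self):
        diffs = np.array([0.5, 0.6, 0.7, 0.55, 0.65])
        ctrl = np.zeros(5)
        m = make_matrix(
            np.array([np.concatenate([ctrl + diffs, ctrl])]),
            [f"case_{i+1}" for i in range(5)] + [f"ctrl_{i+1}" for i in range(5)],
        )
        stats = paired_t_scan(m, make_sample_table(5))
        t_ref, p_ref = closed_form_paired_t(diffs)
        assert stats["t"].iloc[0] == pytest.approx(t_ref, rel=1e-12)
        assert stats["p"].iloc[0] == pytest.approx(p_ref, rel=1e-9)

    def test_pair_shift_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(30, 8))
        ids = [f"case_{i+1}" for i in range(4)] + [f"ctrl_{i+1}" for i in range(4)]
        m1 = make_matrix(vals, ids)
        shifted = vals.copy()
        # add a constant to both members of pair 2 (case_2, ctrl_2)
        shifted[:, 1] += 3.7
        shifted[:, 5] += 3.7
        m2 = make_matrix(shifted, ids)
        table = make_sample_table(4)
        s1, s2 = paired_t_scan(m1, table), paired_t_scan(m2, table)
        np.testing.assert_allclose(s1["t"], s2["t"])
        np.testing.assert_allclose(s1["p"], s2["p"])
        r1 = rank_scores(m1, table)
        r2 = rank_scores(m2, table)
        np.testing.assert_allclose(r1, r2)

    def test_states_follow_group_means(self):
        m = make_matrix(
            np.array([[1.0, 2.0, -1.0, -2.0], [-1.0, -2.0, 1.0, 2.0]]),
            ["case_1", "case_2", "ctrl_1", "ctrl_2"],
        )
        stats = paired_t_scan(m, make_sample_table(2))
        assert list(stats["state_case"]) == ["hypomethylated", "methylated"]
        assert list(stats["state_control"]) == ["methylated", "hypomethylated"]

    def test_incomplete_pairs_dropped_per_locus(self):
        vals = np.array([[1.0, 2.0, np.nan, 0.5, 1.0, 2.0]])
        m = make_matrix(vals, ["case_1", "case_2", "case_3", "ctrl_1", "ctrl_2", "ctrl_3"])
        stats = paired_t_scan(m, make_sample_table(3))
        assert stats["n_complete_pairs"].iloc[0] == 2

    def test_fewer_than_two_complete_pairs_missing(self):
        vals = np.array([[1.0, np.nan, 0.5, np.nan]])
        m = make_matrix(vals, ["case_1", "case_2", "ctrl_1", "ctrl_2"])
        stats = paired_t_scan(m, make_sample_table(2))
        assert np.isnan(stats["t"].iloc[0]) and np.isnan(stats["p"].iloc[0])

    def test_degenerate_constant_offset_flagged(self):
        # all pair differences identical and nonzero: sd = 0, t undefined
        m = make_matrix(
            np.array([[1.5, 2.5, 3.5, 1.0, 2.0, 3.0]]),
            ["case_1", "case_2", "case_3", "ctrl_1", "ctrl_2", "ctrl_3"],
        )
        stats = paired_t_scan(m, make_sample_table(3))
        assert stats["degenerate"].iloc[0]
        assert np.isnan(stats["p"].iloc[0])

    def test_unpaired_sample_rejected(self):
        m = make_matrix(np.zeros((3, 3)), ["case_1", "ctrl_1", "case_2"])
        with pytest.raises(ValueError):
            paired_t_scan(m, make_sample_table(2))


class TestRankScores:
    def _toy(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(5, 5))
        shift = np.array([[0.0], [0.5], [1.0], [0.2], [2.0]])
        noise = rng.normal(0.0, 0.3, size=(5, 5))
        vals = np.hstack([base + shift + noise, base])
        ids = [f"case_{i+1}" for i in range(5)] + [f"ctrl_{i+1}" for i in range(5)]
        return make_matrix(vals, ids), make_sample_table(5)

    def test_zero_mean_difference_scores_zero(self):
        m = make_matrix(
            np.array([[1.0, -1.0, 0.0, 0.0]]), ["case_1", "case_2", "ctrl_1", "ctrl_2"]
        )
        assert rank_scores(m, make_sample_table(2), RankingConfig(s0=0.0)).iloc[0] == 0.0

    def test_scale_behaviour_of_s0(self):
        # with s0 = 0 the score is a pure ratio: doubling every pair
        # difference rescales numerator and denominator alike (t-like
        # scale invariance); with s0 > 0 the doubled data must score
        # strictly higher (the fold-change weighting)
        m, table = self._toy()
        vals = m.values.to_numpy()
        doubled = make_matrix(
            np.hstack([vals[:, 5:] + 2 * (vals[:, :5] - vals[:, 5:]), vals[:, 5:]]),
            m.samples,
        )
        s1 = rank_scores(m, table, RankingConfig(s0=0.0))
        s2 = rank_scores(doubled, table, RankingConfig(s0=0.0))
        np.testing.assert_allclose(s2, s1)
        w1 = rank_scores(m, table, RankingConfig(s0=0.5))
        w2 = rank_scores(doubled, table, RankingConfig(s0=0.5))
        nonzero = w1 > 0
        assert (w2[nonzero] > w1[nonzero]).all()

    def test_matches_brute_force_formula(self):
        m, table = self._toy()
        scores = rank_scores(m, table)  # default s0 = median sd
        diffs = m.values.to_numpy()[:, :5] - m.values.to_numpy()[:, 5:]
        sd = diffs.std(axis=1, ddof=1)
        s0 = np.median(sd)
        expect = np.abs(diffs.mean(axis=1)) / (sd + s0)
        np.testing.assert_allclose(scores.to_numpy(), expect)
        assert list(scores.sort_values(ascending=False).index) == list(
            pd.Series(expect, index=scores.index).sort_values(ascending=False).index
        )

    def test_zero_spread_zero_s0_ranks_first(self):
        m = make_matrix(
            np.array([[2.0, 3.0, 1.0, 2.0], [1.0, 2.5, 0.0, 1.0]]),
            ["case_1", "case_2", "ctrl_1", "ctrl_2"],
        )
        scores = rank_scores(m, make_sample_table(2), RankingConfig(s0=0.0))
        assert np.isinf(scores.iloc[0])  # constant nonzero differences

    def test_negative_s0_rejected(self):
        with pytest.raises(ValueError):
            RankingConfig(s0=-0.1)


class TestPermutationNull:
    def _cohort(self, n_loci=40, k=3, seed=2):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n_loci, 2 * k))
        ids = [f"case_{i+1}" for i in range(k)] + [f"ctrl_{i+1}" for i in range(k)]
        return make_matrix(vals, ids), make_sample_table(k)

    def test_exhaustive_k3_has_seven_patterns(self):
        m, table = self._cohort(k=3)
        null = permutation_null(m, table, n_perm=100, seed=0)
        assert null.exhaustive and null.n_perm == 7

    def test_identity_pattern_reproduces_observed(self):
        m, table = self._cohort(k=4)
        observed = paired_t_scan(m, table)
        # evaluating the identity sign pattern explicitly equals the scan
        diffs, _, _ = diffscan._paired_diffs(m, table)
        t, p, _, _, _ = diffscan._t_from_diffs(diffs * 1.0)
        np.testing.assert_allclose(p, observed["p"])

    def test_min_p_consistent_with_p_matrix(self):
        m, table = self._cohort(k=3)
        null = permutation_null(m, table, n_perm=100, seed=0)
        np.testing.assert_allclose(null.min_p, null.p_matrix.min(axis=1))

    def test_perm_pvalues_match_exhaustive_oracle_k5(self):
        m, table = self._cohort(n_loci=25, k=5, seed=9)
        observed = paired_t_scan(m, table)
        null = permutation_null(m, table, n_perm=31, seed=0)
        assert null.exhaustive
        got = perm_locus_pvalues(observed, null)
        # brute force: all 2^5 sign patterns including the identity
        diffs, _, _ = diffscan._paired_diffs(m, table)
        for i in range(25):
            d = diffs[i]
            t_obs = abs(d.mean() / (d.std(ddof=1) / np.sqrt(5)))
            count = 0
            for pattern in itertools.product([1.0, -1.0], repeat=5):
                pd_ = d * np.array(pattern)
                t_perm = abs(pd_.mean() / (pd_.std(ddof=1) / np.sqrt(5)))
                if t_perm >= t_obs - 1e-12:
                    count += 1
            assert got.iloc[i] == pytest.approx(count / 32.0, abs=1e-12)

    def test_sampled_scheme_excludes_sign_equivalent_patterns(self):
        m, table = self._cohort(k=10)
        null = permutation_null(m, table, n_perm=50, seed=1)
        assert not null.exhaustive and null.n_perm == 50

    def test_full_relabel_runs_unpaired(self):
        m, table = self._cohort(k=3)
        null = permutation_null(m, table, n_perm=20, scheme="full_relabel", seed=4)
        assert null.n_perm == 20
        assert np.isfinite(null.min_p).all()

    def test_bad_arguments(self):
        m, table = self._cohort(k=3)
        with pytest.raises(ValueError):
            permutation_null(m, table, n_perm=0)
        with pytest.raises(ValueError):
            permutation_null(m, table, n_perm=10, scheme="bogus")


class TestSignificanceThreshold:
    def _null(self, min_p):
        return PermutationNull(scheme="full_relabel", n_perm=1, seed=0, min_p=np.array([min_p]))

    @pytest.mark.parametrize(
        "floor,expected",
        [
            (1.5e-5, 1e-5),   # the calibrated genome-wide choice
            (0.04, 1e-2),
            (1.0, 0.5),
            (6e-3, 5e-3),
            (0.2, 0.1),
        ],
    )
    def test_ladder_rule(self, floor, expected):
        stats = pd.DataFrame({"p": [0.5]})
        alpha, observed_floor = significance_threshold(stats, self._null(floor))
        assert alpha == pytest.approx(expected)
        assert observed_floor == pytest.approx(floor)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(
                pd.DataFrame({"p": [0.5]}),
                PermutationNull(scheme="x", n_perm=0, seed=0, min_p=np.array([])),
            )


class TestSelectCandidates:
    def _stats(self, ps, diffs=None):
        n = len(ps)
        return pd.DataFrame(
            {
                "p": ps,
                "difference": diffs if diffs is not None else np.linspace(-1, 1, n),
            },
            index=[f"chr1:{i*100+1}-{i*100+50}" for i in range(n)],
        )

    def test_all_p_one_no_candidates(self):
        sel = select_candidates(self._stats([1.0] * 5), 1e-5, 1e-4)
        assert len(sel["significant"]) == 0 and len(sel["moderate"]) == 0

    def test_tier_counts_match_hand_count(self):
        rng = np.random.default_rng(10)
        ps = rng.uniform(size=20)
        ps[:3] = [1e-6, 5e-7, 2e-6]
        ps[3:8] = [2e-5, 5e-5, 9e-5, 3e-5, 8e-5]
        sel = select_candidates(self._stats(list(ps)), 1e-5, 1e-4)
        assert len(sel["significant"]) == 3
        assert len(sel["moderate"]) == 5
        assert sel["histogram"]["count"].sum() == 20

    def test_sorted_by_p_then_absolute_difference(self):
        stats = self._stats([1e-6, 1e-6, 1e-7], diffs=[0.2, -0.9, 0.1])
        sel = select_candidates(stats, 1e-5, 1e-4)
        assert list(sel["significant"]["p"]) == [1e-7, 1e-6, 1e-6]
        assert abs(sel["significant"]["difference"].iloc[1]) == 0.9

    def test_monotone_in_alpha_star(self):
        rng = np.random.default_rng(11)
        stats = self._stats(list(rng.uniform(size=50) ** 3))
        prev: set = set()
        for alpha in [1e-4, 1e-3, 1e-2, 0.1]:
            sig = set(select_candidates(stats, alpha, 0.5)["significant"].index)
            assert prev <= sig  # raising the threshold never removes a candidate
            prev = sig

    def test_bad_moderate_alpha(self):
        with pytest.raises(ValueError):
            select_candidates(self._stats([0.5]), 1e-4, 1e-5)
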