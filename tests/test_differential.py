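"""Effect estimators, Skillings-Mack and sensitivity tests, selection logic."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evmirna.differential import (
    PairedSeries,
    cross_receptor_sets,
    fold_change,
    group_means_effect,
    matched_pairs_effect,
    rank_and_select,
    rank_sum_test,
    results_frame,
    sensitivity_grid,
    sign_flip_permutation_test,
    skillings_mack,
    skillings_mack_test,
    welch_test,
    zscore_log2fc,
)
from evmirna.exceptions import ContractError, UndefinedTestError


def series_from_diffs(diffs, base=5.0):
    """Complete pairs with the requested trt-vc ΔCq differences."""
    return PairedSeries(
        "m", [(i, base + d, base) for i, d in enumerate(diffs, 1)]
    )


def pair_regression_oracle(pairs):
    """Treatment coefficient of ΔCq ~ treatment + pair dummies on complete pairs."""
    complete = [(t, v) for _, t, v in pairs if not np.isnan(t) and not np.isnan(v)]
    n = len(complete)
    y = np.array([x for t, v in complete for x in (t, v)])
    treat = np.tile([1.0, 0.0], n)
    dummies = np.repeat(np.eye(n), 2, axis=0)
    X = np.column_stack([treat, dummies])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[0]


class TestMatchedPairs:
    def test_hand_example_and_regression_oracle(self):
        s = series_from_diffs([-1.0, -1.4, -0.8])
        r = matched_pairs_effect(s)
        assert r.ddcq == pytest.approx(-1.0667, abs=5e-5)
        assert r.log2fc == pytest.approx(1.0667, abs=5e-5)
        assert r.fc == pytest.approx(2.095, abs=5e-4)
        assert r.sd_log2fc == pytest.approx(0.306, abs=5e-4)
        assert r.ddcq == pytest.approx(pair_regression_oracle(s.pairs), abs=1e-9)

    def test_identical_arms_give_null_effect(self):
        r = matched_pairs_effect(series_from_diffs([0.0, 0.0, 0.0]))
        assert r.ddcq == 0.0 and r.fc == 1.0

    def test_incomplete_pair_dropped_from_estimation(self):
        s = PairedSeries("m", [(1, 5.0, 6.0), (2, 4.0, np.nan)])
        r = matched_pairs_effect(s)
        assert r.ddcq == pytest.approx(-1.0) and r.n_pairs_complete == 1

    def test_zero_complete_pairs_missing_with_reason(self):
        s = PairedSeries("m", [(1, 5.0, np.nan), (2, np.nan, 4.0)])
        r = matched_pairs_effect(s)
        assert np.isnan(r.ddcq) and r.reason == "no_complete_pairs"

    def test_regression_oracle_on_random_incomplete_series(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pairs = []
            for i in range(6):
                t, v = rng.normal(size=2)
                if rng.random() < 0.2:
                    t = np.nan
                pairs.append((i, t, v))
            s = PairedSeries("m", pairs)
            if s.complete_diffs.size == 0:
                continue
            assert matched_pairs_effect(s).ddcq == pytest.approx(
                pair_regression_oracle(s.pairs), abs=1e-9
            )


class TestGroupMeans:
    def test_agrees_with_matched_pairs_on_complete_data(self):
        rng = np.random.default_rng(3)
        pairs = [(i, rng.normal(), rng.normal()) for i in range(6)]
        s = PairedSeries("m", pairs)
        assert group_means_effect(s).ddcq == pytest.approx(
            matched_pairs_effect(s).ddcq, abs=1e-12
        )

    def test_unbalanced_arms(self):
        s = PairedSeries("m", [(1, 3.0, 4.0), (2, 5.0, np.nan)])
        assert group_means_effect(s).ddcq == pytest.approx(0.0)

    def test_empty_arm_missing(self):
        s = PairedSeries("m", [(1, 3.0, np.nan), (2, 5.0, np.nan)])
        r = group_means_effect(s)
        assert np.isnan(r.ddcq) and r.reason == "empty_arm"


@pytest.mark.parametrize(
    "ddcq,fc",
    [(0.0, 1.0), (-0.585, 1.5), (1.0, 0.5)],
)
def test_fold_change_identities(ddcq, fc):
    got_fc, got_lfc = fold_change(ddcq)
    assert got_fc == pytest.approx(fc, abs=5e-4)
    assert got_lfc == -ddcq
    assert got_fc * 2**ddcq == pytest.approx(1.0, abs=1e-12)


class TestSkillingsMack:
    @pytest.mark.parametrize("n,p4", [(4, 0.0455), (5, 0.0253), (6, 0.0143)])
    def test_unanimous_two_treatment_blocks(self, n, p4):
        """SM = n with the closed-form chi-square(1) tail p-values."""
        res = skillings_mack([[1.0, 2.0]] * n)
        assert res.statistic == pytest.approx(n, abs=1e-9)
        assert res.df == 1 and res.n_blocks_used == n
        assert round(res.p, 4) == p4

    def test_single_observation_block_contributes_nothing(self):
        full = skillings_mack([[1.0, 2.0]] * 4)
        extra = skillings_mack([[1.0, 2.0]] * 4 + [[7.0, np.nan]])
        assert extra.statistic == pytest.approx(full.statistic, abs=1e-12)
        assert extra.n_blocks_used == 4

    def test_reduces_to_friedman_on_complete_blocks(self):
        def friedman_oracle(data):
            # classical Friedman statistic from per-block rank sums (no ties)
            n, k = data.shape
            ranks = np.argsort(np.argsort(data, axis=1), axis=1) + 1.0
            rank_sums = ranks.sum(axis=0)
            return 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3 * n * (k + 1)

        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(3, 9))
            # per-block random permutations of distinct values: no ties
            data = np.array([rng.permutation(k).astype(float) for _ in range(n)])
            sm = skillings_mack(data)
            assert sm.statistic == pytest.approx(friedman_oracle(data), abs=1e-9)
            if k >= 3:  # scipy's Friedman needs at least three treatments
                fr = stats.friedmanchisquare(*(data[:, j] for j in range(k)))
                assert sm.statistic == pytest.approx(fr.statistic, abs=1e-9)
                assert sm.p == pytest.approx(fr.pvalue, abs=1e-9)

    def test_monte_carlo_null_matches_asymptotic_direction(self):
        data = [[1.0, 2.0]] * 6
        mc = skillings_mack(data, method="MONTE_CARLO", n_sim=2000, seed=1)
        assert mc.method == "MONTE_CARLO"
        # the discrete two-treatment null puts mass 2/2^6 on unanimity
        assert mc.p == pytest.approx(2 / 64, abs=3 * np.sqrt(0.03 * 0.97 / 2000))

    def test_mid_ranks_for_ties(self):
        # a tied block ranks both treatments 1.5 -> contributes zero
        res = skillings_mack([[1.0, 1.0]] + [[1.0, 2.0]] * 3)
        assert res.statistic == pytest.approx(9 / 4, abs=1e-12)

    def test_all_degenerate_blocks_undefined(self):
        with pytest.raises(UndefinedTestError):
            skillings_mack([[1.0, np.nan], [np.nan, 2.0]])

    def test_series_wrapper(self):
        s = series_from_diffs([-1, -2, -0.5, -1.2, -0.1, -3])
        assert skillings_mack_test(s).p == pytest.approx(0.0143, abs=5e-5)


class TestSignFlip:
    def test_exact_enumeration_example(self):
        assert sign_flip_permutation_test(series_from_diffs([-1, -2, -3])) == 0.25

    def test_all_zero_diffs(self):
        assert sign_flip_permutation_test(series_from_diffs([0.0, 0.0])) == 1.0

    def test_scale_invariance(self):
        d = [-1.0, 0.4, -2.2, -0.7]
        p1 = sign_flip_permutation_test(series_from_diffs(d))
        p2 = sign_flip_permutation_test(series_from_diffs([x * 7.3 for x in d]))
        assert p1 == p2

    def test_monte_carlo_converges_to_exact(self):
        d = [-1.0, 0.4, -2.2, -0.7, -1.5, -0.2]
        s = series_from_diffs(d)
        exact = sign_flip_permutation_test(s)
        n_perm = 100_000
        mc = sign_flip_permutation_test(s, n_perm=n_perm, seed=9, exact=False)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) <= 3 * se

    def test_no_complete_pairs_undefined(self):
        with pytest.raises(UndefinedTestError):
            sign_flip_permutation_test(PairedSeries("m", [(1, 1.0, np.nan)]))


class TestRankSumAndWelch:
    def test_rank_sum_exact_example(self):
        s = PairedSeries("m", [(1, 1.0, 4.0), (2, 2.0, 5.0), (3, 3.0, 6.0)])
        assert rank_sum_test(s) == pytest.approx(0.1, abs=1e-12)

    def test_rank_sum_identical_arms(self):
        s = PairedSeries("m", [(i, float(i), float(i)) for i in range(1, 4)])
        assert rank_sum_test(s) == pytest.approx(1.0)

    def test_rank_sum_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, 2))
        s1 = PairedSeries("m", [(i, t, v) for i, (t, v) in enumerate(vals)])
        s2 = PairedSeries("m", [(i, np.exp(t), np.exp(v)) for i, (t, v) in enumerate(vals)])
        assert rank_sum_test(s1) == pytest.approx(rank_sum_test(s2), abs=1e-12)

    def test_welch_equal_arms(self):
        s = PairedSeries("m", [(i, float(i), float(i)) for i in range(1, 5)])
        assert welch_test(s) == pytest.approx(1.0)

    def test_welch_closed_form_oracle(self):
        s = PairedSeries("m", [(1, 0.0, 10.0), (2, 1.0, 11.0)])
        # t = -10/sqrt(0.25+0.25) = -14.142..., Welch-Satterthwaite df = 2
        t = -10 / np.sqrt(0.5)
        expected = 2 * stats.t.sf(abs(t), 2)
        assert welch_test(s) == pytest.approx(expected, abs=1e-12)

    def test_welch_degenerate_zero_variance(self):
        same = PairedSeries("m", [(1, 2.0, 2.0), (2, 2.0, 2.0)])
        assert welch_test(same) == 1.0
        apart = PairedSeries("m", [(1, 2.0, 5.0), (2, 2.0, 5.0)])
        with pytest.warns(UserWarning, match="zero variance"):
            assert welch_test(apart) == 0.0


class TestSensitivityGrid:
    def test_default_grid_shape_and_agreement_on_complete_data(self):
        rng = np.random.default_rng(8)
        s = PairedSeries("m", [(i, rng.normal(), rng.normal()) for i in range(6)])
        grid = sensitivity_grid(s, seed=1)
        assert len(grid) == 2  # estimators
        p_cols = [c for c in grid.columns if c.startswith("p_")]
        assert set(p_cols) == {"p_skillings_mack", "p_sign_flip", "p_welch", "p_rank_sum"}
        # six (estimator x test) cells in the default grid
        assert len(grid) * 3 == 6
        assert grid["ddcq"].iloc[0] == pytest.approx(grid["ddcq"].iloc[1], abs=1e-12)

    def test_unanimous_toy_closed_forms(self):
        s = series_from_diffs([-1, -2, -0.5, -1.2, -0.1, -3])
        grid = sensitivity_grid(s, seed=1)
        assert grid["p_skillings_mack"].iloc[0] == pytest.approx(0.0143, abs=5e-5)
        assert grid["p_sign_flip"].iloc[0] == pytest.approx(2 / 64, abs=1e-12)

    def test_empty_grid_rejected(self):
        s = series_from_diffs([-1, 1])
        with pytest.raises(ContractError):
            sensitivity_grid(s, estimators=(), tests=())


class TestZScore:
    def test_simple_vector(self):
        assert zscore_log2fc([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_vector_warns_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            assert (zscore_log2fc([2.0, 2.0, 2.0]) == 0).all()

    def test_output_standardized_and_missing_propagates(self):
        x = [1.0, np.nan, 2.0, 4.0]
        z = zscore_log2fc(x)
        assert np.isnan(z[1])
        finite = z[np.isfinite(z)]
        assert finite.mean() == pytest.approx(0.0, abs=1e-12)
        assert finite.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestSelection:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["assay_id", "ddcq", "log2fc", "p_sm"]).assign(
            fc=lambda f: 2 ** f["log2fc"]
        )

    def test_threshold_boundaries(self):
        frame = self.frame([
            ("a", -0.60, 0.60, 0.19),    # discovery + enrichment, not significant
            ("b", -0.585, 0.585, 0.20),  # enrichment only (p not < 0.2)
            ("c", 0.90, -0.90, 0.0143),  # all three
            ("d", -0.30, 0.30, 0.50),    # none
        ])
        sel = rank_and_select(frame)
        assert sel.discovery == ["a", "c"]
        assert sel.enrichment == ["a", "b", "c"]
        assert sel.significant == ["c"]
        assert set(sel.significant) <= set(sel.discovery)

    def test_ranking_by_effect_magnitude_with_lexicographic_ties(self):
        frame = self.frame([
            ("z", 0.5, -0.5, 0.5), ("a", -0.5, 0.5, 0.5), ("m", 1.0, -1.0, 0.5),
        ])
        sel = rank_and_select(frame)
        assert list(sel.table["assay_id"]) == ["m", "a", "z"]


class TestCrossReceptor:
    def test_shared_and_unique(self):
        member, regions = cross_receptor_sets({"R1": ["a", "b"], "R2": ["b", "c"]})
        assert regions == {("R1",): 1, ("R1", "R2"): 1, ("R2",): 1}

    def test_disjoint_sets(self):
        _, regions = cross_receptor_sets({"R1": ["a"], "R2": ["b"]})
        assert ("R1", "R2") not in regions

    def test_four_identical_sets(self):
        sets = {f"R{i}": ["x", "y"] for i in range(1, 5)}
        member, regions = cross_receptor_sets(sets)
        assert regions == {("R1", "R2", "R3", "R4"): 2}

    def test_single_set_rejected(self):
        with pytest.raises(ContractError):
            cross_receptor_sets({"R1": ["a"]})


def test_results_frame_flattens_alt_pvalues():
    s = series_from_diffs([-1, -2, -3])
    r = matched_pairs_effect(s)
    r.p_sm = 0.1
    r.p_alt = {"welch": 0.2}
    frame = results_frame([r])
    assert frame.loc[0, "p_welch"] == 0.2 and frame.loc[0, "p_sm"] == 0.1
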