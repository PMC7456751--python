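"""Stratified z statistic: arithmetic oracles, pooling, look decisions."""

import numpy as np
import pytest

from seqtrial import (
    StratumCounts,
    decide_at_look,
    merge_sparse_strata,
    stratified_z,
    unstratified_z,
)


class TestUnstratifiedZ:
    def test_hand_computed_value(self):
        """Direct evaluation of (p2-p1)/sqrt(p1q1/n1 + p2q2/n2)."""
        res = unstratified_z(StratumCounts.single(81, 32, 162, 97))
        p1, p2 = 32 / 81, 97 / 162
        expected = (p2 - p1) / np.sqrt(p1 * (1 - p1) / 81 + p2 * (1 - p2) / 162)
        assert res.z == pytest.approx(expected, abs=1e-12)
        assert res.estimate == pytest.approx(p2 - p1, abs=1e-12)

    def test_equal_arms_give_zero(self):
        assert unstratified_z(StratumCounts.single(50, 20, 50, 20)).z == 0.0

    def test_orientation(self):
        worse = unstratified_z(StratumCounts.single(50, 30, 50, 20))
        assert worse.z < 0
        mortality = unstratified_z(
            StratumCounts.single(50, 35, 50, 25), direction="decrease"
        )
        assert mortality.z > 0  # fewer deaths on treatment is benefit

    def test_rejects_multiple_strata(self):
        with pytest.raises(ValueError):
            unstratified_z(
                StratumCounts(np.array([5, 5]), np.array([1, 1]),
                              np.array([5, 5]), np.array([1, 1]))
            )


class TestStratifiedZ:
    def test_single_stratum_reduces_to_unstratified(self):
        c = StratumCounts.single(40, 12, 80, 40)
        assert stratified_z(c).z == pytest.approx(unstratified_z(c).z, abs=1e-12)

    def test_two_identical_null_strata_give_zero(self):
        c = StratumCounts(np.array([10, 10]), np.array([5, 5]),
                          np.array([10, 10]), np.array([5, 5]))
        assert stratified_z(c).z == 0.0

    def test_inverse_variance_hand_oracle(self):
        """Pooled z equals the explicit weighted-average arithmetic."""
        c = StratumCounts(np.array([30, 40]), np.array([10, 18]),
                          np.array([35, 42]), np.array([20, 25]))
        d = np.array([20 / 35 - 10 / 30, 25 / 42 - 18 / 40])
        v = np.array([
            (10 / 30) * (20 / 30) / 30 + (20 / 35) * (15 / 35) / 35,
            (18 / 40) * (22 / 40) / 40 + (25 / 42) * (17 / 42) / 42,
        ])
        w = 1.0 / v
        expected = (w @ d) / np.sqrt(w.sum())
        assert stratified_z(c).z == pytest.approx(expected, abs=1e-12)

    def test_null_variance_hand_oracle(self):
        c = StratumCounts(np.array([30]), np.array([10]),
                          np.array([35]), np.array([20]))
        pbar = 30 / 65
        var = pbar * (1 - pbar) * (1 / 30 + 1 / 35)
        expected = (20 / 35 - 10 / 30) / np.sqrt(var)
        assert stratified_z(c, weighting="null_variance").z == pytest.approx(
            expected, abs=1e-12
        )

    def test_balanced_homogeneous_strata_match_unstratified(self):
        """Equal rates and balanced strata: pooled == unstratified to 1e-9."""
        c = StratumCounts(np.array([20, 20]), np.array([8, 8]),
                          np.array([20, 20]), np.array([13, 13]))
        pooled = stratified_z(c).z
        collapsed = unstratified_z(StratumCounts.single(40, 16, 40, 26)).z
        assert pooled == pytest.approx(collapsed, abs=1e-9)

    def test_degenerate_stratum_warns_not_nan(self):
        with pytest.warns(UserWarning):
            res = stratified_z(StratumCounts.single(10, 10, 10, 10))
        assert res.z == 0.0

    def test_empty_arms_rejected(self):
        with pytest.raises(ValueError):
            stratified_z(StratumCounts(np.array([0]), np.array([0]),
                                       np.array([5]), np.array([2])))

    def test_cmh_matches_statsmodels(self):
        """CMH pooling agrees with the statsmodels StratifiedTable score stat."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        tables = [
            np.array([[20, 15], [10, 20]]),  # [[x2, n2-x2],[x1, n1-x1]]
            np.array([[25, 17], [18, 22]]),
        ]
        c = StratumCounts(np.array([30, 40]), np.array([10, 18]),
                          np.array([35, 42]), np.array([20, 25]))
        ours = stratified_z(c, weighting="cmh").z
        st = sm.StratifiedTable(tables)
        theirs = np.sqrt(st.test_null_odds().statistic)
        assert ours == pytest.approx(theirs, abs=1e-8)


class TestMergeSparseStrata:
    def test_adequate_counts_untouched(self):
        c = StratumCounts(np.array([10, 12]), np.array([3, 4]),
                          np.array([11, 9]), np.array([5, 2]))
        assert merge_sparse_strata(c) is c

    def test_sparse_folds_into_nearest(self):
        c = StratumCounts(np.array([1, 30, 20]), np.array([0, 10, 9]),
                          np.array([2, 35, 22]), np.array([1, 20, 11]))
        m = merge_sparse_strata(c)
        assert m.n_strata == 2
        assert m.n1.tolist() == [31, 20]
        assert m.x2.tolist() == [21, 11]

    def test_all_sparse_collapses_to_one(self):
        c = StratumCounts(np.array([1, 1]), np.array([1, 0]),
                          np.array([1, 1]), np.array([0, 1]))
        m = merge_sparse_strata(c)
        assert m.n_strata == 1
        assert m.n1.tolist() == [2]

    def test_totals_preserved(self):
        rng = np.random.default_rng(8)
        n1 = rng.integers(0, 8, 16)
        n2 = rng.integers(0, 8, 16)
        x1 = rng.integers(0, n1 + 1)
        x2 = rng.integers(0, n2 + 1)
        c = StratumCounts(n1, x1, n2, x2)
        m = merge_sparse_strata(c)
        for attr in ("n1", "x1", "n2", "x2"):
            assert getattr(m, attr).sum() == getattr(c, attr).sum()


class TestDecideAtLook:
    @pytest.mark.parametrize(
        "p, look, expected",
        [
            (0.001, 0, "stop-efficacy"),
            (0.9, 0, "stop-futility"),
            (0.5, 0, "continue"),
            (0.01, 1, "stop-efficacy"),
            (0.35, 1, "stop-futility"),
            (0.1, 1, "continue"),
            (0.04, 2, "reject"),
            (0.05, 2, "accept"),
        ],
    )
    def test_decisions_against_three_look_design(self, boundaries_90, p, look, expected):
        from scipy.stats import norm

        from seqtrial.analysis import TestResult

        res = TestResult(z=float(norm.isf(p)), p_one_sided=p, estimate=0.1)
        assert decide_at_look(res, look, boundaries_90) == expected

    def test_monotone_in_p(self, boundaries_90):
        from scipy.stats import norm

        from seqtrial.analysis import TestResult

        order = {"stop-efficacy": 0, "continue": 1, "stop-futility": 2}
        seen = []
        for p in np.linspace(0.0005, 0.99, 60):
            res = TestResult(z=float(norm.isf(p)), p_one_sided=float(p), estimate=0.0)
            seen.append(order[decide_at_look(res, 0, boundaries_90)])
        assert seen == sorted(seen)

    def test_invalid_look(self, boundaries_90):
        from seqtrial.analysis import TestResult

        with pytest.raises(ValueError):
            decide_at_look(TestResult(0.0, 0.5, 0.0), 3, boundaries_90)
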