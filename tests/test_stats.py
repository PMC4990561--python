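"""The four rank tests, their invariances, and the benchmark chain.

Independent oracles: scipy's Friedman implementation, R's friedman.test /
quade.test (values frozen from a fixed fixture), and an exhaustive
within-block permutation distribution for small matrices.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import friedmanchisquare

from affectsync import (aligned_friedman, all_tests, column_stats, friedman,
                        iman_davenport, published_benchmark, quade)


@pytest.fixture(scope="module")
def bench():
    return published_benchmark()


def _random_matrix(seed, n=10, k=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(35, 3, (n, k)),
                        columns=[f"c{j}" for j in range(k)])


class TestColumnStats:
    def test_benchmark_column_stats(self, bench):
        cs = column_stats(bench)
        assert cs.loc["G1", "mean"] == pytest.approx(37.4194, abs=1e-4)
        assert cs.loc["G1", "sd"] == pytest.approx(2.61820374, abs=1e-8)
        assert cs.loc["G1", "max"] == pytest.approx(40.9091)
        assert cs.loc["G1", "argmax"] == "LR"

    def test_identical_entries_sd_zero(self):
        m = pd.DataFrame(np.full((5, 3), 40.0))
        assert (column_stats(m)["sd"] == 0).all()

    def test_single_row_warns_sd_zero(self):
        m = pd.DataFrame([[40.0, 41.0]], columns=["a", "b"])
        with pytest.warns(UserWarning, match="single row"):
            cs = column_stats(m)
        assert (cs["sd"] == 0).all()
        assert cs.loc["a", "mean"] == 40.0


class TestFriedman:
    def test_benchmark_chain(self, bench):
        """Rank sums 16/21/23 give chi2 = 2.6 and p = e^(-1.3)."""
        r = friedman(bench)
        assert r.statistic == pytest.approx(2.6, abs=1e-9)
        assert r.p_value == pytest.approx(np.exp(-1.3), abs=1e-9)
        assert r.p_value == pytest.approx(0.2725, abs=5e-5)

    def test_identical_columns(self):
        m = pd.DataFrame(np.tile([[36.0], [38.0], [40.0]], (1, 3)))
        r = friedman(m)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_agrees_with_scipy(self):
        for seed in range(10):
            m = _random_matrix(seed)
            ours = friedman(m)
            ref = friedmanchisquare(*(m[c] for c in m.columns))
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_missing_entry_is_error(self):
        m = _random_matrix(0)
        m.iloc[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman(m)

    def test_monotone_transform_invariance(self):
        m = _random_matrix(3)
        assert friedman(m).statistic == pytest.approx(
            friedman(np.exp(m / 10)).statistic)


def exact_permutation_interval(m: pd.DataFrame) -> tuple[float, float]:
    """Brute-force within-block permutation distribution of the
    Friedman statistic (independent oracle).  Returns the exact
    p-interval (P(stat > obs), P(stat >= obs)); the gap is the tie mass
    of the discrete distribution at the observed statistic."""
    obs = friedman(m).statistic
    x = m.to_numpy()
    n, k = x.shape
    perms = list(itertools.permutations(range(k)))
    ge = gt = total = 0
    for combo in itertools.product(perms, repeat=n):
        arranged = np.array([x[i, list(p)] for i, p in enumerate(combo)])
        stat = friedman(pd.DataFrame(arranged)).statistic
        ge += stat >= obs - 1e-12
        gt += stat > obs + 1e-12
        total += 1
    return gt / total, ge / total


class TestExactPermutationOracle:
    @pytest.mark.parametrize("n_blocks", [2, 3, 4])
    def test_asymptotic_p_bracketed_by_exact_interval(self, n_blocks):
        """With so few blocks the permutation distribution has only a
        handful of atoms (at n=2, k=3 just four: 0, 1, 3, 4 with mass
        1/6, 1/3, 1/3, 1/6), so no continuous tail can match a single
        exact p to 0.05; what does hold is that the chi-square p always
        lands inside the exact interval [P(>obs), P(>=obs)]."""
        for seed in range(7):
            m = _random_matrix(100 * n_blocks + seed, n=n_blocks, k=3)
            lo, hi = exact_permutation_interval(m)
            p = friedman(m).p_value
            assert lo - 1e-12 <= p <= hi + 1e-12


class TestImanDavenport:
    def test_benchmark_p(self, bench):
        r = iman_davenport(bench)
        assert r.statistic == pytest.approx(9 * 2.6 / (20 - 2.6), abs=1e-9)
        assert r.p_value == pytest.approx(0.2855, abs=5e-5)

    def test_identical_columns(self):
        m = pd.DataFrame(np.tile([[36.0], [38.0], [40.0]], (1, 3)))
        r = iman_davenport(m)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_strictly_increasing_in_friedman_statistic(self):
        """Across random matrices of fixed shape, the F statistic orders
        exactly as the Friedman chi-square does."""
        pairs = sorted((friedman(m).statistic, iman_davenport(m).statistic)
                       for seed in range(25)
                       if (m := _random_matrix(seed)) is not None)
        fs = [f for _, f in pairs]
        assert fs == sorted(fs)

    def test_degenerate_denominator_raises(self):
        # perfectly ordered columns: chi2 reaches n(k-1)
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 4)
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            iman_davenport(m)

    def test_all_tests_reports_the_degenerate_limit(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 4)
        r = all_tests(m)["iman_davenport"]
        assert r.p_value == 0.0


class TestAlignedFriedman:
    def test_benchmark_p(self, bench):
        assert aligned_friedman(bench).p_value == pytest.approx(0.3603,
                                                                abs=5e-5)

    def test_identical_columns(self):
        m = pd.DataFrame(np.tile([[36.0], [38.0], [40.0]], (1, 3)))
        r = aligned_friedman(m)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_block_constant_invariance(self):
        m = _random_matrix(5)
        shifted = m.copy()
        shifted.iloc[4] += 250.0
        assert aligned_friedman(m).statistic == pytest.approx(
            aligned_friedman(shifted).statistic)


class TestQuade:
    def test_benchmark_p(self, bench):
        assert quade(bench).p_value == pytest.approx(0.4396, abs=5e-5)

    def test_identical_columns(self):
        m = pd.DataFrame(np.tile([[36.0], [38.0], [40.0]], (1, 3)))
        with pytest.warns(UserWarning, match="zero residual"):
            r = quade(m)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_scale_invariance(self):
        m = _random_matrix(6)
        assert quade(m).statistic == pytest.approx(quade(3.7 * m).statistic)

    def test_agrees_with_r_oracle(self):
        """Frozen from R (tie-free 6x3 fixture): quade.test gives
        F = 0.083799 (p = 0.920255), friedman.test chi2 = 1.333333
        (p = 0.513417)."""
        m = pd.DataFrame(
            [[36.81, 38.72, 39.03], [35.21, 37.95, 34.52],
             [40.03, 39.48, 41.26], [39.88, 39.94, 42.46],
             [35.48, 37.33, 35.93], [34.31, 29.80, 32.26]])
        assert quade(m).statistic == pytest.approx(0.083799, abs=5e-6)
        assert quade(m).p_value == pytest.approx(0.920255, abs=5e-6)
        assert friedman(m).statistic == pytest.approx(1.333333, abs=5e-6)
        assert friedman(m).p_value == pytest.approx(0.513417, abs=5e-6)


class TestCrossCutting:
    def test_row_permutation_invariance_all_four(self):
        m = _random_matrix(9)
        perm = m.iloc[np.random.default_rng(1).permutation(len(m))]
        for fn in (friedman, iman_davenport, aligned_friedman, quade):
            assert fn(m).statistic == pytest.approx(fn(perm).statistic)

    def test_benchmark_all_four_p_values(self, bench):
        res = all_tests(bench)
        assert res["friedman"].p_value == pytest.approx(0.2725, abs=5e-5)
        assert res["iman_davenport"].p_value == pytest.approx(0.2855, abs=5e-5)
        assert res["aligned_friedman"].p_value == pytest.approx(0.3603,
                                                                abs=5e-5)
        assert res["quade"].p_value == pytest.approx(0.4396, abs=5e-5)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            friedman(pd.DataFrame([[1.0, 2.0]]))
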