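"""Normalization, dispersion estimation, exact test, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exomir.datasets import ENRICHED_MIRNAS
from exomir.differential import (
    classify,
    cpm,
    estimate_common_dispersion,
    exact_count_test,
    fold_ratio,
    run_differential,
)
from exomir.quantify import CountMatrix


def _cm(counts: np.ndarray, lib_sizes=None) -> CountMatrix:
    samples = [f"s{i}" for i in range(counts.shape[1])]
    df = pd.DataFrame(counts, columns=samples, index=[f"m{i}" for i in range(len(counts))])
    lib = pd.Series(lib_sizes, index=samples) if lib_sizes is not None else df.sum(axis=0)
    return CountMatrix(df.astype(int), lib.astype(int), (df > 0).sum(axis=0))


def _labels(n_a=3, n_b=3):
    labels = {}
    for i in range(n_a + n_b):
        labels[f"s{i}"] = "milk" if i < n_a else "exosome"
    return labels


def nb_logpmf(k, mu, phi):
    """Independent NB log-pmf via lgamma (variance mu + phi*mu^2)."""
    if phi == 0.0:
        return k * math.log(mu) - mu - math.lgamma(k + 1)
    r = 1.0 / phi
    p = r / (r + mu)
    return (
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log(1 - p)
    )


def exact_test_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Brute-force enumeration over every split of s = sum_a + sum_b."""
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    mu_a = s * n_a / (n_a + n_b)
    mu_b = s * n_b / (n_a + n_b)
    logw = [
        nb_logpmf(s - k, mu_a, phi / n_a) + nb_logpmf(k, mu_b, phi / n_b)
        for k in range(s + 1)
    ]
    mx = max(logw)
    w = [math.exp(x - mx) for x in logw]
    total = sum(w)
    obs = w[sum_b]
    return min(1.0, sum(x for x in w if x <= obs * (1 + 1e-12)) / total)


class TestCpm:
    def test_printed_library_arithmetic(self):
        # 75 reads in a 1,794,033-read library is 41.80 CPM
        cm = _cm(np.array([[75, 67154]]), lib_sizes=[1_794_033, 234_133])
        out = cpm(cm)
        assert out.iloc[0, 0] == pytest.approx(41.80, abs=0.01)

    def test_zero_library_size_rejected(self):
        cm = _cm(np.array([[1, 2]]), lib_sizes=[100, 100])
        cm.lib_sizes["s0"] = 0
        with pytest.raises(ValueError):
            cpm(cm)

    def test_equal_libraries_scale_linearly(self):
        counts = np.array([[10, 20], [5, 40]])
        cm = _cm(counts, lib_sizes=[1000, 1000])
        out = cpm(cm)
        assert np.allclose(out.to_numpy(), counts / 1000 * 1e6)


class TestDispersion:
    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(31)
        mu = rng.lognormal(np.log(100), 0.8, size=2000)
        counts = rng.poisson(mu[:, None], size=(2000, 6))
        est = estimate_common_dispersion(_cm(counts), _labels(), "milk", "exosome")
        assert est < 0.02

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(32)
        phi = 0.2
        r = 1 / phi
        mu = np.full(2000, 100.0)
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6))
        est = estimate_common_dispersion(_cm(counts), _labels(), "milk", "exosome")
        assert 0.1 <= est <= 0.3

    def test_identical_counts_give_zero(self):
        counts = np.tile([[7], [13], [29]], (1, 6))
        est = estimate_common_dispersion(_cm(counts), _labels(), "milk", "exosome")
        assert est == 0.0


class TestExactTest:
    def test_symmetric_split_has_p_one(self):
        for phi in (0.0, 0.1, 0.5):
            assert exact_count_test(40, 40, 3, 3, phi) == pytest.approx(1.0)

    def test_extreme_poisson_split_matches_binomial_tail(self):
        # (0, 20) with equal replicates: two-sided exact binomial(20, 1/2)
        from scipy import stats

        pmf = stats.binom.pmf(np.arange(21), 20, 0.5)
        expected = pmf[pmf <= pmf[20] * (1 + 1e-12)].sum()
        assert exact_count_test(0, 20, 3, 3, 0.0) == pytest.approx(expected, rel=1e-9)

    def test_matches_bruteforce_on_random_splits(self):
        rng = np.random.default_rng(33)
        for _ in range(60):
            s_a, s_b = int(rng.integers(0, 201)), int(rng.integers(0, 201))
            n_a, n_b = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            phi = float(rng.choice([0.0, 0.1, 0.5]))
            if s_a + s_b == 0:
                continue
            got = exact_count_test(s_a, s_b, n_a, n_b, phi)
            want = exact_test_oracle(s_a, s_b, n_a, n_b, phi)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_monotone_in_imbalance(self):
        # moving counts from A to B (fixed total) weakly decreases p on the B side
        total = 60
        for phi in (0.0, 0.2):
            ps = [exact_count_test(total - b, b, 3, 3, phi) for b in range(30, 61)]
            assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_count_test(-1, 5, 3, 3, 0.1)
        with pytest.raises(ValueError):
            exact_count_test(1, 5, 0, 3, 0.1)


class TestFoldRatio:
    def test_equal_means_give_unity(self):
        ratio, l2 = fold_ratio(10.0, 10.0, 0.5)
        assert ratio == 1.0 and l2 == 0.0

    def test_zero_numerator_stays_finite(self):
        ratio, l2 = fold_ratio(0.0, 140.0, 2.1)
        assert 0 < ratio < np.inf and np.isfinite(l2)

    @given(
        st.floats(0, 1e5, allow_nan=False),
        st.floats(0, 1e5, allow_nan=False),
        st.floats(1e-3, 10, allow_nan=False),
    )
    def test_algebraic_identity(self, a, b, pseudo):
        ratio, _ = fold_ratio(a, b, pseudo)
        assert ratio * (a + pseudo) == pytest.approx(b + pseudo, rel=1e-12)


class TestClassify:
    def test_published_ratio_p_pairs_are_strongly_up(self):
        for m in ENRICHED_MIRNAS:
            assert classify(m.ratio, m.p_value) == ("UP", "UP")

    @pytest.mark.parametrize(
        "ratio,p,expected",
        [
            (5.0, 0.01, ("UP", "NS")),     # between the tiers
            (20.0, 0.2, ("NS", "NS")),     # fails significance
            (0.05, 0.001, ("DOWN", "DOWN")),
            (0.3, 0.001, ("DOWN", "NS")),
            (1.5, 0.001, ("NS", "NS")),
        ],
    )
    def test_tier_boundaries(self, ratio, p, expected):
        assert classify(ratio, p) == expected

    @given(
        st.floats(1e-4, 1e4), st.floats(1e-4, 1e4), st.floats(0, 1, exclude_max=False)
    )
    def test_monotone_and_consistent(self, r1, r2, p):
        lo, hi = sorted((r1, r2))
        rank = {"DOWN": -1, "NS": 0, "UP": 1}
        m2_lo, m10_lo = classify(lo, p)
        m2_hi, m10_hi = classify(hi, p)
        assert rank[m2_hi] >= rank[m2_lo] and rank[m10_hi] >= rank[m10_lo]
        # tier consistency: a mark10 call implies the same mark2 call
        for m2, m10 in ((m2_lo, m10_lo), (m2_hi, m10_hi)):
            if m10 != "NS":
                assert m2 == m10


class TestRunDifferential:
    def test_copied_condition_groups_give_p_one(self):
        rng = np.random.default_rng(35)
        block = rng.poisson(50, size=(40, 3))
        counts = np.concatenate([block, block], axis=1)
        res, _ = run_differential(_cm(counts), _labels())
        assert (res["p_value"] == 1.0).all()
        assert (res["mark2"] == "NS").all()

    def test_all_zero_mirnas_excluded(self):
        counts = np.array([[5, 6, 7, 8, 9, 10], [0, 0, 0, 0, 0, 0]])
        res, _ = run_differential(_cm(counts), _labels())
        assert list(res["mirna"]) == ["m0"]

    def test_volcano_matches_results(self):
        rng = np.random.default_rng(36)
        counts = rng.poisson(30, size=(25, 6))
        counts[0, 3:] *= 40
        res, vol = run_differential(_cm(counts), _labels())
        assert list(vol["mirna"]) == list(res["mirna"])
        assert np.allclose(vol["neglog10_p"], -np.log10(res["p_value"]))
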