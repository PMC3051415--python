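import math

import numpy as np
import pytest

from ancestrykit.informativeness import (
    AlleleFrequencyTable,
    compute_in,
    compute_in_all,
    estimate_frequencies,
    regress_in,
    single_pop_fst,
)
from ancestrykit.io import MISSING, GenotypeMatrix


def brute_force_in(p1: np.ndarray) -> float:
    """Mutual information between a uniformly chosen population and one
    allele drawn from it, computed by explicit loops (independent oracle)."""
    K = len(p1)
    total = 0.0
    for allele_freqs in (list(p1), [1.0 - p for p in p1]):
        pbar = sum(allele_freqs) / K
        if pbar > 0:
            total -= pbar * math.log(pbar)
        for p in allele_freqs:
            if p > 0:
                total += (p / K) * math.log(p)
    return total


def table(freqs, loci=None):
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    K, L = freqs.shape
    return AlleleFrequencyTable(
        [f"pop{i}" for i in range(K)],
        loci or [f"rs{j}" for j in range(L)],
        freqs,
    )


class TestComputeIn:
    def test_identical_frequencies_give_zero(self):
        t = table([[0.4], [0.4], [0.4]])
        assert compute_in(t, "rs0") == pytest.approx(0.0, abs=1e-15)

    def test_fixed_difference_two_pops_is_ln2(self):
        t = table([[1.0], [0.0]])
        assert compute_in(t, "rs0") == pytest.approx(math.log(2), abs=1e-12)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_matches_brute_force_oracle(self, K):
        rng = np.random.default_rng(K)
        for _ in range(200):
            p = rng.uniform(0, 1, size=K)
            t = table(p[:, None])
            assert compute_in(t, "rs0") == pytest.approx(
                brute_force_in(p), abs=1e-12
            )

    def test_bounded_by_ln_k(self):
        rng = np.random.default_rng(0)
        for K in (2, 3, 4):
            p = rng.uniform(0, 1, size=(K, 50))
            vals = compute_in_all(table(p))
            assert (vals >= -1e-15).all()
            assert (vals <= math.log(K) + 1e-12).all()

    def test_invariant_to_population_order_and_allele_relabel(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, size=4)
        base = compute_in(table(p[:, None]), "rs0")
        perm = rng.permutation(4)
        assert compute_in(table(p[perm, None]), "rs0") == pytest.approx(
            base, abs=1e-12
        )
        assert compute_in(table((1 - p)[:, None]), "rs0") == pytest.approx(
            base, abs=1e-12
        )

    def test_requires_two_populations(self):
        with pytest.raises(ValueError, match="2 populations"):
            compute_in(table([[0.5], [0.5]]), "rs0", populations=["pop0"])

    def test_estimated_frequencies_converge_to_truth(self):
        # error of I_n from an estimated panel shrinks roughly as 1/sqrt(n)
        rng = np.random.default_rng(3)
        p_true = np.array([0.9, 0.1, 0.5, 0.3])
        truth = brute_force_in(p_true)
        errors = []
        for n in (50, 200, 800):
            errs = []
            for _ in range(30):
                dos = np.concatenate(
                    [rng.binomial(2, p, size=n) for p in p_true]
                )
                g = GenotypeMatrix(
                    [f"i{i}" for i in range(4 * n)],
                    ["rs0"],
                    dos[:, None],
                    labels=[f"p{k}" for k in range(4) for _ in range(n)],
                )
                est = estimate_frequencies(g)
                errs.append(abs(compute_in(est, "rs0") - truth))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]
        # 16x the panel should shrink the mean error by roughly 4x
        assert errors[2] < errors[0] / 2


class TestSinglePopFst:
    def test_focal_at_mean_gives_zero(self):
        t = table([[0.4], [0.6], [0.5]])
        assert single_pop_fst(t, "rs0", "pop2") == pytest.approx(0.0, abs=1e-15)

    def test_fixed_difference_two_pops_gives_one(self):
        t = table([[1.0], [0.0]])
        assert single_pop_fst(t, "rs0", "pop0") == pytest.approx(1.0)

    def test_monotone_in_focal_deviation(self):
        pbar = 0.5
        prev = -1.0
        for delta in np.linspace(0, 0.5, 11):
            # two symmetric pops keep the unweighted mean at 0.5
            t = table([[pbar + delta], [pbar - delta]])
            val = single_pop_fst(t, "rs0", "pop0")
            assert val >= prev
            prev = val

    def test_degenerate_mean_returns_zero(self):
        t = table([[1.0], [1.0]])
        assert single_pop_fst(t, "rs0", "pop0") == 0.0

    def test_unknown_focal_rejected(self):
        with pytest.raises(KeyError):
            single_pop_fst(table([[0.5], [0.4]]), "rs0", "nope")


class TestRegressIn:
    def test_perfect_fit_has_no_outliers(self):
        x = np.linspace(0.05, 0.6, 24)
        res = regress_in(x, x, pi_level=0.99)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.table["outlier"].sum() == 0

    def test_displaced_point_is_flagged_with_direction(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0.05, 0.6, 25)
        y = x + rng.normal(0, 0.005, size=25)
        y[10] += 0.4  # far beyond any 99% band for sigma ~ 0.005
        res = regress_in(x, y, pi_level=0.99)
        flagged = res.table.index[res.table["outlier"]]
        assert list(flagged) == ["locus11"]
        assert res.table.loc["locus11", "direction"] == "above"

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 30)
        y = 0.3 + 0.8 * x + rng.normal(0, 0.1, 30)
        res = regress_in(x, y)
        # closed-form OLS
        xb, yb = x.mean(), y.mean()
        sxx = ((x - xb) ** 2).sum()
        slope = ((x - xb) * (y - yb)).sum() / sxx
        intercept = yb - slope * xb
        resid = y - intercept - slope * x
        r2 = 1 - (resid ** 2).sum() / ((y - yb) ** 2).sum()
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        # prediction interval closed form
        from scipy import stats as st

        n = len(x)
        s = np.sqrt((resid ** 2).sum() / (n - 2))
        tcrit = st.t.ppf(1 - 0.005, n - 2)
        half = tcrit * s * np.sqrt(1 + 1 / n + (x - xb) ** 2 / sxx)
        np.testing.assert_allclose(
            res.table["pi_high"] - res.table["predicted"], half, atol=1e-10
        )
        np.testing.assert_allclose(
            res.table["predicted"] - res.table["pi_low"], half, atol=1e-10
        )

    def test_slope_vs_one_p_detects_unit_slope(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 100)
        y = x + rng.normal(0, 0.02, 100)
        res = regress_in(x, y)
        assert res.slope_vs_one_p > 0.01
        y2 = 0.5 * x + rng.normal(0, 0.02, 100)
        assert regress_in(x, y2).slope_vs_one_p < 1e-6

    def test_interval_invariants(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 24)
        y = x + rng.normal(0, 0.05, 24)
        res = regress_in(x, y)
        t = res.table
        assert (t["pi_low"] <= t["predicted"]).all()
        assert (t["predicted"] <= t["pi_high"]).all()
        outside = (t["y"] < t["pi_low"]) | (t["y"] > t["pi_high"])
        assert (t["outlier"] == outside).all()

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            regress_in([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


class TestEstimateFrequencies:
    def test_missing_excluded_from_counting(self):
        g = GenotypeMatrix(
            ["a", "b", "c"],
            ["rs0"],
            np.array([[2], [MISSING], [1]]),
            labels=["p", "p", "p"],
        )
        t = estimate_frequencies(g)
        assert t.freq[0, 0] == pytest.approx(3 / 4)
        assert t.counts[0, 0] == 4
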