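"""Statistical procedures against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from bemut.stats import (
    bh_adjust,
    fisher_exact_2x2,
    group_effect_on_arm_density,
    kruskal_wallis,
    multivariable_lm,
    sign_test,
)


def exact_sign_p(n_pos: int, n_used: int) -> float:
    """Two-sided exact binomial oracle via integer arithmetic."""
    if n_used == 0:
        return 1.0
    tail = min(n_pos, n_used - n_pos)
    lower = sum(math.comb(n_used, k) for k in range(0, tail + 1))
    p = 2 * lower / 2**n_used
    if 2 * tail == n_used:  # centre counted twice
        p -= math.comb(n_used, tail) / 2**n_used
    return min(p, 1.0)


def exact_fisher_p(a, b, c, d) -> float:
    """Two-sided Fisher oracle: full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestSignTest:
    def test_46_positive_3_negative_47_ties(self):
        d = np.r_[np.ones(46), -np.ones(3), np.zeros(47)]
        res = sign_test(d)
        assert res.detail == {"n_positive": 46, "n_negative": 3, "n_ties": 47}
        assert res.p_value == pytest.approx(6.981082378842984e-11, rel=1e-9)

    def test_14_positive_1_negative(self):
        res = sign_test(np.r_[np.ones(14), -np.ones(1)])
        assert res.p_value == pytest.approx(2 * 16 / 2**15)

    def test_all_ties_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="ties"):
            res = sign_test(np.zeros(5))
        assert res.p_value == 1.0 and res.n_used == 0

    def test_matches_enumeration_oracle_sampled(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(1, 21))
            k = int(rng.integers(0, n + 1))
            d = np.r_[np.ones(k), -np.ones(n - k)]
            assert sign_test(d).p_value == pytest.approx(exact_sign_p(k, n), rel=1e-12)


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.9

    def test_constant_data(self):
        res = kruskal_wallis([5, 5], [5, 5, 5])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_rank_example(self):
        res = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(3.857142857, rel=1e-6)
        assert res.p_value == pytest.approx(0.0495, abs=2e-4)

    def test_h_statistic_matches_rank_formula_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 5, size=rng.integers(3, 9))
            b = rng.integers(0, 5, size=rng.integers(3, 9))
            if len(set(a) | set(b)) < 2:
                continue
            # independent H computation: average ranks + tie correction
            x = np.concatenate([a, b]).astype(float)
            order = pd.Series(x).rank().to_numpy()
            n, na = len(x), len(a)
            ra, rb = order[:na].sum(), order[na:].sum()
            h = 12 / (n * (n + 1)) * (ra**2 / na + rb**2 / (n - na)) - 3 * (n + 1)
            _, counts = np.unique(x, return_counts=True)
            tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
            h /= tie
            assert kruskal_wallis(a, b).statistic == pytest.approx(h, rel=1e-10)


class TestFisher:
    def test_focal_amp_contrast(self):
        res = fisher_exact_2x2([[0, 41], [8, 33]])
        assert res.p_value == pytest.approx(exact_fisher_p(0, 41, 8, 33), rel=1e-6)
        assert res.p_value == pytest.approx(5.36e-3, rel=0.01)

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == 1.0

    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]).p_value == pytest.approx(2 / 252)

    def test_zero_margin(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]).p_value == 1.0

    def test_matches_enumeration_sampled(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            t = rng.integers(0, 12, size=4)
            if t[:2].sum() == 0 or t[2:].sum() == 0 or t[0] + t[2] == 0 or t[1] + t[3] == 0:
                continue
            got = fisher_exact_2x2(t.reshape(2, 2)).p_value
            want = exact_fisher_p(*t)
            assert got == pytest.approx(want, rel=1e-8)


class TestBH:
    def test_step_up_by_hand(self):
        q, rej = bh_adjust([0.01, 0.02, 0.03, 0.04], 0.05)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_single_p(self):
        q, _ = bh_adjust([0.037], 0.05)
        assert q[0] == pytest.approx(0.037)

    def test_two_values(self):
        q, _ = bh_adjust([0.005, 0.1], 0.05)
        assert np.allclose(q, [0.01, 0.1])

    def test_rejection_set_equals_max_k_rule(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(1, 25))
            p = rng.random(m)
            fdr = float(rng.choice([0.05, 0.1, 0.2]))
            _, rej = bh_adjust(p, fdr)
            # definitional step-up: largest k with p_(k) <= k/m * fdr
            order = np.argsort(p)
            ks = np.nonzero(p[order] <= (np.arange(1, m + 1) / m) * fdr)[0]
            expected = np.zeros(m, dtype=bool)
            if len(ks):
                expected[order[: ks.max() + 1]] = True
            assert (rej == expected).all()


class TestArmDensityPermutation:
    @staticmethod
    def _table(y, meta):
        return pd.DataFrame(
            {"patient_id": meta["patient_id"], "arm": "1p", "density": y}
        )

    def test_same_seed_same_p(self, tiny_meta):
        meta = pd.concat([tiny_meta] * 4, ignore_index=True)
        meta["patient_id"] = [f"P{i}" for i in range(len(meta))]
        rng = np.random.default_rng(0)
        tab = self._table(rng.random(len(meta)), meta)
        p1 = group_effect_on_arm_density(tab, meta, n_perm=500, seed=7).p_value
        p2 = group_effect_on_arm_density(tab, meta, n_perm=500, seed=7).p_value
        assert p1 == p2

    def test_detects_doubled_group(self):
        rng = np.random.default_rng(1)
        n = 41
        meta = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(2 * n)],
                "nsaid_user": [True] * n + [False] * n,
            }
        )
        y = rng.gamma(4, 1, size=2 * n)
        y[n:] *= 2
        tab = self._table(y, meta)
        res = group_effect_on_arm_density(tab, meta, n_perm=2000, seed=0)
        assert res.p_value < 0.01

    def test_low_n_perm_warns(self, tiny_meta):
        meta = pd.concat([tiny_meta] * 2, ignore_index=True)
        meta["patient_id"] = [f"P{i}" for i in range(len(meta))]
        with pytest.warns(UserWarning, match="n_perm"):
            group_effect_on_arm_density(self._table(np.arange(6.0), meta), meta,
                                        n_perm=50, seed=0)


class TestMultivariableLM:
    def test_exact_fit_no_noise(self):
        X = pd.DataFrame({"a": [0, 0, 1, 1.0], "b": [0, 1, 0, 1.0]})
        y = np.expm1(1.0 + 2.0 * X["a"] + 0.5 * X["b"])  # log1p-linear
        tab = multivariable_lm(y, X).set_index("term")
        assert tab.loc["a", "estimate"] == pytest.approx(2.0, abs=1e-10)
        assert tab.loc["b", "estimate"] == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        y = rng.random(20) * 10
        tab = multivariable_lm(y, X, log1p=False).set_index("term")
        Xd = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(tab["estimate"].to_numpy(), beta, atol=1e-8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.random((15, 2)), columns=list("ab"))
        y = rng.random(15)
        perm = rng.permutation(15)
        t1 = multivariable_lm(y, X).set_index("term")["estimate"]
        t2 = multivariable_lm(y[perm], X.iloc[perm].reset_index(drop=True)).set_index("term")["estimate"]
        assert np.allclose(t1, t2)

    def test_collinear_names_aliased_column(self):
        X = pd.DataFrame({"a": [0, 1, 0, 1.0], "dup": [0, 1, 0, 1.0]})
        with pytest.raises(ValueError, match="dup"):
            multivariable_lm([1, 2, 3, 4], X)


class TestSignTestProperties:
    def test_hypothesis_matches_enumeration(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=60)
        @given(st.integers(1, 40), st.data())
        def run(n, data):
            k = data.draw(st.integers(0, n))
            ties = data.draw(st.integers(0, 10))
            d = np.r_[np.ones(k), -np.ones(n - k), np.zeros(ties)]
            res = sign_test(d)
            assert res.p_value == pytest.approx(exact_sign_p(k, n), rel=1e-10)
            assert res.detail["n_ties"] == ties

        run()
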