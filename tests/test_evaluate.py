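import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gliosegkit as gk
from gliosegkit.evaluate import (
    cohen_kappa,
    dice,
    friedman,
    kruskal_wallis,
    overlap_report,
    ppv_sensitivity,
    spearman_rho,
    wilcoxon_signed_rank,
)


def _masks(rng, shape=(12, 12, 12), p=0.3):
    return rng.random(shape) < p, rng.random(shape) < p


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        a[1:4] = True
        assert dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[5:] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_count(self):
        a = np.zeros((4, 1, 1), dtype=bool)
        b = np.zeros((4, 1, 1), dtype=bool)
        a[0] = a[1] = True
        b[1] = b[2] = True
        assert dice(a, b) == 0.5

    def test_empty_conventions(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        f = np.ones((3, 3, 3), dtype=bool)
        assert dice(e, e) == 1.0
        assert dice(e, f) == 0.0

    @given(st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _masks(rng)
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros((2, 2, 2), dtype=bool), np.zeros((3, 3, 3), dtype=bool))


class TestPpvSensitivity:
    def test_counts(self):
        # TP=3, FP=1, FN=3
        auto = np.zeros((7, 1, 1), dtype=bool)
        ref = np.zeros((7, 1, 1), dtype=bool)
        auto[:4] = True
        ref[:3] = True
        ref[4:] = True
        ppv, sens = ppv_sensitivity(auto, ref)
        assert ppv == 0.75
        assert sens == 0.5

    def test_identity(self):
        rng = np.random.default_rng(0)
        a, _ = _masks(rng)
        assert ppv_sensitivity(a, a) == (1.0, 1.0)

    def test_strict_subset(self):
        ref = np.zeros((5, 5, 5), dtype=bool)
        ref[1:4, 1:4, 1:4] = True
        auto = np.zeros_like(ref)
        auto[2, 2, 2] = True
        ppv, sens = ppv_sensitivity(auto, ref)
        assert ppv == 1.0
        assert sens < 1.0

    def test_undefined_reported_as_nan(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        f = np.ones((3, 3, 3), dtype=bool)
        ppv, sens = ppv_sensitivity(e, f)
        assert math.isnan(ppv) and sens == 0.0

    def test_duality(self):
        rng = np.random.default_rng(1)
        a, b = _masks(rng)
        assert ppv_sensitivity(a, b)[0] == ppv_sensitivity(b, a)[1]

    def test_growing_toward_ref_never_decreases_dice_or_sensitivity(self):
        rng = np.random.default_rng(2)
        ref = rng.random((10, 10, 10)) < 0.4
        auto = ref & (rng.random((10, 10, 10)) < 0.3)
        missing = np.argwhere(ref & ~auto)
        prev_d, prev_s = dice(auto, ref), ppv_sensitivity(auto, ref)[1]
        for k in range(0, len(missing), 50):
            grown = auto.copy()
            for v in missing[: k + 1]:
                grown[tuple(v)] = True
            d, s = dice(grown, ref), ppv_sensitivity(grown, ref)[1]
            assert d >= prev_d - 1e-12 and s >= prev_s - 1e-12
            prev_d, prev_s = d, s


class TestOverlapReport:
    def test_identity_label_map(self):
        rng = np.random.default_rng(0)
        lm = gk.LabelMap(codes=rng.integers(0, 5, (10, 10, 10)), spacing=(1, 1, 1))
        rows = overlap_report(lm, lm)
        assert [r.region for r in rows] == ["CETV", "TV", "TVPLUS"]
        for r in rows:
            assert r.dice == 1.0 and r.ppv == 1.0 and r.sensitivity == 1.0
            assert r.abs_err_ml == 0.0 and r.rel_err == 0.0

    def test_harmonic_mean_identity_on_random_pairs(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = gk.LabelMap(codes=rng.integers(0, 5, (8, 8, 8)), spacing=(1, 1, 1))
            b = gk.LabelMap(codes=rng.integers(0, 5, (8, 8, 8)), spacing=(1, 1, 1))
            for r in overlap_report(a, b):
                if not (math.isnan(r.ppv) or math.isnan(r.sensitivity)):
                    if r.ppv + r.sensitivity > 0:
                        expect = 2 * r.ppv * r.sensitivity / (r.ppv + r.sensitivity)
                        assert r.dice == pytest.approx(expect, abs=1e-12)

    def test_rel_err_sign_positive_for_oversegmentation(self):
        ref = np.zeros((8, 8, 8), dtype=np.uint8)
        ref[3:5, 3:5, 3:5] = 4
        auto = np.zeros_like(ref)
        auto[2:6, 2:6, 2:6] = 4
        rows = overlap_report(
            gk.LabelMap(codes=auto, spacing=(1, 1, 1)),
            gk.LabelMap(codes=ref, spacing=(1, 1, 1)),
        )
        assert rows[0].rel_err > 0

    def test_grid_mismatch_rejected(self):
        a = gk.LabelMap(codes=np.zeros((4, 4, 4), dtype=np.uint8), spacing=(1, 1, 1))
        b = gk.LabelMap(codes=np.zeros((5, 5, 5), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            overlap_report(a, b)


def oracle_wilcoxon(d):
    """Exhaustive sign-flip oracle written independently (per-pattern loop)."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    null = []
    for signs in itertools.product([0, 1], repeat=n):
        null.append(sum(r for s, r in zip(signs, ranks) if s))
    null = np.array(null)
    p_le = (null <= w_obs + 1e-12).mean()
    p_ge = (null >= w_obs - 1e-12).mean()
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = x + 50.0
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value < 0.01
        w, p = oracle_wilcoxon(x - y)
        assert res.statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p)

    def test_null_statistic_within_exact_central_band(self):
        """Under exchangeable noise the statistic stays inside the central
        95% of its exact null in ~95% of repetitions."""
        n = 10
        ranks = np.arange(1, n + 1, dtype=float)
        null = np.array([
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ])
        lo, hi = np.quantile(null, [0.025, 0.975])
        hits = 0
        reps = 200
        rng = np.random.default_rng(1)
        for _ in range(reps):
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)  # symmetric paired noise
            res = wilcoxon_signed_rank(x, y)
            hits += lo <= res.statistic <= hi
        assert hits / reps > 0.88

    def test_all_zero_differences_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(x, x)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30) + 1.0
        res = wilcoxon_signed_rank(x, y)
        assert "approx" in res.notes["method"]
        assert 0 <= res.p_value <= 1


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0, 13.0])
        assert spearman_rho(x, x ** 3).statistic == pytest.approx(1.0)
        assert spearman_rho(x, -x).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_enumeration(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman_rho(x, y)
        rhos = []
        for perm in itertools.permutations(range(6)):
            rhos.append(spearmanr(x, y[list(perm)]).statistic)
        p_oracle = np.mean([abs(r) >= abs(res.statistic) - 1e-12 for r in rhos])
        assert res.p_value == pytest.approx(p_oracle)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestNonparametricAnova:
    def test_friedman_identical_series(self):
        s = [1.0, 5.0, 3.0, 2.0]
        res = friedman([s, s, s])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_friedman_needs_three_groups(self):
        with pytest.raises(ValueError, match="k >= 3"):
            friedman([[1.0, 2.0], [2.0, 3.0]])

    def test_kruskal_shifted_group_significant(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(size=12)
        g2 = rng.normal(size=12)
        g3 = rng.normal(size=12) + 5.0
        assert kruskal_wallis([g1, g2, g3]).p_value < 0.01

    def test_kruskal_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([[1.0, 2.0], []])


class TestCohenKappa:
    def test_identical_maps_kappa_one(self):
        rng = np.random.default_rng(0)
        lm = gk.LabelMap(codes=rng.integers(0, 5, (10, 10, 10)), spacing=(1, 1, 1))
        assert cohen_kappa(lm, lm).statistic == pytest.approx(1.0)

    def test_independent_maps_kappa_near_zero(self):
        rng = np.random.default_rng(1)
        shape = (40, 40, 40)
        a = gk.LabelMap(codes=rng.integers(1, 5, shape), spacing=(1, 1, 1))
        b = gk.LabelMap(codes=rng.integers(1, 5, shape), spacing=(1, 1, 1))
        assert abs(cohen_kappa(a, b).statistic) < 0.05

    def test_two_class_confusion_hand_value(self):
        """Confusion [[45, 5], [10, 40]]: po = 0.85, pe = 0.5, kappa = 0.7."""
        auto = np.concatenate([
            np.full(45, 1), np.full(5, 1), np.full(10, 2), np.full(40, 2)
        ])
        ref = np.concatenate([
            np.full(45, 1), np.full(5, 2), np.full(10, 1), np.full(40, 2)
        ])
        lm_a = gk.LabelMap(codes=auto.reshape(100, 1, 1), spacing=(1, 1, 1))
        lm_r = gk.LabelMap(codes=ref.reshape(100, 1, 1), spacing=(1, 1, 1))
        res = cohen_kappa(lm_a, lm_r, support_dilation=0)
        po, pe = 0.85, 0.5 * 0.55 + 0.5 * 0.45
        assert res.statistic == pytest.approx((po - pe) / (1 - pe))
        assert res.notes["po"] == pytest.approx(po)
        assert res.notes["pe"] == pytest.approx(pe)
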