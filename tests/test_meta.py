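"""Effect-size and pooling estimators against hand-derived oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evimap.datamodel import Dataset, EffectRecord, RawOutcome
from evimap.meta import (
    DegenerateInputError,
    ParameterError,
    build_vcv,
    hedges_g,
    leave_one_cluster_out,
    pool_effects,
    pool_fixed_gls,
    pool_random_dl,
    robust_variance,
)


def _effects(y, v, clusters=None):
    clusters = clusters or [f"s{i}" for i in range(len(y))]
    return [
        EffectRecord(c, f"e{i}", yi=yi, vi=vi)
        for i, (yi, vi, c) in enumerate(zip(y, v, clusters))
    ]


class TestHedgesG:
    @pytest.mark.parametrize(
        "raw, g_exp, vg_exp",
        [
            # hand evaluation: d=2, df=18, J=1-3/71
            (RawOutcome(3, 1, 1, 1, 10, 10), 1.915493, 0.285375),
            # minimal df: J = 1 - 3/7, d = 1
            (RawOutcome(1, 0, 1, 1, 2, 2), 4 / 7, (4 / 7) ** 2 * (1 + 0.25)),
        ],
    )
    def test_matches_hand_derivation(self, raw, g_exp, vg_exp):
        g, vg = hedges_g(raw)
        assert g == pytest.approx(g_exp, abs=1e-6)
        assert vg == pytest.approx(vg_exp, abs=1e-6)

    def test_null_difference_gives_zero_g(self):
        raw = RawOutcome(2.0, 2.0, 1.5, 0.8, 12, 15)
        g, vg = hedges_g(raw)
        j = 1 - 3 / (4 * 25 - 1)
        assert g == 0.0
        assert vg == pytest.approx(j**2 * 27 / (12 * 15))

    def test_constant_groups_rejected(self):
        with pytest.raises((DegenerateInputError, Exception)):
            hedges_g(RawOutcome(1.0, 1.0, 1e-300, 1e-300, 5, 5))


class TestVCV:
    def test_rho_zero_is_diagonal(self):
        vcv = build_vcv(_effects([1, 2, 3], [0.1, 0.2, 0.3]), rho=0.0)
        assert np.allclose(vcv.values, np.diag([0.1, 0.2, 0.3]))

    def test_within_cluster_covariance(self):
        vcv = build_vcv(_effects([1, 2], [1.0, 4.0], ["s", "s"]), rho=0.5)
        assert vcv.values[0, 1] == pytest.approx(1.0)  # 0.5 * sqrt(4)
        assert np.allclose(np.diag(vcv.values), [1.0, 4.0])

    def test_across_clusters_zero(self):
        vcv = build_vcv(_effects([1, 2], [1.0, 4.0], ["a", "b"]), rho=0.9)
        assert vcv.values[0, 1] == 0.0

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_rho_range_enforced(self, rho):
        with pytest.raises(ParameterError):
            build_vcv(_effects([1], [1.0]), rho=rho)


class TestFixedGLS:
    def test_worked_two_by_two(self):
        """y=(1,3), v=(1,1), one cluster, rho=0.5 — hand-inverted 2x2 oracle."""
        vcv = build_vcv(_effects([1, 3], [1.0, 1.0], ["s", "s"]), rho=0.5)
        pe = pool_fixed_gls(np.array([1.0, 3.0]), vcv)
        assert pe.estimate == pytest.approx(2.0, abs=1e-12)
        assert pe.se == pytest.approx(math.sqrt(0.75), abs=1e-12)
        assert pe.ci_low == pytest.approx(0.3026, abs=2e-4)
        assert pe.ci_high == pytest.approx(3.6974, abs=2e-4)

    def test_diagonal_reduces_to_ivw(self, rng):
        y = rng.normal(size=5)
        v = rng.uniform(0.05, 0.5, size=5)
        vcv = build_vcv(_effects(y, v), rho=0.0)
        pe = pool_fixed_gls(y, vcv)
        w = 1 / v
        assert pe.estimate == pytest.approx(float(w @ y / w.sum()), rel=1e-10)
        assert pe.se == pytest.approx(math.sqrt(1 / w.sum()), rel=1e-10)

    def test_equal_weights_give_arithmetic_mean(self, rng):
        y = rng.normal(size=4)
        vcv = build_vcv(_effects(y, [0.3] * 4), rho=0.0)
        assert pool_fixed_gls(y, vcv).estimate == pytest.approx(float(y.mean()), rel=1e-10)

    def test_common_cluster_equal_variance_closed_form(self):
        """se^2 = v(1 + (n-1) rho) / n for n equicorrelated effects."""
        n, v, rho = 6, 0.2, 0.4
        y = np.zeros(n)
        vcv = build_vcv(_effects(y, [v] * n, ["s"] * n), rho=rho)
        pe = pool_fixed_gls(y, vcv)
        assert pe.se**2 == pytest.approx(v * (1 + (n - 1) * rho) / n, rel=1e-10)

    def test_se_nondecreasing_in_rho(self):
        y = [0.1, 0.2, 0.3]
        ses = []
        for rho in [0.0, 0.2, 0.5, 0.8]:
            vcv = build_vcv(_effects(y, [0.1] * 3, ["s"] * 3), rho=rho)
            ses.append(pool_fixed_gls(np.array(y), vcv).se)
        assert all(a <= b + 1e-14 for a, b in zip(ses, ses[1:]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        y = rng.normal(size=k)
        v = rng.uniform(0.05, 1.0, size=k)
        cl = [f"c{int(x)}" for x in rng.integers(0, 3, size=k)]
        pe = pool_fixed_gls(y, build_vcv(_effects(y, v, cl), rho=0.3))
        perm = rng.permutation(k)
        pe2 = pool_fixed_gls(
            y[perm],
            build_vcv(_effects(y[perm], v[perm], [cl[i] for i in perm]), rho=0.3),
        )
        assert pe2.estimate == pytest.approx(pe.estimate, abs=1e-12)
        assert pe2.se == pytest.approx(pe.se, abs=1e-12)


class TestRandomDL:
    def test_closed_form_two_effects(self):
        """k=2, y=(0,2), v=(1,1): Q=2, tau2=1, estimate 1, se 1."""
        pe = pool_random_dl(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert pe.tau2 == pytest.approx(1.0)
        assert pe.estimate == pytest.approx(1.0)
        assert pe.se == pytest.approx(1.0)

    def test_homogeneous_reduces_to_fixed(self):
        y = np.full(4, 0.3)
        v = np.array([0.1, 0.2, 0.3, 0.4])
        pe = pool_random_dl(y, v)
        assert pe.tau2 == 0.0
        w = 1 / v
        assert pe.se == pytest.approx(math.sqrt(1 / w.sum()))

    def test_variance_scale_equivariance_when_tau_zero(self):
        y = np.array([0.5, 0.5, 0.5])
        v = np.array([0.1, 0.2, 0.3])
        c = 4.0
        assert pool_random_dl(y, c * v).se == pytest.approx(
            math.sqrt(c) * pool_random_dl(y, v).se
        )

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError):
            pool_random_dl(np.array([1.0]), np.array([1.0]))


class TestRobustVariance:
    def test_singleton_clusters_equal_v_match_hc_form(self):
        """Each effect its own cluster, equal v, rho=0: the classic HC form."""
        y = np.array([0.1, 0.5, -0.3, 0.9])
        v = [0.2] * 4
        vcv = build_vcv(_effects(y, v), rho=0.0)
        pe = robust_variance(y, vcv)
        m = 4
        e = y - y.mean()
        expect = (m / (m - 1)) * float((e**2).sum()) / m**2
        assert pe.estimate == pytest.approx(float(y.mean()))
        assert pe.se**2 == pytest.approx(expect, rel=1e-10)

    def test_zero_residuals_flagged_degenerate(self):
        y = np.full(4, 0.4)
        vcv = build_vcv(_effects(y, [0.1] * 4, ["a", "a", "b", "b"]), rho=0.0)
        pe = robust_variance(y, vcv)
        assert pe.se == 0.0
        assert pe.degenerate

    def test_mirror_image_clusters(self):
        """Two clusters with opposite residuals: two equal squared sums."""
        y = np.array([1.0, 1.0, -1.0, -1.0])
        vcv = build_vcv(_effects(y, [1.0] * 4, ["a", "a", "b", "b"]), rho=0.0)
        pe = robust_variance(y, vcv)
        # w_i = 1 each, Sum w = 4, cluster sums +-2 -> se2 = (2/1)*(4+4)/16 = 1
        assert pe.se**2 == pytest.approx((2 / 1) * (2.0**2 + 2.0**2) / 16.0, rel=1e-10)

    def test_single_cluster_rejected(self):
        y = np.array([1.0, 2.0])
        vcv = build_vcv(_effects(y, [1.0, 1.0], ["s", "s"]), rho=0.0)
        with pytest.raises(ValueError, match="cluster"):
            robust_variance(y, vcv)


class TestLeaveOneClusterOut:
    def _dataset(self, groups):
        effects = []
        for g, (ys, vs) in groups.items():
            for i, (y, v) in enumerate(zip(ys, vs)):
                effects.append(
                    EffectRecord(f"{g}_st{i}", f"{g}_e{i}", yi=y, vi=v, author_cluster=g)
                )
        return Dataset(effects=effects)

    def test_two_clusters_complement_symmetry(self):
        ds = self._dataset({"g1": ([0.1, 0.2], [0.1, 0.1]), "g2": ([0.8], [0.2])})
        table = leave_one_cluster_out(ds, method="fixed_gls", rho=0.0)
        r1 = table[table.cluster == "g1"].iloc[0]
        r2 = table[table.cluster == "g2"].iloc[0]
        assert r1["estimate_without"] == pytest.approx(r2["estimate_own"])
        assert r2["estimate_without"] == pytest.approx(r1["estimate_own"])

    def test_complement_matches_subset_refit(self):
        ds = self._dataset(
            {"g1": ([0.1], [0.1]), "g2": ([0.5, 0.6], [0.2, 0.1]), "g3": ([0.9], [0.3])}
        )
        table = leave_one_cluster_out(ds, method="fixed_gls", rho=0.0)
        for g in ["g1", "g2", "g3"]:
            rest = [e for e in ds.effects if e.author_cluster != g]
            oracle = pool_effects(rest, method="fixed_gls", rho=0.0)
            row = table[table.cluster == g].iloc[0]
            assert row["estimate_without"] == pytest.approx(oracle.estimate, rel=1e-10)
            assert row["se_without"] == pytest.approx(oracle.se, rel=1e-10)

    def test_single_cluster_rejected(self):
        ds = self._dataset({"g1": ([0.1, 0.2], [0.1, 0.1])})
        with pytest.raises(ValueError):
            leave_one_cluster_out(ds)
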