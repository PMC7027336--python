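"""Statistical tests against enumeration, hand-formula and simulation oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from tracerspread import (
    dunn_bonferroni,
    kruskal_wallis,
    mann_whitney_u,
    paired_t_test,
    wilcoxon_signed_rank,
)
from tracerspread import test_normality as normality_test


class TestNormality:
    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normality_test([3.0] * 10)

    @pytest.mark.parametrize("method", ["shapiro-wilk", "kolmogorov-smirnov"])
    def test_gaussian_data_usually_passes(self, method):
        hits = 0
        for seed in range(50):
            v = np.random.default_rng(seed).standard_normal(500)
            hits += normality_test(v, method).pvalue > 0.05
        assert hits >= 45

    @pytest.mark.parametrize("method", ["shapiro-wilk", "kolmogorov-smirnov"])
    def test_uniform_data_usually_fails(self, method):
        hits = 0
        for seed in range(50):
            v = np.random.default_rng(seed).uniform(size=500)
            hits += normality_test(v, method).pvalue < 0.05
        assert hits >= 45


class TestKruskalWallis:
    def test_hand_computed_example(self):
        out = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert out.statistic == pytest.approx(7.2)
        assert out.df == 2
        assert out.pvalue == pytest.approx(0.0273, abs=0.0005)

    def test_identical_groups_h_zero(self):
        out = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert out.statistic == 0.0
        assert out.pvalue == pytest.approx(1.0)

    def test_within_group_permutation_invariance(self):
        a = kruskal_wallis([[3, 1, 2], [6, 4, 5], [9, 7, 8]])
        b = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunnBonferroni:
    def test_two_groups_no_correction(self):
        out = dunn_bonferroni([[1, 2, 3, 4], [6, 7, 8, 9]])
        tab = out.pairwise
        assert len(tab) == 1
        assert tab.p_corrected.iloc[0] == pytest.approx(tab.p_raw.iloc[0])

    def test_three_groups_factor_three(self):
        out = dunn_bonferroni([[1, 2, 3], [4, 5, 6], [2, 3, 4]])
        tab = out.pairwise
        assert len(tab) == 3
        for _, row in tab.iterrows():
            assert row.p_corrected == pytest.approx(
                min(1.0, 3.0 * row.p_raw))

    def test_corrected_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        out = dunn_bonferroni([rng.normal(size=6) for _ in range(4)])
        tab = out.pairwise
        assert (tab.p_corrected >= tab.p_raw - 1e-12).all()
        assert (tab.p_corrected <= 1.0).all()

    def test_raw_p_within_monte_carlo_error_of_permutation_null(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 6), rng.normal(0.8, 1, 5),
                  rng.normal(0.3, 1, 7)]
        out = dunn_bonferroni(groups)
        sizes = [6, 5, 7]
        pooled = np.concatenate(groups)
        bounds = np.cumsum([0] + sizes)

        def zstats(values):
            ranks = sps.rankdata(values)
            n = len(values)
            mr = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(3)]
            _, tc = np.unique(values, return_counts=True)
            vb = n * (n + 1) / 12 - (tc**3 - tc).sum() / (12 * (n - 1))
            return np.array([
                (mr[i] - mr[j]) / np.sqrt(vb * (1 / sizes[i] + 1 / sizes[j]))
                for i, j in itertools.combinations(range(3), 2)])

        z_obs = np.abs(zstats(pooled))
        nperm = 4000
        counts = np.zeros(3)
        for _ in range(nperm):
            counts += np.abs(zstats(rng.permutation(pooled))) >= z_obs - 1e-12
        perm_p = counts / nperm
        for raw, mc in zip(out.pairwise.p_raw, perm_p):
            assert raw == pytest.approx(mc, abs=3.5 * np.sqrt(
                max(mc * (1 - mc), 1e-4) / nperm) + 0.01)


class TestWilcoxon:
    def test_textbook_example(self):
        out = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])
        assert out.statistic == 6.0
        assert out.pvalue == pytest.approx(0.25)

    def test_equal_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_symmetry_under_swap(self):
        x = [1.0, 4.0, 2.5, 7.0]
        y = [0.5, 5.0, 1.0, 3.0]
        assert wilcoxon_signed_rank(x, y).pvalue == pytest.approx(
            wilcoxon_signed_rank(y, x).pvalue)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.permutation(np.arange(1.0, n + 1)) * rng.choice([-1, 1], n)
        p = wilcoxon_signed_rank(d).pvalue
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        w_tot = n * (n + 1) / 2
        extreme = sum(
            min(sum(r for s, r in zip(signs, ranks) if s),
                w_tot - sum(r for s, r in zip(signs, ranks) if s))
            <= min(w_obs, w_tot - w_obs)
            for signs in itertools.product([0, 1], repeat=n))
        assert p == pytest.approx(extreme / 2**n)


class TestMannWhitney:
    def test_textbook_example(self):
        out = mann_whitney_u([1, 2], [3, 4])
        assert out.statistic == 0.0
        assert out.pvalue == pytest.approx(1 / 3)

    def test_identical_multisets_not_significant(self):
        out = mann_whitney_u([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert out.pvalue > 0.9

    def test_u_identity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=7), rng.normal(size=5)
        ux = mann_whitney_u(x, y).statistic
        uy = mann_whitney_u(y, x).statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("nx,ny", [(1, 2), (2, 2), (2, 3), (3, 3),
                                       (3, 4), (4, 4), (2, 6), (3, 5)])
    def test_exact_p_matches_full_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        vals = rng.permutation(np.arange(1.0, nx + ny + 1))
        x, y = vals[:nx], vals[nx:]
        p = mann_whitney_u(x, y).pvalue
        pooled = np.concatenate([x, y])
        u_obs = sum(xi > yj for xi in x for yj in y)
        m = nx * ny
        extreme = total = 0
        for comb in itertools.combinations(range(nx + ny), nx):
            xs = pooled[list(comb)]
            ys = np.delete(pooled, list(comb))
            u = sum(xi > yj for xi in xs for yj in ys)
            extreme += min(u, m - u) <= min(u_obs, m - u_obs)
            total += 1
        assert p == pytest.approx(extreme / total)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2, 3])


class TestPairedT:
    def test_zero_mean_difference(self):
        out = paired_t_test([1, 2, 3], [0, 2, 4])
        assert out.statistic == pytest.approx(0.0)
        assert out.pvalue == pytest.approx(1.0)

    def test_constant_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([2, 3, 4], [1, 2, 3])

    def test_matches_hand_formula_on_five_pairs(self):
        x = np.array([3.1, 4.2, 5.0, 3.8, 4.4])
        y = np.array([2.9, 3.7, 5.2, 3.0, 4.1])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        out = paired_t_test(x, y)
        assert out.statistic == pytest.approx(t_hand)
        assert out.df == 4
        assert out.notes["mean_difference"] == pytest.approx(d.mean())

    def test_sign_antisymmetry(self):
        x = [1.0, 2.0, 4.0, 3.0]
        y = [0.5, 2.5, 3.0, 2.0]
        a = paired_t_test(x, y)
        b = paired_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)


class TestTypeIError:
    @pytest.mark.parametrize("test_fn,label", [
        (lambda r: kruskal_wallis([r.standard_normal(20) for _ in range(3)]),
         "kruskal-wallis"),
        (lambda r: mann_whitney_u(r.standard_normal(20),
                                  r.standard_normal(20)), "mann-whitney"),
        (lambda r: wilcoxon_signed_rank(r.standard_normal(20),
                                        r.standard_normal(20)), "wilcoxon"),
        (lambda r: paired_t_test(r.standard_normal(20),
                                 r.standard_normal(20)), "paired-t"),
    ])
    def test_nominal_level_under_the_null(self, test_fn, label):
        rng = np.random.default_rng(2024)
        n_sim = 2000
        rejections = sum(test_fn(rng).pvalue < 0.05 for _ in range(n_sim))
        assert 0.035 <= rejections / n_sim <= 0.065, label


def test_outcome_pvalue_bounds_enforced():
    from tracerspread.stats import TestOutcome

    with pytest.raises(ValueError):
        TestOutcome(name="x", statistic=0.0, pvalue=1.5)
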