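import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import vqtlscan as v

# width=16 keeps values coarse enough that strictly-monotone float maps
# (like exp(y/50) below) stay injective in double precision
finite_floats = st.floats(-50, 50, allow_nan=False, width=16)


class TestWilcoxon:
    def test_exact_enumeration_worked_example(self):
        # rank-sum of group 0 is minimal (6); 2 of the C(6,3)=20 label
        # assignments are as extreme, so the exact two-sided p is 0.1
        values = [1.2, 2.3, 3.1, 4.8, 5.5, 6.0]
        groups = [0, 0, 0, 1, 1, 1]
        _, p = v.wilcoxon_exact(values, groups)
        assert p == pytest.approx(0.1)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(12)
        g = np.array([0, 1] * 6, dtype=float)
        _, p1 = v.wilcoxon_test(y, g)
        _, p2 = v.wilcoxon_test(y, 1 - g)
        assert p1 == pytest.approx(p2)

    def test_complete_ties_give_p_one(self):
        _, p = v.wilcoxon_test([3.0] * 8, [0, 0, 0, 0, 1, 1, 1, 1])
        assert p == 1.0

    def test_degenerate_class_gives_missing(self):
        s, p = v.wilcoxon_test([1.0, 2.0, 3.0, 4.0], [0, 1, 1, 1])
        assert np.isnan(s) and np.isnan(p)

    def test_approximation_tracks_exact_enumeration(self):
        # tie-corrected normal approximation with continuity correction stays
        # within 0.02 of the exact permutation p for balanced small groups
        rng = np.random.default_rng(7)
        worst = 0.0
        for n in (5, 6):
            for _ in range(50):
                y = rng.standard_normal(2 * n)
                g = np.r_[np.zeros(n), np.ones(n)]
                _, pa = v.wilcoxon_test(y, g)
                _, pe = v.wilcoxon_exact(y, g)
                worst = max(worst, abs(pa - pe))
        assert worst <= 0.02

    def test_matches_mannwhitneyu(self):
        # independent library route: same statistic and p
        rng = np.random.default_rng(3)
        y = rng.standard_normal(40)
        y[5] = y[10]  # inject a tie
        g = (rng.random(40) < 0.5).astype(float)
        u, p = v.wilcoxon_test(y, g)
        ref = stats.mannwhitneyu(
            y[g == 1], y[g == 0], method="asymptotic", use_continuity=True,
            alternative="two-sided",
        )
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(finite_floats, min_size=10, max_size=20),
        shift=finite_floats,
    )
    def test_invariant_to_constant_shift_and_monotone_transform(self, data, shift):
        y = np.asarray(data)
        g = np.array([0, 1] * (len(y) // 2) + [0] * (len(y) % 2), dtype=float)
        _, p0 = v.wilcoxon_test(y, g)
        _, p1 = v.wilcoxon_test(y + shift, g)
        _, p2 = v.wilcoxon_test(np.exp(y / 50.0), g)  # strictly increasing map
        assert p1 == pytest.approx(p0, abs=1e-9)
        assert p2 == pytest.approx(p0, abs=1e-9)


class TestBrownForsythe:
    def test_hand_computed_example(self):
        # |deviation-from-median| ANOVA on A=[0,1,2], B=[0,2,4]:
        # z_A=[1,0,1], z_B=[2,0,2] -> F = 0.8 on (1,4) df
        f, p = v.brown_forsythe_test([0, 1, 2, 0, 2, 4], [0, 0, 0, 1, 1, 1])
        assert f == pytest.approx(0.8)
        assert p == pytest.approx(stats.f.sf(0.8, 1, 4))

    def test_oracle_anova_on_absolute_deviations(self):
        # independent oracle: one-way ANOVA applied to |y - group median|
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.standard_normal(30)
            g = (rng.random(30) < 0.5).astype(float)
            if min((g == 0).sum(), (g == 1).sum()) < 2:
                continue
            f, p = v.brown_forsythe_test(y, g)
            z0 = np.abs(y[g == 0] - np.median(y[g == 0]))
            z1 = np.abs(y[g == 1] - np.median(y[g == 1]))
            ref = stats.f_oneway(z0, z1)
            assert f == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_multisets_give_f_zero(self):
        f, p = v.brown_forsythe_test([1, 2, 5, 1, 2, 5], [0, 0, 0, 1, 1, 1])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_phenotype_is_missing(self):
        f, p = v.brown_forsythe_test([2.0] * 10, [0] * 5 + [1] * 5)
        assert np.isnan(f) and np.isnan(p)

    def test_infinite_f_reports_smallest_positive_p(self):
        # zero spread of deviations within groups, nonzero between
        f, p = v.brown_forsythe_test([0, 0, 0, 0, -1, 1, -1, 1], [0, 0, 0, 0, 1, 1, 1, 1])
        assert np.isinf(f)
        assert 0 < p < 1e-300

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(finite_floats, min_size=10, max_size=20),
        shift=finite_floats,
    )
    def test_invariant_to_shift_and_sign_flip(self, data, shift):
        y = np.asarray(data)
        g = np.array([0, 1] * (len(y) // 2) + [0] * (len(y) % 2), dtype=float)
        f0, _ = v.brown_forsythe_test(y, g)
        f1, _ = v.brown_forsythe_test(y + shift, g)
        f2, _ = v.brown_forsythe_test(-y, g)
        if np.isnan(f0):
            assert np.isnan(f1) and np.isnan(f2)
        else:
            assert f1 == pytest.approx(f0, abs=1e-8)
            assert f2 == pytest.approx(f0, abs=1e-8)


class TestGenomeScan:
    def test_equals_cell_by_cell_loop(self, small_panels):
        g, panels, _ = small_panels
        e = panels["glucose"]
        for test, scalar in [("wilcoxon", v.wilcoxon_test), ("brown_forsythe", v.brown_forsythe_test)]:
            scan = v.genome_scan(e, g, test)
            for j in range(e.n_phenotypes):
                for m in range(0, g.n_markers, 7):
                    s, p = scalar(e.values[:, j], g.calls[:, m])
                    if np.isnan(p):
                        assert np.isnan(scan.p_value[j, m])
                    else:
                        assert scan.p_value[j, m] == pytest.approx(p, rel=1e-12)

    def test_missing_values_fall_back_consistently(self, small_panels):
        g, panels, _ = small_panels
        e = panels["glucose"]
        e.values[3, 1] = np.nan
        g.calls[5, 2] = np.nan
        scan = v.genome_scan(e, g, "wilcoxon")
        for j in [0, 1]:
            for m in [2, 3]:
                _, p = v.wilcoxon_test(e.values[:, j], g.calls[:, m])
                assert scan.p_value[j, m] == pytest.approx(p, rel=1e-12)
        # class sizes reflect the removed observations
        assert scan.n0[1, 2] + scan.n1[1, 2] <= e.n_segregants - 1

    def test_null_panel_p_values_calibrated(self):
        # unlinked markers, no genetic effect: Brown-Forsythe p approximately
        # uniform (KS < 0.05); Wilcoxon discrete hence sub-uniform
        cfg = v.SimConfig(
            n_segregants=109,
            chrom_lengths={"chr1": 205_000},
            cm_per_kb=100.0,  # r ~ 0.5: effectively independent markers
            n_null_phenotypes=200,
            seed=9,
        )
        g = v.simulate_genotypes(cfg)
        panels, _ = v.simulate_expression(g, cfg)
        sb = v.genome_scan(panels["glucose"], g, "brown_forsythe")
        p = sb.p_value.ravel()
        p = p[~np.isnan(p)]
        assert p.size >= 10_000
        assert stats.kstest(p, "uniform").statistic < 0.05
        sw = v.genome_scan(panels["glucose"], g, "wilcoxon")
        pw = sw.p_value.ravel()
        pw = pw[~np.isnan(pw)]
        assert (pw <= 0.01).mean() <= 0.01 + 0.005

    def test_and_epistasis_induces_marginal_variance_heterogeneity(self):
        # y = e*[A=1]*[B=1] + noise with balanced independent A,B gives
        # marginal class variances sigma^2 and sigma^2 + e^2/4 at locus A
        rng = np.random.default_rng(21)
        n, e_eff, sigma = 2000, 2.0, 1.0
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.5
        y = e_eff * (a & b) + rng.standard_normal(n) * sigma
        ratio = y[a].var(ddof=1) / y[~a].var(ddof=1)
        assert ratio == pytest.approx(1 + e_eff**2 / (4 * sigma**2), rel=0.10)
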