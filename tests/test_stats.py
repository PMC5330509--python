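"""Two-way sequential-SS ANOVA, Welch F/t, Bartlett, site correlations."""

import numpy as np
import pytest
from scipy import stats as sps

from isotroph.errors import AnalysisError
from isotroph.stats import (
    bartlett,
    site_correlation,
    two_way_anova,
    welch_oneway,
    welch_t,
)


def balanced_2x2(effect_a=1.0, effect_b=0.0, jitter=0.01):
    """Two replicates per cell at cell mean +- jitter; cell means additive."""
    values, fa, fb = [], [], []
    for a in (0, 1):
        for b in (0, 1):
            mean = effect_a * a + effect_b * b
            for d in (-jitter, jitter):
                values.append(mean + d)
                fa.append(f"A{a}")
                fb.append(f"B{b}")
    return values, fa, fb


class TestTwoWayAnova:
    def test_effect_only_on_first_factor(self):
        values, fa, fb = balanced_2x2(effect_a=1.0)
        table = two_way_anova(values, fa, fb)
        assert table["species"].F > 0
        assert table["site"].F == pytest.approx(0.0, abs=1e-6)
        assert table["species:site"].F == pytest.approx(0.0, abs=1e-6)

    def test_all_equal_observations(self):
        table = two_way_anova([5.0] * 8, ["a"] * 4 + ["b"] * 4, ["x", "y"] * 4)
        for term in ("species", "site", "species:site"):
            assert table[term].F == 0.0

    def test_hand_sum_of_squares_oracle(self):
        """Balanced 3 species x 2 sites, n = 2 per cell: sequential SS reduce
        to the classical balanced formulas, computed here directly."""
        rng = np.random.default_rng(42)
        species = np.repeat(["s1", "s2", "s3"], 4)
        site = np.tile(["L", "Y"], 6)
        y = rng.standard_normal(12) + np.repeat([0.0, 1.0, 2.0], 4)
        table = two_way_anova(y, species, site)

        grand = y.mean()
        ss_species = sum(
            4 * (y[species == s].mean() - grand) ** 2 for s in ("s1", "s2", "s3")
        )
        ss_site = sum(6 * (y[site == s].mean() - grand) ** 2 for s in ("L", "Y"))
        ss_cells = 0.0
        for s in ("s1", "s2", "s3"):
            for t in ("L", "Y"):
                cell = y[(species == s) & (site == t)]
                ss_cells += len(cell) * (cell.mean() - grand) ** 2
        ss_int = ss_cells - ss_species - ss_site
        ss_resid = sum(
            ((y[(species == s) & (site == t)]
              - y[(species == s) & (site == t)].mean()) ** 2).sum()
            for s in ("s1", "s2", "s3") for t in ("L", "Y")
        )
        assert table["species"].ss == pytest.approx(ss_species)
        assert table["site"].ss == pytest.approx(ss_site)
        assert table["species:site"].ss == pytest.approx(ss_int)
        assert table.ss_resid == pytest.approx(ss_resid)
        df_resid = 6
        assert table["species"].F == pytest.approx(
            (ss_species / 2) / (ss_resid / df_resid)
        )

    def test_interaction_df_restricted_to_shared_species(self, rng):
        """With 5 species but only 2 present at both sites, the interaction
        carries 1 df (cells - additive rank)."""
        species, site, values = [], [], []
        layout = {"s1": ["L", "Y"], "s2": ["L", "Y"], "s3": ["L"], "s4": ["Y"], "s5": ["L"]}
        for sp, sites in layout.items():
            for st_ in sites:
                for _ in range(3):
                    species.append(sp)
                    site.append(st_)
                    values.append(float(rng.standard_normal()))
        table = two_way_anova(values, species, site)
        assert table["species"].df == 4
        assert table["site"].df == 1
        assert table["species:site"].df == 1

    def test_affine_invariance_of_F(self, rng):
        values, fa, fb = balanced_2x2(effect_a=1.0, effect_b=0.5, jitter=0.3)
        t1 = two_way_anova(values, fa, fb)
        t2 = two_way_anova([3.0 * v - 7.0 for v in values], fa, fb)
        for term in ("species", "site", "species:site"):
            assert t2[term].F == pytest.approx(t1[term].F, rel=1e-9)


class TestWelchOneway:
    def test_equal_group_means(self):
        res = welch_oneway([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_equals_t_squared(self, rng):
        for _ in range(10):
            x = rng.standard_normal(8) + 1.0
            y = 2.0 * rng.standard_normal(12)
            f = welch_oneway(
                np.concatenate([x, y]), ["x"] * 8 + ["y"] * 12
            )
            t = welch_t(x, y)
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
            assert f.p == pytest.approx(t.p, rel=1e-9)

    def test_shift_invariance(self, rng):
        y = rng.standard_normal(15)
        g = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        assert welch_oneway(y + 100.0, g).statistic == pytest.approx(
            welch_oneway(y, g).statistic, rel=1e-9
        )

    def test_agrees_with_classical_F_when_balanced_equal_variance(self, rng):
        """Two balanced groups with identical sample variances: Welch F
        coincides with the classical one-way F (the k = 2 correction term
        vanishes and the pooled variance equals each group variance)."""
        x = rng.standard_normal(20)
        y = x + 0.7  # shifted copy: exactly equal sample variances
        welch = welch_oneway(np.concatenate([x, y]), ["a"] * 20 + ["b"] * 20)
        classic = sps.f_oneway(x, y)
        assert welch.statistic == pytest.approx(classic.statistic, abs=1e-10)
        assert welch.p == pytest.approx(classic.pvalue, abs=1e-10)


class TestBartlett:
    def test_identical_shifted_groups_give_zero(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        res = bartlett(np.concatenate([x, x + 10, x - 3]), ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 2  # groups minus one

    def test_three_group_direct_formula(self, rng):
        groups = [rng.standard_normal(6), 2 * rng.standard_normal(8), 0.5 * rng.standard_normal(5)]
        y = np.concatenate(groups)
        g = ["a"] * 6 + ["b"] * 8 + ["c"] * 5
        res = bartlett(y, g)
        # direct formula
        k = 3
        ns = np.array([6.0, 8.0, 5.0])
        vs = np.array([v.var(ddof=1) for v in groups])
        N = ns.sum()
        sp2 = ((ns - 1) @ vs) / (N - k)
        num = (N - k) * np.log(sp2) - ((ns - 1) * np.log(vs)).sum()
        den = 1 + (np.sum(1 / (ns - 1)) - 1 / (N - k)) / (3 * (k - 1))
        assert res.statistic == pytest.approx(num / den, rel=1e-9)
        assert res.p == pytest.approx(sps.chi2.sf(num / den, k - 1), rel=1e-9)

    def test_zero_variance_group_is_error(self):
        with pytest.raises(AnalysisError):
            bartlett([1.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"])


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_sign_flip_symmetry(self, rng):
        x, y = rng.standard_normal(7) + 1, rng.standard_normal(9)
        a = welch_t(x, y)
        b = welch_t(y, x)
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p == pytest.approx(a.p)

    def test_textbook_small_samples_closed_formula(self):
        x = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6, 23.1, 19.6])
        y = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2, 21.9, 22.1])
        res = welch_t(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se = np.sqrt(vx / 12 + vy / 12)
        t_direct = (x.mean() - y.mean()) / se
        df_direct = (vx / 12 + vy / 12) ** 2 / (
            (vx / 12) ** 2 / 11 + (vy / 12) ** 2 / 11
        )
        assert res.statistic == pytest.approx(t_direct, rel=1e-12)
        assert res.df == pytest.approx(df_direct, rel=1e-12)
        scipy_res = sps.ttest_ind(x, y, equal_var=False)
        assert res.p == pytest.approx(scipy_res.pvalue, rel=1e-9)

    def test_uniform_p_under_null(self):
        """Two-sided p rejects at ~alpha under the null (2000 replicates)."""
        rng = np.random.default_rng(99)
        rej = sum(
            welch_t(rng.standard_normal(10), rng.standard_normal(12)).p <= 0.05
            for _ in range(2000)
        )
        assert abs(rej / 2000 - 0.05) < 0.02


class TestSiteCorrelation:
    def test_identical_vectors(self):
        res = site_correlation([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(1.0)

    def test_collinear_three_points(self):
        res = site_correlation([1.0, 2.0, 3.0], [10.0, 30.0, 50.0])
        assert abs(res.statistic) == pytest.approx(1.0)

    def test_leave_one_out_flags_planted_outlier(self, rng):
        x = np.linspace(0, 6, 7)
        y = 2.0 * x + 0.05 * rng.standard_normal(7)
        y[3] += 15.0  # planted outlier
        labels = [f"sp{i}" for i in range(7)]
        res = site_correlation(x, y, labels=labels, leave_one_out=True)
        assert res.extra["most_influential"] == "sp3"
        assert res.extra["leave_one_out"]["sp3"]["r"] > abs(res.statistic)

    def test_zero_variance_is_error(self):
        with pytest.raises(AnalysisError):
            site_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
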