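"""Split-plot ANOVA, sphericity epsilons, LSD post-hocs, paired t, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from setshift.stats import (
    StatsError,
    mauchly_test,
    mixed_rm_anova,
    oneway_anova_lsd,
    paired_t,
    pearson_correlation,
    sphericity_epsilons,
)


def _long(Y, groups, subjects=None):
    n, k = Y.shape
    subjects = subjects or [f"s{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(
                dict(subject=subjects[i], group=groups[i], stage=f"w{j}", value=Y[i, j])
            )
    return pd.DataFrame(rows)


class TestSphericity:
    def test_two_levels_hold_trivially(self):
        rng = np.random.default_rng(0)
        assert sphericity_epsilons(rng.normal(size=(10, 2))) == (1.0, 1.0)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(1)
        subj = rng.normal(size=(200, 1))
        X = subj + rng.normal(size=(200, 5))  # equal variances/covariances
        gg, hf = sphericity_epsilons(X)
        assert gg > 0.95
        assert hf >= gg

    def test_gg_lower_bound_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = int(rng.integers(5, 20))
            k = int(rng.integers(3, 7))
            X = rng.normal(size=(n, k)) @ rng.normal(size=(k, k))
            gg, hf = sphericity_epsilons(X)
            assert 1.0 / (k - 1) - 1e-12 <= gg <= 1.0
            assert hf >= gg

    def test_epsilons_match_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5)) @ rng.normal(size=(5, 5))
        gg, hf = sphericity_epsilons(X)
        assert gg == pytest.approx(pg.epsilon(pd.DataFrame(X), correction="gg"), abs=1e-10)
        assert hf == pytest.approx(pg.epsilon(pd.DataFrame(X), correction="hf"), abs=1e-10)

    def test_mauchly_w_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 4)) @ rng.normal(size=(4, 4))
        W, _ = mauchly_test(X)
        assert W == pytest.approx(pg.sphericity(pd.DataFrame(X)).W, abs=1e-10)

    def test_missing_cells_rejected(self):
        X = np.ones((5, 4))
        X[0, 0] = np.nan
        with pytest.raises(StatsError):
            sphericity_epsilons(X)


class TestMixedAnova:
    def test_two_level_within_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(12, 2))
        df = _long(Y, ["g"] * 12)
        (res,) = mixed_rm_anova(df, "group", "stage")
        t = paired_t(Y[:, 0], Y[:, 1])
        assert res.effect == "within"
        assert res.F == pytest.approx(t.t**2, rel=1e-6)
        assert res.p_uncorrected == pytest.approx(t.p, rel=1e-6)

    def test_location_shift_leaves_f_unchanged(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(24, 7))
        groups = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        base = mixed_rm_anova(_long(Y, groups), "group", "stage")
        shifted = mixed_rm_anova(_long(Y + 1000.0, groups), "group", "stage")
        for r0, r1 in zip(base, shifted):
            assert r1.F == pytest.approx(r0.F, rel=1e-9)

    def test_sum_of_squares_partition_is_exact(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(18, 5)) + rng.normal(size=(18, 1))
        groups = np.repeat(["a", "b", "c"], 6)
        n, k, a = 18, 5, 3
        grand = Y.mean()
        ss_total = ((Y - grand) ** 2).sum()
        res = {r.effect: r for r in mixed_rm_anova(_long(Y, list(groups)), "group", "stage")}
        # reconstruct all five components from the returned F ratios' SS
        subj_means = Y.mean(axis=1)
        ss_between_subj = k * ((subj_means - grand) ** 2).sum()
        group_means = np.array([Y[groups == g].mean() for g in ("a", "b", "c")])
        ss_A = k * 6 * ((group_means - grand) ** 2).sum()
        level_means = Y.mean(axis=0)
        ss_B = n * ((level_means - grand) ** 2).sum()
        cells = np.array([Y[groups == g].mean(axis=0) for g in ("a", "b", "c")])
        ss_cells = 6 * ((cells - grand) ** 2).sum()
        ss_AB = ss_cells - ss_A - ss_B
        ss_err = ss_total - ss_between_subj - ss_B - ss_AB
        ss_subj = ss_between_subj - ss_A
        # identity: components sum to the total
        assert ss_A + ss_subj + ss_B + ss_AB + ss_err == pytest.approx(
            ss_total, rel=1e-8
        )
        # and the returned F ratios equal their MS ratios
        assert res["between"].F == pytest.approx(
            (ss_A / (a - 1)) / (ss_subj / (a * 5)), rel=1e-8
        )
        assert res["within"].F == pytest.approx(
            (ss_B / (k - 1)) / (ss_err / ((k - 1) * a * 5)), rel=1e-8
        )

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(24, 7)) + np.linspace(0, 1, 7)
        groups = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        df = _long(Y, groups)
        mine = {r.effect: r for r in mixed_rm_anova(df, "group", "stage")}
        ref = pg.mixed_anova(
            df, dv="value", within="stage", subject="subject", between="group"
        ).set_index("Source")
        assert mine["between"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert mine["within"].F == pytest.approx(ref.loc["stage", "F"], rel=1e-9)
        assert mine["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine["within"].p_uncorrected == pytest.approx(
            ref.loc["stage", "p_unc"], rel=1e-6
        )

    def test_correction_never_shrinks_the_p_value(self):
        rng = np.random.default_rng(9)
        # strongly non-spherical within-covariance (to force a correction)
        # plus a real within-level effect, where the adjustment is conservative
        base = rng.normal(size=(30, 1))
        Y = np.hstack([base + rng.normal(scale=0.1, size=(30, 1)),
                       base + 0.3 + rng.normal(scale=0.1, size=(30, 1)),
                       6.0 + rng.normal(scale=5.0, size=(30, 1)),
                       rng.normal(scale=5.0, size=(30, 1))])
        res = {r.effect: r for r in mixed_rm_anova(_long(Y, ["g"] * 30), "group", "stage")}
        within = res["within"]
        assert within.correction_used in ("GG", "HF")
        assert within.p_corrected >= within.p_uncorrected
        assert within.epsilon_gg <= within.epsilon_hf + 1e-12

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(15, 4))
        groups = ["a"] * 8 + ["b"] * 7
        with pytest.raises(StatsError, match="unbalanced"):
            mixed_rm_anova(_long(Y, groups), "group", "stage")

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(11)
        df = _long(rng.normal(size=(6, 4)), ["a"] * 3 + ["b"] * 3)
        with pytest.raises(StatsError):
            mixed_rm_anova(df.iloc[:-1], "group", "stage")


class TestOneWayLsd:
    def test_two_groups_reduce_to_pooled_t(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=10), rng.normal(0.5, size=10)
        res = oneway_anova_lsd({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b)
        assert res.pairwise[0].p_lsd == pytest.approx(p, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = oneway_anova_lsd({"a": g, "b": g, "c": g})
        assert res.F == pytest.approx(0.0, abs=1e-12)
        for pw in res.pairwise:
            assert pw.mean_diff == 0.0

    def test_agreement_with_direct_sum_of_squares(self):
        rng = np.random.default_rng(13)
        data = {g: rng.normal(i, 1, size=8) for i, g in enumerate("abc")}
        res = oneway_anova_lsd(data)
        F_ref, p_ref = sps.f_oneway(*data.values())
        assert res.F == pytest.approx(F_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            oneway_anova_lsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(StatsError):
            oneway_anova_lsd({"a": [1.0, 2.0]})


class TestPairedT:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        t_sp, p_sp = sps.ttest_rel(x, y)
        assert res.p == pytest.approx(p_sp, abs=1e-10)

    def test_zero_variance_differences_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(StatsError, match="zero variance"):
            paired_t(x, x)
        with pytest.raises(StatsError, match="zero variance"):
            paired_t(x, x + 3.0)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x).r == pytest.approx(1.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(15)
        n, sims = 8, 5000
        X = rng.normal(size=(sims, n))
        Y = rng.normal(size=(sims, n))
        rej = sum(pearson_correlation(X[i], Y[i]).p < 0.05 for i in range(sims))
        lo, hi = sps.binom.interval(0.999, sims, 0.05)
        assert lo <= rej <= hi

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
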