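"""Group-statistics tests: outlier rule, ANOVAs, post-hocs, correlations.

The mixed-ANOVA oracle is an explicit split-plot sums-of-squares
decomposition written from the textbook formulas, independent of the
implementation path.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import brentq

from pefmri.stats import (
    exclude_outliers,
    medication_factor_anova,
    mixed_anova,
    posthoc_within,
    spearman_corr,
    univariate_by_session,
)

SESSIONS = ("placebo", "amisulpride", "pramipexole")


def records_from_matrix(values, groups=None):
    """values[i][j]: subject i, session j -> tidy CopeRecord table."""
    values = np.asarray(values, float)
    n = len(values)
    groups = groups or ["control"] * (n // 2) + ["OCD"] * (n - n // 2)
    rows = []
    for i in range(n):
        for j, s in enumerate(SESSIONS):
            rows.append(
                {
                    "subject_id": f"s{i:02d}",
                    "group": groups[i],
                    "session": s,
                    "roi": "cingulate",
                    "contrast": "pe_neg",
                    "value": values[i, j],
                }
            )
    return pd.DataFrame(rows)


def split_plot_oracle(values, n_per_group):
    """Hand sums-of-squares for a balanced two-group x k-session design.

    Returns dict of (F, df_num, df_den, partial_eta_sq) per effect.
    """
    y = np.asarray(values, float)
    n, k = y.shape
    g = 2
    ng = n_per_group
    gm = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)
    group_of = np.repeat([0, 1], ng)
    group_means = np.array([y[group_of == q].mean() for q in range(g)])
    cell_means = np.array(
        [[y[group_of == q][:, j].mean() for j in range(k)] for q in range(g)]
    )
    ss_group = k * ng * ((group_means - gm) ** 2).sum()
    ss_between = k * ((subj_means - gm) ** 2).sum()
    ss_subj = ss_between - ss_group
    ss_session = n * ((sess_means - gm) ** 2).sum()
    ss_inter = ng * (
        (cell_means - group_means[:, None] - sess_means[None, :] + gm) ** 2
    ).sum()
    ss_within = ((y - subj_means[:, None]) ** 2).sum()
    ss_err = ss_within - ss_session - ss_inter
    out = {}
    out["group"] = (
        (ss_group / (g - 1)) / (ss_subj / (n - g)),
        g - 1,
        n - g,
        ss_group / (ss_group + ss_subj),
    )
    df_err = (n - g) * (k - 1)
    out["session"] = (
        (ss_session / (k - 1)) / (ss_err / df_err),
        k - 1,
        df_err,
        ss_session / (ss_session + ss_err),
    )
    out["interaction"] = (
        (ss_inter / ((g - 1) * (k - 1))) / (ss_err / df_err),
        (g - 1) * (k - 1),
        df_err,
        ss_inter / (ss_inter + ss_err),
    )
    return out


class TestExcludeOutliers:
    def plant(self, base, target_z):
        """Append one value landing at exactly target_z pooled SDs."""

        def pooled_z(v):
            vals = np.append(base, v)
            return (v - vals.mean()) / vals.std(ddof=1)

        hi = base.mean() + 50 * base.std(ddof=1)
        return brentq(lambda v: pooled_z(v) - target_z, base.mean(), hi)

    def test_extreme_point_excluded(self):
        vals = np.zeros((12, 3))
        vals[0, 0] = 0.01  # avoid zero pooled SD
        vals[5, 1] = 10.0
        kept, reports = exclude_outliers(records_from_matrix(vals))
        assert reports[("cingulate", "pe_neg")].excluded == ["s05"]
        assert "s05" not in set(kept["subject_id"])

    def test_exclusion_is_listwise_across_sessions(self):
        vals = np.zeros((12, 3))
        vals[0, 0] = 0.01
        vals[5, 1] = 10.0
        kept, _ = exclude_outliers(records_from_matrix(vals))
        assert len(kept) == 11 * 3  # all three sessions of s05 removed

    def test_29_sd_kept_35_sd_excluded_matches_zscan(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0.0, 1.0, 36 * 3 - 1)
        for target, expect_excluded in ((2.9, False), (3.5, True)):
            planted = self.plant(base, target)
            vals = np.append(base, planted).reshape(36, 3)
            df = records_from_matrix(vals)
            kept, reports = exclude_outliers(df)
            planted_subject = "s35"
            # brute-force z scan over the pooled sample
            allv = df["value"].to_numpy()
            z = np.abs((allv - allv.mean()) / allv.std(ddof=1))
            scan = set(
                df.loc[z > 3.0, "subject_id"]
            )
            assert reports[("cingulate", "pe_neg")].excluded == sorted(scan)
            assert (planted_subject in scan) == expect_excluded

    def test_pooling_is_per_roi_contrast(self):
        vals = np.random.default_rng(9).normal(size=(12, 3))
        df = records_from_matrix(vals)
        other = df.copy()
        other["contrast"] = "pe_pos"
        other.loc[other.subject_id == "s03", "value"] = 25.0
        kept, reports = exclude_outliers(pd.concat([df, other], ignore_index=True))
        assert reports[("cingulate", "pe_pos")].excluded == ["s03"]
        assert reports[("cingulate", "pe_neg")].excluded == []
        # s03 is only dropped from the pe_pos analysis
        assert "s03" in set(kept[kept.contrast == "pe_neg"]["subject_id"])
        assert "s03" not in set(kept[kept.contrast == "pe_pos"]["subject_id"])


class TestMixedAnova:
    def test_matches_split_plot_oracle_on_balanced_toy(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(4, 3)) + np.array([[0.0], [0.0], [1.0], [1.2]])
        res = {r.effect: r for r in mixed_anova(records_from_matrix(vals))}
        oracle = split_plot_oracle(vals, 2)
        for effect, (F, dfn, dfd, eta) in oracle.items():
            assert res[effect].F == pytest.approx(F, rel=1e-8)
            assert res[effect].df_num == dfn
            assert res[effect].df_den == dfd
            assert res[effect].partial_eta_sq == pytest.approx(eta, rel=1e-8)

    def test_identical_group_profiles_give_zero_group_f(self):
        # each control subject has an exact OCD twin: group and interaction
        # sums of squares vanish by construction, error SS does not
        half = np.random.default_rng(10).normal(size=(4, 3))
        vals = np.vstack([half, half])
        res = {r.effect: r for r in mixed_anova(records_from_matrix(vals))}
        assert res["group"].F == pytest.approx(0.0, abs=1e-12)
        assert res["interaction"].F == pytest.approx(0.0, abs=1e-12)

    def test_missing_session_rejected(self):
        df = records_from_matrix(np.random.default_rng(0).normal(size=(6, 3)))
        with pytest.raises(ValueError):
            mixed_anova(df.drop(index=1))

    def test_interaction_type_i_error_near_nominal(self):
        rng = np.random.default_rng(21)
        hits = 0
        reps = 300
        for _ in range(reps):
            vals = rng.normal(size=(12, 3))
            res = {r.effect: r for r in mixed_anova(records_from_matrix(vals))}
            hits += res["interaction"].p < 0.05
        assert 0.02 <= hits / reps <= 0.09


class TestPosthoc:
    def test_identical_sessions_all_p_one(self):
        vals = np.tile(np.random.default_rng(0).normal(size=(6, 1)), (1, 3))
        _, pairs = posthoc_within(records_from_matrix(vals))
        assert all(p.p_adj == 1.0 for p in pairs)

    def test_adjusted_never_below_raw(self):
        vals = np.random.default_rng(1).normal(size=(8, 3))
        _, pairs = posthoc_within(records_from_matrix(vals))
        assert all(p.p_adj >= p.p_raw for p in pairs)
        assert len(pairs) == 3

    def test_planted_placebo_elevation_pattern(self):
        # placebo raised by 0.5 with small within-subject noise: both
        # placebo contrasts significant, drug pair not, in most seeds
        hits = 0
        for s in range(25):
            rng = np.random.default_rng(100 + s)
            base = rng.normal(0.0, 0.4, (15, 1))
            vals = base + rng.normal(0.0, 0.25, (15, 3))
            vals[:, 0] += 0.5
            _, pairs = posthoc_within(
                records_from_matrix(vals, groups=["OCD"] * 15), SESSIONS
            )
            d = {p.pair: p for p in pairs}
            hits += (
                d[("placebo", "amisulpride")].p_adj < 0.05
                and d[("placebo", "pramipexole")].p_adj < 0.05
                and d[("amisulpride", "pramipexole")].p_adj > 0.05
            )
        assert hits >= 20


class TestUnivariate:
    def test_equal_means_zero_f_and_toy_hand_computation(self):
        vals = np.zeros((6, 3))
        vals[:, 0] = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        res = univariate_by_session(records_from_matrix(vals), "placebo")
        assert res.F == pytest.approx(0.0, abs=1e-12)
        # toy 3+3: groups (1,2,3) vs (3,4,5): F = 6
        vals[:, 1] = [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]
        res = univariate_by_session(records_from_matrix(vals), "amisulpride")
        assert res.F == pytest.approx(6.0, rel=1e-10)
        assert (res.df_num, res.df_den) == (1, 4)
        assert res.partial_eta_sq == pytest.approx(6.0 / (6.0 + 4.0), rel=1e-10)

    def test_f_equals_t_squared_on_random_data(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(14, 3))
        df = records_from_matrix(vals)
        res = univariate_by_session(df, "placebo")
        part = df[df.session == "placebo"]
        a = part[part.group == "control"]["value"]
        b = part[part.group == "OCD"]["value"]
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert res.F == pytest.approx(t**2, abs=1e-10)

    def test_empty_group_rejected(self):
        df = records_from_matrix(np.zeros((6, 3)), groups=["OCD"] * 6)
        with pytest.raises(ValueError):
            univariate_by_session(df, "placebo")


class TestMedicationFactor:
    def test_single_class_warns_and_skips_between(self):
        vals = np.random.default_rng(2).normal(size=(8, 3))
        df = records_from_matrix(vals, groups=["OCD"] * 8)
        med = pd.Series({f"s{i:02d}": "high" for i in range(8)})
        with pytest.warns(UserWarning, match="single medication class"):
            res = medication_factor_anova(df, med)
        assert [r.effect for r in res] == ["session"]

    def test_null_medication_factor_p_uniformish(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(150):
            vals = rng.normal(size=(10, 3))
            df = records_from_matrix(vals, groups=["OCD"] * 10)
            med = pd.Series(
                {f"s{i:02d}": m for i, m in enumerate(
                    rng.permutation(["high"] * 5 + ["not_high"] * 5)
                )}
            )
            res = {r.effect: r for r in medication_factor_anova(df, med)}
            ps.append(res["group"].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_session_effect_survives_medication_factor(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 0.2, size=(10, 3)) + np.array([1.0, 0.0, 0.0])
        df = records_from_matrix(vals, groups=["OCD"] * 10)
        med = pd.Series(
            {f"s{i:02d}": ("high" if i < 5 else "not_high") for i in range(10)}
        )
        res = {r.effect: r for r in medication_factor_anova(df, med)}
        assert res["session"].p < 0.01


class TestSpearman:
    def test_perfectly_decreasing(self):
        rho, p = spearman_corr(np.arange(12.0), -np.arange(12.0) ** 3)
        assert rho == pytest.approx(-1.0)
        assert p < 1e-6

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, _ = spearman_corr(x, y)
        rho2, _ = spearman_corr(np.exp(x), y)
        assert rho1 == pytest.approx(rho2)

    def test_fifteen_pair_tie_fixture_matches_rank_formula(self):
        x = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8, 9, 7, 9], float)
        y = np.array([2, 7, 1, 8, 2, 8, 1, 8, 2, 8, 4, 5, 9, 0, 4], float)
        rho, _ = spearman_corr(x, y)
        # brute force: Pearson correlation of average ranks
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_small_n_uses_permutation_and_is_deterministic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 7.0])
        r1 = spearman_corr(x, y)
        r2 = spearman_corr(x, y)
        assert r1 == r2
        assert 0.0 < r1[1] <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr(np.ones(8), np.arange(8.0))
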