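import itertools
import math

import numpy as np
import pandas as pd
import pytest

from persifade.analysis import (
    RegressionFit,
    cross_predict,
    drift_check,
    fillin_regression,
    linear_fit,
    rm_anova,
    speed_from_slope,
    synchrony_estimates,
    within_subject_ci,
)
from persifade.geometry import AnnulusSpec, DisplayGeometry, FillInFeatures, fillin_features


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_rm_anova(cube):
    """Loop-based sums-of-squares decomposition via inclusion-exclusion of
    marginal means; independent of the vectorized implementation."""
    n = cube.shape[0]
    levels = cube.shape[1:]
    k = len(levels)

    def mean_at(keep, idx, s=None):
        sel = [slice(None)] * (k + 1)
        if s is not None:
            sel[0] = s
        for ax, i in zip(keep, idx):
            sel[ax + 1] = i
        return float(np.mean(cube[tuple(sel)]))

    out = {}
    for r in range(1, k + 1):
        for S in itertools.combinations(range(k), r):
            df1 = int(np.prod([levels[j] - 1 for j in S]))
            mult = int(np.prod([levels[j] for j in range(k) if j not in S]))
            ss_eff, ss_err = 0.0, 0.0
            for idx in itertools.product(*(range(levels[j]) for j in S)):
                term = 0.0
                terms_s = [0.0] * n
                for rr in range(r + 1):
                    for T in itertools.combinations(S, rr):
                        sub_idx = tuple(idx[S.index(j)] for j in T)
                        sign = (-1) ** (r - rr)
                        term += sign * mean_at(T, sub_idx)
                        for s in range(n):
                            terms_s[s] += sign * mean_at(T, sub_idx, s=s)
                ss_eff += term ** 2
                ss_err += sum((ts - term) ** 2 for ts in terms_s)
            ss_eff *= n * mult
            ss_err *= mult
            df2 = (n - 1) * df1
            f = (ss_eff / df1) / (ss_err / df2)
            out[":".join(f"f{j}" for j in S)] = (f, df1, df2)
    return out


def oracle_ci_halfwidth(cube, level=0.95):
    from scipy import stats
    n, k = cube.shape
    resid = np.empty_like(cube, dtype=float)
    gm = cube.mean()
    for s in range(n):
        for c in range(k):
            resid[s, c] = cube[s, c] - cube[s].mean() - cube[:, c].mean() + gm
    ms = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return stats.t.ppf(1 - (1 - level) / 2, (n - 1) * (k - 1)) * math.sqrt(ms / n)


def long_form(cube, factor_names):
    rows = []
    for s in range(cube.shape[0]):
        for idx in itertools.product(*(range(l) for l in cube.shape[1:])):
            row = {"subject": f"s{s}", "y": cube[(s,) + idx]}
            row.update({f: i for f, i in zip(factor_names, idx)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synchrony estimates
# ---------------------------------------------------------------------------

class TestSynchronyEstimates:
    def make_records(self):
        rows = []
        for task, dt in [("onset", 30.0), ("offset", 530.0)]:
            for rep in range(3):
                rows.append({"subject": "s1", "size_px": 100, "task": task,
                             "delta_t_ms": dt, "n_reps": 3, "converged": True})
        return pd.DataFrame(rows)

    def test_basic_arithmetic(self):
        est = synchrony_estimates(self.make_records())
        row = est.iloc[0]
        assert (row["E"], row["D_off"], row["VP"]) == (30.0, 530.0, 500.0)
        assert row["sd_on"] == row["sd_off"] == 0.0

    def test_vp_identity(self, exp1_trials):
        est = synchrony_estimates(exp1_trials)
        assert np.allclose(est["VP"], est["D_off"] - est["E"])

    def test_missing_task_cell_marked_incomplete(self):
        rec = self.make_records()
        rec = rec[rec["task"] == "onset"]
        est = synchrony_estimates(rec)
        assert not est["complete"].iloc[0]
        assert np.isnan(est["VP"].iloc[0])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_matches_brute_force_oracle_2x2x2(self):
        rng = np.random.default_rng(0)
        cube = rng.normal(500, 80, size=(9, 2, 2, 2))
        df = long_form(cube, ["f0", "f1", "f2"])
        table = rm_anova(df, "y", ["f0", "f1", "f2"])
        oracle = oracle_rm_anova(cube)
        for effect, (f, df1, df2) in oracle.items():
            row = table.loc[effect]
            assert row["F"] == pytest.approx(f, abs=1e-8, rel=1e-8)
            assert (row["df1"], row["df2"]) == (df1, df2)

    def test_matches_oracle_with_multilevel_factor(self):
        rng = np.random.default_rng(1)
        cube = rng.normal(0, 1, size=(7, 4, 3))
        df = long_form(cube, ["f0", "f1"])
        table = rm_anova(df, "y", ["f0", "f1"])
        for effect, (f, df1, df2) in oracle_rm_anova(cube).items():
            assert table.loc[effect, "F"] == pytest.approx(f, abs=1e-8, rel=1e-8)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(2)
        cube = rng.normal(0, 1, size=(8, 2, 3))
        df = long_form(cube, ["A", "B"])
        mine = rm_anova(df, "y", ["A", "B"])
        theirs = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        assert mine.loc["A", "F"] == pytest.approx(theirs.loc["A", "F Value"])
        assert mine.loc["B", "F"] == pytest.approx(theirs.loc["B", "F Value"])
        assert mine.loc["A:B", "F"] == pytest.approx(theirs.loc["A:B", "F Value"])

    def test_gg_epsilon_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(3)
        cube = rng.normal(0, 1, size=(10, 4))
        cube[:, 0] += rng.normal(0, 3, size=10)  # break sphericity
        df = long_form(cube, ["f0"])
        mine = rm_anova(df, "y", ["f0"])
        theirs = pg.rm_anova(data=df, dv="y", within="f0", subject="subject",
                             correction=True)
        assert mine.loc["f0", "eps_gg"] == pytest.approx(
            float(theirs["eps"].iloc[0]), abs=1e-6)
        gg_col = [c for c in theirs.columns if "GG" in c][0]
        assert mine.loc["f0", "p_gg"] == pytest.approx(
            float(theirs[gg_col].iloc[0]), abs=1e-6)

    def test_equal_means_give_zero_f(self):
        cube = np.tile(np.arange(6, dtype=float)[:, None, None], (1, 2, 2))
        df = long_form(cube, ["f0", "f1"])
        table = rm_anova(df, "y", ["f0", "f1"])
        assert table.loc["f0", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_level_factor_has_unit_epsilon(self):
        rng = np.random.default_rng(4)
        df = long_form(rng.normal(0, 1, size=(6, 2)), ["f0"])
        table = rm_anova(df, "y", ["f0"])
        assert table.loc["f0", "eps_gg"] == 1.0

    def test_unbalanced_input_raises_listing_cells(self):
        rng = np.random.default_rng(5)
        df = long_form(rng.normal(0, 1, size=(5, 2, 2)), ["f0", "f1"])
        df = df[~((df["subject"] == "s0") & (df["f0"] == 1) & (df["f1"] == 0))]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(df, "y", ["f0", "f1"])


class TestWithinSubjectCI:
    def test_matches_explicit_formula(self):
        rng = np.random.default_rng(6)
        cube = rng.normal(100, 10, size=(9, 4))
        df = long_form(cube, ["cond"])
        assert within_subject_ci(df, "y", ["cond"]) == pytest.approx(
            oracle_ci_halfwidth(cube), abs=1e-10)

    def test_zero_interaction_gives_zero_halfwidth(self):
        subj = np.arange(5, dtype=float)[:, None]
        cond = np.array([[1.0, 2.0, 3.0]])
        df = long_form(subj + cond, ["cond"])
        assert within_subject_ci(df, "y", ["cond"]) == pytest.approx(0.0,
                                                                     abs=1e-10)

    def test_invariant_to_per_subject_constant(self):
        rng = np.random.default_rng(7)
        cube = rng.normal(0, 1, size=(8, 3))
        shifted = cube + rng.normal(0, 50, size=(8, 1))
        a = within_subject_ci(long_form(cube, ["c"]), "y", ["c"])
        b = within_subject_ci(long_form(shifted, ["c"]), "y", ["c"])
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_subject_rejected(self):
        df = long_form(np.zeros((1, 3)), ["c"])
        with pytest.raises(ValueError):
            within_subject_ci(df, "y", ["c"])


# ---------------------------------------------------------------------------
# drift QC
# ---------------------------------------------------------------------------

class TestDriftCheck:
    def make(self, values, subject="s1"):
        return pd.DataFrame({
            "subject": subject, "task": "offset",
            "trial_index": np.arange(len(values)),
            "delta_t_ms": values,
        })

    def test_monotone_increase_is_flagged(self):
        out = drift_check(self.make(np.linspace(50, 900, 20)))
        assert out["flagged"].iloc[0]
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_sequence_not_flagged(self):
        out = drift_check(self.make(np.full(20, 400.0)))
        assert not out["flagged"].iloc[0]

    def test_decreasing_sequence_not_flagged(self):
        out = drift_check(self.make(np.linspace(900, 50, 20)))
        assert not out["flagged"].iloc[0]

    def test_rho_matches_manual_rank_correlation(self):
        rng = np.random.default_rng(8)
        y = rng.normal(400, 60, size=25)
        out = drift_check(self.make(y))
        # oracle: Pearson correlation of ranks
        ranks = pd.Series(y).rank().to_numpy()
        manual = np.corrcoef(np.arange(len(y)) + 1, ranks)[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(manual, abs=1e-12)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="offset trials"):
            drift_check(self.make(np.arange(5.0)))


# ---------------------------------------------------------------------------
# regression and speed conversion
# ---------------------------------------------------------------------------

class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        slope, intercept, r = linear_fit(x, 2 * x + 1)
        assert (slope, intercept, r) == pytest.approx((2.0, 1.0, 1.0))

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        y = 3 * x + rng.normal(0, 0.5, 30)
        slope, intercept, r = linear_fit(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert intercept == pytest.approx(beta[0], abs=1e-10)
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert np.sign(r) == np.sign(slope)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFillinRegression:
    def features(self):
        geom = DisplayGeometry()
        return [fillin_features(AnnulusSpec(s, t), geom)
                for s in (100, 200) for t in (25, 75)]

    def test_noiseless_recovery(self):
        feats = self.features()
        b0, b1, b2 = 530.0, -0.05, 1.6
        vp = [b0 + b1 * f.contour_len_px + b2 * f.fill_dist_px for f in feats]
        fit = fillin_regression(vp, feats)
        assert (fit.b0, fit.b1, fit.b2) == pytest.approx((b0, b1, b2))
        assert fit.r == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(10)
        feats = self.features()
        vp = rng.normal(500, 50, size=4)
        fit = fillin_regression(vp, feats)
        X = np.column_stack([np.ones(4),
                             [f.contour_len_px for f in feats],
                             [f.fill_dist_px for f in feats]])
        beta = np.linalg.solve(X.T @ X, X.T @ vp)
        assert (fit.b0, fit.b1, fit.b2) == pytest.approx(tuple(beta))

    def test_sign_pattern_with_reported_condition_means(self):
        # small > large and thick > thin implies negative contour effect and
        # positive thickness effect
        feats = self.features()  # (small,thin) (small,thick) (large,thin) (large,thick)
        vp = [489.7 + 27.8 - 34.5, 489.7 + 27.8 + 34.5,
              489.7 - 27.8 - 34.5, 489.7 - 27.8 + 34.5]
        fit = fillin_regression(vp, feats)
        assert fit.b1 < 0
        assert fit.b2 > 0

    def test_cross_prediction(self):
        feats = self.features()
        fit = RegressionFit(500.0, -0.05, 1.5, 1.0)
        new = [FillInFeatures(100.0, 10.0), FillInFeatures(300.0, 40.0),
               FillInFeatures(500.0, 90.0)]
        pred, r = cross_predict(fit, new, observed=fit.predict(new))
        assert r == pytest.approx(1.0)
        assert pred[0] == pytest.approx(500 - 5 + 15)

    def test_rank_deficient_features_rejected(self):
        feats = [FillInFeatures(c, c / 2) for c in (100.0, 200.0, 300.0, 400.0)]
        with pytest.raises(ValueError, match="rank"):
            fillin_regression([1.0, 2.0, 3.0, 4.0], feats)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            fillin_regression([1.0, 2.0], self.features()[:2])


class TestSpeedFromSlope:
    @pytest.mark.parametrize("slope, speed", [(70.0, 7.142857), (140.0, 3.571429)])
    def test_conversion(self, slope, speed):
        assert speed_from_slope(slope) == pytest.approx(speed, abs=1e-4)

    def test_large_slope_limit(self):
        assert speed_from_slope(1e9) < 1e-6

    def test_nonpositive_slope_rejected(self):
        for bad in (0.0, -5.0):
            with pytest.raises(ValueError):
                speed_from_slope(bad)


class TestMarginalMeanConsistency:
    def test_size_and_thickness_marginals_share_grand_mean(self):
        # arithmetic identity on the reported marginal means
        assert (517.5 + 461.9) / 2 == pytest.approx((524.2 + 455.2) / 2)
        assert (517.5 + 461.9) / 2 == pytest.approx(489.7, abs=0.05)


# ---------------------------------------------------------------------------
# end-to-end pipeline reproductions
# ---------------------------------------------------------------------------

class TestEndToEnd:
    def test_exp1_anova_recovers_study_pattern(self, exp1_trials):
        """Simulated panel with thick-thin and small-large persistence effects:
        both spatial main effects significant, no interactions."""
        est = synchrony_estimates(exp1_trials)
        table = rm_anova(est, "VP", ["size_px", "thickness_px", "modality"])
        assert table.loc["size_px", "p"] < 0.05
        assert table.loc["thickness_px", "p"] < 0.05
        assert table.loc["modality", "p"] < 0.05
        interactions = [e for e in table.index if ":" in e]
        assert all(table.loc[e, "p"] > 0.05 for e in interactions)
        # E must not inherit the persistence effects
        e_table = rm_anova(est, "E", ["size_px", "thickness_px", "modality"])
        assert all(e_table["p"] > 0.05)

    def test_exp2_offset_tracks_physical_duration(self, exp2_trials):
        est = synchrony_estimates(exp2_trials)
        means = est.groupby("duration_ms")[["E", "D_off"]].mean()
        x = means.index.to_numpy(dtype=float)
        on_slope, *_ = linear_fit(x, means["E"].to_numpy())
        off_slope, *_ = linear_fit(x, means["D_off"].to_numpy())
        assert abs(off_slope - 1.0) < 0.1
        assert abs(on_slope) < 0.05
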