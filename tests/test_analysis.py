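"""Condition tables, ANOVA engines, and planned comparisons."""
import json
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapticstrokes.analysis import (
    CHANCE_ORTHOGONAL_PERCENT,
    arcsine_transform,
    build_condition_table,
    contingency_comparison,
    linear_contrast,
    mixed_anova,
    orthogonal_proportion,
    paired_t,
    quarter_split,
    rm_anova,
    run_standard_analysis,
    segment_dataset,
    vtest_by_condition,
    welch_test,
)


class TestOrthogonalProportion:
    def test_example_counts(self):
        assert orthogonal_proportion([90.0, 104.0, 76.0, 0.0]) == pytest.approx(75.0)

    def test_boundary_inclusive_by_default(self):
        assert orthogonal_proportion([75.0, 105.0]) == pytest.approx(100.0)
        assert orthogonal_proportion([75.0, 105.0], closed=False) == 0.0

    @given(st.lists(st.floats(0, 179.99), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_narrower_window_never_larger(self, dirs):
        assert orthogonal_proportion(dirs, 10.0) <= orthogonal_proportion(dirs, 15.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_proportion([])


class TestArcsineTransform:
    @pytest.mark.parametrize("pct,expected", [
        (100.0, math.pi / 2), (0.0, 0.0), (50.0, math.pi / 4)])
    def test_examples(self, pct, expected):
        assert arcsine_transform(pct) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_transform(101.0)


class TestQuarterSplit:
    def test_session_boundaries(self):
        labels = quarter_split([1, 90, 91, 180, 181, 270, 271, 360], 360)
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_288_trials(self):
        labels = quarter_split([72, 73, 288], 288)
        assert labels.tolist() == [1, 2, 4]

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            quarter_split([1], 290)


def _rm_fixture(effects, n_subj=3, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        base = rng.normal(scale=1.0)
        for j, eff in enumerate(effects):
            y = base + eff + (rng.normal(scale=noise) if noise else 0.0)
            rows.append({"participant": s, "level": j, "y": y})
    return pd.DataFrame(rows)


def _rm_anova_oracle(df):
    """From-scratch sums-of-squares one-way repeated-measures F."""
    wide = df.pivot(index="participant", columns="level", values="y").to_numpy()
    n, k = wide.shape
    grand = wide.mean()
    ss_levels = n * np.sum((wide.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((wide.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((wide - grand) ** 2)
    ss_err = ss_total - ss_levels - ss_subj
    return (ss_levels / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self):
        df = _rm_fixture([0.0, 0.6, 1.1], n_subj=3, noise=0.5, seed=2)
        res = rm_anova(df, "y", "level", "participant")
        assert res.F == pytest.approx(_rm_anova_oracle(df), abs=1e-8)
        assert res.df_num == 2 and res.df_den == 4

    def test_null_effect_gives_zero_f(self):
        df = _rm_fixture([0.5, 0.5, 0.5], n_subj=4, noise=None)
        res = rm_anova(df, "y", "level", "participant")
        assert res.F == 0.0 and res.p_value == 1.0

    def test_missing_cell_names_offender(self):
        df = _rm_fixture([0.0, 1.0, 2.0], n_subj=3, noise=0.1)
        df = df[~((df["participant"] == 1) & (df["level"] == 2))]
        with pytest.raises(ValueError, match="missing"):
            rm_anova(df, "y", "level", "participant")

    def test_power_matches_noncentral_f(self, rng):
        """Empirical rejection rate vs the closed-form noncentral-F power."""
        from scipy.stats import f as fdist
        from scipy.stats import ncf
        effects = np.array([0.0, 0.4, 0.8])
        sigma = 1.0
        n, k = 16, 3
        lam = n * np.sum((effects - effects.mean()) ** 2) / sigma**2
        crit = fdist.ppf(0.95, k - 1, (n - 1) * (k - 1))
        power = ncf.sf(crit, k - 1, (n - 1) * (k - 1), lam)
        reps = 400
        hits = 0
        for _ in range(reps):
            wide = (rng.normal(size=(n, 1)) + effects[None, :]
                    + rng.normal(scale=sigma, size=(n, k)))
            grand = wide.mean()
            ss_lv = n * np.sum((wide.mean(0) - grand) ** 2)
            ss_sb = k * np.sum((wide.mean(1) - grand) ** 2)
            ss_err = np.sum((wide - grand) ** 2) - ss_lv - ss_sb
            F = (ss_lv / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
            hits += F > crit
        se = math.sqrt(power * (1 - power) / reps)
        assert abs(hits / reps - power) < 4 * se + 0.02


class TestLinearContrast:
    def test_exact_linearity_owns_all_effect_variance(self):
        df = _rm_fixture([0.0, 1.0, 2.0, 3.0], n_subj=5, noise=None)
        res = linear_contrast(df, "y", "level", "participant")
        assert res.partial_eta_squared == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_degrees_of_freedom(self):
        df = _rm_fixture([0.0, 0.7, 1.0], n_subj=6, noise=0.3, seed=5)
        res = linear_contrast(df, "y", "level", "participant")
        assert res.df_num == 1 and res.df_den == 5
        assert 0.0 < res.p_value < 1.0


def _mixed_fixture(seed=7, n_a=5, n_b=4, p_levels=2, q_levels=3):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_a + n_b):
        g = "A" if s < n_a else "B"
        base = rng.normal()
        for p in range(p_levels):
            for q in range(q_levels):
                rows.append({"subject": s, "group": g, "P": p, "Q": q,
                             "cell": f"{p}{q}",
                             "y": base + 0.5 * p + 0.3 * q
                             + (0.4 if g == "B" else 0.0)
                             + rng.normal()})
    return pd.DataFrame(rows)


_R_ORACLE = textwrap.dedent("""
    suppressMessages({library(car); library(jsonlite)})
    options(contrasts=c("contr.sum","contr.poly"))
    args <- commandArgs(trailingOnly=TRUE)
    d <- read.csv(args[1])
    wide <- reshape(d, idvar=c("subject","group"), timevar="cell",
                    direction="wide")
    ycols <- grep("^y\\\\.", names(wide))
    idata <- unique(d[, c("P","Q")])
    idata$P <- factor(idata$P); idata$Q <- factor(idata$Q)
    mod <- lm(as.matrix(wide[, ycols]) ~ group, data=wide)
    a <- Anova(mod, idata=idata, idesign=~P*Q, type=3)
    s <- suppressWarnings(summary(a, multivariate=FALSE))
    ut <- s$univariate.tests
    gg <- s$pval.adjustments
    out <- list(effects=rownames(ut), F=unname(ut[, "F value"]),
                df1=unname(ut[, "num Df"]), df2=unname(ut[, "den Df"]),
                p=unname(ut[, "Pr(>F)"]),
                gg_effects=rownames(gg), gg_eps=unname(gg[, "GG eps"]))
    cat(toJSON(out, digits=12))
""")


class TestMixedAnova:
    def test_matches_r_car_oracle(self, tmp_path):
        """Split-plot F, dfs and GG epsilons must equal car::Anova (type III,
        sum contrasts) on an unbalanced-groups 2x3 within design."""
        df = _mixed_fixture()
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(_R_ORACLE)
        proc = subprocess.run(["Rscript", str(script), str(csv)],
                              capture_output=True, text=True, timeout=120)
        assert proc.returncode == 0, proc.stderr
        oracle = json.loads(proc.stdout)
        ours = mixed_anova(df, "y", ["P", "Q"], "group", "subject")
        name_map = {"group": "group", "P": "P", "group:P": "P * group",
                    "Q": "Q", "group:Q": "Q * group", "P:Q": "P * Q",
                    "group:P:Q": "P * Q * group"}
        ours_f = dict(zip(ours["effect"], ours["F"]))
        for r_name, F, df1, df2 in zip(oracle["effects"], oracle["F"],
                                       oracle["df1"], oracle["df2"]):
            if r_name == "(Intercept)":
                continue
            mine = ours[ours["effect"] == name_map[r_name]].iloc[0]
            assert mine["F"] == pytest.approx(F, rel=1e-6)
            assert mine["df_num"] == df1 and mine["df_den"] == df2
        eps = dict(zip(oracle["gg_effects"], oracle["gg_eps"]))
        for r_name, e in eps.items():
            mine = ours[ours["effect"] == name_map[r_name]].iloc[0]
            assert mine["gg_epsilon"] == pytest.approx(e, rel=1e-6)

    def test_matches_pingouin_one_within_one_between(self):
        # balanced groups: the type-III and classical SS conventions coincide
        df = _mixed_fixture(q_levels=3, p_levels=1, seed=11, n_a=4, n_b=4)
        df = df.drop(columns=["P"])
        df["cell"] = df["Q"]
        ours = mixed_anova(df, "y", ["Q"], "group", "subject")
        ref = pg.mixed_anova(data=df, dv="y", within="Q", between="group",
                             subject="subject", correction=False)
        for source, eff in (("group", "group"), ("Q", "Q"),
                            ("Interaction", "Q * group")):
            mine = float(ours.loc[ours["effect"] == eff, "F"].iloc[0])
            theirs = float(ref.loc[ref["Source"] == source, "F"].iloc[0])
            assert mine == pytest.approx(theirs, rel=1e-8)

    def test_pure_between_shift_isolates_order_effect(self):
        df = _mixed_fixture(seed=3)
        df["y"] = np.where(df["group"] == "B", 2.0, 0.0)  # constant per group
        res = mixed_anova(df, "y", ["P", "Q"], "group", "subject")
        between_F = float(res.loc[res["effect"] == "group", "F"].iloc[0])
        within_F = res.loc[res["effect"] != "group", "F"]
        assert math.isinf(between_F)
        assert np.allclose(within_F, 0.0)

    def test_relabeling_within_groups_preserves_within_effects(self):
        df = _mixed_fixture(seed=9)
        res1 = mixed_anova(df, "y", ["P", "Q"], "group", "subject")
        relabel = {0: 4, 4: 0, 1: 3, 3: 1, 2: 2, 5: 8, 8: 5, 6: 7, 7: 6}
        df2 = df.assign(subject=df["subject"].map(relabel))
        res2 = mixed_anova(df2, "y", ["P", "Q"], "group", "subject")
        for eff in ("P", "Q", "P * Q"):
            f1 = float(res1.loc[res1["effect"] == eff, "F"].iloc[0])
            f2 = float(res2.loc[res2["effect"] == eff, "F"].iloc[0])
            assert f1 == pytest.approx(f2, rel=1e-10)

    def test_single_between_level_degenerates_with_warning(self):
        df = _mixed_fixture()
        df["group"] = "A"
        with pytest.warns(UserWarning):
            res = mixed_anova(df, "y", ["P", "Q"], "group", "subject")
        assert "group" not in set(res["effect"])


class TestPairwise:
    def test_paired_identical_is_null(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.p_value == 1.0

    def test_welch_type_one_error_under_variance_heterogeneity(self, rng):
        from scipy import stats as sps
        reps = 20_000
        a = rng.normal(0.0, 1.0, size=(reps, 18))
        b = rng.normal(0.0, 2.0, size=(reps, 14))
        p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert 0.03 <= np.mean(p < 0.05) <= 0.07

    def test_hedges_g_against_correction_formula(self, rng):
        a = rng.normal(0.0, 1.0, 18)
        b = rng.normal(0.0, 1.0, 14)
        a = (a - a.mean()) / a.std(ddof=1)          # mean 0, sd 1
        b = (b - b.mean()) / b.std(ddof=1) + 1.0    # mean 1, sd 1
        res = welch_test(b, a)
        m = 18 + 14 - 2
        approx_j = 1.0 - 3.0 / (4.0 * m - 9.0)      # Hedges' approximation
        assert res.hedges_g == pytest.approx(approx_j * 1.0, abs=0.005)

    def test_zero_variance_equal_means(self):
        res = welch_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p_value == 1.0


def _toy_condition_table(percents, quality=0.5, role="initial"):
    rows = []
    for pid, pct in enumerate(percents):
        rows.append({"participant": pid, "quarter": "all", "role": role,
                     "quality_fraction": quality, "demand": "none",
                     "order": "none", "orthogonal_percent": pct,
                     "mean_direction_deg": 90.0, "n_strokes_in_cell": 10})
    return pd.DataFrame(rows)


class TestContingencyComparison:
    def test_identical_datasets_fully_nonsignificant(self):
        tbl = pd.concat([_toy_condition_table([30, 40, 50, 35], q)
                         for q in (0.0, 0.5)])
        res = contingency_comparison(tbl, tbl.copy())
        assert np.allclose(res["p_bonferroni"], 1.0)

    def test_group_swap_flips_sign_only(self):
        a = pd.concat([_toy_condition_table([45, 50, 55, 40], q)
                       for q in (0.0, 0.5)])
        b = pd.concat([_toy_condition_table([20, 25, 15, 30, 22], q)
                       for q in (0.0, 0.5)])
        r1 = contingency_comparison(a, b)
        r2 = contingency_comparison(b, a)
        assert np.allclose(r1["t"].to_numpy(), -r2["t"].to_numpy())
        assert np.allclose(r1["p_raw"].to_numpy(), r2["p_raw"].to_numpy())

    def test_no_shared_levels_rejected(self):
        a = _toy_condition_table([30, 40], quality=0.5)
        b = _toy_condition_table([30, 40], quality=0.25)
        with pytest.raises(ValueError):
            contingency_comparison(a, b)


def _enumerable_strokes():
    """Two participants, two qualities, hand-enumerable initial directions."""
    design_rows, stroke_rows = [], []
    directions = {
        (1, 0.0): [0.0, 30.0, 90.0, 100.0],
        (1, 0.5): [88.0, 92.0, 75.0, 20.0],
        (2, 0.0): [50.0, 60.0, 70.0, 80.0],
        (2, 0.5): [90.0, 90.0, 90.0, 104.9],
    }
    trial = 0
    for pid in (1, 2):
        for q, dirs in ((0.0, directions[(pid, 0.0)]),
                        (0.5, directions[(pid, 0.5)])):
            for d in dirs:
                trial = trial % 8 + 1
                design_rows.append({
                    "participant": pid, "trial_index": trial,
                    "experiment_id": 1, "quality_fraction": q,
                    "orientation_deg": 0.0, "demand": "none"})
                stroke_rows.append({
                    "participant": pid, "trial_index": trial,
                    "direction_deg": d, "is_initial": True,
                    "is_middle": False, "is_last": False, "role": "initial"})
    return pd.DataFrame(stroke_rows), pd.DataFrame(design_rows), directions


class TestConditionTable:
    def test_hand_computed_proportions(self, monkeypatch):
        strokes, design, directions = _enumerable_strokes()
        # restrict the expected quality levels to the fixture's two
        import hapticstrokes.analysis as mod
        monkeypatch.setattr(mod, "_quality_levels", lambda e: (0.0, 0.5))
        tbl = build_condition_table(strokes, design)
        tbl = tbl[tbl["quarter"] == "all"]
        expect = {(1, 0.0): 50.0, (1, 0.5): 75.0, (2, 0.0): 25.0, (2, 0.5): 100.0}
        for (pid, q), pct in expect.items():
            row = tbl[(tbl["participant"] == pid)
                      & np.isclose(tbl["quality_fraction"], q)]
            assert float(row["orthogonal_percent"].iloc[0]) == pytest.approx(pct)
            assert int(row["n_strokes_in_cell"].iloc[0]) == 4

    def test_quality_mismatch_rejected(self):
        strokes, design, _ = _enumerable_strokes()
        with pytest.raises(ValueError, match="quality levels"):
            build_condition_table(strokes, design)  # fixture lacks exp-1 levels

    def test_all_orthogonal_gives_100(self, monkeypatch):
        strokes, design, _ = _enumerable_strokes()
        import hapticstrokes.analysis as mod
        monkeypatch.setattr(mod, "_quality_levels", lambda e: (0.0, 0.5))
        strokes["direction_deg"] = 90.0
        tbl = build_condition_table(strokes, design)
        assert np.allclose(tbl["orthogonal_percent"], 100.0)


class TestPipeline:
    def test_full_battery_on_simulated_session(self, exp1_small, exp1_segmented):
        strokes, summaries = exp1_segmented
        res = run_standard_analysis(strokes, exp1_small.design,
                                    exp1_small.responses, summaries)
        vt = res["vtests"]
        assert set(vt["role"]) == {"initial", "middle", "last"}
        assert len(vt) == 15  # 5 qualities x 3 roles
        assert "initial" in res["anova_orthogonal"]
        assert res["movement_summary"]["mean_strokes_per_trial"] > 2.0
        assert 0.0 < res["percent_correct_overall"] <= 100.0

    def test_pipeline_is_deterministic(self, exp1_small):
        s1, m1 = segment_dataset(exp1_small.trajectories)
        s2, m2 = segment_dataset(exp1_small.trajectories)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(m1, m2)
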