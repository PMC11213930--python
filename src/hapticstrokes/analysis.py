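"""Condition-level statistics: orthogonal-stroke proportions, ANOVAs, and
planned comparisons.

The central outcome measure is the percentage of strokes whose
texture-aligned direction falls within 90 +/- 15 degrees (close to
orthogonal to the ridges); under a uniform axial movement distribution that
chance level is 100 * 30/180 = 16.67%.  Percentages entering ANOVAs are
arcsine-square-root transformed where the corresponding study analyses did
so (percent correct).

Repeated-measures ANOVAs go through pingouin; the three-way mixed design
(Quality x Demand within, Order between) has no implementation in the
installed stack and is computed here from scratch for balanced data, with
Greenhouse-Geisser epsilon and a Mauchly sphericity gate (alpha = 0.05) per
within-subject term.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats, special

from . import circstats
from .circstats import align_to_texture, axial_mean, bonferroni, v_test
from .segmentation import SegmentationConfig, segment_trial, strokes_to_frame

__all__ = [
    "orthogonal_proportion",
    "arcsine_transform",
    "quarter_split",
    "build_condition_table",
    "vtest_by_condition",
    "rm_anova",
    "linear_contrast",
    "mixed_anova",
    "paired_t",
    "welch_test",
    "contingency_comparison",
    "segment_dataset",
    "simulate_and_segment",
    "simulate_contingency_pattern",
    "run_standard_analysis",
]

CHANCE_ORTHOGONAL_PERCENT = 100.0 * 30.0 / 180.0


# --------------------------------------------------------------------------
# elementary outcome measures
# --------------------------------------------------------------------------

def orthogonal_proportion(directions_deg, window_halfwidth_deg: float = 15.0,
                          closed: bool = True) -> float:
    """Percentage of directions within 90 +/- w degrees (boundaries included).

    ``closed=False`` switches to an open interval; the default includes the
    boundary, which only matters for directions landing exactly on it.
    """
    d = np.asarray(directions_deg, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample: orthogonal proportion undefined")
    lo, hi = 90.0 - window_halfwidth_deg, 90.0 + window_halfwidth_deg
    if closed:
        inside = (d >= lo) & (d <= hi)
    else:
        inside = (d > lo) & (d < hi)
    return 100.0 * float(np.count_nonzero(inside)) / d.size


def arcsine_transform(percent):
    """arcsin(sqrt(p/100)), the variance-stabilising transform for percentages."""
    p = np.asarray(percent, dtype=float)
    if np.any(p < 0) or np.any(p > 100):
        raise ValueError("percent must lie in [0, 100]")
    return np.arcsin(np.sqrt(p / 100.0))


def quarter_split(trial_indices, n_trials: int, n_quarters: int = 4) -> np.ndarray:
    """Chronological quarter labels (1-based) for 1-based trial indices."""
    if n_trials % n_quarters != 0:
        raise ValueError(f"{n_trials} trials not divisible into {n_quarters} quarters")
    idx = np.asarray(trial_indices, dtype=int)
    if np.any(idx < 1) or np.any(idx > n_trials):
        raise ValueError("trial indices must lie in 1..n_trials")
    per = n_trials // n_quarters
    return (idx - 1) // per + 1


# --------------------------------------------------------------------------
# condition table
# --------------------------------------------------------------------------

def _cell_stats(directions: np.ndarray, window: float) -> dict:
    res = axial_mean(directions)
    return {
        "orthogonal_percent": orthogonal_proportion(directions, window),
        "mean_direction_deg": res.mean_direction_deg,
        "resultant_length": res.resultant_length,
        "n_strokes_in_cell": int(directions.size),
    }


def build_condition_table(strokes: pd.DataFrame, design: pd.DataFrame,
                          responses: pd.DataFrame | None = None,
                          window_halfwidth_deg: float = 15.0,
                          include_quarters: bool = False,
                          n_quarters: int = 4) -> pd.DataFrame:
    """Aggregate strokes to one row per participant x condition x role cell.

    Each row carries the close-to-orthogonal percentage, the participant's
    axial mean direction (input to the condition-level V-tests), the cell's
    stroke count, and, when responses are given, the percent correct of the
    matching trials.  Trials without a stroke of a given role simply do not
    contribute to that role's cell.
    """
    required = {"participant", "trial_index", "direction_deg"}
    if not required.issubset(strokes.columns):
        raise ValueError(f"strokes table must contain columns {sorted(required)}")
    dsg = design[["participant", "trial_index", "experiment_id",
                  "quality_fraction", "orientation_deg", "demand"]].copy()
    if "order" in design.columns:
        dsg["order"] = design["order"]
    else:
        dsg["order"] = "none"
    exp_id = int(design["experiment_id"].iloc[0])
    expected_q = set(_quality_levels(exp_id))
    found_q = set(np.round(design["quality_fraction"].unique(), 6))
    if found_q != expected_q:
        raise ValueError(f"design quality levels {sorted(found_q)} do not match "
                         f"experiment {exp_id} levels {sorted(expected_q)}")

    merged = strokes.drop(columns=[c for c in ("quality_fraction",
                                               "orientation_deg", "demand")
                                   if c in strokes.columns]) \
                    .merge(dsg, on=["participant", "trial_index"],
                           how="left", validate="many_to_one")
    if merged["quality_fraction"].isna().any():
        bad = merged.loc[merged["quality_fraction"].isna(),
                         ["participant", "trial_index"]].drop_duplicates()
        raise ValueError(f"strokes reference trials missing from the design: "
                         f"{bad.to_dict('records')[:5]}")
    merged["relative_direction_deg"] = align_to_texture(
        merged["direction_deg"].to_numpy(), merged["orientation_deg"].to_numpy())
    n_trials = int(design.groupby("participant")["trial_index"].max().iloc[0])
    merged["quarter"] = quarter_split(merged["trial_index"].to_numpy(),
                                      n_trials, n_quarters)

    correct_lookup = None
    if responses is not None:
        correct_lookup = responses.merge(
            dsg, on=["participant", "trial_index"], validate="one_to_one")

    rows = []
    quarter_values: list = ["all"] + (list(range(1, n_quarters + 1))
                                      if include_quarters else [])
    for role in ("initial", "middle", "last"):
        flag = f"is_{role}"
        sel = merged[merged[flag]] if flag in merged.columns \
            else merged[merged["role"] == role]
        for quarter in quarter_values:
            part = sel if quarter == "all" else sel[sel["quarter"] == quarter]
            group_cols = ["participant", "quality_fraction", "demand", "order"]
            for key, cell in part.groupby(group_cols, sort=True):
                pid, quality, demand, order = key
                row = {"participant": pid, "experiment_id": exp_id,
                       "quality_fraction": quality, "demand": demand,
                       "order": order, "role": role, "quarter": quarter}
                row.update(_cell_stats(
                    cell["relative_direction_deg"].to_numpy(),
                    window_halfwidth_deg))
                rows.append(row)
    table = pd.DataFrame(rows)

    if correct_lookup is not None and not table.empty:
        pc = (correct_lookup
              .groupby(["participant", "quality_fraction", "demand"])["correct"]
              .mean().mul(100.0).rename("percent_correct").reset_index())
        table = table.merge(pc, on=["participant", "quality_fraction", "demand"],
                            how="left")
    return table


def _quality_levels(experiment_id: int) -> tuple[float, ...]:
    from .simulate import QUALITY_LEVELS
    return QUALITY_LEVELS[experiment_id]


# --------------------------------------------------------------------------
# condition-level V-tests
# --------------------------------------------------------------------------

def vtest_by_condition(condition_table: pd.DataFrame,
                       expected_direction_deg: float = 90.0,
                       mode: str = "double",
                       family_size: int | None = None) -> pd.DataFrame:
    """V-tests on participant mean directions, one per condition x role cell.

    Each test asks whether the distribution of individual average movement
    directions concentrates toward 90 deg.  Bonferroni adjustment uses the
    family size (default: the number of tests run here).
    """
    tbl = condition_table[condition_table["quarter"] == "all"]
    rows = []
    for key, cell in tbl.groupby(["quality_fraction", "demand", "role"]):
        quality, demand, role = key
        dirs = cell["mean_direction_deg"].dropna().to_numpy()
        if dirs.size < 2:
            continue
        res = v_test(np.mod(dirs, 180.0), expected_direction_deg, mode=mode)
        rows.append({"quality_fraction": quality, "demand": demand, "role": role,
                     "n": res.n, "V": res.V, "u": res.u, "p_raw": res.p_value,
                     "mean_direction_deg": res.mean_direction_deg,
                     "resultant_length": res.resultant_length_mean})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = bonferroni(out["p_raw"].to_numpy(),
                                         family_size or len(out))
    return out


# --------------------------------------------------------------------------
# ANOVA machinery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p_value: float
    partial_eta_squared: float
    gg_epsilon: float | None = None
    p_uncorrected: float | None = None
    mauchly_p: float | None = None


def rm_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
             mauchly_alpha: float = 0.05) -> AnovaResult:
    """One-way repeated-measures ANOVA with a Greenhouse-Geisser gate.

    The correction is applied when Mauchly's test rejects sphericity at
    ``mauchly_alpha``; both the corrected and uncorrected p-values are kept.
    """
    _check_balance(data, dv, [within], subject)
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      correction=True, detailed=True, effsize="np2")
    row = aov.iloc[0]
    if not np.isfinite(row["F"]) and float(row["SS"]) < 1e-12:
        # no effect variance at all (dv constant across levels): F = 0 by convention
        return AnovaResult(effect=within, F=0.0, df_num=float(row["DF"]),
                           df_den=float(aov.iloc[1]["DF"]), p_value=1.0,
                           partial_eta_squared=0.0, p_uncorrected=1.0,
                           mauchly_p=1.0)
    k = data[within].nunique()
    eps = float(row["eps"]) if "eps" in aov.columns else 1.0
    p_unc = float(row["p_unc"])
    p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in aov.columns else p_unc
    sph_p = float(row["p_spher"]) if "p_spher" in aov.columns else 1.0
    violated = sph_p < mauchly_alpha and k > 2
    p = p_gg if violated else p_unc
    df1, df2 = float(row["DF"]), float(aov.iloc[1]["DF"])
    if violated:
        df1, df2 = eps * df1, eps * df2
    return AnovaResult(effect=within, F=float(row["F"]), df_num=df1, df_den=df2,
                       p_value=p, partial_eta_squared=float(row["np2"]),
                       gg_epsilon=eps if violated else None,
                       p_uncorrected=p_unc, mauchly_p=sph_p)


def linear_contrast(data: pd.DataFrame, dv: str, within: str,
                    subject: str) -> AnovaResult:
    """Linear polynomial contrast across the ordered within-factor levels.

    Per-subject contrast scores against equally spaced linear weights;
    F(1, n-1) is the squared one-sample t of those scores.
    """
    wide = _to_wide(data, dv, [within], subject)
    k = wide.shape[1]
    levels = np.arange(k, dtype=float)
    w = levels - levels.mean()
    w = w / np.sqrt(np.sum(w**2))
    scores = wide.to_numpy() @ w
    n = scores.size
    sd = scores.std(ddof=1)
    if sd == 0:
        # exactly linear means with no residual: the contrast owns all the effect
        nonzero = abs(scores.mean()) > 0
        return AnovaResult(effect=f"{within} (linear)", F=math.inf if nonzero else 0.0,
                           df_num=1.0, df_den=float(n - 1),
                           p_value=0.0 if nonzero else 1.0,
                           partial_eta_squared=1.0 if nonzero else 0.0)
    t = scores.mean() / (sd / math.sqrt(n))
    F = t * t
    p = float(stats.f.sf(F, 1, n - 1))
    np2 = F / (F + (n - 1))
    return AnovaResult(effect=f"{within} (linear)", F=float(F), df_num=1.0,
                       df_den=float(n - 1), p_value=p,
                       partial_eta_squared=float(np2))


def _to_wide(data: pd.DataFrame, dv: str, within: list[str],
             subject: str) -> pd.DataFrame:
    agg = data.groupby([subject] + within, sort=True)[dv].mean().reset_index()
    wide = agg.pivot_table(index=subject, columns=within, values=dv, sort=True)
    return wide


def _check_balance(data: pd.DataFrame, dv: str, within: list[str],
                   subject: str) -> None:
    wide = _to_wide(data, dv, within, subject)
    if wide.isna().any().any():
        missing = [(s, c) for s in wide.index for c in wide.columns
                   if pd.isna(wide.loc[s, c])]
        raise ValueError(f"missing within-subject cells: {missing[:5]}")


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the contrast space (complement of 1)."""
    basis = np.eye(k) - np.full((k, k), 1.0 / k)
    q, _ = np.linalg.qr(basis)
    # drop the column (numerically) parallel to 1
    keep = [j for j in range(k) if abs(q[:, j] @ np.ones(k)) < 1e-8]
    return q[:, keep[:k - 1]]


def _gg_and_mauchly(sscp_e: np.ndarray, df_e: int) -> tuple[float, float]:
    """Greenhouse-Geisser epsilon and Mauchly p from an error SSCP matrix."""
    d = sscp_e.shape[0]
    if d < 2:
        return 1.0, 1.0
    sigma = sscp_e / df_e
    tr = np.trace(sigma)
    eps = (tr * tr) / (d * np.trace(sigma @ sigma))
    eps = float(np.clip(eps, 1.0 / d, 1.0))
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return eps, 0.0  # singular covariance: treat sphericity as violated
    log_w = logdet - d * math.log(tr / d)
    f = d * (d + 1) // 2 - 1
    c = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * df_e)
    chi2 = -c * df_e * log_w
    return eps, float(stats.chi2.sf(chi2, f))


def mixed_anova(data: pd.DataFrame, dv: str, within: list[str] | str,
                between: str | None, subject: str,
                mauchly_alpha: float = 0.05) -> pd.DataFrame:
    """Mixed-design ANOVA for balanced data: up to two within factors and one
    between factor, e.g. Quality x Demand (within) x Order (between).

    Split-plot decomposition via orthonormal within-cell transforms and a
    between-subjects linear model, so unequal group sizes are handled by
    least squares.  Each within-involving term gets its own error stratum,
    Greenhouse-Geisser epsilon, and Mauchly gate.  With a single between
    group the between effect degenerates and only within effects are
    reported (with a warning).
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova supports one or two within factors")
    _check_balance(data, dv, within, subject)
    wide = _to_wide(data, dv, within, subject)
    level_counts = [data[w].nunique() for w in within]
    Y = wide.to_numpy()
    subjects = wide.index.to_numpy()
    n = Y.shape[0]

    if between is not None:
        grp = (data.groupby(subject)[between].first()).reindex(subjects)
        groups = sorted(grp.unique())
        if len(groups) < 2:
            warnings.warn("between factor has a single level; "
                          "reporting within effects only", stacklevel=2)
            between = None
    if between is not None:
        counts = grp.value_counts()
        if counts.min() < 2:
            raise ValueError("each between-subjects group needs >= 2 participants")
        X = np.ones((n, len(groups)))
        for j, g in enumerate(groups[:-1]):
            X[:, j + 1] = np.where(grp == g, 1.0,
                                   np.where(grp == groups[-1], -1.0, 0.0))
        terms = {"(Intercept)": [0], between: list(range(1, len(groups)))}
    else:
        X = np.ones((n, 1))
        terms = {"(Intercept)": [0]}

    xtx_inv = np.linalg.inv(X.T @ X)
    df_e = n - X.shape[1]

    # within-cell transform matrices per within term
    cs = [_orthonormal_contrasts(k) for k in level_counts]
    ones = [np.full((k, 1), 1.0 / math.sqrt(k)) for k in level_counts]
    if len(within) == 1:
        transforms = {"(between)": ones[0], within[0]: cs[0]}
    else:
        transforms = {
            "(between)": np.kron(ones[0], ones[1]),
            within[0]: np.kron(cs[0], ones[1]),
            within[1]: np.kron(ones[0], cs[1]),
            f"{within[0]} * {within[1]}": np.kron(cs[0], cs[1]),
        }

    rows = []
    for wname, M in transforms.items():
        Z = Y @ M
        beta = xtx_inv @ X.T @ Z
        resid = Z - X @ beta
        sscp_e = resid.T @ resid
        d = M.shape[1]
        eps, mauchly_p = _gg_and_mauchly(sscp_e, df_e)
        for tname, cols in terms.items():
            if wname == "(between)" and tname == "(Intercept)":
                continue  # grand mean, not an effect
            L = np.zeros((len(cols), X.shape[1]))
            for i, cidx in enumerate(cols):
                L[i, cidx] = 1.0
            lb = L @ beta
            middle = np.linalg.inv(L @ xtx_inv @ L.T)
            sscp_h = lb.T @ middle @ lb
            df_h = len(cols)
            tr_h, tr_e = float(np.trace(sscp_h)), float(np.trace(sscp_e))
            zero_tol = 1e-12 * max(float(np.trace(Y.T @ Y)), 1.0)
            if tr_e < zero_tol:
                # no residual variance in this stratum: F is 0 (no effect) or
                # infinite (pure effect), never numerical noise
                F = math.inf if tr_h >= zero_tol else 0.0
            else:
                F = (tr_h / (df_h * d)) / (tr_e / (df_e * d))
            df1, df2 = df_h * d, df_e * d
            p_unc = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
            if wname == "(between)":
                effect = tname
            elif tname == "(Intercept)":
                effect = wname
            else:
                effect = f"{wname} * {tname}"
            violated = d > 1 and mauchly_p < mauchly_alpha
            p_gg = float(stats.f.sf(F, eps * df1, eps * df2)) if d > 1 else p_unc
            rows.append({
                "effect": effect, "F": float(F),
                "df_num": float(df1), "df_den": float(df2),
                "p_uncorrected": p_unc,
                "gg_epsilon": eps if d > 1 else None,
                "p_gg": p_gg if d > 1 else None,
                "mauchly_p": mauchly_p if d > 1 else None,
                "p_value": p_gg if violated else p_unc,
                "df_num_adj": eps * df1 if violated else float(df1),
                "df_den_adj": eps * df2 if violated else float(df2),
                "partial_eta_squared": (tr_h / (tr_h + tr_e)
                                        if tr_h + tr_e >= zero_tol else 0.0),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pairwise tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_value: float
    cohens_d: float  # mean difference / SD of differences


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    hedges_g: float


def paired_t(a, b) -> PairedTResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return PairedTResult(0.0, a.size - 1, 1.0, 0.0)
    res = stats.ttest_rel(a, b)
    return PairedTResult(float(res.statistic), a.size - 1, float(res.pvalue),
                         float(diff.mean() / sd))


def _hedges_correction(df: float) -> float:
    """Exact small-sample bias correction J(df) = Gamma(df/2)/(sqrt(df/2)Gamma((df-1)/2))."""
    return math.exp(special.gammaln(df / 2.0)
                    - 0.5 * math.log(df / 2.0)
                    - special.gammaln((df - 1.0) / 2.0))


def welch_test(group_a, group_b) -> WelchResult:
    """Welch's t-test with Hedges' g (pooled-SD, small-sample corrected)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal = a.mean() == b.mean()
        return WelchResult(0.0 if equal else math.inf,
                           float(a.size + b.size - 2),
                           1.0 if equal else 0.0, 0.0 if equal else math.inf)
    res = stats.ttest_ind(a, b, equal_var=False)
    na, nb = a.size, b.size
    df_w = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp
    g = d * _hedges_correction(na + nb - 2)
    return WelchResult(float(res.statistic), float(df_w), float(res.pvalue),
                       float(g))


def contingency_comparison(table_high: pd.DataFrame, table_low: pd.DataFrame,
                           qualities: tuple[float, ...] = (0.0, 0.5),
                           role: str = "initial") -> pd.DataFrame:
    """Welch tests of orthogonal-initial percentages between two experiments,
    one per shared quality level, Bonferroni-corrected across the levels."""

    def _participant_percents(tbl: pd.DataFrame, q: float) -> np.ndarray:
        sel = tbl[(tbl["quarter"] == "all") & (tbl["role"] == role)
                  & (np.isclose(tbl["quality_fraction"], q))]
        return (sel.groupby("participant")["orthogonal_percent"].mean()
                .to_numpy())

    shared = [q for q in qualities
              if _participant_percents(table_high, q).size
              and _participant_percents(table_low, q).size]
    if not shared:
        raise ValueError("no shared quality levels between the two datasets")
    rows = []
    for q in shared:
        a = _participant_percents(table_high, q)
        b = _participant_percents(table_low, q)
        res = welch_test(a, b)
        rows.append({"quality_fraction": q, "mean_high": a.mean(),
                     "mean_low": b.mean(), "t": res.t, "df": res.df,
                     "p_raw": res.p_value, "hedges_g": res.hedges_g})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p_raw"].to_numpy(), len(shared))
    return out


# --------------------------------------------------------------------------
# contingency-pattern replication experiment
# --------------------------------------------------------------------------

def simulate_contingency_pattern(n_replicates: int = 200, seed: int = 0,
                                 kappa: float = 2.0,
                                 n_trials_per_cell: int = 48,
                                 n_participants_high: int = 18,
                                 n_participants_low: int = 14,
                                 weight_high_q50: float = 0.5,
                                 weight_low_q50: float = 0.1,
                                 alpha: float = 0.05,
                                 family_size: int = 6) -> dict:
    """Replicate the high- vs low-contingency comparison at the level of
    initial-stroke directions.

    Each replicate simulates one high-contingency session set (the mixture
    weight at 50% prior quality set to ``weight_high_q50``) and one
    low-contingency set (``weight_low_q50``), with the study's participant
    counts, 48 initial strokes per quality x demand cell, and w(0) = 0.
    Condition-level V-tests run on participant mean directions per cell,
    Bonferroni-corrected for the six initial-stroke cells of a session.
    The replicated pattern is:

    * both 50%-quality cells significant in the high-contingency set,
    * no 0%-quality cell significant in either set,
    * at most one 50%-quality cell significant in the low-contingency set
      (the study's own data showed exactly one), and
    * a higher mean orthogonal-initial percentage at 50% quality in the
      high-contingency set.

    Returns the fraction of replicates showing the full pattern plus the
    component rates.
    """
    rng = np.random.default_rng(seed)
    threshold = alpha / family_size

    def cell(n_part: int, w: float) -> tuple[np.ndarray, np.ndarray]:
        means = np.empty(n_part)
        props = np.empty(n_part)
        for i in range(n_part):
            d = circstats.sample_axial_mixture(n_trials_per_cell, w, 90.0,
                                               kappa, rng)
            means[i] = axial_mean(d).mean_direction_deg
            props[i] = orthogonal_proportion(d)
        return means, props

    def significant(means: np.ndarray) -> bool:
        return v_test(np.mod(means, 180.0)).p_value < threshold

    comp = np.zeros(5)
    n_pattern = 0
    for _ in range(n_replicates):
        h50 = [cell(n_participants_high, weight_high_q50) for _ in range(2)]
        h0 = [cell(n_participants_high, 0.0) for _ in range(2)]
        l50 = [cell(n_participants_low, weight_low_q50) for _ in range(2)]
        l0 = [cell(n_participants_low, 0.0) for _ in range(2)]
        c_high_sig = all(significant(m) for m, _ in h50)
        c_high0_ns = not any(significant(m) for m, _ in h0)
        c_low0_ns = not any(significant(m) for m, _ in l0)
        c_low_reduced = not all(significant(m) for m, _ in l50)
        c_prop = (np.mean(np.concatenate([p for _, p in h50]))
                  > np.mean(np.concatenate([p for _, p in l50])))
        flags = [c_high_sig, c_high0_ns, c_low0_ns, c_low_reduced, c_prop]
        comp += np.asarray(flags, dtype=float)
        n_pattern += int(all(flags))
    rates = comp / n_replicates
    return {
        "pattern_rate": n_pattern / n_replicates,
        "rate_high_50_significant": rates[0],
        "rate_high_0_nonsignificant": rates[1],
        "rate_low_0_nonsignificant": rates[2],
        "rate_low_50_reduced": rates[3],
        "rate_proportion_ordered": rates[4],
        "n_replicates": n_replicates,
    }


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------

def segment_dataset(trajectories: dict, cfg: SegmentationConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every trajectory; returns (strokes, per-trial summaries)."""
    cfg = cfg or SegmentationConfig()
    stroke_frames, summary_rows = [], []
    for (participant, trial_index), traj in trajectories.items():
        seg = segment_trial(traj, cfg)
        if seg.strokes:
            stroke_frames.append(strokes_to_frame(seg, traj,
                                                  participant=participant))
        summary_rows.append({"participant": participant,
                             "trial_index": trial_index,
                             "n_strokes": seg.summary.n_strokes,
                             "n_switches": seg.summary.n_switches,
                             "time_on_stimuli_s": seg.summary.time_on_stimuli_s})
    strokes = (pd.concat(stroke_frames, ignore_index=True)
               if stroke_frames else pd.DataFrame())
    return strokes, pd.DataFrame(summary_rows)


def simulate_and_segment(experiment_id: int, n_participants: int,
                         params=None, seed: int = 0,
                         cfg: SegmentationConfig | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                    pd.DataFrame]:
    """Simulate an experiment participant by participant and segment on the
    fly, keeping only tabular results (suitable for full study sizes).

    Returns (strokes, design, responses, summaries).
    """
    from .simulate import SimParams, design_to_frame, simulate_participant
    params = params or SimParams()
    cfg = cfg or SegmentationConfig()
    stroke_frames, designs, responses, summary_rows = [], [], [], []
    for pid in range(1, n_participants + 1):
        pdata = simulate_participant(experiment_id, pid, params, seed)
        designs.append(design_to_frame(pdata.trials, participant=pid,
                                       order=pdata.order))
        responses.append(pdata.responses)
        strokes_p, summaries_p = segment_dataset(
            {(pid, idx): traj for idx, traj in pdata.trajectories.items()}, cfg)
        stroke_frames.append(strokes_p)
        summary_rows.append(summaries_p)
    return (pd.concat(stroke_frames, ignore_index=True),
            pd.concat(designs, ignore_index=True),
            pd.concat(responses, ignore_index=True),
            pd.concat(summary_rows, ignore_index=True))


def run_standard_analysis(strokes: pd.DataFrame, design: pd.DataFrame,
                          responses: pd.DataFrame | None = None,
                          summaries: pd.DataFrame | None = None,
                          window_halfwidth_deg: float = 15.0,
                          axial_mode: str = "double",
                          top_quality: float | None = None) -> dict:
    """The study's standard per-experiment analysis battery.

    Builds the condition table, runs the condition-level V-tests, the
    orthogonal-percentage ANOVA for initial/middle/last strokes (repeated
    measures for experiment 1, three-way mixed for experiments 2 and 3),
    the linear quality trend for initial strokes, the quarter analysis at
    the highest quality, the percent-correct ANOVA on arcsine-transformed
    values, and (for the demand experiments) paired demand comparisons of
    the movement summaries.
    """
    exp_id = int(design["experiment_id"].iloc[0])
    table = build_condition_table(strokes, design, responses,
                                  window_halfwidth_deg, include_quarters=True)
    results: dict = {"condition_table": table}
    results["vtests"] = vtest_by_condition(table, mode=axial_mode)

    full = table[table["quarter"] == "all"]
    anovas: dict[str, pd.DataFrame] = {}
    for role in ("initial", "middle", "last"):
        cell = full[full["role"] == role]
        if cell.empty:
            continue
        if exp_id == 1:
            res = rm_anova(cell, "orthogonal_percent", "quality_fraction",
                           "participant")
            anovas[role] = pd.DataFrame([vars(res)])
        else:
            anovas[role] = mixed_anova(cell, "orthogonal_percent",
                                       ["quality_fraction", "demand"],
                                       "order", "participant")
    results["anova_orthogonal"] = anovas

    initial = full[full["role"] == "initial"]
    if not initial.empty:
        collapsed = (initial.groupby(["participant", "quality_fraction"])
                     ["orthogonal_percent"].mean().reset_index())
        results["linear_trend_initial"] = linear_contrast(
            collapsed, "orthogonal_percent", "quality_fraction", "participant")

    top_q = top_quality if top_quality is not None \
        else float(design["quality_fraction"].max())
    quarters = table[(table["quarter"] != "all") & (table["role"] == "initial")
                     & np.isclose(table["quality_fraction"], top_q)]
    if not quarters.empty:
        qtab = (quarters.groupby(["participant", "quarter"])
                ["orthogonal_percent"].mean().reset_index())
        complete = qtab.groupby("participant")["quarter"].count()
        keep = complete[complete == qtab["quarter"].nunique()].index
        dropped = len(complete) - len(keep)
        if dropped:
            warnings.warn(f"{dropped} participant(s) dropped from the quarter "
                          "analysis for missing quarter cells", stacklevel=2)
        qtab = qtab[qtab["participant"].isin(keep)]
        if qtab["participant"].nunique() >= 3:
            results["quarter_anova"] = rm_anova(qtab, "orthogonal_percent",
                                                "quarter", "participant")
            wide = qtab.pivot(index="participant", columns="quarter",
                              values="orthogonal_percent")
            posthoc = []
            cols = sorted(wide.columns)
            for a, b in zip(cols, cols[1:]):
                r = paired_t(wide[b].to_numpy(), wide[a].to_numpy())
                posthoc.append({"comparison": f"Q{b} - Q{a}", "t": r.t,
                                "df": r.df, "p_raw": r.p_value,
                                "cohens_d": r.cohens_d})
            ph = pd.DataFrame(posthoc)
            ph["p_bonferroni"] = bonferroni(ph["p_raw"].to_numpy(), len(ph))
            results["quarter_posthoc"] = ph

    if responses is not None and "percent_correct" in table.columns:
        pc = (full[full["role"] == "initial"]
              .groupby(["participant", "quality_fraction"])["percent_correct"]
              .mean().reset_index())
        pc["asin_correct"] = arcsine_transform(pc["percent_correct"].to_numpy())
        results["anova_percent_correct"] = pd.DataFrame([vars(rm_anova(
            pc, "asin_correct", "quality_fraction", "participant"))])

    if summaries is not None and exp_id in (2, 3):
        sm = summaries.merge(design[["participant", "trial_index", "demand"]],
                             on=["participant", "trial_index"])
        agg = (sm.groupby(["participant", "demand"])
               [["n_strokes", "n_switches", "time_on_stimuli_s"]]
               .mean().reset_index())
        wide = agg.pivot(index="participant", columns="demand")
        demand_rows = []
        for dvname in ("n_strokes", "n_switches", "time_on_stimuli_s"):
            hi = wide[(dvname, "high")].to_numpy()
            lo = wide[(dvname, "low")].to_numpy()
            r = paired_t(hi, lo)
            demand_rows.append({"measure": dvname, "t": r.t, "df": r.df,
                                "p_value": r.p_value, "cohens_d": r.cohens_d})
        results["demand_tests"] = pd.DataFrame(demand_rows)

    if summaries is not None:
        results["movement_summary"] = {
            "mean_strokes_per_trial": float(summaries["n_strokes"].mean()),
            "mean_switches_per_trial": float(summaries["n_switches"].mean()),
            "mean_time_on_stimuli_s": float(summaries["time_on_stimuli_s"].mean()),
        }
    if responses is not None:
        results["percent_correct_overall"] = float(
            100.0 * responses["correct"].mean())
    return results
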