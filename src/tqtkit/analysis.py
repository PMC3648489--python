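"""Endpoint construction and the crossover statistical analyses.

Implements the change-from-baseline endpoints, the primary mixed-model ANCOVA
with the two placebo periods pooled as a single treatment level, the
by-timepoint repeated-measurements contrasts, the positive-control assay
sensitivity test, categorical/outlier incidence, the sex subgroup analysis and
the pre-specified sensitivity analyses (single-placebo re-analysis, global
average baseline, one-step QT analysis with RR covariate).

The decision rule throughout: a treatment is "negative" for QTc prolongation
iff the upper bound of the two-sided 90% CI of the placebo-corrected contrast
falls below the 10 ms margin — exactly dual to the one-sided 5% test.
The two dose-level tests form an intersection-union test, so no multiplicity
adjustment is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from tqtkit.design import PLACEBO

DEFAULT_MARGIN = 10.0
DEFAULT_ALPHA = 0.05

#: Endpoint windows (inclusive) in hours post-dose.
WINDOWS = {
    "window_1_4h": (1.0, 4.0),
    "window_2_4h": (2.0, 4.0),
    "window_0p5_24h": (0.5, 24.0),
}

_EPS = 1e-9


class UnestimableError(ValueError):
    pass


@dataclass
class ContrastResult:
    """One placebo-corrected treatment comparison."""

    treatment: str
    n: int
    adjusted_mean_cfb: float
    se_adjusted_mean: float
    placebo_adjusted_mean_cfb: float
    diff_ms: float
    se_diff: float
    df: float
    ci90: tuple[float, float]
    p_one_sided_vs_margin: float
    p_superiority: float
    margin: float = DEFAULT_MARGIN
    extra: dict = field(default_factory=dict)

    @property
    def negative(self) -> bool:
        """True iff the upper 90% CI bound excludes the margin."""
        return self.ci90[1] < self.margin

    def to_dict(self) -> dict:
        d = {
            "treatment": self.treatment,
            "n": self.n,
            "adjusted_mean_cfb": self.adjusted_mean_cfb,
            "se_adjusted_mean": self.se_adjusted_mean,
            "placebo_adjusted_mean_cfb": self.placebo_adjusted_mean_cfb,
            "diff_ms": self.diff_ms,
            "se_diff": self.se_diff,
            "df": self.df,
            "ci90_lower": self.ci90[0],
            "ci90_upper": self.ci90[1],
            "p_one_sided_vs_margin": self.p_one_sided_vs_margin,
            "p_superiority": self.p_superiority,
            "negative_at_margin": self.negative,
        }
        d.update(self.extra)
        return d


@dataclass(frozen=True)
class CategoricalRules:
    """Threshold rules for the categorical/outlier analyses.

    Notable-change rules are conjunctions: both the percentage condition and
    the absolute condition must hold.
    """

    qtc_absolute_thresholds: tuple[float, ...] = (450.0, 480.0)
    qtc_change_thresholds: tuple[float, ...] = (30.0,)
    hr_pct_change: float = 25.0
    hr_low_bpm: float = 50.0
    hr_high_bpm: float = 100.0
    pr_pct_increase: float = 25.0
    pr_abs_ms: float = 200.0
    qrs_pct_increase: float = 10.0
    qrs_abs_ms: float = 110.0


# ---------------------------------------------------------------------------
# change from baseline
# ---------------------------------------------------------------------------

def compute_cfb(
    timepoint_values: pd.DataFrame,
    baselines: pd.DataFrame,
    scope: str = "window_1_4h",
    value_col: str = "qtc_ms",
) -> pd.DataFrame:
    """Change-from-baseline rows for a windowed or per-timepoint scope.

    Windowed scopes average the timepoint values inside the (inclusive) window
    first and then subtract the period baseline; ``scope='timepoint'`` keeps
    one row per post-dose timepoint.  Subject/period combinations without a
    baseline are dropped (full-analysis-set rule, count in ``attrs``).
    """
    base_col = f"baseline_{value_col}"
    if base_col not in baselines.columns:
        raise KeyError(f"baselines lack column {base_col}")
    post = timepoint_values[timepoint_values["time_h"] > 0].copy()
    merged = post.merge(
        baselines[["subject_id", "period", base_col]],
        on=["subject_id", "period"],
        how="inner",
    )
    n_dropped = len(post) - len(merged)
    keys = [
        c
        for c in ("subject_id", "sex", "sequence", "period", "treatment")
        if c in merged.columns
    ]
    if scope == "timepoint":
        out = merged[keys + ["time_h", value_col, base_col]].copy()
        out["cfb_ms"] = out[value_col] - out[base_col]
    else:
        lo, hi = WINDOWS[scope]
        win = merged[(merged["time_h"] >= lo - _EPS) & (merged["time_h"] <= hi + _EPS)]
        g = win.groupby(keys, as_index=False)
        out = g[[value_col, base_col]].mean()
        out["n_timepoints"] = g["time_h"].count()["time_h"].to_numpy()
        out["cfb_ms"] = out[value_col] - out[base_col]
    out = out.rename(columns={base_col: "baseline_ms"})
    out.attrs["scope"] = scope
    out.attrs["rows_dropped_missing_baseline"] = int(n_dropped)
    return out


# ---------------------------------------------------------------------------
# mixed ANCOVA
# ---------------------------------------------------------------------------

def _build_design_matrix(df: pd.DataFrame, active: str, covariates: list[str]):
    """Intercept + sequence/period factors (if informative) + active indicator
    + covariates.  Returns (X, column names, index of active indicator)."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in ("sequence", "period"):
        if factor in df.columns and df[factor].nunique() > 1:
            levels = sorted(df[factor].unique())
            for lev in levels[1:]:
                cols.append((df[factor] == lev).to_numpy(dtype=float))
                names.append(f"{factor}[{lev}]")
    active_idx = len(names)
    cols.append((df["treatment"] == active).to_numpy(dtype=float))
    names.append("active")
    for cov in covariates:
        if cov in df.columns:
            x = df[cov].to_numpy(dtype=float)
            cols.append(x - x.mean())  # centred: intercept = placebo adjusted mean
            names.append(cov)
    X = np.column_stack(cols)
    return X, names, active_idx


def _fit_mixed(y, X, groups):
    """REML mixed model with subject random intercept; OLS fallback on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True, maxiter=200)
            beta = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[: len(beta), : len(beta)]
            if np.all(np.isfinite(beta)) and np.all(np.isfinite(np.diag(cov))):
                return beta, cov, "mixedlm"
        except (np.linalg.LinAlgError, ValueError):
            pass
        res = sm.OLS(y, X).fit()
        return np.asarray(res.params), np.asarray(res.cov_params()), "ols"


def fit_contrast(
    df: pd.DataFrame,
    active: str,
    value_col: str = "cfb_ms",
    covariates: tuple[str, ...] = ("baseline_ms",),
    placebo_label: str = PLACEBO,
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
) -> ContrastResult:
    """Mixed ANCOVA contrast of one active treatment against (pooled) placebo.

    Fits ``value ~ sequence + period + active + covariates`` with a subject
    random intercept on the rows of the active treatment plus all placebo
    rows (both placebo periods enter as one treatment level).  The active
    indicator's coefficient is the placebo-corrected difference.  Two-sided
    ``(1 - 2*alpha)`` CI and one-sided p-values use the t distribution with
    residual degrees of freedom ``nobs - rank(X)``.
    """
    sub = df[df["treatment"].isin([active, placebo_label])]
    if (sub["treatment"] == active).sum() == 0 or (sub["treatment"] == placebo_label).sum() == 0:
        raise UnestimableError(f"need both {active!r} and {placebo_label!r} rows")
    if sub["treatment"].nunique() < 2:
        raise UnestimableError("only one treatment level present")
    y = sub[value_col].to_numpy(dtype=float)
    X, names, ai = _build_design_matrix(sub, active, list(covariates))
    groups = sub["subject_id"].to_numpy()
    beta, cov, method = _fit_mixed(y, X, groups)
    diff = float(beta[ai])
    se = float(math.sqrt(cov[ai, ai]))
    dof = len(y) - np.linalg.matrix_rank(X)
    tcrit = stats.t.ppf(1 - alpha, dof)
    # g-computation adjusted means: mean prediction with indicator forced 0/1
    X0 = X.copy()
    X0[:, ai] = 0.0
    xbar0 = X0.mean(axis=0)
    adj_placebo = float(xbar0 @ beta)
    adj_active = adj_placebo + diff
    xbar1 = xbar0.copy()
    xbar1[ai] = 1.0
    se_active = float(math.sqrt(xbar1 @ cov @ xbar1))
    p_margin = float(stats.t.cdf((diff - margin) / se, dof))
    p_sup = float(1 - stats.t.cdf(diff / se, dof))
    return ContrastResult(
        treatment=active,
        n=int(sub.loc[sub["treatment"] == active, "subject_id"].nunique()),
        adjusted_mean_cfb=adj_active,
        se_adjusted_mean=se_active,
        placebo_adjusted_mean_cfb=adj_placebo,
        diff_ms=diff,
        se_diff=se,
        df=float(dof),
        ci90=(diff - tcrit * se, diff + tcrit * se),
        p_one_sided_vs_margin=p_margin,
        p_superiority=p_sup,
        margin=margin,
        extra={"fit_method": method},
    )


def fit_primary_ancova(
    cfb_rows: pd.DataFrame,
    actives: tuple[str, ...] | None = None,
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
    covariates: tuple[str, ...] = ("baseline_ms",),
) -> dict[str, ContrastResult]:
    """Primary analysis: one pairwise mixed ANCOVA per active treatment, each
    using that treatment's rows together with both placebo periods."""
    if actives is None:
        actives = tuple(t for t in cfb_rows["treatment"].unique() if t != PLACEBO)
    return {
        a: fit_contrast(cfb_rows, a, margin=margin, alpha=alpha, covariates=covariates)
        for a in actives
    }


def fit_rmc_by_timepoint(
    cfb_timepoint_rows: pd.DataFrame,
    actives: tuple[str, ...] | None = None,
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-timepoint placebo-corrected contrasts (repeated-measurements analogue).

    Each post-dose timepoint is analysed with the same mixed ANCOVA as the
    primary endpoint; timepoints at which an active treatment was not measured
    (positive-control 8/12/24 h) are skipped, never imputed.  Returns a tidy
    table with one row per treatment x timepoint and reports the maximum upper
    CI bound per treatment in ``attrs['max_upper_ci']``.
    """
    if actives is None:
        actives = tuple(t for t in cfb_timepoint_rows["treatment"].unique() if t != PLACEBO)
    rows = []
    for t in sorted(cfb_timepoint_rows["time_h"].unique()):
        at_t = cfb_timepoint_rows[np.isclose(cfb_timepoint_rows["time_h"], t)]
        for a in actives:
            if (at_t["treatment"] == a).sum() == 0:
                continue
            res = fit_contrast(at_t, a, margin=margin, alpha=alpha)
            d = res.to_dict()
            d["time_h"] = t
            rows.append(d)
    out = pd.DataFrame(rows)
    out.attrs["max_upper_ci"] = (
        out.groupby("treatment")["ci90_upper"].max().to_dict() if len(out) else {}
    )
    return out


def assay_sensitivity_test(
    cfb_rows_2_4h: pd.DataFrame,
    control: str = "control",
    alpha: float = DEFAULT_ALPHA,
) -> ContrastResult:
    """One-sided superiority test of the positive control on the 2-4 h window.

    H0: placebo-corrected difference <= 0.  Assay sensitivity is demonstrated
    iff ``p_superiority < alpha`` (stored in ``extra['assay_sensitive']``).
    """
    res = fit_contrast(cfb_rows_2_4h, control, alpha=alpha)
    res.extra["assay_sensitive"] = bool(res.p_superiority < alpha)
    return res


# ---------------------------------------------------------------------------
# categorical / outlier analyses
# ---------------------------------------------------------------------------

def categorical_analysis(
    timepoint_values: pd.DataFrame,
    cfb_timepoint_rows: pd.DataFrame,
    rules: CategoricalRules | None = None,
    qtc_col: str = "qtc_ms",
    control: str = "control",
) -> pd.DataFrame:
    """Incidence of QTc threshold exceedances, period-adjusted.

    For each treatment, the numerator counts subject-periods with at least one
    post-dose value beyond the threshold inside the treatment's observation
    window (0.5-24 h; 0.5-6 h for the positive control) and the denominator is
    the number of observed subject-periods.  Because placebo is given in two
    periods, this denominator convention is exactly the "incidence adjusted
    for the number of periods" rule: the placebo rate is the average of the
    two per-period rates when both are complete.
    """
    rules = rules or CategoricalRules()
    rows = []
    for trt, sub in timepoint_values[timepoint_values["time_h"] > 0].groupby("treatment"):
        hi = 6.0 if trt == control else 24.0
        win = sub[(sub["time_h"] >= 0.5 - _EPS) & (sub["time_h"] <= hi + _EPS)]
        exposed = win.groupby(["subject_id", "period"]).size()
        n_sp = len(exposed)
        for thr in rules.qtc_absolute_thresholds:
            exceed = win[win[qtc_col] > thr].groupby(["subject_id", "period"]).size()
            rows.append(
                {
                    "treatment": trt,
                    "rule": f"{qtc_col}>{thr:g}",
                    "kind": "absolute",
                    "n_exceeding": len(exceed),
                    "n_subject_periods": n_sp,
                    "incidence_pct": 100.0 * len(exceed) / n_sp if n_sp else 0.0,
                }
            )
    for trt, sub in cfb_timepoint_rows.groupby("treatment"):
        hi = 6.0 if trt == control else 24.0
        win = sub[(sub["time_h"] >= 0.5 - _EPS) & (sub["time_h"] <= hi + _EPS)]
        exposed = win.groupby(["subject_id", "period"]).size()
        n_sp = len(exposed)
        for thr in rules.qtc_change_thresholds:
            exceed = win[win["cfb_ms"] > thr].groupby(["subject_id", "period"]).size()
            rows.append(
                {
                    "treatment": trt,
                    "rule": f"change>{thr:g}",
                    "kind": "change",
                    "n_exceeding": len(exceed),
                    "n_subject_periods": n_sp,
                    "incidence_pct": 100.0 * len(exceed) / n_sp if n_sp else 0.0,
                }
            )
    return pd.DataFrame(rows)


def notable_changes(
    timepoint_values: pd.DataFrame,
    baselines: pd.DataFrame,
    rules: CategoricalRules | None = None,
) -> pd.DataFrame:
    """Flag notable HR/PR/QRS changes from the period baseline.

    Each rule is a conjunction of a percentage-change condition and an
    absolute-value condition; a record is notable only if both hold.
    """
    rules = rules or CategoricalRules()
    post = timepoint_values[timepoint_values["time_h"] > 0].merge(
        baselines, on=["subject_id", "period"], how="inner"
    )
    flags = []
    if {"hr_bpm", "baseline_hr_bpm"} <= set(post.columns):
        pct = 100.0 * (post["hr_bpm"] - post["baseline_hr_bpm"]).abs() / post["baseline_hr_bpm"]
        notable = (pct >= rules.hr_pct_change) & (
            (post["hr_bpm"] < rules.hr_low_bpm) | (post["hr_bpm"] > rules.hr_high_bpm)
        )
        flags.append(("hr", pct, notable))
    if {"pr_ms", "baseline_pr_ms"} <= set(post.columns):
        pct = 100.0 * (post["pr_ms"] - post["baseline_pr_ms"]) / post["baseline_pr_ms"]
        notable = (pct >= rules.pr_pct_increase) & (post["pr_ms"] > rules.pr_abs_ms)
        flags.append(("pr", pct, notable))
    if {"qrs_ms", "baseline_qrs_ms"} <= set(post.columns):
        pct = 100.0 * (post["qrs_ms"] - post["baseline_qrs_ms"]) / post["baseline_qrs_ms"]
        notable = (pct >= rules.qrs_pct_increase) & (post["qrs_ms"] > rules.qrs_abs_ms)
        flags.append(("qrs", pct, notable))
    out = []
    for param, pct, notable in flags:
        sub = post.loc[
            notable, [c for c in ("subject_id", "period", "treatment", "time_h") if c in post]
        ].copy()
        sub["parameter"] = param
        sub["pct_change"] = pct[notable].to_numpy()
        out.append(sub)
    if not out:
        return pd.DataFrame(
            columns=["subject_id", "period", "treatment", "time_h", "parameter", "pct_change"]
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# subgroup and sensitivity analyses
# ---------------------------------------------------------------------------

def subgroup_analysis(
    cfb_rows: pd.DataFrame,
    factor: str = "sex",
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, dict[str, ContrastResult]]:
    """Re-run the primary analysis within each level of ``factor``.

    Levels in which a contrast is unestimable are skipped with a warning.
    """
    out: dict[str, dict[str, ContrastResult]] = {}
    for level, sub in cfb_rows.groupby(factor):
        try:
            fits = fit_primary_ancova(sub, margin=margin, alpha=alpha)
        except UnestimableError as exc:
            warnings.warn(f"subgroup {factor}={level} skipped: {exc}")
            continue
        if not fits:
            warnings.warn(f"subgroup {factor}={level} skipped: no active treatments")
            continue
        out[str(level)] = fits
    if not out:
        warnings.warn(f"no estimable level of {factor}; subgroup analysis skipped")
    return out


def _placebo_occasions(cfb_rows: pd.DataFrame) -> pd.Series:
    """Chronological placebo occasion (1 or 2) per placebo row, by period order."""
    placebo = cfb_rows["treatment"] == PLACEBO
    ranked = (
        cfb_rows[placebo]
        .groupby("subject_id")["period"]
        .rank(method="first")
        .astype(int)
    )
    occ = pd.Series(np.nan, index=cfb_rows.index)
    occ[placebo] = ranked
    return occ


def sensitivity_single_placebo(
    cfb_rows: pd.DataFrame,
    actives: tuple[str, ...] | None = None,
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Primary ANCOVA re-fit with placebo period 1 only, period 2 only, both.

    Returns a tidy table of estimates, SEs, CIs and single/double SE ratios —
    the efficiency comparison of the replicated placebo design.
    """
    occ = _placebo_occasions(cfb_rows)
    keep1 = (cfb_rows["treatment"] != PLACEBO) | (occ == 1)
    keep2 = (cfb_rows["treatment"] != PLACEBO) | (occ == 2)
    modes = {
        "placebo_period_1_only": cfb_rows[keep1],
        "placebo_period_2_only": cfb_rows[keep2],
        "both_placebo_periods": cfb_rows,
    }
    rows = []
    for mode, df in modes.items():
        for a, res in fit_primary_ancova(df, actives=actives, margin=margin, alpha=alpha).items():
            d = res.to_dict()
            d["model"] = mode
            rows.append(d)
    out = pd.DataFrame(rows)
    both = out[out["model"] == "both_placebo_periods"].set_index("treatment")["se_diff"]
    out["se_ratio_vs_double"] = out.apply(
        lambda r: r["se_diff"] / both[r["treatment"]], axis=1
    )
    return out


def sensitivity_global_baseline(
    cfb_rows: pd.DataFrame,
    actives: tuple[str, ...] | None = None,
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, ContrastResult]:
    """Primary analysis with the covariate replaced by the subject's average
    baseline across all periods (global average baseline)."""
    df = cfb_rows.copy()
    df["global_baseline_ms"] = df.groupby("subject_id")["baseline_ms"].transform("mean")
    return {
        a: fit_contrast(
            df, a, covariates=("global_baseline_ms",), margin=margin, alpha=alpha
        )
        for a in (
            actives
            if actives is not None
            else tuple(t for t in df["treatment"].unique() if t != PLACEBO)
        )
    }


def one_step_qt_analysis(
    qt_cfb_rows: pd.DataFrame,
    rr_cfb_rows: pd.DataFrame,
    actives: tuple[str, ...] | None = None,
    margin: float = DEFAULT_MARGIN,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, ContrastResult]:
    """One-step procedure: ANCOVA of uncorrected QT change from baseline with
    the RR change from baseline as an additional covariate.

    ``qt_cfb_rows``/``rr_cfb_rows`` are windowed CfB tables computed on
    ``qt_ms`` and ``rr_ms`` respectively (same scope).  If RR shows no
    variation the covariate is dropped and the fit reduces to the uncorrected
    QT ANCOVA.
    """
    rr = rr_cfb_rows[["subject_id", "period", "cfb_ms"]].rename(
        columns={"cfb_ms": "rr_cfb_ms"}
    )
    df = qt_cfb_rows.merge(rr, on=["subject_id", "period"], how="inner")
    covs: tuple[str, ...] = ("baseline_ms", "rr_cfb_ms")
    if df["rr_cfb_ms"].nunique() < 2:
        covs = ("baseline_ms",)
    if actives is None:
        actives = tuple(t for t in df["treatment"].unique() if t != PLACEBO)
    return {
        a: fit_contrast(df, a, covariates=covs, margin=margin, alpha=alpha)
        for a in actives
    }
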