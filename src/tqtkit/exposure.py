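"""Concentration-QTc exposure-response: linear mixed model and prediction at Cmax.

Pairs time-matched plasma concentrations with the placebo-corrected QTc change
from baseline (the two placebo periods' CfB values are arithmetically averaged
per subject and timepoint before subtraction), fits a linear model with a
subject random intercept per dose, and predicts the effect at the geometric
mean Cmax.  CI conventions: two-sided 95% for the slope, 90% for the
prediction (delta method on the fixed-effect covariance, normal quantiles).
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


class PairingError(ValueError):
    pass


@dataclass
class ErFit:
    """Per-dose linear exposure-response fit."""

    dose_label: str
    n_pairs: int
    intercept: float
    slope: float
    slope_se: float
    slope_ci95: tuple[float, float]
    cov: np.ndarray = field(repr=False, default=None)
    fit_method: str = "mixedlm"

    def to_dict(self) -> dict:
        return {
            "treatment": self.dose_label,
            "n_pairs": self.n_pairs,
            "intercept_ms": self.intercept,
            "slope_ms_per_nmol_l": self.slope,
            "slope_se": self.slope_se,
            "slope_ci95_lower": self.slope_ci95[0],
            "slope_ci95_upper": self.slope_ci95[1],
            "fit_method": self.fit_method,
        }


def build_er_pairs(
    cfb_timepoint_rows: pd.DataFrame, pk_table: pd.DataFrame
) -> pd.DataFrame:
    """Time-matched (concentration, placebo-corrected CfB) pairs.

    For each subject and nominal post-dose timepoint the placebo CfB is
    averaged over the placebo periods present and subtracted from the on-drug
    CfB; the pair exists only if the PK sample at that subject/period/time is
    present.  Missing pairs are counted in ``attrs['n_unmatched']``.
    """
    placebo_avg = (
        cfb_timepoint_rows[cfb_timepoint_rows["treatment"] == PLACEBO]
        .groupby(["subject_id", "time_h"], as_index=False)["cfb_ms"]
        .mean()
        .rename(columns={"cfb_ms": "placebo_cfb_ms"})
    )
    drug = cfb_timepoint_rows[
        cfb_timepoint_rows["treatment"].isin(pk_table["treatment"].unique())
    ]
    merged = drug.merge(placebo_avg, on=["subject_id", "time_h"], how="inner")
    merged["ddqtc_ms"] = merged["cfb_ms"] - merged["placebo_cfb_ms"]
    out = merged.merge(
        pk_table[["subject_id", "period", "treatment", "time_h", "conc_nmol_l"]],
        on=["subject_id", "period", "treatment", "time_h"],
        how="inner",
    )
    if out.empty:
        raise PairingError("PK and ECG tables share no subject/timepoint")
    out = out[
        ["subject_id", "period", "treatment", "time_h", "conc_nmol_l", "ddqtc_ms"]
    ].reset_index(drop=True)
    out.attrs["n_unmatched"] = int(len(merged) - len(out))
    return out


def fit_er_model(pairs: pd.DataFrame, by_dose: bool = True) -> dict[str, ErFit]:
    """Fit ``ddqtc ~ concentration`` with a subject random intercept.

    One fit per dose level by default (``by_dose=False`` pools all pairs under
    the label ``'pooled'``).  Falls back to OLS when the mixed fit is singular
    (e.g. zero between-subject variance), where both estimators coincide.
    """
    groups = pairs.groupby("treatment") if by_dose else [("pooled", pairs)]
    out: dict[str, ErFit] = {}
    for label, sub in groups:
        conc = sub["conc_nmol_l"].to_numpy(dtype=float)
        if np.var(conc) == 0:
            raise ValueError(f"{label}: concentration variance is zero")
        y = sub["ddqtc_ms"].to_numpy(dtype=float)
        X = sm.add_constant(conc)
        method = "mixedlm"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(y, X, groups=sub["subject_id"].to_numpy()).fit(
                    reml=True, maxiter=200
                )
                beta = np.asarray(res.fe_params)
                cov = np.asarray(res.cov_params())[:2, :2]
                if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(np.diag(cov)))):
                    raise ValueError("non-finite mixed fit")
            except (np.linalg.LinAlgError, ValueError):
                ols = sm.OLS(y, X).fit()
                beta, cov, method = np.asarray(ols.params), np.asarray(ols.cov_params()), "ols"
        slope, se = float(beta[1]), float(math.sqrt(cov[1, 1]))
        z95 = stats.norm.ppf(0.975)
        out[str(label)] = ErFit(
            dose_label=str(label),
            n_pairs=len(sub),
            intercept=float(beta[0]),
            slope=slope,
            slope_se=se,
            slope_ci95=(slope - z95 * se, slope + z95 * se),
            cov=cov,
            fit_method=method,
        )
    return out


def predict_at_cmax(fit: ErFit, gmean_cmax: float, level: float = 0.90) -> dict:
    """Predicted placebo-corrected effect at a concentration, with CI.

    ``prediction = intercept + slope * gmean_cmax``; the CI uses the delta
    method on the fixed-effect covariance (variance ``x' V x`` with
    ``x = (1, cmax)``), normal quantiles.
    """
    x = np.array([1.0, gmean_cmax])
    pred = float(x @ np.array([fit.intercept, fit.slope]))
    se = float(math.sqrt(max(float(x @ fit.cov @ x), 0.0)))  # guard FP round-off
    z = stats.norm.ppf(0.5 + level / 2.0)
    return {
        "gmean_cmax": gmean_cmax,
        "prediction_ms": pred,
        "se": se,
        f"ci{int(level * 100)}_lower": pred - z * se,
        f"ci{int(level * 100)}_upper": pred + z * se,
    }


def er_table(
    pairs: pd.DataFrame, cmax_by_dose: dict[str, float], by_dose: bool = True
) -> pd.DataFrame:
    """Assemble the per-dose slope/intercept/prediction summary table."""
    fits = fit_er_model(pairs, by_dose=by_dose)
    rows = []
    for label, fit in fits.items():
        d = fit.to_dict()
        if label in cmax_by_dose:
            d.update(predict_at_cmax(fit, cmax_by_dose[label]))
        rows.append(d)
    return pd.DataFrame(rows)
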