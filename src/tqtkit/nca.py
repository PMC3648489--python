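"""Noncompartmental PK analysis: Cmax/tmax, AUC(0-tz) and geometric summaries.

AUC uses the linear-up/log-down convention: ascending segments are integrated
with the linear trapezoid, descending segments with the log trapezoid
``(C1 - C2) / ln(C1/C2) * dt``.  Integration stops at tz, the last time with a
quantifiable (>= LLOQ) concentration; unquantifiable values mid-profile are
excluded from the integration grid and flagged (a documented choice — the
underlying method only defines the endpoint "to the last quantifiable time
point").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Assay lower limit of quantification, nmol/L.
DEFAULT_LLOQ = 1.11


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PkProfile:
    """One subject-period concentration-time series (times strictly increasing)."""

    subject_id: str
    period: int
    treatment: str
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        c = np.asarray(self.concentrations)
        if t.size != c.size:
            raise ValueError("times and concentrations differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PkProfile":
        df = df.sort_values("time_h")
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            period=int(df["period"].iloc[0]),
            treatment=str(df["treatment"].iloc[0]),
            times=tuple(df["time_h"].astype(float)),
            concentrations=tuple(df["conc_nmol_l"].astype(float)),
        )


@dataclass(frozen=True)
class NcaResult:
    subject_id: str
    period: int
    treatment: str
    cmax: float
    tmax: float
    auc_0_tz: float
    tz: float
    n_blq_excluded: int = 0


def compute_cmax_tmax(profile: PkProfile, lloq: float = DEFAULT_LLOQ) -> tuple[float, float]:
    """Peak concentration and its time; ties broken by first occurrence."""
    t = np.asarray(profile.times)
    c = np.asarray(profile.concentrations)
    quant = c >= lloq
    if not quant.any():
        raise InsufficientDataError("no quantifiable concentration")
    imax = int(np.argmax(c))  # argmax returns the first maximiser
    return float(c[imax]), float(t[imax])


def _quantifiable_grid(profile: PkProfile, lloq: float):
    """Integration grid: t<=0 points kept as dosed zeros, post-dose points kept
    only if quantifiable; truncated at tz."""
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    quant = (c >= lloq) | (t <= 0)
    n_excluded = int((~quant).sum())
    t, c = t[quant], c[quant]
    post_quant = np.where(np.asarray(c) >= lloq)[0]
    if post_quant.size == 0:
        raise InsufficientDataError("no quantifiable concentration")
    tz_idx = post_quant[-1]
    return t[: tz_idx + 1], c[: tz_idx + 1], n_excluded


def compute_auc_0_tz(profile: PkProfile, lloq: float = DEFAULT_LLOQ) -> tuple[float, float, int]:
    """AUC from zero to the last quantifiable time, lin-up/log-down.

    Returns ``(auc, tz, n_blq_excluded)``.  Descending segments ending at a
    zero concentration fall back to the linear trapezoid (the log formula is
    undefined there).
    """
    t, c, n_excluded = _quantifiable_grid(profile, lloq)
    if t.size < 2:
        raise InsufficientDataError("need >= 2 quantifiable points for AUC")
    auc = 0.0
    for (t1, c1), (t2, c2) in zip(zip(t, c), zip(t[1:], c[1:])):
        dt = t2 - t1
        if c2 >= c1 or c1 <= 0 or c2 <= 0:
            auc += 0.5 * (c1 + c2) * dt
        else:
            auc += (c1 - c2) / math.log(c1 / c2) * dt
    return float(auc), float(t[-1]), n_excluded


def analyse_profile(profile: PkProfile, lloq: float = DEFAULT_LLOQ) -> NcaResult:
    cmax, tmax = compute_cmax_tmax(profile, lloq)
    auc, tz, n_excl = compute_auc_0_tz(profile, lloq)
    return NcaResult(
        subject_id=profile.subject_id,
        period=profile.period,
        treatment=profile.treatment,
        cmax=cmax,
        tmax=tmax,
        auc_0_tz=auc,
        tz=tz,
        n_blq_excluded=n_excl,
    )


def nca_table(pk_df: pd.DataFrame, lloq: float = DEFAULT_LLOQ) -> pd.DataFrame:
    """Per subject-period NCA results from a long PK table."""
    rows = []
    for _, sub in pk_df.groupby(["subject_id", "period", "treatment"]):
        try:
            res = analyse_profile(PkProfile.from_frame(sub), lloq)
        except InsufficientDataError:
            continue
        rows.append(res.__dict__)
    if not rows:
        raise InsufficientDataError("no analysable PK profile")
    return pd.DataFrame(rows)


def geometric_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric CV% of a positive sample.

    ``gMean = exp(mean(log x))``; ``gCV% = 100*sqrt(exp(var(log x)) - 1)``
    with the n-1 variance denominator.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    if np.any(x <= 0):
        raise ValueError("geometric statistics need strictly positive values")
    logs = np.log(x)
    gmean = float(np.exp(logs.mean()))
    gvar = float(logs.var(ddof=1)) if x.size > 1 else 0.0
    gcv = 100.0 * math.sqrt(math.exp(gvar) - 1.0)
    return gmean, gcv


def summarize_nca(nca_df: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level summary: gMean/gCV for Cmax and AUC, median/range for tmax."""
    rows = []
    for trt, sub in nca_df.groupby("treatment"):
        cmax_g, cmax_cv = geometric_stats(sub["cmax"])
        auc_g, auc_cv = geometric_stats(sub["auc_0_tz"])
        rows.append(
            {
                "treatment": trt,
                "n": len(sub),
                "auc_0_tz_gmean": auc_g,
                "auc_0_tz_gcv_pct": auc_cv,
                "cmax_gmean": cmax_g,
                "cmax_gcv_pct": cmax_cv,
                "tmax_median": float(sub["tmax"].median()),
                "tmax_min": float(sub["tmax"].min()),
                "tmax_max": float(sub["tmax"].max()),
            }
        )
    return pd.DataFrame(rows)
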