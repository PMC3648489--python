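"""ECG record reduction and heart-rate correction of the QT interval.

Reduction order is fixed: beat-level intervals are averaged to one value per
ECG replicate, replicates are averaged to one value per scheduled timepoint,
and the heart-rate correction is applied to the timepoint-level QT/RR pair.
Period baselines are the mean of the pre-dose timepoints (``time_h < 0``).

All corrections share the parameterisation ``QTc = QT * (1000 / RR)**delta``
(QT and RR in ms), so QTc equals QT at RR = 1000 ms for every method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

INTERVAL_COLS = ("qt_ms", "rr_ms", "pr_ms", "qrs_ms")

BAZETT_DELTA = 0.5
FRIDERICIA_DELTA = 1.0 / 3.0


class MissingDataError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class CorrectionModel:
    """A heart-rate correction ``QTc = QT * (1000/RR)**delta``.

    ``method`` is one of ``bazett``, ``fridericia``, ``population``,
    ``individual``.  Fixed methods carry their exponent in ``delta``;
    the individual method stores one exponent per subject in
    ``individual_deltas``.
    """

    method: str
    delta: float | None = None
    individual_deltas: dict[str, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def bazett(cls) -> "CorrectionModel":
        return cls(method="bazett", delta=BAZETT_DELTA)

    @classmethod
    def fridericia(cls) -> "CorrectionModel":
        return cls(method="fridericia", delta=FRIDERICIA_DELTA)

    def delta_for(self, subject_id: str | None = None) -> float:
        if self.method == "individual":
            if self.individual_deltas is None or subject_id not in self.individual_deltas:
                raise KeyError(f"no individual exponent for subject {subject_id!r}")
            return self.individual_deltas[subject_id]
        if self.delta is None:
            raise ValueError(f"correction model {self.method!r} has no exponent")
        return self.delta

    def qtc_column_name(self) -> str:
        return {
            "bazett": "qtcb_ms",
            "fridericia": "qtcf_ms",
            "population": "qtcn_ms",
            "individual": "qtci_ms",
        }.get(self.method, "qtc_ms")


def apply_correction(
    qt_ms, rr_ms, model: CorrectionModel, subject_id: str | None = None
):
    """Correct QT for heart rate: ``qt * (1000/rr)**delta``.

    Accepts scalars or arrays; for the individual method a single
    ``subject_id`` must identify the exponent.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("rr_ms must be positive")
    delta = model.delta_for(subject_id)
    out = qt * (1000.0 / rr) ** delta
    return float(out) if out.ndim == 0 else out


def average_beats(beat_rows: pd.DataFrame) -> pd.DataFrame:
    """Average beat-level intervals to one row per ECG replicate.

    Groups on subject/period/treatment/time/replicate (plus any of
    sequence/sex present) and takes the arithmetic mean of each interval.
    """
    if beat_rows.empty:
        raise MissingDataError("no beat rows to average")
    keys = [
        c
        for c in ("subject_id", "sex", "sequence", "period", "treatment", "time_h", "replicate")
        if c in beat_rows.columns
    ]
    cols = [c for c in INTERVAL_COLS if c in beat_rows.columns]
    out = beat_rows.groupby(keys, as_index=False, sort=True)[cols].mean()
    return out


def average_triplicate(ecg_rows: pd.DataFrame) -> pd.DataFrame:
    """Average replicate-level rows to one row per scheduled timepoint.

    Missing replicates are tolerated: available replicates are averaged and
    the number contributing is recorded in ``replicate_count``.  Adds the
    derived heart rate ``hr_bpm = 60000 / rr_ms``.
    """
    if ecg_rows.empty:
        raise MissingDataError("no replicate rows to average")
    keys = [
        c
        for c in ("subject_id", "sex", "sequence", "period", "treatment", "time_h")
        if c in ecg_rows.columns
    ]
    cols = [c for c in INTERVAL_COLS if c in ecg_rows.columns]
    g = ecg_rows.groupby(keys, as_index=False, sort=True)
    out = g[cols].mean()
    out["replicate_count"] = g["replicate"].count()["replicate"].to_numpy()
    if "rr_ms" in out.columns:
        out["hr_bpm"] = 60000.0 / out["rr_ms"]
    return out


def derive_baseline(
    timepoint_values: pd.DataFrame, value_cols: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Period-specific baselines: mean over pre-dose (``time_h < 0``) timepoints.

    Returns one row per subject x period with ``baseline_<col>`` columns.
    Subject/period combinations with no pre-dose timepoint are absent from the
    output (full-analysis-set rule: they are excluded downstream, never
    imputed).
    """
    pre = timepoint_values[timepoint_values["time_h"] < 0]
    if pre.empty:
        raise MissingDataError("no pre-dose timepoints available for baselines")
    if value_cols is None:
        value_cols = tuple(
            c
            for c in timepoint_values.columns
            if c.endswith("_ms") or c.endswith("_bpm")
        )
    base = pre.groupby(["subject_id", "period"], as_index=False)[list(value_cols)].mean()
    base = base.rename(columns={c: f"baseline_{c}" for c in value_cols})
    return base


def drug_free_records(timepoint_values: pd.DataFrame, placebo_label: str = "placebo") -> pd.DataFrame:
    """Records usable for exponent estimation: every pre-dose timepoint plus
    all placebo-period records."""
    mask = (timepoint_values["time_h"] < 0) | (
        timepoint_values["treatment"] == placebo_label
    )
    return timepoint_values[mask]


def _check_rr_variation(df: pd.DataFrame) -> None:
    if df["rr_ms"].nunique() < 2:
        raise DegenerateInputError("no RR variation; exponent is not identifiable")


def estimate_population_delta(drug_free_rows: pd.DataFrame) -> CorrectionModel:
    """Population exponent via a linear mixed model on the log scale.

    Fits ``log(QT) = a_i + delta * log(RR/1000)`` with a random intercept per
    subject; ``delta`` is the fixed-effect slope.  The returned model applies
    ``QTc = QT * (1000/RR)**delta``.
    """
    df = drug_free_rows.dropna(subset=["qt_ms", "rr_ms"])
    if df["subject_id"].nunique() < 2:
        raise DegenerateInputError("population fit needs >= 2 subjects")
    _check_rr_variation(df)
    y = np.log(df["qt_ms"].to_numpy())
    x = np.log(df["rr_ms"].to_numpy() / 1000.0)
    exog = sm.add_constant(x)
    groups = df["subject_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
            delta = float(res.fe_params[1])
            se = float(res.bse_fe[1])
        except (np.linalg.LinAlgError, ValueError):
            ols = sm.OLS(y, exog).fit()
            delta, se = float(ols.params[1]), float(ols.bse[1])
    ci = (delta - 1.96 * se, delta + 1.96 * se)
    return CorrectionModel(
        method="population",
        delta=delta,
        diagnostics={"se": se, "ci95": ci, "n_records": len(df)},
    )


def estimate_individual_deltas(
    drug_free_rows: pd.DataFrame, min_records: int = 3
) -> CorrectionModel:
    """Per-subject exponents by least squares of log(QT) on log(RR/1000).

    Subjects with fewer than ``min_records`` usable records or with no RR
    variation are flagged in ``diagnostics['excluded']`` and excluded.
    """
    deltas: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for sid, sub in drug_free_rows.dropna(subset=["qt_ms", "rr_ms"]).groupby("subject_id"):
        if len(sub) < min_records:
            excluded[str(sid)] = "too few records"
            continue
        if sub["rr_ms"].nunique() < 2:
            excluded[str(sid)] = "no RR variation"
            continue
        x = np.log(sub["rr_ms"].to_numpy() / 1000.0)
        y = np.log(sub["qt_ms"].to_numpy())
        slope = float(np.polyfit(x, y, 1)[0])
        deltas[str(sid)] = slope
    if not deltas:
        raise DegenerateInputError("no subject admits an individual exponent fit")
    return CorrectionModel(
        method="individual",
        individual_deltas=deltas,
        diagnostics={"excluded": excluded, "n_subjects": len(deltas)},
    )


def add_corrections(
    timepoint_values: pd.DataFrame, models: list[CorrectionModel]
) -> pd.DataFrame:
    """Append one QTc column per correction model to a timepoint-level table."""
    out = timepoint_values.copy()
    for model in models:
        col = model.qtc_column_name()
        if model.method == "individual":
            vals = np.empty(len(out))
            for i, (sid, qt, rr) in enumerate(
                zip(out["subject_id"], out["qt_ms"], out["rr_ms"])
            ):
                vals[i] = apply_correction(qt, rr, model, subject_id=str(sid))
            out[col] = vals
        else:
            out[col] = apply_correction(out["qt_ms"], out["rr_ms"], model)
    return out


def prepare_timepoints(
    beat_rows: pd.DataFrame, correction: CorrectionModel | None = None
) -> pd.DataFrame:
    """Full reduction pipeline: beats -> replicates -> timepoints [-> QTc]."""
    tp = average_triplicate(average_beats(beat_rows))
    if correction is not None:
        tp = add_corrections(tp, [correction])
        tp = tp.rename(columns={correction.qtc_column_name(): "qtc_ms"})
    return tp
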