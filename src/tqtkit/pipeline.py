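"""End-to-end pipeline: data (simulated or loaded) -> prep -> analyses -> reports.

Emits the trial's report tables as CSV plus a machine-readable ``results.json``
and a run log with seed and package versions.  Fully deterministic given
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

import tqtkit
from tqtkit import analysis, ecg, exposure, nca
from tqtkit.io import validate_inputs
from tqtkit.synthetic import PkSimParams, SimulationConfig, simulate_trial


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def default_demo_config() -> dict:
    """A small packaged demo: 12 subjects, real control effect, null test drug."""
    return {
        "simulate": {
            "n_subjects": 12,
            "dropout_count": 1,
            "control_effect_ms": 12.0,
            "conc_slope_ms_per_nmol": 0.0,
        },
        "correction": "population",
        "endpoint": "window_1_4h",
        "margin": 10.0,
        "alpha": 0.05,
        "analyses": {
            "subgroup": True,
            "sensitivity_single_placebo": True,
            "sensitivity_global_baseline": True,
            "one_step": True,
        },
    }


def _build_correction(method: str, timepoints: pd.DataFrame) -> ecg.CorrectionModel:
    if method == "bazett":
        return ecg.CorrectionModel.bazett()
    if method == "fridericia":
        return ecg.CorrectionModel.fridericia()
    drug_free = ecg.drug_free_records(timepoints)
    if method == "population":
        return ecg.estimate_population_delta(drug_free)
    if method == "individual":
        return ecg.estimate_individual_deltas(drug_free)
    raise ValueError(f"unknown correction method {method!r}")


def run_pipeline(config: dict, seed: int, out_dir) -> dict:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    ``config`` either carries a ``simulate`` block (forwarded to
    :class:`SimulationConfig`) or ``ecg_csv``/``pk_csv`` paths.  Returns the
    results dictionary that is also written to ``results.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": seed}

    # --- stage: data -------------------------------------------------------
    try:
        if "simulate" in config:
            sim_cfg = SimulationConfig(**config["simulate"])
            pk_params = PkSimParams(**config.get("pk", {}))
            ecg_df, pk_df = simulate_trial(sim_cfg, pk_params, seed=seed)
            ecg_df.to_csv(out / "ecg.csv", index=False)
            pk_df.to_csv(out / "pk.csv", index=False)
        else:
            ecg_df = pd.read_csv(config["ecg_csv"])
            pk_df = pd.read_csv(config["pk_csv"]) if config.get("pk_csv") else None
    except Exception as exc:  # noqa: BLE001 - re-tagged
        raise PipelineError("data", exc) from exc

    # --- stage: validation -------------------------------------------------
    report = validate_inputs(ecg_df, pk_df)
    results["validation"] = report.to_dict()
    if not report.ok:
        raise PipelineError("validation", ValueError("; ".join(report.errors)))

    # --- stage: ecg prep ---------------------------------------------------
    try:
        timepoints = ecg.average_triplicate(ecg.average_beats(ecg_df))
        correction = _build_correction(config.get("correction", "population"), timepoints)
        timepoints = ecg.add_corrections(timepoints, [correction])
        timepoints = timepoints.rename(columns={correction.qtc_column_name(): "qtc_ms"})
        baselines = ecg.derive_baseline(timepoints)
        timepoints.to_csv(out / "timepoints.csv", index=False)
        results["correction"] = {
            "method": correction.method,
            "delta": correction.delta,
            "diagnostics": {
                k: v for k, v in correction.diagnostics.items() if k != "excluded"
            },
        }
    except Exception as exc:
        raise PipelineError("ecg_prep", exc) from exc

    margin = float(config.get("margin", 10.0))
    alpha = float(config.get("alpha", 0.05))
    endpoint = config.get("endpoint", "window_1_4h")
    toggles = config.get("analyses", {})

    # --- stage: endpoints + analyses --------------------------------------
    try:
        cfb_primary = analysis.compute_cfb(timepoints, baselines, scope=endpoint)
        cfb_2_4 = analysis.compute_cfb(timepoints, baselines, scope="window_2_4h")
        cfb_tp = analysis.compute_cfb(timepoints, baselines, scope="timepoint")

        primary = analysis.fit_primary_ancova(cfb_primary, margin=margin, alpha=alpha)
        pd.DataFrame([r.to_dict() for r in primary.values()]).to_csv(
            out / "primary_analysis.csv", index=False
        )
        results["primary"] = {k: v.to_dict() for k, v in primary.items()}
        results["negative_trial"] = all(
            v.negative for k, v in primary.items() if k != "control"
        )

        assay = analysis.assay_sensitivity_test(cfb_2_4, alpha=alpha)
        results["assay_sensitivity"] = assay.to_dict()

        rmc = analysis.fit_rmc_by_timepoint(cfb_tp, margin=margin, alpha=alpha)
        rmc.to_csv(out / "by_timepoint.csv", index=False)
        results["max_upper_ci_by_treatment"] = rmc.attrs["max_upper_ci"]

        cat = analysis.categorical_analysis(timepoints, cfb_tp)
        cat.to_csv(out / "categorical.csv", index=False)
        notable = analysis.notable_changes(timepoints, baselines)
        notable.to_csv(out / "notable_changes.csv", index=False)
        results["n_notable_changes"] = int(len(notable))

        if toggles.get("subgroup", True) and "sex" in cfb_primary.columns:
            sub = analysis.subgroup_analysis(cfb_primary, margin=margin, alpha=alpha)
            pd.DataFrame(
                [
                    dict(level=lvl, **res.to_dict())
                    for lvl, d in sub.items()
                    for res in d.values()
                ]
            ).to_csv(out / "subgroup.csv", index=False)
        if toggles.get("sensitivity_single_placebo", True):
            sens = analysis.sensitivity_single_placebo(cfb_primary, margin=margin, alpha=alpha)
            sens.to_csv(out / "placebo_sensitivity.csv", index=False)
            results["mean_se_ratio_single_vs_double"] = float(
                sens.loc[sens["model"] != "both_placebo_periods", "se_ratio_vs_double"].mean()
            )
        if toggles.get("sensitivity_global_baseline", True):
            glob = analysis.sensitivity_global_baseline(cfb_primary, margin=margin, alpha=alpha)
            pd.DataFrame([r.to_dict() for r in glob.values()]).to_csv(
                out / "global_baseline_sensitivity.csv", index=False
            )
        if toggles.get("one_step", True):
            qt_cfb = analysis.compute_cfb(timepoints, baselines, scope=endpoint, value_col="qt_ms")
            rr_cfb = analysis.compute_cfb(timepoints, baselines, scope=endpoint, value_col="rr_ms")
            one_step = analysis.one_step_qt_analysis(qt_cfb, rr_cfb, margin=margin, alpha=alpha)
            pd.DataFrame([r.to_dict() for r in one_step.values()]).to_csv(
                out / "one_step_qt.csv", index=False
            )
    except Exception as exc:
        raise PipelineError("qt_analysis", exc) from exc

    # --- stage: NCA + exposure-response ------------------------------------
    if pk_df is not None and len(pk_df):
        try:
            nca_df = nca.nca_table(pk_df, lloq=float(config.get("lloq", nca.DEFAULT_LLOQ)))
            nca_df.to_csv(out / "nca_subject.csv", index=False)
            summary = nca.summarize_nca(nca_df)
            summary.to_csv(out / "nca_summary.csv", index=False)
            results["nca"] = summary.to_dict(orient="records")
        except Exception as exc:
            raise PipelineError("pk_nca", exc) from exc
        try:
            pairs = exposure.build_er_pairs(cfb_tp, pk_df)
            pairs.to_csv(out / "er_pairs.csv", index=False)
            cmax_by_dose = dict(zip(summary["treatment"], summary["cmax_gmean"]))
            er = exposure.er_table(pairs, cmax_by_dose)
            er.to_csv(out / "er_fits.csv", index=False)
            results["exposure_response"] = er.to_dict(orient="records")
        except Exception as exc:
            raise PipelineError("exposure_response", exc) from exc

    # --- run log -----------------------------------------------------------
    results["versions"] = {
        "tqtkit": tqtkit.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
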