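"""Synthetic TQT trial data: full ECG + PK tables and fast endpoint-level sets.

Two levels of fidelity:

* :func:`simulate_trial` writes beat-level ECG rows and PK concentration rows
  for a five-period double-placebo crossover with the trial's measurement
  schedule (triplicate ECGs at -60/-50/-40 min and 0.5-24 h post-dose, the
  last three post-dose timepoints dropped in positive-control periods).
* :func:`simulate_endpoint_level` emits one change-from-baseline value per
  subject x period under a plain normal model, calibrated so the SD of the
  within-subject (active - single placebo) difference matches the 14 ms
  endpoint SD used by the sample-size calculus.

The QT generative model at beat level is
``QT = a_i * (RR/1000)**delta_i + circadian + period + treatment effect
+ timepoint noise + replicate noise + beat noise``:
a multiplicative heart-rate relationship with known exponent (so the
correction-fit recovery is testable) plus additive effect terms on the ms
scale.

The PK model is a one-compartment profile with first-order absorption and
log-normal between-subject variability; its defaults are calibrated to the
trial's reported summaries (median tmax ~1.5 h, geometric-mean Cmax ~770
nmol/L and AUC ~4900 nmol*h/L for the 25 mg therapeutic dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tqtkit.design import (
    PLACEBO,
    CrossoverDesign,
    assign_placebo_symbols,
    generate_williams_design,
    randomise,
)

#: Pre-dose ECG schedule: -60, -50, -40 minutes, in hours.
PRE_DOSE_TIMES = (-1.0, -50.0 / 60.0, -40.0 / 60.0)
#: Post-dose ECG schedule in hours.
POST_DOSE_TIMES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
#: Positive-control periods omit the last three post-dose timepoints.
CONTROL_POST_DOSE_TIMES = POST_DOSE_TIMES[:-3]

N_REPLICATES = 3
N_BEATS = 4

#: Conversion factor mg -> nmol for the test drug (molar mass ~450.9 g/mol).
MG_TO_NMOL = 2218.0

TEST_DRUG_TREATMENTS = ("therapeutic", "supratherapeutic")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PkSimParams:
    """One-compartment PK with first-order absorption.

    ``C(t) = (dose_nmol / v_over_f) * ka/(ka-ke) * (exp(-ke t) - exp(-ka t))``.

    Defaults reproduce the therapeutic-dose calibration targets:
    tmax = ln(ka/ke)/(ka-ke) ~ 1.5 h, Cmax(25 mg) ~ 768 nmol/L,
    AUC(25 mg) = dose_nmol/(v_over_f*ke) ~ 4850 nmol*h/L.
    Between-subject variability is log-normal on ka, ke and V/F.
    """

    ka: float = 1.5
    ke: float = 0.22
    v_over_f: float = 52.0
    mg_to_nmol: float = MG_TO_NMOL
    between_subject_cv: float = 0.20
    ka_cv: float = 0.35
    ke_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0 or self.v_over_f <= 0 or self.mg_to_nmol <= 0:
            raise ValueError("all PK parameters must be positive")
        if math.isclose(self.ka, self.ke):
            raise ValueError("ka == ke is not supported (degenerate flip-flop form)")


def pk_concentration(params: PkSimParams, dose_mg: float, times) -> np.ndarray:
    """Deterministic concentration-time curve (nmol/L); zero at and before t=0."""
    t = np.asarray(times, dtype=float)
    dose_nmol = dose_mg * params.mg_to_nmol
    scale = (dose_nmol / params.v_over_f) * params.ka / (params.ka - params.ke)
    conc = scale * (np.exp(-params.ke * t) - np.exp(-params.ka * t))
    conc = np.where(t <= 0, 0.0, conc)
    return np.maximum(conc, 0.0)


def subject_pk_params(params: PkSimParams, rng: np.random.Generator) -> PkSimParams:
    """Draw one subject's PK parameters with log-normal between-subject spread.

    V/F carries ``between_subject_cv`` (drives the Cmax/AUC geometric CV);
    absorption gets the wider ``ka_cv`` (drives the tmax range); elimination
    the narrow ``ke_cv``.
    """

    def _ln(cv: float) -> float:
        return rng.lognormal(0.0, math.sqrt(math.log(1 + cv**2)))

    ka = params.ka * _ln(params.ka_cv)
    ke = params.ke * _ln(params.ke_cv)
    v = params.v_over_f * _ln(params.between_subject_cv)
    if math.isclose(ka, ke):  # vanishing-probability guard
        ka *= 1.01
    return replace(params, ka=ka, ke=ke, v_over_f=v)


def simulate_pk_profile(
    params: PkSimParams, dose_mg: float, times, seed: int | np.random.Generator
) -> pd.DataFrame:
    """One subject's concentration-time profile with between-subject variability."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted strictly ascending")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = subject_pk_params(params, rng)
    return pd.DataFrame({"time_h": t, "conc_nmol_l": pk_concentration(p, dose_mg, t)})


def analytic_tmax(params: PkSimParams) -> float:
    """Closed-form time of peak concentration, ``ln(ka/ke)/(ka-ke)``."""
    return math.log(params.ka / params.ke) / (params.ka - params.ke)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the full-trial ECG/PK generator.

    Variance components (all in ms unless noted):

    * ``between_subject_sd_qt`` — spread of the subject QT intercepts.
    * ``within_subject_period_sd`` — random subject-by-period offset (shared by
      baseline and post-dose timepoints, so it cancels in change from
      baseline).
    * ``timepoint_sd`` — independent noise per scheduled timepoint; the
      dominant term of the endpoint variance.
    * ``triplicate_sd`` — per-ECG replicate offset.
    * ``beat_sd`` — per-beat QT noise; ``rr_beat_sd`` the per-beat RR noise.

    The implied endpoint SD (within-subject active-minus-placebo difference of
    the 1-4 h change from baseline) is available from
    :func:`implied_endpoint_sd`; defaults yield ~13.9 ms against the 14 ms
    target.
    """

    n_subjects: int = 30
    qt_intercept_ms: float = 400.0
    between_subject_sd_qt: float = 20.0
    within_subject_period_sd: float = 5.0
    timepoint_sd: float = 13.6
    triplicate_sd: float = 5.0
    beat_sd: float = 5.0
    rr_beat_sd: float = 15.0
    circadian_amplitude_ms: float = 2.0
    circadian_phase_h: float = 3.0
    conc_slope_ms_per_nmol: float = 0.0
    control_effect_ms: float = 12.0
    control_effect_window_h: tuple[float, float] = (0.5, 6.0)
    delta: float = 0.294
    delta_between_sd: float = 0.02
    hr_mean_bpm: float = 60.0
    hr_between_sd: float = 6.0
    hr_within_sd: float = 7.0
    pr_mean_ms: float = 160.0
    qrs_mean_ms: float = 95.0
    period_effects_ms: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    dropout_count: int = 3
    doses_mg: dict = field(
        default_factory=lambda: {"therapeutic": 25.0, "supratherapeutic": 200.0}
    )
    endpoint_sd_target: float = 14.0

    def __post_init__(self) -> None:
        sds = (
            self.between_subject_sd_qt,
            self.within_subject_period_sd,
            self.timepoint_sd,
            self.triplicate_sd,
            self.beat_sd,
            self.rr_beat_sd,
            self.hr_between_sd,
            self.hr_within_sd,
            self.delta_between_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be >= 0")
        if not 0 <= self.dropout_count < self.n_subjects:
            raise ValueError("dropout_count must be in [0, n_subjects)")


def implied_endpoint_sd(config: SimulationConfig) -> float:
    """Analytic SD of the within-subject (active - placebo) difference of the
    1-4 h change from baseline implied by the variance components.

    A timepoint value averages 3 replicates of 4 beats, so its variance is
    ``timepoint_sd^2 + triplicate_sd^2/3 + beat_sd^2/12``; the change from
    baseline averages 6 window timepoints and 3 baseline timepoints
    (variance factor 1/6 + 1/3 = 1/2), and the difference of two periods
    doubles it.  Subject and subject-by-period terms cancel.
    """
    tp_var = (
        config.timepoint_sd**2
        + config.triplicate_sd**2 / N_REPLICATES
        + config.beat_sd**2 / (N_REPLICATES * N_BEATS)
    )
    return math.sqrt(tp_var)


def _circadian(config: SimulationConfig, time_h: np.ndarray) -> np.ndarray:
    return config.circadian_amplitude_ms * np.sin(
        2.0 * np.pi * (time_h - config.circadian_phase_h) / 24.0
    )


def simulate_trial(
    config: SimulationConfig,
    pk: PkSimParams | None = None,
    seed: int = 0,
    design: CrossoverDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one full trial: beat-level ECG rows and PK concentration rows.

    Returns ``(ecg_table, pk_table)``.  The ECG table has one row per
    subject x period x timepoint x replicate x beat with columns
    ``subject_id, sex, sequence, period, treatment, time_h, replicate, beat,
    qt_ms, rr_ms, pr_ms, qrs_ms``.  PK rows cover test-drug periods only
    (pre-dose sample at -1 h with zero concentration).  Dropout removes all
    data from a sampled discontinuation period onwards; nothing is imputed.
    """
    pk = pk or PkSimParams()
    rng = np.random.default_rng(seed)
    if design is None:
        design = assign_placebo_symbols(generate_williams_design(5))
    if design.symbol_to_treatment is None:
        raise ConfigurationError("design must carry a symbol-to-treatment assignment")
    alloc = randomise(design, config.n_subjects, seed=int(rng.integers(2**31)))

    # dropout: subjects and their discontinuation periods
    dropout_ids = rng.choice(config.n_subjects, size=config.dropout_count, replace=False)
    disc_period = {
        int(i): int(rng.integers(2, design.n_periods + 1)) for i in dropout_ids
    }

    ecg_chunks = []
    pk_chunks = []
    for i in range(config.n_subjects):
        row = alloc.iloc[i]
        sid = row["subject_id"]
        sex = "M" if i % 2 == 0 else "F"
        intercept = config.qt_intercept_ms + rng.normal(0.0, config.between_subject_sd_qt)
        delta_i = config.delta + rng.normal(0.0, config.delta_between_sd)
        hr_i = config.hr_mean_bpm + rng.normal(0.0, config.hr_between_sd)
        pr_i = config.pr_mean_ms + rng.normal(0.0, 10.0)
        qrs_i = config.qrs_mean_ms + rng.normal(0.0, 5.0)
        treatments = design.treatments_for(int(row["sequence_index"]))
        last_period = disc_period.get(i, design.n_periods + 1)
        for p, trt in enumerate(treatments, start=1):
            if p >= last_period:
                break
            post = CONTROL_POST_DOSE_TIMES if trt == "control" else POST_DOSE_TIMES
            times = np.array(PRE_DOSE_TIMES + tuple(post))
            period_off = config.period_effects_ms[p - 1] + rng.normal(
                0.0, config.within_subject_period_sd
            )
            # treatment effect per timepoint
            effect = np.zeros_like(times)
            if trt in TEST_DRUG_TREATMENTS:
                p_i = subject_pk_params(pk, rng)
                conc = pk_concentration(p_i, config.doses_mg[trt], times)
                effect = config.conc_slope_ms_per_nmol * conc
                pk_times = np.concatenate([[-1.0], np.asarray(post)])
                pk_chunks.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "period": p,
                            "treatment": trt,
                            "time_h": pk_times,
                            "conc_nmol_l": pk_concentration(p_i, config.doses_mg[trt], pk_times),
                        }
                    )
                )
            elif trt == "control":
                lo, hi = config.control_effect_window_h
                effect = np.where(
                    (times >= lo) & (times <= hi), config.control_effect_ms, 0.0
                )
            circ = _circadian(config, times)
            eps_tp = rng.normal(0.0, config.timepoint_sd, size=times.size)
            hr_tp = hr_i + rng.normal(0.0, config.hr_within_sd, size=times.size)
            hr_tp = np.clip(hr_tp, 35.0, 130.0)
            rr_tp = 60000.0 / hr_tp
            n_tp = times.size
            n_rows = n_tp * N_REPLICATES * N_BEATS
            t_col = np.repeat(times, N_REPLICATES * N_BEATS)
            rep_col = np.tile(np.repeat(np.arange(1, N_REPLICATES + 1), N_BEATS), n_tp)
            beat_col = np.tile(np.arange(1, N_BEATS + 1), n_tp * N_REPLICATES)
            eps_rep = rng.normal(0.0, config.triplicate_sd, size=n_tp * N_REPLICATES)
            rr_beat = np.repeat(rr_tp, N_REPLICATES * N_BEATS) + rng.normal(
                0.0, config.rr_beat_sd, size=n_rows
            )
            rr_beat = np.maximum(rr_beat, 300.0)
            qt_beat = (
                intercept * (rr_beat / 1000.0) ** delta_i
                + np.repeat(circ + period_off + effect + eps_tp, N_REPLICATES * N_BEATS)
                + np.repeat(eps_rep, N_BEATS)
                + rng.normal(0.0, config.beat_sd, size=n_rows)
            )
            qt_beat = np.minimum(qt_beat, 0.9 * rr_beat)  # physiological guard
            ecg_chunks.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "sex": sex,
                        "sequence": row["sequence"],
                        "period": p,
                        "treatment": trt,
                        "time_h": t_col,
                        "replicate": rep_col,
                        "beat": beat_col,
                        "qt_ms": qt_beat,
                        "rr_ms": rr_beat,
                        "pr_ms": pr_i + rng.normal(0.0, 3.0, size=n_rows),
                        "qrs_ms": qrs_i + rng.normal(0.0, 2.0, size=n_rows),
                    }
                )
            )
    ecg = pd.concat(ecg_chunks, ignore_index=True)
    pk_table = (
        pd.concat(pk_chunks, ignore_index=True)
        if pk_chunks
        else pd.DataFrame(
            columns=["subject_id", "period", "treatment", "time_h", "conc_nmol_l"]
        )
    )
    return ecg, pk_table


def simulate_endpoint_level(
    n_completers: int,
    design_type: str = "double_placebo_5p",
    sigma2: float = 98.0,
    true_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Endpoint-level dataset: one change-from-baseline value per subject x period.

    ``sigma2`` is the per-period CfB variance; the default 98 makes the SD of
    (active - single placebo) equal sqrt(2*98) = 14 ms.  The double-placebo
    design emits two placebo rows per subject (``placebo_occasion`` 1 and 2).
    Subjects cycle through the design's Williams sequences, so period and
    sequence factors are estimable (and orthogonal to treatment when
    ``n_completers`` is a multiple of the sequence count).
    """
    if n_completers < 1:
        raise ValueError("n_completers must be positive")
    if design_type == "double_placebo_5p":
        d = assign_placebo_symbols(generate_williams_design(5))
    elif design_type == "single_placebo_4p":
        d = assign_placebo_symbols(generate_williams_design(4), n_placebo_symbols=1)
    else:
        raise ValueError(f"unknown design_type {design_type!r}")
    effects = {"therapeutic": 0.0, "supratherapeutic": 0.0, "control": 0.0}
    if true_effects:
        effects.update(true_effects)
    rng = np.random.default_rng(seed)
    sd = math.sqrt(sigma2)
    rows = []
    for i in range(n_completers):
        sid = f"S{i + 1:03d}"
        seq_idx = i % d.n_sequences
        occasion = 0
        for p, trt in enumerate(d.treatments_for(seq_idx), start=1):
            mean = 0.0 if trt == PLACEBO else effects[trt]
            occ = None
            if trt == PLACEBO:
                occasion += 1
                occ = occasion
            rows.append(
                {
                    "subject_id": sid,
                    "sequence": "".join(d.sequences[seq_idx]),
                    "period": p,
                    "treatment": trt,
                    "placebo_occasion": occ,
                    "cfb_ms": mean + rng.normal(0.0, sd),
                }
            )
    return pd.DataFrame(rows)
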