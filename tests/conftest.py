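import pytest

from tqtkit import analysis, ecg
from tqtkit.synthetic import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def trial():
    """One default synthetic trial (30 subjects, 3 dropouts, 12 ms control effect)."""
    return simulate_trial(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def timepoints(trial):
    ecg_df, _ = trial
    return ecg.average_triplicate(ecg.average_beats(ecg_df))


@pytest.fixture(scope="session")
def population_model(timepoints):
    return ecg.estimate_population_delta(ecg.drug_free_records(timepoints))


@pytest.fixture(scope="session")
def corrected(timepoints, population_model):
    tp = ecg.add_corrections(timepoints, [population_model])
    return tp.rename(columns={population_model.qtc_column_name(): "qtc_ms"})


@pytest.fixture(scope="session")
def baselines(corrected):
    return ecg.derive_baseline(corrected)


@pytest.fixture(scope="session")
def cfb_primary(corrected, baselines):
    return analysis.compute_cfb(corrected, baselines, scope="window_1_4h")


@pytest.fixture(scope="session")
def cfb_timepoint(corrected, baselines):
    return analysis.compute_cfb(corrected, baselines, scope="timepoint")
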