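import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulsetransit import SimulationConfig, analyze_recording, simulate_experiment
from pulsetransit.datasets import default_txa_cohort

settings.register_profile(
    "deterministic", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")


@pytest.fixture
def clean_config():
    """Noiseless, stationary, perfectly regular beat train."""
    return SimulationConfig(
        duration=12.0,
        heart_rate_mean=75.0,
        heart_rate_cv=0.0,
        baseline_sPAP=30.0,
        baseline_dPAP=15.0,
        target_sPAP=30.0,
        target_dPAP=15.0,
        pwtt_jitter_sd=0.0,
        pressure_jitter_sd=0.0,
        noise_sd=0.0,
        premature_prob=0.0,
        seed=7,
    )


@pytest.fixture
def clean_experiment(clean_config):
    return simulate_experiment(clean_config)


def nearest_truth_index(truth_times: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Index of the closest ground-truth beat for each estimated time."""
    return np.array([int(np.argmin(np.abs(truth_times - t))) for t in times])


@pytest.fixture(scope="session")
def txa_cohort_run():
    """The default six-animal drug-infusion cohort, fully analysed.

    Session-scoped: simulation plus analysis of ~2000 beats is shared by
    the recovery and exclusion-rule tests.
    """
    cohort = default_txa_cohort(seed=1)
    out = {}
    for animal, config in cohort.items():
        experiment = simulate_experiment(config)
        beat_table, pair_table, counts = analyze_recording(experiment.recording)
        out[animal] = {
            "config": config,
            "truth": experiment.truth,
            "beats": beat_table,
            "pairs": pair_table,
            "counts": counts,
        }
    return out
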