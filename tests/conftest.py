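import numpy as np
import pytest

from saccnoise.dynamics import PlantParameters, TimeGrid
from saccnoise.profiles import MainSequenceModel
from saccnoise.stats import detect_matrix
from saccnoise.synth import TrialEnsemble


@pytest.fixture(scope="session")
def plant() -> PlantParameters:
    return PlantParameters()


@pytest.fixture(scope="session")
def ms() -> MainSequenceModel:
    return MainSequenceModel()


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid.for_duration(0.080, 5e-4)


def ensemble_from_positions(
    Y: np.ndarray,
    rate: float = 1000.0,
    motor_errors: np.ndarray | None = None,
    planned: np.ndarray | None = None,
) -> TrialEnsemble:
    """Build an ensemble directly from a (n_trials, T) position matrix."""
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    det = detect_matrix(Y, rate=rate)
    return TrialEnsemble(
        time=np.arange(Y.shape[1]) / rate,
        positions=Y,
        motor_errors=np.full(n, 10.0) if motor_errors is None else np.asarray(motor_errors, float),
        planned_amplitudes=np.full(n, np.nan) if planned is None else np.asarray(planned, float),
        onsets=det["onset"],
        offsets=det["offset"],
        onset_times=det["onset_time"],
        offset_times=det["offset_time"],
        amplitudes=det["amplitude"],
        durations=det["duration"],
        peak_velocities=det["peak_velocity"],
        peak_indices=det["peak_index"],
    )
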