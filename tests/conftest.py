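import numpy as np
import pytest

from gastropk.ivivc import DEFAULT_FREE_PARAMETERS, calibrate, nca_metrics, predict
from gastropk.synth import default_study, generate_plasma

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """The standard synthetic study: ground-truth physiology + release triplet."""
    return default_study(STUDY_SEED)


@pytest.fixture(scope="session")
def truth(study):
    return study.ground_truth_physiology


@pytest.fixture(scope="session")
def medium_calibration(study, truth):
    """Calibration of the 4 default free parameters on the noisy 'medium' curve.

    Session-scoped because this is the expensive step of the
    calibrate-once-predict-twice workflow; several tests interrogate it.
    """
    dataset = generate_plasma(study, "medium")
    return calibrate(dataset, truth, list(DEFAULT_FREE_PARAMETERS))


@pytest.fixture(scope="session")
def triplet_predictions(study, medium_calibration):
    """Zero-refit predictions for all three formulations plus observed NCA."""
    t_grid = np.linspace(0.0, 24.0, 193)
    out = {}
    for label in ("fast", "medium", "slow"):
        observed = generate_plasma(study, label)
        traj, metrics = predict(medium_calibration, study.dose_event(label), t_grid)
        obs_metrics = nca_metrics(
            observed.times, observed.concentrations, extrapolate=True
        )
        out[label] = {
            "trajectory": traj,
            "predicted": metrics,
            "observed": obs_metrics,
            "dataset": observed,
        }
    return out
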