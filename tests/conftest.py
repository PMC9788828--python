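import numpy as np
import pandas as pd
import pytest

from killicog import synthetic as syn
from killicog.trackio import PoseTrack


def make_track(coords: dict, fps: float = 20.0, fish_id: str = "f1", trial: int = 1,
               likelihood: dict | None = None) -> PoseTrack:
    """Build a PoseTrack from {keypoint: (x_array, y_array)} test data."""
    data = {}
    n = None
    for kp, (x, y) in coords.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        n = len(x)
        lik = np.ones(n) if likelihood is None or kp not in likelihood else np.asarray(
            likelihood[kp], float
        )
        data[(kp, "x")] = x
        data[(kp, "y")] = y
        data[(kp, "likelihood")] = lik
    df = pd.DataFrame(data, index=pd.RangeIndex(n))
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return PoseTrack(data=df, fish_id=fish_id, trial_number=trial, fps=fps)


@pytest.fixture(scope="session")
def small_session():
    """A 3-fish synthetic conditioning session with ground truth."""
    cfg = syn.TrackSimConfig(n_fish=3, seed=11)
    return syn.simulate_tracks(cfg)


@pytest.fixture(scope="session")
def clean_session():
    """Artifact-free session: no noise, no dropouts, no teleports."""
    cfg = syn.TrackSimConfig(n_fish=2, noise_sd=0.0, dropout_p=0.0, teleport_p=0.0, seed=7)
    return syn.simulate_tracks(cfg)
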