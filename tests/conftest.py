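import numpy as np
import pandas as pd
import pytest

from sealhab import envstack, pipeline, synth
from sealhab.synth import ArgosNoiseSpec, SyntheticWorldConfig, TruthModel


@pytest.fixture(scope="session")
def small_config():
    return SyntheticWorldConfig(nlat=40, nlon=40, n_days=25, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_config):
    """Small derived stack shared across tests (25 days, 40x40 cells)."""
    return envstack.add_derived_layers(synth.generate_env_stack(small_config))


@pytest.fixture(scope="session")
def truth():
    return TruthModel(beta=5.0)


@pytest.fixture(scope="session")
def noise_low():
    return ArgosNoiseSpec().scaled(0.5)


@pytest.fixture(scope="session")
def tracks(small_stack, truth, noise_low):
    obs, true_paths, dives = synth.generate_tracks(
        small_stack, truth, 3, noise=noise_low, seed=7, duration_range_days=(15, 22), n_dive_tagged=2
    )
    return obs, true_paths, dives


@pytest.fixture(scope="session")
def reg_tracks(tracks, noise_low):
    obs, _, _ = tracks
    return pipeline.preprocess_tracks(obs, noise_low)


def make_track(times_s, lons, lats, iid="s1", cls="3"):
    """Helper: build a track frame from raw arrays (times in seconds)."""
    t0 = pd.Timestamp("2019-03-01")
    return pd.DataFrame(
        {
            "individual_id": iid,
            "timestamp": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
            "lon": np.asarray(lons, float),
            "lat": np.asarray(lats, float),
            "location_class": cls,
        }
    )
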