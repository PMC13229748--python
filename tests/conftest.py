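import numpy as np
import pytest

from respcam.synthetic import default_scene, generate_channel_bundle, render_frames


@pytest.fixture(scope="session")
def clean_scene():
    """Short noiseless, drift-free, artifact-free recording."""
    return default_scene(rr_bpm=15.0, duration_s=20.0, noise_sd=0.0, drift_amp=0.0,
                         artifact_rate_per_min=0.0, rr_variability=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_frames(clean_scene):
    return render_frames(clean_scene)


@pytest.fixture(scope="session")
def clean_bundle(clean_scene):
    return generate_channel_bundle(clean_scene)


@pytest.fixture(scope="session")
def default_bundle():
    scene = default_scene(rr_bpm=15.0, seed=0)
    return scene, generate_channel_bundle(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
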