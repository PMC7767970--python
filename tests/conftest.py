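import numpy as np
import pytest

from oscimap import preprocess, synthetic


@pytest.fixture
def one_cluster_scene():
    """Noiseless single-cluster scene: 5 Hz, 10 mV pp, 48x48 @ 40 fps."""
    return synthetic.SceneConfig(
        frame_size=(48, 48), frame_rate=40.0, duration_s=5.0,
        clusters=(synthetic.ClusterSpec(center=(24, 24), frequency_hz=5.0,
                                        amplitude_mv=10.0),),
        noise_sd=0.0, seed=0)


@pytest.fixture
def one_cluster_fixture(one_cluster_scene):
    return synthetic.generate_sto_movie(one_cluster_scene)


@pytest.fixture
def noisy_fixture():
    """Default-noise two-cluster scene used across pipeline tests."""
    scene = synthetic.random_scene(seed=42, n_clusters=2)
    return synthetic.generate_sto_movie(scene)


def make_movie(data, frame_rate=40.0, pitch=17.86, origin="raw"):
    return preprocess.Movie(np.asarray(data, dtype=float), frame_rate, pitch,
                            origin)
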