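import numpy as np
import pytest

from hystnet import (
    BandSpec,
    EEGRecording,
    SynthConnectomeSpec,
    WindowPlan,
    synth_connectome,
)


@pytest.fixture(scope="session")
def rate():
    return 250.0


@pytest.fixture()
def toy_recording(rate):
    """Four deterministic channels, 260 s, with all four state epochs."""
    rng = np.random.default_rng(7)
    n = int(260 * rate)
    t = np.arange(n) / rate
    data = np.vstack(
        [
            np.cos(2 * np.pi * 10 * t),
            np.cos(2 * np.pi * 10 * t - np.pi / 3) + 0.05 * rng.standard_normal(n),
            np.cos(2 * np.pi * 6 * t + 1.0),
            rng.standard_normal(n),
        ]
    )
    sec = int(rate)
    epochs = {
        "baseline": (0, 65 * sec),
        "induction": (65 * sec, 130 * sec),
        "unconscious": (130 * sec, 195 * sec),
        "emergence": (195 * sec, 260 * sec),
    }
    return EEGRecording(data, rate, ["F1", "F2", "P1", "P2"], epochs)


@pytest.fixture(scope="session")
def small_plan():
    return WindowPlan(epoch_len=60.0, win_len=10.0)


@pytest.fixture(scope="session")
def alpha_band():
    return BandSpec(9.0, 11.0, "alpha")


@pytest.fixture(scope="session")
def small_connectome():
    """12-node connected spatial graph, cheap enough for every model test."""
    return synth_connectome(
        SynthConnectomeSpec(n_nodes=12, target_mean_degree=4.0, extent=80.0, seed=3)
    )


@pytest.fixture(scope="session")
def default_connectome():
    """The 78-node study connectome."""
    return synth_connectome(SynthConnectomeSpec(seed=1))
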