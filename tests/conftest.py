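import numpy as np
import pytest

from gaitfreeze.signal_io import CHANNELS, GaitRecording, LabeledDataset
from gaitfreeze.synthetic_data import SyntheticConfig, make_dataset


@pytest.fixture()
def tiny_recording() -> GaitRecording:
    """Three-row, nine-channel recording with one of each annotation."""
    rng = np.random.default_rng(0)
    return GaitRecording(
        subject_id="tiny",
        timestamps=np.array([0, 15, 31]),
        samples=rng.normal(size=(3, 9)),
        annotations=np.array([0, 1, 2]),
    )


@pytest.fixture()
def recording_file(tmp_path, tiny_recording):
    from gaitfreeze.signal_io import write_daphnet

    path = tmp_path / "tiny.txt"
    write_daphnet(tiny_recording, path)
    return path


def make_separable_dataset(
    n: int = 64, length: int = 128, channels: int = 2, gap: float = 1.0, seed: int = 0
) -> LabeledDataset:
    """Two well-separated Gaussian sequence clusters, half per class."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(0.0, 0.3, (n, length, channels)) + gap * y[:, None, None]
    return LabeledDataset(X=x, y=y, channel_ids=CHANNELS[:channels])


@pytest.fixture(scope="session")
def default_synthetic():
    """One standard-conditions synthetic dataset, shared across tests."""
    return make_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def clean_synthetic():
    """Fully-expressed, low-noise dataset (every episode on every channel)."""
    return make_dataset(SyntheticConfig(seed=11, channel_expression=1.0, noise_sd=0.05))
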