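import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record():
    """3-channel, 2-second record at 256 Hz with one seizure annotation."""
    from seizurekit.records import Annotation, EEGRecord

    t = np.arange(512) / 256.0
    data = np.vstack(
        [
            np.sin(2 * np.pi * 10 * t),
            np.cos(2 * np.pi * 10 * t),
            np.sin(2 * np.pi * 25 * t),
        ]
    )
    return EEGRecord(
        data=data,
        fs=256.0,
        channel_labels=["FP1-F7", "F7-T7", "T7-P7"],
        record_id="fixture-0",
        annotations=[Annotation(1.0, 2.0, "seizure")],
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Spectrally well-separated two-class synthetic windows (single channel,
    one-second at 256 Hz): strong gamma + spike-wave in the seizure class,
    modest broadband noise."""
    from seizurekit.synthetic import SeizureParams, SyntheticSpec, generate_dataset

    spec = SyntheticSpec(
        n_records=300,
        n_channels=1,
        n_samples=256,
        fs=256.0,
        seizure_fraction=0.5,
        seizure_params=SeizureParams(gamma_amp=2.0, burst_amp=3.0),
        noise_sd=0.3,
        seed=7,
    )
    return generate_dataset(spec)
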