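import numpy as np
import pytest

from eegroute.synth import CohortSpec, RawRecording, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects, 12 s, 16 channels — fast enough for unit tests."""
    spec = CohortSpec(n_subjects_per_class=2, duration=12.0, sfreq=250.0,
                      n_channels=16, effect={"delta": 2.0}, seed=42)
    return generate_cohort(spec)


@pytest.fixture()
def sine_recording():
    """Deterministic multi-sine recording for filter oracles (8 ch, 10 s)."""
    sfreq = 250.0
    t = np.arange(int(10 * sfreq)) / sfreq
    data = np.zeros((8, t.size))
    for c in range(8):
        data[c] = 20 * np.sin(2 * np.pi * 10 * t + 0.3 * c)
    return RawRecording(subject_id="s1", label=0, data=data, sfreq=sfreq,
                        channel_names=[f"E{i}" for i in range(8)])


def make_recording(data, sfreq=250.0, label=0, subject_id="s1"):
    return RawRecording(subject_id=subject_id, label=label,
                        data=np.asarray(data, dtype=float), sfreq=sfreq,
                        channel_names=[f"E{i}" for i in range(len(data))])
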