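import numpy as np
import pytest

from humscan.soae import CalibratedRecording
from humscan.stimulus import P_REF, load_stimulus_table
from humscan.synth import SyntheticRecordingSpec, generate_recording


@pytest.fixture(scope="session")
def stimulus_table():
    return load_stimulus_table()


def tone(frequency, level_db_spl, duration_s, fs):
    """Plain sinusoid at a given dB SPL (pascals)."""
    t = np.arange(int(round(duration_s * fs))) / fs
    amplitude = np.sqrt(2.0) * P_REF * 10 ** (level_db_spl / 20.0)
    return amplitude * np.sin(2 * np.pi * frequency * t)


@pytest.fixture(scope="session")
def dual_mic_fixture():
    """Standard synthetic dual-microphone recording: one 2-kHz emission at
    0 dB SPL over a -20 dB SPL/bin floor, half the noise power coherent."""
    spec = SyntheticRecordingSpec(
        duration=60.0,
        sampling_rate=10000.0,
        soaes=[(2000.0, 0.0, 2.0, 10.0)],
        noise_floor_level_at_1khz=-20.0,
        noise_slope=-10.0,
        coherent_fraction=0.5,
        ear="left",
        seed=202,
    )
    rec, truth = generate_recording(spec)
    return spec, rec, truth


@pytest.fixture()
def silent_tone_recording():
    """120 s of a pure 1 kHz tone at 10 dB SPL, no noise."""
    fs = 10000
    return CalibratedRecording(
        samples=tone(1000.0, 10.0, 120.0, fs), sampling_rate=fs, ear="left"
    )
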