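import logging

import numpy as np
import pandas as pd
import pytest

from emgspeech import EMGRecording, SimConfig, simulate_participant

logging.getLogger("emgspeech").setLevel(logging.ERROR)

FS = 2148.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(values, fs=FS, muscle="DAO", participant="A01", group="A"):
    return EMGRecording(participant, group, muscle, fs, np.asarray(values, float))


@pytest.fixture
def tone_recording():
    """1-s unit 10 Hz sinusoid."""
    t = np.arange(int(FS)) / FS
    return make_recording(np.sin(2 * np.pi * 10 * t))


@pytest.fixture
def tiny_config():
    """Smallest useful simulated study: 2+2 participants, one short context."""
    return SimConfig(n_group_a=2, n_group_b=2, contexts=("reading",),
                     session_s=15.0, disfluency_rate_a=8.0,
                     disfluency_rate_b=12.0, seed=7)


@pytest.fixture
def tiny_participant(tiny_config):
    return simulate_participant(tiny_config, 2)  # first group-B participant


def synthetic_feature_table(rng, n_a=20, n_b=30, segs_fluent=10, segs_disfluent=5,
                            amp_shift=None, band_shift=None):
    """Segment-level feature table with known group structure, no signals.

    ``amp_shift``/``band_shift`` map (group, muscle, label) to a
    multiplicative factor on the respective metric.
    """
    from emgspeech import MUSCLES, CONTEXTS, DISFLUENCY_TYPES

    amp_shift = amp_shift or {}
    band_shift = band_shift or {}
    rows = []
    for group, n in (("A", n_a), ("B", n_b)):
        for i in range(n):
            pid = f"{group}{i:02d}"
            subject = np.exp(0.3 * rng.standard_normal())
            floor = np.exp(0.3 * rng.standard_normal())
            for muscle in MUSCLES:
                for label, k in (("fluent", segs_fluent), ("disfluent", segs_disfluent)):
                    fa = amp_shift.get((group, muscle, label), 1.0)
                    fb = band_shift.get((group, muscle, label), 1.0)
                    for j in range(k):
                        amp = subject * fa * (1 + 0.25 * rng.standard_normal())
                        band = floor * fb * (1 + 0.25 * rng.standard_normal())
                        rows.append({
                            "participant": pid, "group": group, "muscle": muscle,
                            "start_s": float(j), "label": label,
                            "dtype": (DISFLUENCY_TYPES[j % 3]
                                      if label == "disfluent" else None),
                            "context": CONTEXTS[j % 2],
                            "iemg": abs(amp), "mean_amp": abs(amp),
                            "rms": abs(amp), "band_power": abs(band),
                            "total_power": 100.0, "band_fraction": abs(band),
                        })
    return pd.DataFrame(rows)
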