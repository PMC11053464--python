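"""Ground-truthed synthetic studies: determinism, rates, spectra, files."""

import json

import numpy as np
import pytest
from scipy import stats as sst

from emgspeech import (
    SimConfig,
    StudyManifest,
    features_for_participant,
    preprocess,
    read_annotations,
    read_recording,
    simulate_events,
    simulate_participant,
    simulate_study,
)
from emgspeech.features import compute_spectrum


def test_same_seed_gives_bit_identical_signals(tiny_config):
    a = simulate_participant(tiny_config, 1)
    b = simulate_participant(tiny_config, 1)
    for m in a.recordings:
        assert np.array_equal(a.recordings[m].values, b.recordings[m].values)
    assert a.events == b.events


def test_different_channels_and_participants_differ(tiny_config):
    p = simulate_participant(tiny_config, 0)
    q = simulate_participant(tiny_config, 1)
    assert not np.allclose(p.recordings["DAO"].values, p.recordings["OO"].values)
    assert not np.allclose(p.recordings["DAO"].values, q.recordings["DAO"].values)


def test_zero_rate_yields_no_events():
    cfg = SimConfig(disfluency_rate_a=0.0, contexts=("reading",), session_s=30.0)
    assert simulate_events(cfg, 0, "A") == []


def test_event_counts_follow_the_rate():
    # 2 events/min over 10 minutes: mean 20; check the mean over seeds and
    # that every count stays within wide Poisson bounds
    counts = []
    for seed in range(40):
        cfg = SimConfig(contexts=("reading",), session_s=600.0,
                        disfluency_rate_b=2.0, seed=seed)
        counts.append(len(simulate_events(cfg, 40, "B")))
    lo, hi = sst.poisson.ppf([0.005, 0.995], 20)
    assert lo <= np.mean(counts) <= hi
    assert min(counts) >= sst.poisson.ppf(1e-5, 20)


def test_events_stay_inside_their_context_block():
    cfg = SimConfig(contexts=("reading", "call"), session_s=25.0,
                    disfluency_rate_b=20.0, seed=3)
    blocks = {c: (a, b) for a, b, c in cfg.context_blocks}
    events = simulate_events(cfg, 50, "B")
    assert events, "expected events at this rate"
    for e in events:
        a, b = blocks[e.context]
        assert a <= e.onset_s < e.offset_s <= b


def test_event_durations_respect_type_ranges():
    cfg = SimConfig(contexts=("reading",), session_s=600.0,
                    disfluency_rate_b=20.0, seed=5)
    events = simulate_events(cfg, 41, "B")
    for e in events:
        dur = e.offset_s - e.onset_s
        if e.dtype == "block":
            assert dur <= 2.0 + 1e-9
        else:
            assert dur <= 1.5 + 1e-9


def test_band_fraction_floor_is_small_without_injection():
    cfg = SimConfig(n_group_a=1, n_group_b=1, contexts=("reading",),
                    session_s=15.0, tremor_floor=0.0, mains_amp=0.0, seed=2)
    df = features_for_participant(simulate_participant(cfg, 0))
    assert df.band_fraction.mean() < 3.0  # band-shaped-noise floor


def test_mains_peak_removed_by_notch(tiny_config):
    import dataclasses
    cfg = dataclasses.replace(tiny_config, mains_amp=0.05)
    rec = simulate_participant(cfg, 0).recordings["DAO"]
    def power_at_60(values):
        spec = compute_spectrum(values[:int(cfg.fs) * 10], cfg.fs)
        sel = np.abs(spec.freqs - 60.0) <= 1.0
        return spec.psd[sel].sum()
    before = power_at_60(rec.values)
    after = power_at_60(preprocess(rec, "notch_only").values)
    assert after < 0.1 * before


def test_signals_respect_acquisition_range(tiny_config):
    p = simulate_participant(tiny_config, 3)
    for rec in p.recordings.values():
        assert np.max(np.abs(rec.values)) <= 11.0


def test_band_fraction_monotone_in_tremor_gain():
    fracs = []
    for gain in (0.0, 0.01, 0.03):
        cfg = SimConfig(n_group_a=0, n_group_b=2, contexts=("reading",),
                        session_s=15.0,
                        tremor_gain={("B", "ZM", "fluent"): gain,
                                     ("B", "ZM", "disfluent"): gain},
                        seed=6)
        df = features_for_participant(simulate_participant(cfg, 0))
        fracs.append(df[df.muscle == "ZM"].band_fraction.mean())
    assert fracs[0] < fracs[1] < fracs[2]


def test_amplitude_effect_scales_disfluent_windows():
    base = dict(n_group_a=0, n_group_b=3, contexts=("reading",), session_s=20.0,
                disfluency_rate_b=12.0, seed=8)
    df0 = features_for_participant(simulate_participant(SimConfig(**base), 0))
    cfg = SimConfig(**base, amp_effect={("B", "DAO", "disfluent"): 0.4})
    df1 = features_for_participant(simulate_participant(cfg, 0))
    d0 = df0[(df0.muscle == "DAO") & (df0.label == "disfluent")].mean_amp.mean()
    d1 = df1[(df1.muscle == "DAO") & (df1.label == "disfluent")].mean_amp.mean()
    f0 = df0[(df0.muscle == "DAO") & (df0.label == "fluent")].mean_amp.mean()
    f1 = df1[(df1.muscle == "DAO") & (df1.label == "fluent")].mean_amp.mean()
    assert d1 < 0.8 * d0          # disfluent windows suppressed
    assert abs(f1 - f0) / f0 < 0.1  # fluent windows untouched


# --- study on disk -------------------------------------------------------


def test_study_emission_and_roundtrip(tmp_path, tiny_config):
    study = simulate_study(tiny_config, tmp_path / "study")
    manifest = StudyManifest.from_json(tmp_path / "study" / "manifest.json")
    manifest.validate(tmp_path / "study")
    assert len(manifest.participants) == 4
    entry = manifest.participants[0]
    assert set(entry["signals"]) == {"DAO", "OO", "M", "S", "ZM"}

    part = simulate_participant(tiny_config, 0)
    rec = read_recording(tmp_path / "study" / entry["signals"]["ZM"],
                         participant_id=entry["participant_id"],
                         group=entry["group"], muscle="ZM", fs=manifest.fs)
    assert np.allclose(rec.values, part.recordings["ZM"].values, atol=1e-9)
    events = read_annotations(tmp_path / "study" / entry["annotations"])
    assert len(events) == len(part.events)
    for got, want in zip(events, part.events):
        assert got.onset_s == pytest.approx(want.onset_s, abs=1e-9)
        assert got.offset_s == pytest.approx(want.offset_s, abs=1e-9)
        assert (got.dtype, got.context) == (want.dtype, want.context)

    truth = json.loads((tmp_path / "study" / "ground_truth.json").read_text())
    assert truth["events"][entry["participant_id"]] == [
        [e.onset_s, e.offset_s, e.dtype, e.context] for e in part.events]


def test_control_channel_spikes_at_onsets(tmp_path, tiny_config):
    simulate_study(tiny_config, tmp_path / "study")
    manifest = StudyManifest.from_json(tmp_path / "study" / "manifest.json")
    for entry in manifest.participants:
        events = read_annotations(tmp_path / "study" / entry["annotations"])
        if events:
            break
    from emgspeech.signal_io import read_signal
    control = read_signal(tmp_path / "study" / entry["control"])
    fs = manifest.fs
    for e in events:
        i = int(np.floor(e.onset_s * fs))
        assert control[i] == 5.0
    assert (control > 0).sum() <= len(events) * int(round(0.01 * fs)) + len(events)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(fs=500.0)
    with pytest.raises(ValueError):
        SimConfig(dtype_mix={"repetition": 0.7, "prolongation": 0.2, "block": 0.2})
    with pytest.raises(ValueError):
        SimConfig(tremor_mode="fm")
    with pytest.raises(ValueError):
        SimConfig(disfluency_rate_a=-1.0)
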