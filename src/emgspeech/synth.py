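"""Synthetic multi-muscle EMG studies with known ground truth.

Each simulated participant produces one shared time base covering the four
session phases (spontaneous personal-data speech, reading, phone call,
exposition) and five simultaneously recorded muscle channels plus a control
channel that spikes at each disfluency onset.

Signal model per channel:

* carrier: Gaussian noise band-shaped to the mid EMG band (unit RMS), a
  standard surrogate for surface EMG interference patterns; its low edge is
  kept steep and above the tremor band so the carrier contributes no 5-15 Hz
  power of its own;
* speech envelope: a tonic level plus Poisson-arriving Hann-shaped bursts,
  shared in shape across conditions;
* condition scaling: the envelope is multiplied by the participant's
  baseline amplitude, a log-normal between-participant factor, and a
  per-(group, muscle, condition) effect factor ramped smoothly at event
  boundaries — the dials the recovery tests turn;
* tremor: a narrowband 5-15 Hz stochastic oscillation scaled like the
  signal.  Every channel carries a participant-specific physiological
  tremor floor; group effects add gain on top of it in the targeted
  (group, muscle, condition) cells.  Because both tremor and carrier ride
  the same amplitude envelope, a pure amplitude effect moves band power and
  total power together and leaves the band fraction unchanged.  An "am"
  mode instead modulates the carrier envelope, moving the oscillation into
  the envelope spectrum only;
* mains: 60 Hz plus harmonics with 1/k amplitude roll-off and random phases;
* the sum is clipped to the +-11 mV acquisition range.

Everything is reproducible from a single integer seed via independent
`numpy` seed sequences per participant and channel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .signal_io import (
    CONTEXTS,
    MUSCLES,
    EMGRecording,
    EventAnnotation,
    StudyManifest,
    write_annotations,
    write_recording,
    write_signal,
)

__all__ = [
    "SimConfig",
    "SimStudy",
    "ParticipantData",
    "simulate_events",
    "simulate_recording",
    "simulate_participant",
    "iter_participants",
    "simulate_study",
]

#: Event-duration ranges in seconds, uniform within each range.
DTYPE_DURATION_S = {
    "repetition": (0.2, 1.5),
    "prolongation": (0.2, 1.5),
    "block": (0.3, 2.0),
}

_CARRIER_BAND_HZ = (35.0, 450.0)
_TREMOR_BAND_HZ = (5.0, 15.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings.

    Amplitudes are mV; rates are per second (bursts) or per minute
    (disfluencies).  ``amp_effect`` and ``tremor_gain`` map
    ``(group, muscle, condition)`` to a multiplicative amplitude factor and
    a tremor gain relative to the carrier RMS respectively; unlisted cells
    default to factor 1 and gain 0.
    """

    n_group_a: int = 30
    n_group_b: int = 55
    fs: float = 2148.0
    contexts: tuple[str, ...] = CONTEXTS
    session_s: float = 60.0  # per context block
    baseline_amp: Mapping[str, float] = field(
        default_factory=lambda: {m: 0.05 for m in MUSCLES})
    subject_sigma: float = 0.4  # log-normal spread of participant baselines
    tremor_floor: float = 0.022  # median physiological tremor gain, all channels
    tremor_floor_sigma: float = 0.2  # log-normal spread of the tremor floor
    tonic_level: float = 0.4
    burst_rate: float = 2.0  # speech bursts per second
    burst_duration_s: tuple[float, float] = (0.15, 0.45)
    disfluency_rate_a: float = 1.0  # events per minute, non-stuttering group
    disfluency_rate_b: float = 8.0  # events per minute, stuttering group
    dtype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"repetition": 0.5, "prolongation": 0.25, "block": 0.25})
    amp_effect: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    tremor_gain: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    tremor_mode: str = "additive"  # or "am"
    mains_amp: float = 0.01
    mains_hz: float = 60.0
    mains_rolloff: float = 1.0  # harmonic k amplitude scales as k**-rolloff
    clip_mv: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 900:
            raise ValueError("fs must exceed 900 Hz (Nyquist above the EMG band)")
        if abs(sum(self.dtype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("dtype_mix probabilities must sum to 1")
        if self.tremor_mode not in ("additive", "am"):
            raise ValueError("tremor_mode must be 'additive' or 'am'")
        for name in ("session_s", "burst_rate", "disfluency_rate_a",
                     "disfluency_rate_b", "mains_amp", "subject_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def context_blocks(self) -> list[tuple[float, float, str]]:
        return [(i * self.session_s, (i + 1) * self.session_s, c)
                for i, c in enumerate(self.contexts)]

    @property
    def total_duration_s(self) -> float:
        return self.session_s * len(self.contexts)

    def participant_ids(self) -> list[tuple[str, str]]:
        ids = [(f"A{i + 1:02d}", "A") for i in range(self.n_group_a)]
        ids += [(f"B{i + 1:02d}", "B") for i in range(self.n_group_b)]
        return ids


@dataclass
class ParticipantData:
    """In-memory bundle for one participant: five channels, shared events."""

    participant_id: str
    group: str
    recordings: dict[str, EMGRecording]
    events: list[EventAnnotation]
    context_blocks: list[tuple[float, float, str]]
    control: np.ndarray | None = None


@dataclass
class SimStudy:
    manifest: StudyManifest
    ground_truth: dict
    out_dir: Path


# ---------------------------------------------------------------------------
# random streams


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *key]))


_EVENT_STREAM = 0x5E
_SCALE_STREAM = 0x5C


# ---------------------------------------------------------------------------
# events


def simulate_events(config: SimConfig, participant_index: int, group: str
                    ) -> list[EventAnnotation]:
    """Disfluency annotations from a homogeneous rate process per context."""
    rate_per_min = config.disfluency_rate_a if group == "A" else config.disfluency_rate_b
    rng = _rng(config, participant_index, _EVENT_STREAM)
    dtypes = list(config.dtype_mix)
    probs = np.array([config.dtype_mix[d] for d in dtypes])
    events: list[EventAnnotation] = []
    for start, end, context in config.context_blocks:
        block_s = end - start
        count = rng.poisson(rate_per_min * block_s / 60.0)
        for _ in range(count):
            dtype = dtypes[rng.choice(len(dtypes), p=probs)]
            lo, hi = DTYPE_DURATION_S[dtype]
            dur = rng.uniform(lo, hi)
            onset = rng.uniform(start, max(start, end - dur))
            offset = min(onset + dur, end - 1e-3)
            if offset - onset < 0.05:
                continue  # degenerate sliver at the block edge
            events.append(EventAnnotation(onset, offset, dtype, context))
    return sorted(events, key=lambda e: (e.onset_s, e.offset_s))


# ---------------------------------------------------------------------------
# signals


@lru_cache(maxsize=16)
def _band_response(n: int, fs: float, lo: float, hi: float, trans: float
                   ) -> np.ndarray:
    """Band-pass amplitude response with raised-cosine transitions."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    hi = min(hi, 0.99 * fs / 2)
    H = np.zeros_like(freqs)
    H[(freqs >= lo) & (freqs <= hi)] = 1.0
    rise = (freqs > lo - trans) & (freqs < lo)
    H[rise] = 0.5 * (1 + np.cos(np.pi * (freqs[rise] - lo) / trans))
    fall = (freqs > hi) & (freqs < hi + trans)
    H[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - hi) / trans))
    return H


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], trans: float = 2.0) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``.

    Synthesized in the frequency domain: independent complex-Gaussian
    spectral amplitudes shaped by a band-pass response with raised-cosine
    transition edges of width ``trans`` Hz.  The steep edges keep each
    component strictly inside its band, so the EMG carrier contributes no
    power of its own to the 5-15 Hz tremor band.
    """
    from scipy.fft import irfft, next_fast_len

    nfft = next_fast_len(n)
    H = _band_response(nfft, fs, *band, trans)
    spec = (rng.standard_normal(H.size) + 1j * rng.standard_normal(H.size)) * H
    x = irfft(spec, nfft)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _carrier_noise(rng: np.random.Generator, n: int, fs: float,
                   band: tuple[float, float]) -> np.ndarray:
    return _band_noise(rng, n, fs, band, trans=5.0)


def _tremor_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 5-15 Hz narrowband noise, synthesized at a low rate.

    The oscillation has no content above ~17 Hz, so it is generated on a
    128 Hz grid and linearly interpolated to the acquisition rate.
    """
    coarse_fs = 128.0
    if fs <= 2 * coarse_fs:
        return _band_noise(rng, n, fs, _TREMOR_BAND_HZ)
    m = int(math.ceil(n / fs * coarse_fs)) + 2
    y = _band_noise(rng, m, coarse_fs, _TREMOR_BAND_HZ)
    x = np.interp(np.arange(n) / fs, np.arange(m) / coarse_fs, y)
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    """Speech-activity envelope on the full sample grid (tonic + bursts).

    The burst process is shared across conditions: a disfluency changes the
    channel only through the injected amplitude factor or tremor gain, so
    that with no injected effect every comparison is exactly null, in
    amplitude and in spectral composition alike.
    """
    coarse_fs = 100.0
    duration = n / config.fs
    nc = int(math.ceil(duration * coarse_fs)) + 1
    env = np.full(nc, config.tonic_level)
    n_bursts = rng.poisson(config.burst_rate * duration)
    for _ in range(n_bursts):
        dur = rng.uniform(*config.burst_duration_s)
        center = rng.uniform(0.0, duration)
        amp = rng.uniform(0.5, 1.0)
        w = max(3, int(round(dur * coarse_fs)))
        i0 = int(round(center * coarse_fs - w / 2))
        bump = amp * np.hanning(w)
        a, b = max(0, i0), min(nc, i0 + w)
        if b > a:
            env[a:b] += bump[a - i0:b - i0]
    t = np.arange(n) / config.fs
    return np.interp(t, np.arange(nc) / coarse_fs, env)


#: Ramp length for condition transitions (seconds).  Muscle activation does
#: not switch instantaneously at a labelled event boundary; a hard gate would
#: also act as a square-wave modulator whose sidebands bleed carrier power
#: into the 5-15 Hz analysis band.
CONDITION_RAMP_S = 0.35


def _event_activation(config: SimConfig, n: int,
                      events: Sequence[EventAnnotation]) -> np.ndarray:
    """Smooth 0..1 disfluency activation on the full sample grid."""
    coarse_fs = 100.0
    duration = n / config.fs
    nc = int(math.ceil(duration * coarse_fs)) + 1
    act = np.zeros(nc)
    for e in events:
        a = max(0, int(round(e.onset_s * coarse_fs)))
        b = min(nc, int(round(e.offset_s * coarse_fs)))
        act[a:b] = 1.0
    w = max(3, int(round(CONDITION_RAMP_S * coarse_fs)) | 1)
    kernel = np.hanning(w)
    act = np.convolve(act, kernel / kernel.sum(), mode="same")
    t = np.arange(n) / config.fs
    return np.interp(t, np.arange(nc) / coarse_fs, act)


def _mains(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    """Power-line interference; uses waveform periodicity when fs/mains is rational."""
    if config.mains_amp <= 0:
        return np.zeros(n)
    k_max = int((config.fs / 2 * 0.999) // config.mains_hz)
    k_max = max(1, min(k_max, 7))
    phases = rng.uniform(0, 2 * np.pi, size=k_max)
    amps = config.mains_amp * np.arange(1, k_max + 1) ** (-config.mains_rolloff)

    period = None
    if float(config.fs).is_integer() and float(config.mains_hz).is_integer():
        g = math.gcd(int(config.mains_hz), int(config.fs))
        period = int(config.fs) // g  # samples per full cycle of every harmonic
    if period is not None and period <= 100_000 and n > 2 * period:
        t = np.arange(period) / config.fs
        template = np.zeros(period)
        for k in range(1, k_max + 1):
            template += amps[k - 1] * np.sin(2 * np.pi * k * config.mains_hz * t
                                             + phases[k - 1])
        reps = int(math.ceil(n / period))
        return np.tile(template, reps)[:n]
    t = np.arange(n) / config.fs
    out = np.zeros(n)
    for k in range(1, k_max + 1):
        out += amps[k - 1] * np.sin(2 * np.pi * k * config.mains_hz * t + phases[k - 1])
    return out


def simulate_recording(
    config: SimConfig,
    participant_index: int,
    participant_id: str,
    group: str,
    muscle: str,
    events: Sequence[EventAnnotation],
) -> EMGRecording:
    """One muscle channel for one participant, reproducible from the seed."""
    muscle_index = MUSCLES.index(muscle)
    rng = _rng(config, participant_index, muscle_index)
    scale_rng = _rng(config, participant_index, muscle_index, _SCALE_STREAM)
    n = int(round(config.fs * config.total_duration_s))

    subject_scale = float(np.exp(config.subject_sigma * scale_rng.standard_normal()))
    base = config.baseline_amp[muscle] * subject_scale
    # everyone carries some physiological tremor; its strength varies by
    # channel, giving each participant their own 5-15 Hz band-fraction floor
    floor_gain = config.tremor_floor * float(
        np.exp(config.tremor_floor_sigma * scale_rng.standard_normal()))

    carrier = _carrier_noise(rng, n, config.fs, _CARRIER_BAND_HZ)
    env = _burst_envelope(rng, config, n)

    f_fluent = config.amp_effect.get((group, muscle, "fluent"), 1.0)
    f_disfluent = config.amp_effect.get((group, muscle, "disfluent"), 1.0)
    g_fluent = config.tremor_gain.get((group, muscle, "fluent"), 0.0)
    g_disfluent = config.tremor_gain.get((group, muscle, "disfluent"), 0.0)
    condition_dependent = (f_fluent != f_disfluent) or (g_fluent != g_disfluent)
    activation = (_event_activation(config, n, events)
                  if (events and condition_dependent) else 0.0)

    factor = f_fluent + (f_disfluent - f_fluent) * activation
    amp = base * env * factor

    signal = amp * carrier

    if floor_gain > 0 or g_fluent > 0 or g_disfluent > 0:
        tremor = _tremor_noise(rng, n, config.fs)
        gain = floor_gain + g_fluent + (g_disfluent - g_fluent) * activation
        if config.tremor_mode == "additive":
            # scaled like the signal itself, so a pure amplitude effect
            # changes band power and total power proportionally
            signal = signal + amp * gain * tremor
        else:  # amplitude modulation of the carrier
            signal = amp * (1.0 + gain * tremor) * carrier

    signal = signal + _mains(rng, config, n)
    np.clip(signal, -config.clip_mv, config.clip_mv, out=signal)
    return EMGRecording(participant_id, group, muscle, config.fs, signal)


def simulate_participant(config: SimConfig, participant_index: int) -> ParticipantData:
    pid, group = config.participant_ids()[participant_index]
    events = simulate_events(config, participant_index, group)
    recordings = {
        m: simulate_recording(config, participant_index, pid, group, m, events)
        for m in MUSCLES
    }
    return ParticipantData(pid, group, recordings, events, config.context_blocks)


def iter_participants(config: SimConfig):
    """Yield ParticipantData one at a time (signals freed as you go)."""
    for idx in range(len(config.participant_ids())):
        yield simulate_participant(config, idx)


def _control_channel(config: SimConfig, events: Sequence[EventAnnotation]) -> np.ndarray:
    """Sixth sensor: a 5 mV, 10 ms rectangular spike at each disfluency onset."""
    n = int(round(config.fs * config.total_duration_s))
    out = np.zeros(n)
    w = max(1, int(round(0.01 * config.fs)))
    for e in events:
        i0 = int(math.floor(e.onset_s * config.fs))
        out[i0:min(n, i0 + w)] = 5.0
    return out


def simulate_study(config: SimConfig, out_dir: str | Path, *, overwrite: bool = False
                   ) -> SimStudy:
    """Emit a full study to disk: signals, annotations, manifest, ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[dict] = []
    truth: dict = {
        "amp_effect": {"|".join(k): v for k, v in config.amp_effect.items()},
        "tremor_gain": {"|".join(k): v for k, v in config.tremor_gain.items()},
        "seed": config.seed,
        "events": {},
    }
    for idx in range(len(config.participant_ids())):
        part = simulate_participant(config, idx)
        pdir = out_dir / part.participant_id
        signals = {}
        for muscle, rec in part.recordings.items():
            rel = f"{part.participant_id}/{muscle}.txt"
            write_recording(rec, out_dir / rel, overwrite=overwrite)
            signals[muscle] = rel
        ann_rel = f"{part.participant_id}/annotations.csv"
        write_annotations(part.events, out_dir / ann_rel, overwrite=overwrite)
        control_rel = f"{part.participant_id}/control.txt"
        write_signal(_control_channel(config, part.events), out_dir / control_rel,
                     overwrite=overwrite,
                     header=(f"participant={part.participant_id} channel=control unit=mV",))
        entries.append({
            "participant_id": part.participant_id,
            "group": part.group,
            "signals": signals,
            "annotations": ann_rel,
            "control": control_rel,
        })
        truth["events"][part.participant_id] = [
            [e.onset_s, e.offset_s, e.dtype, e.context] for e in part.events
        ]
        del part
    manifest = StudyManifest(
        fs=config.fs,
        participants=entries,
        context_blocks=[[a, b, c] for a, b, c in config.context_blocks],
    )
    manifest.to_json(out_dir / "manifest.json")
    cfg = asdict(config)
    cfg["amp_effect"] = truth["amp_effect"]
    cfg["tremor_gain"] = truth["tremor_gain"]
    cfg["baseline_amp"] = dict(config.baseline_amp)
    cfg["dtype_mix"] = dict(config.dtype_mix)
    truth["config"] = cfg
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return SimStudy(manifest, truth, out_dir)


def scaled_study_config(
    seed: int,
    amp_effect: Mapping[tuple[str, str, str], float] | None = None,
    tremor_gain: Mapping[tuple[str, str, str], float] | None = None,
) -> SimConfig:
    """Study configuration at the full group sizes with shortened sessions.

    Recording sessions are cut to two 20 s context blocks; the per-minute
    disfluency rates are raised in compensation so that each participant
    still contributes a realistic number of fluent and disfluent analysis
    windows per cell, as the full-length protocol would.  Group sizes,
    sampling rate, effect dials and all signal-model settings are the
    standard ones.
    """
    return SimConfig(
        contexts=("reading", "exposition"),
        session_s=20.0,
        disfluency_rate_a=12.0,
        disfluency_rate_b=15.0,
        amp_effect=amp_effect or {},
        tremor_gain=tremor_gain or {},
        seed=seed,
    )
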