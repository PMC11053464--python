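"""End-to-end orchestration: simulate/load -> preprocess -> segment ->
featurize -> compare -> report.

`analyze_participants` is the in-memory core shared by the disk-backed
`run_pipeline` and by simulation studies that never touch disk.  One
feature-table row is produced per (participant, muscle, segment); the
comparison plan then runs on the table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .features import BandSpec, featurize_batch
from .filtering import preprocess_multi
from .segmentation import (
    SegmentationPolicy,
    extract_disfluent_segments,
    extract_fluent_segments,
)
from .signal_io import StudyManifest, read_annotations, read_recording
from .stats import ComparisonPlan, ComparisonResult, results_to_frame, run_plan
from .synth import ParticipantData

__all__ = ["RunConfig", "PipelineResult", "analyze_participants", "run_pipeline",
           "report", "features_for_participant"]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "participant", "group", "muscle", "start_s", "label", "dtype", "context",
    "iemg", "mean_amp", "rms", "band_power", "total_power", "band_fraction",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on."""

    manifest_path: str | Path
    out_dir: str | Path
    band: BandSpec = BandSpec()
    policy: SegmentationPolicy = SegmentationPolicy()
    plan: ComparisonPlan = ComparisonPlan()
    mode_amplitude: str = "full"
    mode_band: str = "notch_only"
    seed: int = 0


@dataclass
class PipelineResult:
    features: pd.DataFrame
    results: list[ComparisonResult]
    report_text: str
    log_lines: list[str] = field(default_factory=list)


def features_for_participant(
    part: ParticipantData,
    *,
    band: BandSpec = BandSpec(),
    policy: SegmentationPolicy = SegmentationPolicy(),
    mode_amplitude: str = "full",
    mode_band: str = "notch_only",
) -> pd.DataFrame:
    """Segment one participant's shared time base and featurize all channels.

    Fluent windows are selected once on the shared time base (the five
    sensors record simultaneously) and reused across muscles.
    """
    first = next(iter(part.recordings.values()))
    fluent = extract_fluent_segments(first, part.events, policy, part.context_blocks)
    disfluent = extract_disfluent_segments(first, part.events, policy)
    segments = fluent + disfluent
    rows: list[list] = []
    for muscle, rec in part.recordings.items():
        pre = preprocess_multi(rec.values, rec.fs, (mode_amplitude, mode_band))
        vectors = featurize_batch(segments, pre[mode_amplitude], pre[mode_band], band)
        for seg, fv in zip(segments, vectors):
            rows.append([
                part.participant_id, part.group, muscle, seg.start_s, seg.label,
                seg.dtype, seg.context, fv.iemg, fv.mean_amp, fv.rms,
                fv.band_power, fv.total_power, fv.band_fraction,
            ])
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def analyze_participants(
    participants: Iterable[ParticipantData],
    *,
    band: BandSpec = BandSpec(),
    policy: SegmentationPolicy = SegmentationPolicy(),
    plan: ComparisonPlan = ComparisonPlan(),
    mode_amplitude: str = "full",
    mode_band: str = "notch_only",
) -> PipelineResult:
    """Feature extraction plus the full comparison plan, in memory."""
    frames: list[pd.DataFrame] = []
    log_lines: list[str] = []
    n_recordings = 0
    for part in participants:
        df = features_for_participant(
            part, band=band, policy=policy,
            mode_amplitude=mode_amplitude, mode_band=mode_band)
        n_recordings += len(part.recordings)
        frames.append(df)
    features = (pd.concat(frames, ignore_index=True)
                if frames else pd.DataFrame(columns=FEATURE_COLUMNS))
    n_fluent = int((features["label"] == "fluent").sum())
    n_disfluent = int((features["label"] == "disfluent").sum())
    log_lines.append(f"recordings read: {n_recordings}")
    log_lines.append(f"feature rows: {len(features)} "
                     f"(fluent {n_fluent}, disfluent {n_disfluent})")
    results = run_plan(features, plan) if len(features) else []
    log_lines.append(f"contrast cells evaluated: {len(results)}")
    log_lines.append(
        "settings: alpha=%g equal_var=%s fdr=%s pool_segments=%s band=[%g,%g]Hz "
        "modes=(%s,%s) gap=%gs guard=%gs target=%d"
        % (plan.alpha, plan.equal_var, plan.fdr_correct, plan.pool_segments,
           band.lo_hz, band.hi_hz, mode_amplitude, mode_band,
           policy.min_gap_s, policy.guard_s, policy.n_fluent_target))
    return PipelineResult(features, results, report(results), log_lines)


def report(results: list[ComparisonResult]) -> str:
    """One line per evaluated contrast; significant ones flagged with '*'."""
    if not results:
        return "no contrasts evaluated"
    lines = []
    for r in sorted(results, key=lambda r: (r.metric, r.stratum, r.contrast, r.muscle)):
        flag = " *" if r.significant else ""
        lines.append(
            f"{r.metric} | {r.stratum} | {r.contrast} | {r.muscle} | "
            f"n=({r.n_x},{r.n_y}) | diff={r.percent_difference:+.1f}% | "
            f"p={r.p_value:.4f}{flag}"
        )
    return "\n".join(lines)


def _load_participants(manifest: StudyManifest, base_dir: Path
                       ) -> Iterable[ParticipantData]:
    blocks = [tuple(b) for b in manifest.context_blocks]
    for entry in manifest.participants:
        pid = entry["participant_id"]
        group = entry["group"]
        recordings = {}
        for muscle, rel in entry["signals"].items():
            path = base_dir / rel
            if not path.exists():
                raise FileNotFoundError(f"stage=load: missing signal file {path}")
            recordings[muscle] = read_recording(
                path, participant_id=pid, group=group, muscle=muscle, fs=manifest.fs)
        events = read_annotations(base_dir / entry["annotations"])
        yield ParticipantData(pid, group, recordings, events, blocks)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Disk-backed run: read a manifest, analyze, write all outputs.

    Writes features.csv, comparisons.csv, report.txt, run_log.txt and a
    frozen copy of the effective configuration.  Deterministic given the
    configuration (the default greedy segmentation draws no random numbers;
    the seed feeds the optional random strategy).
    """
    manifest_path = Path(config.manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"stage=load: manifest not found: {manifest_path}")
    base_dir = manifest_path.parent
    manifest = StudyManifest.from_json(manifest_path)
    policy = config.policy
    if policy.seed != config.seed:
        from dataclasses import replace
        policy = replace(policy, seed=config.seed)
    result = analyze_participants(
        _load_participants(manifest, base_dir),
        band=config.band, policy=policy, plan=config.plan,
        mode_amplitude=config.mode_amplitude, mode_band=config.mode_band)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    results_to_frame(result.results).to_csv(out / "comparisons.csv", index=False)
    (out / "report.txt").write_text(result.report_text + "\n")
    (out / "run_log.txt").write_text("\n".join(result.log_lines) + "\n")
    effective = {
        "manifest": str(manifest_path),
        "seed": config.seed,
        "band": asdict(config.band),
        "policy": asdict(policy),
        "plan": {
            "contrasts": [list(map(list, c)) for c in config.plan.contrasts],
            "metrics": list(config.plan.metrics),
            "strata": list(config.plan.strata),
            "alpha": config.plan.alpha,
            "equal_var": config.plan.equal_var,
            "fdr_correct": config.plan.fdr_correct,
            "pool_segments": config.plan.pool_segments,
        },
        "mode_amplitude": config.mode_amplitude,
        "mode_band": config.mode_band,
    }
    (out / "effective_config.json").write_text(json.dumps(effective, indent=2))
    return result
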