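"""Group comparisons of per-participant muscle activity.

The analysis aggregates segment-level features to per-participant means for
each (muscle, condition) cell, normalizes each comparison by the pooled mean
activity, screens normality with the Shapiro-Wilk test, and contrasts cells
with two-sided Student t-tests at alpha = 0.05 (pooled variance; paired for
within-participant fluent-vs-disfluent contrasts).  Each per-test p-value is
reported as is: no multiplicity correction is applied by default, matching
per-test reporting at p < 0.05; a Benjamini-Hochberg adjustment is offered
as an explicit extension.

Comparisons are run overall and stratified by speech context (all four
session phases) and by disfluency type (repetition, prolongation, block;
the fluent side of a type stratum is the unrestricted fluent cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .signal_io import MUSCLES

__all__ = [
    "ParticipantSummary",
    "ComparisonResult",
    "ComparisonPlan",
    "DEFAULT_CONTRASTS",
    "summarize",
    "normalize_mean_activity",
    "shapiro_wilk",
    "t_test",
    "percent_difference",
    "run_plan",
    "results_to_frame",
]

log = logging.getLogger(__name__)

#: (group_x, condition_x) vs (group_y, condition_y)
DEFAULT_CONTRASTS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("A", "fluent"), ("B", "fluent")),
    (("A", "fluent"), ("B", "disfluent")),
    (("A", "disfluent"), ("B", "fluent")),
    (("A", "disfluent"), ("B", "disfluent")),
    (("A", "fluent"), ("A", "disfluent")),
    (("B", "fluent"), ("B", "disfluent")),
)

METRIC_COLUMNS = {"mean_amplitude": "mean_amp", "band_fraction": "band_fraction"}


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    group: str
    muscle: str
    condition: str
    mean_amplitude: float
    mean_band_fraction: float
    n_segments: int
    stratum: str | None = None


@dataclass(frozen=True)
class ComparisonResult:
    muscle: str
    contrast: str
    metric: str
    stratum: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    percent_difference: float
    shapiro_p_x: float
    shapiro_p_y: float
    t_stat: float
    p_value: float
    significant: bool
    paired: bool


@dataclass(frozen=True)
class ComparisonPlan:
    contrasts: tuple = DEFAULT_CONTRASTS
    metrics: tuple[str, ...] = ("mean_amplitude", "band_fraction")
    strata: tuple[str, ...] = ("overall", "context", "dtype")
    alpha: float = 0.05
    equal_var: bool = True  # Student (pooled variance); False gives Welch
    fdr_correct: bool = False  # Benjamini-Hochberg across the plan (extension)
    pool_segments: bool = False  # pool segments instead of participant means

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if len(set(self.contrasts)) != len(self.contrasts):
            raise ValueError("contrasts must be unique")


# ---------------------------------------------------------------------------
# elementary operations


def summarize(features: pd.DataFrame, stratum: str | None = None
              ) -> list[ParticipantSummary]:
    """Per-participant cell means of the segment-level feature table.

    ``features`` needs columns participant, group, muscle, label, mean_amp,
    band_fraction (plus context/dtype when stratifying).
    """
    keys = ["participant", "group", "muscle", "label"]
    if stratum is not None:
        keys.append(stratum)
    out: list[ParticipantSummary] = []
    for key, sub in features.groupby(keys, dropna=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        out.append(ParticipantSummary(
            participant_id=str(key[0]),
            group=str(key[1]),
            muscle=str(key[2]),
            condition=str(key[3]),
            mean_amplitude=float(sub["mean_amp"].mean()),
            mean_band_fraction=float(sub["band_fraction"].mean()),
            n_segments=int(len(sub)),
            stratum=None if stratum is None else str(key[4]),
        ))
    return out


def normalize_mean_activity(values: np.ndarray) -> np.ndarray:
    """Divide by the pooled mean so the normalized values average to 1."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("pooled mean activity must be positive to normalize")
    return values / mean


def shapiro_wilk(values: np.ndarray) -> float:
    """Shapiro-Wilk normality p-value (delegates to scipy.stats.shapiro)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    return float(sst.shapiro(values).pvalue)


def t_test(values_x: np.ndarray, values_y: np.ndarray, *, paired: bool = False,
           equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student t-test; pooled variance unless ``equal_var=False``."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        if x.size < 2:
            raise ValueError("paired test requires at least 2 pairs")
        if np.ptp(x - y) == 0:
            raise ValueError("zero variance of the paired differences")
        res = sst.ttest_rel(x, y)
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("unpaired test requires at least 2 values per side")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("zero pooled variance")
        res = sst.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def percent_difference(mean_hi: float, mean_lo: float) -> float:
    """100 * (hi - lo) / lo, the 'higher by N percent' convention."""
    if mean_lo <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_hi - mean_lo) / mean_lo


# ---------------------------------------------------------------------------
# the comparison plan


def _strata(features: pd.DataFrame, plan: ComparisonPlan
            ) -> list[tuple[str, str | None, str | None]]:
    """(label, column, value) triples: overall plus observed strata levels."""
    out: list[tuple[str, str | None, str | None]] = []
    if "overall" in plan.strata:
        out.append(("overall", None, None))
    if "context" in plan.strata and "context" in features.columns:
        for c in sorted(features["context"].dropna().unique()):
            out.append((f"context:{c}", "context", c))
    if "dtype" in plan.strata and "dtype" in features.columns:
        for d in sorted(features["dtype"].dropna().unique()):
            out.append((f"dtype:{d}", "dtype", d))
    return out


def _stratum_frame(features: pd.DataFrame, stratum_col: str | None,
                   stratum_val: str | None) -> pd.DataFrame:
    if stratum_col is None:
        return features
    if stratum_col == "dtype":
        # a disfluency-type stratum does not restrict the fluent side
        keep = (features["label"] == "fluent") | (features["dtype"] == stratum_val)
        return features[keep]
    return features[features[stratum_col] == stratum_val]


class _CellMeans:
    """Per-participant cell means for one stratum, precomputed once."""

    def __init__(self, features: pd.DataFrame, metric_cols: Sequence[str],
                 pool_segments: bool):
        self.pool = pool_segments
        keys = ["group", "label", "muscle"]
        if pool_segments:
            self.table = features.set_index(keys)[list(metric_cols)].sort_index()
        else:
            self.table = (features
                          .groupby(keys + ["participant"], observed=True)[list(metric_cols)]
                          .mean()
                          .reset_index("participant")
                          .sort_index())

    def cell(self, group: str, condition: str, muscle: str, metric_col: str
             ) -> pd.Series:
        try:
            sub = self.table.loc[(group, condition, muscle)]
        except KeyError:
            return pd.Series(dtype=float)
        if isinstance(sub, pd.Series):  # single row
            sub = sub.to_frame().T
        if self.pool:
            return sub[metric_col].reset_index(drop=True).astype(float)
        return pd.Series(sub[metric_col].to_numpy(dtype=float),
                         index=sub["participant"].to_numpy())


def run_plan(features: pd.DataFrame, plan: ComparisonPlan = ComparisonPlan()
             ) -> list[ComparisonResult]:
    """Run every contrast x muscle x metric x stratum with sufficient data.

    Values entering a contrast are per-participant cell means (or pooled
    segments if configured), normalized by the pooled mean of both sides.
    Within-group contrasts are paired on participants having both
    conditions; between-group contrasts use the unpaired pooled-variance
    test.  Cells with fewer than 2 values per side are skipped.
    """
    muscles = [m for m in MUSCLES if m in set(features["muscle"])]
    metric_cols = [METRIC_COLUMNS[m] for m in plan.metrics]
    cells = {
        label: _CellMeans(_stratum_frame(features, s_col, s_val), metric_cols,
                          plan.pool_segments)
        for label, s_col, s_val in _strata(features, plan)
    }
    results: list[ComparisonResult] = []
    for (gx, cx), (gy, cy) in plan.contrasts:
        contrast = f"{gx}-{cx} vs {gy}-{cy}"
        paired = gx == gy and not plan.pool_segments
        for metric in plan.metrics:
            col = METRIC_COLUMNS[metric]
            for stratum_label, table in cells.items():
                for muscle in muscles:
                    vx = table.cell(gx, cx, muscle, col)
                    vy = table.cell(gy, cy, muscle, col)
                    if paired:
                        joined = pd.concat([vx.rename("x"), vy.rename("y")],
                                           axis=1, join="inner").dropna()
                        x = joined["x"].to_numpy()
                        y = joined["y"].to_numpy()
                    else:
                        x = vx.dropna().to_numpy()
                        y = vy.dropna().to_numpy()
                    if len(x) < 2 or len(y) < 2:
                        log.debug("skipping %s %s %s %s: insufficient data",
                                  contrast, muscle, metric, stratum_label)
                        continue
                    pooled = np.concatenate([x, y])
                    if pooled.mean() > 0:
                        norm = normalize_mean_activity(pooled)
                        x, y = norm[:len(x)], norm[len(x):]
                    try:
                        t, p = t_test(x, y, paired=paired, equal_var=plan.equal_var)
                    except ValueError as exc:
                        log.debug("skipping %s %s %s %s: %s",
                                  contrast, muscle, metric, stratum_label, exc)
                        continue
                    mx, my = float(x.mean()), float(y.mean())
                    lo, hi = sorted((mx, my))
                    pdiff = percent_difference(hi, lo) if lo > 0 else float("nan")
                    if mx < my:
                        pdiff = -pdiff
                    def _sw(v: np.ndarray) -> float:
                        try:
                            return shapiro_wilk(v)
                        except ValueError:
                            return float("nan")
                    results.append(ComparisonResult(
                        muscle=muscle, contrast=contrast, metric=metric,
                        stratum=stratum_label, n_x=len(x), n_y=len(y),
                        mean_x=mx, mean_y=my, percent_difference=pdiff,
                        shapiro_p_x=_sw(x), shapiro_p_y=_sw(y),
                        t_stat=t, p_value=p, significant=bool(p < plan.alpha),
                        paired=paired,
                    ))
    if plan.fdr_correct and results:
        results = _apply_bh(results, plan.alpha)
    return results


def _apply_bh(results: list[ComparisonResult], alpha: float) -> list[ComparisonResult]:
    """Benjamini-Hochberg significance flags across the whole plan."""
    from dataclasses import replace

    p = np.array([r.p_value for r in results])
    order = np.argsort(p)
    m = len(p)
    passed = np.zeros(m, dtype=bool)
    threshold = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= alpha * rank / m:
            threshold = rank
    for rank, idx in enumerate(order, start=1):
        passed[idx] = rank <= threshold
    return [replace(r, significant=bool(ok)) for r, ok in zip(results, passed)]


def results_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    cols = ["contrast", "muscle", "metric", "stratum", "n_x", "n_y", "mean_x",
            "mean_y", "percent_difference", "shapiro_p_x", "shapiro_p_y",
            "t_stat", "p_value", "significant", "paired"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)
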