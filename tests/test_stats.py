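"""Aggregation, normalization and the two-sample comparison machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from emgspeech import (
    ComparisonPlan,
    normalize_mean_activity,
    percent_difference,
    results_to_frame,
    run_plan,
    shapiro_wilk,
    summarize,
    t_test,
)

from conftest import synthetic_feature_table


# --- summarize -----------------------------------------------------------


def test_summarize_cell_means():
    df = pd.DataFrame({
        "participant": ["p1"] * 2 + ["p2"],
        "group": ["A"] * 3, "muscle": ["DAO"] * 3,
        "label": ["fluent"] * 3,
        "mean_amp": [1.0, 3.0, 5.0], "band_fraction": [2.0, 4.0, 6.0],
    })
    out = {s.participant_id: s for s in summarize(df)}
    assert out["p1"].mean_amplitude == 2.0  # mean of 1 and 3
    assert out["p1"].n_segments == 2
    assert out["p2"].mean_amplitude == 5.0
    assert out["p2"].n_segments == 1


def test_summarize_matches_independent_recomputation(rng):
    df = synthetic_feature_table(rng, n_a=3, n_b=3, segs_fluent=4, segs_disfluent=2)
    out = summarize(df)
    for s in out[:20]:
        sub = df[(df.participant == s.participant_id) & (df.muscle == s.muscle)
                 & (df.label == s.condition)]
        assert s.mean_amplitude == pytest.approx(sum(sub.mean_amp) / len(sub))
        assert s.mean_band_fraction == pytest.approx(
            sum(sub.band_fraction) / len(sub))


# --- normalization -------------------------------------------------------


def test_normalize_examples():
    out = normalize_mean_activity(np.array([2.0, 4.0]))
    assert np.allclose(out, [2 / 3, 4 / 3])
    assert out.mean() == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(normalize_mean_activity(np.full(5, 3.3)), 1.0)
    with pytest.raises(ValueError):
        normalize_mean_activity(np.array([0.0, 0.0]))


def test_normalization_leaves_t_statistic_unchanged(rng):
    x = rng.lognormal(size=12)
    y = rng.lognormal(size=15)
    t_raw, _ = t_test(x, y)
    pooled = normalize_mean_activity(np.concatenate([x, y]))
    t_norm, _ = t_test(pooled[:12], pooled[12:])
    assert t_norm == pytest.approx(t_raw, rel=1e-12)


# --- shapiro-wilk --------------------------------------------------------


def test_shapiro_calibration_on_normal_and_exponential():
    hits_normal = 0
    hits_expo = 0
    n_seeds = 100
    for seed in range(n_seeds):
        r = np.random.default_rng(seed)
        if shapiro_wilk(r.standard_normal(50)) > 0.05:
            hits_normal += 1
        if shapiro_wilk(r.exponential(size=50)) < 0.05:
            hits_expo += 1
    assert hits_normal >= 0.90 * n_seeds
    assert hits_expo >= 0.90 * n_seeds


def test_shapiro_degenerate_inputs():
    with pytest.raises(ValueError):
        shapiro_wilk(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        shapiro_wilk(np.full(10, 3.0))


# --- t-test --------------------------------------------------------------


def test_t_test_identical_samples():
    t, p = t_test(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
    assert (t, p) == (0.0, 1.0)


def test_t_test_textbook_example():
    # pooled variance 1, se = sqrt(2/3), t = -3 / 0.8165
    t, p = t_test(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
    assert t == pytest.approx(-3.674, abs=1e-3)
    assert p == pytest.approx(0.0213, abs=2e-4)


def test_paired_t_matches_closed_form():
    x = np.array([1.0, 2.0, 4.0])
    y = np.array([0.5, 1.0, 2.5])
    d = x - y
    t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
    t, p = t_test(x, y, paired=True)
    assert t == pytest.approx(t_expected, rel=1e-12)
    assert p == pytest.approx(2 * sst.t.sf(abs(t_expected), df=2), rel=1e-12)


def test_t_test_error_paths():
    with pytest.raises(ValueError):
        t_test(np.array([1.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        t_test(np.full(5, 2.0), np.full(4, 2.0))  # zero pooled variance
    with pytest.raises(ValueError):
        t_test(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]), paired=True)


def test_t_test_null_calibration_vectorized():
    r = np.random.default_rng(2024)
    x = r.standard_normal((2000, 30))
    y = r.standard_normal((2000, 30))
    _, p = sst.ttest_ind(x, y, axis=1, equal_var=True)
    rate = float((p < 0.05).mean())
    assert 0.04 <= rate <= 0.06


# --- percent difference --------------------------------------------------


def test_percent_difference():
    assert percent_difference(3.14, 1.0) == pytest.approx(214.0)
    assert percent_difference(1.0, 1.0) == 0.0
    assert percent_difference(2.0, 1.0) == 100.0
    with pytest.raises(ValueError):
        percent_difference(1.0, 0.0)


# --- the comparison plan -------------------------------------------------


def test_null_plan_rejects_at_alpha(rng):
    sigs = []
    for _ in range(12):
        df = synthetic_feature_table(rng)
        sigs += [r.significant for r in run_plan(df, ComparisonPlan(strata=("overall",)))]
    rate = np.mean(sigs)
    assert 0.01 <= rate <= 0.10  # Monte-Carlo bounds around alpha = 0.05


def test_targeted_band_boost_is_recovered(rng):
    shift = {("B", "ZM", "fluent"): 1.6, ("B", "ZM", "disfluent"): 1.6}
    hits = {m: 0 for m in ("DAO", "OO", "M", "S", "ZM")}
    reps = 8
    for _ in range(reps):
        df = synthetic_feature_table(rng, band_shift=shift)
        for r in run_plan(df, ComparisonPlan(strata=("overall",))):
            if r.metric == "band_fraction" and r.contrast == "A-fluent vs B-fluent" \
                    and r.significant:
                hits[r.muscle] += 1
    assert hits["ZM"] >= 0.8 * reps
    assert all(hits[m] <= 0.3 * reps for m in ("DAO", "OO", "M", "S"))


def test_amplitude_suppression_direction(rng):
    shift = {("B", "DAO", "disfluent"): 0.4}
    df = synthetic_feature_table(rng, amp_shift=shift)
    res = [r for r in run_plan(df, ComparisonPlan(strata=("overall",)))
           if r.metric == "mean_amplitude" and r.muscle == "DAO"
           and r.contrast == "A-disfluent vs B-disfluent"]
    assert len(res) == 1
    assert res[0].significant
    assert res[0].percent_difference > 0  # group A higher


def test_plan_scale_invariance(rng):
    df = synthetic_feature_table(rng, n_a=8, n_b=8, segs_fluent=4, segs_disfluent=3)
    res1 = run_plan(df, ComparisonPlan(strata=("overall",)))
    df2 = df.copy()
    for col in ("iemg", "mean_amp", "rms", "band_power", "band_fraction"):
        df2[col] *= 7.3
    res2 = run_plan(df2, ComparisonPlan(strata=("overall",)))
    assert [r.p_value for r in res1] == pytest.approx([r.p_value for r in res2])


def test_plan_pairs_within_group_and_skips_thin_cells(rng):
    df = synthetic_feature_table(rng, n_a=6, n_b=6)
    # remove disfluent cells for all but one A participant: within-A paired
    # contrast lacks pairs and between-group A-disfluent contrasts lack data
    keep = (df.label == "fluent") | (df.group == "B") | (df.participant == "A00")
    res = run_plan(df[keep], ComparisonPlan(strata=("overall",)))
    contrasts = {r.contrast for r in res}
    assert "A-fluent vs A-disfluent" not in contrasts
    assert "A-disfluent vs B-disfluent" not in contrasts
    assert all(r.paired == (r.contrast in ("A-fluent vs A-disfluent",
                                           "B-fluent vs B-disfluent"))
               for r in res)


def test_results_frame_layout(rng):
    df = synthetic_feature_table(rng, n_a=4, n_b=4, segs_fluent=3, segs_disfluent=2)
    res = run_plan(df)
    frame = results_to_frame(res)
    assert list(frame.columns)[:4] == ["contrast", "muscle", "metric", "stratum"]
    assert len(frame) == len(res)
    assert frame.p_value.between(0, 1).all()
    assert (frame.significant == (frame.p_value < 0.05)).all()
    # strata include overall, contexts, and disfluency types
    kinds = {s.split(":")[0] for s in frame.stratum}
    assert kinds == {"overall", "context", "dtype"}
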