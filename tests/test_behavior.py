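from math import comb

import numpy as np
import pandas as pd
import pytest

from ndba.behavior import (
    LisasParams,
    aggregate,
    exclude_chance_subjects,
    group_behavior_vector,
    lisas,
    rt_accuracy_coupling,
)
from ndba.design import generate_design
from ndba.synth import SyntheticConfig, generate_behavior, generate_patterns, task_true_distances


def _trials(rows):
    return pd.DataFrame(rows, columns=["subject", "task", "run", "stimulus_id", "rt_ms", "correct"])


def test_lisas_closed_form():
    assert lisas(600.0, 0.1, LisasParams(100.0, 0.2)) == pytest.approx(650.0)
    # no errors anywhere: identity
    assert lisas(700.0, 0.0, LisasParams(100.0, 0.2)) == pytest.approx(700.0)
    assert lisas(700.0, 0.3, LisasParams(100.0, 0.0)) == pytest.approx(700.0)
    # doubling S_RT doubles the penalty term only
    base = lisas(600.0, 0.1, LisasParams(100.0, 0.2))
    doubled = lisas(600.0, 0.1, LisasParams(200.0, 0.2))
    assert doubled - 600.0 == pytest.approx(2 * (base - 600.0))
    with pytest.raises(ValueError):
        lisas(-1.0, 0.1, LisasParams(100.0, 0.2))


def test_lisas_never_below_mean_rt(rng):
    for _ in range(50):
        rt = rng.uniform(200, 1200)
        pe = rng.uniform(0, 1)
        params = LisasParams(rng.uniform(0, 300), rng.uniform(0, 0.5))
        assert lisas(rt, pe, params) >= rt


def test_aggregate_simple_cells():
    rows = [("s1", "animacy", 0, 0, 700 + 10 * i, True) for i in range(6)]
    rows += [("s1", "animacy", 0, 1, 800, True), ("s1", "animacy", 1, 1, 900, False)]
    agg = aggregate(_trials(rows), rt_basis="all")
    cell0 = agg[agg.stimulus_id == 0].iloc[0]
    assert cell0.prop_error == 0.0
    assert cell0.mean_rt_ms == pytest.approx(725.0)
    assert cell0.n_trials == 6
    cell1 = agg[agg.stimulus_id == 1].iloc[0]
    assert cell1.prop_error == pytest.approx(0.5)
    assert cell1.mean_rt_ms == pytest.approx(850.0)


def test_aggregate_matches_brute_force_recount(rng):
    rows = []
    for i in range(50):
        rows.append(
            (
                f"s{rng.integers(2)}",
                "shape",
                int(rng.integers(3)),
                int(rng.integers(4)),
                float(rng.uniform(300, 1200)),
                bool(rng.random() < 0.8),
            )
        )
    trials = _trials(rows)
    agg = aggregate(trials, rt_basis="all")
    for _, row in agg.iterrows():
        sel = trials[
            (trials.subject == row.subject)
            & (trials.task == row.task)
            & (trials.stimulus_id == row.stimulus_id)
        ]
        assert row.n_trials == len(sel)
        assert row.prop_error == pytest.approx(1 - sel.correct.mean())
        assert row.mean_rt_ms == pytest.approx(sel.rt_ms.mean())
        assert row.median_rt_ms == pytest.approx(sel.rt_ms.median())


def test_correct_only_rt_basis_changes_rt_not_errors():
    rows = [
        ("s1", "animacy", 0, 0, 500.0, True),
        ("s1", "animacy", 0, 0, 1500.0, False),
    ]
    agg_all = aggregate(_trials(rows), rt_basis="all")
    agg_c = aggregate(_trials(rows), rt_basis="correct-only")
    assert agg_all.iloc[0].mean_rt_ms == pytest.approx(1000.0)
    assert agg_c.iloc[0].mean_rt_ms == pytest.approx(500.0)
    assert agg_all.iloc[0].prop_error == agg_c.iloc[0].prop_error == pytest.approx(0.5)


def test_group_vector_is_subject_mean():
    rows = [("s1", "animacy", 0, s, 600.0 + s, True) for s in range(3)]
    rows += [("s2", "animacy", 0, s, 800.0 + s, True) for s in range(3)]
    agg = aggregate(_trials(rows))
    vec = group_behavior_vector(agg, "animacy")
    np.testing.assert_allclose(vec.values, [700.0, 701.0, 702.0])
    vec1 = group_behavior_vector(agg, "animacy", subjects=["s1"])
    np.testing.assert_allclose(vec1.values, [600.0, 601.0, 602.0])


def test_group_vector_matches_recount(rng, design):
    cfg = SyntheticConfig(n_subjects=5, grid_shape=(8, 5, 5), region_voxels=30, seed=4)
    _, true = generate_patterns(design, cfg)
    trials = generate_behavior(design, {"animacy": true["animacy"]}, cfg)
    agg = aggregate(trials)
    vec = group_behavior_vector(agg, "animacy")
    per_subject = agg.pivot_table(index="stimulus_id", columns="subject", values="lisas_ms")
    np.testing.assert_allclose(vec.values, per_subject.mean(axis=1).values)


def test_planted_coupling_gives_negative_rt_accuracy_r(design):
    """With distance speeding and improving responses, slow stimuli are the
    inaccurate ones: group mean r(RT, accuracy) < 0."""
    cfg = SyntheticConfig(
        n_subjects=12, grid_shape=(8, 5, 5), region_voxels=30, seed=6,
        n_runs_per_task=6, rt_noise_sd_ms=60.0,
        asymmetry={"bar": 1.0, "blob": 1.0}, accuracy_link_scale=2.5,
    )
    _, true = generate_patterns(design, cfg)
    trials = generate_behavior(design, {"shape": true["shape"]}, cfg)
    agg = aggregate(trials, rt_basis="all")
    _, mean_r, t, p = rt_accuracy_coupling(agg, "shape")
    assert mean_r < 0
    assert p < 0.05


def test_independent_rt_and_accuracy_give_null_coupling(rng):
    rows = []
    for subj in range(6):
        for s in range(32):
            for t in range(6):
                rows.append(
                    (f"s{subj}", "animacy", t % 3, s,
                     float(rng.uniform(500, 900)), bool(rng.random() < 0.8))
                )
    agg = aggregate(_trials(rows), rt_basis="all")
    _, mean_r, _, p = rt_accuracy_coupling(agg, "animacy")
    assert abs(mean_r) < 0.15


def test_perfectly_linear_coupling_fixture():
    rows = []
    for subj in ("s1", "s2"):
        for s in range(8):
            # accuracy affine in RT (prop_error = s/8, RT = 500 + 10 s) -> r = -1
            for t in range(8):
                rows.append((subj, "animacy", 0, s, 500.0 + 10 * s, t >= s))
    agg = aggregate(_trials(rows), rt_basis="all")
    rs, mean_r, _, _ = rt_accuracy_coupling(agg, "animacy")
    assert mean_r == pytest.approx(-1.0, abs=1e-9)


def test_exclusion_by_exact_binomial():
    rows = []
    for subj, p_correct in (("good", 0.9), ("bad", 0.5)):
        rng = np.random.default_rng(0 if subj == "good" else 1)
        for task in ("animacy", "shape"):
            for i in range(192):
                rows.append(
                    (subj, task, i % 3, i % 32, 700.0, bool(rng.random() < p_correct))
                )
    kept, excluded, rec = exclude_chance_subjects(_trials(rows))
    assert kept == ["good"] and excluded == ["bad"]
    # boundary case agrees with the exact binomial tail sum
    k, n = 110, 192
    tail = sum(comb(n, j) for j in range(k, n + 1)) / 2**n
    row = rec[(rec.subject == "good")].iloc[0]
    assert 0 <= row.p_above_chance <= 1
    boundary = _trials(
        [("s", "animacy", i % 3, i % 32, 700.0, i < k) for i in range(n)]
    )
    _, _, rec_b = exclude_chance_subjects(boundary)
    assert rec_b.iloc[0].p_above_chance == pytest.approx(tail, rel=1e-12)


def test_schema_validation():
    with pytest.raises(ValueError, match="missing columns"):
        aggregate(pd.DataFrame({"subject": ["a"]}))
    with pytest.raises(ValueError):
        aggregate(_trials([("s", "t", 0, 0, -5.0, True)]))
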