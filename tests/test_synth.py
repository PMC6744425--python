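import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ndba.design import generate_design
from ndba.lda import crossval_accuracy, dataset_samples, leave_one_run_out
from ndba.synth import (
    RT_FLOOR_MS,
    SyntheticConfig,
    default_region_layout,
    generate_behavior,
    generate_images,
    generate_patterns,
    task_true_distances,
)


def _loro_accuracy(ds, labels, voxels=None):
    values = ds.values if voxels is None else ds.values[:, :, voxels]
    X, stim, runs = dataset_samples(values)
    y = labels[stim]
    acc, _ = crossval_accuracy(X, y, leave_one_run_out(runs))
    return acc


def test_patterns_deterministic(design):
    cfg = SyntheticConfig(n_subjects=2, grid_shape=(8, 5, 5), region_voxels=30, seed=3)
    a, ta = generate_patterns(design, cfg)
    b, tb = generate_patterns(design, cfg)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.values, y.values)
    np.testing.assert_array_equal(ta["animacy"], tb["animacy"])
    c, _ = generate_patterns(design, SyntheticConfig(
        n_subjects=2, grid_shape=(8, 5, 5), region_voxels=30, seed=4))
    assert not np.array_equal(a[0].values, c[0].values)


def test_null_signal_decodes_at_chance(design):
    cfg = SyntheticConfig(
        n_subjects=1, grid_shape=(8, 5, 5), region_voxels=30,
        signal_sd={"loc_like": {"animacy": 0.0}, "evc_like": {"shape": 0.0}}, seed=5,
    )
    datasets, true = generate_patterns(design, cfg)
    acc = _loro_accuracy(datasets[0], design.labels("animacy"))
    assert abs(acc - 0.5) < 0.16  # ~3 binomial SEs over 96 samples
    # no planted class separation: correct-side distances center on zero
    assert abs(np.mean(design.class_sign("animacy") * true["animacy"])) < 0.5


def test_signal_is_region_local(design, small_patterns):
    cfg, datasets, _ = small_patterns
    regions = cfg.regions()
    background = np.setdiff1d(
        np.arange(cfg.n_voxels), np.concatenate(list(regions.values()))
    )
    ds = datasets[0]
    acc_loc = _loro_accuracy(ds, design.labels("animacy"), regions["loc_like"])
    acc_bg = _loro_accuracy(ds, design.labels("animacy"), background[:40])
    acc_evc = _loro_accuracy(ds, design.labels("animacy"), regions["evc_like"])
    assert acc_loc > 0.85
    assert abs(acc_bg - 0.5) < 0.16
    assert abs(acc_evc - 0.5) < 0.16


def test_true_distance_structure(design, small_patterns):
    cfg, _, true = small_patterns
    correct_side = design.class_sign("animacy") * true["animacy"]
    # planted separation 4.0 with exemplar spread 0.5 around it
    assert abs(np.mean(correct_side) - 4.0) < 0.5
    assert 0.2 < np.std(correct_side) < 1.0


def test_behavior_noise_free_rank_anticorrelation(design):
    cfg = SyntheticConfig(
        n_subjects=1, grid_shape=(8, 5, 5), region_voxels=30,
        rt_noise_sd_ms=0.0, seed=9,
        asymmetry={"animate": 1.0, "inanimate": 0.0},
    )
    _, true = generate_patterns(design, cfg)
    trials = generate_behavior(design, {"animacy": true["animacy"]}, cfg)
    per_stim = trials.groupby("stimulus_id")["rt_ms"].mean()
    animate = design.category_members("animacy", "animate")
    inanimate = design.category_members("animacy", "inanimate")
    rho, _ = stats.spearmanr(per_stim.loc[animate], np.abs(true["animacy"])[animate])
    assert rho == pytest.approx(-1.0)
    # decoupled category: constant RT
    assert per_stim.loc[inanimate].std() == pytest.approx(0.0)


def test_behavior_trial_counts_and_floor(design):
    cfg = SyntheticConfig(n_subjects=2, grid_shape=(8, 5, 5), region_voxels=30, seed=2)
    _, true = generate_patterns(design, cfg)
    trials = generate_behavior(design, task_true_distances(true), cfg)
    counts = trials.groupby(["subject", "task", "stimulus_id"]).size()
    assert set(counts) == {cfg.n_runs_per_task * cfg.n_repeats_per_run}
    assert set(trials["task"]) == {"animacy", "shape", "crisscross"}
    assert (trials["rt_ms"] >= RT_FLOOR_MS).all()


def test_behavior_deterministic_and_seed_sensitive(design):
    cfg = SyntheticConfig(n_subjects=1, grid_shape=(8, 5, 5), region_voxels=30, seed=2)
    _, true = generate_patterns(design, cfg)
    t1 = generate_behavior(design, {"animacy": true["animacy"]}, cfg)
    t2 = generate_behavior(design, {"animacy": true["animacy"]}, cfg)
    pd.testing.assert_frame_equal(t1, t2)


def test_accuracy_link_couples_with_distance(design):
    cfg = SyntheticConfig(
        n_subjects=8, grid_shape=(8, 5, 5), region_voxels=30, seed=3,
        asymmetry={"animate": 1.0, "inanimate": 1.0}, accuracy_link_scale=2.5,
    )
    _, true = generate_patterns(design, cfg)
    trials = generate_behavior(design, {"animacy": true["animacy"]}, cfg)
    acc = trials.groupby("stimulus_id")["correct"].mean()
    r, _ = stats.pearsonr(acc, np.abs(true["animacy"]))
    assert r > 0.3


def test_missing_distance_rejected(design):
    cfg = SyntheticConfig(n_subjects=1, grid_shape=(8, 5, 5), region_voxels=30)
    with pytest.raises(ValueError):
        generate_behavior(design, {"animacy": np.zeros(5)}, cfg)


def test_region_layout_validation(design):
    cfg = SyntheticConfig(
        grid_shape=(8, 5, 5),
        region_layout={"loc_like": np.arange(10), "evc_like": np.arange(5, 15)},
    )
    with pytest.raises(ValueError, match="disjoint"):
        cfg.validate()
    cfg = SyntheticConfig(
        grid_shape=(8, 5, 5),
        region_layout={"evc_like": np.arange(10)},  # loc_like missing
    )
    with pytest.raises(ValueError, match="empty layout"):
        cfg.validate()


def test_default_regions_disjoint_and_sized():
    layout = default_region_layout((18, 11, 11), 150)
    assert len(layout["evc_like"]) == len(layout["loc_like"]) == 150
    assert not np.intersect1d(layout["evc_like"], layout["loc_like"]).size


def test_images_encode_shape_not_animacy(design):
    images = generate_images(design, size=128, seed=1)
    assert images.shape == (32, 128, 128)
    assert images.min() >= 0.0 and images.max() <= 1.0
    shapes = design.labels("shape")
    for i in range(32):
        rows, cols = np.nonzero(images[i] > 0)
        aspect = (cols.max() - cols.min() + 1) / (rows.max() - rows.min() + 1)
        if shapes[i] == "bar":
            assert aspect > 2.0
        else:
            assert aspect < 1.5
    np.testing.assert_array_equal(images, generate_images(design, size=128, seed=1))
    with pytest.raises(ValueError):
        generate_images(design, size=32, seed=1)
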