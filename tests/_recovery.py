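"""Scaled-down parameter-recovery replicates shared by the heavier tests.

Each replicate generates a small pattern + behavior dataset, takes the
planted regions as the analysis ROIs (the searchlight step is validated
separately), computes cross-validated boundary distances per subject, and
correlates them with the group LISAS vector. Small voxel grids keep a single
replicate in the ~0.2 s range so Monte-Carlo loops stay cheap.
"""

from __future__ import annotations

import numpy as np

from ndba.analysis import (
    category_asymmetry_test,
    correlate_distance_behavior,
    crisscross_distance,
    group_inference,
)
from ndba.behavior import aggregate, group_behavior_vector
from ndba.design import DIMENSION_CLASSES, generate_design
from ndba.lda import (
    crossval_distance_matrix,
    crossval_distances,
    dataset_samples,
    kfold_split,
)
from ndba.reliability import balanced_splits, joint_estimate
from ndba.synth import (
    SyntheticConfig,
    generate_behavior,
    generate_patterns,
    task_true_distances,
)

DESIGN = generate_design()

SMALL_GRID = (10, 5, 5)
SMALL_REGION = 40


def small_config(seed: int, **overrides) -> SyntheticConfig:
    base = dict(
        n_subjects=8,
        grid_shape=SMALL_GRID,
        region_voxels=SMALL_REGION,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def roi_distances(ds, labels, roi_idx, run_subset=None, n_folds=5, seed=0):
    """Fold-averaged correct-side distances restricted to an ROI / run subset."""
    runs_sel = list(range(ds.n_runs)) if run_subset is None else list(run_subset)
    sub = ds.values[:, runs_sel, :][:, :, roi_idx]
    X, stim, runs = dataset_samples(sub)
    y = labels[stim]
    folds = kfold_split(
        y, runs=runs if len(runs_sel) > 1 else None, n_folds=n_folds, seed=seed
    )
    return crossval_distances(X, y, stim, folds).values


def roi_distance_matrix(ds, labels, roi_idx, n_folds=5, seed=0):
    """Held-out correct-side distances per [stimulus x run] for one subject."""
    X, stim, runs = dataset_samples(ds.values[:, :, roi_idx])
    y = labels[stim]
    folds = kfold_split(y, runs=runs, n_folds=n_folds, seed=seed)
    return crossval_distance_matrix(X, y, stim, runs, folds)[2]


def ndba_replicate(seed: int, task: str = "animacy", **config_overrides) -> dict:
    """One scaled replicate of the distance-behavior analysis for one task.

    Returns per-category group statistics plus the paired asymmetry test,
    using the planted region of the task's dimension as the ROI (and both
    regions for the crisscross task's combined predictor).
    """
    cfg = small_config(seed, **config_overrides)
    datasets, true = generate_patterns(DESIGN, cfg)
    trials = generate_behavior(
        DESIGN, {task: task_true_distances(true)[task]}, cfg
    )
    agg = aggregate(trials)
    scores = group_behavior_vector(agg, task)
    regions = cfg.regions()
    preds = {}
    for ds in datasets:
        subj_seed = int(ds.subject_id[-2:])
        if task == "crisscross":
            d_anim = roi_distances(
                ds, DESIGN.labels("animacy"), regions["loc_like"], seed=subj_seed
            )
            d_shape = roi_distances(
                ds, DESIGN.labels("shape"), regions["evc_like"], seed=subj_seed + 100
            )
            preds[ds.subject_id] = {
                "combined": crisscross_distance(d_anim, d_shape),
                "animacy": d_anim,
                "shape": d_shape,
            }
        else:
            region = "loc_like" if task == "animacy" else "evc_like"
            preds[ds.subject_id] = {
                task: roi_distances(ds, DESIGN.labels(task), regions[region], seed=subj_seed)
            }
    out = {
        "scores": scores,
        "predictors": preds,
        "config": cfg,
        "datasets": datasets,
        "trials": trials,
    }
    key = "combined" if task == "crisscross" else task
    cat_rs = {}
    for category in DIMENSION_CLASSES[task]:
        subset = DESIGN.category_members(task, category)
        rs = correlate_distance_behavior(
            {s: p[key] for s, p in preds.items()}, scores, subset=subset
        )
        mean_r, t, df, p = group_inference(rs)
        cat_rs[category] = rs
        out[category] = {"mean_r": mean_r, "t": t, "p": p}
    neg, pos = DIMENSION_CLASSES[task]
    t_d, p_d = category_asymmetry_test(cat_rs[pos], cat_rs[neg])
    out["asymmetry"] = {"t": t_d, "p": p_d}
    return out


def replicate_reliability(seed: int, task: str = "animacy", n_folds: int = 5, **config_overrides) -> dict:
    """Group mean r and its joint-reliability ceiling for one scaled replicate."""
    rep = ndba_replicate(seed, task=task, **config_overrides)
    cfg = rep["config"]
    regions = cfg.regions()
    region = "loc_like" if task == "animacy" else "evc_like"
    run_ids = list(range(cfg.n_runs_per_task))
    rng = np.random.default_rng(seed + 1)
    splits = balanced_splits(run_ids, 100, rng)

    trials = rep["trials"]
    r_beh = []
    for first, second in splits:
        halves = []
        for half in (first, second):
            agg_h = aggregate(trials[trials["run"].isin(half)])
            halves.append(group_behavior_vector(agg_h, task).to_numpy())
        a, b = halves
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3 and a[ok].std() > 0 and b[ok].std() > 0:
            r_beh.append(np.corrcoef(a[ok], b[ok])[0, 1])

    labels = DESIGN.labels(task)
    r_neu = []
    for ds in rep["datasets"]:
        matrix = roi_distance_matrix(
            ds, labels, regions[region], n_folds=n_folds, seed=int(ds.subject_id[-2:])
        )
        for first, second in splits:
            pair = [
                matrix[:, list(first)].mean(axis=1),
                matrix[:, list(second)].mean(axis=1),
            ]
            if np.std(pair[0]) > 0 and np.std(pair[1]) > 0:
                r_neu.append(np.corrcoef(pair[0], pair[1])[0, 1])

    est = joint_estimate(
        float(np.mean(r_beh)),
        float(np.mean(r_neu)),
        len(splits),
        split_sizes=(len(splits[0][0]), len(splits[0][1])),
        n_units=len(run_ids),
    )
    rs = correlate_distance_behavior(
        {ds.subject_id: rep["predictors"][ds.subject_id][task] for ds in rep["datasets"]},
        rep["scores"],
    )
    mean_r = float(rs.mean())
    return {"mean_r": mean_r, "joint": est.joint, "estimate": est}
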