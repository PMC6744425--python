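"""End-to-end orchestration: simulate -> decode -> score -> correlate -> ceiling.

Stage order: synthetic generation (patterns, behavior, images), GIST
descriptor control, behavior scoring (exclusions, LISAS, group vectors),
searchlight decoding with FDR and top-voxel ROI selection per dimension,
cross-validated boundary distances per ROI, distance-behavior correlation per
ROI x task x category with group inference and category-asymmetry tests, and
split-half joint-reliability ceilings per cell.

Everything is a pure function of the run configuration and its root seed;
rerunning with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .analysis import (
    NdbaResult,
    category_asymmetry_test,
    correlate_distance_behavior,
    crisscross_distance,
    group_inference,
    percentile_scale,
)
from .behavior import aggregate, exclude_chance_subjects, group_behavior_vector, rt_accuracy_coupling
from .design import DIMENSION_CLASSES, TASK_DIMENSION, TASKS, StimulusDesign, generate_design
from .gist import compute_gist_batch, crossdecode_descriptors
from .lda import crossval_distance_matrix, crossval_distances, dataset_samples, kfold_split
from .reliability import ReliabilityEstimate, balanced_splits, joint_estimate
from .searchlight import (
    EmptyRoiError,
    build_neighborhoods,
    group_significance,
    run_searchlight,
    select_top_voxels,
)
from .synth import (
    SyntheticConfig,
    generate_behavior,
    generate_images,
    generate_patterns,
    substream,
    task_true_distances,
)

STAGES = ("simulate", "gist", "behavior", "searchlight", "distances", "ndba", "reliability")

#: searchlight dimension -> name of the ROI it defines (the planted layout
#: localizes animacy in a high-level "LOC-like" block and shape in a low-level
#: "EVC-like" block, mirroring where each dimension is typically decodable)
ROI_OF_DIMENSION = {"animacy": "loc_like", "shape": "evc_like"}
DIMENSION_OF_ROI = {v: k for k, v in ROI_OF_DIMENSION.items()}


@dataclass
class RunConfig:
    """Analysis settings; defaults reproduce the method's stated settings
    (k=100 neighborhoods, FDR threshold 0.005, top 10% voxels, 4/5 split)."""

    mode: str = "synthetic"
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    k_neighbors: int = 100
    q_threshold: float = 0.005
    top_fraction: float = 0.10
    n_folds: int = 5
    shrinkage: float | str = "auto"
    rt_basis: str = "correct-only"
    percentile_scope: str = "all"  # percentile-scale over all stimuli or per category
    n_splits: int = 100
    run_gist: bool = True
    write_nifti: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode != "synthetic":
            raise ValueError("only synthetic mode is implemented")
        if self.percentile_scope not in ("all", "category"):
            raise ValueError("percentile_scope must be 'all' or 'category'")
        self.synth = dataclasses.replace(self.synth, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["grid_shape"] = list(d["synth"]["grid_shape"])
        if d["synth"]["region_layout"] is not None:
            d["synth"]["region_layout"] = {
                k: np.asarray(v).tolist() for k, v in d["synth"]["region_layout"].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        if "grid_shape" in synth:
            synth["grid_shape"] = tuple(synth["grid_shape"])
        if synth.get("region_layout"):
            synth["region_layout"] = {
                k: np.asarray(v, dtype=int) for k, v in synth["region_layout"].items()
            }
        return cls(synth=SyntheticConfig(**synth), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict
    warnings: list
    output_files: list

    def to_json(self) -> str:
        return json.dumps(
            dataclasses.asdict(self), sort_keys=True, indent=1, default=_json_default
        )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    return str(obj)


def _fold_seed(root_seed: int, name: str, index: int = 0) -> int:
    return int(substream(root_seed, name, index).integers(2**31))


def _distances_for_runs(
    values: np.ndarray,
    labels: np.ndarray,
    run_subset: list[int],
    n_folds: int,
    shrinkage,
    seed: int,
) -> np.ndarray:
    """Fold-averaged correct-side distances from a subset of runs."""
    sub = values[:, run_subset, :]
    X, stim, runs = dataset_samples(sub)
    y = labels[stim]
    folds = kfold_split(
        y, runs=runs if len(run_subset) > 1 else None, n_folds=n_folds, seed=seed
    )
    return crossval_distances(X, y, stim, folds, shrinkage=shrinkage).values


def _distance_matrix(
    values: np.ndarray, labels: np.ndarray, n_folds: int, shrinkage, seed: int
) -> np.ndarray:
    """Held-out correct-side distances per [stimulus x run] for one subject."""
    X, stim, runs = dataset_samples(values)
    y = labels[stim]
    folds = kfold_split(y, runs=runs, n_folds=n_folds, seed=seed)
    _, _, matrix = crossval_distance_matrix(X, y, stim, runs, folds, shrinkage=shrinkage)
    return matrix


def _cell_predictor(
    dists: dict[str, np.ndarray], task: str, scope: str, design: StimulusDesign
) -> np.ndarray:
    """Full-length predictor vector for one ROI and task.

    Single-dimension tasks use that dimension's distances directly; the
    crisscross task uses the percentile-summed combination, scaled either
    across all stimuli (default) or within each category.
    """
    if task in ("animacy", "shape"):
        return dists[task]
    if scope == "all":
        return crisscross_distance(dists["animacy"], dists["shape"])
    combined = np.empty(design.n_stimuli)
    for category in DIMENSION_CLASSES[TASK_DIMENSION[task]]:
        subset = design.category_members(TASK_DIMENSION[task], category)
        combined[subset] = percentile_scale(dists["animacy"][subset]) + percentile_scale(
            dists["shape"][subset]
        )
    return combined


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    last_stage: str = "reliability",
) -> RunReport:
    """Run the pipeline through ``last_stage`` and return the run report.

    A failure confined to one ROI x task combination (e.g. an empty ROI) is
    recorded as a warning and that cell is skipped, not fatal.
    """
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}")
    n_stages = STAGES.index(last_stage) + 1
    active = set(STAGES[:n_stages])
    cfg = config
    report_warnings: list[str] = []
    stages: dict = {}
    outputs: list[str] = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---- simulate -------------------------------------------------------
    design = generate_design()
    datasets, true_dims = generate_patterns(design, cfg.synth)
    trials = generate_behavior(design, task_true_distances(true_dims), cfg.synth)
    images = generate_images(design, cfg.synth.image_size, seed=cfg.synth.seed)
    stages["simulate"] = {
        "n_subjects": cfg.synth.n_subjects,
        "n_stimuli": design.n_stimuli,
        "n_runs": cfg.synth.n_runs_per_task,
        "n_voxels": cfg.synth.n_voxels,
        "n_trials": int(len(trials)),
        "region_layout": {k: v for k, v in cfg.synth.regions().items()},
    }
    if out is not None:
        from . import io as ndba_io

        outputs.append(str(ndba_io.save_design_json(design, out / "design.json")))
        outputs.append(str(ndba_io.save_behavior_csv(trials, out / "behavior.csv")))
        if cfg.write_nifti:
            for ds in datasets:
                outputs.append(
                    str(ndba_io.save_patterns_nifti(ds, out / f"{ds.subject_id}_patterns.nii.gz"))
                )
            outputs += [str(p) for p in ndba_io.save_images_png(images, out / "images")]

    # ---- gist control ---------------------------------------------------
    if "gist" in active and cfg.run_gist:
        descriptors = compute_gist_batch(images)
        gist_stage = {}
        for dim in ("shape", "animacy"):
            mean_acc, folds = crossdecode_descriptors(descriptors, design, dim)
            gist_stage[dim] = {"mean_accuracy": mean_acc, "fold_accuracies": folds}
        stages["gist"] = gist_stage
        if out is not None:
            desc_df = pd.DataFrame(descriptors)
            desc_df.insert(0, "stimulus_id", design.stimulus_id)
            desc_df.to_csv(out / "gist_descriptors.csv", index=False, float_format="%.8g")
            outputs.append(str(out / "gist_descriptors.csv"))

    # ---- behavior -------------------------------------------------------
    group_scores: dict[str, pd.Series] = {}
    kept: list[str] = []
    if "behavior" in active:
        kept, excluded, exclusion_records = exclude_chance_subjects(trials)
        if excluded:
            report_warnings.append(f"excluded at-chance subjects: {excluded}")
        if not kept:
            report_warnings.append(
                "all subjects at chance: behavior and downstream stages skipped"
            )
            stages["behavior"] = {"kept_subjects": [], "excluded_subjects": excluded}
            active -= {"behavior", "searchlight", "distances", "ndba", "reliability"}
    if "behavior" in active:
        kept_trials = trials[trials["subject"].isin(kept)]
        agg = aggregate(kept_trials, rt_basis=cfg.rt_basis)
        beh_stage = {"kept_subjects": kept, "excluded_subjects": excluded, "tasks": {}}
        for task in TASKS:
            group_scores[task] = group_behavior_vector(agg, task, subjects=kept)
            cell = kept_trials[kept_trials["task"] == task]
            per_subj_acc = cell.groupby("subject")["correct"].mean()
            per_subj_med = cell.groupby("subject")["rt_ms"].median()
            try:
                _, mean_r, t, p = rt_accuracy_coupling(agg, task)
                coupling = {"mean_r": mean_r, "t": t, "p": p}
            except ValueError as exc:
                coupling = {"error": str(exc)}
            beh_stage["tasks"][task] = {
                "mean_accuracy": float(per_subj_acc.mean()),
                "sd_accuracy": float(per_subj_acc.std(ddof=1)),
                "median_rt_ms": float(per_subj_med.median()),
                "rt_error_coupling": coupling,
            }
        stages["behavior"] = beh_stage
        if out is not None:
            agg.to_csv(out / "behavior_aggregated.csv", index=False, float_format="%.6f")
            exclusion_records.to_csv(out / "exclusions.csv", index=False, float_format="%.6g")
            outputs += [str(out / "behavior_aggregated.csv"), str(out / "exclusions.csv")]

    # ---- searchlight ----------------------------------------------------
    rois: dict[str, np.ndarray | None] = {}
    if "searchlight" in active and len(kept) < 2:
        report_warnings.append("fewer than 2 subjects: searchlight group test skipped")
        active -= {"searchlight", "distances", "ndba", "reliability"}
    if "searchlight" in active:
        kept_idx = [i for i, ds in enumerate(datasets) if ds.subject_id in kept]
        coords = datasets[0].voxel_coords
        neighborhoods = build_neighborhoods(coords, k=cfg.k_neighbors)
        sl_stage = {}
        for dim in ("animacy", "shape"):
            labels = design.labels(dim)
            maps = np.stack(
                [
                    run_searchlight(
                        datasets[i], labels, neighborhoods, shrinkage=cfg.shrinkage
                    )
                    for i in kept_idx
                ]
            )
            result = group_significance(maps, q_threshold=cfg.q_threshold)
            group_mean = np.nanmean(maps, axis=0)
            roi_name = ROI_OF_DIMENSION[dim]
            try:
                roi = select_top_voxels(
                    group_mean, result.significant_mask, coords, fraction=cfg.top_fraction
                )
            except EmptyRoiError:
                roi = None
                report_warnings.append(
                    f"no significant {dim} decoding: empty ROI, NDBA skipped for {roi_name}"
                )
            rois[roi_name] = roi
            # synthetic-mode diagnostic: mean accuracy at background centers,
            # i.e. voxels more than two neighborhood radii from any voxel of
            # the region(s) planted with this dimension's signal
            bg_mean = float("nan")
            planted_regions = [
                r for r, dd in cfg.synth.signal_sd.items() if dd.get(dim, 0) > 0
            ]
            if planted_regions:
                planted_idx = np.concatenate(
                    [cfg.synth.regions()[r] for r in planted_regions]
                )
                center_nb = neighborhoods[len(neighborhoods) // 2]
                radius = np.linalg.norm(
                    coords[center_nb.members] - coords[center_nb.center], axis=1
                ).max()
                d_to_planted = np.min(
                    np.linalg.norm(
                        coords[:, None, :].astype(float) - coords[planted_idx][None, :, :],
                        axis=2,
                    ),
                    axis=1,
                )
                background = d_to_planted > 2 * radius
                if background.any():
                    bg_mean = float(np.nanmean(group_mean[background]))
            sl_stage[dim] = {
                "background_mean_accuracy": bg_mean,
                "roi": roi_name,
                "n_significant": int(result.significant_mask.sum()),
                "roi_size": int(roi.sum()) if roi is not None else 0,
                "roi_voxels": np.flatnonzero(roi).tolist() if roi is not None else [],
                "significant_voxels": np.flatnonzero(result.significant_mask).tolist(),
                "mean_accuracy_in_roi": (
                    float(np.nanmean(group_mean[roi])) if roi is not None else float("nan")
                ),
            }
            if out is not None and cfg.write_nifti:
                from . import io as ndba_io

                for name, vals in (
                    (f"searchlight_{dim}_accuracy", group_mean),
                    (f"searchlight_{dim}_q", result.q_map),
                ):
                    outputs.append(
                        str(ndba_io.save_map_nifti(vals, coords, out / f"{name}.nii.gz"))
                    )
        stages["searchlight"] = sl_stage

    # ---- distances ------------------------------------------------------
    # correct-side distances per ROI x classifier dimension x subject; the
    # per-run distance components are kept for split-half reliability
    distances: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    dist_matrices: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    if "distances" in active:
        kept_ds = [ds for ds in datasets if ds.subject_id in kept]
        for roi_name, roi in rois.items():
            if roi is None:
                continue
            roi_idx = np.flatnonzero(roi)
            distances[roi_name] = {}
            dist_matrices[roi_name] = {}
            for dim in ("animacy", "shape"):
                labels = design.labels(dim)
                per_subj = {}
                per_subj_mat = {}
                for ds in kept_ds:
                    seed = _fold_seed(cfg.seed, f"folds/{roi_name}/{dim}", int(ds.subject_id[-2:]))
                    matrix = _distance_matrix(
                        ds.values[:, :, roi_idx], labels, cfg.n_folds, cfg.shrinkage, seed
                    )
                    per_subj_mat[ds.subject_id] = matrix
                    per_subj[ds.subject_id] = matrix.mean(axis=1)
                distances[roi_name][dim] = per_subj
                dist_matrices[roi_name][dim] = per_subj_mat
        stages["distances"] = {
            roi: {dim: {s: v for s, v in subj.items()} for dim, subj in dd.items()}
            for roi, dd in distances.items()
        }

    # ---- ndba -----------------------------------------------------------
    cells: list[NdbaResult] = []
    asymmetry_rows = []
    if "ndba" in active:
        for roi_name in sorted(distances):
            for task in TASKS:
                task_dim = TASK_DIMENSION[task]
                cat_labels = DIMENSION_CLASSES[task_dim]
                subjects = sorted(distances[roi_name]["animacy"])
                cat_rs = {}
                for category in cat_labels:
                    subset = design.category_members(task_dim, category)
                    preds = {
                        s: _cell_predictor(
                            {d: distances[roi_name][d][s] for d in ("animacy", "shape")},
                            task,
                            cfg.percentile_scope,
                            design,
                        )
                        for s in subjects
                    }
                    rs = correlate_distance_behavior(preds, group_scores[task], subset=subset)
                    mean_r, t, df, p = group_inference(rs)
                    cat_rs[category] = rs
                    cells.append(
                        NdbaResult(
                            roi=roi_name,
                            task=task,
                            category=category,
                            per_subject_r=rs,
                            mean_r=mean_r,
                            t=t,
                            df=df,
                            p=p,
                        )
                    )
                try:
                    t_diff, p_diff = category_asymmetry_test(
                        cat_rs[cat_labels[1]], cat_rs[cat_labels[0]]
                    )
                    asymmetry_rows.append(
                        {
                            "roi": roi_name,
                            "task": task,
                            "category_a": cat_labels[1],
                            "category_b": cat_labels[0],
                            "t": t_diff,
                            "p": p_diff,
                        }
                    )
                except ValueError as exc:
                    report_warnings.append(f"asymmetry test failed for {roi_name}/{task}: {exc}")

    # ---- reliability ----------------------------------------------------
    reliability: dict[tuple[str, str, str], ReliabilityEstimate] = {}
    if "reliability" in active and cells:
        run_ids = list(range(cfg.synth.n_runs_per_task))
        rng = np.random.default_rng(_fold_seed(cfg.seed, "reliability"))
        splits = balanced_splits(run_ids, cfg.n_splits, rng)
        kept_trials = trials[trials["subject"].isin(kept)]

        beh_halves: dict[str, list[tuple[pd.Series, pd.Series]]] = {}
        for task in TASKS:
            halves = []
            for first, second in splits:
                vecs = []
                for half_runs in (first, second):
                    sub = kept_trials[
                        (kept_trials["task"] == task)
                        & (kept_trials["run"].isin(half_runs))
                    ]
                    agg_half = aggregate(sub, rt_basis=cfg.rt_basis)
                    vecs.append(group_behavior_vector(agg_half, task, subjects=kept))
                halves.append((vecs[0], vecs[1]))
            beh_halves[task] = halves

        # neural halves: run-subset means of the full cross-validation's
        # per-run distance components (same estimation regime as the full
        # vector, so the Spearman-Brown length assumption applies)
        neural_halves: dict[str, dict[str, dict[str, list]]] = {}
        for roi_name in sorted(distances):
            neural_halves[roi_name] = {}
            for dim in ("animacy", "shape"):
                per_subj = {}
                for subject, matrix in dist_matrices[roi_name][dim].items():
                    per_subj[subject] = [
                        (
                            matrix[:, list(first)].mean(axis=1),
                            matrix[:, list(second)].mean(axis=1),
                        )
                        for first, second in splits
                    ]
                neural_halves[roi_name][dim] = per_subj

        for cell in cells:
            task_dim = TASK_DIMENSION[cell.task]
            subset = design.category_members(task_dim, cell.category)
            r_beh = []
            for vec_a, vec_b in beh_halves[cell.task]:
                a = vec_a.reindex(subset).to_numpy(dtype=float)
                b = vec_b.reindex(subset).to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() >= 3 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
                    r_beh.append(stats.pearsonr(a[ok], b[ok])[0])
            r_neu = []
            for subject, halves in neural_halves[cell.roi]["animacy"].items():
                for si in range(len(splits)):
                    pair = []
                    for hi in range(2):
                        dists = {
                            d: neural_halves[cell.roi][d][subject][si][hi]
                            for d in ("animacy", "shape")
                        }
                        pair.append(
                            _cell_predictor(
                                dists, cell.task, cfg.percentile_scope, design
                            )[subset]
                        )
                    if np.std(pair[0]) > 0 and np.std(pair[1]) > 0:
                        r_neu.append(stats.pearsonr(pair[0], pair[1])[0])
            if not r_beh or not r_neu:
                report_warnings.append(
                    f"reliability undefined for {cell.roi}/{cell.task}/{cell.category}"
                )
                continue
            est = joint_estimate(
                float(np.mean(r_beh)),
                float(np.mean(r_neu)),
                len(splits),
                split_sizes=(len(splits[0][0]), len(splits[0][1])),
                n_units=len(run_ids),
            )
            reliability[(cell.roi, cell.task, cell.category)] = est
            cell.joint_reliability = est.joint

    # ---- assemble -------------------------------------------------------
    if cells:
        stages["ndba"] = {
            "cells": [
                {
                    "roi": c.roi,
                    "task": c.task,
                    "category": c.category,
                    "mean_r": c.mean_r,
                    "t": c.t,
                    "df": c.df,
                    "p": c.p,
                    "joint_reliability": c.joint_reliability,
                }
                for c in cells
            ],
            "asymmetry": asymmetry_rows,
        }
        if reliability:
            stages["reliability"] = {
                "/".join(k): {
                    "r_full_behavior": est.r_full_behavior,
                    "r_full_neural": est.r_full_neural,
                    "joint": est.joint,
                    "n_splits": est.n_splits,
                }
                for k, est in reliability.items()
            }
        if out is not None:
            tidy = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "roi": c.roi,
                            "task": c.task,
                            "category": c.category,
                            "subject": c.per_subject_r.index,
                            "r": c.per_subject_r.values,
                        }
                    )
                    for c in cells
                ],
                ignore_index=True,
            )
            tidy.to_csv(out / "results.csv", index=False, float_format="%.8f")
            summary = pd.DataFrame(
                [
                    {
                        "roi": c.roi,
                        "task": c.task,
                        "category": c.category,
                        "mean_r": c.mean_r,
                        "t": c.t,
                        "df": c.df,
                        "p": c.p,
                        "joint_reliability": c.joint_reliability,
                    }
                    for c in cells
                ]
            )
            summary.to_csv(out / "summary.csv", index=False, float_format="%.8f")
            pd.DataFrame(asymmetry_rows).to_csv(
                out / "asymmetry.csv", index=False, float_format="%.8f"
            )
            outputs += [
                str(out / "results.csv"),
                str(out / "summary.csv"),
                str(out / "asymmetry.csv"),
            ]
    elif "ndba" in active and not distances:
        stages["ndba"] = {"cells": [], "asymmetry": []}

    report = RunReport(
        config=cfg.to_dict(),
        version=__version__,
        stages=stages,
        warnings=report_warnings,
        output_files=outputs,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report
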