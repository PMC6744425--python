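"""Standard-format readers and writers: NIfTI volumes, CSV tables, JSON design.

Pattern datasets are written as a 4-D NIfTI image (one 3-D volume per
stimulus x run, stimulus-major) on a 3 mm isotropic grid, with a JSON sidecar
carrying the subject id, the design labels, and the volume ordering. Behavior
travels as the trial CSV schema (subject, task, run, stimulus_id, rt_ms,
correct). All round trips are lossless to float64 precision for values and
exact for labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .behavior import TRIAL_COLUMNS, validate_trials
from .design import StimulusDesign
from .synth import PatternDataset

VOXEL_MM = 3.0


def save_patterns_nifti(dataset: PatternDataset, path: str | Path) -> Path:
    """Write a PatternDataset as 4-D NIfTI plus a JSON sidecar."""
    path = Path(path)
    coords = dataset.voxel_coords
    shape = tuple(coords.max(axis=0) - coords.min(axis=0) + 1)
    origin = coords.min(axis=0)
    S, R, V = dataset.values.shape
    vol = np.full(shape + (S * R,), np.nan)
    ix, iy, iz = (coords - origin).T
    for s in range(S):
        for r in range(R):
            vol[ix, iy, iz, s * R + r] = dataset.values[s, r]
    img = nib.Nifti1Image(vol, affine=np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0]))
    nib.save(img, path)
    sidecar = {
        "subject_id": dataset.subject_id,
        "n_stimuli": S,
        "n_runs": R,
        "volume_order": "stimulus-major",
        "voxel_coords": coords.tolist(),
        "design": json.loads(dataset.design.to_json()),
    }
    sidecar_path = path.with_suffix("").with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar))
    return path


def load_patterns_nifti(path: str | Path) -> PatternDataset:
    path = Path(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    img = nib.load(path)
    vol = np.asarray(img.dataobj, dtype=float)
    coords = np.asarray(sidecar["voxel_coords"], dtype=int)
    origin = coords.min(axis=0)
    ix, iy, iz = (coords - origin).T
    S, R = sidecar["n_stimuli"], sidecar["n_runs"]
    values = np.empty((S, R, coords.shape[0]))
    for s in range(S):
        for r in range(R):
            values[s, r] = vol[ix, iy, iz, s * R + r]
    design = StimulusDesign.from_json(json.dumps(sidecar["design"]))
    return PatternDataset(
        subject_id=sidecar["subject_id"],
        values=values,
        voxel_coords=coords,
        design=design,
    )


def save_map_nifti(
    values: np.ndarray, voxel_coords: np.ndarray, path: str | Path
) -> Path:
    """Write a per-voxel statistic map (accuracy/p/q/mask) as 3-D NIfTI."""
    path = Path(path)
    coords = np.asarray(voxel_coords, dtype=int)
    origin = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - origin + 1)
    vol = np.full(shape, np.nan)
    ix, iy, iz = (coords - origin).T
    vol[ix, iy, iz] = np.asarray(values, dtype=float)
    nib.save(nib.Nifti1Image(vol, affine=np.diag([VOXEL_MM] * 3 + [1.0])), path)
    return path


def save_behavior_csv(trials: pd.DataFrame, path: str | Path) -> Path:
    validate_trials(trials)
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.6f")
    return path


def load_behavior_csv(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    validate_trials(trials)
    trials["correct"] = trials["correct"].astype(bool)
    return trials


def save_design_json(design: StimulusDesign, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(design.to_json())
    return path


def load_design_json(path: str | Path) -> StimulusDesign:
    return StimulusDesign.from_json(Path(path).read_text())


def save_images_png(images: np.ndarray, outdir: str | Path) -> list[Path]:
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        p = outdir / f"stimulus-{i:03d}.png"
        iio.imwrite(p, (np.clip(img, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


def load_image_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img / 255.0
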