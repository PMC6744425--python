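"""Synthetic study generator: voxel patterns, behavior, and stimulus images.

Emulates an event-related categorization study: S stimuli in four clusters
crossing animacy and shape (plus a crisscrossing indoor/outdoor grouping),
scanned over ``n_runs_per_task`` runs with ``n_repeats_per_run`` presentations
per stimulus per run. Voxel patterns are beta-like per-run estimates with
spatially localized category signal: an animacy signal planted in a compact
"LOC-like" voxel block and a shape signal in an "EVC-like" block, embedded in
uninformative background noise.

Behavior follows the distance-to-bound rationale: a stimulus's reaction time
decreases linearly with its true (noise-free) distance from the planted
category boundary, and its accuracy increases with that distance through a
logistic link. Per-category slope multipliers allow one-sided (asymmetric)
coupling, e.g. coupling for animate stimuli only.

All generators are pure functions of (arguments, seed); every component draws
from a named substream of the root seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .design import DIMENSION_CLASSES, TASK_DIMENSION, TASKS, StimulusDesign

RT_FLOOR_MS = 150.0


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Deterministic named RNG substream of a root seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode()), int(index)])


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the simulated study conditions.

    ``signal_sd`` maps region -> {dimension: category mean shift} (the planted
    class separation along a region-local discriminant direction, in pattern
    units). ``asymmetry`` maps a category label to a multiplier in [0, 1] on
    the RT-distance slope; unlisted labels default to 1.
    """

    n_subjects: int = 8
    n_runs_per_task: int = 3
    n_repeats_per_run: int = 2
    grid_shape: tuple[int, int, int] = (18, 11, 11)
    region_voxels: int = 150
    region_layout: dict[str, np.ndarray] | None = None
    signal_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "loc_like": {"animacy": 4.0},
            "evc_like": {"shape": 4.0},
        }
    )
    exemplar_offset_sd: float = 0.5
    run_noise_sd: float = 1.0
    rt_intercept_ms: float = 900.0
    rt_slope_ms_per_distance: float = -60.0
    rt_noise_sd_ms: float = 150.0
    asymmetry: dict[str, float] = field(
        default_factory=lambda: {
            "animate": 1.0,
            "inanimate": 0.0,
            "indoor": 1.0,
            "outdoor": 0.0,
        }
    )
    accuracy_link_scale: float = 1.7
    image_size: int = 128
    seed: int = 0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_runs_per_task < 1 or self.n_repeats_per_run < 1:
            raise ValueError("subject/run/repeat counts must be >= 1")
        for name in ("exemplar_offset_sd", "rt_noise_sd_ms", "accuracy_link_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.run_noise_sd <= 0 or self.rt_intercept_ms <= 0:
            raise ValueError("run_noise_sd and rt_intercept_ms must be positive")
        for region, dims in self.signal_sd.items():
            for dim, a in dims.items():
                if a < 0:
                    raise ValueError("signal_sd entries must be nonnegative")
                if dim not in DIMENSION_CLASSES:
                    raise ValueError(f"unknown signal dimension {dim!r}")
        layout = self.regions()
        all_idx = np.concatenate([v for v in layout.values()]) if layout else np.array([])
        if len(all_idx) != len(np.unique(all_idx)):
            raise ValueError("region index sets must be disjoint")
        if len(all_idx) and (all_idx.min() < 0 or all_idx.max() >= self.n_voxels):
            raise ValueError("region indices out of range")
        for region, dims in self.signal_sd.items():
            if any(a > 0 for a in dims.values()) and (
                region not in layout or len(layout[region]) == 0
            ):
                raise ValueError(
                    f"nonzero signal_sd for region {region!r} with empty layout"
                )

    def regions(self) -> dict[str, np.ndarray]:
        """Resolved region layout (defaults to two compact blocks)."""
        if self.region_layout is not None:
            return {k: np.asarray(v, dtype=int) for k, v in self.region_layout.items()}
        return default_region_layout(self.grid_shape, self.region_voxels)


@dataclass
class PatternDataset:
    """Per-subject beta-like pattern estimates [stimulus x run x voxel]."""

    subject_id: str
    values: np.ndarray
    voxel_coords: np.ndarray  # (V, 3) integer grid coordinates, unique
    design: StimulusDesign

    def __post_init__(self) -> None:
        S, R, V = self.values.shape
        if S != self.design.n_stimuli:
            raise ValueError("stimulus axis length must match the design")
        if self.voxel_coords.shape != (V, 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern values must be finite")
        if len(np.unique(self.voxel_coords, axis=0)) != V:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]


def grid_coords(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """All voxel coordinates of a full grid, lexicographic in (x, y, z)."""
    nx, ny, nz = grid_shape
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)


def default_region_layout(
    grid_shape: tuple[int, int, int], region_voxels: int = 150
) -> dict[str, np.ndarray]:
    """Two disjoint compact blocks ("EVC-like" and "LOC-like") in the grid.

    Each block is the ``region_voxels`` nearest voxels to a center placed at
    a quarter / three quarters of the longest grid axis.
    """
    coords = grid_coords(grid_shape).astype(float)
    long_axis = int(np.argmax(grid_shape))
    c1 = (np.asarray(grid_shape, dtype=float) - 1) / 2.0
    c2 = c1.copy()
    c1[long_axis] = (grid_shape[long_axis] - 1) * 0.25
    c2[long_axis] = (grid_shape[long_axis] - 1) * 0.75
    layout = {}
    for name, center in (("evc_like", c1), ("loc_like", c2)):
        d = np.linalg.norm(coords - center, axis=1)
        order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2], d))
        layout[name] = np.sort(order[:region_voxels])
    if np.intersect1d(layout["evc_like"], layout["loc_like"]).size:
        raise ValueError("grid too small: default regions overlap")
    return layout


def generate_patterns(
    design: StimulusDesign, config: SyntheticConfig
) -> tuple[list[PatternDataset], dict[str, np.ndarray]]:
    """Generate per-subject pattern datasets plus the planted true distances.

    Pattern value = category mean shift along a region-local unit direction
    (one direction per dimension, drawn per subject) + a per-exemplar offset
    along that direction (shared across subjects and runs; this creates
    exemplar-level distance variation) + i.i.d. Gaussian run noise.

    Returns (datasets, true_distances) where ``true_distances[dim]`` is the
    per-stimulus signed distance from the planted boundary for that dimension
    (positive on a stimulus's own correct side for on-side exemplars).
    """
    config.validate()
    S = design.n_stimuli
    coords = grid_coords(config.grid_shape)
    V = config.n_voxels
    layout = config.regions()

    # planted amplitude per dimension (root-sum-square across regions)
    dims = sorted({d for dd in config.signal_sd.values() for d in dd})
    amp = {
        d: float(
            np.sqrt(
                sum(
                    config.signal_sd[r].get(d, 0.0) ** 2
                    for r in config.signal_sd
                )
            )
        )
        for d in dims
    }

    rng_ex = substream(config.seed, "exemplars")
    offsets = {d: rng_ex.normal(0.0, config.exemplar_offset_sd, size=S) for d in dims}
    true_distances = {
        d: design.class_sign(d) * amp[d] + offsets[d] for d in dims
    }

    datasets = []
    for subj in range(config.n_subjects):
        rng = substream(config.seed, "patterns", subj)
        mean = np.zeros((S, V))
        for d in dims:
            v = np.zeros(V)
            for region, dd in config.signal_sd.items():
                a = dd.get(d, 0.0)
                if a == 0.0:
                    continue
                idx = layout[region]
                # random-sign, equal-magnitude loading: every region voxel
                # carries the same information density
                u = rng.choice([-1.0, 1.0], size=len(idx))
                u /= np.linalg.norm(u)
                v[idx] += a * u
            norm = np.linalg.norm(v)
            if norm > 0:
                # signed exemplar distance maps onto the unit direction
                mean += np.outer(design.class_sign(d) * amp[d] + offsets[d], v / norm)
        noise = rng.normal(0.0, config.run_noise_sd, size=(S, config.n_runs_per_task, V))
        values = mean[:, None, :] + noise
        datasets.append(
            PatternDataset(
                subject_id=f"sub-{subj:02d}",
                values=values,
                voxel_coords=coords,
                design=design,
            )
        )
    return datasets, true_distances


def task_true_distances(
    true_distances: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-task planted distances driving behavior.

    The animacy and shape tasks use their own dimension's distance. The
    crisscross task uses the city-block combination (mean of the two absolute
    distances), since neither dimension alone separates indoor from outdoor.
    """
    out = {}
    if "animacy" in true_distances:
        out["animacy"] = true_distances["animacy"]
    if "shape" in true_distances:
        out["shape"] = true_distances["shape"]
    if "animacy" in true_distances and "shape" in true_distances:
        out["crisscross"] = 0.5 * (
            np.abs(true_distances["animacy"]) + np.abs(true_distances["shape"])
        )
    return out


def generate_behavior(
    design: StimulusDesign,
    true_distances: dict[str, np.ndarray],
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Trial-level behavior for every subject x task x run x repeat.

    RT = intercept + slope * asymmetry(category) * |true distance| + noise,
    truncated below at 150 ms. Correctness is Bernoulli with
    p(correct) = logistic(d_eff / accuracy_link_scale), which maps distance 0
    to chance (0.5) and large distances toward 1. The effective distance
    d_eff = asym * |d| + (1 - asym) * mean|d| interpolates between full
    distance dependence (asym = 1) and a flat category-typical accuracy
    (asym = 0), so the asymmetry multiplier gates both behavioral channels:
    a fully decoupled category has constant expected RT and accuracy.
    """
    config.validate()
    S = design.n_stimuli
    for task, dist in true_distances.items():
        if len(np.asarray(dist)) != S:
            raise ValueError(f"need one true distance per stimulus for task {task!r}")
    rows = []
    n_trials = config.n_runs_per_task * config.n_repeats_per_run
    for subj in range(config.n_subjects):
        subject = f"sub-{subj:02d}"
        for task in sorted(true_distances):
            rng = substream(config.seed, f"behavior/{task}", subj)
            dist = np.abs(np.asarray(true_distances[task], dtype=float))
            labels = design.labels(TASK_DIMENSION.get(task, task))
            mult = np.asarray([config.asymmetry.get(l, 1.0) for l in labels])
            mean_rt = (
                config.rt_intercept_ms
                + config.rt_slope_ms_per_distance * mult * dist
            )
            d_eff = mult * dist + (1.0 - mult) * dist.mean()
            p_correct = 1.0 / (1.0 + np.exp(-d_eff / max(config.accuracy_link_scale, 1e-12)))
            for run in range(config.n_runs_per_task):
                for _rep in range(config.n_repeats_per_run):
                    rt = np.maximum(
                        mean_rt + rng.normal(0.0, config.rt_noise_sd_ms, size=S),
                        RT_FLOOR_MS,
                    )
                    correct = rng.random(S) < p_correct
                    for s in range(S):
                        rows.append(
                            (subject, task, run, s, float(rt[s]), bool(correct[s]))
                        )
    trials = pd.DataFrame(
        rows, columns=["subject", "task", "run", "stimulus_id", "rt_ms", "correct"]
    )
    assert (
        trials.groupby(["subject", "task", "stimulus_id"]).size() == n_trials
    ).all()
    return trials


def generate_images(
    design: StimulusDesign, size: int = 128, seed: int = 0
) -> np.ndarray:
    """Greyscale stimulus images [S x size x size] in [0, 1].

    Bar-like stimuli are high-aspect-ratio ellipses (aspect 2.5-3.5), blob-like
    are near-circular (aspect 1.05-1.4). Orientation, position, intensity and
    texture jitter are drawn independently of cluster and animacy, so animacy
    is not image-recoverable by construction.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    S = design.n_stimuli
    images = np.zeros((S, size, size))
    shapes = design.labels("shape")
    for s in range(S):
        rng = substream(seed, "images", s)
        aspect = rng.uniform(2.5, 3.5) if shapes[s] == "bar" else rng.uniform(1.05, 1.4)
        area_radius = size * rng.uniform(0.26, 0.30)  # sqrt(major*minor)
        major = area_radius * np.sqrt(aspect)
        minor = area_radius / np.sqrt(aspect)
        angle = float(np.clip(rng.normal(0.0, 0.1), -0.25, 0.25))
        cy = size / 2 + rng.normal(0.0, size * 0.01)
        cx = size / 2 + rng.normal(0.0, size * 0.01)
        rr, cc = _draw_ellipse(
            cy, cx, minor, major, rotation=angle, shape=(size, size)
        )
        img = np.zeros((size, size))
        base = rng.uniform(0.55, 0.85)
        texture = rng.normal(0.0, 0.08, size=len(rr))
        img[rr, cc] = np.clip(base + texture, 0.05, 1.0)
        images[s] = img
    return images


def default_config(**overrides) -> SyntheticConfig:
    """The default simulated study conditions, with optional field overrides."""
    return replace(SyntheticConfig(), **overrides)
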