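"""Volume-based searchlight decoding, group inference with FDR, ROI selection.

Each voxel's "neighborhood" is its k nearest voxels (k=100 by default) by
Euclidean distance on the 3-D grid coordinates. An LDA classifier is trained
on the neighborhood's voxels under leave-one-run-out cross-validation and the
held-out accuracy is stored at the center voxel. Group significance is a
one-sample t-test of per-subject accuracies against chance at each voxel,
Benjamini-Hochberg FDR-adjusted across voxels; the analysis ROI is the top
fraction (default 10%) of highest group-mean accuracy voxels inside the
significant mask.

The per-neighborhood LDA fits are batched across neighborhoods (stacked
covariance solves) so whole-volume maps stay cheap on one core.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lda import leave_one_run_out


class EmptyRoiError(RuntimeError):
    """No significant decoding: the ROI would be empty and the analysis skipped."""


@dataclass
class Neighborhood:
    center: int
    members: np.ndarray  # includes the center; k nearest by grid distance


@dataclass
class SearchlightResult:
    accuracy_maps: np.ndarray  # (n_subjects, V)
    p_map: np.ndarray
    q_map: np.ndarray
    significant_mask: np.ndarray
    roi_mask: np.ndarray | None = None


def build_neighborhoods(voxel_coords: np.ndarray, k: int = 100) -> list[Neighborhood]:
    """k-nearest-neighbor searchlight neighborhoods, one per voxel.

    Ties in distance are broken by (z, y, x) lexicographic coordinate order
    so neighborhoods are deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = np.asarray(voxel_coords, dtype=float)
    V = coords.shape[0]
    if len(np.unique(coords, axis=0)) != V:
        raise ValueError("voxel coordinates must be unique")
    k = min(k, V)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    out = []
    for center in range(V):
        d = np.linalg.norm(coords - coords[center], axis=1)
        order = np.lexsort((x, y, z, d))
        out.append(Neighborhood(center=center, members=order[:k].copy()))
    return out


def _batched_lw_shrinkage(Xc: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage per neighborhood for centered [N, n, k] data."""
    N, n, k = Xc.shape
    S = np.einsum("nij,nil->njl", Xc, Xc) / n
    m = np.trace(S, axis1=1, axis2=2) / k
    eye = np.eye(k)
    d2 = np.sum((S - m[:, None, None] * eye) ** 2, axis=(1, 2)) / k
    sq_norms = np.sum(Xc**2, axis=2)  # (N, n)
    b2 = (np.sum(sq_norms**2, axis=1) / n - np.sum(S**2, axis=(1, 2))) / (n * k)
    b2 = np.clip(b2, 0.0, d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(d2 > 0, b2 / np.maximum(d2, 1e-300), 0.0)
    return rho, S, m


def _batched_fold_predictions(
    train: np.ndarray,
    y_train: np.ndarray,
    test: np.ndarray,
    members: np.ndarray,
    shrinkage: float | str,
) -> np.ndarray:
    """Decision values for test samples in every neighborhood of a chunk.

    train: (n_tr, V); test: (n_te, V); members: (N, k) voxel indices.
    Returns (N, n_te) decision values (positive -> class1).
    """
    n_tr = train.shape[0]
    mask1 = y_train.astype(bool)
    Xn = train[:, members]  # (n_tr, N, k)
    Xn = np.ascontiguousarray(np.swapaxes(Xn, 0, 1))  # (N, n_tr, k)
    mu0 = Xn[:, ~mask1].mean(axis=1)
    mu1 = Xn[:, mask1].mean(axis=1)
    Xc = Xn.copy()
    Xc[:, ~mask1] -= mu0[:, None, :]
    Xc[:, mask1] -= mu1[:, None, :]
    k = Xn.shape[2]
    eye = np.eye(k)
    if shrinkage == "auto":
        rho, S, m = _batched_lw_shrinkage(Xc)
    else:
        rho = np.full(Xn.shape[0], float(shrinkage))
        dof = max(n_tr - 2, 1)
        S = np.einsum("nij,nil->njl", Xc, Xc) / dof
        m = np.trace(S, axis1=1, axis2=2) / k
    Sigma = (1.0 - rho)[:, None, None] * S + (rho * m)[:, None, None] * eye
    diff = mu1 - mu0
    try:
        w = np.linalg.solve(Sigma, diff[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        w = np.stack([np.linalg.pinv(Sg) @ df for Sg, df in zip(Sigma, diff)])
    b = -np.einsum("nk,nk->n", w, (mu0 + mu1) / 2.0)
    Xt = test[:, members]  # (n_te, N, k)
    scores = np.einsum("ink,nk->ni", Xt, w) + b[:, None]
    return scores


def run_searchlight(
    dataset,
    labels: np.ndarray,
    neighborhoods: list[Neighborhood],
    scheme: str = "leave_one_run_out",
    shrinkage: float | str = "auto",
    chunk_size: int = 256,
) -> np.ndarray:
    """Per-voxel cross-validated decoding accuracy map for one subject.

    ``labels`` gives one binary class label per stimulus; samples are the
    per-run pattern estimates. Neighborhoods whose classifier cannot be fit
    yield NaN (with a warning) rather than aborting the map.
    """
    if scheme != "leave_one_run_out":
        raise ValueError("searchlight supports the leave_one_run_out scheme")
    values = dataset.values
    S, R, V = values.shape
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    y_stim = (labels == classes[1]).astype(int)
    acc = np.full(V, np.nan)
    members = np.stack([nb.members for nb in neighborhoods])
    centers = np.array([nb.center for nb in neighborhoods])
    correct = np.zeros(len(neighborhoods))
    total = 0
    folds = leave_one_run_out(np.tile(np.arange(R), S))
    X = values.reshape(S * R, V)
    y = np.repeat(y_stim, R)
    for train, test in folds:
        total += len(test)
        for lo in range(0, len(neighborhoods), chunk_size):
            sel = slice(lo, lo + chunk_size)
            try:
                scores = _batched_fold_predictions(
                    X[train], y[train], X[test], members[sel], shrinkage
                )
            except (np.linalg.LinAlgError, FloatingPointError):
                warnings.warn("searchlight chunk failed to fit; NaN assigned")
                correct[sel] = np.nan
                continue
            pred = (scores > 0).astype(int)
            correct[sel] += np.sum(pred == y[test][None, :], axis=1)
    acc[centers] = correct / total
    return acc


def group_significance(
    accuracy_maps: np.ndarray,
    chance: float = 0.5,
    q_threshold: float = 0.005,
) -> SearchlightResult:
    """One-sided group t-test against chance per voxel, BH-FDR across voxels.

    Voxels with NaN accuracy in any subject are excluded (NaN p/q, not in the
    mask). A voxel where all subjects are exactly at or below chance with zero
    variance gets p = 1.
    """
    maps = np.asarray(accuracy_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need accuracy maps from >= 2 subjects")
    n, V = maps.shape
    valid = np.all(np.isfinite(maps), axis=0)
    p = np.full(V, np.nan)
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean - chance) / (sd / math.sqrt(n))
    zero_sd = valid & (sd == 0)
    pos = valid & ~zero_sd
    p[pos] = stats.t.sf(t[pos], df)
    p[zero_sd & (mean > chance)] = 0.0
    p[zero_sd & (mean <= chance)] = 1.0
    q = np.full(V, np.nan)
    if valid.any():
        _, q_valid, _, _ = multipletests(p[valid], method="fdr_bh")
        q[valid] = q_valid
    mask = np.zeros(V, dtype=bool)
    mask[valid] = q[valid] <= q_threshold
    return SearchlightResult(
        accuracy_maps=maps, p_map=p, q_map=q, significant_mask=mask
    )


def select_top_voxels(
    group_mean_accuracy: np.ndarray,
    significant_mask: np.ndarray,
    voxel_coords: np.ndarray,
    fraction: float = 0.10,
) -> np.ndarray:
    """ROI mask: the ceil(fraction * |mask|) highest-accuracy voxels in the mask.

    Ties are broken by (z, y, x) lexicographic coordinate order; NaN accuracies
    are excluded from ranking.
    """
    mask = np.asarray(significant_mask, dtype=bool)
    if not mask.any():
        raise EmptyRoiError("no significant decoding: empty mask")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    acc = np.asarray(group_mean_accuracy, dtype=float)
    coords = np.asarray(voxel_coords)
    idx = np.flatnonzero(mask & np.isfinite(acc))
    if idx.size == 0:
        raise EmptyRoiError("all masked voxels have undefined accuracy")
    n_select = min(math.ceil(fraction * int(mask.sum())), idx.size)
    order = np.lexsort(
        (coords[idx, 0], coords[idx, 1], coords[idx, 2], -acc[idx])
    )
    roi = np.zeros(len(mask), dtype=bool)
    roi[idx[order[:n_select]]] = True
    return roi


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(a, b).sum() / union)
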