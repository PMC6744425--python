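"""Regularized two-class linear discriminant analysis with signed distances.

The classifier is Fisher's LDA with a shrinkage-regularized pooled covariance:
``w = S^-1 (mu1 - mu0)`` where ``S = (1-g) * pooled covariance + g * (tr/p) I``.
Shrinkage ``g`` may be a fixed value in [0, 1] or ``"auto"`` for Ledoit-Wolf
analytic shrinkage toward the scaled identity — essential in the searchlight
regime where features (voxels) outnumber samples.

Signed distances ``d(x) = (w.x + b) / ||w||`` are geometric distances from the
decision hyperplane; with true labels supplied they are reported with the
"correct side positive" convention used by distance-to-bound analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass
class LdaModel:
    weights: np.ndarray
    bias: float
    class_means: np.ndarray  # (2, p); row order matches ``classes``
    classes: np.ndarray  # the two labels; sign(w.x + b) > 0 -> classes[1]
    shrinkage: float  # the shrinkage actually applied
    pooled_covariance_condition: float = np.nan

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError("feature count does not match the fitted model")
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[(self.decision_values(X) > 0).astype(int)]


@dataclass
class DistanceVector:
    """Fold-averaged signed distances per stimulus from a decision boundary."""

    stimulus_id: np.ndarray
    values: np.ndarray
    n_folds_averaged: int = 1
    sign_convention: str = "correct_side_positive"

    def __len__(self) -> int:
        return len(self.values)


def ledoit_wolf_shrinkage(Xc: np.ndarray) -> float:
    """Analytic Ledoit-Wolf shrinkage intensity for centered rows ``Xc``."""
    n, p = Xc.shape
    S = Xc.T @ Xc / n
    m = np.trace(S) / p
    d2 = np.sum((S - m * np.eye(p)) ** 2) / p
    if d2 <= 0:
        return 0.0
    sq_norms = np.sum(Xc**2, axis=1)
    b2 = (np.sum(sq_norms**2) / n - np.sum(S**2)) / (n * p)
    b2 = min(max(b2, 0.0), d2)
    return float(b2 / d2)


def fit_lda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | str = "auto"
) -> LdaModel:
    """Fit a shrinkage-LDA on samples ``X`` with binary labels ``y``.

    The bias places the boundary at the class-mean midpoint (equal priors).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    if shrinkage != "auto" and not (0.0 <= float(shrinkage) <= 1.0):
        raise ValueError("shrinkage must be 'auto' or in [0, 1]")
    n, p = X.shape
    m0 = X[y == classes[0]].mean(axis=0)
    m1 = X[y == classes[1]].mean(axis=0)
    Xc = X.copy()
    Xc[y == classes[0]] -= m0
    Xc[y == classes[1]] -= m1
    if shrinkage == "auto":
        gamma = ledoit_wolf_shrinkage(Xc)
        S = Xc.T @ Xc / n
    else:
        gamma = float(shrinkage)
        dof = max(n - 2, 1)
        S = Xc.T @ Xc / dof
    mu = np.trace(S) / p
    Sigma = (1.0 - gamma) * S + gamma * mu * np.eye(p)
    diff = m1 - m0
    try:
        w = np.linalg.solve(Sigma, diff)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(Sigma) @ diff
    cond = float(np.linalg.cond(Sigma)) if p <= 200 else np.nan
    b = float(-w @ (m0 + m1) / 2.0)
    return LdaModel(
        weights=w,
        bias=b,
        class_means=np.stack([m0, m1]),
        classes=classes,
        shrinkage=gamma,
        pooled_covariance_condition=cond,
    )


def signed_distance(
    model: LdaModel, X: np.ndarray, y_true: np.ndarray | None = None
) -> np.ndarray:
    """Geometric signed distance of each row of ``X`` from the boundary.

    Without labels, positive values lie on the ``classes[1]`` side. With
    ``y_true``, positive means "on the own class's correct side" (a held-out
    prediction is correct iff its correct-side distance is > 0).
    """
    norm = float(np.linalg.norm(model.weights))
    if norm == 0.0:
        raise ValueError("degenerate model: ||w|| = 0")
    d = model.decision_values(X) / norm
    if y_true is not None:
        sign = np.where(np.asarray(y_true) == model.classes[1], 1.0, -1.0)
        d = d * sign
    return d


# ---------------------------------------------------------------------------
# cross-validation schemes
# ---------------------------------------------------------------------------

def leave_one_run_out(runs: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per run: train on all other runs, test on that run."""
    runs = np.asarray(runs)
    folds = []
    for r in np.unique(runs):
        test = np.flatnonzero(runs == r)
        train = np.flatnonzero(runs != r)
        folds.append((train, test))
    return folds


def kfold_split(
    y: np.ndarray,
    runs: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (default 5, i.e. a 4/5 train-test split).

    Folds are stratified jointly by class and (when given) run so every fold
    sees both classes and all runs; each sample is held out exactly once.
    """
    y = np.asarray(y)
    if runs is not None:
        _, yi = np.unique(y, return_inverse=True)
        _, ri = np.unique(np.asarray(runs), return_inverse=True)
        strata = yi * (ri.max() + 1) + ri
    else:
        strata = y
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), strata)]


def crossval_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    shrinkage: float | str = "auto",
) -> tuple[float, list[float]]:
    """Cross-validated accuracy: mean and per-fold proportions correct."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    per_fold = []
    for train, test in folds:
        model = fit_lda(X[train], y[train], shrinkage=shrinkage)
        per_fold.append(float(np.mean(model.predict(X[test]) == y[test])))
    return float(np.mean(per_fold)), per_fold


def crossval_distances(
    X: np.ndarray,
    y: np.ndarray,
    stimulus_ids: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    shrinkage: float | str = "auto",
) -> DistanceVector:
    """Fold-averaged correct-side signed distances, one value per stimulus.

    For each fold an LDA is fit on the training samples and signed distances
    are computed for the held-out samples; each stimulus's distances are then
    averaged over every fold/occurrence in which it was held out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    stimulus_ids = np.asarray(stimulus_ids)
    unique_stim = np.unique(stimulus_ids)
    sums = {s: 0.0 for s in unique_stim}
    counts = {s: 0 for s in unique_stim}
    for train, test in folds:
        model = fit_lda(X[train], y[train], shrinkage=shrinkage)
        d = signed_distance(model, X[test], y_true=y[test])
        for s, v in zip(stimulus_ids[test], d):
            sums[s] += v
            counts[s] += 1
    if any(c == 0 for c in counts.values()):
        missing = [int(s) for s in unique_stim if counts[s] == 0]
        raise ValueError(f"invalid scheme: stimuli never tested: {missing}")
    values = np.array([sums[s] / counts[s] for s in unique_stim])
    return DistanceVector(
        stimulus_id=unique_stim, values=values, n_folds_averaged=len(folds)
    )


def crossval_distance_matrix(
    X: np.ndarray,
    y: np.ndarray,
    stimulus_ids: np.ndarray,
    unit_ids: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    shrinkage: float | str = "auto",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Held-out correct-side distances resolved per (stimulus, unit).

    Like :func:`crossval_distances` but keeps the per-unit (e.g. per-run)
    distance components instead of averaging them away: entry [i, j] is the
    mean held-out distance of stimulus i's samples from unit j. Averaging the
    matrix across units reproduces the fold-averaged distance vector; keeping
    the columns allows split-half reliability of the same estimates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    stimulus_ids = np.asarray(stimulus_ids)
    unit_ids = np.asarray(unit_ids)
    stim_index = np.unique(stimulus_ids)
    unit_index = np.unique(unit_ids)
    sums = np.zeros((len(stim_index), len(unit_index)))
    counts = np.zeros_like(sums)
    s_pos = {s: i for i, s in enumerate(stim_index)}
    u_pos = {u: j for j, u in enumerate(unit_index)}
    for train, test in folds:
        model = fit_lda(X[train], y[train], shrinkage=shrinkage)
        d = signed_distance(model, X[test], y_true=y[test])
        for s, u, v in zip(stimulus_ids[test], unit_ids[test], d):
            sums[s_pos[s], u_pos[u]] += v
            counts[s_pos[s], u_pos[u]] += 1
    if (counts == 0).any():
        raise ValueError("invalid scheme: some stimulus x unit cell never tested")
    return stim_index, unit_index, sums / counts


def cross_decode(
    X: np.ndarray,
    sample_stimulus: np.ndarray,
    design,
    dimension: str,
    shrinkage: float | str = "auto",
    zscore: bool = False,
) -> tuple[float, list[float]]:
    """Cross-decoding across matched cluster pairs.

    Train a classifier for ``dimension`` on samples from one cluster pair
    (matched on the orthogonal dimension), test on the complementary pair;
    both directions are run and their accuracies averaged.
    """
    from .design import matched_cluster_pairs  # local import avoids cycle

    X = np.asarray(X, dtype=float)
    sample_stimulus = np.asarray(sample_stimulus)
    stim_cluster = dict(zip(design.stimulus_id, design.cluster))
    sample_cluster = np.asarray([stim_cluster[s] for s in sample_stimulus], dtype=object)
    labels = design.labels(dimension)
    y = np.asarray([labels[s] for s in sample_stimulus], dtype=object)
    per_fold = []
    for train_clusters, test_clusters in matched_cluster_pairs(design, dimension):
        tr = np.isin(sample_cluster, train_clusters)
        te = np.isin(sample_cluster, test_clusters)
        Xtr, Xte = X[tr], X[te]
        if zscore:
            mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mean) / sd
            Xte = (Xte - mean) / sd
        model = fit_lda(Xtr, y[tr], shrinkage=shrinkage)
        per_fold.append(float(np.mean(model.predict(Xte) == y[te])))
    return float(np.mean(per_fold)), per_fold


def dataset_samples(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a [stimulus x run x voxel] array into samples.

    Returns (X, stimulus index per sample, run index per sample).
    """
    S, R, V = values.shape
    X = values.reshape(S * R, V)
    stim = np.repeat(np.arange(S), R)
    runs = np.tile(np.arange(R), S)
    return X, stim, runs
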