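"""Distance-behavior correlation, group inference, and crisscross predictors.

The core statistic of distance-to-bound analysis: within a category, each
subject's fold-averaged correct-side distances from the classifier boundary
are linearly (Pearson) correlated with the group-averaged accuracy-adjusted
RT vector; the per-subject correlations are then tested against zero with a
one-sample t-test. For a category grouping that crisscrosses two linearly
separable dimensions, the predictor is the sum of the two dimensions'
percentile-scaled distances (a city-block combination in which both
dimensions receive equal weight by construction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NdbaResult:
    """Group summary for one ROI x task x category cell."""

    roi: str
    task: str
    category: str
    per_subject_r: pd.Series
    mean_r: float
    t: float
    df: int
    p: float
    joint_reliability: float = float("nan")


def correlate_distance_behavior(
    distances_by_subject: dict[str, np.ndarray],
    group_scores: pd.Series,
    subset: np.ndarray | None = None,
) -> pd.Series:
    """Per-subject Pearson r between distances and the group behavior vector.

    ``distances_by_subject`` maps subject id to a per-stimulus distance vector
    aligned with ``group_scores`` (indexed by stimulus_id). ``subset``
    restricts to a category's stimulus ids. Subjects with zero variance in
    either vector are excluded with a warning.
    """
    scores = group_scores
    if subset is not None:
        scores = scores.loc[np.asarray(subset)]
    if len(scores) < 3:
        raise ValueError("need >= 3 stimuli to correlate")
    idx = scores.index.to_numpy()
    rs = {}
    for subject, dist in distances_by_subject.items():
        d = np.asarray(dist, dtype=float)[idx]
        s = scores.to_numpy(dtype=float)
        if np.std(d) == 0 or np.std(s) == 0:
            warnings.warn(f"zero variance for subject {subject}; correlation undefined")
            continue
        rs[subject] = float(stats.pearsonr(d, s)[0])
    return pd.Series(rs, name="r")


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))


def group_inference(
    per_subject_r: pd.Series | np.ndarray, use_fisher_z: bool = False
) -> tuple[float, float, int, float]:
    """One-sample two-sided t-test of per-subject correlations against zero.

    Returns (mean r, t, df, p). By default the test is on raw r values;
    ``use_fisher_z`` applies the variance-stabilizing transform first (the
    mean is still reported on the r scale).
    """
    r = np.asarray(per_subject_r, dtype=float)
    if len(r) < 2:
        raise ValueError("need >= 2 subjects")
    vals = fisher_z(r) if use_fisher_z else r
    mean_r = float(np.mean(r))
    df = len(r) - 1
    sd = float(np.std(vals, ddof=1))
    if sd <= 1e-12 * (1.0 + abs(float(np.mean(vals)))):
        if np.mean(vals) == 0:
            return mean_r, 0.0, df, 1.0
        t = math.inf if np.mean(vals) > 0 else -math.inf
        return mean_r, t, df, 0.0
    t, p = stats.ttest_1samp(vals, 0.0)
    return mean_r, float(t), df, float(p)


def category_asymmetry_test(
    r_category_a: pd.Series, r_category_b: pd.Series
) -> tuple[float, float]:
    """Paired two-sided t-test of within-subject correlation differences."""
    common = r_category_a.index.intersection(r_category_b.index)
    if len(common) < 2:
        raise ValueError("need >= 2 paired subjects")
    diff = (r_category_a.loc[common] - r_category_b.loc[common]).to_numpy(dtype=float)
    if np.std(diff, ddof=1) <= 1e-12 * (1.0 + abs(float(np.mean(diff)))):
        if np.mean(diff) == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, float(np.mean(diff))), 0.0
    t, p = stats.ttest_rel(
        r_category_a.loc[common].to_numpy(dtype=float),
        r_category_b.loc[common].to_numpy(dtype=float),
    )
    return float(t), float(p)


def percentile_scale(values: np.ndarray) -> np.ndarray:
    """Rank-based percentile scaling to [0, 100].

    value -> 100 * (rank - 0.5) / n with mean ranks for ties; a strictly
    monotone transform of ranks (all-equal input maps to all 50).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D vector of >= 2 values")
    ranks = stats.rankdata(values, method="average")
    return 100.0 * (ranks - 0.5) / len(values)


def crisscross_distance(
    animacy_distances: np.ndarray, shape_distances: np.ndarray
) -> np.ndarray:
    """City-block combined predictor: sum of percentile-scaled distances.

    Both inputs must be correct-side signed distances for the same stimuli
    (each from its own dimension's ROI/classifier); percentile scaling gives
    the two dimensions equal weight before summation.
    """
    a = np.asarray(animacy_distances, dtype=float)
    b = np.asarray(shape_distances, dtype=float)
    if a.shape != b.shape:
        raise ValueError("distance vectors must have the same length")
    return percentile_scale(a) + percentile_scale(b)
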