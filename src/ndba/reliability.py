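"""Split-half reliability, Spearman-Brown correction, and joint noise ceilings.

The attainable correlation between two noisy measures is bounded by the
square root of the product of their reliabilities. Reliability of each
measure is estimated by correlating per-stimulus aggregates from two halves
of the data (random balanced splits of runs, averaged over splits) and
correcting to full length with the Spearman-Brown formula
``r_full = 2 r_half / (1 + r_half)``.
"""

from __future__ import annotations

import itertools
import warnings
from math import comb
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats


@dataclass
class ReliabilityEstimate:
    r_half_behavior: float
    r_half_neural: float
    r_full_behavior: float
    r_full_neural: float
    joint: float  # NaN when undefined (negative product)
    n_splits: int
    sign_inverted_for_display: bool = False

    @property
    def joint_defined(self) -> bool:
        return np.isfinite(self.joint)

    def display_joint(self) -> float:
        """Sign-inverted ceiling for plotting against negative correlations."""
        return -self.joint


def balanced_splits(
    units: Sequence, n_splits: int, rng: np.random.Generator
) -> list[tuple[list, list]]:
    """Random balanced partitions of ``units`` into two halves.

    For an odd number of units the halves differ in size by one. When fewer
    distinct balanced partitions exist than ``n_splits``, all are enumerated
    (deterministically) instead of sampled.
    """
    units = list(units)
    n = len(units)
    if n < 2:
        raise ValueError("cannot split fewer than 2 units")
    half = n // 2
    n_distinct = comb(n, half) // (2 if n % 2 == 0 else 1)
    if n_distinct <= n_splits:
        splits = []
        for combo in itertools.combinations(range(n), half):
            if n % 2 == 0 and 0 not in combo:
                continue  # deduplicate mirror-image partitions
            first = [units[i] for i in combo]
            second = [units[i] for i in range(n) if i not in combo]
            splits.append((first, second))
        return splits
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append(
            ([units[i] for i in perm[:half]], [units[i] for i in perm[half:]])
        )
    return splits


def split_half(
    units: Sequence,
    half_vector: Callable[[list], np.ndarray],
    n_splits: int = 100,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Mean split-half correlation of per-stimulus vectors.

    ``half_vector`` maps a list of units (e.g. runs) to the per-stimulus
    aggregate computed from those units only. Returns the mean Pearson r over
    splits and the per-split values; splits with zero variance in either half
    are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rs = []
    for first, second in balanced_splits(units, n_splits, rng):
        a = np.asarray(half_vector(first), dtype=float)
        b = np.asarray(half_vector(second), dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn("zero-variance half vector; split skipped")
            continue
        rs.append(float(stats.pearsonr(a, b)[0]))
    if not rs:
        raise ValueError("no valid splits")
    return float(np.mean(rs)), rs


def split_half_array(
    per_unit: np.ndarray, n_splits: int = 100, seed: int = 0
) -> tuple[float, list[float]]:
    """Split-half reliability of a [stimulus x unit] array (mean aggregation)."""
    per_unit = np.asarray(per_unit, dtype=float)
    if per_unit.ndim != 2 or per_unit.shape[1] < 2:
        raise ValueError("need a [stimulus x unit] array with >= 2 units")
    units = list(range(per_unit.shape[1]))
    return split_half(
        units, lambda us: per_unit[:, us].mean(axis=1), n_splits=n_splits, seed=seed
    )


def spearman_brown(r_half: float) -> float:
    """Reliability of the full-length measure from a half-length reliability."""
    if not (-1.0 <= r_half <= 1.0):
        raise ValueError("r_half must be in [-1, 1]")
    if r_half <= -1.0 + 1e-12:
        warnings.warn("r_half at the -1 boundary; result clamped")
        return -1.0
    return float(2.0 * r_half / (1.0 + r_half))


def prophecy_full_reliability(
    r_split: float, n_first: int, n_second: int, n_total: int
) -> float:
    """Full-length reliability from a split into unequal halves.

    Models each unit (e.g. run) as signal plus i.i.d. noise, so the
    correlation between the means of ``n_first`` and ``n_second`` units is
    ``1 / sqrt((1 + u/n1)(1 + u/n2))`` with ``u`` the noise-to-signal
    variance ratio; solving for ``u`` and projecting to ``n_total`` units
    generalizes the Spearman-Brown formula (to which it reduces exactly for
    equal halves spanning the data). Non-positive split correlations are
    passed through the classic formula (clamped at -1).
    """
    for n in (n_first, n_second, n_total):
        if n < 1:
            raise ValueError("unit counts must be >= 1")
    if not (-1.0 <= r_split <= 1.0):
        raise ValueError("r_split must be in [-1, 1]")
    if r_split <= 0.0:
        return spearman_brown(max(r_split, -1.0))
    if r_split == 1.0:
        return 1.0
    a = 1.0 / (n_first * n_second)
    b = 1.0 / n_first + 1.0 / n_second
    c = 1.0 - 1.0 / r_split**2
    u = (-b + np.sqrt(b**2 - 4 * a * c)) / (2 * a)
    return float(1.0 / (1.0 + u / n_total))


def joint_reliability(r_full_behavior: float, r_full_neural: float) -> float:
    """Joint noise ceiling: sqrt of the product of the two reliabilities.

    Returns NaN (undefined) when the product is negative.
    """
    for r in (r_full_behavior, r_full_neural):
        if not (-1.0 <= r <= 1.0):
            raise ValueError("reliabilities must be in [-1, 1]")
    product = r_full_behavior * r_full_neural
    if product < 0:
        warnings.warn("negative reliability product; joint ceiling undefined")
        return float("nan")
    return float(np.sqrt(product))


def joint_estimate(
    r_half_behavior: float,
    r_half_neural: float,
    n_splits: int,
    split_sizes: tuple[int, int] | None = None,
    n_units: int | None = None,
) -> ReliabilityEstimate:
    """Assemble a full estimate from the two mean split-half correlations.

    With ``split_sizes`` and ``n_units`` given, the unequal-half length
    correction is used instead of the classic two-fold formula.
    """
    if split_sizes is not None and n_units is not None:
        n1, n2 = split_sizes
        r_fb = prophecy_full_reliability(r_half_behavior, n1, n2, n_units)
        r_fn = prophecy_full_reliability(r_half_neural, n1, n2, n_units)
    else:
        r_fb = spearman_brown(r_half_behavior)
        r_fn = spearman_brown(r_half_neural)
    return ReliabilityEstimate(
        r_half_behavior=float(r_half_behavior),
        r_half_neural=float(r_half_neural),
        r_full_behavior=r_fb,
        r_full_neural=r_fn,
        joint=joint_reliability(r_fb, r_fn),
        n_splits=n_splits,
    )
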