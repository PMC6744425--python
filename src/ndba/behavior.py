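"""Trial-level behavior aggregation, LISAS scoring, and coupling diagnostics.

LISAS (linearly integrated speed-accuracy score) is an accuracy-adjusted RT:
``LISAS_j = RT_j + (S_RT / S_PE) * PE_j`` where RT_j is a stimulus's mean RT,
PE_j its proportion error, S_RT the subject's RT standard deviation over
trials in the task, and S_PE the standard deviation of the subject's
per-stimulus proportion errors. The ratio puts the error penalty on the RT
(ms) scale; when a subject makes no errors (S_PE = 0) LISAS reduces to the
mean RT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRIAL_COLUMNS = ["subject", "task", "run", "stimulus_id", "rt_ms", "correct"]


@dataclass
class LisasParams:
    """Subject-level scaling terms for the LISAS error penalty."""

    s_rt: float  # SD of RT (ms) over the subject's trials in the task
    s_pe: float  # SD of per-stimulus proportion error

    def __post_init__(self) -> None:
        if self.s_rt < 0 or self.s_pe < 0:
            raise ValueError("LISAS scale parameters must be nonnegative")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"behavior table is missing columns: {missing}")
    if len(trials) == 0:
        raise ValueError("behavior table is empty")
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("rt_ms must be positive")
    return trials


def lisas(mean_rt: float, prop_error: float, params: LisasParams) -> float:
    """Accuracy-adjusted RT for one stimulus (ms)."""
    if mean_rt < 0 or not (0.0 <= prop_error <= 1.0):
        raise ValueError("mean_rt must be >= 0 and prop_error in [0, 1]")
    if params.s_pe == 0:
        return float(mean_rt)
    return float(mean_rt + (params.s_rt / params.s_pe) * prop_error)


def aggregate(trials: pd.DataFrame, rt_basis: str = "correct-only") -> pd.DataFrame:
    """Per (subject, task, stimulus) aggregates with LISAS scores.

    ``rt_basis`` selects whether RT summaries use correct trials only
    (default) or all trials. Cells with no usable RT trials are flagged via
    NaN RTs and a warning; proportion error always uses all trials.
    """
    validate_trials(trials)
    if rt_basis not in ("correct-only", "all"):
        raise ValueError("rt_basis must be 'correct-only' or 'all'")
    t = trials.copy()
    t["correct"] = t["correct"].astype(bool)
    rt_source = t[t["correct"]] if rt_basis == "correct-only" else t

    keys = ["subject", "task", "stimulus_id"]
    counts = t.groupby(keys, sort=True).agg(
        n_trials=("rt_ms", "size"), prop_error=("correct", lambda c: 1.0 - c.mean())
    )
    rts = rt_source.groupby(keys, sort=True).agg(
        mean_rt_ms=("rt_ms", "mean"), median_rt_ms=("rt_ms", "median")
    )
    agg = counts.join(rts).reset_index()
    if agg["mean_rt_ms"].isna().any():
        n_bad = int(agg["mean_rt_ms"].isna().sum())
        warnings.warn(
            f"{n_bad} subject x task x stimulus cells have no usable RT trials"
        )

    # subject x task scale terms for the LISAS penalty
    out = []
    for (subject, task), cell in agg.groupby(["subject", "task"], sort=True):
        trial_rts = rt_source[
            (rt_source["subject"] == subject) & (rt_source["task"] == task)
        ]["rt_ms"]
        s_rt = float(trial_rts.std(ddof=1)) if len(trial_rts) > 1 else 0.0
        s_pe = float(cell["prop_error"].std(ddof=1)) if len(cell) > 1 else 0.0
        params = LisasParams(s_rt=s_rt if np.isfinite(s_rt) else 0.0, s_pe=s_pe)
        cell = cell.copy()
        cell["lisas_ms"] = [
            lisas(rt, pe, params) if np.isfinite(rt) else np.nan
            for rt, pe in zip(cell["mean_rt_ms"], cell["prop_error"])
        ]
        out.append(cell)
    result = pd.concat(out, ignore_index=True)
    return result[
        keys + ["mean_rt_ms", "median_rt_ms", "prop_error", "lisas_ms", "n_trials"]
    ]


def group_behavior_vector(
    aggregated: pd.DataFrame,
    task: str,
    score: str = "lisas_ms",
    subjects: list[str] | None = None,
) -> pd.Series:
    """Group-average behavioral score per stimulus for one task.

    ``subjects`` restricts the average (e.g. after chance-level exclusion).
    """
    sel = aggregated[aggregated["task"] == task]
    if subjects is not None:
        sel = sel[sel["subject"].isin(subjects)]
    if len(sel) == 0:
        raise ValueError(f"no aggregated rows for task {task!r}")
    vec = sel.groupby("stimulus_id", sort=True)[score].mean()
    vec.name = score
    return vec


def rt_accuracy_coupling(
    aggregated: pd.DataFrame, task: str
) -> tuple[pd.Series, float, float, float]:
    """Per-subject correlation between per-stimulus mean RT and accuracy.

    Returns (per-subject r, group mean r, t statistic, two-sided p) from a
    one-sample t-test of the correlations against zero. Speed-accuracy
    integration assumes this correlation is negative: stimuli answered slowly
    are also answered less accurately.
    """
    sel = aggregated[aggregated["task"] == task]
    rs = {}
    for subject, cell in sel.groupby("subject", sort=True):
        cell = cell.dropna(subset=["mean_rt_ms"])
        if len(cell) < 3:
            continue
        if cell["mean_rt_ms"].nunique() < 2 or cell["prop_error"].nunique() < 2:
            continue
        r, _ = stats.pearsonr(cell["mean_rt_ms"], 1.0 - cell["prop_error"])
        rs[subject] = r
    r_series = pd.Series(rs, name="r")
    if len(r_series) < 2:
        raise ValueError("need correlations from >= 2 subjects")
    t, p = stats.ttest_1samp(r_series.values, 0.0)
    return r_series, float(r_series.mean()), float(t), float(p)


def exclude_chance_subjects(
    trials: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Exclude subjects indistinguishable from chance on any task.

    Per subject per task, an exact one-sided binomial test of overall accuracy
    against 0.5; a subject failing the test on at least one task is excluded
    from all analyses. Returns (kept, excluded, per-test records).
    """
    validate_trials(trials)
    records = []
    for (subject, task), cell in trials.groupby(["subject", "task"], sort=True):
        n = len(cell)
        k = int(cell["correct"].astype(bool).sum())
        p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
        records.append(
            {
                "subject": subject,
                "task": task,
                "n_trials": n,
                "accuracy": k / n,
                "p_above_chance": float(p),
                "above_chance": p < alpha,
            }
        )
    rec = pd.DataFrame(records)
    excluded = sorted(rec.loc[~rec["above_chance"], "subject"].unique())
    kept = sorted(set(rec["subject"]) - set(excluded))
    return kept, excluded, rec
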