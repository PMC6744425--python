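"""Stimulus design: category clusters and the orthogonal label structure.

The design crosses animacy (animate/inanimate) with real-world shape
(bar-like/blob-like) using four object clusters — pets, insects, tools,
vegetables — of equal size, and adds a "crisscross" indoor/outdoor grouping
that spans both animacy levels and both shape levels, so it is not linearly
separable along either dimension alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLUSTERS = ("pets", "insects", "tools", "vegetables")

CLUSTER_ANIMACY = {
    "pets": "animate",
    "insects": "animate",
    "tools": "inanimate",
    "vegetables": "inanimate",
}

#: indoor objects are the pets (caged indoors) and tools (kitchen/bathroom items)
CLUSTER_CRISSCROSS = {
    "pets": "indoor",
    "insects": "outdoor",
    "tools": "indoor",
    "vegetables": "outdoor",
}

#: which clusters are bar-like vs blob-like is a modelling choice
#: (one bar and one blob cluster per animacy level, i.e. counterbalanced)
DEFAULT_SHAPE_ASSIGNMENT = {
    "pets": "blob",
    "insects": "bar",
    "tools": "bar",
    "vegetables": "blob",
}

#: dimension -> (negative-side label, positive-side label)
DIMENSION_CLASSES = {
    "animacy": ("inanimate", "animate"),
    "shape": ("blob", "bar"),
    "crisscross": ("outdoor", "indoor"),
}

TASKS = ("animacy", "shape", "crisscross")

#: task -> the design dimension whose two levels are the response categories
TASK_DIMENSION = {"animacy": "animacy", "shape": "shape", "crisscross": "crisscross"}


@dataclass(frozen=True)
class StimulusDesign:
    """Label structure over exemplar stimuli.

    All fields are length-S arrays aligned on ``stimulus_id`` (0..S-1).
    """

    stimulus_id: np.ndarray
    cluster: np.ndarray
    animacy: np.ndarray
    shape: np.ndarray
    crisscross: np.ndarray

    def __post_init__(self) -> None:
        s = len(self.stimulus_id)
        for name in ("cluster", "animacy", "shape", "crisscross"):
            if len(getattr(self, name)) != s:
                raise ValueError(f"field {name!r} length != {s}")
        if not np.array_equal(self.stimulus_id, np.arange(s)):
            raise ValueError("stimulus_id must be 0..S-1 in order")
        counts = pd.Series(self.cluster).value_counts()
        if set(counts.index) != set(CLUSTERS) or counts.nunique() != 1:
            raise ValueError("need four equally sized clusters")
        for cl in CLUSTERS:
            m = self.cluster == cl
            for dim in ("animacy", "shape", "crisscross"):
                if len(np.unique(getattr(self, dim)[m])) != 1:
                    raise ValueError(f"{dim} not constant within cluster {cl!r}")
        # shape counterbalanced: each animacy level has one bar and one blob cluster
        frame = self.to_frame().drop_duplicates("cluster")
        cells = frame.groupby(["animacy", "shape"]).size()
        if len(cells) != 4 or cells.nunique() != 1:
            raise ValueError("shape must be counterbalanced across animacy")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_id)

    def labels(self, dimension: str) -> np.ndarray:
        """Per-stimulus labels for one of animacy/shape/crisscross."""
        if dimension not in DIMENSION_CLASSES:
            raise ValueError(f"unknown dimension {dimension!r}")
        return getattr(self, dimension)

    def class_sign(self, dimension: str) -> np.ndarray:
        """+1 for the positive-side class of ``dimension``, -1 for the other."""
        pos = DIMENSION_CLASSES[dimension][1]
        return np.where(self.labels(dimension) == pos, 1.0, -1.0)

    def members(self, cluster: str) -> np.ndarray:
        """Stimulus ids belonging to a cluster."""
        return self.stimulus_id[self.cluster == cluster]

    def category_members(self, dimension: str, label: str) -> np.ndarray:
        """Stimulus ids with a given label on a dimension."""
        return self.stimulus_id[self.labels(dimension) == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": self.stimulus_id,
                "cluster": self.cluster,
                "animacy": self.animacy,
                "shape": self.shape,
                "crisscross": self.crisscross,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {k: self.to_frame()[k].tolist() for k in self.to_frame().columns}
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusDesign":
        d = json.loads(text)
        return cls(
            stimulus_id=np.asarray(d["stimulus_id"]),
            cluster=np.asarray(d["cluster"]),
            animacy=np.asarray(d["animacy"]),
            shape=np.asarray(d["shape"]),
            crisscross=np.asarray(d["crisscross"]),
        )


def generate_design(
    n_per_cluster: int = 8, shape_assignment: dict[str, str] | None = None
) -> StimulusDesign:
    """Build the 2 (animacy) x 2 (shape) x crisscross design.

    Parameters
    ----------
    n_per_cluster:
        Number of exemplar stimuli per cluster (default 8, i.e. 32 stimuli).
    shape_assignment:
        Optional cluster -> {"bar", "blob"} mapping; must assign one bar and
        one blob cluster within each animacy level.
    """
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    shapes = dict(DEFAULT_SHAPE_ASSIGNMENT if shape_assignment is None else shape_assignment)
    if set(shapes) != set(CLUSTERS) or set(shapes.values()) != {"bar", "blob"}:
        raise ValueError("shape_assignment must map all four clusters to bar/blob")
    cluster = np.repeat(np.asarray(CLUSTERS, dtype=object), n_per_cluster)
    return StimulusDesign(
        stimulus_id=np.arange(4 * n_per_cluster),
        cluster=cluster,
        animacy=np.asarray([CLUSTER_ANIMACY[c] for c in cluster], dtype=object),
        shape=np.asarray([shapes[c] for c in cluster], dtype=object),
        crisscross=np.asarray([CLUSTER_CRISSCROSS[c] for c in cluster], dtype=object),
    )


def matched_cluster_pairs(
    design: StimulusDesign, dimension: str
) -> list[tuple[list[str], list[str]]]:
    """Cross-decoding folds: train on one cluster pair matched on the nuisance
    dimension and differing on ``dimension``; test on the complementary pair.

    Returns two (train_clusters, test_clusters) tuples (both directions).
    """
    if dimension not in ("animacy", "shape"):
        raise ValueError("cross-decoding is defined for animacy and shape")
    other = "shape" if dimension == "animacy" else "animacy"
    frame = design.to_frame().drop_duplicates("cluster")
    groups = []
    for _, g in frame.groupby(other, sort=True):
        if len(g) != 2 or g[dimension].nunique() != 2:
            raise ValueError("design does not support matched-pair cross-decoding")
        groups.append(sorted(g["cluster"].tolist()))
    if len(groups) != 2:
        raise ValueError("design does not support matched-pair cross-decoding")
    return [(groups[0], groups[1]), (groups[1], groups[0])]
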