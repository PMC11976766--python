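"""Border-based pointwise reliability (density principle).

For every attribute, the training "borders" are the instances of each
class closest to the opposite class, plus the attribute's global min and
max.  A test instance's reliability is ``rel(x) = 1 - m_x / m`` where
``m_x`` counts the attributes on which the instance would become a border
if it were added to the training set — evaluated under both hypothetical
labels, since the true label is unknown at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "AttributeBorders",
    "BorderSet",
    "ReliabilityReport",
    "compute_borders",
    "would_become_border",
    "reliability_score",
    "proband_reliability_stats",
]


@dataclass(frozen=True)
class AttributeBorders:
    """Border structure of one attribute."""

    border_values: Tuple[Tuple[float, ...], Tuple[float, ...]]  # per class 0/1
    min_value: float
    max_value: float
    cross_distance: float            # minimal |a - b| between the classes
    class_values: Tuple[Tuple[float, ...], Tuple[float, ...]]   # unique sorted


@dataclass(frozen=True)
class BorderSet:
    attributes: Tuple[AttributeBorders, ...]

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)


def compute_borders(features: np.ndarray, labels: Sequence[int]) -> BorderSet:
    """Per-attribute border values for a binary-labeled training matrix.

    For each attribute and each class, every instance value at minimal
    absolute distance to the opposite class is a border (ties all count);
    the attribute's global min and max complete the set.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("features must be a 2-D matrix with >= 1 attribute")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")

    attrs: List[AttributeBorders] = []
    for j in range(x.shape[1]):
        v0 = np.unique(x[y == classes[0], j])
        v1 = np.unique(x[y == classes[1], j])
        dist = np.abs(v0[:, None] - v1[None, :])
        d = float(dist.min())
        b0 = tuple(sorted(float(v) for v in v0[np.isclose(dist.min(axis=1), d)]))
        b1 = tuple(sorted(float(v) for v in v1[np.isclose(dist.min(axis=0), d)]))
        attrs.append(
            AttributeBorders(
                border_values=(b0, b1),
                min_value=float(x[:, j].min()),
                max_value=float(x[:, j].max()),
                cross_distance=d,
                class_values=(
                    tuple(float(v) for v in v0),
                    tuple(float(v) for v in v1),
                ),
            )
        )
    return BorderSet(attributes=tuple(attrs))


def would_become_border(borders: BorderSet, x: Sequence[float]) -> int:
    """Number of attributes on which ``x`` would become a training border.

    Label-free: an attribute counts when the value falls strictly outside
    the training range, or lies strictly closer to *both* classes than the
    classes are to each other (i.e. inside the open inter-class margin, so
    insertion under either label would make it the new nearest-to-opposite
    instance).  Attributes where the classes overlap (cross distance 0,
    e.g. boolean features present in both classes) can only be counted via
    the range rule.
    """
    vec = np.asarray(x, dtype=float)
    if vec.shape != (borders.n_attributes,):
        raise ValueError(
            f"expected {borders.n_attributes} attributes, got shape {vec.shape}"
        )
    m_x = 0
    for j, attr in enumerate(borders.attributes):
        v = float(vec[j])
        if v < attr.min_value or v > attr.max_value:
            m_x += 1
            continue
        if attr.cross_distance > 0.0:
            d0 = min(abs(v - w) for w in attr.class_values[0])
            d1 = min(abs(v - w) for w in attr.class_values[1])
            if d0 < attr.cross_distance and d1 < attr.cross_distance:
                m_x += 1
    return m_x


def reliability_score(m_x: int, m: int) -> float:
    """rel(x) = 1 - m_x / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= m_x <= m:
        raise ValueError(f"m_x must be in [0, {m}], got {m_x}")
    return 1.0 - m_x / m


@dataclass(frozen=True)
class ReliabilityReport:
    median: float
    std: float
    minimum: float
    fraction_max_reliability: float
    n: int


def proband_reliability_stats(scores: Sequence[float]) -> ReliabilityReport:
    """Median, SD, minimum and exact fraction of scores equal to 1."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no reliability scores")
    return ReliabilityReport(
        median=float(np.median(arr)),
        std=float(np.std(arr)),
        minimum=float(arr.min()),
        fraction_max_reliability=float(np.mean(arr == 1.0)),
        n=int(arr.size),
    )


def reliability_scores(
    borders: BorderSet, features: np.ndarray
) -> np.ndarray:
    """rel(x) for every row of a test feature matrix."""
    x = np.asarray(features, dtype=float)
    m = borders.n_attributes
    return np.array(
        [reliability_score(would_become_border(borders, row), m) for row in x]
    )
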