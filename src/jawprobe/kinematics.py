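"""Time- and space-normalized kinematic measures of jaw movement.

Three measurement series are derived from each landmark trajectory:

``mouth_opening``
    The ratio of mouth width (distance between the cheilion landmarks) to
    mouth height (distance between stomion superius and inferius).  Note the
    orientation: the ratio *decreases* as the mouth opens, and is singular at
    full closure; the height denominator is floored at ``EPSILON_HEIGHT``
    times the facial width to keep values finite.  A
    ``height_over_width`` convention is available as a configuration switch.

``mouth_opening_velocity``
    The first derivative of the time-normalized mouth-opening series, in
    measurement units per unit of normalized time.  Because features are
    z-scored across participants downstream, absolute time units cancel.

``pogonion_lateral``
    The absolute lateral deviation of the pogonion (chin tip) from the
    facial midline defined at rest, normalized by facial width.  The midline
    is the perpendicular bisector of the rest exocanthion pair; facial width
    is the mean of the three rest bilateral distances (zygion, tragion,
    exocanthion).

All three are ratios of distances and therefore invariant under translation,
rotation and uniform scaling of the image coordinates.  Raw per-frame series
are linearly interpolated onto 1000 equally spaced points of normalized time
t in [0, 1] before sub-period extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import ceil, floor
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import (
    BILATERAL_PAIRS,
    CANONICAL_WORDS,
    LandmarkTrajectory,
    canonical_word,
)

#: Floor on the mouth-height denominator, as a fraction of facial width.
EPSILON_HEIGHT = 1e-3

#: Number of normalized timepoints.
N_TIMEPOINTS = 1000

MEASUREMENTS: tuple[str, ...] = (
    "mouth_opening",
    "mouth_opening_velocity",
    "pogonion_lateral",
)

#: Which measurements characterise each kinematically evaluated criterion.
CRITERION_MEASUREMENTS: dict[str, tuple[str, ...]] = {
    "jaw_range": ("mouth_opening",),
    "jaw_control": ("mouth_opening_velocity", "pogonion_lateral"),
}


class KinematicsError(ValueError):
    """Degenerate geometry or invalid series."""


@dataclass(frozen=True)
class SubPeriodInterval:
    """A sub-period of a word's production, in percent of word duration."""

    start_pct: float
    end_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_pct < self.end_pct <= 100):
            raise KinematicsError(
                f"invalid sub-period [{self.start_pct}, {self.end_pct}]: "
                "need 0 <= start < end <= 100"
            )


IntervalTable = Mapping[tuple[str, str], tuple[SubPeriodInterval, ...]]


def _parse_interval_mapping(data: Mapping) -> dict[tuple[str, str], tuple[SubPeriodInterval, ...]]:
    table: dict[tuple[str, str], tuple[SubPeriodInterval, ...]] = {}
    for word, criteria in data.items():
        word = canonical_word(word)
        for criterion, intervals in criteria.items():
            table[(word, criterion)] = tuple(
                SubPeriodInterval(float(a), float(b)) for a, b in intervals
            )
    return table


def load_interval_table(path=None) -> dict[tuple[str, str], tuple[SubPeriodInterval, ...]]:
    """Load sub-period intervals keyed by (word, criterion).

    With no ``path``, the packaged expert-defined table is used; a YAML file of
    the same shape may override it.
    """
    if path is None:
        text = resources.files("jawprobe.data").joinpath("subperiods.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    table = _parse_interval_mapping(yaml.safe_load(text))
    missing = [
        (w, c)
        for w in CANONICAL_WORDS
        for c in CRITERION_MEASUREMENTS
        if (w, c) not in table
    ]
    if missing:
        raise KinematicsError(f"interval table missing entries for {missing}")
    return table


#: Packaged default sub-period intervals.
SUBPERIOD_INTERVALS: dict[tuple[str, str], tuple[SubPeriodInterval, ...]] = load_interval_table()


def _distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(a, float) - np.asarray(b, float), axis=-1)


def face_width(traj: LandmarkTrajectory) -> float:
    """Facial width: mean of the three bilateral rest distances."""
    dists = [
        float(_distance(traj.rest_landmark(l), traj.rest_landmark(r)))
        for l, r in BILATERAL_PAIRS
    ]
    if min(dists) <= 0 or not all(np.isfinite(dists)):
        raise KinematicsError(
            f"{traj.participant_id}/{traj.word}: degenerate rest frame "
            "(coincident bilateral landmarks)"
        )
    return float(np.mean(dists))


def mouth_opening_series(
    traj: LandmarkTrajectory, convention: str = "width_over_height"
) -> np.ndarray:
    """Raw per-frame mouth-opening ratio.

    Default convention is width / height (decreasing with opening); the
    height denominator is floored at ``EPSILON_HEIGHT * face_width``.
    """
    width = _distance(traj.landmark("cheilion_left"), traj.landmark("cheilion_right"))
    height = _distance(
        traj.landmark("stomion_superius"), traj.landmark("stomion_inferius")
    )
    if np.any(width <= 0):
        frame = int(np.flatnonzero(width <= 0)[0])
        raise KinematicsError(
            f"{traj.participant_id}/{traj.word}: coincident cheilion landmarks "
            f"at frame {frame}"
        )
    fw = face_width(traj)
    height = np.maximum(height, EPSILON_HEIGHT * fw)
    if convention == "width_over_height":
        return width / height
    if convention == "height_over_width":
        return height / width
    raise KinematicsError(f"unknown opening convention {convention!r}")


def pogonion_lateral_series(traj: LandmarkTrajectory) -> np.ndarray:
    """Raw per-frame absolute lateral deviation of the pogonion from the rest
    midline, normalized by facial width."""
    fw = face_width(traj)
    ex_l = traj.rest_landmark("exocanthion_left")
    ex_r = traj.rest_landmark("exocanthion_right")
    axis = ex_r - ex_l
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise KinematicsError(
            f"{traj.participant_id}/{traj.word}: coincident rest exocanthion landmarks"
        )
    unit = axis / norm            # lateral direction
    midpoint = (ex_l + ex_r) / 2.0
    signed = (traj.landmark("pogonion") - midpoint) @ unit
    return np.abs(signed) / fw


def time_normalize(values: Sequence[float], n: int = N_TIMEPOINTS) -> np.ndarray:
    """Linearly interpolate a raw series onto ``n`` equally spaced points of
    normalized time [0, 1].  The first and last samples are preserved exactly;
    the operation is idempotent at fixed ``n``."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise KinematicsError("time_normalize needs a 1-D series of length >= 2")
    if not np.isfinite(values).all():
        raise KinematicsError("non-finite value in series")
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, values)


def derivative_series(values: Sequence[float]) -> np.ndarray:
    """First derivative of a normalized series per unit normalized time:
    central differences on interior points, one-sided at the endpoints."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise KinematicsError("derivative needs a series of length >= 2")
    dt = 1.0 / (values.size - 1)
    return np.gradient(values, dt)


def extract_subperiods(
    values: Sequence[float], intervals: Sequence[SubPeriodInterval]
) -> list[np.ndarray]:
    """Slice a normalized series into closed sub-period segments.

    Segment k holds samples with index i satisfying
    ``start_pct/100 <= i/(n-1) <= end_pct/100``, i.e. first index
    ``ceil(start_pct/100 * (n-1))``, last ``floor(end_pct/100 * (n-1))``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    segments = []
    for interval in intervals:
        lo = ceil(interval.start_pct / 100.0 * (n - 1) - 1e-9)
        hi = floor(interval.end_pct / 100.0 * (n - 1) + 1e-9)
        if hi < lo:
            raise KinematicsError(
                f"sub-period [{interval.start_pct}, {interval.end_pct}] selects "
                f"no samples from a series of length {n}"
            )
        segments.append(values[lo : hi + 1])
    return segments


def range_of_motion(segment: Sequence[float]) -> float:
    """Range of motion of a segment: max minus min (>= 0)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise KinematicsError("range_of_motion of an empty segment")
    return float(segment.max() - segment.min())


def measurement_series(
    traj: LandmarkTrajectory,
    measurement: str,
    n: int = N_TIMEPOINTS,
    convention: str = "width_over_height",
    smooth_window: int = 0,
) -> np.ndarray:
    """Full pipeline from trajectory to one time-normalized measurement series.

    ``smooth_window`` optionally applies a centred moving average of that many
    frames to the raw series before normalization (default off).
    """
    if measurement in ("mouth_opening", "mouth_opening_velocity"):
        raw = mouth_opening_series(traj, convention=convention)
    elif measurement == "pogonion_lateral":
        raw = pogonion_lateral_series(traj)
    else:
        raise KinematicsError(f"unknown measurement {measurement!r}")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        raw = np.convolve(raw, kernel, mode="same")
    series = time_normalize(raw, n=n)
    if measurement == "mouth_opening_velocity":
        series = derivative_series(series)
    return series
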