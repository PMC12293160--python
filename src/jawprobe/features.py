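"""Per-word |z|-score features for appropriateness classification.

For a participant, word, criterion and measurement, the feature is built by:

1. computing the participant's range of motion (max - min) of the
   time-normalized measurement series within each expert-defined sub-period
   interval of the word;
2. z-scoring each interval's range of motion against the mean and sample SD
   of the same quantity over **all other** participants scored appropriate
   (1) on that criterion and word — the reference pool excludes the
   participant being featurised, so a participant's feature never depends on
   their own range of motion or score;
3. averaging the absolute z-scores over the word's intervals (most words
   have one interval; Papa has two, with per-interval reference statistics
   so its two gestures are compared like-for-like).

Participants scored inappropriate still receive features — they are the
classification targets; only the reference pool is appropriateness-filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CANONICAL_WORDS, Cohort
from .kinematics import (
    CRITERION_MEASUREMENTS,
    SUBPERIOD_INTERVALS,
    IntervalTable,
    extract_subperiods,
    measurement_series,
    range_of_motion,
)

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """Reference pool too small or degenerate."""


class DegenerateReferenceError(FeatureError):
    """Reference values have zero spread; the z-score is undefined."""


@dataclass(frozen=True)
class ReferenceStats:
    """Reference mean / SD of one interval's range of motion."""

    word: str
    measurement: str
    interval_index: int
    mean: float
    sd: float
    n_ref: int


def rom_table(
    cohort: Cohort,
    criterion: str,
    measurements: tuple[str, ...] | None = None,
    intervals: IntervalTable | None = None,
    convention: str = "width_over_height",
) -> pd.DataFrame:
    """Per-interval range of motion for every available trajectory.

    Columns: participant, word, measurement, interval_index, rom.  Missing
    trajectories are skipped with a logged warning (they surface downstream
    as absent feature rows).
    """
    if criterion not in CRITERION_MEASUREMENTS:
        raise FeatureError(
            f"criterion {criterion!r} has no kinematic measurements; expected one "
            f"of {sorted(CRITERION_MEASUREMENTS)}"
        )
    if measurements is None:
        measurements = CRITERION_MEASUREMENTS[criterion]
    if intervals is None:
        intervals = SUBPERIOD_INTERVALS
    records = []
    for participant in cohort.participants:
        pid = participant.participant_id
        for word in CANONICAL_WORDS:
            traj = cohort.trajectories.get((pid, word))
            if traj is None:
                logger.warning("no trajectory for %s/%s; row skipped", pid, word)
                continue
            word_intervals = intervals[(word, criterion)]
            for measurement in measurements:
                series = measurement_series(traj, measurement, convention=convention)
                for k, segment in enumerate(extract_subperiods(series, word_intervals)):
                    records.append((pid, word, measurement, k, range_of_motion(segment)))
    return pd.DataFrame(
        records, columns=["participant", "word", "measurement", "interval_index", "rom"]
    )


def reference_stats(
    roms: pd.DataFrame,
    cohort: Cohort,
    word: str,
    measurement: str,
    criterion: str,
    exclude: str,
    interval_index: int = 0,
) -> ReferenceStats:
    """Mean and sample SD (n-1) of one interval's range of motion over all
    participants other than ``exclude`` scored appropriate on (criterion, word)."""
    mask = (
        (roms["word"] == word)
        & (roms["measurement"] == measurement)
        & (roms["interval_index"] == interval_index)
        & (roms["participant"] != exclude)
    )
    rows = roms[mask]
    appropriate = [
        pid
        for pid in rows["participant"]
        if cohort.participant(pid).score_sheet.score(criterion, word) == 1
    ]
    values = rows[rows["participant"].isin(appropriate)]["rom"].to_numpy(float)
    if values.size < 2:
        raise FeatureError(
            f"fewer than 2 appropriate reference participants for "
            f"({word}, {criterion}, {measurement}, interval {interval_index})"
        )
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise DegenerateReferenceError(
            f"degenerate reference (all values equal) for "
            f"({word}, {criterion}, {measurement}, interval {interval_index})"
        )
    return ReferenceStats(
        word=word,
        measurement=measurement,
        interval_index=interval_index,
        mean=float(values.mean()),
        sd=sd,
        n_ref=int(values.size),
    )


def z_feature(
    roms: pd.DataFrame,
    cohort: Cohort,
    participant_id: str,
    word: str,
    criterion: str,
    measurement: str,
) -> float:
    """The scalar feature: mean over intervals of |z| of the participant's
    range of motion against interval-specific reference statistics."""
    rows = roms[
        (roms["participant"] == participant_id)
        & (roms["word"] == word)
        & (roms["measurement"] == measurement)
    ].sort_values("interval_index")
    if rows.empty:
        raise FeatureError(f"no range-of-motion rows for {participant_id}/{word}")
    zs = []
    for _, row in rows.iterrows():
        ref = reference_stats(
            roms,
            cohort,
            word=word,
            measurement=measurement,
            criterion=criterion,
            exclude=participant_id,
            interval_index=int(row["interval_index"]),
        )
        zs.append(abs((float(row["rom"]) - ref.mean) / ref.sd))
    return float(np.mean(zs))


def build_feature_table(
    cohort: Cohort,
    criterion: str,
    measurements: tuple[str, ...] | None = None,
    intervals: IntervalTable | None = None,
    convention: str = "width_over_height",
) -> pd.DataFrame:
    """One feature row per participant x word x measurement.

    Columns: participant, word, criterion, measurement, feature, label — with
    label in {"appropriate", "inappropriate"} taken from the score sheet.
    Jaw range uses the mouth-opening measurement alone; jaw control uses
    mouth-opening velocity and pogonion lateral deviation (the two rows per
    participant-word are the combined-model inputs).
    """
    if measurements is None:
        measurements = CRITERION_MEASUREMENTS[criterion]
    roms = rom_table(
        cohort, criterion, measurements=measurements, intervals=intervals,
        convention=convention,
    )

    # Vectorised leave-one-out reference stats per (word, measurement, interval):
    # for participant i the pool is every *other* appropriate-scored participant.
    score_lookup = {
        (p.participant_id, w): p.score_sheet.score(criterion, w)
        for p in cohort.participants
        for w in CANONICAL_WORDS
    }
    roms = roms.copy()
    roms["appropriate"] = [
        score_lookup[(pid, w)] for pid, w in zip(roms["participant"], roms["word"])
    ]

    records = []
    for (word, measurement), grp in roms.groupby(["word", "measurement"], sort=False):
        z_by_participant: dict[str, list[float]] = {}
        ok = True
        for _, sub in grp.groupby("interval_index", sort=True):
            values = sub["rom"].to_numpy(float)
            app = sub["appropriate"].to_numpy(bool)
            pids = sub["participant"].to_numpy()
            pool = values[app]
            n_pool = pool.size
            sum_pool, sumsq_pool = pool.sum(), (pool**2).sum()
            for value, is_app, pid in zip(values, app, pids):
                n = n_pool - int(is_app)
                s = sum_pool - (value if is_app else 0.0)
                ss = sumsq_pool - (value**2 if is_app else 0.0)
                if n < 2:
                    logger.warning(
                        "fewer than 2 reference participants for %s/%s (%s); "
                        "feature rows skipped", word, measurement, criterion,
                    )
                    ok = False
                    break
                mean = s / n
                var = max((ss - n * mean**2) / (n - 1), 0.0)
                sd = float(np.sqrt(var))
                if sd == 0.0:
                    raise DegenerateReferenceError(
                        f"degenerate reference (all values equal) for "
                        f"({word}, {criterion}, {measurement})"
                    )
                z_by_participant.setdefault(pid, []).append(abs((value - mean) / sd))
            if not ok:
                break
        if not ok:
            continue
        for pid, zs in z_by_participant.items():
            label = "appropriate" if score_lookup[(pid, word)] else "inappropriate"
            records.append(
                (pid, word, criterion, measurement, float(np.mean(zs)), label)
            )
    table = pd.DataFrame(
        records,
        columns=["participant", "word", "criterion", "measurement", "feature", "label"],
    )
    if not table.empty and not np.isfinite(table["feature"]).all():
        raise FeatureError("non-finite feature value")
    return table
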