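"""Domain types and delimited-text I/O for mandibular-probe-word cohorts.

A cohort bundles three kinds of records:

* per-participant **score sheets** — 5 binary mandibular criteria
  (jaw range, jaw control/stability, open-close phase, voicing transitions,
  syllable structure) scored appropriate (1) / inappropriate (0) for each of
  the 10 mandibular-stage probe words;
* per-participant **metadata** — diagnostic group (TD / SSD), age, and
  optional phoneme-accuracy percentages (PCC / PVC / PPC);
* per-(participant, word) **landmark trajectories** — frame-by-frame 2-D
  image coordinates of 11 named facial landmarks, recorded at 60 frames/s,
  plus one landmark set captured at rest.

Coordinates are image pixels (x rightward, y downward).  Every derived
kinematic measure is a ratio of distances, so the axis convention only
affects the sign of lateral deviation, whose absolute value is used
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 10 mandibular-stage probe words, in canonical order.
CANONICAL_WORDS: tuple[str, ...] = (
    "Ba", "Eye", "Map", "Um", "Ham", "Papa", "Bob", "Pam", "Pup", "Pie",
)

#: The five binary mandibular scoring criteria, in canonical order.
CRITERIA: tuple[str, ...] = (
    "jaw_range",
    "jaw_control",
    "phase",
    "voicing_transitions",
    "syllable_structure",
)

#: The 11 facial landmarks consumed by the kinematic measures.
LANDMARK_NAMES: tuple[str, ...] = (
    "cheilion_left",
    "cheilion_right",
    "stomion_superius",
    "stomion_inferius",
    "pogonion",
    "zygion_left",
    "zygion_right",
    "tragion_left",
    "tragion_right",
    "exocanthion_left",
    "exocanthion_right",
)

_LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARK_NAMES)}

#: Bilateral upper-face pairs whose rest distances define facial width.
BILATERAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("zygion_left", "zygion_right"),
    ("tragion_left", "tragion_right"),
    ("exocanthion_left", "exocanthion_right"),
)

GROUPS: tuple[str, str] = ("TD", "SSD")

_WORD_LOOKUP = {w.lower(): w for w in CANONICAL_WORDS}


class CohortError(ValueError):
    """Structural or validation error in cohort data."""


def canonical_word(word: str) -> str:
    """Return the canonical spelling of a probe word (case-insensitive)."""
    try:
        return _WORD_LOOKUP[str(word).strip().lower()]
    except KeyError:
        raise CohortError(
            f"unknown probe word {word!r}; expected one of {CANONICAL_WORDS}"
        ) from None


def landmark_index(name: str) -> int:
    """Row index of a landmark in a trajectory's coordinate array."""
    try:
        return _LANDMARK_INDEX[name]
    except KeyError:
        raise CohortError(f"unknown landmark {name!r}") from None


@dataclass(frozen=True)
class LandmarkTrajectory:
    """One word production: frames x 11 landmarks x (x, y), plus a rest posture.

    ``coords`` has shape ``(n_frames, 11, 2)`` and ``rest`` shape ``(11, 2)``,
    rows ordered as :data:`LANDMARK_NAMES`.
    """

    participant_id: str
    word: str
    coords: np.ndarray
    rest: np.ndarray
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        rest = np.asarray(self.rest, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "rest", rest)
        object.__setattr__(self, "word", canonical_word(self.word))
        if coords.ndim != 3 or coords.shape[1:] != (len(LANDMARK_NAMES), 2):
            raise CohortError(
                f"coords must have shape (n_frames, {len(LANDMARK_NAMES)}, 2); "
                f"got {coords.shape}"
            )
        if coords.shape[0] < 2:
            raise CohortError(
                f"{self.participant_id}/{self.word}: trajectory needs >= 2 frames"
            )
        if rest.shape != (len(LANDMARK_NAMES), 2):
            raise CohortError(
                f"{self.participant_id}/{self.word}: rest frame must contain all "
                f"{len(LANDMARK_NAMES)} landmarks"
            )
        if not np.isfinite(coords).all() or not np.isfinite(rest).all():
            raise CohortError(
                f"{self.participant_id}/{self.word}: non-finite coordinate"
            )
        if not self.frame_rate > 0:
            raise CohortError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def landmark(self, name: str) -> np.ndarray:
        """Per-frame (x, y) of one landmark, shape ``(n_frames, 2)``."""
        return self.coords[:, landmark_index(name), :]

    def rest_landmark(self, name: str) -> np.ndarray:
        return self.rest[landmark_index(name), :]

    def transformed(self, matrix: np.ndarray, offset: Sequence[float]) -> "LandmarkTrajectory":
        """Apply an affine map ``p -> matrix @ p + offset`` to every landmark
        (rest frame included).  Used to probe similarity invariance."""
        matrix = np.asarray(matrix, dtype=float)
        offset = np.asarray(offset, dtype=float)
        return LandmarkTrajectory(
            participant_id=self.participant_id,
            word=self.word,
            coords=self.coords @ matrix.T + offset,
            rest=self.rest @ matrix.T + offset,
            frame_rate=self.frame_rate,
        )


@dataclass(frozen=True)
class ScoreSheet:
    """5 x 10 binary appropriateness matrix (criteria x canonical words)."""

    participant_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=int)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(CRITERIA), len(CANONICAL_WORDS)):
            raise CohortError(
                f"{self.participant_id}: scores must be "
                f"{len(CRITERIA)}x{len(CANONICAL_WORDS)}; got {scores.shape}"
            )
        if not np.isin(scores, (0, 1)).all():
            bad = scores[~np.isin(scores, (0, 1))][0]
            raise CohortError(
                f"{self.participant_id}: score entries must be 0 or 1 (found {bad})"
            )

    def criterion_scores(self, criterion: str) -> np.ndarray:
        if criterion not in CRITERIA:
            raise CohortError(f"unknown criterion {criterion!r}")
        return self.scores[CRITERIA.index(criterion)]

    def score(self, criterion: str, word: str) -> int:
        return int(self.criterion_scores(criterion)[CANONICAL_WORDS.index(canonical_word(word))])

    @property
    def criterion_totals(self) -> dict[str, int]:
        return {c: int(t) for c, t in zip(CRITERIA, self.scores.sum(axis=1))}

    @property
    def percent_total(self) -> float:
        """Mandibular percent total: 100 x (sum of all 50 entries) / 50."""
        return 100.0 * float(self.scores.sum()) / self.scores.size


def mandibular_summary(sheet: ScoreSheet) -> dict[str, float]:
    """Per-criterion totals (0-10) plus the mandibular percent total (0-100)."""
    out: dict[str, float] = dict(sheet.criterion_totals)
    out["percent_total"] = sheet.percent_total
    return out


@dataclass(frozen=True)
class Participant:
    participant_id: str
    group: str
    age_months: int
    score_sheet: ScoreSheet
    phoneme_accuracy: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(
                f"{self.participant_id}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.age_months < 0:
            raise CohortError(f"{self.participant_id}: age_months must be >= 0")
        if self.score_sheet.participant_id != self.participant_id:
            raise CohortError(
                f"score sheet id {self.score_sheet.participant_id!r} does not match "
                f"participant {self.participant_id!r}"
            )
        if self.phoneme_accuracy is not None:
            for key, value in self.phoneme_accuracy.items():
                if not 0.0 <= float(value) <= 100.0:
                    raise CohortError(
                        f"{self.participant_id}: phoneme percentage {key}={value} "
                        "outside [0, 100]"
                    )


@dataclass
class Cohort:
    """Participants plus their landmark trajectories keyed by (id, word)."""

    participants: list[Participant]
    trajectories: dict[tuple[str, str], LandmarkTrajectory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate participant ids: {dupes}")
        known = set(ids)
        for pid, word in self.trajectories:
            if pid not in known:
                raise CohortError(
                    f"trajectory references unknown participant {pid!r}"
                )
            canonical_word(word)

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.participant_id == pid:
                return p
        raise CohortError(f"unknown participant {pid!r}")

    def trajectory(self, pid: str, word: str) -> LandmarkTrajectory:
        key = (pid, canonical_word(word))
        try:
            return self.trajectories[key]
        except KeyError:
            raise CohortError(f"no trajectory for {key}") from None

    def groups(self) -> dict[str, list[Participant]]:
        out: dict[str, list[Participant]] = {g: [] for g in GROUPS}
        for p in self.participants:
            out[p.group].append(p)
        return out


# ---------------------------------------------------------------------------
# File I/O.  All formats are UTF-8 CSV with a header row.
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["participant", "word", "frame", "landmark", "x", "y"]
_SCORE_COLUMNS = ["participant", "criterion"] + [w.lower() for w in CANONICAL_WORDS]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")


def load_landmark_table(path, frame_rate: float = 60.0) -> dict[tuple[str, str], LandmarkTrajectory]:
    """Read a long-format landmark CSV into trajectories.

    Expected columns: ``participant, word, frame, landmark, x, y``.  Frames of
    each (participant, word) must be consecutive integers from 0; rows with
    ``frame = -1`` encode the rest posture.  A trajectory without explicit rest
    rows falls back to the first frame of that participant's "Um" production
    (a near-closed posture); the fallback is logged.
    """
    df = pd.read_csv(path)
    _require_columns(df, _TRAJ_COLUMNS, str(path))
    df = df.copy()
    df["word"] = [canonical_word(w) for w in df["word"]]
    unknown = set(df["landmark"]) - set(LANDMARK_NAMES)
    if unknown:
        raise CohortError(f"{path}: unknown landmark names {sorted(unknown)}")
    dup = df.duplicated(subset=["participant", "word", "frame", "landmark"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CohortError(
            f"{path}: duplicate row for participant={row['participant']!r} "
            f"word={row['word']!r} frame={int(row['frame'])} landmark={row['landmark']!r}"
        )
    if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
        bad = df[~np.isfinite(df[["x", "y"]].astype(float)).all(axis=1)].iloc[0]
        raise CohortError(
            f"{path}: non-finite coordinate for participant={bad['participant']!r} "
            f"word={bad['word']!r} frame={int(bad['frame'])}"
        )

    n_marks = len(LANDMARK_NAMES)
    raw: dict[tuple[str, str], tuple[np.ndarray, np.ndarray | None]] = {}
    for (pid, word), grp in df.groupby(["participant", "word"], sort=False):
        pid = str(pid)
        rest_rows = grp[grp["frame"] == -1]
        move_rows = grp[grp["frame"] != -1]
        frames = np.sort(move_rows["frame"].unique())
        if len(frames) == 0 or frames[0] != 0 or not np.array_equal(
            frames, np.arange(len(frames))
        ):
            raise CohortError(
                f"{path}: frames of {pid}/{word} must be consecutive integers from 0"
            )
        coords = np.full((len(frames), n_marks, 2), np.nan)
        idx = move_rows["frame"].to_numpy(int)
        marks = np.array([landmark_index(m) for m in move_rows["landmark"]])
        coords[idx, marks, 0] = move_rows["x"].to_numpy(float)
        coords[idx, marks, 1] = move_rows["y"].to_numpy(float)
        incomplete = np.isnan(coords).any(axis=(1, 2))
        if incomplete.any():
            f = int(np.flatnonzero(incomplete)[0])
            missing = [
                LANDMARK_NAMES[m]
                for m in np.flatnonzero(np.isnan(coords[f]).any(axis=1))
            ]
            raise CohortError(
                f"{path}: {pid}/{word} frame {f} missing landmark(s) {missing}"
            )
        rest: np.ndarray | None = None
        if len(rest_rows):
            rest = np.full((n_marks, 2), np.nan)
            marks = np.array([landmark_index(m) for m in rest_rows["landmark"]])
            rest[marks, 0] = rest_rows["x"].to_numpy(float)
            rest[marks, 1] = rest_rows["y"].to_numpy(float)
            if np.isnan(rest).any():
                missing = [
                    LANDMARK_NAMES[m]
                    for m in np.flatnonzero(np.isnan(rest).any(axis=1))
                ]
                raise CohortError(
                    f"{path}: {pid}/{word} rest frame missing landmark(s) {missing}"
                )
        raw[(pid, word)] = (coords, rest)

    trajectories: dict[tuple[str, str], LandmarkTrajectory] = {}
    for (pid, word), (coords, rest) in raw.items():
        if rest is None:
            um = raw.get((pid, "Um"))
            if um is None:
                raise CohortError(
                    f"{path}: {pid}/{word} has no rest rows (frame = -1) and no "
                    "'Um' production to fall back on"
                )
            rest = um[0][0]
            logger.warning(
                "%s/%s: no rest rows; using first frame of 'Um' as rest posture",
                pid, word,
            )
        trajectories[(pid, word)] = LandmarkTrajectory(
            participant_id=pid, word=word, coords=coords, rest=rest,
            frame_rate=frame_rate,
        )
    return trajectories


def write_landmark_table(trajectories: Mapping[tuple[str, str], LandmarkTrajectory], path) -> None:
    records = []
    for (pid, word), traj in trajectories.items():
        for mi, name in enumerate(LANDMARK_NAMES):
            records.append((pid, word, -1, name, traj.rest[mi, 0], traj.rest[mi, 1]))
        for f in range(traj.n_frames):
            for mi, name in enumerate(LANDMARK_NAMES):
                records.append(
                    (pid, word, f, name, traj.coords[f, mi, 0], traj.coords[f, mi, 1])
                )
    pd.DataFrame(records, columns=_TRAJ_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )


def load_score_table(path) -> list[ScoreSheet]:
    """Read a score-sheet CSV: one row per participant x criterion, a column per
    canonical word (lower-case headers), entries in {0, 1}."""
    df = pd.read_csv(path)
    _require_columns(df, _SCORE_COLUMNS, str(path))
    word_cols = [w.lower() for w in CANONICAL_WORDS]
    values = df[word_cols].to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = values[~np.isin(values, (0, 1))][0]
        raise CohortError(f"{path}: score entry {bad!r} outside {{0, 1}}")
    sheets = []
    for pid, grp in df.groupby("participant", sort=False):
        crits = set(grp["criterion"])
        missing = [c for c in CRITERIA if c not in crits]
        if missing:
            raise CohortError(f"{path}: participant {pid!r} missing criteria {missing}")
        extra = crits - set(CRITERIA)
        if extra:
            raise CohortError(f"{path}: participant {pid!r} unknown criteria {sorted(extra)}")
        scores = np.stack(
            [
                grp[grp["criterion"] == c][word_cols].to_numpy(int)[0]
                for c in CRITERIA
            ]
        )
        sheets.append(ScoreSheet(participant_id=str(pid), scores=scores))
    return sheets


def write_score_table(sheets: Iterable[ScoreSheet], path) -> None:
    records = []
    for sheet in sheets:
        for ci, criterion in enumerate(CRITERIA):
            records.append(
                [sheet.participant_id, criterion, *sheet.scores[ci].tolist()]
            )
    pd.DataFrame(records, columns=_SCORE_COLUMNS).to_csv(path, index=False)


def load_participant_table(path, sheets: Iterable[ScoreSheet]) -> list[Participant]:
    """Read participant metadata (``participant,group,age_months[,pcc,pvc,ppc]``)
    and join it against previously loaded score sheets."""
    df = pd.read_csv(path)
    _require_columns(df, ["participant", "group", "age_months"], str(path))
    by_id = {s.participant_id: s for s in sheets}
    participants = []
    for _, row in df.iterrows():
        pid = str(row["participant"])
        if pid not in by_id:
            raise CohortError(f"{path}: participant {pid!r} has no score sheet")
        phoneme = None
        if {"pcc", "pvc", "ppc"} <= set(df.columns) and np.isfinite(
            [row["pcc"], row["pvc"], row["ppc"]]
        ).all():
            phoneme = {k: float(row[k]) for k in ("pcc", "pvc", "ppc")}
        participants.append(
            Participant(
                participant_id=pid,
                group=str(row["group"]),
                age_months=int(row["age_months"]),
                score_sheet=by_id[pid],
                phoneme_accuracy=phoneme,
            )
        )
    return participants


def write_participant_table(participants: Iterable[Participant], path) -> None:
    records = []
    for p in participants:
        acc = p.phoneme_accuracy or {}
        records.append(
            (
                p.participant_id,
                p.group,
                p.age_months,
                acc.get("pcc", np.nan),
                acc.get("pvc", np.nan),
                acc.get("ppc", np.nan),
            )
        )
    pd.DataFrame(
        records, columns=["participant", "group", "age_months", "pcc", "pvc", "ppc"]
    ).to_csv(path, index=False, float_format="%.4f")


def load_cohort(trajectory_path, score_path, participant_path, frame_rate: float = 60.0) -> Cohort:
    sheets = load_score_table(score_path)
    participants = load_participant_table(participant_path, sheets)
    trajectories = load_landmark_table(trajectory_path, frame_rate=frame_rate)
    return Cohort(participants=participants, trajectories=trajectories)


def write_cohort(cohort: Cohort, trajectory_path, score_path, participant_path) -> None:
    write_landmark_table(cohort.trajectories, trajectory_path)
    write_score_table([p.score_sheet for p in cohort.participants], score_path)
    write_participant_table(cohort.participants, participant_path)
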