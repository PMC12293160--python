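"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Two generators are provided:

* :func:`generate_score_sheets` draws binary score sheets entry-wise from
  per-criterion Bernoulli probabilities for the TD and SSD groups.  The
  default probabilities are the published per-criterion mean totals of the
  41 TD / 13 SSD validation cohort divided by 10, so criterion totals are
  Binomial(10, p) with the observed group means.

* :func:`generate_trajectory` synthesises landmark trajectories whose jaw
  gestures follow one raised-cosine open-close bump per syllable, with the
  appropriateness flags deterministically modulating opening amplitude
  (jaw range) and lateral / frame-to-frame noise (jaw control).

:func:`generate_cohort` couples the two: each participant's kinematic
generation flags are copied from their perceptual jaw-range / jaw-control
scores with a configurable agreement probability, enabling controlled
parameter-recovery experiments downstream.

All randomness flows through explicit integer seeds; identical parameters
and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import (
    CANONICAL_WORDS,
    CRITERIA,
    Cohort,
    LandmarkTrajectory,
    Participant,
    ScoreSheet,
    canonical_word,
    landmark_index,
)

#: Default per-criterion appropriateness probabilities, columns (TD, SSD):
#: the published group mean criterion totals of the validation cohort / 10.
DEFAULT_P_APPROPRIATE = np.array(
    [
        [0.829, 0.646],  # jaw_range
        [0.695, 0.538],  # jaw_control
        [0.654, 0.523],  # phase
        [0.907, 0.792],  # voicing_transitions
        [0.976, 0.954],  # syllable_structure
    ]
)

#: Published phoneme-accuracy group summaries (mean, SD), used to draw the
#: optional PCC/PVC/PPC metadata: keys map to (TD, SSD) pairs.
DEFAULT_PHONEME_SUMMARIES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "pvc": ((91.23, 8.30), (79.50, 16.17)),
    "pcc": ((89.93, 10.22), (80.18, 13.84)),
    "ppc": ((89.93, 7.31), (79.75, 9.93)),
}

#: Gestures (open-close jaw cycles) per word; Papa carries two syllables.
DEFAULT_SYLLABLE_COUNTS: dict[str, int] = {w: 1 for w in CANONICAL_WORDS}
DEFAULT_SYLLABLE_COUNTS["Papa"] = 2


class SyntheticError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class ScoreGenParams:
    """Parameters of the score-sheet generator."""

    n_td: int = 41
    n_ssd: int = 13
    p_appropriate: np.ndarray = field(
        default_factory=lambda: DEFAULT_P_APPROPRIATE.copy()
    )
    with_phoneme_accuracy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.p_appropriate, dtype=float)
        object.__setattr__(self, "p_appropriate", p)
        if p.shape != (len(CRITERIA), 2):
            raise SyntheticError(
                f"p_appropriate must be {len(CRITERIA)}x2 (criteria x (TD, SSD))"
            )
        if np.any((p < 0) | (p > 1)):
            raise SyntheticError("probabilities must lie in [0, 1]")
        if self.n_td < 0 or self.n_ssd < 0:
            raise SyntheticError("group counts must be >= 0")


@dataclass(frozen=True)
class TrajectoryGenParams:
    """Parameters of the landmark-trajectory generator.

    Length scales are fractions of ``face_width_px`` unless stated otherwise.
    The flag-dependent knobs are: ``range_scale_inappropriate`` multiplies the
    opening amplitude when the jaw-range flag is 0 (< 1 restricted, > 1
    overextended); ``lateral_sd_*`` set the SD of per-frame pogonion lateral
    noise by jaw-control flag; ``velocity_jitter_inappropriate`` is the SD of
    per-frame mouth-height noise added when the jaw-control flag is 0.
    ``amplitude_between_sd`` is the between-production SD of the opening
    amplitude, without which all appropriate productions would be identical.
    """

    duration_s: float = 0.8
    frame_rate: float = 60.0
    face_width_px: float = 200.0
    open_amplitude: float = 0.25
    amplitude_between_sd: float = 0.02
    rest_height: float = 0.02
    range_scale_inappropriate: float = 0.5
    lateral_sd_appropriate: float = 0.005
    lateral_sd_inappropriate: float = 0.02
    velocity_jitter_inappropriate: float = 0.05
    width_noise_sd: float = 0.001
    syllable_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SYLLABLE_COUNTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise SyntheticError("duration_s must be positive")
        if self.frame_rate <= 0:
            raise SyntheticError("frame_rate must be positive")
        for name in (
            "amplitude_between_sd",
            "lateral_sd_appropriate",
            "lateral_sd_inappropriate",
            "velocity_jitter_inappropriate",
            "width_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")


def _participant_ids(n_td: int, n_ssd: int) -> list[tuple[str, str]]:
    return [(f"TD{i + 1:03d}", "TD") for i in range(n_td)] + [
        (f"SSD{i + 1:03d}", "SSD") for i in range(n_ssd)
    ]


def generate_score_sheets(params: ScoreGenParams) -> list[Participant]:
    """Draw one participant (metadata + score sheet) per cohort member.

    Each of the 50 sheet entries is an independent Bernoulli draw with the
    probability of that participant's group and criterion.  Ages are uniform
    over 36-42 months; optional PCC/PVC/PPC are Gaussian draws from the
    published group summaries, clipped to [0, 100].
    """
    rng = np.random.default_rng(params.seed)
    participants = []
    for pid, group in _participant_ids(params.n_td, params.n_ssd):
        col = 0 if group == "TD" else 1
        p = params.p_appropriate[:, col][:, None]
        scores = (rng.random((len(CRITERIA), len(CANONICAL_WORDS))) < p).astype(int)
        phoneme = None
        if params.with_phoneme_accuracy:
            phoneme = {}
            for key, summaries in DEFAULT_PHONEME_SUMMARIES.items():
                mean, sd = summaries[col]
                phoneme[key] = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
        participants.append(
            Participant(
                participant_id=pid,
                group=group,
                age_months=int(rng.integers(36, 43)),
                score_sheet=ScoreSheet(participant_id=pid, scores=scores),
                phoneme_accuracy=phoneme,
            )
        )
    return participants


def _face_geometry(w: float) -> np.ndarray:
    """Static landmark layout for a face of width ``w`` (image pixels, y down).

    Bilateral distances are 0.9w (exocanthion), 1.1w (tragion) and 1.0w
    (zygion), so their mean — the facial-width normalizer — equals ``w``.
    """
    pts = np.zeros((11, 2))

    def put(name: str, x: float, y: float) -> None:
        pts[landmark_index(name)] = (x, y)

    put("exocanthion_left", -0.45 * w, 0.00 * w)
    put("exocanthion_right", 0.45 * w, 0.00 * w)
    put("tragion_left", -0.55 * w, 0.10 * w)
    put("tragion_right", 0.55 * w, 0.10 * w)
    put("zygion_left", -0.50 * w, 0.25 * w)
    put("zygion_right", 0.50 * w, 0.25 * w)
    put("cheilion_left", -0.20 * w, 0.60 * w)
    put("cheilion_right", 0.20 * w, 0.60 * w)
    # stomion and pogonion are dynamic; filled per frame
    return pts


def _gesture_heights(
    t: np.ndarray,
    duration: float,
    n_syllables: int,
    amplitude: float,
    rest: float,
    amplitude_noise: np.ndarray | None = None,
) -> np.ndarray:
    """Mouth height over time: rest height plus one raised-cosine bump per
    syllable, syllables occupying consecutive equal windows.

    ``amplitude_noise`` holds per-frame deviations of the achieved opening
    amplitude (jaw-control instability); it is modulated by the gesture
    envelope so the mouth still closes cleanly between syllables.
    """
    h = np.full_like(t, rest)
    window = duration / n_syllables
    for k in range(n_syllables):
        local = (t - k * window) / window
        mask = (local >= 0) & (local <= 1)
        envelope = np.sin(np.pi * local[mask]) ** 2
        amp = amplitude
        if amplitude_noise is not None:
            amp = amplitude + amplitude_noise[mask]
        h[mask] += amp * envelope
    return h


def generate_trajectory(
    word: str,
    jaw_range_flag: int,
    jaw_control_flag: int,
    params: TrajectoryGenParams,
    rng: np.random.Generator | None = None,
    participant_id: str = "synthetic",
) -> LandmarkTrajectory:
    """Synthesise one word production.

    ``jaw_range_flag`` / ``jaw_control_flag`` follow the scoring convention:
    1 = appropriate, 0 = inappropriate.
    """
    word = canonical_word(word)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    w = params.face_width_px
    n_frames = max(2, int(round(params.duration_s * params.frame_rate)))
    t = np.arange(n_frames) / params.frame_rate

    amplitude = params.open_amplitude * w
    if params.amplitude_between_sd > 0:
        amplitude += rng.normal(0.0, params.amplitude_between_sd * w)
        amplitude = max(amplitude, 0.05 * params.open_amplitude * w)
    if not jaw_range_flag:
        amplitude *= params.range_scale_inappropriate

    n_syll = int(dict(params.syllable_counts).get(word, 1))
    rest_h = params.rest_height * w
    amplitude_noise = None
    if not jaw_control_flag and params.velocity_jitter_inappropriate > 0:
        amplitude_noise = rng.normal(
            0.0, params.velocity_jitter_inappropriate * w, size=n_frames
        )
    height = _gesture_heights(
        t, params.duration_s, n_syll, amplitude, rest_h, amplitude_noise
    )
    height = np.maximum(height, 0.2 * rest_h)

    lateral_sd = (
        params.lateral_sd_appropriate
        if jaw_control_flag
        else params.lateral_sd_inappropriate
    )
    lateral = (
        rng.normal(0.0, lateral_sd * w, size=n_frames)
        if lateral_sd > 0
        else np.zeros(n_frames)
    )

    base = _face_geometry(w)
    coords = np.broadcast_to(base, (n_frames, 11, 2)).copy()
    if params.width_noise_sd > 0:
        for name in ("cheilion_left", "cheilion_right"):
            coords[:, landmark_index(name), 0] += rng.normal(
                0.0, params.width_noise_sd * w, size=n_frames
            )
    mouth_y = 0.60 * w
    coords[:, landmark_index("stomion_superius")] = np.column_stack(
        [np.zeros(n_frames), mouth_y - height / 2.0]
    )
    coords[:, landmark_index("stomion_inferius")] = np.column_stack(
        [np.zeros(n_frames), mouth_y + height / 2.0]
    )
    # chin lowers with the opening gesture and carries the lateral noise
    coords[:, landmark_index("pogonion")] = np.column_stack(
        [lateral, 0.85 * w + 0.5 * height]
    )

    rest = base.copy()
    rest[landmark_index("stomion_superius")] = (0.0, mouth_y - rest_h / 2.0)
    rest[landmark_index("stomion_inferius")] = (0.0, mouth_y + rest_h / 2.0)
    rest[landmark_index("pogonion")] = (0.0, 0.85 * w + 0.5 * rest_h)

    return LandmarkTrajectory(
        participant_id=participant_id,
        word=word,
        coords=coords,
        rest=rest,
        frame_rate=params.frame_rate,
    )


def generate_cohort(
    score_params: ScoreGenParams | None = None,
    traj_params: TrajectoryGenParams | None = None,
    coupling: float = 1.0,
) -> Cohort:
    """Full synthetic cohort: score sheets plus trajectories for all 10 words.

    ``coupling`` is the probability that the kinematic generation flags equal
    the participant's perceptual jaw-range / jaw-control scores; with
    probability ``1 - coupling`` a flag is flipped.  ``coupling = 1``
    reproduces the scores exactly; ``coupling = 0.5`` makes the kinematics
    independent of the scores, putting downstream classification at chance.
    """
    if score_params is None:
        score_params = ScoreGenParams()
    if traj_params is None:
        traj_params = TrajectoryGenParams()
    if not 0.5 <= coupling <= 1.0:
        raise SyntheticError("coupling must lie in [0.5, 1]")

    participants = generate_score_sheets(score_params)
    master = np.random.default_rng(traj_params.seed)
    trajectories: dict[tuple[str, str], LandmarkTrajectory] = {}
    for participant in participants:
        sheet = participant.score_sheet
        for word in CANONICAL_WORDS:
            flags = {}
            for criterion in ("jaw_range", "jaw_control"):
                flag = sheet.score(criterion, word)
                if master.random() >= coupling:
                    flag = 1 - flag
                flags[criterion] = flag
            trajectories[(participant.participant_id, word)] = generate_trajectory(
                word,
                jaw_range_flag=flags["jaw_range"],
                jaw_control_flag=flags["jaw_control"],
                params=traj_params,
                rng=master,
                participant_id=participant.participant_id,
            )
    return Cohort(participants=participants, trajectories=trajectories)


def null_cohort_params(seed: int = 0, n_td: int = 41, n_ssd: int = 13) -> ScoreGenParams:
    """Score parameters with no group signal: both groups share the TD
    probabilities.  Useful for type-I-error and chance-level experiments."""
    p = DEFAULT_P_APPROPRIATE.copy()
    p[:, 1] = p[:, 0]
    return ScoreGenParams(n_td=n_td, n_ssd=n_ssd, p_appropriate=p, seed=seed)


def strong_effect_params(seed: int = 0, **overrides) -> TrajectoryGenParams:
    """Trajectory parameters with a strong, low-noise kinematic effect:
    markedly restricted openings for inappropriate jaw range and clearly
    elevated lateral / frame-to-frame noise for inappropriate jaw control."""
    defaults = dict(
        range_scale_inappropriate=0.3,
        amplitude_between_sd=0.01,
        lateral_sd_appropriate=0.003,
        lateral_sd_inappropriate=0.03,
        velocity_jitter_inappropriate=0.05,
        seed=seed,
    )
    defaults.update(overrides)
    return TrajectoryGenParams(**defaults)
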