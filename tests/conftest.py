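import numpy as np
import pytest

from jawprobe import (
    Cohort,
    LandmarkTrajectory,
    Participant,
    ScoreGenParams,
    ScoreSheet,
    TrajectoryGenParams,
    generate_cohort,
)
from jawprobe.cohort import LANDMARK_NAMES, landmark_index


def make_trajectory(
    participant_id="P1",
    word="Ba",
    n_frames=30,
    face_width=200.0,
    mouth_width=80.0,
    heights=None,
    lateral=None,
    frame_rate=60.0,
):
    """Hand-built trajectory with controllable mouth height / chin lateral
    position per frame; upper face static with bilateral distances 0.9w,
    1.1w, 1.0w (mean = face_width)."""
    w = face_width
    if heights is None and lateral is not None:
        heights = np.full(len(np.asarray(lateral)), 20.0)
    elif heights is None:
        heights = np.full(n_frames, 20.0)
    heights = np.asarray(heights, float)
    n_frames = len(heights)
    if lateral is None:
        lateral = np.zeros(n_frames)
    lateral = np.asarray(lateral, float)

    base = np.zeros((len(LANDMARK_NAMES), 2))

    def put(pts, name, x, y):
        pts[landmark_index(name)] = (x, y)

    put(base, "exocanthion_left", -0.45 * w, 0.0)
    put(base, "exocanthion_right", 0.45 * w, 0.0)
    put(base, "tragion_left", -0.55 * w, 0.1 * w)
    put(base, "tragion_right", 0.55 * w, 0.1 * w)
    put(base, "zygion_left", -0.5 * w, 0.25 * w)
    put(base, "zygion_right", 0.5 * w, 0.25 * w)
    put(base, "cheilion_left", -mouth_width / 2, 0.6 * w)
    put(base, "cheilion_right", mouth_width / 2, 0.6 * w)

    coords = np.broadcast_to(base, (n_frames, len(LANDMARK_NAMES), 2)).copy()
    coords[:, landmark_index("stomion_superius")] = np.column_stack(
        [np.zeros(n_frames), 0.6 * w - heights / 2]
    )
    coords[:, landmark_index("stomion_inferius")] = np.column_stack(
        [np.zeros(n_frames), 0.6 * w + heights / 2]
    )
    coords[:, landmark_index("pogonion")] = np.column_stack(
        [lateral, 0.85 * w + heights / 2]
    )

    rest = base.copy()
    put(rest, "stomion_superius", 0.0, 0.6 * w - 2.0)
    put(rest, "stomion_inferius", 0.0, 0.6 * w + 2.0)
    put(rest, "pogonion", 0.0, 0.85 * w)
    return LandmarkTrajectory(
        participant_id=participant_id,
        word=word,
        coords=coords,
        rest=rest,
        frame_rate=frame_rate,
    )


def make_participant(pid, group="TD", scores=None, age=38, phoneme=None):
    if scores is None:
        scores = np.ones((5, 10), int)
    return Participant(
        participant_id=pid,
        group=group,
        age_months=age,
        score_sheet=ScoreSheet(participant_id=pid, scores=scores),
        phoneme_accuracy=phoneme,
    )


@pytest.fixture
def toy_trajectory():
    return make_trajectory()


@pytest.fixture(scope="session")
def small_cohort():
    """Small perfectly coupled synthetic cohort reused by feature tests."""
    return generate_cohort(
        ScoreGenParams(n_td=12, n_ssd=4, seed=7),
        TrajectoryGenParams(seed=8),
        coupling=1.0,
    )


@pytest.fixture(scope="session")
def study_scale_cohort():
    """41 TD + 13 SSD cohort with default generator parameters."""
    return generate_cohort(
        ScoreGenParams(seed=17), TrajectoryGenParams(seed=18), coupling=1.0
    )
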