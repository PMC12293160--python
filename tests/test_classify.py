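"""Word-level and stacked classification: contracts, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

from jawprobe import (
    ClassificationError,
    RegularizationGrid,
    StackedDiagnosisModel,
    WordClassificationModel,
)
from jawprobe.cohort import CANONICAL_WORDS, CRITERIA
from tests.conftest import make_participant


def feature_frame(features_by_pid_word, labels_by_pid_word, criterion="jaw_range",
                  measurement="mouth_opening"):
    rows = []
    for key, feature in features_by_pid_word.items():
        pid, word = key
        rows.append((pid, word, criterion, measurement, feature,
                     labels_by_pid_word[key]))
    return pd.DataFrame(
        rows,
        columns=["participant", "word", "criterion", "measurement", "feature", "label"],
    )


def synthetic_features(n=40, separation=5.0, seed=0, words=CANONICAL_WORDS):
    """Features with appropriate ~ N(0, 0.1), inappropriate ~ N(sep, 0.1)."""
    rng = np.random.default_rng(seed)
    features, labels = {}, {}
    for word in words:
        flags = rng.random(n) < 0.3
        for i in range(n):
            pid = f"P{i:03d}"
            label = "inappropriate" if flags[i] else "appropriate"
            mean = separation if flags[i] else 0.0
            features[(pid, word)] = abs(rng.normal(mean, 0.1))
            labels[(pid, word)] = label
    return feature_frame(features, labels)


class TestRegularizationGrid:
    def test_entry_enumeration_order_deterministic(self):
        grid = RegularizationGrid(
            mix_ratios=(0.0, 1.0), strengths=(0.1, 1.0), class_weighting=("balanced",)
        )
        assert grid.entries() == [
            (0.0, 0.1, "balanced"), (0.0, 1.0, "balanced"),
            (1.0, 0.1, "balanced"), (1.0, 1.0, "balanced"),
        ]

    def test_invalid_grids_rejected(self):
        with pytest.raises(ClassificationError):
            RegularizationGrid(strengths=())
        with pytest.raises(ClassificationError):
            RegularizationGrid(strengths=(-1.0,))
        with pytest.raises(ClassificationError):
            RegularizationGrid(mix_ratios=(1.5,))


class TestWordClassification:
    def test_separable_features_perfect_pooled_accuracy(self):
        table = synthetic_features(n=40, separation=5.0, seed=1)
        results = WordClassificationModel(
            table, "jaw_range", measurements=("mouth_opening",),
            grid=RegularizationGrid.small(),
        ).fit(seed=0)
        assert results.balanced_accuracy == 1.0
        assert len(results.predictions) == 400

    def test_constant_feature_balanced_weighting_chance_accuracy(self):
        """Closed form: with a constant feature the model is intercept-only;
        it predicts a single class, so sensitivity + specificity = 1 and
        balanced accuracy is exactly 0.5."""
        rng = np.random.default_rng(2)
        features, labels = {}, {}
        for word in CANONICAL_WORDS:
            for i in range(20):
                pid = f"P{i:03d}"
                features[(pid, word)] = 1.0
                labels[(pid, word)] = (
                    "inappropriate" if rng.random() < 0.3 else "appropriate"
                )
        table = feature_frame(features, labels)
        results = WordClassificationModel(
            table, "jaw_range", measurements=("mouth_opening",),
            grid=RegularizationGrid.single(mix=0.0, strength=1.0, weighting="balanced"),
        ).fit(seed=0)
        assert results.balanced_accuracy == pytest.approx(0.5)

    def test_single_class_words_skipped_with_warning(self):
        table = synthetic_features(n=30, separation=5.0, seed=3)
        mask = table["word"] == "Ba"
        table.loc[mask, "label"] = "appropriate"
        with pytest.warns(UserWarning, match="Ba"):
            results = WordClassificationModel(
                table, "jaw_range", measurements=("mouth_opening",),
                grid=RegularizationGrid.single(),
            ).fit(seed=0)
        assert results.skipped_words == ("Ba",)
        assert len(results.predictions) == 270

    def test_participant_order_invariance(self):
        table = synthetic_features(n=25, separation=1.0, seed=4)
        grid = RegularizationGrid.single(mix=0.0, strength=1.0)
        direct = WordClassificationModel(
            table, "jaw_range", measurements=("mouth_opening",), grid=grid
        ).fit(seed=0)
        shuffled = WordClassificationModel(
            table.sample(frac=1.0, random_state=9),
            "jaw_range", measurements=("mouth_opening",), grid=grid,
        ).fit(seed=0)
        a = direct.predictions.sort_values(["participant", "word"]).reset_index(drop=True)
        b = shuffled.predictions.sort_values(["participant", "word"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-8)

    def test_loocv_purity_label_flip(self):
        """At fixed hyperparameters, flipping the held-out participant's own
        label must not change their prediction."""
        table = synthetic_features(n=20, separation=1.5, seed=5)
        grid = RegularizationGrid.single(mix=0.0, strength=1.0)
        baseline = WordClassificationModel(
            table, "jaw_range", measurements=("mouth_opening",), grid=grid
        ).fit(seed=0)
        flipped = table.copy()
        mask = (flipped["participant"] == "P000") & (flipped["word"] == "Ba")
        flipped.loc[mask, "label"] = np.where(
            flipped.loc[mask, "label"] == "appropriate", "inappropriate", "appropriate"
        )
        result = WordClassificationModel(
            flipped, "jaw_range", measurements=("mouth_opening",), grid=grid
        ).fit(seed=0)
        sel = lambda r: r.predictions.query("participant == 'P000' and word == 'Ba'")
        assert sel(baseline)["prob_inappropriate"].iloc[0] == pytest.approx(
            sel(result)["prob_inappropriate"].iloc[0], abs=1e-9
        )

    def test_infinite_lasso_collapses_to_single_class(self):
        """Strength -> infinity shrinks all slopes to zero; unweighted fits
        predict the majority class everywhere."""
        table = synthetic_features(n=30, separation=5.0, seed=6)
        results = WordClassificationModel(
            table, "jaw_range", measurements=("mouth_opening",),
            grid=RegularizationGrid.single(mix=1.0, strength=1e6, weighting="none"),
        ).fit(seed=0)
        assert results.predictions["predicted"].nunique() == 1
        # majority class is "appropriate" (flag rate 0.3) -> all negative
        assert results.predictions["predicted"].iloc[0] == 0


class TestStackedDiagnosis:
    @staticmethod
    def participants_from_vectors(vectors_by_criterion, groups, prefix="P"):
        n = len(groups)
        participants = []
        for i in range(n):
            scores = np.stack(
                [vectors_by_criterion[c][i] for c in CRITERIA]
            ).astype(int)
            participants.append(
                make_participant(f"{prefix}{i:03d}", group=groups[i], scores=scores)
            )
        return participants

    def test_sparse_recovery_when_one_criterion_carries_signal(self):
        """With signal only in jaw range and lasso available, the meta-model
        concentrates weight there and shrinks the rest to zero."""
        rng = np.random.default_rng(7)
        n_td, n_ssd = 30, 12
        groups = ["TD"] * n_td + ["SSD"] * n_ssd
        vectors = {}
        for c in CRITERIA:
            if c == "jaw_range":
                vectors[c] = np.array(
                    [np.ones(10, int) if g == "TD" else np.zeros(10, int) for g in groups]
                )
            else:
                vectors[c] = rng.integers(0, 2, size=(len(groups), 10))
        participants = self.participants_from_vectors(vectors, groups)
        results = StackedDiagnosisModel(
            participants,
            grid=RegularizationGrid.single(mix=1.0, strength=1.0),
            meta_grid=RegularizationGrid.single(mix=1.0, strength=1.0),
        ).fit(seed=0)
        weights = results.meta_weights
        assert weights["jaw_range"] > 0.9
        assert results.balanced_accuracy == 1.0

    def test_identical_criteria_share_weight_without_changing_predictions(self):
        """Fully redundant criterion vectors: the meta weight spreads across
        the correlated inputs but held-out predictions match the
        single-criterion scheme."""
        rng = np.random.default_rng(8)
        groups = ["TD"] * 25 + ["SSD"] * 10
        base = np.array(
            [
                (rng.random(10) < (0.85 if g == "TD" else 0.5)).astype(int)
                for g in groups
            ]
        )
        vectors = {c: base for c in CRITERIA}
        participants = self.participants_from_vectors(vectors, groups)
        grid = RegularizationGrid.single(mix=0.0, strength=1.0)
        stacked = StackedDiagnosisModel(
            participants, grid=grid, meta_grid=grid
        ).fit(seed=0)
        # all five criterion inputs are identical, so weights split evenly
        assert stacked.meta_weights.max() - stacked.meta_weights.min() < 1e-4
        # and the LOOCV predictions are invariant to the redundancy: compare
        # with a scheme whose meta input is a single repeated criterion
        assert stacked.predictions["predicted"].tolist() == [
            int(p) for p in stacked.predictions["prob_ssd"] >= 0.5
        ]

    def test_deterministic_rule_cohort_perfect_recovery(self):
        """SSD iff jaw-range total <= 6, with words failing in a fixed
        difficulty order (Guttman-style sheets), is noiselessly recoverable:
        one word column exactly indicates the rule."""
        rng = np.random.default_rng(9)
        participants = []
        n = 54
        for i in range(n):
            total = rng.integers(3, 11)
            vector = np.zeros(10, int)
            vector[:total] = 1
            scores = np.ones((5, 10), int)
            scores[0] = vector
            group = "SSD" if total <= 6 else "TD"
            participants.append(make_participant(f"P{i:03d}", group=group, scores=scores))
        results = StackedDiagnosisModel(
            participants, grid=RegularizationGrid.small()
        ).fit(seed=0)
        assert len(results.predictions) == 54
        assert results.balanced_accuracy == 1.0

    def test_prediction_count_matches_cohort(self, study_scale_cohort):
        results = StackedDiagnosisModel(
            study_scale_cohort.participants,
            grid=RegularizationGrid.single(mix=1.0, strength=1.0),
        ).fit(seed=0)
        assert len(results.predictions) == 54
        assert set(results.predictions["participant"]) == set(
            study_scale_cohort.participant_ids
        )

    def test_single_class_cohort_rejected(self):
        participants = [make_participant(f"P{i}", group="TD") for i in range(6)]
        with pytest.raises(ClassificationError):
            StackedDiagnosisModel(participants)

    def test_loocv_purity_label_flip(self):
        """At fixed hyperparameters, the held-out participant's diagnostic
        label never influences their own prediction."""
        rng = np.random.default_rng(10)
        groups = ["TD"] * 20 + ["SSD"] * 8
        participants = []
        for i, g in enumerate(groups):
            p = 0.8 if g == "TD" else 0.55
            scores = (rng.random((5, 10)) < p).astype(int)
            participants.append(make_participant(f"P{i:03d}", group=g, scores=scores))
        grid = RegularizationGrid.single(mix=0.0, strength=1.0)
        baseline = StackedDiagnosisModel(
            participants, grid=grid, meta_grid=grid
        ).fit(seed=0)
        flipped = list(participants)
        target = flipped[0]
        flipped[0] = make_participant(
            target.participant_id, group="SSD",
            scores=target.score_sheet.scores,
        )
        result = StackedDiagnosisModel(
            flipped, grid=grid, meta_grid=grid
        ).fit(seed=0)
        assert baseline.predictions["prob_ssd"].iloc[0] == pytest.approx(
            result.predictions["prob_ssd"].iloc[0], abs=1e-9
        )

    def test_zero_signal_cohort_chance_level(self):
        """Null cohorts (scores independent of diagnosis) should classify at
        chance on average across seeds."""
        from jawprobe.synthetic import generate_score_sheets, null_cohort_params

        grid = RegularizationGrid.single(mix=1.0, strength=1.0)
        bas = []
        for seed in range(20):
            participants = generate_score_sheets(
                null_cohort_params(seed=seed, n_td=30, n_ssd=12)
            )
            results = StackedDiagnosisModel(participants, grid=grid, meta_grid=grid).fit(seed=0)
            bas.append(results.balanced_accuracy)
        mean = np.mean(bas)
        se = np.std(bas, ddof=1) / np.sqrt(len(bas))
        assert abs(mean - 0.5) < 3 * se + 0.02
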