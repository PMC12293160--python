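"""Leave-one-out logistic classification of appropriateness and diagnosis.

Two modelling objects are exposed, each in the model / results idiom:

* :class:`WordClassificationModel` — per-word logistic regression of the
  binary appropriateness score (jaw range or jaw control) on the |z|
  kinematic features, evaluated under leave-one-out cross-validation and
  pooled across the 10 words into one confusion summary.  The positive
  class is "inappropriate".

* :class:`StackedDiagnosisModel` — the two-level diagnostic scheme: one
  logistic model per scoring criterion over its ten-valued binary word
  vector, and a logistic meta-classifier over the five criterion outputs
  predicting TD vs SSD.  The positive class is SSD.

Both schemes are regularised with an elastic-net penalty whose mixing ratio
(0 = ridge, 1 = lasso), strength and class weighting are grid-searched to
maximise leave-one-out balanced accuracy.  Following the original analysis
design, hyperparameters are selected once on the full dataset via that
leave-one-out objective and then frozen — an optimistic choice whose lack
of generalisability is inherent to the procedure; a stricter nested mode
(:meth:`StackedDiagnosisModel.fit` with ``nested=True``) re-tunes inside
every outer fold.

The decision threshold is a predicted probability of 0.5, with exact ties
resolved to the positive (inappropriate / SSD) class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import CANONICAL_WORDS, CRITERIA, Cohort, Participant
from .evaluate import ConfusionSummary, precision_recall_points
from .kinematics import CRITERION_MEASUREMENTS

_TOL = 1e-8
_MAX_ITER = 10_000


class ClassificationError(ValueError):
    """Invalid classification input (e.g. a single-class dataset)."""


@dataclass(frozen=True)
class RegularizationGrid:
    """Elastic-net hyperparameter grid.

    ``mix_ratios`` interpolate ridge (0) to lasso (1); ``strengths`` are
    penalty weights (the inverse of scikit-learn's C); ``class_weighting``
    entries are "none" or "balanced".
    """

    mix_ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    strengths: tuple[float, ...] = tuple(float(s) for s in np.logspace(-2, 2, 9))
    class_weighting: tuple[str, ...] = ("none", "balanced")

    def __post_init__(self) -> None:
        if not self.mix_ratios or not self.strengths or not self.class_weighting:
            raise ClassificationError("grid lists must be non-empty")
        if any(not 0 <= m <= 1 for m in self.mix_ratios):
            raise ClassificationError("mix ratios must lie in [0, 1]")
        if any(s <= 0 for s in self.strengths):
            raise ClassificationError("strengths must be positive")
        if any(w not in ("none", "balanced") for w in self.class_weighting):
            raise ClassificationError("class_weighting entries must be none|balanced")

    def entries(self) -> list[tuple[float, float, str]]:
        """Grid entries in deterministic enumeration order (ties in the
        search are broken by the first entry)."""
        return list(product(self.mix_ratios, self.strengths, self.class_weighting))

    @classmethod
    def small(cls) -> "RegularizationGrid":
        """Reduced grid for replicate Monte-Carlo studies: lasso/ridge ends
        only, three strengths, balanced weighting."""
        return cls(
            mix_ratios=(0.0, 1.0),
            strengths=(0.1, 1.0, 10.0),
            class_weighting=("balanced",),
        )

    @classmethod
    def single(cls, mix: float = 0.0, strength: float = 1.0, weighting: str = "balanced") -> "RegularizationGrid":
        return cls(mix_ratios=(mix,), strengths=(strength,), class_weighting=(weighting,))


def replicate_grids() -> tuple[RegularizationGrid, RegularizationGrid]:
    """Criterion- and meta-level grids for replicate simulation studies of
    the stacked scheme.

    The criterion level carries little tuning benefit on ten-valued binary
    vectors, so it searches only the penalty type; the meta level — cheap
    because level-one folds are shared across its entries — keeps a fuller
    search over penalty type, strength and class weighting.
    """
    criterion_grid = RegularizationGrid(
        mix_ratios=(0.0, 1.0), strengths=(1.0,), class_weighting=("balanced",)
    )
    meta_grid = RegularizationGrid(
        mix_ratios=(0.0, 1.0),
        strengths=(0.1, 1.0, 3.16, 10.0),
        class_weighting=("balanced", "none"),
    )
    return criterion_grid, meta_grid


def _fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    mix: float,
    strength: float,
    weighting: str,
    seed: int = 0,
) -> LogisticRegression:
    """One deterministic penalised logistic fit (C = 1 / strength)."""
    solver = "liblinear" if mix in (0.0, 1.0) else "saga"
    model = LogisticRegression(
        C=1.0 / strength,
        l1_ratio=float(mix),
        solver=solver,
        tol=_TOL,
        max_iter=_MAX_ITER,
        class_weight=None if weighting == "none" else "balanced",
        random_state=seed,
        # liblinear penalises the intercept; a large intercept_scaling makes
        # it effectively unpenalised, consistent with the other solvers
        intercept_scaling=100.0 if solver == "liblinear" else 1.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    if solver == "liblinear" and not np.any(model.coef_):
        # fully shrunk slopes: liblinear's residual intercept penalty pulls
        # the intercept to 0; replace it with the unpenalised intercept-only
        # MLE (the logit of the class-weight-adjusted positive rate)
        pos = float(np.mean(y == model.classes_[1]))
        if weighting == "balanced":
            pos = 0.5
        pos = min(max(pos, 1e-12), 1 - 1e-12)
        model.intercept_ = np.array([np.log(pos / (1.0 - pos))])
    return model


def _prob_positive(model: LogisticRegression, X: np.ndarray) -> np.ndarray:
    idx = int(np.flatnonzero(model.classes_ == 1)[0])
    return model.predict_proba(X)[:, idx]


def _predict(prob: np.ndarray) -> np.ndarray:
    return (prob >= 0.5).astype(int)


def _loocv_probs(X: np.ndarray, y: np.ndarray, entry, seed: int) -> np.ndarray:
    """Held-out positive-class probabilities for every row."""
    mix, strength, weighting = entry
    n = len(y)
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        classes = np.unique(y[mask])
        if classes.size == 1:
            # held out the only member of a class: the fold's model can only
            # predict the remaining class
            out[i] = float(classes[0] == 1)
            continue
        model = _fit_logistic(X[mask], y[mask], mix, strength, weighting, seed)
        out[i] = _prob_positive(model, X[i : i + 1])[0]
    return out


# ---------------------------------------------------------------------------
# Word-level appropriateness classification
# ---------------------------------------------------------------------------


@dataclass
class WordClassificationResults:
    """Pooled LOOCV predictions and metrics of a word-level scheme."""

    criterion: str
    measurements: tuple[str, ...]
    predictions: pd.DataFrame
    confusion: ConfusionSummary
    hyperparams: tuple[float, float, str]
    grid_scores: pd.DataFrame
    skipped_words: tuple[str, ...]

    @property
    def balanced_accuracy(self) -> float:
        return self.confusion.balanced_accuracy

    @property
    def balanced_precision(self) -> float:
        return self.confusion.balanced_precision

    def precision_recall(self) -> pd.DataFrame:
        return precision_recall_points(
            self.predictions["prob_inappropriate"], self.predictions["truth"]
        )

    def plot_precision_recall(self, ax=None):
        from .evaluate import plot_precision_recall

        return plot_precision_recall(
            self.precision_recall(), ax=ax,
            label=f"{self.criterion}: {'+'.join(self.measurements)}",
        )

    def summary(self) -> str:
        cm = self.confusion
        mix, strength, weighting = self.hyperparams
        lines = [
            f"Word-level appropriateness classification: {self.criterion}",
            f"  measurements:        {', '.join(self.measurements)}",
            f"  pooled observations: {cm.n} "
            f"(positive class 'inappropriate': {cm.tp + cm.fn})",
            f"  hyperparameters:     mix={mix:g}  strength={strength:g}  "
            f"weighting={weighting}",
            f"  confusion [tp fn / fp tn]: {cm.tp} {cm.fn} / {cm.fp} {cm.tn}",
            f"  sensitivity={cm.sensitivity:.2f}  specificity={cm.specificity:.2f}  "
            f"ppv={cm.ppv:.2f}  npv={cm.npv:.2f}",
            f"  balanced accuracy={cm.balanced_accuracy:.2f}  "
            f"balanced precision={cm.balanced_precision:.2f}",
        ]
        if self.skipped_words:
            lines.append(f"  skipped single-class words: {', '.join(self.skipped_words)}")
        return "\n".join(lines)


class WordClassificationModel:
    """Per-word logistic classification of appropriateness from |z| features.

    Parameters
    ----------
    features
        Long feature table (participant, word, criterion, measurement,
        feature, label) as built by
        :func:`jawprobe.features.build_feature_table`.
    measurements
        Measurement subset to use as predictors; rows of other measurements
        are ignored.  Multiple measurements give a multi-feature model (the
        combined jaw-control scheme).
    grid
        Hyperparameter grid searched to maximise pooled LOOCV balanced
        accuracy.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        criterion: str,
        measurements: Sequence[str] | None = None,
        grid: RegularizationGrid | None = None,
    ) -> None:
        if criterion not in CRITERION_MEASUREMENTS:
            raise ClassificationError(f"unsupported criterion {criterion!r}")
        self.criterion = criterion
        self.measurements = tuple(measurements or CRITERION_MEASUREMENTS[criterion])
        self.grid = grid or RegularizationGrid()
        table = features[
            (features["criterion"] == criterion)
            & (features["measurement"].isin(self.measurements))
        ]
        if table.empty:
            raise ClassificationError("no feature rows for the requested criterion")
        wide = table.pivot_table(
            index=["participant", "word", "label"],
            columns="measurement",
            values="feature",
        ).reset_index()
        missing = [m for m in self.measurements if m not in wide.columns]
        if missing:
            raise ClassificationError(f"feature table lacks measurements {missing}")
        wide = wide.dropna(subset=list(self.measurements))
        self._wide = wide

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        criterion: str,
        measurements: Sequence[str] | None = None,
        grid: RegularizationGrid | None = None,
        intervals=None,
        convention: str = "width_over_height",
    ) -> "WordClassificationModel":
        from .features import build_feature_table

        features = build_feature_table(
            cohort, criterion, intervals=intervals, convention=convention
        )
        return cls(features, criterion, measurements=measurements, grid=grid)

    def _word_blocks(self):
        blocks = []
        skipped = []
        for word in CANONICAL_WORDS:
            sub = self._wide[self._wide["word"] == word]
            if sub.empty:
                continue
            y = (sub["label"] == "inappropriate").to_numpy(int)
            if len(set(y.tolist())) < 2:
                skipped.append(word)
                warnings.warn(
                    f"word {word!r} has a single appropriateness class; skipped",
                    stacklevel=3,
                )
                continue
            X = sub[list(self.measurements)].to_numpy(float)
            blocks.append((word, sub["participant"].to_numpy(), X, y))
        if not blocks:
            raise ClassificationError("no word with both appropriateness classes")
        return blocks, tuple(skipped)

    def fit(self, seed: int = 0) -> WordClassificationResults:
        """Grid-search hyperparameters by pooled LOOCV balanced accuracy and
        return the pooled predictions of the selected entry."""
        blocks, skipped = self._word_blocks()
        best = None
        grid_rows = []
        for entry in self.grid.entries():
            records = []
            for word, pids, X, y in blocks:
                probs = _loocv_probs(X, y, entry, seed)
                for pid, truth, prob in zip(pids, y, probs):
                    records.append((pid, word, int(truth), float(prob)))
            preds = pd.DataFrame(
                records, columns=["participant", "word", "truth", "prob_inappropriate"]
            )
            preds["predicted"] = _predict(preds["prob_inappropriate"].to_numpy())
            cm = ConfusionSummary.from_predictions(preds["truth"], preds["predicted"])
            score = cm.balanced_accuracy
            grid_rows.append((*entry, score))
            if best is None or score > best[0]:
                best = (score, entry, preds, cm)
        _, entry, preds, cm = best
        return WordClassificationResults(
            criterion=self.criterion,
            measurements=self.measurements,
            predictions=preds,
            confusion=cm,
            hyperparams=entry,
            grid_scores=pd.DataFrame(
                grid_rows, columns=["mix", "strength", "weighting", "balanced_accuracy"]
            ),
            skipped_words=skipped,
        )


def loocv_word_classification(
    features: pd.DataFrame,
    criterion: str,
    measurements: Sequence[str] | None = None,
    grid: RegularizationGrid | None = None,
    seed: int = 0,
) -> WordClassificationResults:
    """Functional wrapper over :class:`WordClassificationModel`."""
    return WordClassificationModel(
        features, criterion, measurements=measurements, grid=grid
    ).fit(seed=seed)


# ---------------------------------------------------------------------------
# Stacked diagnostic classification
# ---------------------------------------------------------------------------


@dataclass
class StackedDiagnosisResults:
    """LOOCV predictions, metrics and normalized weights of the stacked scheme."""

    predictions: pd.DataFrame
    confusion: ConfusionSummary
    criterion_hyperparams: dict[str, tuple[float, float, str]]
    meta_hyperparams: tuple[float, float, str]
    criterion_weights: pd.DataFrame
    meta_weights: pd.Series
    criterion_grid_scores: pd.DataFrame
    meta_grid_scores: pd.DataFrame

    @property
    def balanced_accuracy(self) -> float:
        return self.confusion.balanced_accuracy

    @property
    def balanced_precision(self) -> float:
        return self.confusion.balanced_precision

    def precision_recall(self) -> pd.DataFrame:
        return precision_recall_points(
            self.predictions["prob_ssd"], self.predictions["truth"]
        )

    def plot_precision_recall(self, ax=None):
        from .evaluate import plot_precision_recall

        return plot_precision_recall(self.precision_recall(), ax=ax, label="diagnosis")

    def summary(self) -> str:
        cm = self.confusion
        lines = [
            "Stacked diagnostic classification (TD vs SSD)",
            f"  participants: {cm.n} (SSD: {cm.tp + cm.fn})",
            f"  confusion [tp fn / fp tn]: {cm.tp} {cm.fn} / {cm.fp} {cm.tn}",
            f"  sensitivity={cm.sensitivity:.2f}  specificity={cm.specificity:.2f}  "
            f"ppv={cm.ppv:.2f}  npv={cm.npv:.2f}",
            f"  balanced accuracy={cm.balanced_accuracy:.2f}  "
            f"balanced precision={cm.balanced_precision:.2f}",
            "  normalized meta-weights:",
        ]
        for criterion, weight in self.meta_weights.items():
            lines.append(f"    {criterion:<20s} {weight:.3f}")
        return "\n".join(lines)


def _criterion_matrix(participants: Sequence[Participant]) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    X = {
        c: np.stack([p.score_sheet.criterion_scores(c) for p in participants]).astype(float)
        for c in CRITERIA
    }
    y = np.array([1 if p.group == "SSD" else 0 for p in participants], dtype=int)
    pids = [p.participant_id for p in participants]
    return X, y, pids


def _normalized(values: np.ndarray) -> np.ndarray:
    total = np.abs(values).sum()
    return np.abs(values) / total if total > 0 else np.zeros_like(values)


class StackedDiagnosisModel:
    """Two-level diagnostic classifier over the five criterion score vectors.

    Level one fits a logistic model per criterion on its 10 binary word
    scores; level two fits a logistic meta-classifier on the criterion
    models' outputs (predicted probabilities by default, hard labels with
    ``meta_input="label"``) to predict SSD.
    """

    def __init__(
        self,
        participants: Sequence[Participant],
        grid: RegularizationGrid | None = None,
        meta_grid: RegularizationGrid | None = None,
        meta_input: str = "probability",
    ) -> None:
        if meta_input not in ("probability", "label"):
            raise ClassificationError("meta_input must be 'probability' or 'label'")
        self.participants = list(participants)
        self.grid = grid or RegularizationGrid()
        self.meta_grid = meta_grid or self.grid
        self.meta_input = meta_input
        self._X, self._y, self._pids = _criterion_matrix(self.participants)
        if len(set(self._y.tolist())) < 2:
            raise ClassificationError("both diagnostic classes must be present")

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "StackedDiagnosisModel":
        return cls(cohort.participants, **kwargs)

    # -- scheme internals ---------------------------------------------------

    def _meta_features(
        self, models: dict[str, LogisticRegression], X: dict[str, np.ndarray], rows: np.ndarray
    ) -> np.ndarray:
        cols = []
        for criterion in CRITERIA:
            prob = _prob_positive(models[criterion], X[criterion][rows])
            cols.append(prob if self.meta_input == "probability" else _predict(prob))
        return np.column_stack(cols).astype(float)

    def _fit_level_one(
        self, rows: np.ndarray, hyperparams: dict[str, tuple], seed: int
    ) -> dict[str, LogisticRegression]:
        return {
            c: _fit_logistic(self._X[c][rows], self._y[rows], *hyperparams[c], seed)
            for c in CRITERIA
        }

    def _level_one_folds(self, criterion_hp: dict[str, tuple], seed: int):
        """Per held-out fold: training meta-features, training labels and the
        held-out meta-feature row, with level-one models fit without the
        held-out case.  Shared across meta-level grid entries, which only
        refit the meta model."""
        n = len(self._y)
        idx = np.arange(n)
        folds = []
        for i in range(n):
            train = idx[idx != i]
            models = self._fit_level_one(train, criterion_hp, seed)
            meta_X = self._meta_features(models, self._X, train)
            held = self._meta_features(models, self._X, idx[i : i + 1])
            folds.append((meta_X, self._y[train], held))
        return folds

    def _scheme_loocv_probs(
        self, criterion_hp: dict[str, tuple], meta_hp: tuple, seed: int,
        folds=None,
    ) -> np.ndarray:
        """Held-out SSD probability per participant, refitting both levels
        without the held-out case."""
        if folds is None:
            folds = self._level_one_folds(criterion_hp, seed)
        out = np.empty(len(folds))
        for i, (meta_X, y_train, held) in enumerate(folds):
            meta = _fit_logistic(meta_X, y_train, *meta_hp, seed)
            out[i] = _prob_positive(meta, held)[0]
        return out

    # -- fitting ------------------------------------------------------------

    def _tune_criterion_level(self, seed: int):
        hyperparams = {}
        rows = []
        for criterion in CRITERIA:
            X, y = self._X[criterion], self._y
            best = None
            for entry in self.grid.entries():
                probs = _loocv_probs(X, y, entry, seed)
                cm = ConfusionSummary.from_predictions(y, _predict(probs))
                score = cm.balanced_accuracy
                rows.append((criterion, *entry, score))
                if best is None or score > best[0]:
                    best = (score, entry)
            hyperparams[criterion] = best[1]
        scores = pd.DataFrame(
            rows, columns=["criterion", "mix", "strength", "weighting", "balanced_accuracy"]
        )
        return hyperparams, scores

    def fit(self, seed: int = 0, nested: bool = False) -> StackedDiagnosisResults:
        """Tune, evaluate under LOOCV, and refit on the full data.

        Default procedure: criterion-level hyperparameters are tuned first
        (per-criterion LOOCV balanced accuracy), then the meta level is tuned
        by full-scheme LOOCV with the criterion level frozen; the reported
        predictions are those of the selected meta entry.  With
        ``nested=True`` the whole tuning procedure is instead repeated inside
        every outer fold (no outer case ever influences its own
        hyperparameters); this is slower and not the original design.
        """
        if nested:
            return self._fit_nested(seed)
        criterion_hp, criterion_scores = self._tune_criterion_level(seed)
        folds = self._level_one_folds(criterion_hp, seed)
        best = None
        meta_rows = []
        for entry in self.meta_grid.entries():
            probs = self._scheme_loocv_probs(criterion_hp, entry, seed, folds=folds)
            cm = ConfusionSummary.from_predictions(self._y, _predict(probs))
            score = cm.balanced_accuracy
            meta_rows.append((*entry, score))
            if best is None or score > best[0]:
                best = (score, entry, probs, cm)
        _, meta_hp, probs, cm = best
        return self._results(
            criterion_hp, meta_hp, probs, cm, criterion_scores,
            pd.DataFrame(meta_rows, columns=["mix", "strength", "weighting", "balanced_accuracy"]),
            seed,
        )

    def _fit_nested(self, seed: int) -> StackedDiagnosisResults:
        n = len(self._y)
        idx = np.arange(n)
        probs = np.empty(n)
        for i in range(n):
            train = idx[idx != i]
            inner = StackedDiagnosisModel(
                [self.participants[j] for j in train],
                grid=self.grid, meta_grid=self.meta_grid, meta_input=self.meta_input,
            )
            hp, _ = inner._tune_criterion_level(seed)
            best = None
            for entry in inner.meta_grid.entries():
                inner_probs = inner._scheme_loocv_probs(hp, entry, seed)
                cm = ConfusionSummary.from_predictions(inner._y, _predict(inner_probs))
                if best is None or cm.balanced_accuracy > best[0]:
                    best = (cm.balanced_accuracy, entry)
            models = self._fit_level_one(train, hp, seed)
            meta_X = self._meta_features(models, self._X, train)
            meta = _fit_logistic(meta_X, self._y[train], *best[1], seed)
            held = self._meta_features(models, self._X, idx[i : i + 1])
            probs[i] = _prob_positive(meta, held)[0]
        cm = ConfusionSummary.from_predictions(self._y, _predict(probs))
        hp, criterion_scores = self._tune_criterion_level(seed)
        best = None
        meta_rows = []
        for entry in self.meta_grid.entries():
            p = self._scheme_loocv_probs(hp, entry, seed)
            c = ConfusionSummary.from_predictions(self._y, _predict(p))
            meta_rows.append((*entry, c.balanced_accuracy))
            if best is None or c.balanced_accuracy > best[0]:
                best = (c.balanced_accuracy, entry)
        return self._results(
            hp, best[1], probs, cm, criterion_scores,
            pd.DataFrame(meta_rows, columns=["mix", "strength", "weighting", "balanced_accuracy"]),
            seed,
        )

    def _results(
        self, criterion_hp, meta_hp, probs, cm, criterion_scores, meta_scores, seed
    ) -> StackedDiagnosisResults:
        # full-data refit for the normalized coefficient report
        all_rows = np.arange(len(self._y))
        models = self._fit_level_one(all_rows, criterion_hp, seed)
        meta_X = self._meta_features(models, self._X, all_rows)
        meta = _fit_logistic(meta_X, self._y, *meta_hp, seed)
        criterion_weights = pd.DataFrame(
            {
                c: _normalized(models[c].coef_.ravel())
                for c in CRITERIA
            },
            index=list(CANONICAL_WORDS),
        )
        meta_weights = pd.Series(
            _normalized(meta.coef_.ravel()), index=list(CRITERIA), name="weight"
        )
        predictions = pd.DataFrame(
            {
                "participant": self._pids,
                "truth": self._y,
                "prob_ssd": probs,
                "predicted": _predict(probs),
            }
        )
        return StackedDiagnosisResults(
            predictions=predictions,
            confusion=cm,
            criterion_hyperparams=dict(criterion_hp),
            meta_hyperparams=tuple(meta_hp),
            criterion_weights=criterion_weights,
            meta_weights=meta_weights,
            criterion_grid_scores=criterion_scores,
            meta_grid_scores=meta_scores,
        )


def fit_stacked_diagnosis(
    participants: Sequence[Participant],
    grid: RegularizationGrid | None = None,
    seed: int = 0,
    **kwargs,
) -> StackedDiagnosisResults:
    """Functional wrapper over :class:`StackedDiagnosisModel.fit`."""
    return StackedDiagnosisModel(participants, grid=grid, **kwargs).fit(seed=seed)


def loocv_stacked_diagnosis(
    participants: Sequence[Participant],
    grid: RegularizationGrid | None = None,
    seed: int = 0,
    **kwargs,
) -> StackedDiagnosisResults:
    """Alias of :func:`fit_stacked_diagnosis`; fitting always evaluates the
    scheme under leave-one-out cross-validation."""
    return fit_stacked_diagnosis(participants, grid=grid, seed=seed, **kwargs)
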