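"""Classifier tuning and evaluation with participant-grouped validation.

Four classifier families (decision tree, random forest, logistic
regression, AdaBoost over tree stumps/trees) are tuned jointly over
featurization settings and hyperparameters by grid search with
stratified *group* five-fold cross-validation: participants — never
blocks — are partitioned into folds with the AF prevalence balanced, so
no participant's blocks ever appear on both sides of a split.
Generalization is additionally probed with leave-one-participant-out
CV, and a fitted model can be applied to blocks recorded by a different
sensor to measure robustness to sensor-location shifts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .preprocess import FeatureDataset
from .types import (
    BlockPrediction,
    ClassifierConfig,
    CVResult,
    EvalReport,
    Family,
    RhythmLabel,
    SensorPlacement,
    SpectrumSetting,
)

# ---------------------------------------------------------------------------
# The tuning grid

TABLE_HIGHCUTS: Tuple[float, ...] = (10.0, 20.0, 40.0, 250.0)
TABLE_LOWCUTS: Tuple[float, ...] = (0.0, 0.5, 0.7, 1.0, 1.2)
TABLE_NBINS: Tuple[int, ...] = (3, 5, 10, 30, 40, 50, 100, 150)

#: Hyperparameter value lists per family, in grid order.
TABLE_HYPERPARAMETERS: Dict[Family, Dict[str, tuple]] = {
    Family.DT: {"max_depth": (1, 3, 5, 7, 10, 15)},
    Family.RF: {"max_depth": (1, 3, 5, 7, 10, 15, 20, 25, 30, 40)},
    Family.LR: {"C": (1e-8, 1e-6, 1e-4, 1e-2, 1.0, 1e2, 1e4, 1e6, 1e8)},
    Family.ADA: {
        "learning_rate": (1.0, 0.9, 0.8),
        "max_depth": (1, 2, 3, 4, 5, 6, 7, 8),
    },
}

FAMILY_ORDER: Tuple[Family, ...] = (Family.DT, Family.RF, Family.LR, Family.ADA)


def default_settings() -> List[SpectrumSetting]:
    """All featurization settings of the tuning grid, in deterministic
    (highcut, lowcut, nbins) order."""
    return [
        SpectrumSetting(low, high, nb)
        for high in TABLE_HIGHCUTS
        for low in TABLE_LOWCUTS
        for nb in TABLE_NBINS
    ]


def full_grid(
    families: Sequence[Family] = FAMILY_ORDER,
    settings: Optional[Sequence[SpectrumSetting]] = None,
) -> List[ClassifierConfig]:
    """The full joint grid (families x hyperparameters x settings) in
    deterministic lexicographic order; ties in the search break toward
    the earliest config in this order."""
    if settings is None:
        settings = default_settings()
    configs: List[ClassifierConfig] = []
    for family in families:
        names = list(TABLE_HYPERPARAMETERS[family])
        for values in itertools.product(
            *(TABLE_HYPERPARAMETERS[family][n] for n in names)
        ):
            hp = dict(zip(names, values))
            for setting in settings:
                configs.append(ClassifierConfig.make(family, setting, **hp))
    return configs


# ---------------------------------------------------------------------------
# Grouped folds

def make_group_stratified_folds(
    participants: Sequence[Tuple[str, RhythmLabel]],
    k: int,
    seed: int,
) -> Dict[str, int]:
    """Assign each participant to one of ``k`` folds, balancing the AF
    prevalence: participants are shuffled within class and dealt
    round-robin (the deal continues across classes so fold sizes differ
    by at most one)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(participants):
        raise ValueError(f"k={k} exceeds the {len(participants)} participants")
    ids = [pid for pid, _ in participants]
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids must be unique")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, int] = {}
    cursor = 0
    for label in (RhythmLabel.AF, RhythmLabel.NON_AF):
        members = sorted(pid for pid, lbl in participants if RhythmLabel(lbl) is label)
        rng.shuffle(members)
        for pid in members:
            assignment[pid] = cursor % k
            cursor += 1
    return assignment


def audit_no_leakage(train_ids: Iterable[str], val_ids: Iterable[str]) -> None:
    """Assert that no participant contributes blocks to both partitions."""
    overlap = set(train_ids) & set(val_ids)
    if overlap:
        raise AssertionError(f"participant leakage across folds: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Models

@dataclass
class FittedModel:
    """A trained classifier bound to its featurization setting.

    When the training labels were single-class the model degenerates to
    a constant prediction with score 0 (non-AF) or 1 (AF).
    """

    config: ClassifierConfig
    estimator: Optional[object]
    constant: Optional[RhythmLabel] = None

    @property
    def n_features(self) -> int:
        return self.config.setting.nbins

    def predict(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Return (predicted labels, AF-class scores) for feature rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature matrix must have {self.n_features} columns, "
                f"got shape {X.shape}"
            )
        if self.constant is not None:
            labels = np.full(len(X), self.constant.value, dtype=object)
            scores = np.full(len(X), 1.0 if self.constant is RhythmLabel.AF else 0.0)
            return labels, scores
        labels = self.estimator.predict(X)
        af_col = int(np.flatnonzero(self.estimator.classes_ == RhythmLabel.AF.value)[0])
        scores = self.estimator.predict_proba(X)[:, af_col]
        return labels, scores


def make_estimator(config: ClassifierConfig, seed: int = 0):
    """Instantiate the scikit-learn estimator for one grid point.

    Hyperparameters not in the grid stay at library defaults (recorded
    in the run manifest via the library version).
    """
    hp = config.params
    if config.family is Family.DT:
        return DecisionTreeClassifier(max_depth=int(hp["max_depth"]), random_state=seed)
    if config.family is Family.RF:
        return RandomForestClassifier(
            max_depth=int(hp["max_depth"]), random_state=seed, n_jobs=1
        )
    if config.family is Family.LR:
        return LogisticRegression(C=float(hp["C"]), max_iter=2000)
    if config.family is Family.ADA:
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=int(hp["max_depth"])),
            learning_rate=float(hp["learning_rate"]),
            random_state=seed,
        )
    raise ValueError(f"unknown family {config.family}")  # pragma: no cover


def fit_model(
    X: np.ndarray, y: Sequence[str], config: ClassifierConfig, seed: int = 0
) -> FittedModel:
    """Fit one configuration; a single-class training set yields a
    constant predictor rather than an error."""
    X = np.asarray(X, dtype=float)
    y = np.asarray([RhythmLabel(v).value for v in y], dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if X.shape[1] != config.setting.nbins:
        raise ValueError(
            f"feature matrix width {X.shape[1]} does not match the "
            f"setting's {config.setting.nbins} bins"
        )
    classes = np.unique(y)
    if len(classes) == 1:
        return FittedModel(config=config, estimator=None,
                           constant=RhythmLabel(classes[0]))
    estimator = make_estimator(config, seed)
    with warnings.catch_warnings():
        # LR at extreme C values may hit the iteration cap; the grid
        # treats such points as any other candidate.
        warnings.simplefilter("ignore")
        estimator.fit(X, y)
    return FittedModel(config=config, estimator=estimator)


def predict_blocks(
    model: FittedModel, meta: pd.DataFrame, X: np.ndarray
) -> List[BlockPrediction]:
    """Predict rows of a feature matrix, carrying block identity along."""
    labels, scores = model.predict(X)
    out = []
    for (_, row), lbl, score in zip(meta.iterrows(), labels, scores):
        placement = row.get("placement")
        out.append(
            BlockPrediction(
                participant_id=row["participant_id"],
                placement=SensorPlacement(placement)
                if isinstance(placement, (str, SensorPlacement)) and placement
                else None,
                start_sample=int(row["start_sample"]),
                predicted=RhythmLabel(lbl),
                score=float(score),
            )
        )
    return out


def fit_predict(
    train_X: np.ndarray,
    train_y: Sequence[str],
    test_X: np.ndarray,
    config: ClassifierConfig,
    seed: int = 0,
    test_meta: Optional[pd.DataFrame] = None,
) -> List[BlockPrediction]:
    """Fit on the training features and predict the test features."""
    model = fit_model(train_X, train_y, config, seed)
    if test_meta is None:
        test_meta = pd.DataFrame(
            {
                "participant_id": [f"row{i}" for i in range(len(test_X))],
                "placement": [None] * len(test_X),
                "start_sample": np.zeros(len(test_X), dtype=int),
            }
        )
    return predict_blocks(model, test_meta, test_X)


# ---------------------------------------------------------------------------
# Grid search and CV

def _participants_of(dataset: FeatureDataset) -> List[Tuple[str, RhythmLabel]]:
    return [
        (pid, RhythmLabel(lbl))
        for pid, lbl in dataset.meta.groupby("participant_id", sort=True)["label"]
        .first()
        .items()
    ]


def grid_search(
    dataset: FeatureDataset,
    configs: Sequence[ClassifierConfig],
    k: int = 5,
    seed: int = 0,
    return_all: bool = False,
):
    """Evaluate every grid point by stratified group k-fold CV and return
    the config with the highest mean fold accuracy (ties -> earliest
    config in grid order). Every fold is audited for participant
    leakage."""
    if not configs:
        raise ValueError("the grid is empty")
    if dataset.n_included == 0:
        raise ValueError("no included blocks to train on")
    for config in configs:
        if config.setting not in dataset.features:
            raise ValueError(f"dataset lacks features for setting {config.setting}")

    folds = make_group_stratified_folds(_participants_of(dataset), k, seed)
    fold_of = dataset.meta["participant_id"].map(folds).to_numpy()
    pids = dataset.meta["participant_id"].to_numpy()
    y = dataset.meta["label"].to_numpy()

    best: Optional[CVResult] = None
    results: List[CVResult] = []
    for config in configs:
        X = dataset.features[config.setting]
        accs = []
        for fold in range(k):
            val = fold_of == fold
            if not val.any():
                continue
            audit_no_leakage(pids[~val], pids[val])
            model = fit_model(X[~val], y[~val], config, seed)
            pred, _ = model.predict(X[val])
            accs.append(float(np.mean(pred == y[val])))
        result = CVResult.from_folds(config, accs)
        results.append(result)
        if best is None or result.mean_accuracy > best.mean_accuracy:
            best = result
    return (best, results) if return_all else best


def loocv_by_participant(
    dataset: FeatureDataset, config: ClassifierConfig, seed: int = 0
) -> Tuple[pd.DataFrame, float, float]:
    """Leave-one-participant-out CV: per-participant block accuracy plus
    the across-participant mean and (sample) SD."""
    participants = _participants_of(dataset)
    if len(participants) < 2:
        raise ValueError("leave-one-participant-out CV needs >= 2 participants")
    X = dataset.features[config.setting]
    pids = dataset.meta["participant_id"].to_numpy()
    y = dataset.meta["label"].to_numpy()
    rows = []
    for pid, label in participants:
        held = pids == pid
        if not held.any():  # pragma: no cover - absent participants lack rows
            continue
        model = fit_model(X[~held], y[~held], config, seed)
        pred, _ = model.predict(X[held])
        rows.append(
            {
                "participant_id": pid,
                "label": label.value,
                "n_blocks": int(held.sum()),
                "accuracy": float(np.mean(pred == y[held])),
            }
        )
    table = pd.DataFrame(rows)
    accs = table["accuracy"].to_numpy()
    sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    return table, float(np.mean(accs)), sd


# ---------------------------------------------------------------------------
# Evaluation

def evaluate(
    predictions: Sequence, labels: Mapping[str, RhythmLabel]
) -> EvalReport:
    """Confusion-matrix metrics over block predictions; AF is positive.

    AUC is computed from the AF-class scores by trapezoidal integration
    of the ROC curve (equivalently the normalized Mann–Whitney U
    statistic); it is None when scores are unavailable or only one class
    is present.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("cannot evaluate an empty prediction list")
    tp = fp = tn = fn = 0
    truths, scores = [], []
    for p in predictions:
        truth = RhythmLabel(labels[p.participant_id])
        pred = RhythmLabel(p.predicted)
        if truth is RhythmLabel.AF:
            tp += pred is RhythmLabel.AF
            fn += pred is RhythmLabel.NON_AF
        else:
            tn += pred is RhythmLabel.NON_AF
            fp += pred is RhythmLabel.AF
        truths.append(truth)
        scores.append(getattr(p, "score", None))
    auc = None
    if all(s is not None for s in scores):
        y_true = np.array([t is RhythmLabel.AF for t in truths])
        if 0 < y_true.sum() < len(y_true):
            auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
        else:
            warnings.warn("AUC undefined: only one class present", stacklevel=2)
    return EvalReport.from_counts(int(tp), int(fp), int(tn), int(fn), auc)


def cross_location_apply(
    model: FittedModel, dataset: FeatureDataset
) -> Tuple[EvalReport, List[BlockPrediction]]:
    """Apply a model trained on one sensor to blocks recorded by another
    (featurized under the model's own setting)."""
    if model.config.setting not in dataset.features:
        raise ValueError(
            f"dataset lacks features under the model's setting "
            f"{model.config.setting}"
        )
    X = dataset.features[model.config.setting]
    preds = predict_blocks(model, dataset.meta, X)
    report = evaluate(preds, dataset.labels_by_participant())
    return report, preds
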