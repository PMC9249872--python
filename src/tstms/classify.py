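"""Class-weighted one-vs-one gradient-boosted classification under LOOCV.

Emotional state is a five-way problem (amusement, disgust, fear, sexual
arousal, neutral) evaluated subject-wise: leave-one-subject-out
cross-validation (LOOCV) holds out all trials of one subject per fold, so a
model can never exploit subject identity.  Class imbalance is handled on two
fronts: training uses a weighted loss with

    class_weight[i] = n_samples / (n_classes * n_samples_of_class_i),

while the held-out test trials are randomly undersampled to the smallest
class so that chance-level metrics keep their textbook values (subset
accuracy 1/k, ROC AUC 0.5).  The multiclass model is one-vs-one: k(k-1)/2
binary gradient-boosted-tree classifiers (LightGBM) whose pairwise
probabilities are averaged into a k-class probability vector.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score

from tstms.recording import CLASS_LABELS

log = logging.getLogger(__name__)

#: modest boosted-tree defaults; tuned for a wide (61k-column), short
#: (tens-to-hundreds of trials) matrix, all config-exposed
DEFAULT_HYPERPARAMS = {
    "n_estimators": 30,
    "num_leaves": 4,
    "learning_rate": 0.15,
    "min_child_samples": 5,
    "max_bin": 15,
    "colsample_bytree": 0.5,
}


@dataclass
class Dataset:
    """Feature matrix plus per-trial metadata.

    Every subject must contribute trials of at least two classes, otherwise
    its LOOCV fold cannot be scored meaningfully.
    """

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    gender: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValueError("X, y and subjects must have equal lengths")
        for s in np.unique(self.subjects):
            if len(np.unique(self.y[self.subjects == s])) < 2:
                raise ValueError(f"subject {s} contributes fewer than 2 classes")

    @property
    def classes(self) -> list[str]:
        return [c for c in CLASS_LABELS if c in set(self.y)]


@dataclass
class FoldResult:
    """Scored predictions for one held-out subject."""

    subject: str
    proba: np.ndarray
    y_pred: np.ndarray
    y_true: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        if self.proba.size:
            if np.any(self.proba < -1e-12):
                raise ValueError("probabilities must be nonnegative")
            if np.max(np.abs(self.proba.sum(axis=1) - 1.0)) > 1e-9:
                raise ValueError("probability rows must sum to 1")


@dataclass
class MetricsReport:
    """All headline metrics plus per-fold breakdowns."""

    roc_auc: dict[str, float]
    balanced_accuracy: dict[str, float]
    subset_accuracy: float
    confusion_percent: np.ndarray
    classes: list[str]
    per_fold: list[dict] = field(default_factory=list)

    @property
    def macro_roc_auc(self) -> float:
        return float(np.mean(list(self.roc_auc.values())))


def class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency weights: n_samples / (n_classes * count_i)."""
    if any(c <= 0 for c in counts.values()):
        raise ValueError("all class counts must be positive")
    n = sum(counts.values())
    k = len(counts)
    return {label: n / (k * c) for label, c in counts.items()}


def loocv_folds(ds: Dataset):
    """Yield ``(train_idx, test_idx, subject)`` per held-out subject."""
    subjects = np.unique(ds.subjects)
    if subjects.size < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    for s in subjects:
        test = np.flatnonzero(ds.subjects == s)
        train = np.flatnonzero(ds.subjects != s)
        yield train, test, s


def undersample_test(y_test: np.ndarray, seed: int,
                     classes: list[str] | None = None) -> np.ndarray:
    """Indices of a balanced subsample: every class cut to the smallest count.

    Sampling is uniform without replacement and fully determined by ``seed``.
    A class missing from the fold is skipped with a warning rather than
    failing the fold.
    """
    y_test = np.asarray(y_test)
    classes = classes or [c for c in CLASS_LABELS if c in set(y_test)]
    counts = {}
    for c in classes:
        n = int(np.sum(y_test == c))
        if n == 0:
            log.warning("class %s absent from test fold; skipped", c)
        else:
            counts[c] = n
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    for c in counts:
        idx = np.flatnonzero(y_test == c)
        keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class OvOModel:
    """k(k-1)/2 pairwise binary boosters with averaged probabilities."""

    classes: list[str]
    models: dict[tuple[str, str], lgb.Booster]

    @property
    def n_binary(self) -> int:
        return len(self.models)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Average pairwise-coupled probabilities into k-class rows."""
        k = len(self.classes)
        votes = np.zeros((len(X), k))
        for (c1, c2), booster in self.models.items():
            p2 = booster.predict(X)  # P(label == c2)
            i1, i2 = self.classes.index(c1), self.classes.index(c2)
            votes[:, i1] += 1.0 - p2
            votes[:, i2] += p2
        return votes / votes.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]


def _lgb_params(hyperparams: dict | None, seed: int) -> tuple[dict, int]:
    """Translate the config-facing hyperparameters to booster params."""
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    n_rounds = int(hp.pop("n_estimators"))
    params = {
        "objective": "binary",
        "learning_rate": hp.pop("learning_rate"),
        "num_leaves": hp.pop("num_leaves"),
        "min_data_in_leaf": hp.pop("min_child_samples"),
        "max_bin": hp.pop("max_bin"),
        "feature_fraction": hp.pop("colsample_bytree"),
        "verbosity": -1,
        "seed": seed,
        "feature_pre_filter": False,
        "enable_bundle": False,
        # cap the histogram cache: with tens of thousands of columns the
        # default per-leaf histogram allocation dominates small fits
        "histogram_pool_size": 16,
    }
    params.update(hp)
    return params, n_rounds


def train_ovo(
    X: np.ndarray,
    y: np.ndarray,
    weights: dict[str, float] | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> OvOModel:
    """Fit the one-vs-one ensemble with per-sample class weights.

    ``weights`` defaults to the inverse-frequency weights of the training
    labels; each pairwise model sees only its two classes' trials, weighted
    by the full-problem class weights so imbalance is penalized consistently.
    The feature matrix is binned once and shared across the pairwise models
    (binning a 61k-column matrix dominates a single binary fit).
    """
    y = np.asarray(y)
    classes = [c for c in CLASS_LABELS if c in set(y)]
    counts = {c: int(np.sum(y == c)) for c in classes}
    for c, n in counts.items():
        if n < 2:
            raise ValueError(f"class {c} has {n} < 2 training trials")
    if weights is None:
        weights = class_weights(counts)
    params, n_rounds = _lgb_params(hyperparams, seed)
    full = lgb.Dataset(
        np.asarray(X, dtype=np.float32),
        params={"max_bin": params["max_bin"], "enable_bundle": False,
                "feature_pre_filter": False, "verbosity": -1},
        free_raw_data=False,
    )
    full.construct()
    models = {}
    for c1, c2 in itertools.combinations(classes, 2):
        sel = np.flatnonzero((y == c1) | (y == c2))
        yb = (y[sel] == c2).astype(int)
        sw = np.where(yb == 0, weights[c1], weights[c2])
        dpair = full.subset(sel.tolist())
        dpair.construct()  # materialize shared bins before attaching labels
        dpair.set_label(yb)
        dpair.set_weight(sw)
        models[(c1, c2)] = lgb.train(params, dpair, num_boost_round=n_rounds)
    return OvOModel(classes=classes, models=models)


def subset_accuracy(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Exact-match rate: fraction of trials whose label is predicted exactly."""
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    if y_pred.size == 0:
        raise ValueError("empty predictions")
    if y_pred.shape != y_true.shape:
        raise ValueError("length mismatch")
    return float(np.mean(y_pred == y_true))


def _balanced_accuracy_ovr(y_pred, y_true, cls) -> float | None:
    """Mean of one-vs-rest sensitivity and specificity for one class."""
    pos = y_true == cls
    if pos.all() or not pos.any():
        return None
    sens = float(np.mean(y_pred[pos] == cls))
    spec = float(np.mean(y_pred[~pos] != cls))
    return (sens + spec) / 2.0


def evaluate(folds: list[FoldResult]) -> MetricsReport:
    """Aggregate fold results into the headline metric report.

    Per-class one-vs-rest ROC AUC and balanced accuracy are computed per
    fold and averaged across folds (folds whose test set lacks both a
    positive and a negative example for a class are omitted from that
    class's average); subset accuracy pools all held-out trials; the
    confusion matrix is the elementwise median of per-fold count matrices,
    row-normalized to percentages.
    """
    if not folds:
        raise ValueError("no folds to evaluate")
    classes = folds[0].classes
    aucs: dict[str, list[float]] = {c: [] for c in classes}
    baccs: dict[str, list[float]] = {c: [] for c in classes}
    conf_stack = []
    correct = total = 0
    per_fold = []
    for fr in folds:
        for j, c in enumerate(classes):
            pos = fr.y_true == c
            if pos.any() and not pos.all():
                aucs[c].append(roc_auc_score(pos.astype(int), fr.proba[:, j]))
            else:
                log.info("fold %s lacks both classes for %s AUC; omitted",
                         fr.subject, c)
            b = _balanced_accuracy_ovr(fr.y_pred, fr.y_true, c)
            if b is not None:
                baccs[c].append(b)
        conf_stack.append(
            confusion_matrix(fr.y_true, fr.y_pred, labels=classes)
        )
        correct += int(np.sum(fr.y_pred == fr.y_true))
        total += len(fr.y_true)
        per_fold.append(
            {
                "subject": str(fr.subject),
                "subset_accuracy": subset_accuracy(fr.y_pred, fr.y_true),
            }
        )
    med = np.median(np.stack(conf_stack), axis=0)
    row_sums = med.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf_pct = np.where(row_sums > 0, med / row_sums * 100.0, 0.0)
    return MetricsReport(
        roc_auc={c: float(np.mean(v)) for c, v in aucs.items() if v},
        balanced_accuracy={c: float(np.mean(v)) for c, v in baccs.items() if v},
        subset_accuracy=correct / total,
        confusion_percent=conf_pct,
        classes=classes,
        per_fold=per_fold,
    )


def run_loocv(
    ds: Dataset,
    hyperparams: dict | None = None,
    seed: int = 0,
    undersample: bool = True,
) -> list[FoldResult]:
    """Train and score every LOOCV fold.

    Training always uses the class-weighted loss on the full (imbalanced)
    training split; the held-out subject's trials are balanced by seeded
    undersampling before scoring when ``undersample`` is set.
    """
    results = []
    for fold_i, (train, test, subject) in enumerate(loocv_folds(ds)):
        model = train_ovo(ds.X[train], ds.y[train],
                          hyperparams=hyperparams, seed=seed)
        if undersample:
            sel = undersample_test(ds.y[test], seed=seed + fold_i)
            test = test[sel]
        proba = model.predict_proba(ds.X[test])
        results.append(
            FoldResult(
                subject=str(subject),
                proba=proba,
                y_pred=np.asarray(model.classes)[np.argmax(proba, axis=1)],
                y_true=ds.y[test],
                classes=model.classes,
            )
        )
    return results
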