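"""Machine-learning ranking of model signatures.

A classifier is taught what "looks like depression" from human data alone and
then asked, for each animal-model signature, how confident it is that the
model belongs to the depression class.  Two training-set constructions are
used, both exploiting the sign structure of the formatted signatures:

* *real + reversed*: each human depression dataset contributes one case
  instance and its elementwise sign-reversed copy as the matched control —
  the control is literally "anti-depression" expression.
* *shuffled + reversed*: the reference portrait's top-gene values are
  randomly permuted across genes (the multiset of signed values, hence every
  sign, is preserved) a number of times; each shuffle is a case and its
  negation a control.

Per (training set x classifier) pair every model receives a case
probability; probabilities are converted to ranks and the final rank is the
mean of the per-pair ranks, re-ranked.  Averaging ranks rather than raw
probabilities keeps differently calibrated classifiers on a common scale.

Classifiers are injected through a tiny fit/predict-case-probability
contract.  The package ships two: a linear-margin classifier (logistic
regression) and a small feed-forward network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .exceptions import ContractError, InvalidInputError
from .portrait import Portrait
from .signatures import GeneSignature

__all__ = [
    "FeatureSpace",
    "TrainingSet",
    "LinearMarginClassifier",
    "FeedForwardClassifier",
    "feature_vector",
    "build_training_real",
    "build_training_shuffled",
    "ml_rank",
    "crossval_accuracy",
]

CASE, CONTROL = 1, 0


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered gene features and their reference (portrait) values.

    Built from the top-``n_features`` portrait genes by |consensus value|;
    an explicit ``exclude`` list drops genes known to be poorly represented
    in the model datasets.
    """

    genes: tuple[str, ...]
    reference_values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError("feature space has duplicate genes")
        if len(self.genes) != len(self.reference_values):
            raise InvalidInputError("feature genes and reference values differ in length")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_portrait(
        cls, portrait: Portrait | GeneSignature, n_features: int = 2000,
        exclude: tuple[str, ...] = (),
    ) -> "FeatureSpace":
        values = portrait.values
        banned = {g.upper() for g in exclude}
        ranked = sorted(
            (g for g in values if g not in banned),
            key=lambda g: (-abs(values[g]), g),
        )[:n_features]
        return cls(
            genes=tuple(ranked),
            reference_values=np.array([values[g] for g in ranked], dtype=float),
        )


@dataclass
class TrainingSet:
    """Balanced case/control instances over one feature space."""

    X: np.ndarray
    y: np.ndarray
    provenance: str
    feature_genes: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise InvalidInputError("X and y disagree on the number of instances")

    @property
    def n_instances(self) -> int:
        return int(self.X.shape[0])


def feature_vector(sig: GeneSignature, space: FeatureSpace) -> np.ndarray:
    """Project a signature onto the feature genes; absent genes contribute 0."""
    if len(space) == 0:
        raise InvalidInputError("feature space is empty")
    vals = sig.values
    return np.array([vals.get(g, 0.0) for g in space.genes], dtype=float)


def build_training_real(
    human_datasets: list[GeneSignature], space: FeatureSpace
) -> TrainingSet:
    """Case = each human dataset; control = its sign-reversed copy (2n instances)."""
    if len(human_datasets) < 2:
        raise InvalidInputError(
            f"real training needs >= 2 human datasets; got {len(human_datasets)}"
        )
    X, y = [], []
    for ds in human_datasets:
        v = feature_vector(ds, space)
        X.extend([v, -v])
        y.extend([CASE, CONTROL])
    return TrainingSet(
        X=np.asarray(X), y=np.asarray(y), provenance="real_reversed",
        feature_genes=space.genes,
    )


def build_training_shuffled(
    portrait: Portrait | GeneSignature,
    space: FeatureSpace,
    n_shuffles: int = 20,
    seed: int = 0,
) -> TrainingSet:
    """Case = gene-shuffled portrait values; control = its sign-reversed copy.

    Each shuffle permutes which gene carries which value, so the multiset of
    signed values (and in particular every sign) is preserved while the
    gene-to-value assignment is randomised.  2 * ``n_shuffles`` instances.
    """
    if n_shuffles < 1:
        raise InvalidInputError(f"n_shuffles must be >= 1; got {n_shuffles}")
    rng = np.random.default_rng(seed)
    base = space.reference_values
    X, y = [], []
    for _ in range(n_shuffles):
        v = rng.permutation(base)
        X.extend([v, -v])
        y.extend([CASE, CONTROL])
    return TrainingSet(
        X=np.asarray(X), y=np.asarray(y), provenance="shuffled_reversed",
        feature_genes=space.genes,
    )


class LinearMarginClassifier:
    """L2-regularised logistic regression with calibrated probabilities."""

    name = "linear_margin"

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self._est = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearMarginClassifier":
        self._est = LogisticRegression(C=self.C, max_iter=5000, random_state=self.seed)
        self._est.fit(X, y)
        return self

    def predict_case_proba(self, X: np.ndarray) -> np.ndarray:
        case_col = list(self._est.classes_).index(CASE)
        return self._est.predict_proba(X)[:, case_col]


class FeedForwardClassifier:
    """Small fully connected network (one hidden layer) with softmax output."""

    name = "feed_forward"

    def __init__(self, hidden: int = 32, seed: int = 0, max_iter: int = 800):
        self.hidden = hidden
        self.seed = seed
        self.max_iter = max_iter
        self._est = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeedForwardClassifier":
        self._est = MLPClassifier(
            hidden_layer_sizes=(self.hidden,),
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", category=ConvergenceWarning)
            self._est.fit(X, y)
        return self

    def predict_case_proba(self, X: np.ndarray) -> np.ndarray:
        case_col = list(self._est.classes_).index(CASE)
        return self._est.predict_proba(X)[:, case_col]


def default_classifiers(seed: int = 0) -> list:
    return [LinearMarginClassifier(seed=seed), FeedForwardClassifier(seed=seed)]


def _check_classifier(clf) -> None:
    if not (hasattr(clf, "fit") and hasattr(clf, "predict_case_proba")):
        raise ContractError(
            f"classifier {clf!r} must expose fit(X, y) and predict_case_proba(X)"
        )


def ml_rank(
    models: list[GeneSignature],
    training_sets: list[TrainingSet],
    classifiers: list,
    space: FeatureSpace,
) -> pd.DataFrame:
    """Rank models by mean per-(training set x classifier) case-probability rank.

    Returns a DataFrame with one row per model: the case probability and
    rank under every pair, the mean rank, and the final re-ranked order
    (``ml_rank`` 1 = most depression-like; ties broken by dataset id).
    """
    if not models:
        raise InvalidInputError("need at least one model to rank")
    if not training_sets or not classifiers:
        raise InvalidInputError("need >= 1 training set and >= 1 classifier")
    for clf in classifiers:
        _check_classifier(clf)

    ids = [m.dataset_id for m in models]
    M = np.asarray([feature_vector(m, space) for m in models])
    out = pd.DataFrame({"dataset_id": ids})
    rank_cols = []
    for ts in training_sets:
        for clf in classifiers:
            label = f"{ts.provenance}.{getattr(clf, 'name', type(clf).__name__)}"
            clf.fit(ts.X, ts.y)
            probs = np.asarray(clf.predict_case_proba(M), dtype=float)
            out[f"proba.{label}"] = probs
            # rank 1 = highest case probability; average ranks on ties
            ranks = pd.Series(-probs).rank(method="average").to_numpy()
            out[f"rank.{label}"] = ranks
            rank_cols.append(f"rank.{label}")
    out["mean_rank"] = out[rank_cols].mean(axis=1)
    out = out.sort_values(["mean_rank", "dataset_id"], kind="mergesort").reset_index(drop=True)
    out["ml_rank"] = np.arange(1, len(out) + 1)
    return out


def crossval_accuracy(ts: TrainingSet, classifier, folds: int = 10, seed: int = 0) -> float:
    """Stratified k-fold cross-validation accuracy of a training set, in percent."""
    _check_classifier(classifier)
    if folds < 2:
        raise InvalidInputError(f"folds must be >= 2; got {folds}")
    if folds > ts.n_instances:
        raise InvalidInputError(
            f"folds={folds} exceeds the number of instances ({ts.n_instances})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(ts.X, ts.y):
        classifier.fit(ts.X[train_idx], ts.y[train_idx])
        probs = classifier.predict_case_proba(ts.X[test_idx])
        pred = (np.asarray(probs) >= 0.5).astype(int)
        correct += int((pred == ts.y[test_idx]).sum())
    return 100.0 * correct / ts.n_instances


def write_ml_ranking(table: pd.DataFrame, path, float_format: str = "%.10g") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=float_format, lineterminator="\n")
    return path
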