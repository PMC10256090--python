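"""Hierarchical SVM classification of window features.

Three prediction pathways map feature vectors to the four activity classes:

* P1 — one four-way SVM;
* P2 — background-vs-rest, then hover-vs-{inward,outward}, then
  inward-vs-outward;
* P3 — background-vs-rest, then a three-way SVM.

Each stage is an RBF-kernel SVM whose ``(C, gamma)`` are chosen by Bayesian
optimization of internal cross-validated accuracy; feature standardization is
fit on the training data of each stage only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from beeradar import _bayesopt
from beeradar.sim import CLASSES

logger = logging.getLogger(__name__)

#: Search box for the RBF SVM, in log10 space: C in [1e-3, 1e3],
#: gamma in [1e-4, 1e1].
HYPER_BOUNDS = ((-3.0, 3.0), (-4.0, 1.0))


@dataclass(frozen=True)
class Stage:
    """One cascade stage: a grouping of true labels into stage outputs.

    ``grouping`` maps each class label in the stage's domain to the token the
    stage should output for it; ``pass_token`` names the output routed on to
    the next stage (None for a terminal stage).
    """

    name: str
    grouping: dict[str, str]
    pass_token: str | None


@dataclass(frozen=True)
class PathwaySpec:
    id: str
    stages: tuple[Stage, ...]


def _bg_vs_rest() -> Stage:
    return Stage(
        "background-vs-rest",
        {"background": "background", "hover": "rest", "inward": "rest", "outward": "rest"},
        "rest",
    )


PATHWAYS: dict[str, PathwaySpec] = {
    "P1": PathwaySpec("P1", (Stage("four-way", {c: c for c in CLASSES}, None),)),
    "P2": PathwaySpec(
        "P2",
        (
            _bg_vs_rest(),
            Stage(
                "hover-vs-inout",
                {"hover": "hover", "inward": "inout", "outward": "inout"},
                "inout",
            ),
            Stage("in-vs-out", {"inward": "inward", "outward": "outward"}, None),
        ),
    ),
    "P3": PathwaySpec(
        "P3",
        (
            _bg_vs_rest(),
            Stage(
                "three-way",
                {"hover": "hover", "inward": "inward", "outward": "outward"},
                None,
            ),
        ),
    ),
}


def get_pathway(pathway: str | PathwaySpec) -> PathwaySpec:
    if isinstance(pathway, PathwaySpec):
        return pathway
    try:
        return PATHWAYS[pathway]
    except KeyError:
        raise ValueError(f"unknown pathway {pathway!r}; expected one of {list(PATHWAYS)}")


@dataclass
class TrainedPathway:
    """Fitted stage models plus the hyperparameters chosen for each stage."""

    pathway: PathwaySpec
    stage_models: list  # Pipeline or ("const", token)
    hyperparams: list[dict]
    seed: int


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1_macro: float
    confusion: np.ndarray  # rows = true, cols = predicted, CLASSES order
    per_fold: list["Metrics"] | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1_macro": self.f1_macro,
            "confusion": self.confusion.tolist(),
            "classes": list(CLASSES),
        }


def _make_svm(log_c: float, log_gamma: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=10.0**log_c, gamma=10.0**log_gamma)),
        ]
    )


def _fit_stage(
    X: np.ndarray,
    y_tokens: np.ndarray,
    hyperopt_budget: int,
    rng: np.random.Generator,
    seed: int,
):
    classes, counts = np.unique(y_tokens, return_counts=True)
    if len(classes) < 2:
        logger.warning(
            "stage has a single class %r present; using a constant predictor",
            classes[0] if len(classes) else None,
        )
        token = str(classes[0]) if len(classes) else None
        return ("const", token), {"constant": token}
    inner = int(min(3, counts.min()))
    if inner < 2 or hyperopt_budget < 1:
        model = _make_svm(0.0, np.log10(1.0 / X.shape[1]))
        model.fit(X, y_tokens)
        return model, {"log_c": 0.0, "log_gamma": float(np.log10(1.0 / X.shape[1]))}
    cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)

    def objective(params: np.ndarray) -> float:
        model = _make_svm(params[0], params[1])
        return float(np.mean(cross_val_score(model, X, y_tokens, cv=cv)))

    best, _, _ = _bayesopt.maximize(objective, HYPER_BOUNDS, hyperopt_budget, rng)
    model = _make_svm(best[0], best[1])
    model.fit(X, y_tokens)
    return model, {"log_c": float(best[0]), "log_gamma": float(best[1])}


def train_pathway(
    features: np.ndarray,
    labels: np.ndarray,
    pathway_spec: str | PathwaySpec = "P1",
    hyperopt_budget: int = 30,
    seed: int = 0,
) -> TrainedPathway:
    """Fit all cascade stages of a pathway on a labelled feature matrix.

    Deterministic given the seed; each stage's training set is the subset of
    samples whose true label belongs to that stage's domain.
    """
    spec = get_pathway(pathway_spec)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) with matching labels")
    rng = np.random.default_rng(seed)
    models, params = [], []
    for stage in spec.stages:
        domain = set(stage.grouping)
        mask = np.isin(y, list(domain))
        tokens = np.asarray([stage.grouping[lab] for lab in y[mask]])
        model, p = _fit_stage(X[mask], tokens, hyperopt_budget, rng, seed)
        models.append(model)
        params.append(p)
    return TrainedPathway(spec, models, params, seed)


def predict(trained_pathway: TrainedPathway, features: np.ndarray) -> np.ndarray:
    """Apply the stage cascade; every sample receives exactly one class label."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n_expected = _n_features(trained_pathway)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(
            f"feature length {X.shape[1]} does not match training length {n_expected}"
        )
    out = np.empty(len(X), dtype=object)
    pending = np.arange(len(X))
    for stage, model in zip(trained_pathway.pathway.stages, trained_pathway.stage_models):
        if len(pending) == 0:
            break
        if isinstance(model, tuple):  # constant stage
            tokens = np.full(len(pending), model[1], dtype=object)
        else:
            tokens = model.predict(X[pending]).astype(object)
        if stage.pass_token is None:
            out[pending] = tokens
            pending = pending[:0]
        else:
            done = tokens != stage.pass_token
            out[pending[done]] = tokens[done]
            pending = pending[~done]
    if len(pending):  # constant pass-through stage ended the cascade early
        out[pending] = trained_pathway.pathway.stages[-1].pass_token
    return out.astype(str)


def _n_features(trained: TrainedPathway) -> int | None:
    for model in trained.stage_models:
        if not isinstance(model, tuple):
            return model.named_steps["scale"].n_features_in_
    return None


def compute_metrics(true_labels, predicted_labels) -> Metrics:
    """Accuracy, weighted precision/recall, macro F1 and the 4x4 confusion."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if len(y_true) == 0:
        raise ValueError("cannot compute metrics on empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("label arrays must have equal length")
    labels = list(CLASSES)
    return Metrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(
            precision_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)
        ),
        recall=float(
            recall_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)
        ),
        f1_macro=float(
            f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)
        ),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
    )


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    pathway_spec: str | PathwaySpec = "P1",
    folds: int = 10,
    seed: int = 0,
    hyperopt_budget: int = 30,
) -> Metrics:
    """Stratified k-fold evaluation with no leakage.

    Standardization and the hyperparameter search are re-run inside every
    fold.  Scalar metrics are the mean over folds; the confusion matrix is
    summed over folds.  If the smallest class has fewer members than
    ``folds``, the fold count is reduced with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count < folds:
        logger.warning(
            "smallest class has %d members; reducing folds from %d to %d",
            min_count,
            folds,
            min_count,
        )
        folds = min_count
    if folds < 2:
        raise ValueError("cross-validation requires folds >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(folds)
    per_fold = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        trained = train_pathway(
            X[tr], y[tr], pathway_spec, hyperopt_budget, int(fold_seeds[f] % 2**31)
        )
        per_fold.append(compute_metrics(y[te], predict(trained, X[te])))
    return Metrics(
        accuracy=float(np.mean([m.accuracy for m in per_fold])),
        precision=float(np.mean([m.precision for m in per_fold])),
        recall=float(np.mean([m.recall for m in per_fold])),
        f1_macro=float(np.mean([m.f1_macro for m in per_fold])),
        confusion=np.sum([m.confusion for m in per_fold], axis=0),
        per_fold=per_fold,
    )
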