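"""Iterative probability-stacking ensemble over the advanced features.

Each round, six classical classifiers (k-nearest neighbours, logistic
regression, RBF support-vector machine, Gaussian naive Bayes, decision
tree, random forest) compete on the current feature matrix under k-fold
cross-validation.  The learner with the best out-of-fold accuracy wins;
its out-of-fold class-1 probability column is appended to the matrix,
which becomes the input of the next round.  Starting from the 8-column
advanced matrix, t completed rounds yield 8 + t columns (e.g. 13 after
5 rounds).  Iteration stops at ``max_iter`` or once the best accuracy
changes by less than ``tol`` between consecutive rounds.

Appended columns are out-of-fold to keep later rounds leak-free; for
predicting new windows each round's winner is refit on the full
training matrix and the winners are applied in sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .folds import FoldAssignment

logger = logging.getLogger(__name__)

LEARNER_ORDER: tuple[str, ...] = (
    "knn", "logistic", "svm", "naive_bayes", "decision_tree", "random_forest",
)


def default_learners(seed: int = 0) -> dict[str, BaseEstimator]:
    """The six learners with pinned hyperparameters, in fixed order."""
    return {
        "knn": KNeighborsClassifier(n_neighbors=5),
        "logistic": LogisticRegression(C=1.0, max_iter=1000),
        # RBF SVM with Platt-scaled probability outputs
        "svm": CalibratedClassifierCV(
            SVC(C=1.0, gamma="scale", random_state=seed),
            method="sigmoid", ensemble=False,
        ),
        "naive_bayes": GaussianNB(),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
    }


@dataclass
class IterationResult:
    winner: str
    cv_accuracy: float
    column: np.ndarray                 # out-of-fold class-1 probabilities
    per_learner_accuracy: dict[str, float]
    refit_model: BaseEstimator         # winner refit on all rows
    # leakage provenance, as in the extractor: per fold the training rows
    trained_rows: list[np.ndarray]
    producer_fold: np.ndarray


def _oof_eval(est: BaseEstimator, X: np.ndarray, y: np.ndarray,
              folds: FoldAssignment):
    probs = np.full(len(y), np.nan)
    preds = np.empty(len(y), dtype=int)
    trained_rows, producer = [], np.full(len(y), -1, dtype=int)
    for fold in range(folds.k):
        tr, te = folds.rows_not_in_fold(fold), folds.rows_in_fold(fold)
        model = clone(est)
        model.fit(X[tr], y[tr])
        pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
        probs[te] = model.predict_proba(X[te])[:, pos_col]
        preds[te] = model.predict(X[te])
        trained_rows.append(tr)
        producer[te] = fold
    accuracy = float((preds == y).mean())
    return accuracy, probs, trained_rows, producer


def run_iteration(
    matrix: np.ndarray,
    labels: np.ndarray,
    folds: FoldAssignment,
    learners: dict[str, BaseEstimator] | None = None,
) -> IterationResult:
    """One stacking round: evaluate the six learners, pick the winner.

    The winner is the learner with the highest out-of-fold accuracy;
    exact ties go to the earlier learner in the fixed order.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError("matrix rows must match labels")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (a single class)")
    if learners is None:
        learners = default_learners()

    accuracies: dict[str, float] = {}
    results = {}
    for name, est in learners.items():
        acc, probs, trained_rows, producer = _oof_eval(est, X, y, folds)
        accuracies[name] = acc
        results[name] = (probs, trained_rows, producer)
    winner = max(learners, key=lambda name: accuracies[name])  # ties -> first
    probs, trained_rows, producer = results[winner]
    refit = clone(learners[winner])
    refit.fit(X, y)
    return IterationResult(
        winner=winner,
        cv_accuracy=accuracies[winner],
        column=probs,
        per_learner_accuracy=accuracies,
        refit_model=refit,
        trained_rows=trained_rows,
        producer_fold=producer,
    )


@dataclass
class EnrichedMatrix:
    """The growing n x (8 + t) matrix with per-column provenance."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    base_columns: int
    provenance: list[dict] = field(default_factory=list)
    refit_models: list[BaseEstimator] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def n_iterations(self) -> int:
        return self.matrix.shape[1] - self.base_columns

    def accuracy_history(self) -> list[float]:
        return [p["cv_accuracy"] for p in self.provenance]

    def transform(self, new_matrix: np.ndarray) -> np.ndarray:
        """Enrich new rows by applying each round's refit winner in turn."""
        X = np.asarray(new_matrix, dtype=float)
        if X.shape[1] != self.base_columns:
            raise ValueError(
                f"expected {self.base_columns} base columns, got {X.shape[1]}"
            )
        for model in self.refit_models:
            pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
            col = model.predict_proba(X)[:, pos_col]
            X = np.column_stack([X, col])
        return X


def iterate(
    matrix: np.ndarray,
    labels: np.ndarray,
    folds: FoldAssignment,
    learners: dict[str, BaseEstimator] | None = None,
    max_iter: int = 10,
    tol: float = 1e-4,
    ids: Sequence[str] | None = None,
    iteration_results: list[IterationResult] | None = None,
) -> EnrichedMatrix:
    """Run stacking rounds until convergence or ``max_iter``.

    ``iteration_results``, when given a list, collects every round's
    full :class:`IterationResult` (used by the leakage-audit tests).
    """
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    X = np.asarray(matrix, dtype=float).copy()
    base = X.shape[1]
    ids = tuple(ids) if ids is not None else tuple(str(i) for i in range(len(X)))
    enriched = EnrichedMatrix(ids=ids, matrix=X, base_columns=base)
    prev_acc = None
    for it in range(max_iter):
        result = run_iteration(enriched.matrix, labels, folds, learners)
        if iteration_results is not None:
            iteration_results.append(result)
        enriched.matrix = np.column_stack([enriched.matrix, result.column])
        enriched.provenance.append({
            "iteration": it + 1,
            "winner": result.winner,
            "cv_accuracy": result.cv_accuracy,
        })
        enriched.refit_models.append(result.refit_model)
        logger.info("stacking round %d: winner=%s acc=%.4f",
                    it + 1, result.winner, result.cv_accuracy)
        if prev_acc is not None and abs(result.cv_accuracy - prev_acc) < tol:
            enriched.stop_reason = (
                f"converged (|delta acc| < {tol:g} at iteration {it + 1})"
            )
            break
        prev_acc = result.cv_accuracy
    else:
        enriched.stop_reason = f"max_iter {max_iter} reached"
    return enriched


def write_enriched_tsv(enriched: EnrichedMatrix, tsv_path,
                       provenance_path=None) -> None:
    import json
    from pathlib import Path

    n_extra = enriched.n_iterations
    header = ["id"] + [f"f{i + 1}" for i in range(enriched.base_columns + n_extra)]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for sid, row in zip(enriched.ids, enriched.matrix):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    if provenance_path is not None:
        Path(provenance_path).write_text(json.dumps({
            "base_columns": enriched.base_columns,
            "iterations": enriched.provenance,
            "stop_reason": enriched.stop_reason,
        }, indent=2) + "\n")
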