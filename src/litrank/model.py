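"""Penalty tuning and training of the linear relevance classifier.

The classifier is L2-regularized logistic regression (dual formulation,
LIBLINEAR solver family) over raw keyword-count vectors, with termination
tolerance e = 0.1 and the penalty parameter C tuned by a fixed two-stage
grid search under five-fold cross-validation:

1. Evaluate CV accuracy at the eight points C = 2^x, x = -3..4.
2. If the training set is small (< 5,000 vectors), or of moderate size
   (< 10,000 vectors) with best first-stage CV accuracy below 80%, also
   evaluate a fixed neighborhood of the best first-stage point:

   ====  ======  ===============================
     x   C=2^x   neighborhood C values
   ====  ======  ===============================
    -3   0.125   0.05, 0.1, 0.15
    -2   0.25    0.15, 0.2, 0.3, 0.35
    -1   0.5     0.3, 0.4, 0.6, 0.7
     0   1.0     0.75, 1.25, 1.5
     1   2.0     1.5, 2.5, 3.0
     2   4.0     3.0, 3.5, 4.5, 5.0, 6.0
     3   8.0     6.0, 7.0, 9.0, 10.0, 11.0
     4   16.0    11.0, 12.0, 13.0, 14.0, 15.0
   ====  ======  ===============================

The C with the highest CV accuracy over every evaluated point wins; ties
break toward the smallest C (strongest regularization).  The final model is
fit on all of A∪B and scores any vector with the probability of belonging
to set A — the sigmoid of the linear decision value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .features import SparseVector, labels_array, to_csr

FIRST_STAGE_EXPONENTS = tuple(range(-3, 5))

_REFINEMENT_TABLE: dict[int, tuple[float, ...]] = {
    -3: (0.05, 0.1, 0.15),
    -2: (0.15, 0.2, 0.3, 0.35),
    -1: (0.3, 0.4, 0.6, 0.7),
    0: (0.75, 1.25, 1.5),
    1: (1.5, 2.5, 3.0),
    2: (3.0, 3.5, 4.5, 5.0, 6.0),
    3: (6.0, 7.0, 9.0, 10.0, 11.0),
    4: (11.0, 12.0, 13.0, 14.0, 15.0),
}

#: Training-set sizes controlling the second grid-search stage.
SMALL_TRAINING_SET = 5_000
MODERATE_TRAINING_SET = 10_000
REFINE_ACCURACY_BELOW = 0.80


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings: tolerance e (default 0.1) and CV folds (default 5)."""

    solver: str = "L2-regularized logistic regression (dual)"
    tolerance_e: float = 0.1
    folds: int = 5

    def __post_init__(self):
        if self.tolerance_e <= 0:
            raise ValueError("tolerance must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class GridPoint:
    C: float
    cv_accuracy: float
    stage: str = "first"  # "first" or "refine"
    x: int | None = None  # exponent, first-stage points only


@dataclass
class TunedModel:
    """Trained linear model with its tuning trace.

    ``weights`` is sparse by dimension; the score of a vector v is
    sigmoid(sum_d w[d]*v[d] + intercept), the probability of set A.
    ``test_set_accuracy`` is the re-classification accuracy on the A∪B
    training vectors themselves (the default test arrangement).
    """

    weights: dict[int, float]
    intercept: float
    n_dims: int
    chosen_C: float
    cv_accuracy: float
    trace: list[GridPoint] = field(default_factory=list)
    test_set_accuracy: float = float("nan")
    config: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0

    def decision_value(self, vec: SparseVector) -> float:
        return sum(self.weights.get(d, 0.0) * c for d, c in vec.entries.items()) \
            + self.intercept

    def probability_a(self, vec: SparseVector) -> float:
        """Probability that the abstract belongs to set A, in [0, 1]."""
        return float(1.0 / (1.0 + np.exp(-self.decision_value(vec))))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "weights": {str(d): w for d, w in self.weights.items()},
            "intercept": self.intercept,
            "n_dims": self.n_dims,
            "chosen_C": self.chosen_C,
            "cv_accuracy": self.cv_accuracy,
            "test_set_accuracy": self.test_set_accuracy,
            "trace": [{"C": p.C, "cv_accuracy": p.cv_accuracy,
                       "stage": p.stage, "x": p.x} for p in self.trace],
            "seed": self.seed,
            "config": {"solver": self.config.solver,
                       "tolerance_e": self.config.tolerance_e,
                       "folds": self.config.folds},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TunedModel":
        doc = json.loads(Path(path).read_text())
        cfg = SolverConfig(**doc["config"])
        return cls(weights={int(d): w for d, w in doc["weights"].items()},
                   intercept=doc["intercept"], n_dims=doc["n_dims"],
                   chosen_C=doc["chosen_C"], cv_accuracy=doc["cv_accuracy"],
                   trace=[GridPoint(p["C"], p["cv_accuracy"], p["stage"], p["x"])
                          for p in doc["trace"]],
                   test_set_accuracy=doc["test_set_accuracy"],
                   config=cfg, seed=doc["seed"])


def first_stage_grid() -> tuple[float, ...]:
    """The eight first-stage C values, 2^x for x = -3..4, ascending."""
    return tuple(2.0 ** x for x in FIRST_STAGE_EXPONENTS)


def refinement_values(x_best: int) -> tuple[float, ...]:
    """Neighborhood C values for the best first-stage exponent."""
    try:
        return _REFINEMENT_TABLE[int(x_best)]
    except KeyError:
        raise ValueError(f"exponent {x_best} outside the first-stage range [-3, 4]")


def should_refine(n_training_vectors: int, best_first_stage_accuracy: float) -> bool:
    """Second-stage trigger: small set, or moderate set with accuracy < 80%."""
    return (n_training_vectors < SMALL_TRAINING_SET
            or (n_training_vectors < MODERATE_TRAINING_SET
                and best_first_stage_accuracy < REFINE_ACCURACY_BELOW))


def _fit_liblinear(X, y, C: float, cfg: SolverConfig) -> LogisticRegression:
    # default penalty is L2; liblinear + dual=True is the dual-form LR solver
    clf = LogisticRegression(C=C, solver="liblinear", dual=True,
                             tol=cfg.tolerance_e, random_state=0)
    clf.fit(X, y)
    return clf


def assign_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: seeded shuffle per label, then round-robin."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    return fold_of


def cross_validate(vectors: Sequence[SparseVector], C: float,
                   cfg: SolverConfig | None = None, seed: int = 0) -> float:
    """Five-fold (by default) cross-validated accuracy at penalty C.

    Folds are assigned by a seeded stratified partition, so the result is
    deterministic given the seed.  A fold that happens to hold out only one
    class is still scored.
    """
    cfg = cfg or SolverConfig()
    if len(vectors) < cfg.folds:
        raise ValueError(f"need at least {cfg.folds} vectors for {cfg.folds}-fold CV")
    y = labels_array(vectors)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present in the training set")
    n_dims = 1 + max((d for v in vectors for d in v.entries), default=0)
    X = to_csr(vectors, n_dims)
    fold_of = assign_folds(y, cfg.folds, seed)
    correct = 0
    for k in range(cfg.folds):
        test = fold_of == k
        if not test.any():
            continue
        train = ~test
        if len(np.unique(y[train])) < 2:
            continue
        clf = _fit_liblinear(X[train], y[train], C, cfg)
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / len(vectors)


def select_C(vectors: Sequence[SparseVector], cfg: SolverConfig | None = None,
             seed: int = 0) -> tuple[float, list[GridPoint]]:
    """Two-stage grid search for the penalty parameter.

    Returns the winning C and the full evaluation trace.  Ties in CV
    accuracy break toward the smallest C.
    """
    cfg = cfg or SolverConfig()
    trace: list[GridPoint] = []
    for x in FIRST_STAGE_EXPONENTS:
        C = 2.0 ** x
        acc = cross_validate(vectors, C, cfg, seed)
        trace.append(GridPoint(C, acc, "first", x))
    best_first = max(trace, key=lambda p: (p.cv_accuracy, -p.C))
    if should_refine(len(vectors), best_first.cv_accuracy):
        for C in refinement_values(best_first.x):
            acc = cross_validate(vectors, C, cfg, seed)
            trace.append(GridPoint(C, acc, "refine"))
    chosen = max(trace, key=lambda p: (p.cv_accuracy, -p.C))
    return chosen.C, trace


def train_final(vectors: Sequence[SparseVector], chosen_C: float,
                cfg: SolverConfig | None = None, n_dims: int | None = None,
                trace: Sequence[GridPoint] = (), cv_accuracy: float = float("nan"),
                seed: int = 0) -> TunedModel:
    """Fit the final model on all of A∪B at the chosen penalty.

    The training vectors double as the default test set: the reported
    test-set accuracy is the model's re-classification accuracy on them.
    """
    cfg = cfg or SolverConfig()
    y = labels_array(vectors)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present in the training set")
    if n_dims is None:
        n_dims = 1 + max((d for v in vectors for d in v.entries), default=0)
    X = to_csr(vectors, n_dims)
    clf = _fit_liblinear(X, y, chosen_C, cfg)
    coef = clf.coef_.ravel()
    # liblinear orders classes ascending (0=B, 1=A), so coef already points at A
    model = TunedModel(
        weights={int(d): float(coef[d]) for d in np.flatnonzero(coef)},
        intercept=float(clf.intercept_[0]),
        n_dims=n_dims, chosen_C=chosen_C, cv_accuracy=cv_accuracy,
        trace=list(trace), config=cfg, seed=seed)
    model.test_set_accuracy = float((clf.predict(X) == y).mean())
    return model
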