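"""Imbalance-aware boosting over a heterogeneous base-learner roster.

The training set keeps all n positives in every round; each round draws
n negatives (with replacement) from a weight distribution maintained
over the negative set only, fits one base learner on that balanced
subset, measures its error rate eps_t on the *whole* negative training
set, and multiplies the weights of the misclassified negatives by

    f_t = log_size( size * (1 - eps_t) / eps_t ),

where size is the number of negatives. The logarithm base equal to the
negative-set size deliberately slows weight growth on large negative
pools: f_t > 1 exactly when the learner beats chance on negatives,
f_t = 1 at eps_t = 0.5, and f_t < 1 beyond. The T fitted hypotheses
vote with weights alpha_t = ln((1 - e_t)/e_t) (e_t the learner's
unweighted error on the full training set, clamped away from 0 and 1),
the standard boosting vote weight.

Rounds cycle through a registry of named algorithm kinds; the default
registry holds 20 kinds spanning nearest-neighbour, tree, margin,
probabilistic and baseline families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Callable, Optional, Sequence, Union

import joblib
import numpy as np

logger = logging.getLogger("dnabind")

_MODEL_FORMAT = "dnabind-model-1"


@dataclass
class TrainingSet:
    """Feature matrix plus aligned labels in {-1, +1}.

    Row order is significant: protocol steps such as "the first k
    negatives" refer to row order, which is preserved end-to-end.
    """

    X: np.ndarray
    y: np.ndarray
    ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if len(self.y) != len(self.X):
            raise ValueError(f"{len(self.X)} rows but {len(self.y)} labels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must take values in {-1, +1}")
        if self.ids is not None and len(self.ids) != len(self.X):
            raise ValueError("ids must align with rows")

    @property
    def n_positives(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negatives(self) -> int:
        return int(np.sum(self.y == -1))

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, indices: np.ndarray) -> "TrainingSet":
        ids = [self.ids[i] for i in indices] if self.ids is not None else None
        return TrainingSet(self.X[indices], self.y[indices], ids)


# ---------------------------------------------------------------------------
# Base-learner registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseLearnerSpec:
    """A named classification algorithm kind with hyperparameter overrides."""

    kind: str
    params: tuple = ()  # (key, value) pairs; hashable for frozen dataclass

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_FACTORIES:
            raise ValueError(
                f"unknown base-learner kind {self.kind!r}; "
                f"registered: {sorted(LEARNER_FACTORIES)}"
            )

    @property
    def hyperparams(self) -> dict:
        return dict(self.params)


def _factory(builder: Callable, seeded: bool = True) -> Callable:
    def make(seed: int, **params):
        if seeded:
            params.setdefault("random_state", seed)
        return builder(**params)

    return make


def _build_factories() -> dict:
    from sklearn.dummy import DummyClassifier
    from sklearn.linear_model import (
        LogisticRegression,
        Perceptron,
        RidgeClassifier,
        SGDClassifier,
    )
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
    from sklearn.svm import SVC, LinearSVC
    from sklearn.tree import DecisionTreeClassifier
    from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier

    def knn(k):
        return lambda **p: KNeighborsClassifier(n_neighbors=k, **p)

    return {
        # nearest-neighbour family (k = 1, 5, 15)
        "knn1": _factory(knn(1), seeded=False),
        "knn5": _factory(knn(5), seeded=False),
        "knn15": _factory(knn(15), seeded=False),
        # tree family
        "tree": _factory(DecisionTreeClassifier),
        "tree_entropy": _factory(
            lambda **p: DecisionTreeClassifier(criterion="entropy", **p)
        ),
        "tree_depth5": _factory(lambda **p: DecisionTreeClassifier(max_depth=5, **p)),
        "tree_depth3": _factory(lambda **p: DecisionTreeClassifier(max_depth=3, **p)),
        "stump": _factory(lambda **p: DecisionTreeClassifier(max_depth=1, **p)),
        "random_tree": _factory(
            lambda **p: DecisionTreeClassifier(
                splitter="random", max_features="sqrt", **p
            )
        ),
        "random_forest": _factory(
            lambda **p: RandomForestClassifier(n_estimators=50, **p)
        ),
        "extra_trees": _factory(
            lambda **p: ExtraTreesClassifier(n_estimators=50, **p)
        ),
        # margin / function family
        "linear_svm": _factory(lambda **p: LinearSVC(**p)),
        "rbf_svm": _factory(lambda **p: SVC(kernel="rbf", gamma="scale", **p)),
        "logistic": _factory(lambda **p: LogisticRegression(max_iter=2000, **p)),
        "ridge": _factory(lambda **p: RidgeClassifier(**p)),
        "sgd": _factory(lambda **p: SGDClassifier(**p)),
        "perceptron": _factory(lambda **p: Perceptron(**p)),
        # probabilistic / prototype / baseline
        "gaussian_nb": _factory(lambda **p: GaussianNB(**p), seeded=False),
        "nearest_centroid": _factory(lambda **p: NearestCentroid(**p), seeded=False),
        "majority": _factory(lambda **p: DummyClassifier(strategy="most_frequent", **p)),
    }


LEARNER_FACTORIES = _build_factories()

_DEFAULT_ORDER = (
    "knn1",
    "knn5",
    "knn15",
    "tree",
    "tree_entropy",
    "tree_depth5",
    "tree_depth3",
    "stump",
    "random_tree",
    "random_forest",
    "extra_trees",
    "linear_svm",
    "rbf_svm",
    "logistic",
    "ridge",
    "sgd",
    "perceptron",
    "gaussian_nb",
    "nearest_centroid",
    "majority",
)


def default_registry() -> list[BaseLearnerSpec]:
    """The default roster of 20 base-learner kinds, in cycling order."""
    return [BaseLearnerSpec(kind) for kind in _DEFAULT_ORDER]


def build_learner(spec: BaseLearnerSpec, seed: int):
    """Instantiate an unfitted scikit-learn estimator for a spec."""
    return LEARNER_FACTORIES[spec.kind](seed, **spec.hyperparams)


# ---------------------------------------------------------------------------
# Weight algebra
# ---------------------------------------------------------------------------

def initial_weights(l: int) -> np.ndarray:
    """Uniform weight distribution over l negatives (each 1/l)."""
    if l < 1:
        raise ValueError("need at least one negative sample")
    return np.full(l, 1.0 / l)


def sample_negatives(
    negatives: np.ndarray,
    weights: np.ndarray,
    k: int,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Draw k negative rows with replacement, row i with probability weights[i]."""
    if k < 1:
        raise ValueError("must draw at least one negative sample")
    negatives = np.asarray(negatives)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _sample_indices(np.asarray(weights, dtype=float), k, rng)
    return negatives[idx]


def _sample_indices(weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"weights must sum to 1 (got {total!r})")
    return rng.choice(len(weights), size=k, replace=True, p=weights / total)


def weight_factor(eps: float, size: int, eps_min: Optional[float] = None) -> float:
    """Weight-increase factor f = log_size(size * (1 - eps)/eps).

    ``eps`` is clamped into [eps_min, 1 - eps_min] (default
    eps_min = 1/(2*size)) so the factor stays finite at eps in {0, 1}.
    f > 1 iff eps < 0.5; f = 1 at eps = 0.5; f < 1 for eps > 0.5.
    """
    if size < 2:
        raise ValueError("size must be >= 2 (logarithm base degenerate)")
    if eps_min is None:
        eps_min = 1.0 / (2 * size)
    eps = min(max(eps, eps_min), 1.0 - eps_min)
    return math.log(size * (1.0 - eps) / eps) / math.log(size)


def update_weights(
    weights: np.ndarray, misclassified: Sequence[int], factor: float
) -> np.ndarray:
    """Multiply misclassified weights by ``factor``, then renormalize to sum 1."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    updated = np.asarray(weights, dtype=float).copy()
    mis = np.asarray(list(misclassified), dtype=int)
    if len(mis):
        updated[mis] *= factor
    return updated / updated.sum()


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class BoostingRound:
    """One fitted hypothesis with its audit quantities."""

    learner: object
    kind: str
    alpha: float  # vote weight
    eps: float    # unweighted error on the full negative training set
    factor: float # weight-increase factor applied after this round
    train_error: float  # unweighted error on the full training set


@dataclass
class EnsembleModel:
    """A trained weighted-vote ensemble with its full weight history."""

    rounds: list[BoostingRound]
    weight_history: np.ndarray  # (T+1, l): W_1 ... W_{T+1}
    n_features: int
    feature_names: Optional[tuple[str, ...]] = None
    groupings: Optional[tuple] = None  # (name, (g1, g2, g3)) per property
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([r.alpha for r in self.rounds])

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Normalized weighted-vote score in [-1, 1] per row."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            got = X.shape[1] if X.ndim == 2 else None
            raise ValueError(
                f"feature dimension mismatch: model expects {self.n_features}, got {got}"
            )
        votes = np.vstack([r.learner.predict(X) for r in self.rounds])
        alphas = self.alphas
        total = alphas.sum()
        if total <= 0:
            # All vote weights clamped to zero: fall back to a uniform vote.
            alphas = np.ones_like(alphas)
            total = alphas.sum()
        return (alphas @ votes) / total

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels in {-1, +1} and scores per row; exact score ties go negative.

        The negative class dominates the application prior (most
        proteins do not bind DNA), so a tied vote is resolved
        conservatively.
        """
        scores = self.decision_scores(X)
        labels = np.where(scores > 0, 1, -1)
        return labels, scores


def train(
    data: TrainingSet,
    registry: Optional[Sequence[BaseLearnerSpec]] = None,
    rounds: Optional[int] = None,
    seed: int = 0,
    vote: str = "weighted",
) -> EnsembleModel:
    """Train the boosting ensemble.

    Parameters
    ----------
    data :
        Training set with at least one positive and one negative row.
    registry :
        Ordered base-learner specs; round t uses registry[(t-1) mod len].
        Defaults to the 20-kind roster of :func:`default_registry`.
    rounds :
        Number of boosting rounds T; defaults to len(registry).
    seed :
        Master seed for negative sampling and learner randomness.
    vote :
        "weighted" for alpha_t = ln((1-e_t)/e_t) clamped to [0, 10];
        "uniform" for equal vote weights.
    """
    if registry is None:
        registry = default_registry()
    registry = list(registry)
    if not registry:
        raise ValueError("registry must be non-empty")
    if vote not in ("weighted", "uniform"):
        raise ValueError(f"vote must be 'weighted' or 'uniform', got {vote!r}")
    T = len(registry) if rounds is None else int(rounds)
    if T < 1:
        raise ValueError("need at least one boosting round")

    n, l = data.n_positives, data.n_negatives
    if n == 0 or l == 0:
        raise ValueError(
            f"training needs both classes (got {n} positives, {l} negatives)"
        )
    X_pos = data.X[data.y == 1]
    X_neg = data.X[data.y == -1]
    m = len(data)

    rng = np.random.default_rng(seed)
    weights = initial_weights(l)
    history = [weights]
    fitted: list[BoostingRound] = []
    y_pos = np.ones(n, dtype=int)
    y_neg = -np.ones(n, dtype=int)
    eps_min_full = 1.0 / (2 * m)

    for t in range(T):
        spec = registry[t % len(registry)]
        sample_seed = int(rng.integers(0, 2**31 - 1))
        learner_seed = int(rng.integers(0, 2**31 - 1))
        idx = _sample_indices(weights, n, np.random.default_rng(sample_seed))
        X_round = np.vstack([X_pos, X_neg[idx]])
        y_round = np.concatenate([y_pos, y_neg])
        learner = build_learner(spec, learner_seed)
        try:
            learner.fit(X_round, y_round)
        except Exception as exc:  # noqa: BLE001 - any learner failure skips the round
            logger.warning("round %d: base learner %r failed to fit (%s); skipped",
                           t + 1, spec.kind, exc)
            continue

        pred_neg = np.asarray(learner.predict(X_neg))
        mis = np.flatnonzero(pred_neg != -1)
        eps = len(mis) / l
        factor = weight_factor(eps, l)
        weights = update_weights(weights, mis, factor)
        history.append(weights)

        pred_all = np.asarray(learner.predict(data.X))
        e = float(np.mean(pred_all != data.y))
        e = min(max(e, eps_min_full), 1.0 - eps_min_full)
        if vote == "weighted":
            alpha = float(np.clip(math.log((1.0 - e) / e), 0.0, 10.0))
        else:
            alpha = 1.0
        fitted.append(
            BoostingRound(
                learner=learner,
                kind=spec.kind,
                alpha=alpha,
                eps=eps,
                factor=factor,
                train_error=e,
            )
        )

    if not fitted:
        raise RuntimeError("every boosting round failed to fit a base learner")

    return EnsembleModel(
        rounds=fitted,
        weight_history=np.vstack(history),
        n_features=data.X.shape[1],
        seed=seed,
        metadata={"vote": vote, "requested_rounds": T},
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path: Union[str, PathLike]) -> None:
    """Serialize a trained model (single archive file, format-versioned)."""
    joblib.dump({"format": _MODEL_FORMAT, "model": model}, path)


def load_model(path: Union[str, PathLike]) -> EnsembleModel:
    """Load a model written by :func:`save_model`."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path!r} is not a recognized model archive")
    return payload["model"]
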