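"""Random-forest classifier for pair vectors, with a Naive Bayes baseline.

The forest follows the classic recipe: each of ``ntree`` trees is grown
on a bootstrap sample, considering ``mtry`` randomly selected features
per split under the Gini criterion; generalization error is estimated
out-of-bag (OOB) and the predicted probability of a pair is the fraction
of tree votes for the interaction class.  ``mtry`` is tuned by scanning
a grid (default 5..100 step 5) and picking the value with the lowest
mean OOB error over repeated fits.  Variable importance is measured by
permutation: a feature's values are shuffled and the resulting drop in
accuracy is its score.

scikit-learn's ``RandomForestClassifier`` provides the tree growing and
OOB machinery; the vote-fraction probability and permutation importance
conventions are fixed here and recorded in the model metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

DEFAULT_NTREE = 600
MTRY_GRID = tuple(range(5, 101, 5))


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    return X, y


@dataclass
class TrainedForest:
    """A fitted random forest plus its training metadata.

    ``oob_error`` is the out-of-bag misclassification rate; predicted
    probabilities are vote fractions over the ``ntree`` trees.
    """

    forest: RandomForestClassifier
    ntree: int
    mtry: int
    seed: int
    oob_error: float
    n_features: int
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)


def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int | None = None,
    ntree: int = DEFAULT_NTREE,
    seed: int = 0,
    class_weight: str | dict | None = None,
) -> TrainedForest:
    """Grow a random forest of ``ntree`` bootstrap trees with Gini splits.

    ``mtry`` is the number of features considered per split (default
    sqrt of the feature count).  The data are used as-is — no class
    reweighting by default; pass ``class_weight="balanced"`` to opt in.
    """
    X, y = _check_xy(X, y)
    n_features = X.shape[1]
    if mtry is None:
        mtry = max(1, int(np.sqrt(n_features)))
    if not 1 <= mtry <= n_features:
        raise ValueError(f"mtry={mtry} outside [1, {n_features}]")
    forest = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        random_state=int(seed) % (2**31),
        class_weight=class_weight,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedForest(
        forest=forest,
        ntree=ntree,
        mtry=mtry,
        seed=seed,
        oob_error=1.0 - float(forest.oob_score_),
        n_features=n_features,
        metadata={
            "probability": "fraction of tree votes for the positive class",
            "importance": "permutation (accuracy drop under feature shuffling)",
        },
    )


def predict_proba(model: TrainedForest, X: np.ndarray) -> np.ndarray:
    """Positive-class probability as the fraction of tree votes."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    classes = model.forest.classes_
    pos = int(np.where(classes == classes.max())[0][0])
    votes = np.zeros(X.shape[0])
    for tree in model.forest.estimators_:
        votes += (tree.predict(X) == classes[pos])
    return votes / len(model.forest.estimators_)


def tune_mtry(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[int, ...] = MTRY_GRID,
    ntree: int = DEFAULT_NTREE,
    seed: int = 0,
    repeats: int = 5,
) -> tuple[int, dict[int, float]]:
    """Pick the mtry with the lowest mean OOB error over repeated fits.

    Returns ``(best_mtry, profile)`` where ``profile`` maps each grid
    value to its mean OOB error.  Ties break toward smaller mtry.
    """
    X, y = _check_xy(X, y)
    if not grid:
        raise ValueError("mtry grid must be non-empty")
    if max(grid) > X.shape[1]:
        raise ValueError(f"grid values must be <= {X.shape[1]} features")
    rng = np.random.default_rng(seed)
    profile: dict[int, float] = {}
    for m in sorted(grid):
        errs = [
            train_rf(X, y, mtry=m, ntree=ntree, seed=int(rng.integers(2**31))).oob_error
            for _ in range(repeats)
        ]
        profile[m] = float(np.mean(errs))
    best = min(profile, key=lambda m: (profile[m], m))
    return best, profile


def feature_importance(
    model: TrainedForest,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Permutation importance: accuracy drop when a feature is shuffled."""
    from sklearn.inspection import permutation_importance

    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    result = permutation_importance(
        model.forest, X, y, n_repeats=n_repeats,
        random_state=int(seed) % (2**31), scoring="accuracy", n_jobs=1,
    )
    return result.importances_mean


def select_top_features(importances: np.ndarray, k: int = 300) -> np.ndarray:
    """Indices of the k highest-importance features, ties broken by index."""
    importances = np.asarray(importances)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > importances.size:
        raise ValueError(f"k={k} exceeds {importances.size} features")
    # stable sort on (-score, index) gives deterministic tie-breaking
    order = np.lexsort((np.arange(importances.size), -importances))
    return np.sort(order[:k])


class MixedNaiveBayes:
    """Naive Bayes over mixed binary/continuous pair features.

    Each feature is modeled independently given the class: Bernoulli
    with Laplace smoothing for binary features (the fingerprint bits),
    Gaussian for continuous ones (the protein descriptors).  Posteriors
    are accumulated in log space.
    """

    def __init__(self, binary_mask: np.ndarray | None = None):
        self.binary_mask = binary_mask

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MixedNaiveBayes":
        X, y = _check_xy(X, y)
        self.classes_ = np.unique(y)
        if self.binary_mask is None:
            self.binary_mask = np.array(
                [set(np.unique(col)) <= {0.0, 1.0} for col in X.T]
            )
        mask = self.binary_mask
        self.log_prior_ = np.log(
            np.array([(y == c).mean() for c in self.classes_])
        )
        self.theta_ = []   # Bernoulli P(bit=1 | class), Laplace-smoothed
        self.mu_ = []
        self.var_ = []
        var_floor = 1e-9 * max(float(X[:, ~mask].var()) if (~mask).any() else 1.0, 1e-12)
        for c in self.classes_:
            Xc = X[y == c]
            self.theta_.append((Xc[:, mask].sum(axis=0) + 1.0) / (len(Xc) + 2.0))
            if (~mask).any():
                self.mu_.append(Xc[:, ~mask].mean(axis=0))
                self.var_.append(Xc[:, ~mask].var(axis=0) + var_floor)
            else:
                self.mu_.append(np.empty(0))
                self.var_.append(np.empty(0))
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mask = self.binary_mask
        jll = np.empty((X.shape[0], len(self.classes_)))
        for i, _ in enumerate(self.classes_):
            ll = np.full(X.shape[0], self.log_prior_[i])
            theta = self.theta_[i]
            Xb = X[:, mask]
            ll += Xb @ np.log(theta) + (1 - Xb) @ np.log1p(-theta)
            if (~mask).any():
                Xg = X[:, ~mask]
                mu, var = self.mu_[i], self.var_[i]
                ll += (-0.5 * (np.log(2 * np.pi * var) + (Xg - mu) ** 2 / var)).sum(axis=1)
            jll[:, i] = ll
        return jll

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the positive (largest-label) class."""
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        post = np.exp(jll)
        post /= post.sum(axis=1, keepdims=True)
        return post[:, int(np.argmax(self.classes_))]


def train_nb(X: np.ndarray, y: np.ndarray, binary_mask: np.ndarray | None = None) -> MixedNaiveBayes:
    """Fit the mixed Bernoulli/Gaussian Naive Bayes baseline."""
    return MixedNaiveBayes(binary_mask=binary_mask).fit(X, y)
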