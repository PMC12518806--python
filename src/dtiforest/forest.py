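"""The logistic-forest hybrid classifier.

Two interpretable base learners are combined:

* a logistic-regression ensemble fit by Newton-Raphson — the feature space
  is partitioned at random into N near-equal subspaces, one logistic model
  is fit per subspace, and the ensemble probability is the member mean
  (binary decisions threshold at 0.5; multi-class is one-vs-rest with
  renormalized scores);
* a random forest of CART-style trees grown on bootstrap resamples with
  exhaustive midpoint-threshold search maximizing the Gini impurity
  decrease, voting by tree majority, with Gini importance accumulated as
  the sample-weighted impurity decrease over all nodes splitting on a
  feature.

Predictions are fused either by weighted averaging of the two probability
vectors or by a two-model vote (disagreements resolved by the
higher-weighted model). The fusion weights are context-aware: a
declarative map from a context key (by default the candidate predicted
class) to a weight pair overrides the base weights — e.g. the forest is
weighted more heavily for cancer-related records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LogisticModel",
    "logistic_probability",
    "fit_logistic",
    "SubspaceLogisticEnsemble",
    "fit_logistic_subspace_ensemble",
    "gini_impurity",
    "impurity_decrease",
    "TreeNode",
    "DecisionTree",
    "Forest",
    "fit_forest",
    "predict_forest",
    "gini_importance",
    "HybridModel",
    "combine_hybrid",
    "LogisticForestClassifier",
]

_BETA_CAP = 50.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # overflow-safe logistic link
    return np.exp(-np.logaddexp(0.0, -np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# Logistic regression by Newton-Raphson
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Binary logistic model: P(y=1|x) = 1 / (1 + exp(-(b0 + x.b)))."""

    intercept: float
    coef: np.ndarray
    n_iterations: int = 0
    converged: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef.size:
            raise ValueError(
                f"expected {self.coef.size} features, got {X.shape[1]}")
        z = self.intercept + X @ self.coef
        return _sigmoid(z)


def logistic_probability(x: np.ndarray, model: LogisticModel) -> float:
    """Probability of the positive class for a single feature vector."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.coef.size:
        raise ValueError(
            f"dimension mismatch: {x.size} vs {model.coef.size}")
    return float(model.predict_proba(x[None, :])[0])


def _log_likelihood(z: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*z - log(1 + e^z), computed stably
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> LogisticModel:
    """Newton-Raphson fit of a binary logistic model.

    The update is beta <- beta - G^{-1} grad with G the Hessian of the
    negative log-likelihood; a ridge term (doubling from 1e-8) is added
    when G is singular, and steps that would decrease the log-likelihood
    are halved. Parameter norms exceeding a cap flag non-convergence
    (complete separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, q = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary {0, 1}")
    if q >= n:
        raise ValueError(
            f"need fewer features than samples (q={q} >= N={n})")
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(q + 1)
    z = Xd @ beta
    ll = _log_likelihood(z, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(z)
        grad = Xd.T @ (y - p)
        w = p * (1.0 - p)
        G = Xd.T @ (Xd * w[:, None])
        ridge = 0.0
        while True:
            try:
                step = np.linalg.solve(
                    G + ridge * np.eye(q + 1), grad)
                break
            except np.linalg.LinAlgError:
                ridge = 1e-8 if ridge == 0.0 else ridge * 2.0
        # halve the step until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            z_cand = Xd @ cand
            ll_cand = _log_likelihood(z_cand, y)
            if ll_cand >= ll - 1e-12:
                break
            scale *= 0.5
        beta, z, ll = cand, z_cand, ll_cand
        if np.linalg.norm(beta) > _BETA_CAP:
            return LogisticModel(float(beta[0]), beta[1:].copy(), it, False)
        if np.linalg.norm(scale * step) < tol:
            converged = True
            break
    # complete separation: fitted probabilities saturate onto the labels,
    # so no finite maximum-likelihood estimate exists
    p_final = _sigmoid(z)
    if np.all(np.abs(p_final - y) < 1e-8):
        converged = False
    return LogisticModel(float(beta[0]), beta[1:].copy(), it, converged)


@dataclass
class SubspaceLogisticEnsemble:
    """Logistic models over a random near-equal partition of the features;
    the ensemble probability is the member mean."""

    subspaces: list          # list of index arrays
    models: list             # parallel list of LogisticModel

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        probs = [
            m.predict_proba(X[:, idx])
            for idx, m in zip(self.subspaces, self.models)
        ]
        return np.mean(probs, axis=0)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def fit_logistic_subspace_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    n_subspaces: int = 3,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SubspaceLogisticEnsemble:
    """Partition the features at random into ``n_subspaces`` near-equal
    groups (sizes differ by at most one) and fit one binary logistic
    model per group."""
    X = np.asarray(X, dtype=float)
    q = X.shape[1]
    if n_subspaces < 1:
        raise ValueError("n_subspaces must be >= 1")
    if n_subspaces > q:
        raise ValueError("more subspaces than features")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(q)
    subspaces = [np.sort(part) for part in np.array_split(perm, n_subspaces)]
    models = [fit_logistic(X[:, idx], y, max_iter, tol) for idx in subspaces]
    return SubspaceLogisticEnsemble(subspaces, models)


# ---------------------------------------------------------------------------
# Gini machinery and decision trees
# ---------------------------------------------------------------------------

def gini_impurity(class_counts: Sequence[float]) -> float:
    """j(s) = 1 - sum_i (N_i / N)^2 over class proportions."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero class counts")
    e = counts / total
    return float(1.0 - np.sum(e ** 2))


def impurity_decrease(
    parent_counts: Sequence[float],
    left_counts: Sequence[float],
    right_counts: Sequence[float],
) -> float:
    """delta j(s) = j(s) - e_q * j(s_q) - e_p * j(s_p), with e_q, e_p the
    child sample fractions."""
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.allclose(left + right, parent):
        raise ValueError("child counts must sum to parent counts")
    n = parent.sum()
    nl, nr = left.sum(), right.sum()
    val = gini_impurity(parent)
    if nl > 0:
        val -= (nl / n) * gini_impurity(left)
    if nr > 0:
        val -= (nr / n) * gini_impurity(right)
    return float(val)


@dataclass
class TreeNode:
    """One node of a classification tree; internal nodes carry the split,
    leaves carry the class decision."""

    counts: np.ndarray
    impurity: float
    n_samples: int
    feature: Optional[int] = None
    threshold: Optional[float] = None
    decrease: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def leaf_class(self) -> int:
        return int(np.argmax(self.counts))  # tie -> smallest class index


def _best_split(X, y_codes, n_classes, feature_subset, min_leaf):
    """Exhaustive midpoint-threshold search over the candidate features.

    Returns (feature, threshold, decrease) or None. Ties in the impurity
    decrease break to the lowest feature index, then lowest threshold
    (guaranteed by ascending scan order with strict improvement).
    """
    n = X.shape[0]
    parent_counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    parent_gini = 1.0 - np.sum((parent_counts / n) ** 2)
    best = None
    best_dec = 1e-12  # require a strictly positive decrease
    for f in sorted(feature_subset):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), y_codes[order]] = 1.0
        cum = np.cumsum(onehot, axis=0)
        # split after position i (left = first i+1 samples)
        pos = np.flatnonzero(xs[:-1] < xs[1:])
        if pos.size == 0:
            continue
        nl = (pos + 1).astype(float)
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        if not ok.any():
            continue
        pos = pos[ok]
        nl, nr = nl[ok], nr[ok]
        left = cum[pos]
        right = parent_counts[None, :] - left
        gl = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gr = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        dec = parent_gini - (nl / n) * gl - (nr / n) * gr
        i = int(np.argmax(dec))
        if dec[i] > best_dec:
            best_dec = float(dec[i])
            thr = 0.5 * (xs[pos[i]] + xs[pos[i] + 1])
            best = (f, float(thr), best_dec)
    return best


def _grow(X, y_codes, n_classes, rng, m_try, max_depth, min_leaf, depth):
    n = X.shape[0]
    counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    node = TreeNode(
        counts=counts,
        impurity=gini_impurity(counts),
        n_samples=n,
    )
    if (max_depth is not None and depth >= max_depth) \
            or n < 2 * min_leaf or node.impurity == 0.0:
        return node
    p = X.shape[1]
    subset = rng.choice(p, size=min(m_try, p), replace=False)
    split = _best_split(X, y_codes, n_classes, subset, min_leaf)
    if split is None:
        return node
    f, thr, dec = split
    mask = X[:, f] <= thr
    node.feature, node.threshold, node.decrease = f, thr, dec
    node.left = _grow(X[mask], y_codes[mask], n_classes, rng,
                      m_try, max_depth, min_leaf, depth + 1)
    node.right = _grow(X[~mask], y_codes[~mask], n_classes, rng,
                       m_try, max_depth, min_leaf, depth + 1)
    return node


@dataclass
class DecisionTree:
    root: TreeNode
    n_classes: int

    def predict_one(self, x: np.ndarray) -> int:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.leaf_class

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.predict_one(x) for x in X], dtype=int)

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.left)
                stack.append(node.right)


@dataclass
class Forest:
    trees: list
    tree_seeds: list
    classes: np.ndarray
    n_features: int

    def __len__(self):
        return len(self.trees)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 15,
    m_try: Optional[int] = None,
    max_depth: Optional[int] = None,
    min_leaf: int = 1,
    seed: int = 0,
) -> Forest:
    """Grow ``n_trees`` trees on bootstrap resamples; at each node an
    exhaustive threshold search over ``m_try`` random features (default
    sqrt of the feature count) maximizes the Gini impurity decrease."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if n_trees < 1:
        raise ValueError("need at least one tree")
    classes = np.unique(y)
    code = {c: k for k, c in enumerate(classes)}
    y_codes = np.array([code[v] for v in y], dtype=int)
    p = X.shape[1]
    if m_try is None:
        m_try = max(1, int(np.sqrt(p)))
    ss = np.random.SeedSequence(seed)
    tree_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_trees)]
    trees = []
    n = X.shape[0]
    for ts in tree_seeds:
        rng = np.random.default_rng(ts)
        boot = rng.integers(0, n, size=n)
        root = _grow(X[boot], y_codes[boot], len(classes), rng,
                     m_try, max_depth, min_leaf, depth=0)
        trees.append(DecisionTree(root, len(classes)))
    return Forest(trees, tree_seeds, classes, p)


def predict_forest(forest: Forest, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over trees. Returns (labels, vote-fraction
    probabilities); vote ties break to the smallest class index."""
    X = np.asarray(X, dtype=float)
    votes = np.stack([t.predict(X) for t in forest.trees])  # trees x n
    n_classes = len(forest.classes)
    n = X.shape[0]
    proba = np.zeros((n, n_classes))
    for k in range(n_classes):
        proba[:, k] = (votes == k).mean(axis=0)
    labels_idx = np.argmax(proba, axis=1)  # argmax takes smallest on ties
    return forest.classes[labels_idx], proba


def gini_importance(forest: Forest) -> np.ndarray:
    """Per-feature Gini importance: sum over trees and over nodes
    splitting on the feature of (node sample fraction) * impurity
    decrease."""
    imp = np.zeros(forest.n_features)
    for tree in forest.trees:
        n_root = tree.root.n_samples
        for node in tree.nodes():
            if not node.is_leaf:
                imp[node.feature] += (node.n_samples / n_root) * node.decrease
    return imp


# ---------------------------------------------------------------------------
# Hybrid fusion
# ---------------------------------------------------------------------------

@dataclass
class HybridModel:
    """Fitted logistic ensemble + forest with the fusion policy."""

    lr: object                       # per-class SubspaceLogisticEnsemble list
    rf: Forest
    classes: np.ndarray
    class_names: Optional[list] = None
    mode: str = "average"            # or "majority"
    base_weights: tuple = (0.5, 0.5)
    context_weight_map: dict = field(default_factory=lambda: {
        "cancer": (0.3, 0.7),        # forest weighted more heavily
    })
    decision_threshold: float = 0.5

    def weights_for(self, context: Optional[str]) -> tuple:
        w = self.context_weight_map.get(context, self.base_weights) \
            if context is not None else self.base_weights
        total = w[0] + w[1]
        if total <= 0:
            raise ValueError("weights must have positive sum")
        return (w[0] / total, w[1] / total)

    def name_of(self, class_index: int) -> Optional[str]:
        if self.class_names is None:
            return None
        return self.class_names[class_index]


def combine_hybrid(
    lr_proba: np.ndarray,
    rf_proba: np.ndarray,
    model: HybridModel,
    context: Optional[str] = None,
) -> tuple[int, np.ndarray]:
    """Fuse one record's class-probability vectors from the two models.

    ``average`` mode returns the weighted mean with context-adjusted
    weights. ``majority`` mode lets each model vote its argmax; agreement
    wins, disagreement is resolved by the higher-weighted model (equal
    weights fall back to the averaging rule). When no explicit context is
    given, the candidate class of the base-weight average supplies it.
    Returns (class index, fused probability vector).
    """
    lr_proba = np.asarray(lr_proba, dtype=float)
    rf_proba = np.asarray(rf_proba, dtype=float)
    if lr_proba.shape != rf_proba.shape:
        raise ValueError("probability vectors must share classes")
    for v in (lr_proba, rf_proba):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("probability vector does not sum to 1")
    if context is None:
        prelim = (model.base_weights[0] * lr_proba
                  + model.base_weights[1] * rf_proba)
        context = model.name_of(int(np.argmax(prelim)))
    w_lr, w_rf = model.weights_for(context)
    fused = w_lr * lr_proba + w_rf * rf_proba
    if model.mode == "average":
        if fused.size == 2:
            label = int(fused[1] >= model.decision_threshold)
        else:
            label = int(np.argmax(fused))
        return label, fused
    if model.mode != "majority":
        raise ValueError(f"unknown mode {model.mode!r}")
    lr_vote = int(np.argmax(lr_proba))
    rf_vote = int(np.argmax(rf_proba))
    if lr_vote == rf_vote:
        return lr_vote, fused
    if w_lr > w_rf:
        return lr_vote, fused
    if w_rf > w_lr:
        return rf_vote, fused
    # equal weights: two-voter majority undefined; averaging fallback
    return int(np.argmax(fused)), fused


class LogisticForestClassifier:
    """scikit-learn style hybrid classifier: subspace logistic ensemble
    (one-vs-rest for multi-class) fused with a Gini random forest.

    Parameters
    ----------
    n_subspaces : feature groups for the logistic ensemble.
    n_trees, m_try, max_depth, min_leaf : forest shape.
    mode : "average" (weighted probability mean) or "majority".
    base_weights : (w_lr, w_rf) used when no context rule fires.
    context_weight_map : context key -> weight pair overrides.
    class_names : optional names aligned with the sorted class labels,
        used to key the context map from the candidate prediction.
    """

    def __init__(self, n_subspaces=3, n_trees=15, m_try=None,
                 max_depth=None, min_leaf=1, mode="average",
                 base_weights=(0.5, 0.5), context_weight_map=None,
                 decision_threshold=0.5, class_names=None,
                 max_iter=50, tol=1e-6, seed=0):
        self.n_subspaces = n_subspaces
        self.n_trees = n_trees
        self.m_try = m_try
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.mode = mode
        self.base_weights = base_weights
        self.context_weight_map = context_weight_map
        self.decision_threshold = decision_threshold
        self.class_names = class_names
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        n, q = X.shape
        # the subspace partition exists to uphold q < N per member model;
        # raise the partition count when features outnumber samples
        min_sub = int(np.ceil(q / max(n - 1, 1)))
        n_sub = min(max(self.n_subspaces, min_sub), q)
        self.lr_ensembles_ = []
        for c in self.classes_:
            yc = (y == c).astype(float)
            self.lr_ensembles_.append(fit_logistic_subspace_ensemble(
                X, yc, n_subspaces=n_sub, seed=self.seed,
                max_iter=self.max_iter, tol=self.tol))
        self.forest_ = fit_forest(
            X, y, n_trees=self.n_trees, m_try=self.m_try,
            max_depth=self.max_depth, min_leaf=self.min_leaf,
            seed=self.seed)
        cmap = self.context_weight_map
        self.model_ = HybridModel(
            lr=self.lr_ensembles_,
            rf=self.forest_,
            classes=self.classes_,
            class_names=self.class_names,
            mode=self.mode,
            base_weights=tuple(self.base_weights),
            context_weight_map=dict(cmap) if cmap is not None
            else {"cancer": (0.3, 0.7)},
            decision_threshold=self.decision_threshold,
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("LogisticForestClassifier is not fitted")

    def lr_proba(self, X) -> np.ndarray:
        """One-vs-rest logistic scores renormalized to sum to 1."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        scores = np.column_stack(
            [ens.predict_proba(X) for ens in self.lr_ensembles_])
        totals = scores.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return scores / totals

    def rf_proba(self, X) -> np.ndarray:
        self._check_fitted()
        _, proba = predict_forest(self.forest_, np.asarray(X, dtype=float))
        return proba

    def predict_proba(self, X, contexts=None) -> np.ndarray:
        self._check_fitted()
        lrp = self.lr_proba(X)
        rfp = self.rf_proba(X)
        fused = np.zeros_like(lrp)
        for i in range(lrp.shape[0]):
            ctx = contexts[i] if contexts is not None else None
            _, fused[i] = combine_hybrid(lrp[i], rfp[i], self.model_, ctx)
        return fused

    def predict(self, X, contexts=None) -> np.ndarray:
        self._check_fitted()
        lrp = self.lr_proba(X)
        rfp = self.rf_proba(X)
        out = np.empty(lrp.shape[0], dtype=self.classes_.dtype)
        for i in range(lrp.shape[0]):
            ctx = contexts[i] if contexts is not None else None
            label, _ = combine_hybrid(lrp[i], rfp[i], self.model_, ctx)
            out[i] = self.classes_[label]
        return out

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def feature_importances_(self) -> np.ndarray:
        self._check_fitted()
        return gini_importance(self.forest_)

    def to_json(self) -> str:
        """Serialize the fitted parameters (logistic coefficients, fusion
        policy, forest shape) for round-tripping reports."""
        self._check_fitted()
        payload = {
            "classes": self.classes_.tolist(),
            "class_names": self.class_names,
            "mode": self.mode,
            "base_weights": list(self.model_.base_weights),
            "context_weight_map": {
                k: list(v) for k, v in self.model_.context_weight_map.items()
            },
            "decision_threshold": self.decision_threshold,
            "n_trees": len(self.forest_),
            "tree_seeds": self.forest_.tree_seeds,
            "logistic": [
                {
                    "subspaces": [idx.tolist() for idx in ens.subspaces],
                    "intercepts": [m.intercept for m in ens.models],
                    "coefs": [m.coef.tolist() for m in ens.models],
                }
                for ens in self.lr_ensembles_
            ],
        }
        return json.dumps(payload, indent=2)

    def get_params(self, deep=True):
        return {
            "n_subspaces": self.n_subspaces, "n_trees": self.n_trees,
            "m_try": self.m_try, "max_depth": self.max_depth,
            "min_leaf": self.min_leaf, "mode": self.mode,
            "base_weights": self.base_weights,
            "context_weight_map": self.context_weight_map,
            "decision_threshold": self.decision_threshold,
            "class_names": self.class_names,
            "max_iter": self.max_iter, "tol": self.tol, "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
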