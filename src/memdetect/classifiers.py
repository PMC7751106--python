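"""Base learners: fused majority-vote KNN, evidential KNN, and adapters.

The evidential k-nearest-neighbor classifier treats each neighbor as a piece
of Dempster-Shafer evidence: a neighbor of class *c* at distance *d*
contributes a simple support function with mass

    m({c}) = alpha0 * exp(-gamma_c * d^2),      m(frame) = 1 - m({c}),

and the K mass functions are pooled by Dempster's rule of combination.  The
query is assigned the class with the larger pignistic probability.  Both the
plain and the evidential KNN are also used in fused form: ten sub-classifiers
with K = 1..10 vote by majority, which is less sensitive to the choice of K
than any single setting.

SVM (RBF kernel), gradient boosting, and random forest are wrapped as thin
adapters around scikit-learn with an optional accuracy-driven grid search.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import ParameterGrid, cross_val_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .encoders import PsePSSMEncoder
from .seqio import LabeledDataset

Algorithm = Literal["KNN", "OETKNN", "SVM", "GBM", "RF"]


@dataclasses.dataclass(frozen=True)
class EvidentialParams:
    """Kernel parameters of the evidential KNN mass functions.

    ``alpha0`` bounds the support a single neighbor can lend its class;
    ``gamma`` holds one positive distance-kernel scale per class (class label
    -> scale).  When ``gamma`` is None a per-class heuristic is fitted:
    gamma_c = 1 / mean squared distance among training members of class c.
    """

    alpha0: float = 0.95
    gamma: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha0 < 1:
            raise ValueError("alpha0 must be in (0, 1)")
        if self.gamma is not None and any(g <= 0 for g in self.gamma.values()):
            raise ValueError("gamma scales must be positive")


@dataclasses.dataclass(frozen=True)
class NeighborSet:
    """Ordered nearest neighbors of one query.

    Sorted by distance ascending; equal distances keep training-set order so
    every downstream tie rule is deterministic.
    """

    query_id: str
    neighbors: list[tuple[int, float, int]]  # (training index, distance, label)


def _validate_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1 (1 = membrane)")
    return y


class _NeighborBase(BaseEstimator, ClassifierMixin):
    """Shared fit/distance machinery for the neighbor-based classifiers."""

    def fit(self, X, y):  # noqa: N803
        X = np.asarray(X, dtype=float)
        y = _validate_binary(y)
        if len(X) == 0:
            raise ValueError("training set is empty")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.array([0, 1])
        self._post_fit()
        return self

    def _post_fit(self) -> None:
        pass

    def _neighbor_order(self, dist_row: np.ndarray) -> np.ndarray:
        # stable sort: distance ties resolve to the lower training index
        return np.argsort(dist_row, kind="stable")

    def _dist_to_train(self, X: np.ndarray) -> np.ndarray:
        return pairwise_distances(np.asarray(X, dtype=float), self.X_)

    def predict(self, X) -> np.ndarray:  # noqa: N803
        check_is_fitted(self, "X_")
        dist = self._dist_to_train(X)
        return np.array([self._predict_row(row)[0] for row in dist])

    def predict_score(self, X) -> np.ndarray:  # noqa: N803
        """Positive-class score in [0, 1] for each query."""
        check_is_fitted(self, "X_")
        dist = self._dist_to_train(X)
        return np.array([self._predict_row(row)[1] for row in dist])

    def predict_proba(self, X) -> np.ndarray:  # noqa: N803
        s = self.predict_score(X)
        return np.column_stack([1 - s, s])

    def loo_predict(self) -> tuple[np.ndarray, np.ndarray]:
        """Leave-one-out labels and scores over the training set.

        Implemented by masking the self-distance in a precomputed pairwise
        matrix; identical to refitting without the held-out sample because the
        learners are instance-based.
        """
        check_is_fitted(self, "X_")
        dist = pairwise_distances(self.X_)
        np.fill_diagonal(dist, np.inf)
        out = [self._predict_row(row) for row in dist]
        return np.array([o[0] for o in out]), np.array([o[1] for o in out])

    def _predict_row(self, dist_row: np.ndarray) -> tuple[int, float]:
        raise NotImplementedError


def _plain_knn_label(labels_sorted: np.ndarray, k: int) -> int:
    votes = labels_sorted[:k]
    pos = int(votes.sum())
    neg = k - pos
    if pos == neg:  # even K split: fall back to the nearest neighbor
        return int(labels_sorted[0])
    return int(pos > neg)


class MajorityVoteKNN(_NeighborBase):
    """Fusion of plain KNN classifiers with K = 1..k_max by majority vote.

    The score is the fraction of positive sub-votes; a split vote resolves to
    the K=1 (nearest neighbor) label.  K values above the training-set size
    are dropped.
    """

    def __init__(self, k_max: int = 10):
        self.k_max = k_max

    def _predict_row(self, dist_row: np.ndarray) -> tuple[int, float]:
        order = self._neighbor_order(dist_row)
        finite = order[np.isfinite(dist_row[order])]
        if len(finite) == 0:
            raise ValueError("no training neighbors available")
        labels_sorted = self.y_[finite]
        k_cap = min(self.k_max, len(finite))
        sub = [_plain_knn_label(labels_sorted, k) for k in range(1, k_cap + 1)]
        pos = sum(sub)
        score = pos / len(sub)
        if pos * 2 == len(sub):
            return int(sub[0]), score
        return int(pos * 2 > len(sub)), score


def dempster_binary_masses(
    alphas: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Combine simple support masses on a two-class frame by Dempster's rule.

    ``alphas[i]`` is the mass neighbor *i* puts on its own class
    ``labels[i]``; the remainder goes to the whole frame.  Returns the
    normalized combined masses (m_pos, m_neg, m_frame).
    """
    one_minus = 1.0 - np.asarray(alphas, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos_prod = float(np.prod(one_minus[labels == 1]))
    neg_prod = float(np.prod(one_minus[labels == 0]))
    u_pos = (1.0 - pos_prod) * neg_prod
    u_neg = (1.0 - neg_prod) * pos_prod
    u_frame = pos_prod * neg_prod
    norm = u_pos + u_neg + u_frame
    if norm == 0.0:  # total conflict; unreachable for alpha0 < 1
        return 0.5, 0.5, 0.0
    return u_pos / norm, u_neg / norm, u_frame / norm


class EvidentialKNN(_NeighborBase):
    """Evidence-theoretic KNN with a fixed neighborhood size K.

    The positive-class score is the pignistic probability
    BetP(pos) = m({pos}) + m(frame)/2; a score of exactly 0.5 resolves to the
    nearest neighbor's label.
    """

    def __init__(self, n_neighbors: int = 1, alpha0: float = 0.95, gamma=None):
        self.n_neighbors = n_neighbors
        self.alpha0 = alpha0
        self.gamma = gamma

    def _post_fit(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.n_neighbors > len(self.y_):
            raise ValueError(
                f"n_neighbors={self.n_neighbors} exceeds training size {len(self.y_)}"
            )
        EvidentialParams(alpha0=self.alpha0)  # range check
        if self.gamma is not None:
            self.gamma_ = dict(self.gamma)
        else:
            self.gamma_ = fit_gamma_heuristic(self.X_, self.y_)

    def _masses(self, dist_row: np.ndarray) -> tuple[float, float, float, int]:
        order = self._neighbor_order(dist_row)
        finite = order[np.isfinite(dist_row[order])]
        if len(finite) == 0:
            raise ValueError("no training neighbors available")
        k = min(self.n_neighbors, len(finite))
        nn = finite[:k]
        labels = self.y_[nn]
        d2 = dist_row[nn] ** 2
        gammas = np.array([self.gamma_[int(c)] for c in labels])
        alphas = self.alpha0 * np.exp(-gammas * d2)
        m_pos, m_neg, m_frame = dempster_binary_masses(alphas, labels)
        return m_pos, m_neg, m_frame, int(self.y_[finite[0]])

    def _predict_row(self, dist_row: np.ndarray) -> tuple[int, float]:
        m_pos, _, m_frame, nearest_label = self._masses(dist_row)
        betp = m_pos + m_frame / 2.0
        if betp == 0.5:
            return nearest_label, betp
        return int(betp > 0.5), betp


class FusedEvidentialKNN(_NeighborBase):
    """Majority vote over evidential KNN sub-classifiers with K = 1..k_max.

    Shares the fused-KNN contract: score = positive sub-vote fraction, split
    votes resolve to the K=1 evidential label.
    """

    def __init__(self, k_max: int = 10, alpha0: float = 0.95, gamma=None):
        self.k_max = k_max
        self.alpha0 = alpha0
        self.gamma = gamma

    def _post_fit(self) -> None:
        EvidentialParams(alpha0=self.alpha0)
        if self.gamma is not None:
            self.gamma_ = dict(self.gamma)
        else:
            self.gamma_ = fit_gamma_heuristic(self.X_, self.y_)

    def _sub_labels(self, dist_row: np.ndarray) -> list[int]:
        sub = []
        k_cap = min(self.k_max, int(np.isfinite(dist_row).sum()))
        member = EvidentialKNN(alpha0=self.alpha0)
        member.X_, member.y_, member.gamma_ = self.X_, self.y_, self.gamma_
        for k in range(1, k_cap + 1):
            member.n_neighbors = k
            sub.append(member._predict_row(dist_row)[0])
        return sub

    def _predict_row(self, dist_row: np.ndarray) -> tuple[int, float]:
        sub = self._sub_labels(dist_row)
        pos = sum(sub)
        score = pos / len(sub)
        if pos * 2 == len(sub):
            return int(sub[0]), score
        return int(pos * 2 > len(sub)), score


def fit_gamma_heuristic(X: np.ndarray, y: np.ndarray) -> dict[int, float]:
    """Per-class kernel scale: inverse mean squared within-class distance.

    Falls back to the pooled mean squared distance (or 1.0 on degenerate
    data) when a class has fewer than two members or zero spread.
    """
    dist2 = pairwise_distances(X) ** 2
    n = len(y)
    pooled = dist2[np.triu_indices(n, k=1)]
    pooled_mean = float(pooled.mean()) if len(pooled) else 0.0
    fallback = 1.0 / pooled_mean if pooled_mean > 0 else 1.0
    gamma: dict[int, float] = {}
    for c in (0, 1):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            gamma[c] = fallback
            continue
        sub = dist2[np.ix_(idx, idx)]
        mean_sq = float(sub[np.triu_indices(len(idx), k=1)].mean())
        gamma[c] = 1.0 / mean_sq if mean_sq > 0 else fallback
    return gamma


# ---------------------------------------------------------------------------
# spec-surface functions over the estimators


def knn_vote_predict(
    train_X, train_y, q, k_max: int = 10
) -> tuple[int, float]:
    """Fused-KNN prediction for a single query vector."""
    clf = MajorityVoteKNN(k_max=k_max).fit(train_X, train_y)
    q = np.asarray(q, dtype=float).reshape(1, -1)
    return int(clf.predict(q)[0]), float(clf.predict_score(q)[0])


def oetknn_predict(
    train_X, train_y, q, k: int, params: EvidentialParams | None = None
) -> tuple[int, float]:
    """Evidential-KNN prediction for a single query vector."""
    params = params or EvidentialParams()
    clf = EvidentialKNN(n_neighbors=k, alpha0=params.alpha0, gamma=params.gamma)
    clf.fit(train_X, train_y)
    q = np.asarray(q, dtype=float).reshape(1, -1)
    return int(clf.predict(q)[0]), float(clf.predict_score(q)[0])


def oetknn_fused_predict(
    train_X, train_y, q, k_max: int = 10, params: EvidentialParams | None = None
) -> tuple[int, float]:
    """Fused evidential-KNN prediction for a single query vector."""
    params = params or EvidentialParams()
    clf = FusedEvidentialKNN(k_max=k_max, alpha0=params.alpha0, gamma=params.gamma)
    clf.fit(train_X, train_y)
    q = np.asarray(q, dtype=float).reshape(1, -1)
    return int(clf.predict(q)[0]), float(clf.predict_score(q)[0])


_DEFAULT_GRIDS = {
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": [0.01, 0.1, 1.0]},
    "GBM": {"n_estimators": [50, 100], "max_depth": [2, 3]},
    "RF": {"max_features": [1, "sqrt", None]},
}


def _make_adapter(algorithm: str, seed: int = 0, **params):
    if algorithm == "SVM":
        return SVC(kernel="rbf", random_state=seed, **params)
    if algorithm == "GBM":
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=200, random_state=seed, **params)
    raise ValueError(f"unknown adapter algorithm {algorithm!r}")


@dataclasses.dataclass
class TrainedClassifier:
    """A fitted base classifier and the encoding context it was trained on."""

    algorithm: str
    encoding: str
    lam: int
    k: int | None
    model: BaseEstimator

    def predict(self, X) -> np.ndarray:  # noqa: N803
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)), dtype=int)

    def predict_score(self, X) -> np.ndarray:  # noqa: N803
        X = np.asarray(X, dtype=float)
        if hasattr(self.model, "predict_score"):
            return self.model.predict_score(X)
        if hasattr(self.model, "predict_proba"):
            return self.model.predict_proba(X)[:, 1]
        # margin squashed into (0, 1); monotone, so ROC-compatible
        return 1.0 / (1.0 + np.exp(-self.model.decision_function(X)))


def fit_adapter(
    algorithm: str,
    X,
    y,
    hyper_grid: dict | None = None,
    cv: int = 3,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit an off-the-shelf SVM/GBM/RF with an optional accuracy grid search.

    Ties in cross-validated accuracy resolve to the lexicographically
    smallest parameter combination, so the selection is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = _validate_binary(y)
    if len(np.unique(y)) < 2:
        raise ValueError("adapter training requires both classes present")
    grid = hyper_grid if hyper_grid is not None else {}
    if grid:
        best_params, best_acc = None, -np.inf
        for params in ParameterGrid(dict(sorted(grid.items()))):
            est = _make_adapter(algorithm, seed=seed, **params)
            acc = cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean()
            if acc > best_acc + 1e-12:
                best_acc, best_params = acc, params
        model = _make_adapter(algorithm, seed=seed, **best_params).fit(X, y)
    else:
        model = _make_adapter(algorithm, seed=seed).fit(X, y)
    return TrainedClassifier(algorithm, "PsePSSM", -1, None, model)


@dataclasses.dataclass
class ClassifierBank:
    """Ordered collection of trained classifiers indexed by (λ, K).

    ``per_k`` banks hold one evidential/plain KNN per (λ, K) pair (the V500
    layout); otherwise one fused classifier per λ (the V50 layout, or one
    adapter per λ for SVM/GBM/RF).
    """

    algorithm: str
    members: list[TrainedClassifier]

    @property
    def size(self) -> int:
        return len(self.members)

    def index(self) -> list[tuple[int, int | None]]:
        return [(m.lam, m.k) for m in self.members]


def make_bank_member(
    algorithm: str,
    lam: int,
    k: int | None,
    alpha0: float = 0.95,
    k_max: int = 10,
    seed: int = 0,
) -> TrainedClassifier:
    """Construct an unfitted bank member for (algorithm, λ, K)."""
    if algorithm == "OETKNN":
        model = (
            EvidentialKNN(n_neighbors=k, alpha0=alpha0)
            if k is not None
            else FusedEvidentialKNN(k_max=k_max, alpha0=alpha0)
        )
    elif algorithm == "KNN":
        if k is not None:
            from sklearn.neighbors import KNeighborsClassifier

            model = KNeighborsClassifier(n_neighbors=k)
        else:
            model = MajorityVoteKNN(k_max=k_max)
    elif algorithm in ("SVM", "GBM", "RF"):
        if k is not None:
            raise ValueError(f"{algorithm} banks are per-λ only")
        model = _make_adapter(algorithm, seed=seed)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return TrainedClassifier(algorithm, "PsePSSM", lam, k, model)


def bank_layout(
    algorithm: str, lambdas: Sequence[int], per_k: bool, k_max: int = 10
) -> list[tuple[int, int | None]]:
    """Enumerate the (λ, K) index of a bank in its canonical order."""
    if per_k:
        if algorithm not in ("OETKNN", "KNN"):
            raise ValueError("per-K banks exist only for KNN/OETKNN")
        return [(lam, k) for lam in lambdas for k in range(1, k_max + 1)]
    return [(lam, None) for lam in lambdas]


def train_classifier_bank(
    dataset: LabeledDataset,
    algorithm: str,
    lambdas: Sequence[int] = range(50),
    per_k: bool = False,
    alpha0: float = 0.95,
    k_max: int = 10,
    seed: int = 0,
) -> ClassifierBank:
    """Train one classifier per λ (or per (λ, K)) on Pse-PSSM features.

    The full-scale layouts are 50 members (λ = 0..49, fused) and 500 members
    (λ = 0..49 crossed with K = 1..10).
    """
    if not dataset.records:
        raise ValueError("dataset is empty")
    if dataset.profiles is None:
        raise ValueError("classifier banks require PSSM profiles")
    min_l = min(r.length for r in dataset.records)
    for lam in lambdas:
        if lam >= min_l:
            offender = min(dataset.records, key=lambda r: r.length)
            raise ValueError(
                f"lambda={lam} >= length {offender.length} of record "
                f"{offender.id!r}"
            )
    y = dataset.y()
    profiles = [dataset.profiles[r.id] for r in dataset.records]
    members = []
    features = {
        lam: PsePSSMEncoder(lam=lam).fit(profiles).transform(profiles)
        for lam in set(lambdas)
    }
    for lam, k in bank_layout(algorithm, lambdas, per_k, k_max):
        member = make_bank_member(algorithm, lam, k, alpha0, k_max, seed)
        member.model.fit(features[lam], y)
        members.append(member)
    return ClassifierBank(algorithm, members)
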