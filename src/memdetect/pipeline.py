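"""End-to-end membrane-detection pipeline.

``SelectiveVotingBank`` is the workhorse estimator: it fits a bank of
Pse-PSSM classifiers (one per λ, or per (λ, K)), builds the leave-one-out
vote matrix over the training set, ranks the constituent classifiers by
mRMR, selects the best-performing prefix, and predicts by majority vote over
the selected members.  ``TopologyIntegratedClassifier`` wraps a fitted bank
and folds in external transmembrane-topology calls through the weighted-vote
rule.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classifiers import ClassifierBank, make_bank_member, bank_layout
from .encoders import PsePSSMEncoder
from .ensembles import (
    RankedList,
    SelectionResult,
    all_vote,
    incremental_select,
    mrmr_rank,
    selective_vote,
)
from .evaluate import confusion, loocv, metrics
from .integrate import batch_integrate
from .seqio import LabeledDataset, ProfileMatrix, TopologyCall


def _lambda_features(
    profiles: Sequence[ProfileMatrix], lambdas: Sequence[int], center_only: bool = False
) -> dict[int, np.ndarray]:
    return {
        lam: PsePSSMEncoder(lam=lam, center_only=center_only)
        .fit(profiles)
        .transform(profiles)
        for lam in sorted(set(lambdas))
    }


def build_loocv_vote_matrix(
    profiles: Sequence[ProfileMatrix],
    y: np.ndarray,
    algorithm: str = "OETKNN",
    lambdas: Sequence[int] = range(10),
    per_k: bool = True,
    alpha0: float = 0.95,
    k_max: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int | None]]]:
    """Leave-one-out 0/1 votes of every bank member over the training set.

    Returns (n_samples x n_members matrix, member (λ, K) layout).  Neighbor
    members use the masked-distance fast path; adapters are refitted per
    fold.
    """
    y = np.asarray(y, dtype=int)
    layout = bank_layout(algorithm, lambdas, per_k, k_max)
    features = _lambda_features(profiles, [lam for lam, _ in layout])
    columns = []
    for lam, k in layout:
        member = make_bank_member(algorithm, lam, k, alpha0, k_max, seed)
        pred, _, _ = loocv(member.model, features[lam], y)
        columns.append(pred)
    return np.column_stack(columns), layout


class SelectiveVotingBank(BaseEstimator, ClassifierMixin):
    """Selective-voting ensemble over a Pse-PSSM classifier bank.

    Parameters
    ----------
    algorithm : {"OETKNN", "KNN", "SVM", "GBM", "RF"}
        Base learner family.  The per-(λ, K) layout exists for the two
        neighbor families only.
    lambdas : sequence of int
        Pse-PSSM λ values of the bank (full scale: 0..49).
    per_k : bool
        Cross λ with K = 1..k_max (the "V500" layout) instead of one fused
        classifier per λ (the "V50" layout).
    selective : bool
        Fuse only the mRMR-selected prefix; when False, all members vote.

    Fitted attributes (trailing underscore) include the LOOCV vote matrix,
    the mRMR ranking, the selection, and per-stage training metrics.
    """

    def __init__(
        self,
        algorithm: str = "OETKNN",
        lambdas: Sequence[int] = tuple(range(10)),
        per_k: bool = True,
        k_max: int = 10,
        alpha0: float = 0.95,
        selective: bool = True,
        seed: int = 0,
    ):
        self.algorithm = algorithm
        self.lambdas = lambdas
        self.per_k = per_k
        self.k_max = k_max
        self.alpha0 = alpha0
        self.selective = selective
        self.seed = seed

    def fit(self, X: Sequence[ProfileMatrix], y):  # noqa: N803
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array([0, 1])
        self.layout_ = bank_layout(self.algorithm, self.lambdas, self.per_k, self.k_max)
        self.vote_matrix_, _ = build_loocv_vote_matrix(
            X, y, self.algorithm, self.lambdas, self.per_k,
            self.alpha0, self.k_max, self.seed,
        )
        self.all_vote_labels_ = all_vote(self.vote_matrix_)
        self.all_vote_report_ = metrics(confusion(self.all_vote_labels_, y))
        if self.selective and self.vote_matrix_.shape[1] >= 2:
            self.ranking_: RankedList = mrmr_rank(self.vote_matrix_, y)
            self.selection_: SelectionResult = incremental_select(
                self.vote_matrix_, y, self.ranking_
            )
            self.loo_labels_ = selective_vote(self.vote_matrix_, self.selection_)
        else:
            self.ranking_ = RankedList(list(range(self.vote_matrix_.shape[1])), [])
            self.selection_ = SelectionResult(
                self.vote_matrix_.shape[1],
                list(range(self.vote_matrix_.shape[1])),
                float((self.all_vote_labels_ == y).mean()),
            )
            self.loo_labels_ = self.all_vote_labels_
        self.loo_report_ = metrics(confusion(self.loo_labels_, y))
        # train the selected members on the full training set for prediction
        features = _lambda_features(X, [lam for lam, _ in self.layout_])
        self.members_ = []
        for idx in self.selection_.member_indices:
            lam, k = self.layout_[idx]
            member = make_bank_member(
                self.algorithm, lam, k, self.alpha0, self.k_max, self.seed
            )
            member.model.fit(features[lam], y)
            self.members_.append(member)
        self.bank_ = ClassifierBank(self.algorithm, self.members_)
        return self

    def member_votes(self, X: Sequence[ProfileMatrix]) -> np.ndarray:  # noqa: N803
        """Votes of the selected members on new profiles (n x |S|)."""
        check_is_fitted(self, "members_")
        features = _lambda_features(X, [m.lam for m in self.members_])
        return np.column_stack(
            [m.predict(features[m.lam]) for m in self.members_]
        )

    def predict(self, X: Sequence[ProfileMatrix]) -> np.ndarray:  # noqa: N803
        return all_vote(self.member_votes(X))

    def predict_score(self, X: Sequence[ProfileMatrix]) -> np.ndarray:  # noqa: N803
        """Positive vote fraction over the selected members."""
        return self.member_votes(X).mean(axis=1)

    def loo_member_votes(self) -> np.ndarray:
        """Training-set LOOCV votes restricted to the selected members."""
        check_is_fitted(self, "vote_matrix_")
        return self.vote_matrix_[:, self.selection_.member_indices]


class TopologyIntegratedClassifier(BaseEstimator, ClassifierMixin):
    """Selective-voting bank fused with external topology calls.

    ``fit`` trains the underlying bank; ``predict`` accepts the profile list
    plus optional topology calls and applies the weighted-vote integration
    rule to each protein.
    """

    def __init__(self, bank: SelectiveVotingBank | None = None):
        self.bank = bank

    def fit(self, X: Sequence[ProfileMatrix], y):  # noqa: N803
        self.bank_ = self.bank if self.bank is not None else SelectiveVotingBank()
        if not hasattr(self.bank_, "members_"):
            self.bank_.fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict(
        self,
        X: Sequence[ProfileMatrix],  # noqa: N803
        topology: Sequence[TopologyCall] | None = None,
        ids: Sequence[str] | None = None,
    ) -> np.ndarray:
        check_is_fitted(self, "bank_")
        votes = self.bank_.member_votes(X)
        ensemble = all_vote(votes)
        if topology is None:
            return ensemble
        if ids is None:
            ids = [p.protein_id for p in X]
        final, _ = batch_integrate(ids, votes, ensemble, topology)
        return final


def run_loocv_pipeline(
    dataset: LabeledDataset,
    algorithm: str = "OETKNN",
    lambdas: Sequence[int] = range(10),
    per_k: bool = True,
    alpha0: float = 0.95,
    k_max: int = 10,
    topology: Sequence[TopologyCall] | None = None,
    seed: int = 0,
) -> dict:
    """Training-set LOOCV evaluation of all three pipeline stages.

    Returns a dict with the all-voting, selective-voting, and (when topology
    calls are given) integrated labels and metric reports, plus the ranking
    and selection artefacts.
    """
    if dataset.profiles is None:
        raise ValueError("pipeline requires PSSM profiles")
    y = dataset.y()
    profiles = [dataset.profiles[r.id] for r in dataset.records]
    bank = SelectiveVotingBank(
        algorithm=algorithm, lambdas=lambdas, per_k=per_k,
        alpha0=alpha0, k_max=k_max, seed=seed,
    ).fit(profiles, y)
    out = {
        "bank": bank,
        "all_vote_labels": bank.all_vote_labels_,
        "all_vote_report": bank.all_vote_report_,
        "selection": bank.selection_,
        "ranking": bank.ranking_,
        "selective_labels": bank.loo_labels_,
        "selective_report": bank.loo_report_,
    }
    if topology is not None:
        final, report = batch_integrate(
            dataset.ids,
            bank.loo_member_votes(),
            bank.loo_labels_,
            topology,
            truth=y,
        )
        out["integrated_labels"] = final
        out["integrated_report"] = report
    return out


__all__ = [
    "SelectiveVotingBank",
    "TopologyIntegratedClassifier",
    "build_loocv_vote_matrix",
    "run_loocv_pipeline",
]
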