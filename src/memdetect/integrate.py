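"""Weighted-vote integration of the selective ensemble with topology calls.

A transmembrane-topology predictor with near-perfect specificity (such as a
consensus tool) is a highly trustworthy source of *positive* evidence: when
it reports at least one transmembrane segment, that call is given weight
|S| - 1, where |S| is the number of selected constituent classifiers.  With
that weight the fused decision flips to positive exactly when at least one
constituent classifier also voted positive; a topology call with zero
segments carries no weight and never demotes the ensemble decision (topology
tools are blind to surface-bound membrane proteins, so their negatives are
uninformative).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .evaluate import MetricsReport, confusion, metrics
from .seqio import TopologyCall


@dataclasses.dataclass(frozen=True)
class IntegrationConfig:
    """Weighted-voting configuration.

    ``topology_weight`` defaults to (number of selected constituent
    classifiers - 1); with that weight the closed-form rule in
    :func:`integrate_decide` and explicit weighted counting coincide.
    """

    topology_weight: int
    require_agreement: bool = True

    def __post_init__(self) -> None:
        if self.topology_weight < 0:
            raise ValueError("topology_weight must be >= 0")


def integrate_decide(
    constituent_votes: Sequence[int],
    ensemble_label: int,
    topo: TopologyCall | None,
) -> int:
    """Combine one protein's ensemble decision with its topology call.

    The ensemble label flips to positive if and only if the topology call is
    membrane (>= 1 TMS) and at least one constituent classifier agrees; in
    every other case the ensemble label stands.
    """
    votes = np.asarray(constituent_votes, dtype=int)
    if votes.size == 0:
        raise ValueError("constituent vote list is empty")
    if topo is not None and topo.is_membrane and votes.any():
        return 1
    return int(ensemble_label)


def weighted_vote_decide(
    constituent_votes: Sequence[int],
    topo: TopologyCall | None,
    config: IntegrationConfig | None = None,
    tie_label: int | None = None,
) -> int:
    """Explicit weighted-count formulation of the integration rule.

    Positive votes are the constituent positives plus ``topology_weight``
    when the topology call is membrane; negatives are the constituent
    negatives.  With weight |S| - 1 this coincides with
    :func:`integrate_decide` whenever the ensemble label is the plain
    majority of the constituent votes (ties following ``tie_label``).
    """
    votes = np.asarray(constituent_votes, dtype=int)
    if votes.size == 0:
        raise ValueError("constituent vote list is empty")
    if config is None:
        config = IntegrationConfig(topology_weight=len(votes) - 1)
    pos = int(votes.sum())
    neg = len(votes) - pos
    if topo is not None and topo.is_membrane:
        pos += config.topology_weight
    if pos == neg:
        if tie_label is None:
            tie_label = int(votes[0])
        return tie_label
    return int(pos > neg)


def batch_integrate(
    ids: Sequence[str],
    constituent_votes: np.ndarray,
    ensemble_labels: Sequence[int],
    calls: Sequence[TopologyCall],
    truth: Sequence[int] | None = None,
) -> tuple[np.ndarray, MetricsReport | None]:
    """Apply the integration rule per protein; ids without a call keep the
    ensemble label.

    ``constituent_votes`` is the selected-subset vote matrix (rows align with
    ``ids``).  Returns final labels and, when truth is given, a metrics
    report.
    """
    votes = np.asarray(constituent_votes, dtype=int)
    ensemble_labels = np.asarray(ensemble_labels, dtype=int)
    if votes.shape[0] != len(ids) or len(ensemble_labels) != len(ids):
        raise ValueError("ids, votes and ensemble labels must align")
    by_id = {c.protein_id: c for c in calls}
    final = np.array(
        [
            integrate_decide(votes[i], ensemble_labels[i], by_id.get(pid))
            for i, pid in enumerate(ids)
        ]
    )
    report = None
    if truth is not None:
        report = metrics(confusion(final, np.asarray(truth, dtype=int)))
    return final, report
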