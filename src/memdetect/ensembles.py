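"""Vote fusion over classifier banks: *all voting* and *selective voting*.

*All voting* takes the majority over every constituent classifier's binary
vote.  *Selective voting* first ranks the constituent classifiers by a
minimum-redundancy maximum-relevance (mRMR) criterion — mutual information is
approximated from the Pearson correlation as MI = -1/2 ln(1 - rho^2) — then
runs incremental selection over ranked prefixes and fuses only the prefix
with the highest criterion accuracy.

Seven all-voting ensemble variants are defined over the Pse-PSSM banks:
SVM, GBM and RF (50 per-λ adapters each), KNN V50 and OET-KNN V50 (50 fused
per-λ classifiers), and KNN V500 and OET-KNN V500 (500 per-(λ, K)
classifiers).
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: The seven all-voting ensemble variants: (name, algorithm, per_K).
ALL_VOTING_VARIANTS: list[tuple[str, str, bool]] = [
    ("SVM", "SVM", False),
    ("GBM", "GBM", False),
    ("RF", "RF", False),
    ("KNN V50", "KNN", False),
    ("KNN V500", "KNN", True),
    ("OET-KNN V50", "OETKNN", False),
    ("OET-KNN V500", "OETKNN", True),
]

#: Cap applied to the MI approximation when |rho| = 1 (the formula diverges).
MI_CAP = -0.5 * np.log(1e-12)


@dataclasses.dataclass(frozen=True)
class RankedList:
    """mRMR ranking of vote-matrix columns.

    ``order`` is a complete permutation of column indices; ``scores`` holds
    the selection criterion value at each step (relevance for the first pick,
    the MID value afterwards).
    """

    order: list[int]
    scores: list[float]


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    """Outcome of incremental selection over ranked prefixes."""

    subset_size: int
    member_indices: list[int]
    criterion_accuracy: float


def _check_votes(vm: np.ndarray) -> np.ndarray:
    vm = np.asarray(vm)
    if vm.ndim != 2 or vm.shape[1] == 0:
        raise ValueError("vote matrix must be 2-D with at least one column")
    if not set(np.unique(vm)) <= {0, 1}:
        raise ValueError("vote matrix entries must be 0/1")
    return vm.astype(int)


def all_vote(vm: np.ndarray) -> np.ndarray:
    """Majority label per row; a split vote follows the first column.

    The first column is the bank's first-ranked member, so the tie rule stays
    data-driven rather than class-biased.
    """
    vm = _check_votes(vm)
    pos = vm.sum(axis=1)
    n_cols = vm.shape[1]
    labels = (2 * pos > n_cols).astype(int)
    tie = 2 * pos == n_cols
    labels[tie] = vm[tie, 0]
    return labels


def mi_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation-based mutual-information approximation -1/2 ln(1-rho^2).

    A zero-variance column carries no information and returns 0; |rho| = 1
    returns the finite cap so orderings stay well defined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    if a.size < 2:
        raise ValueError("columns must have length >= 2")
    if a.std() == 0 or b.std() == 0:
        return 0.0
    rho = np.corrcoef(a, b)[0, 1]
    rho2 = min(rho * rho, 1.0)
    if rho2 >= 1.0 - 1e-12:
        return float(MI_CAP)
    return float(-0.5 * np.log1p(-rho2))


#: Scores within this distance of the step maximum count as tied; ties
#: resolve to the lowest column index.  Shields the ordering from float
#: round-off when two columns carry mathematically identical information.
MRMR_TIE_TOL = 1e-12


def _argmax_lowest_index(values: np.ndarray, candidates: list[int]) -> int:
    best = max(values)
    for j, v in zip(candidates, values):
        if v >= best - MRMR_TIE_TOL:
            return j
    return candidates[int(np.argmax(values))]  # unreachable


def mrmr_rank(vm: np.ndarray, y: np.ndarray) -> RankedList:
    """Greedy mRMR ordering of vote columns under the MID scheme.

    The first column maximizes relevance MI(c, y); each later pick maximizes
    relevance minus mean redundancy with the already-selected columns.
    Criterion ties resolve to the lower column index.
    """
    vm = _check_votes(vm)
    n_cols = vm.shape[1]
    if n_cols < 2:
        raise ValueError("mRMR ranking needs at least two columns")
    y = np.asarray(y, dtype=float)
    relevance = np.array([mi_correlation(vm[:, j], y) for j in range(n_cols)])
    # pairwise redundancy, filled in as columns get selected
    redundancy = np.zeros((n_cols, n_cols))
    order: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_cols))

    first = _argmax_lowest_index(relevance, remaining)
    order.append(first)
    scores.append(float(relevance[first]))
    remaining.remove(first)
    for j in remaining:
        redundancy[first, j] = redundancy[j, first] = mi_correlation(
            vm[:, first], vm[:, j]
        )

    while remaining:
        mid = np.array(
            [relevance[j] - redundancy[order, j].mean() for j in remaining]
        )
        pick = _argmax_lowest_index(mid, remaining)
        scores.append(float(mid[remaining.index(pick)]))
        order.append(pick)
        remaining.remove(pick)
        for j in remaining:
            redundancy[pick, j] = redundancy[j, pick] = mi_correlation(
                vm[:, pick], vm[:, j]
            )
    return RankedList(order, scores)


def prefix_accuracies(
    vm: np.ndarray, y: np.ndarray, ranked: RankedList
) -> np.ndarray:
    """All-vote accuracy of every ranked prefix s_1..s_n."""
    vm = _check_votes(vm)
    y = np.asarray(y, dtype=int)
    accs = np.empty(len(ranked.order))
    for i in range(1, len(ranked.order) + 1):
        labels = all_vote(vm[:, ranked.order[:i]])
        accs[i - 1] = (labels == y).mean()
    return accs


def incremental_select(
    vm: np.ndarray, y: np.ndarray, ranked: RankedList
) -> SelectionResult:
    """Pick the ranked prefix with maximal all-vote accuracy.

    Accuracy ties resolve to the smallest prefix, favouring the leaner
    ensemble.
    """
    vm = _check_votes(vm)
    if sorted(ranked.order) != list(range(vm.shape[1])):
        raise ValueError("ranking must cover every vote-matrix column")
    accs = prefix_accuracies(vm, y, ranked)
    best = int(np.argmax(accs))  # argmax: first (smallest) prefix on ties
    return SelectionResult(best + 1, list(ranked.order[: best + 1]), float(accs[best]))


def selective_vote(vm: np.ndarray, sel: SelectionResult) -> np.ndarray:
    """All-vote restricted to the selected member columns."""
    vm = _check_votes(vm)
    if not sel.member_indices:
        raise ValueError("selection is empty")
    if max(sel.member_indices) >= vm.shape[1]:
        raise ValueError("selection indexes a missing column")
    return all_vote(vm[:, sel.member_indices])


def select_and_vote(
    vm: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, SelectionResult, RankedList]:
    """Full selective-voting pass: rank, select, fuse."""
    ranked = mrmr_rank(vm, y)
    sel = incremental_select(vm, y, ranked)
    return selective_vote(vm, sel), sel, ranked
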