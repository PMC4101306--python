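"""Co-training of graph-based semi-supervised members with pseudo-labels.

Several member classifiers — each a graph-SSL solver with its own
hyperparameters (neighbor count ``k``, smoothness tradeoff ``mu``, optionally
a feature subset) — repeatedly predict labels for the unlabeled rows.  Where
the members agree (unanimity by default), the prediction becomes a
pseudo-label, the labeled set grows, and the members resolve again on the
enlarged label vector.  The loop stops at the first iteration that adds no
pseudo-label, when no unlabeled rows remain, or at ``max_iter``.

Member similarity graphs depend only on the features, so each is built once
and reused across iterations; only the label vector changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .dataset import PatientTable, encode
from .exceptions import ContractError, ParameterError
from .graph import SimilarityGraph, SSLSolution, build_graph, predict_labels, solve_ssl

logger = logging.getLogger(__name__)

__all__ = [
    "MemberConfig",
    "SSLMember",
    "ScriptedMember",
    "CoTrainState",
    "IterationRecord",
    "agreement_pseudo_label",
    "cotrain",
    "final_scores",
]


@dataclass(frozen=True)
class MemberConfig:
    """Hyperparameters of one ensemble member."""

    member_id: str
    k: int
    mu: float
    feature_subset: Optional[tuple[str, ...]] = None


#: default two-member ensemble: a tight smooth graph and a wide stiff one
DEFAULT_MEMBERS = (
    MemberConfig("m1", k=7, mu=1.0),
    MemberConfig("m2", k=15, mu=0.01),
)


class SSLMember:
    """A graph-SSL classifier bound to one similarity graph.

    The graph is built once from the encoded table (restricted to
    ``feature_subset`` if the config names one) and reused for every solve.
    """

    def __init__(self, config: MemberConfig, table: PatientTable, alpha: Union[float, str] = "auto"):
        self.config = config
        enc = encode(table)
        if config.feature_subset:
            Z = enc.select_variables(config.feature_subset)
        else:
            Z = enc.Z
        self.graph: SimilarityGraph = build_graph(Z, k=config.k, alpha=alpha)

    @property
    def member_id(self) -> str:
        return self.config.member_id

    def solve(self, y: np.ndarray) -> SSLSolution:
        return solve_ssl(self.graph, y, mu=self.config.mu)

    def predict_unlabeled(self, y: np.ndarray, unlabeled_idx: np.ndarray, iteration: int):
        """Predicted labels and scores for the unlabeled rows."""
        sol = self.solve(y)
        labels = predict_labels(sol)
        return labels[unlabeled_idx], sol.f[unlabeled_idx]


class ScriptedMember:
    """A member whose per-iteration predictions are supplied up front.

    Useful for deterministic walkthroughs of the agreement mechanics: the
    ``script`` is a list (one entry per iteration) of ``{row_index: label}``
    mappings; rows absent from an entry abstain.  Iterations past the end of
    the script repeat its last entry.
    """

    def __init__(self, member_id: str, script: Sequence[Dict[int, int]]):
        if not script:
            raise ParameterError("script must contain at least one iteration")
        self.member_id = member_id
        self.script = [dict(s) for s in script]

    def predict_unlabeled(self, y: np.ndarray, unlabeled_idx: np.ndarray, iteration: int):
        entry = self.script[min(iteration - 1, len(self.script) - 1)]
        labels = np.array([entry.get(int(i), 0) for i in unlabeled_idx], dtype=np.int64)
        return labels, None


@dataclass
class IterationRecord:
    """Log of one co-training iteration."""

    iteration: int
    member_predictions: Dict[str, np.ndarray]
    pseudo_indices: np.ndarray
    pseudo_labels: np.ndarray
    remaining_unlabeled: int


@dataclass
class CoTrainState:
    """Final state of a co-training run."""

    y_current: np.ndarray
    pseudo_mask: np.ndarray
    iteration: int
    history: List[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def unlabeled_idx(self) -> np.ndarray:
        return np.flatnonzero(self.y_current == 0)


def agreement_pseudo_label(predictions: np.ndarray, rule: str = "unanimity") -> np.ndarray:
    """Combine member votes into pseudo-labels.

    ``predictions`` is ``m x nu`` over ``{-1, 0, +1}`` (0 = abstain).
    Unanimity assigns a label iff every member gives the same nonzero vote;
    majority requires a strict majority among nonzero votes with no tie.
    Unresolved points get 0 and stay unlabeled.
    """
    P = np.asarray(predictions, dtype=np.int64)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ParameterError("need a 2-D vote matrix with at least 2 members")
    if rule == "unanimity":
        first = P[0]
        same = np.all(P == first, axis=0)
        return np.where(same & (first != 0), first, 0)
    if rule == "majority":
        pos = np.sum(P == 1, axis=0)
        neg = np.sum(P == -1, axis=0)
        out = np.zeros(P.shape[1], dtype=np.int64)
        out[pos > P.shape[0] / 2] = 1
        out[neg > P.shape[0] / 2] = -1
        return out
    raise ParameterError(f"unknown agreement rule {rule!r}")


def _as_members(members, table: Optional[PatientTable]):
    """Accept MemberConfig lists (materialized to SSLMembers) or member objects."""
    members = list(members)
    if len(members) < 2:
        raise ParameterError("co-training needs at least 2 members")
    if all(isinstance(m, MemberConfig) for m in members):
        if len(set(members)) != len(members):
            raise ParameterError("member configs must be pairwise distinct")
        if table is None:
            raise ContractError("a PatientTable is required to build SSL members from configs")
        return [SSLMember(cfg, table) for cfg in members]
    return members


def cotrain(
    table: Optional[PatientTable],
    members,
    rule: str = "unanimity",
    max_iter: int = 100,
    tau: float = 0.0,
) -> CoTrainState:
    """Run the co-training loop until no pseudo-label is added.

    ``members`` is either a list of :class:`MemberConfig` (SSL members are
    built on ``table``) or a list of objects exposing ``predict_unlabeled``.
    ``tau`` is an optional confidence gate: a point is only eligible for a
    pseudo-label when every member's score magnitude is at least ``tau``
    (scoreless members, e.g. scripted ones, always pass the gate).

    Original labels are immutable; the unlabeled set never grows, so the
    loop terminates within ``nu + 1`` iterations regardless of ``max_iter``.
    """
    if max_iter <= 0:
        raise ParameterError(f"max_iter must be positive, got {max_iter}")
    if table is None:
        raise ContractError("cotrain requires a PatientTable")
    member_objs = _as_members(members, table)

    y = table.y.copy()
    if not np.any(y):
        logger.warning("no labeled rows: co-training returns the zero labeling")
    pseudo_mask = np.zeros(table.n, dtype=bool)
    history: List[IterationRecord] = []
    iteration = 0
    stop_reason = "no unlabeled rows" if table.nu == 0 else ""

    while table.nu > 0 and iteration < max_iter:
        unlabeled = np.flatnonzero(y == 0)
        if unlabeled.size == 0:
            stop_reason = "all rows labeled"
            break
        iteration += 1
        votes = np.zeros((len(member_objs), unlabeled.size), dtype=np.int64)
        confident = np.ones(unlabeled.size, dtype=bool)
        preds: Dict[str, np.ndarray] = {}
        for mi, member in enumerate(member_objs):
            labels, scores = member.predict_unlabeled(y, unlabeled, iteration)
            votes[mi] = labels
            preds[member.member_id] = labels.copy()
            if tau > 0 and scores is not None:
                confident &= np.abs(scores) >= tau
        pseudo = agreement_pseudo_label(votes, rule=rule)
        pseudo = np.where(confident, pseudo, 0)

        added = np.flatnonzero(pseudo != 0)
        y[unlabeled[added]] = pseudo[added]
        pseudo_mask[unlabeled[added]] = True
        remaining = int(np.count_nonzero(y == 0))
        history.append(
            IterationRecord(
                iteration=iteration,
                member_predictions=preds,
                pseudo_indices=unlabeled[added],
                pseudo_labels=pseudo[added],
                remaining_unlabeled=remaining,
            )
        )
        logger.info("co-training iteration %d: added %d pseudo-labels, %d unlabeled remain",
                    iteration, added.size, remaining)
        if added.size == 0:
            stop_reason = "no pseudo-labels added"
            break
        if remaining == 0:
            stop_reason = "all rows labeled"
            break
    else:
        if table.nu > 0:
            stop_reason = stop_reason or "max_iter reached"

    return CoTrainState(
        y_current=y,
        pseudo_mask=pseudo_mask,
        iteration=iteration,
        history=history,
        stop_reason=stop_reason or "converged",
    )


def final_scores(state: CoTrainState, members) -> np.ndarray:
    """Average of the members' score vectors from a final solve on ``y_current``.

    Used as the ranking score (e.g. for AUC).  Members must be solver-backed
    (``SSLMember`` or anything with a ``solve`` method).
    """
    fs = []
    for member in members:
        if not hasattr(member, "solve"):
            raise ContractError(f"member {getattr(member, 'member_id', member)!r} cannot produce scores")
        fs.append(member.solve(state.y_current).f)
    return np.mean(fs, axis=0)


def history_frame(state: CoTrainState):
    """Per-iteration summary as a DataFrame (iteration, added, remaining)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "iteration": [r.iteration for r in state.history],
            "pseudo_added": [len(r.pseudo_indices) for r in state.history],
            "remaining_unlabeled": [r.remaining_unlabeled for r in state.history],
        }
    )
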