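"""Vote recording and annotation-quality arithmetic.

Human annotators judge individual predication instances ("was this relation
correctly extracted from this sentence?") with outcome *correct*,
*not_correct* or *undecided*.  This module aggregates such votes three ways:

* :func:`vote_summary` — vote-level counts and integer percentages over
  decided votes.
* :func:`instance_summary` — per-instance outcome classes (always correct,
  at least once wrong, more correct than wrong, tied, ...), optionally
  restricted to instances judged by at least / exactly *k* distinct
  evaluators.
* :func:`agreement` — a simple inter-evaluator agreement ratio: among
  instances with exactly *k* evaluators, the fraction judged unanimously
  (all correct or all wrong).

Undecided votes are excluded from every percentage denominator and from
evaluator counts; percentages are integer percents, rounded half up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOMES",
    "EvaluationVote",
    "EvaluationLog",
    "VoteSummary",
    "InstanceSummary",
    "record_vote",
    "vote_summary",
    "instance_summary",
    "agreement",
    "int_percent",
]

OUTCOMES = ("correct", "not_correct", "undecided")


def int_percent(numerator: int, denominator: int) -> Optional[int]:
    """Integer percent, round half up; None when the denominator is zero."""
    if denominator == 0:
        return None
    return (200 * numerator + denominator) // (2 * denominator)


@dataclass(frozen=True)
class EvaluationVote:
    """One vote by one user on one predication instance."""

    user_id: str
    instance_id: str
    outcome: str  # "correct" | "not_correct" | "undecided"
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class EvaluationLog:
    """Collection of votes with one effective vote per (user, instance)."""

    _votes: dict[tuple[str, str], EvaluationVote] = field(default_factory=dict)

    def record(self, vote: EvaluationVote) -> None:
        key = (vote.user_id, vote.instance_id)
        if key in self._votes:
            logger.warning(
                "user %s re-voted on instance %s; keeping latest outcome %r",
                vote.user_id,
                vote.instance_id,
                vote.outcome,
            )
        self._votes[key] = vote

    def votes(self) -> list[EvaluationVote]:
        return list(self._votes.values())

    def __len__(self) -> int:
        return len(self._votes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvaluationLog):
            return NotImplemented
        return self._votes == other._votes

    def instance_ids(self) -> set[str]:
        return {iid for _, iid in self._votes}

    def by_instance(self) -> dict[str, list[EvaluationVote]]:
        out: dict[str, list[EvaluationVote]] = {}
        for vote in self._votes.values():
            out.setdefault(vote.instance_id, []).append(vote)
        return out


def record_vote(log: EvaluationLog, user: str, instance: str, outcome: str,
                timestamp: str = "") -> EvaluationLog:
    """Append a vote; a re-vote by the same (user, instance) replaces the old one."""
    log.record(EvaluationVote(user_id=user, instance_id=instance,
                              outcome=outcome, timestamp=timestamp))
    return log


@dataclass(frozen=True)
class VoteSummary:
    """Vote-level tallies; percentages over decided (correct/wrong) votes only."""

    n_votes_decided: int
    n_correct: int
    n_wrong: int
    n_undecided: int
    pct_correct: Optional[int]
    pct_wrong: Optional[int]


def vote_summary(log: EvaluationLog) -> VoteSummary:
    """Tally votes; integer percents of decided votes (round half up)."""
    n_correct = sum(1 for v in log.votes() if v.outcome == "correct")
    n_wrong = sum(1 for v in log.votes() if v.outcome == "not_correct")
    n_undecided = sum(1 for v in log.votes() if v.outcome == "undecided")
    decided = n_correct + n_wrong
    return VoteSummary(
        n_votes_decided=decided,
        n_correct=n_correct,
        n_wrong=n_wrong,
        n_undecided=n_undecided,
        pct_correct=int_percent(n_correct, decided),
        pct_wrong=int_percent(n_wrong, decided),
    )


@dataclass(frozen=True)
class InstanceSummary:
    """Per-instance outcome classes over a (possibly filtered) instance set.

    Partition laws: always_correct + always_wrong + mixed == n_instances and
    more_correct + more_wrong + tied == n_instances, where *mixed* means the
    instance received both outcomes.
    """

    n_instances: int
    at_least_once_correct: int
    at_least_once_wrong: int
    always_correct: int
    always_wrong: int
    more_correct_than_wrong: int
    more_wrong_than_correct: int
    tied: int
    pct_at_least_once_correct: Optional[int]
    pct_at_least_once_wrong: Optional[int]
    pct_always_correct: Optional[int]
    pct_always_wrong: Optional[int]
    pct_more_correct_than_wrong: Optional[int]
    pct_more_wrong_than_correct: Optional[int]
    pct_tied: Optional[int]


FilterKind = Literal["none", "at_least", "exactly"]


def _decided_by_instance(log: EvaluationLog) -> dict[str, list[str]]:
    """instance -> decided outcomes (one per distinct user with a decided vote)."""
    out: dict[str, list[str]] = {}
    for iid, votes in log.by_instance().items():
        decided = [v.outcome for v in votes if v.outcome != "undecided"]
        if decided:
            out[iid] = decided
    return out


def instance_summary(
    log: EvaluationLog, filter_kind: FilterKind = "none", k: int = 1
) -> InstanceSummary:
    """Classify instances by their decided-vote composition.

    ``filter_kind`` restricts to instances judged by at least / exactly
    ``k`` distinct evaluators (counting only users with a decided vote on
    the instance), applied *before* class computation; percentages are over
    the filtered instance count.
    """
    if filter_kind not in ("none", "at_least", "exactly"):
        raise ValueError(f"unknown filter kind {filter_kind!r}")
    if filter_kind != "none" and k < 1:
        raise ValueError("evaluator-count filter requires k >= 1")
    per_instance = _decided_by_instance(log)
    if filter_kind == "at_least":
        per_instance = {i: o for i, o in per_instance.items() if len(o) >= k}
    elif filter_kind == "exactly":
        per_instance = {i: o for i, o in per_instance.items() if len(o) == k}

    n = len(per_instance)
    once_c = once_w = all_c = all_w = more_c = more_w = tied = 0
    for outcomes in per_instance.values():
        c = sum(1 for o in outcomes if o == "correct")
        w = len(outcomes) - c
        once_c += c > 0
        once_w += w > 0
        all_c += w == 0
        all_w += c == 0
        if c > w:
            more_c += 1
        elif w > c:
            more_w += 1
        else:
            tied += 1
    return InstanceSummary(
        n_instances=n,
        at_least_once_correct=once_c,
        at_least_once_wrong=once_w,
        always_correct=all_c,
        always_wrong=all_w,
        more_correct_than_wrong=more_c,
        more_wrong_than_correct=more_w,
        tied=tied,
        pct_at_least_once_correct=int_percent(once_c, n),
        pct_at_least_once_wrong=int_percent(once_w, n),
        pct_always_correct=int_percent(all_c, n),
        pct_always_wrong=int_percent(all_w, n),
        pct_more_correct_than_wrong=int_percent(more_c, n),
        pct_more_wrong_than_correct=int_percent(more_w, n),
        pct_tied=int_percent(tied, n),
    )


def agreement(log: EvaluationLog, k: int) -> Optional[float]:
    """Unanimity ratio among instances with exactly ``k`` evaluators.

    The ratio of instances where all k decided votes agree (all correct or
    all wrong) to all instances with exactly k decided-vote evaluators.
    Returns None when no instance qualifies.  Requires ``k >= 2``.
    """
    if k < 2:
        raise ValueError("agreement requires k >= 2 evaluators")
    qualifying = [o for o in _decided_by_instance(log).values() if len(o) == k]
    if not qualifying:
        return None
    unanimous = sum(1 for outcomes in qualifying if len(set(outcomes)) == 1)
    return unanimous / len(qualifying)


def summary_dict(log: EvaluationLog) -> dict:
    """Full evaluation report as one JSON-serializable mapping."""
    vs = vote_summary(log)
    blocks: dict[str, object] = {
        "votes": vs.__dict__,
        "instances_all": instance_summary(log).__dict__,
        "instances_min2_evaluators": instance_summary(log, "at_least", 2).__dict__,
        "instances_exactly3_evaluators": instance_summary(log, "exactly", 3).__dict__,
    }
    for k in (2, 3):
        try:
            blocks[f"agreement_exactly{k}"] = agreement(log, k)
        except ValueError:  # pragma: no cover - k fixed >= 2
            pass
    return blocks


def votes_from_iterable(records: Iterable[tuple[str, str, str]]) -> EvaluationLog:
    """Build a log from (user, instance, outcome) triples."""
    log = EvaluationLog()
    for user, instance, outcome in records:
        record_vote(log, user, instance, outcome)
    return log
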