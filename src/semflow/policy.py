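"""Reinforcement-style policy bookkeeping over the knowledge space.

Every executed task leaves a policy record: success (state 1) links the
context to the workflow, the persisted solution location, and a reward of
exactly 1/n for each of the n services involved; failure (state 0) still
rewards the m steps that ran successfully with 1/m each, so partially
working services gain priority when alternatives are searched later.
Rewards use exact rational arithmetic so conservation holds bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .composer import Workflow
from .context import MatchLevel, TaskContext, context_from_statements, context_to_statements, match_contexts
from .executor import ExecutionTrace, Outcome, evaluate_outcome, execute
from .kg import KnowledgeSpace, Literal, Triple
from .registry import Registry


class NoPriorKnowledge(LookupError):
    """No transferable recorded solution exists for this context."""


@dataclass(frozen=True)
class PolicyRecord:
    record_id: str
    context_ref: str
    state: int  # 1 success, 0 failure
    solution_iloc: Optional[str]
    workflow: Optional[Workflow]
    solution_reward: Fraction
    step_rewards: tuple[tuple[str, Fraction], ...]

    def __post_init__(self) -> None:
        if self.state not in (0, 1):
            raise ValueError("state must be 0 or 1")
        if not 0 <= self.solution_reward <= 1:
            raise ValueError("solution reward must lie in [0, 1]")
        total = sum((r for _, r in self.step_rewards), Fraction(0))
        if self.state == 1:
            if self.solution_iloc is None and self.workflow is None:
                raise ValueError("success must register a solution")
            if total != 1:
                raise ValueError(f"success step rewards must sum to exactly 1, got {total}")
        else:
            if self.solution_iloc is not None:
                raise ValueError("failure registers no solution location")
            if total > 1:
                raise ValueError("failure step rewards must sum to at most 1")

    def reward_of(self, service: str) -> Fraction:
        return sum((r for s, r in self.step_rewards if s == service), Fraction(0))


def _frac_str(f: Fraction) -> str:
    return f"{f.numerator}/{f.denominator}"


def _parse_frac(text: str) -> Fraction:
    return Fraction(text)


def _next_record_id(space: KnowledgeSpace) -> str:
    existing = space.subjects("policies", prefix="pol:")
    seq = sum(1 for s in existing if "#" not in s)
    return f"pol:{seq:08d}"


def _record_to_triples(rec: PolicyRecord) -> list[Triple]:
    s = rec.record_id
    ts = [
        Triple(s, "rdf:type", "sf:Policy"),
        Triple(s, "hasContext", rec.context_ref),
        Triple(s, "hasState", Literal(rec.state, "number")),
        Triple(s, "hasSolutionReward", Literal(_frac_str(rec.solution_reward), "string")),
        Triple(
            s,
            "hasWorkflowSteps",
            Literal(json.dumps(list(rec.workflow.steps) if rec.workflow else []), "string"),
        ),
        Triple(
            s,
            "hasWorkflowKinds",
            Literal(json.dumps(list(rec.workflow.kinds) if rec.workflow else []), "string"),
        ),
    ]
    if rec.solution_iloc is not None:
        ts.append(Triple(s, "hasSolutionIloc", Literal(rec.solution_iloc, "string")))
    for i, (service, reward) in enumerate(rec.step_rewards):
        node = f"{s}#r{i}"
        ts += [
            Triple(s, "hasStepReward", node),
            Triple(node, "hasIndex", Literal(i, "number")),
            Triple(node, "hasService", Literal(service, "string")),
            Triple(node, "hasReward", Literal(_frac_str(reward), "string")),
        ]
    return ts


def _lit(space: KnowledgeSpace, subject: str, predicate: str) -> Optional[Literal]:
    hits = space.match("policies", subject=subject, predicate=predicate)
    if not hits:
        return None
    obj = hits[0].object
    return obj if isinstance(obj, Literal) else None


def record_from_triples(space: KnowledgeSpace, record_id: str) -> PolicyRecord:
    state = int(_lit(space, record_id, "hasState").value)
    steps = tuple(json.loads(str(_lit(space, record_id, "hasWorkflowSteps").value)))
    kinds = tuple(json.loads(str(_lit(space, record_id, "hasWorkflowKinds").value)))
    workflow = Workflow(steps, kinds) if steps else None
    iloc_lit = _lit(space, record_id, "hasSolutionIloc")
    reward_nodes = [
        str(t.object) for t in space.match("policies", subject=record_id, predicate="hasStepReward")
    ]
    def node_idx(node: str) -> int:
        return int(_lit(space, node, "hasIndex").value)
    rewards = []
    for node in sorted(reward_nodes, key=node_idx):
        rewards.append(
            (
                str(_lit(space, node, "hasService").value),
                _parse_frac(str(_lit(space, node, "hasReward").value)),
            )
        )
    ctx_hits = space.match("policies", subject=record_id, predicate="hasContext")
    return PolicyRecord(
        record_id=record_id,
        context_ref=str(ctx_hits[0].object),
        state=state,
        solution_iloc=str(iloc_lit.value) if iloc_lit else None,
        workflow=workflow,
        solution_reward=_parse_frac(str(_lit(space, record_id, "hasSolutionReward").value)),
        step_rewards=tuple(rewards),
    )


def all_records(space: KnowledgeSpace) -> list[PolicyRecord]:
    ids = [s for s in space.subjects("policies", prefix="pol:") if "#" not in s]
    return [record_from_triples(space, rid) for rid in sorted(ids)]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def record_outcome(
    space: KnowledgeSpace,
    ctx: TaskContext,
    trace: ExecutionTrace,
    outcome: Outcome,
    solution_reward: Optional[Fraction] = None,
) -> tuple[KnowledgeSpace, PolicyRecord]:
    """Write the policy for one executed task.

    Success with n steps: each step earns exactly 1/n (sum exactly 1).
    Failure with m >= 1 successfully invoked steps: each earns 1/m; with
    m = 0 the record carries an empty reward list.
    """
    if outcome.state == 1:
        n = len(trace.workflow.steps)
        rewards = tuple((s, Fraction(1, n)) for s in trace.workflow.steps)
        sol_reward = Fraction(1) if solution_reward is None else solution_reward
    else:
        survived = trace.succeeded_steps
        m = len(survived)
        rewards = tuple((s, Fraction(1, m)) for s in survived) if m else ()
        sol_reward = Fraction(0) if solution_reward is None else solution_reward

    rec = PolicyRecord(
        record_id=_next_record_id(space),
        context_ref=ctx.subject,
        state=outcome.state,
        solution_iloc=outcome.solution_iloc,
        workflow=trace.workflow if trace.workflow.steps else None,
        solution_reward=sol_reward,
        step_rewards=rewards,
    )
    space.add("contexts", context_to_statements(ctx))
    space.add("policies", _record_to_triples(rec))
    return space, rec


def record_planning_failure(
    space: KnowledgeSpace, ctx: TaskContext
) -> tuple[KnowledgeSpace, PolicyRecord]:
    """Failure policy for a task no chain could be planned for: state 0,
    no workflow, empty reward list — the recorded experience tells the
    administrators which capability is missing."""
    rec = PolicyRecord(
        record_id=_next_record_id(space),
        context_ref=ctx.subject,
        state=0,
        solution_iloc=None,
        workflow=None,
        solution_reward=Fraction(0),
        step_rewards=(),
    )
    space.add("contexts", context_to_statements(ctx))
    space.add("policies", _record_to_triples(rec))
    return space, rec


def lookup_policy(
    space: KnowledgeSpace, ctx: TaskContext
) -> list[tuple[PolicyRecord, MatchLevel]]:
    """All recorded policies whose stored context matches at EXACT or
    TRANSFERABLE level, best first: (level desc, solution reward desc,
    recency desc)."""
    hits = []
    for rec in all_records(space):
        try:
            stored = context_from_statements(space, rec.context_ref)
        except Exception:
            continue
        level = match_contexts(ctx, stored)
        if level > MatchLevel.NONE:
            hits.append((rec, level))
    # record ids are zero-padded sequence numbers, so lexicographic order is
    # chronological; stable two-pass sort yields recency desc within ties
    hits.sort(key=lambda item: item[0].record_id, reverse=True)
    hits.sort(key=lambda item: (-int(item[1]), -item[0].solution_reward))
    return hits


def service_priority(space: KnowledgeSpace, service_name: str) -> Fraction:
    """Cumulative reward a service has earned across every policy record."""
    return sum((rec.reward_of(service_name) for rec in all_records(space)), Fraction(0))


def service_priorities(space: KnowledgeSpace) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for rec in all_records(space):
        for service, reward in rec.step_rewards:
            out[service] = out.get(service, Fraction(0)) + reward
    return out


def transfer_solution(
    space: KnowledgeSpace,
    new_ctx: TaskContext,
    registry: Registry,
    payload: object,
    seed: int = 0,
    solution_store: Optional[str] = None,
    step_params: Optional[dict] = None,
) -> tuple[ExecutionTrace, PolicyRecord]:
    """Composition transfer: reuse the best transferable recorded workflow
    on a new dataset, retraining every stage; the planner is never invoked.
    A new policy record is written for the new context."""
    hits = [
        rec
        for rec, level in lookup_policy(space, new_ctx)
        if level == MatchLevel.TRANSFERABLE and rec.state == 1 and rec.workflow is not None
    ]
    if not hits:
        raise NoPriorKnowledge(
            "no transferable prior solution for this context; fall back to composition"
        )
    best = hits[0]
    trace = execute(best.workflow, payload, registry, seed=seed, step_params=step_params)
    outcome = evaluate_outcome(trace, new_ctx, solution_store)
    _, rec = record_outcome(space, new_ctx, trace, outcome)
    return trace, rec


def continuous_update(space: KnowledgeSpace) -> KnowledgeSpace:
    """Offline learning pass: for each distinct context, mark the preferred
    solution = the record with the highest solution reward (ties -> most
    recent). Idempotent."""
    old = space.match("policies", predicate="hasPreferredSolution")
    space.discard("policies", old)
    by_ctx: dict[str, PolicyRecord] = {}
    for rec in all_records(space):
        cur = by_ctx.get(rec.context_ref)
        if cur is None or (rec.solution_reward, rec.record_id) > (cur.solution_reward, cur.record_id):
            by_ctx[rec.context_ref] = rec
    for ctx_ref, rec in by_ctx.items():
        space.add("policies", [Triple(ctx_ref, "hasPreferredSolution", rec.record_id)])
    return space


def preferred_solutions(space: KnowledgeSpace) -> dict[str, str]:
    return {
        t.subject: str(t.object)
        for t in space.match("policies", predicate="hasPreferredSolution")
    }


def adjust_solution_reward(
    space: KnowledgeSpace, record_id: str, value: float
) -> KnowledgeSpace:
    """Human feedback hook: replace a record's solution reward with a
    clamped [0, 1] value (semantics of the number are user-defined)."""
    clamped = Fraction(min(max(float(value), 0.0), 1.0)).limit_denominator(10**6)
    old = space.match("policies", subject=record_id, predicate="hasSolutionReward")
    space.discard("policies", old)
    space.add(
        "policies",
        [Triple(record_id, "hasSolutionReward", Literal(_frac_str(clamped), "string"))],
    )
    return space
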