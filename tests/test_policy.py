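"""Reward rules, policy lookup, transfer, and offline re-ranking."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest

from semflow.composer import Workflow
from semflow.context import DatasetSignature, MatchLevel, TaskContext
from semflow.executor import ExecutionTrace, FAILED, Outcome, SKIPPED, SUCCEEDED, execute
from semflow.kg import KnowledgeSpace
from semflow.policy import (
    NoPriorKnowledge,
    all_records,
    continuous_update,
    lookup_policy,
    preferred_solutions,
    record_outcome,
    record_planning_failure,
    record_from_triples,
    service_priority,
    transfer_solution,
)
from semflow.synth import HEART_COLUMNS, make_parkinsonlike_table


def _ctx(columns=HEART_COLUMNS, domain="medical"):
    return TaskContext(
        "csv_path", domain, "optimized_model",
        DatasetSignature(100, len(columns), tuple(columns), "tabular"),
    )


def _workflow(steps):
    kinds = ["csv_path"] + [f"k{i}" for i in range(len(steps) - 1)] + ["optimized_model"]
    return Workflow(tuple(steps), tuple(kinds))


def _success_trace(steps, seed=0):
    w = _workflow(steps)
    return ExecutionTrace(w, [SUCCEEDED] * len(steps), None, object(), {"accuracy": 0.9}, seed=seed)


def _failure_trace(steps, fail_at):
    w = _workflow(steps)
    statuses = [SUCCEEDED] * fail_at + [FAILED] + [SKIPPED] * (len(steps) - fail_at - 1)
    return ExecutionTrace(w, statuses, fail_at, None, {})


class TestRewardRules:
    def test_four_step_success_rewards_quarter_each(self):
        space = KnowledgeSpace()
        _, rec = record_outcome(space, _ctx(), _success_trace(["a", "b", "c", "d"]),
                                Outcome(1, "loc", 0.9))
        assert all(r == Fraction(1, 4) for _, r in rec.step_rewards)
        assert sum(r for _, r in rec.step_rewards) == 1

    def test_failure_with_three_survivors_rewards_thirds(self):
        space = KnowledgeSpace()
        _, rec = record_outcome(space, _ctx(), _failure_trace(["a", "b", "c", "d"], 3),
                                Outcome(0, None, None))
        assert rec.state == 0
        assert [r for _, r in rec.step_rewards] == [Fraction(1, 3)] * 3
        assert rec.solution_iloc is None

    def test_failure_with_zero_survivors_has_no_rewards(self):
        space = KnowledgeSpace()
        _, rec = record_outcome(space, _ctx(), _failure_trace(["a", "b"], 0),
                                Outcome(0, None, None))
        assert rec.step_rewards == ()

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_reward_conservation(self, seed):
        rng = random.Random(seed)
        space = KnowledgeSpace()
        for i in range(40):
            n = rng.randrange(1, 9)
            steps = [f"s{i}_{j}" for j in range(n)]
            if rng.random() < 0.5:
                _, rec = record_outcome(space, _ctx(), _success_trace(steps),
                                        Outcome(1, "loc", 0.5))
                assert sum(r for _, r in rec.step_rewards) == 1
                assert all(r == Fraction(1, n) for _, r in rec.step_rewards)
            else:
                m = rng.randrange(0, n)
                _, rec = record_outcome(space, _ctx(), _failure_trace(steps, m),
                                        Outcome(0, None, None))
                assert all(r == Fraction(1, m) for _, r in rec.step_rewards)

    def test_record_round_trips_through_triples(self):
        space = KnowledgeSpace()
        _, rec = record_outcome(space, _ctx(), _success_trace(["a", "b", "c"]),
                                Outcome(1, "/tmp/somewhere", 0.8))
        assert record_from_triples(space, rec.record_id) == rec


class TestLookup:
    def test_empty_store_gives_empty_list(self):
        assert lookup_policy(KnowledgeSpace(), _ctx()) == []

    def test_exact_hit_after_success(self):
        space = KnowledgeSpace()
        record_outcome(space, _ctx(), _success_trace(["a", "b"]), Outcome(1, "loc", 0.9))
        hits = lookup_policy(space, _ctx())
        assert len(hits) == 1 and hits[0][1] is MatchLevel.EXACT

    def test_transferable_hit_for_different_schema(self):
        space = KnowledgeSpace()
        record_outcome(space, _ctx(), _success_trace(["a", "b"]), Outcome(1, "loc", 0.9))
        parkinson = _ctx(columns=tuple(make_parkinsonlike_table(50, 0)[0].frame.columns))
        hits = lookup_policy(space, parkinson)
        assert len(hits) == 1 and hits[0][1] is MatchLevel.TRANSFERABLE

    def test_unrelated_context_sees_nothing(self):
        space = KnowledgeSpace()
        record_outcome(space, _ctx(), _success_trace(["a", "b"]), Outcome(1, "loc", 0.9))
        other = TaskContext("counts_csv_path", "medical", "cluster_labels",
                            DatasetSignature(10, 0, (), "counts"))
        assert lookup_policy(space, other) == []


class TestServicePriority:
    def test_unrewarded_service_is_zero(self):
        assert service_priority(KnowledgeSpace(), "ghost") == 0

    def test_priority_accumulates_across_records(self):
        space = KnowledgeSpace()
        # one 4-step success (1/4) plus one failure where the service was
        # one of the 2 surviving steps (1/2) -> cumulative 3/4
        record_outcome(space, _ctx(), _success_trace(["x", "b", "c", "d"]),
                       Outcome(1, "loc", 0.9))
        record_outcome(space, _ctx(), _failure_trace(["x", "z", "w"], 2),
                       Outcome(0, None, None))
        assert service_priority(space, "x") == Fraction(3, 4)
        assert service_priority(space, "b") == Fraction(1, 4)


class TestTransfer:
    def test_transfer_reuses_recorded_workflow_without_planner(self, default_env, heart_csv, parkinson_csv):
        space, registry = default_env
        from semflow.context import build_context
        from semflow.services import svc_csv_load

        heart_ctx = build_context(
            {"input_kind": "csv_path", "domain": "medical",
             "desired_output_kind": "optimized_model"},
            svc_csv_load(str(heart_csv)),
        )
        workflow = Workflow(
            ("csv_loader", "data_split", "classification_pipeline", "rfecv_optimize"),
            ("csv_path", "labeled_table", "split_data", "classification_model", "optimized_model"),
        )
        trace = execute(workflow, str(heart_csv), registry, seed=3)
        from semflow.executor import evaluate_outcome
        record_outcome(space, heart_ctx, trace, evaluate_outcome(trace, heart_ctx))

        park_ctx = build_context(
            {"input_kind": "csv_path", "domain": "medical",
             "desired_output_kind": "optimized_model"},
            svc_csv_load(str(parkinson_csv)),
        )
        new_trace, new_rec = transfer_solution(space, park_ctx, registry,
                                               str(parkinson_csv), seed=5)
        assert new_trace.workflow.steps == workflow.steps
        assert new_rec.state == 1
        assert new_rec.context_ref == park_ctx.subject
        assert len(all_records(space)) == 2

    def test_no_transferable_hit_signals_no_prior_knowledge(self, default_env, parkinson_csv):
        space, registry = default_env
        park = _ctx(columns=("a", "b", "target"))
        with pytest.raises(NoPriorKnowledge):
            transfer_solution(space, park, registry, str(parkinson_csv), seed=0)

    def test_higher_reward_record_preferred(self):
        space = KnowledgeSpace()
        record_outcome(space, _ctx(), _success_trace(["a", "b"]),
                       Outcome(1, "loc1", 0.9), solution_reward=Fraction(1, 2))
        record_outcome(space, _ctx(), _success_trace(["c", "d"]),
                       Outcome(1, "loc2", 0.9), solution_reward=Fraction(1))
        parkinson = _ctx(columns=("p1", "p2", "target"))
        hits = [r for r, lvl in lookup_policy(space, parkinson)
                if lvl is MatchLevel.TRANSFERABLE and r.state == 1]
        assert hits[0].workflow.steps == ("c", "d")


class TestContinuousUpdate:
    def test_marker_lands_on_highest_reward(self):
        space = KnowledgeSpace()
        record_outcome(space, _ctx(), _success_trace(["a"]),
                       Outcome(1, "l1", 0.4), solution_reward=Fraction(2, 5))
        record_outcome(space, _ctx(), _success_trace(["b"]),
                       Outcome(1, "l2", 0.9), solution_reward=Fraction(9, 10))
        continuous_update(space)
        markers = preferred_solutions(space)
        assert markers[_ctx().subject] == "pol:00000001"

    def test_idempotence(self):
        space = KnowledgeSpace()
        record_outcome(space, _ctx(), _success_trace(["a"]), Outcome(1, "l", 0.5))
        record_outcome(space, _ctx(columns=("x", "target")), _success_trace(["b"]),
                       Outcome(1, "l2", 0.6))
        continuous_update(space)
        snapshot = {p: space.partition(p) for p in ("policies",)}
        continuous_update(space)
        assert {p: space.partition(p) for p in ("policies",)} == snapshot

    @pytest.mark.parametrize("seed", range(3))
    def test_markers_equal_brute_force_argmax(self, seed):
        rng = random.Random(seed)
        space = KnowledgeSpace()
        contexts = [_ctx(domain=f"d{i}") for i in range(3)]
        for i in range(12):
            ctx = rng.choice(contexts)
            record_outcome(space, ctx, _success_trace([f"s{i}"]),
                           Outcome(1, f"l{i}", 0.5),
                           solution_reward=Fraction(rng.randrange(1, 10), 10))
        continuous_update(space)
        markers = preferred_solutions(space)
        recs = all_records(space)
        for ctx_ref in {r.context_ref for r in recs}:
            best = max((r for r in recs if r.context_ref == ctx_ref),
                       key=lambda r: (r.solution_reward, r.record_id))
            assert markers[ctx_ref] == best.record_id


class TestPlanningFailure:
    def test_planning_failure_record_has_empty_rewards(self):
        space = KnowledgeSpace()
        _, rec = record_planning_failure(space, _ctx())
        assert rec.state == 0 and rec.workflow is None and rec.step_rewards == ()
        assert record_from_triples(space, rec.record_id) == rec
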