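"""Task orchestration: the request -> reasoning -> knowledge loop.

``run_task`` realizes the full provisioning cycle: build the task context,
search recorded policies (exact reuse or transfer first), otherwise plan
candidate workflows, execute them, evaluate and record every outcome, and
bank world facts such as selected feature subsets. The CLI is a thin layer
over this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import kg
from .composer import (
    Preference,
    Workflow,
    apply_preferences,
    compose,
    find_single_service,
    rank,
)
from .context import MatchLevel, TaskContext, build_context
from .executor import ExecutionTrace, Outcome, evaluate_outcome, execute
from .kg import KnowledgeSpace
from .policy import (
    NoPriorKnowledge,
    PolicyRecord,
    continuous_update,
    lookup_policy,
    record_outcome,
    record_planning_failure,
    transfer_solution,
)
from .registry import Registry
from .services import OptimizedModel, svc_csv_load, svc_feature_projection, svc_load_counts
from .world import FeatureSelectionFact, record_feature_fact, reuse_features

log_request = logging.getLogger("semflow.request")
log_reason = logging.getLogger("semflow.reasoning")
log_knowledge = logging.getLogger("semflow.knowledge")


@dataclass
class RunConfig:
    knowledge_store: Optional[str] = None
    solution_store: Optional[str] = None
    seed: int = 0
    max_depth: int = 8
    qc_percentile: float = 5.0
    cv_folds: int = 5
    top_k: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 <= self.qc_percentile < 100:
            raise ValueError("qc_percentile must lie in [0, 100)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


@dataclass
class RunReport:
    context: TaskContext
    route: str  # "exact" | "transfer" | "planned" | "planning_failure"
    planner_invocations: int
    candidates: list[Workflow]
    traces: list[ExecutionTrace]
    outcomes: list[Outcome]
    records: list[PolicyRecord]
    chosen: Optional[tuple[Workflow, Outcome]]
    feature_reuse: bool = False

    @property
    def success(self) -> bool:
        return self.chosen is not None


def load_payload_and_preview(input_kind: str, data_path: str):
    """Resolve the raw payload (a path, for path kinds) and a readable
    preview for signature derivation."""
    if input_kind == "csv_path":
        return data_path, svc_csv_load(data_path)
    if input_kind == "counts_csv_path":
        return data_path, svc_load_counts(data_path)
    raise ValueError(f"cannot load payload of kind {input_kind!r} from a file path")


def _step_params(request: Mapping, config: RunConfig) -> dict:
    params = {name: dict(p) for name, p in (request.get("params") or {}).items()}
    params.setdefault("counts_quality_control", {}).setdefault("qc_percentile", config.qc_percentile)
    params.setdefault("rfecv_optimize", {}).setdefault("cv_folds", config.cv_folds)
    return params


def _maybe_record_feature_fact(
    space: KnowledgeSpace, ctx: TaskContext, trace: ExecutionTrace, rec: PolicyRecord
) -> None:
    out = trace.final_output
    if isinstance(out, OptimizedModel) and not out.via_feature_reuse:
        fact = FeatureSelectionFact(
            schema_key=tuple(ctx.signature.column_names),
            selected_features=tuple(out.selected_features),
            source_policy=rec.record_id,
            metric=out.metrics.get("accuracy"),
        )
        record_feature_fact(space, fact)
        log_knowledge.info(
            "world fact: %d/%d features selected for schema of %d columns",
            len(fact.selected_features), len(fact.schema_key) - 1, len(fact.schema_key),
        )


def _reuse_overrides(
    space: KnowledgeSpace, ctx: TaskContext, workflow: Workflow
) -> Optional[dict]:
    """If world knowledge stores a feature subset for this exact schema and
    the workflow contains an optimizer stage (output kind optimized_model),
    swap that step for the projection service."""
    stored = reuse_features(space, ctx.signature)
    if stored is None:
        return None
    for i, kind in enumerate(workflow.kinds[1:]):
        if kind == "optimized_model":
            return {i: (svc_feature_projection, {"features": stored})}
    return None


def run_task(
    space: KnowledgeSpace,
    request: Mapping,
    data_path: Optional[str] = None,
    payload: object = None,
    preview: object = None,
    preferences: Optional[Preference] = None,
    config: Optional[RunConfig] = None,
    dry_run: bool = False,
) -> RunReport:
    """Execute the full task-provisioning cycle and grow the knowledge
    space. ``request`` needs input_kind / domain / desired_output_kind and
    may carry per-service ``params``."""
    config = config or RunConfig()
    registry = Registry(space)

    if payload is None:
        if data_path is None:
            raise ValueError("either a payload or a data path is required")
        payload, preview = load_payload_and_preview(request["input_kind"], data_path)
    elif preview is None:
        preview = payload

    ctx = build_context(request, preview)
    log_request.info("task context %s: %s -> %s (%s)", ctx.subject, ctx.input_kind,
                     ctx.desired_output_kind, ctx.domain)
    step_params = _step_params(request, config)

    hits = lookup_policy(space, ctx)
    exact = [r for r, lvl in hits if lvl == MatchLevel.EXACT and r.state == 1 and r.workflow]
    transferable = [r for r, lvl in hits if lvl == MatchLevel.TRANSFERABLE and r.state == 1 and r.workflow]

    # --- exact reuse: the recorded solution is loaded, no planning -------
    if exact and not dry_run:
        workflow = exact[0].workflow
        log_reason.info("exact context match %s: reusing recorded workflow, planner skipped",
                        exact[0].record_id)
        overrides = _reuse_overrides(space, ctx, workflow)
        trace = execute(workflow, payload, registry, seed=config.seed,
                        step_params=step_params, step_overrides=overrides)
        outcome = evaluate_outcome(trace, ctx, config.solution_store)
        _, rec = record_outcome(space, ctx, trace, outcome)
        if outcome.state == 1:
            _maybe_record_feature_fact(space, ctx, trace, rec)
        continuous_update(space)
        _persist(space, config)
        chosen = (workflow, outcome) if outcome.state == 1 else None
        return RunReport(ctx, "exact", 0, [workflow], [trace], [outcome], [rec], chosen,
                         feature_reuse=trace.feature_reuse)

    # --- transfer: adapt the best transferable recorded solution ---------
    if transferable and not dry_run:
        log_reason.info("transferable context match: composition transfer, planner skipped")
        trace, rec = transfer_solution(
            space, ctx, registry, payload, seed=config.seed,
            solution_store=config.solution_store, step_params=step_params,
        )
        outcome = Outcome(rec.state, rec.solution_iloc,
                          trace.metrics.get("accuracy") if rec.state else None)
        if rec.state == 1:
            _maybe_record_feature_fact(space, ctx, trace, rec)
        continuous_update(space)
        _persist(space, config)
        chosen = (trace.workflow, outcome) if rec.state == 1 else None
        return RunReport(ctx, "transfer", 0, [trace.workflow], [trace], [outcome], [rec], chosen,
                         feature_reuse=trace.feature_reuse)

    # --- plan: single service first, then composed chains ----------------
    singles = [
        Workflow((d.name,), (ctx.input_kind, ctx.desired_output_kind))
        for d in find_single_service(ctx, registry)
    ]
    chains = compose(ctx, registry, max_depth=config.max_depth)
    seen = set()
    candidates = []
    for w in rank(singles + chains, policy_store=space):
        if w.steps not in seen:
            seen.add(w.steps)
            candidates.append(w)
    if preferences is not None:
        candidates = apply_preferences(candidates, preferences, registry)
    log_reason.info("planner produced %d candidate workflow(s)", len(candidates))

    if not candidates:
        _, rec = record_planning_failure(space, ctx)
        log_knowledge.info("planning failure recorded as %s", rec.record_id)
        _persist(space, config)
        return RunReport(ctx, "planning_failure", 1, [], [], [], [rec], None)

    if dry_run:
        return RunReport(ctx, "planned", 1, candidates, [], [], [], None)

    to_run = candidates if config.top_k is None else candidates[: config.top_k]
    traces: list[ExecutionTrace] = []
    outcomes: list[Outcome] = []
    records: list[PolicyRecord] = []
    feature_reuse = False
    for workflow in to_run:
        overrides = _reuse_overrides(space, ctx, workflow)
        trace = execute(workflow, payload, registry, seed=config.seed,
                        step_params=step_params, step_overrides=overrides)
        outcome = evaluate_outcome(trace, ctx, config.solution_store)
        _, rec = record_outcome(space, ctx, trace, outcome)
        if outcome.state == 1:
            _maybe_record_feature_fact(space, ctx, trace, rec)
        feature_reuse = feature_reuse or trace.feature_reuse
        traces.append(trace)
        outcomes.append(outcome)
        records.append(rec)

    successes = [
        (w, o) for w, o, t in zip(to_run, outcomes, traces) if o.state == 1
    ]
    chosen = None
    if successes:
        chosen = max(
            successes,
            key=lambda item: (item[1].metric if item[1].metric is not None else float("-inf")),
        )
    continuous_update(space)
    _persist(space, config)
    return RunReport(ctx, "planned", 1, candidates, traces, outcomes, records, chosen,
                     feature_reuse=feature_reuse)


def _persist(space: KnowledgeSpace, config: RunConfig) -> None:
    if config.knowledge_store is None:
        return
    path = Path(config.knowledge_store)
    dialect = "turtle" if path.suffix in (".ttl", ".turtle") else "ntriples"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(kg.serialize(space, dialect))


def load_space(path: str) -> KnowledgeSpace:
    p = Path(path)
    if not p.exists():
        return KnowledgeSpace()
    dialect = "turtle" if p.suffix in (".ttl", ".turtle") else "ntriples"
    return kg.parse(p.read_text(), dialect)
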