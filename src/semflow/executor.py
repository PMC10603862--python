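"""Step-by-step workflow execution with faithful failure accounting.

A run never raises out of :func:`execute`: every step outcome is recorded
in an :class:`ExecutionTrace`, including exactly how far a failing run got
(succeeded steps, the failing index, skipped remainder). Successful final
artifacts can be persisted to a content-addressed solution store and
replayed on new data.
"""

from __future__ import annotations

import hashlib
import importlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

import joblib

from .composer import Workflow, validate_workflow
from .context import TaskContext
from .registry import Registry

SUCCEEDED = "succeeded"
FAILED = "failed"
SKIPPED = "skipped"


class InvokeError(ValueError):
    pass


def resolve_invoke_path(path: str) -> Callable:
    """``local:<module>:<function>`` resolves to an in-process callable.
    Remote URIs are stored in descriptors but refused at execution time."""
    if path.startswith(("http://", "https://")):
        raise InvokeError(
            f"remote invoke path {path!r} refused: only local invocation is supported"
        )
    if not path.startswith("local:"):
        raise InvokeError(f"unsupported invoke path {path!r}; expected 'local:module:function'")
    try:
        module_name, func_name = path[len("local:"):].rsplit(":", 1)
        module = importlib.import_module(module_name)
        return getattr(module, func_name)
    except (ValueError, ImportError, AttributeError) as exc:
        raise InvokeError(f"cannot resolve invoke path {path!r}: {exc}") from exc


@dataclass
class ExecutionTrace:
    workflow: Workflow
    step_status: list[str]
    failure_index: Optional[int]
    final_output: object
    metrics: dict
    error: Optional[str] = None
    step_notes: dict[int, str] = field(default_factory=dict)
    feature_reuse: bool = False
    seed: int = 0

    @property
    def succeeded_steps(self) -> list[str]:
        return [
            s
            for s, status in zip(self.workflow.steps, self.step_status)
            if status == SUCCEEDED
        ]

    @property
    def is_success(self) -> bool:
        return self.failure_index is None


def execute(
    workflow: Workflow,
    payload: object,
    registry: Registry,
    seed: int = 0,
    step_params: Optional[Mapping[str, Mapping]] = None,
    step_overrides: Optional[Mapping[int, tuple[Callable, Mapping]]] = None,
) -> ExecutionTrace:
    """Invoke each step in order, feeding each output to the next step.

    ``step_params`` maps service name -> keyword parameters. A
    ``step_overrides`` entry swaps the callable at one index (used for
    world-knowledge feature reuse); the trace notes the substitution.
    """
    # precondition: the chain must be structurally valid for the registry
    validate_workflow(workflow, registry, workflow.kinds[0], workflow.kinds[-1])

    statuses = [SKIPPED] * len(workflow.steps)
    notes: dict[int, str] = {}
    feature_reuse = False
    current = payload
    error = None
    failure_index: Optional[int] = None

    for i, step in enumerate(workflow.steps):
        params = dict((step_params or {}).get(step, {}))
        try:
            if step_overrides and i in step_overrides:
                fn, extra = step_overrides[i]
                params.update(extra)
                notes[i] = f"step {step!r} overridden by {fn.__name__}"
                feature_reuse = feature_reuse or fn.__name__ == "svc_feature_projection"
            else:
                fn = resolve_invoke_path(registry.get(step).invoke_path)
            current = fn(current, seed=seed, params=params)
            statuses[i] = SUCCEEDED
        except Exception as exc:
            statuses[i] = FAILED
            failure_index = i
            error = f"{step}: {exc}"
            current = None
            break

    metrics = dict(getattr(current, "metrics", {}) or {}) if failure_index is None else {}
    return ExecutionTrace(
        workflow=workflow,
        step_status=statuses,
        failure_index=failure_index,
        final_output=current if failure_index is None else None,
        metrics=metrics,
        error=error,
        step_notes=notes,
        feature_reuse=feature_reuse,
        seed=seed,
    )


@dataclass(frozen=True)
class Outcome:
    state: int  # 1 success, 0 failure
    solution_iloc: Optional[str]
    metric: Optional[float]


def evaluate_outcome(
    trace: ExecutionTrace,
    ctx: TaskContext,
    solution_store: Optional[str] = None,
) -> Outcome:
    """Success (state 1) iff every step succeeded and the chain's final data
    kind is the desired output kind; on success the final artifact is
    persisted (when a store is configured) and its location returned."""
    ok = trace.is_success and trace.workflow.kinds[-1] == ctx.desired_output_kind
    if not ok:
        return Outcome(0, None, None)
    metric = trace.metrics.get("accuracy")
    iloc = None
    if solution_store is not None:
        iloc = persist_solution(trace, ctx, solution_store)
    return Outcome(1, iloc, float(metric) if metric is not None else None)


def persist_solution(trace: ExecutionTrace, ctx: TaskContext, store: str) -> str:
    """Write the fitted final artifact plus a workflow manifest into a
    content-addressed directory; returns the directory path (the solution
    iloc)."""
    digest = hashlib.sha1(
        json.dumps(
            [list(trace.workflow.steps), list(trace.workflow.kinds), ctx.subject, trace.seed]
        ).encode()
    ).hexdigest()[:16]
    root = Path(store) / digest
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "workflow": {"steps": list(trace.workflow.steps), "kinds": list(trace.workflow.kinds)},
        "context": ctx.subject,
        "seed": trace.seed,
        "metrics": trace.metrics,
        "feature_reuse": trace.feature_reuse,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(trace.final_output, root / "solution.joblib")
    return str(root)


def load_solution(iloc: str) -> tuple[dict, object]:
    root = Path(iloc)
    manifest = json.loads((root / "manifest.json").read_text())
    artifact = joblib.load(root / "solution.joblib")
    return manifest, artifact


def replay(iloc: str, frame) -> object:
    """Reload a persisted solution and apply it to new rows."""
    _, artifact = load_solution(iloc)
    if not hasattr(artifact, "predict"):
        raise InvokeError("persisted solution does not support prediction replay")
    return artifact.predict(frame)
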