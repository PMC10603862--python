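"""Workflow composition: the reasoning step.

Services form a directed multigraph whose nodes are data kinds and whose
edges are services (primary input kind -> output kind). A workflow is a
simple chain (no repeated service) from the task's input kind to its
desired output kind. Composition enumerates every such chain up to a depth
bound; ranking orders candidates by length, accumulated policy reward, and
a lexicographic tie-break so the result is total and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .context import TaskContext
from .kg import KnowledgeSpace
from .registry import Registry, ServiceDescriptor

DEFAULT_MAX_DEPTH = 8


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class Workflow:
    """An ordered service chain. ``kinds`` records the data kind flowing
    before/after each step, so ``len(kinds) == len(steps) + 1``; the binding
    between adjacent steps is the shared kind ``kinds[i + 1]``."""

    steps: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.kinds) != len(self.steps) + 1:
            raise CompositionError("kinds must have exactly one more entry than steps")
        if len(set(self.steps)) != len(self.steps):
            raise CompositionError("a workflow never repeats a service")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def bindings(self) -> tuple[tuple[str, str, str], ...]:
        """(producer step, data kind, consumer step) for each adjacency."""
        return tuple(
            (self.steps[i], self.kinds[i + 1], self.steps[i + 1])
            for i in range(len(self.steps) - 1)
        )

    def describe(self) -> str:
        parts = [self.kinds[0]]
        for step, kind in zip(self.steps, self.kinds[1:]):
            parts.append(f"--[{step}]--> {kind}")
        return " ".join(parts)


def validate_workflow(
    workflow: Workflow,
    registry: Registry,
    input_kind: str,
    desired_output_kind: str,
) -> None:
    """Independent structural validator used by tests and the executor."""
    if not workflow.steps:
        raise CompositionError("empty workflow")
    if workflow.kinds[0] != input_kind:
        raise CompositionError(
            f"workflow starts at {workflow.kinds[0]!r}, task input is {input_kind!r}"
        )
    if workflow.kinds[-1] != desired_output_kind:
        raise CompositionError(
            f"workflow ends at {workflow.kinds[-1]!r}, task wants {desired_output_kind!r}"
        )
    for i, step in enumerate(workflow.steps):
        if step not in registry:
            raise CompositionError(f"step {step!r} is not registered")
        d = registry.get(step)
        if d.input_kind != workflow.kinds[i]:
            raise CompositionError(
                f"step {step!r} consumes {d.input_kind!r} but receives {workflow.kinds[i]!r}"
            )
        if d.output_kind != workflow.kinds[i + 1]:
            raise CompositionError(
                f"step {step!r} produces {d.output_kind!r} but chain expects {workflow.kinds[i + 1]!r}"
            )


def find_single_service(ctx: TaskContext, registry: Registry) -> list[ServiceDescriptor]:
    """All services that alone take the task's input kind to its desired
    output kind (sorted by name); empty list when none exists."""
    return [
        d
        for d in registry.descriptors()
        if d.input_kind == ctx.input_kind and d.output_kind == ctx.desired_output_kind
    ]


def compose(
    ctx: TaskContext,
    registry: Registry,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> list[Workflow]:
    """Enumerate every simple service chain of length <= max_depth from the
    task's input kind to its desired output kind, in deterministic order
    (shorter first, then lexicographic by step names)."""
    if max_depth < 1:
        raise CompositionError("max_depth must be >= 1")
    edges = sorted(
        ((d.name, d.input_kind, d.output_kind) for d in registry.descriptors()),
        key=lambda e: e[0],
    )
    results: list[Workflow] = []
    steps: list[str] = []
    kinds: list[str] = [ctx.input_kind]
    used: set[str] = set()

    def dfs(current_kind: str) -> None:
        if steps and current_kind == ctx.desired_output_kind:
            results.append(Workflow(tuple(steps), tuple(kinds)))
            # a chain may legitimately pass through the goal kind and
            # reach it again later, so the search continues below
        if len(steps) >= max_depth:
            return
        for name, in_kind, out_kind in edges:
            if in_kind != current_kind or name in used:
                continue
            steps.append(name)
            kinds.append(out_kind)
            used.add(name)
            dfs(out_kind)
            steps.pop()
            kinds.pop()
            used.discard(name)

    dfs(ctx.input_kind)
    results.sort(key=lambda w: (len(w.steps), w.steps))
    return results


def rank(
    candidates: Sequence[Workflow],
    policy_store: Optional[KnowledgeSpace] = None,
    priorities: Optional[dict[str, Fraction]] = None,
) -> list[Workflow]:
    """Total deterministic order: shorter chains first, then higher
    cumulative service reward, then lexicographic step names. ``priorities``
    (service -> cumulative reward) may be supplied directly; otherwise they
    are derived from the policy store."""
    if priorities is None:
        if policy_store is not None:
            from .policy import service_priorities

            priorities = service_priorities(policy_store)
        else:
            priorities = {}

    def key(w: Workflow):
        reward = sum((priorities.get(s, Fraction(0)) for s in w.steps), Fraction(0))
        return (len(w.steps), -reward, w.steps)

    return sorted(candidates, key=key)


@dataclass(frozen=True)
class Preference:
    """Per-stage service pins: for every candidate, the step that produces
    the given data kind must be the named service."""

    stage_filter: tuple[tuple[str, str], ...]  # (stage output kind, service name)


def apply_preferences(
    candidates: Sequence[Workflow],
    prefs: Preference,
    registry: Registry,
) -> list[Workflow]:
    for kind, name in prefs.stage_filter:
        if name not in registry:
            raise CompositionError(f"preference names unregistered service {name!r}")
    pinned = dict(prefs.stage_filter)
    out = []
    for w in candidates:
        ok = True
        for step, produced in zip(w.steps, w.kinds[1:]):
            want = pinned.get(produced)
            if want is not None and step != want:
                ok = False
                break
        if ok:
            out.append(w)
    return out
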