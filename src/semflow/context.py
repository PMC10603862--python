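"""Task contexts: the semantic key under which all knowledge is filed.

A context combines the input data kind, the free-text application domain,
the desired output kind, and a dataset signature (shape, column names,
modality). Two contexts can match exactly (same task on the same schema),
be transferable (same task, different dataset), or be unrelated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .kg import KnowledgeSpace, Literal, Triple
from .kinds import DATA_KINDS, MODALITIES


class ContextError(ValueError):
    pass


class MatchLevel(IntEnum):
    NONE = 0
    TRANSFERABLE = 1
    EXACT = 2


@dataclass(frozen=True)
class DatasetSignature:
    n_rows: int
    n_columns: int
    column_names: tuple[str, ...]
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ContextError(f"unknown modality {self.modality!r}")
        if self.modality in ("tabular", "counts") and self.n_columns != len(self.column_names):
            raise ContextError(
                f"n_columns={self.n_columns} does not match {len(self.column_names)} column names"
            )

    def schema_equal(self, other: "DatasetSignature") -> bool:
        """Schema equality deliberately ignores the row count: two draws from
        the same table schema should compare equal. Column order matters."""
        return (
            self.n_columns == other.n_columns
            and self.column_names == other.column_names
            and self.modality == other.modality
        )


@dataclass(frozen=True)
class TaskContext:
    input_kind: str
    domain: str
    desired_output_kind: str
    signature: DatasetSignature

    def __post_init__(self) -> None:
        for kind in (self.input_kind, self.desired_output_kind):
            if kind not in DATA_KINDS:
                raise ContextError(f"unknown data kind {kind!r}")
        if self.input_kind == self.desired_output_kind:
            raise ContextError(
                "input kind equals desired output kind — the task requires no computation"
            )
        if not self.domain:
            raise ContextError("domain must be non-empty")

    @property
    def subject(self) -> str:
        """Deterministic triple-store subject for this context."""
        blob = json.dumps(
            [
                self.input_kind,
                self.domain.lower(),
                self.desired_output_kind,
                self.signature.n_rows,
                self.signature.n_columns,
                list(self.signature.column_names),
                self.signature.modality,
            ]
        )
        return "ctx:" + hashlib.sha1(blob.encode()).hexdigest()[:12]


def infer_modality(frame: pd.DataFrame) -> str:
    """Heuristic: a wide all-integer non-negative numeric table reads as a
    count matrix; anything else tabular. Callers may override."""
    if frame.shape[1] >= 50:
        values = frame.to_numpy()
        if np.issubdtype(values.dtype, np.number):
            if np.all(values >= 0) and np.all(np.equal(np.mod(values, 1), 0)):
                return "counts"
    return "tabular"


def build_context(
    request: Mapping[str, str],
    data_preview: Union[pd.DataFrame, "np.ndarray", object],
) -> TaskContext:
    """Derive a full context from a request and a readable data preview.

    ``request`` needs ``input_kind``, ``domain``, ``desired_output_kind``;
    an optional ``modality`` key overrides the inference heuristic.
    """
    for key in ("input_kind", "domain", "desired_output_kind"):
        if key not in request or not request[key]:
            raise ContextError(f"request missing {key!r}")

    preview = data_preview
    if hasattr(preview, "frame"):  # LabeledTable duck-type
        preview = preview.frame
    if hasattr(preview, "counts"):  # CountMatrix duck-type
        counts = preview
        if counts.counts.size == 0:
            raise ContextError("empty dataset")
        sig = DatasetSignature(
            n_rows=counts.counts.shape[0],
            n_columns=counts.counts.shape[1],
            column_names=tuple(counts.gene_ids),
            modality="counts",
        )
        return TaskContext(request["input_kind"], request["domain"], request["desired_output_kind"], sig)

    if isinstance(preview, pd.DataFrame):
        if preview.empty:
            raise ContextError("empty dataset")
        modality = request.get("modality") or infer_modality(preview)
        sig = DatasetSignature(
            n_rows=len(preview),
            n_columns=preview.shape[1],
            column_names=tuple(str(c) for c in preview.columns),
            modality=modality,
        )
        return TaskContext(request["input_kind"], request["domain"], request["desired_output_kind"], sig)

    if isinstance(preview, str):
        # text payloads carry no columnar signature
        if not preview:
            raise ContextError("empty dataset")
        sig = DatasetSignature(0, 0, (), request.get("modality") or "text")
        return TaskContext(request["input_kind"], request["domain"], request["desired_output_kind"], sig)

    raise ContextError(f"unreadable data preview of type {type(preview).__name__}")


def match_contexts(a: TaskContext, b: TaskContext) -> MatchLevel:
    """EXACT if task and schema agree; TRANSFERABLE if only the dataset
    differs; NONE otherwise. Symmetric; domain compares case-insensitively."""
    same_task = (
        a.input_kind == b.input_kind
        and a.desired_output_kind == b.desired_output_kind
        and a.domain.lower() == b.domain.lower()
    )
    if not same_task:
        return MatchLevel.NONE
    if a.signature.schema_equal(b.signature):
        return MatchLevel.EXACT
    return MatchLevel.TRANSFERABLE


# ---------------------------------------------------------------------------
# Triple mapping (lossless round trip)
# ---------------------------------------------------------------------------

def context_to_statements(ctx: TaskContext) -> list[Triple]:
    s = ctx.subject
    return [
        Triple(s, "rdf:type", "sf:TaskContext"),
        Triple(s, "hasInputKind", Literal(ctx.input_kind, "string")),
        Triple(s, "hasDomain", Literal(ctx.domain, "string")),
        Triple(s, "hasDesiredOutputKind", Literal(ctx.desired_output_kind, "string")),
        Triple(s, "hasRowCount", Literal(int(ctx.signature.n_rows), "number")),
        Triple(s, "hasColumnCount", Literal(int(ctx.signature.n_columns), "number")),
        Triple(s, "hasColumnNames", Literal(json.dumps(list(ctx.signature.column_names)), "string")),
        Triple(s, "hasModality", Literal(ctx.signature.modality, "string")),
    ]


def _one(space: KnowledgeSpace, partition: str, subject: str, predicate: str) -> Literal:
    hits = space.match(partition, subject=subject, predicate=predicate)
    if len(hits) != 1 or not isinstance(hits[0].object, Literal):
        raise ContextError(f"cannot reconstruct context {subject}: bad {predicate}")
    return hits[0].object


def context_from_statements(
    space: KnowledgeSpace, subject: str, partition: str = "contexts"
) -> TaskContext:
    sig = DatasetSignature(
        n_rows=int(_one(space, partition, subject, "hasRowCount").value),
        n_columns=int(_one(space, partition, subject, "hasColumnCount").value),
        column_names=tuple(json.loads(str(_one(space, partition, subject, "hasColumnNames").value))),
        modality=str(_one(space, partition, subject, "hasModality").value),
    )
    return TaskContext(
        input_kind=str(_one(space, partition, subject, "hasInputKind").value),
        domain=str(_one(space, partition, subject, "hasDomain").value),
        desired_output_kind=str(_one(space, partition, subject, "hasDesiredOutputKind").value),
        signature=sig,
    )
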