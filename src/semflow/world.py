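"""World knowledge: reusable facts learned while solving tasks.

The chief fact type records which features an optimization run selected
for a given table schema; a later task whose dataset has exactly the same
ordered column names reuses the stored subset instead of re-running the
elimination loop. Text answers and image vectors are stored losslessly for
the corresponding (descriptor-only) service families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .context import DatasetSignature
from .kg import KnowledgeSpace, Literal, Triple


class WorldFactError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSelectionFact:
    schema_key: tuple[str, ...]
    selected_features: tuple[str, ...]
    source_policy: Optional[str] = None
    metric: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise WorldFactError("selected feature set must be non-empty")
        missing = [f for f in self.selected_features if f not in self.schema_key]
        if missing:
            raise WorldFactError(f"selected features not in schema: {missing}")


@dataclass(frozen=True)
class AnswerFact:
    topic: str
    answer: str
    human_reward: float


@dataclass(frozen=True)
class ImageVectorFact:
    vector: tuple[float, ...]
    label: str


def _next_id(space: KnowledgeSpace, prefix: str) -> str:
    seq = len(space.subjects("world", prefix=prefix))
    return f"{prefix}{seq:08d}"


def record_feature_fact(space: KnowledgeSpace, fact: FeatureSelectionFact) -> KnowledgeSpace:
    s = _next_id(space, "fact:feat:")
    ts = [
        Triple(s, "rdf:type", "sf:FeatureSelectionFact"),
        Triple(s, "hasSchema", Literal(json.dumps(list(fact.schema_key)), "string")),
        Triple(s, "hasSelected", Literal(json.dumps(list(fact.selected_features)), "string")),
    ]
    if fact.source_policy is not None:
        ts.append(Triple(s, "hasSourcePolicy", fact.source_policy))
    if fact.metric is not None:
        ts.append(Triple(s, "hasMetric", Literal(float(fact.metric), "number")))
    space.add("world", ts)
    return space


def _lit(space: KnowledgeSpace, subject: str, predicate: str) -> Optional[Literal]:
    hits = space.match("world", subject=subject, predicate=predicate)
    if not hits:
        return None
    obj = hits[0].object
    return obj if isinstance(obj, Literal) else None


def feature_facts(space: KnowledgeSpace) -> list[FeatureSelectionFact]:
    out = []
    for s in space.subjects("world", prefix="fact:feat:"):
        src = space.match("world", subject=s, predicate="hasSourcePolicy")
        metric = _lit(space, s, "hasMetric")
        out.append(
            FeatureSelectionFact(
                schema_key=tuple(json.loads(str(_lit(space, s, "hasSchema").value))),
                selected_features=tuple(json.loads(str(_lit(space, s, "hasSelected").value))),
                source_policy=str(src[0].object) if src else None,
                metric=float(metric.value) if metric else None,
            )
        )
    return out


def reuse_features(
    space: KnowledgeSpace, signature: DatasetSignature
) -> Optional[tuple[str, ...]]:
    """Return a stored selected-feature subset iff the signature's column
    names equal a stored schema key exactly (order-sensitive); among
    several matching facts the best metric wins, then recency."""
    columns = tuple(signature.column_names)
    matches = [
        (i, f)
        for i, f in enumerate(feature_facts(space))
        if f.schema_key == columns
    ]
    if not matches:
        return None
    matches.sort(key=lambda item: (-(item[1].metric if item[1].metric is not None else -1.0), -item[0]))
    return matches[0][1].selected_features


def store_fact(
    space: KnowledgeSpace, fact: Union[AnswerFact, ImageVectorFact]
) -> KnowledgeSpace:
    if isinstance(fact, AnswerFact):
        s = _next_id(space, "fact:ans:")
        space.add(
            "world",
            [
                Triple(s, "rdf:type", "sf:AnswerFact"),
                Triple(s, "hasTopic", Literal(fact.topic, "string")),
                Triple(s, "hasAnswer", Literal(fact.answer, "string")),
                Triple(s, "hasHumanReward", Literal(float(fact.human_reward), "number")),
            ],
        )
        return space
    if isinstance(fact, ImageVectorFact):
        s = _next_id(space, "fact:img:")
        space.add(
            "world",
            [
                Triple(s, "rdf:type", "sf:ImageVectorFact"),
                Triple(s, "hasVector", Literal(json.dumps([repr(v) for v in fact.vector]), "string")),
                Triple(s, "hasLabel", Literal(fact.label, "string")),
            ],
        )
        return space
    raise WorldFactError(f"unknown fact type {type(fact).__name__}")


def answer_facts(space: KnowledgeSpace, topic: Optional[str] = None) -> list[AnswerFact]:
    out = []
    for s in space.subjects("world", prefix="fact:ans:"):
        fact = AnswerFact(
            topic=str(_lit(space, s, "hasTopic").value),
            answer=str(_lit(space, s, "hasAnswer").value),
            human_reward=float(_lit(space, s, "hasHumanReward").value),
        )
        if topic is None or fact.topic == topic:
            out.append(fact)
    return out


def image_facts(space: KnowledgeSpace, label: Optional[str] = None) -> list[ImageVectorFact]:
    out = []
    for s in space.subjects("world", prefix="fact:img:"):
        fact = ImageVectorFact(
            vector=tuple(float(v) for v in json.loads(str(_lit(space, s, "hasVector").value))),
            label=str(_lit(space, s, "hasLabel").value),
        )
        if label is None or fact.label == label:
            out.append(fact)
    return out
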