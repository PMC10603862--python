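"""Partitioned triple store: the framework's knowledge space.

All knowledge the framework accumulates — service descriptions, task
contexts, policies, and world facts — is held as subject/predicate/object
triples in one of four named partitions. Identifiers are opaque strings;
literals carry a kind tag (string, number, boolean). Persistence goes
through rdflib in N-Triples or Turtle, with partition membership encoded
as comment-delimited sections so both dialects stay plain and portable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Union
from urllib.parse import quote, unquote

from rdflib import Graph, Namespace, URIRef
from rdflib import Literal as _RDFLiteral
from rdflib.namespace import XSD

#: Single project namespace for all identifiers, so serializations are stable.
NS = Namespace("urn:semflow:")

PARTITIONS: tuple[str, ...] = ("services", "contexts", "policies", "world")

#: Sentinel partition name meaning "search every partition".
ALL = "ALL"

_MARKER = "# semflow-partition:"

# Floats carry a project datatype rather than xsd:double because Turtle
# writers abbreviate doubles to numeric tokens with precision loss; an
# opaque datatype keeps the lexical form (repr) verbatim both ways.
_FLOAT_DT = URIRef(str(NS) + "float")

# Strings containing control characters are written escaped (and tagged) so
# strict N-Triples parsers accept them and round trips stay exact.
_ESCAPED_DT = URIRef(str(NS) + "escaped-string")

_DIALECTS = {
    "ntriples": "nt",
    "nt": "nt",
    "turtle": "turtle",
    "ttl": "turtle",
}


class KnowledgeError(ValueError):
    """Base error for knowledge-space operations."""


class UnknownPartitionError(KnowledgeError):
    def __init__(self, name: object):
        super().__init__(
            f"unknown partition {name!r}; valid partitions are {list(PARTITIONS)}"
        )
        self.partition = name


class KnowledgeParseError(KnowledgeError):
    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"parse error at line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Literal:
    """A typed literal object value.

    ``kind`` is one of ``string`` (str), ``number`` (int or float, finite),
    ``boolean`` (bool).
    """

    value: Union[str, int, float, bool]
    kind: str

    def __post_init__(self) -> None:
        if self.kind == "string":
            if not isinstance(self.value, str):
                raise KnowledgeError(f"string literal requires str, got {self.value!r}")
        elif self.kind == "boolean":
            if not isinstance(self.value, bool):
                raise KnowledgeError(f"boolean literal requires bool, got {self.value!r}")
        elif self.kind == "number":
            if isinstance(self.value, bool) or not isinstance(self.value, (int, float)):
                raise KnowledgeError(f"number literal requires int/float, got {self.value!r}")
            if isinstance(self.value, float) and not math.isfinite(self.value):
                raise KnowledgeError("number literal must be finite")
        else:
            raise KnowledgeError(f"unknown literal kind {self.kind!r}")

    @classmethod
    def of(cls, value: Union[str, int, float, bool]) -> "Literal":
        """Build a literal inferring the kind tag from the Python type."""
        if isinstance(value, bool):
            return cls(value, "boolean")
        if isinstance(value, (int, float)):
            return cls(value, "number")
        return cls(str(value), "string")


@dataclass(frozen=True)
class Triple:
    """One statement. Subject and predicate are non-empty identifiers; the
    object is either an identifier (str) or a :class:`Literal` — a literal
    never appears in subject position by construction."""

    subject: str
    predicate: str
    object: Union[str, Literal]

    def __post_init__(self) -> None:
        if not isinstance(self.subject, str) or not self.subject:
            raise KnowledgeError(f"subject must be a non-empty string, got {self.subject!r}")
        if not isinstance(self.predicate, str) or not self.predicate:
            raise KnowledgeError(f"predicate must be a non-empty string, got {self.predicate!r}")
        if not isinstance(self.object, (str, Literal)):
            raise KnowledgeError(f"object must be identifier or Literal, got {self.object!r}")


def _object_key(obj: Union[str, Literal]) -> str:
    if isinstance(obj, Literal):
        return f"L:{obj.kind}:{obj.value!r}"
    return f"I:{obj}"


def _triple_key(t: Triple) -> tuple[str, str, str]:
    return (t.subject, t.predicate, _object_key(t.object))


class KnowledgeSpace:
    """Four named sets of triples with set-semantic insertion."""

    def __init__(self) -> None:
        self._parts: dict[str, set[Triple]] = {p: set() for p in PARTITIONS}

    # -- basic container protocol -------------------------------------
    def partition(self, name: str) -> frozenset[Triple]:
        if name not in self._parts:
            raise UnknownPartitionError(name)
        return frozenset(self._parts[name])

    def partition_sizes(self) -> dict[str, int]:
        return {p: len(ts) for p, ts in self._parts.items()}

    def __len__(self) -> int:
        return sum(len(ts) for ts in self._parts.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeSpace):
            return NotImplemented
        return self._parts == other._parts

    def __iter__(self) -> Iterator[tuple[str, Triple]]:
        for p in PARTITIONS:
            for t in sorted(self._parts[p], key=_triple_key):
                yield p, t

    def copy(self) -> "KnowledgeSpace":
        dup = KnowledgeSpace()
        for p in PARTITIONS:
            dup._parts[p] = set(self._parts[p])
        return dup

    # -- mutation ------------------------------------------------------
    def add(self, partition: str, triples: Iterable[Triple]) -> "KnowledgeSpace":
        if partition not in self._parts:
            raise UnknownPartitionError(partition)
        for t in triples:
            if not isinstance(t, Triple):
                raise KnowledgeError(f"expected Triple, got {t!r}")
            self._parts[partition].add(t)
        return self

    def discard(self, partition: str, triples: Iterable[Triple]) -> "KnowledgeSpace":
        """Internal helper for marker rewrites; public growth is monotone."""
        if partition not in self._parts:
            raise UnknownPartitionError(partition)
        for t in triples:
            self._parts[partition].discard(t)
        return self

    # -- query ---------------------------------------------------------
    def match(
        self,
        partition: str = ALL,
        subject: Optional[str] = None,
        predicate: Optional[str] = None,
        object: Optional[Union[str, Literal]] = None,
    ) -> list[Triple]:
        """Return triples unifying with the pattern; ``None`` is a wildcard.

        Output order is deterministic: sorted by (subject, predicate, object).
        """
        if partition == ALL:
            names: tuple[str, ...] = PARTITIONS
        elif partition in self._parts:
            names = (partition,)
        else:
            raise UnknownPartitionError(partition)
        out = []
        for name in names:
            for t in self._parts[name]:
                if subject is not None and t.subject != subject:
                    continue
                if predicate is not None and t.predicate != predicate:
                    continue
                if object is not None and t.object != object:
                    continue
                out.append(t)
        out.sort(key=_triple_key)
        return out

    def subjects(self, partition: str, prefix: str = "") -> list[str]:
        """Distinct subjects in a partition (optionally by prefix), sorted."""
        if partition not in self._parts:
            raise UnknownPartitionError(partition)
        subs = {t.subject for t in self._parts[partition] if t.subject.startswith(prefix)}
        return sorted(subs)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def add_triples(space: KnowledgeSpace, partition: str, triples: Iterable[Triple]) -> KnowledgeSpace:
    return space.add(partition, triples)


def match(
    space: KnowledgeSpace,
    partition: str = ALL,
    subject: Optional[str] = None,
    predicate: Optional[str] = None,
    object: Optional[Union[str, Literal]] = None,
) -> list[Triple]:
    return space.match(partition, subject, predicate, object)


# ---------------------------------------------------------------------------
# rdflib conversion
# ---------------------------------------------------------------------------

def _to_node(ident: str) -> URIRef:
    return URIRef(str(NS) + quote(ident, safe=""))


def _to_object_node(obj: Union[str, Literal]):
    if isinstance(obj, str):
        return _to_node(obj)
    if obj.kind == "boolean":
        return _RDFLiteral("true" if obj.value else "false", datatype=XSD.boolean)
    if obj.kind == "number":
        if isinstance(obj.value, int):
            return _RDFLiteral(repr(obj.value), datatype=XSD.integer)
        return _RDFLiteral(repr(obj.value), datatype=_FLOAT_DT)
    if any(ord(c) < 0x20 or ord(c) == 0x7F for c in obj.value):
        escaped = obj.value.encode("unicode_escape").decode("ascii")
        return _RDFLiteral(escaped, datatype=_ESCAPED_DT)
    return _RDFLiteral(obj.value)


def _from_ident_node(node) -> str:
    s = str(node)
    ns = str(NS)
    if s.startswith(ns):
        return unquote(s[len(ns):])
    return s


def _from_object_node(node) -> Union[str, Literal]:
    if isinstance(node, _RDFLiteral):
        dt = node.datatype
        if dt == XSD.boolean:
            return Literal(str(node).strip().lower() in ("true", "1"), "boolean")
        if dt in (XSD.integer, XSD.int, XSD.long, XSD.short):
            return Literal(int(node), "number")
        if dt == _FLOAT_DT or dt in (XSD.double, XSD.float, XSD.decimal):
            return Literal(float(node), "number")
        if dt == _ESCAPED_DT:
            return Literal(str(node).encode("ascii").decode("unicode_escape"), "string")
        return Literal(str(node), "string")
    return _from_ident_node(node)


def _partition_graph(triples: Iterable[Triple]) -> Graph:
    g = Graph()
    g.bind("sf", NS)
    for t in sorted(triples, key=_triple_key):
        g.add((_to_node(t.subject), _to_node(t.predicate), _to_object_node(t.object)))
    return g


def serialize(space: KnowledgeSpace, dialect: str = "ntriples") -> str:
    """Serialize the whole space as one text document.

    Each partition is a section introduced by a ``# semflow-partition:``
    comment; comments are legal in both N-Triples and Turtle, so the whole
    document remains a valid file in the declared dialect.
    """
    if dialect not in _DIALECTS:
        raise KnowledgeError(f"unknown dialect {dialect!r}; use 'ntriples' or 'turtle'")
    fmt = _DIALECTS[dialect]
    sections = []
    for p in PARTITIONS:
        body = _partition_graph(space.partition(p)).serialize(format=fmt)
        sections.append(f"{_MARKER} {p}\n{body.strip()}\n")
    return "\n".join(sections)


def _parse_chunk(text: str, fmt: str, offset: int) -> list[Triple]:
    g = Graph()
    try:
        g.parse(data=text, format=fmt)
    except Exception as exc:
        # Locate the offending line for N-Triples (one statement per line).
        if fmt == "nt":
            for i, line in enumerate(text.splitlines()):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                probe = Graph()
                try:
                    probe.parse(data=line, format="nt")
                except Exception:
                    raise KnowledgeParseError(str(exc), line=offset + i + 1) from exc
        raise KnowledgeParseError(str(exc)) from exc
    out = []
    for s, p, o in g:
        out.append(Triple(_from_ident_node(s), _from_ident_node(p), _from_object_node(o)))
    return out


def parse(text: str, dialect: str = "ntriples") -> KnowledgeSpace:
    """Inverse of :func:`serialize`: ``parse(serialize(s, d), d) == s``."""
    if dialect not in _DIALECTS:
        raise KnowledgeError(f"unknown dialect {dialect!r}; use 'ntriples' or 'turtle'")
    fmt = _DIALECTS[dialect]
    space = KnowledgeSpace()
    current: Optional[str] = None
    chunk_lines: list[str] = []
    chunk_start = 0

    def flush() -> None:
        if current is None:
            return
        body = "\n".join(chunk_lines)
        if body.strip():
            space.add(current, _parse_chunk(body, fmt, chunk_start))

    for lineno, line in enumerate(text.splitlines()):
        if line.strip().startswith(_MARKER):
            flush()
            name = line.strip()[len(_MARKER):].strip()
            if name not in PARTITIONS:
                raise UnknownPartitionError(name)
            current = name
            chunk_lines = []
            chunk_start = lineno + 1
        else:
            if current is None and line.strip() and not line.strip().startswith("#"):
                raise KnowledgeParseError(
                    "statement outside any partition section", line=lineno + 1
                )
            chunk_lines.append(line)
    flush()
    return space
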