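"""Microservice registration per the nine-parameter descriptor ontology.

A descriptor carries exactly nine top-level parameters: name, description,
framework, dependencies, inputs, outputs, category, license, invoke_path.
Descriptors live as triples in the ``services`` partition of the knowledge
space; the :class:`Registry` is a typed view over that partition.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .kg import KnowledgeSpace, Literal, Triple
from .kinds import DATA_KINDS

NINE_PARAMETERS: tuple[str, ...] = (
    "name",
    "description",
    "framework",
    "dependencies",
    "inputs",
    "outputs",
    "category",
    "license",
    "invoke_path",
)

_NAME_RE = re.compile(r"^[A-Za-z0-9_-]{1,64}$")


class DescriptorError(ValueError):
    """Validation failure; ``errors`` maps parameter name -> problem."""

    def __init__(self, errors: Mapping[str, str]):
        self.errors = dict(errors)
        detail = "; ".join(f"{k}: {v}" for k, v in sorted(self.errors.items()))
        super().__init__(f"invalid service descriptor — {detail}")


class DuplicateServiceError(ValueError):
    def __init__(self, name: str):
        super().__init__(f"service name {name!r} is already registered (no duplication allowed)")
        self.name = name


class UnknownServiceError(KeyError):
    pass


@dataclass(frozen=True)
class PortSpec:
    """A typed input or output port."""

    name: str
    data_kind: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("port name must be non-empty")
        if self.data_kind not in DATA_KINDS:
            raise ValueError(f"unknown data kind {self.data_kind!r}")


@dataclass(frozen=True)
class Dependency:
    id: str
    install_uri: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("dependency id must be non-empty")


@dataclass(frozen=True)
class ServiceDescriptor:
    name: str
    description: str
    framework: str
    dependencies: tuple[Dependency, ...]
    inputs: tuple[PortSpec, ...]
    outputs: tuple[PortSpec, ...]
    category: str
    license: str
    invoke_path: str

    @property
    def input_kind(self) -> str:
        """Data kind of the primary (first) input port."""
        return self.inputs[0].data_kind

    @property
    def output_kind(self) -> str:
        return self.outputs[0].data_kind

    def as_record(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "framework": self.framework,
            "dependencies": [
                {"id": d.id, "install_uri": d.install_uri, "version": d.version}
                for d in self.dependencies
            ],
            "inputs": [{"name": p.name, "data_kind": p.data_kind} for p in self.inputs],
            "outputs": [{"name": p.name, "data_kind": p.data_kind} for p in self.outputs],
            "category": self.category,
            "license": self.license,
            "invoke_path": self.invoke_path,
        }


def _check_ports(raw: object, errors: dict, key: str, exactly_one: bool) -> tuple[PortSpec, ...]:
    if not isinstance(raw, (list, tuple)) or not raw:
        errors[key] = "must be a non-empty list of ports"
        return ()
    if exactly_one and len(raw) != 1:
        errors[key] = f"exactly one {key[:-1]} port required, got {len(raw)}"
        return ()
    ports = []
    for i, item in enumerate(raw):
        try:
            if isinstance(item, PortSpec):
                ports.append(item)
            else:
                ports.append(PortSpec(str(item["name"]), str(item["data_kind"])))
        except (KeyError, TypeError, ValueError) as exc:
            errors[key] = f"port {i}: {exc}"
            return ()
    return tuple(ports)


def validate_descriptor(record: Mapping) -> ServiceDescriptor:
    """Check all nine parameters and return a typed descriptor.

    Raises :class:`DescriptorError` listing every missing or malformed
    parameter. Name legibility = non-empty, at most 64 characters, drawn
    from alphanumerics, underscore, and hyphen.
    """
    errors: dict[str, str] = {}
    for key in NINE_PARAMETERS:
        if key not in record:
            errors[key] = "missing"
    extra = set(record) - set(NINE_PARAMETERS)
    if extra:
        for key in sorted(extra):
            errors[key] = "unknown parameter"
    if errors:
        raise DescriptorError(errors)

    name = record["name"]
    if not isinstance(name, str) or not _NAME_RE.match(name or ""):
        errors["name"] = (
            "illegible name: must be 1-64 characters of [A-Za-z0-9_-]"
        )

    for key in ("description", "framework", "category", "license", "invoke_path"):
        if not isinstance(record[key], str) or not record[key]:
            errors[key] = "must be a non-empty string"

    deps: list[Dependency] = []
    raw_deps = record["dependencies"]
    if not isinstance(raw_deps, (list, tuple)):
        errors["dependencies"] = "must be a list"
    else:
        for i, item in enumerate(raw_deps):
            try:
                if isinstance(item, Dependency):
                    deps.append(item)
                else:
                    deps.append(
                        Dependency(
                            str(item["id"]),
                            str(item.get("install_uri", "")),
                            str(item.get("version", "")),
                        )
                    )
            except (KeyError, TypeError, ValueError) as exc:
                errors["dependencies"] = f"dependency {i}: {exc}"
                break

    inputs = _check_ports(record["inputs"], errors, "inputs", exactly_one=False)
    outputs = _check_ports(record["outputs"], errors, "outputs", exactly_one=True)

    if errors:
        raise DescriptorError(errors)
    return ServiceDescriptor(
        name=name,
        description=record["description"],
        framework=record["framework"],
        dependencies=tuple(deps),
        inputs=inputs,
        outputs=outputs,
        category=record["category"],
        license=record["license"],
        invoke_path=record["invoke_path"],
    )


# ---------------------------------------------------------------------------
# Triple mapping
# ---------------------------------------------------------------------------

def _subject(name: str) -> str:
    return f"svc:{name}"


def descriptor_to_triples(d: ServiceDescriptor) -> list[Triple]:
    s = _subject(d.name)
    ts = [
        Triple(s, "rdf:type", "sf:Microservice"),
        Triple(s, "hasName", Literal(d.name, "string")),
        Triple(s, "hasDescription", Literal(d.description, "string")),
        Triple(s, "hasFramework", Literal(d.framework, "string")),
        Triple(s, "hasCategory", Literal(d.category, "string")),
        Triple(s, "hasLicense", Literal(d.license, "string")),
        Triple(s, "hasInvokePath", Literal(d.invoke_path, "string")),
    ]
    for i, dep in enumerate(d.dependencies):
        node = f"{s}#dep{i}"
        ts += [
            Triple(s, "hasDependency", node),
            Triple(node, "hasIndex", Literal(i, "number")),
            Triple(node, "hasId", Literal(dep.id, "string")),
            Triple(node, "hasInstallUri", Literal(dep.install_uri, "string")),
            Triple(node, "hasVersion", Literal(dep.version, "string")),
        ]
    for prefix, pred, ports in (("in", "hasInputPort", d.inputs), ("out", "hasOutputPort", d.outputs)):
        for i, port in enumerate(ports):
            node = f"{s}#{prefix}{i}"
            ts += [
                Triple(s, pred, node),
                Triple(node, "hasIndex", Literal(i, "number")),
                Triple(node, "hasPortName", Literal(port.name, "string")),
                Triple(node, "hasDataKind", Literal(port.data_kind, "string")),
            ]
    return ts


def _literal_of(space: KnowledgeSpace, subject: str, predicate: str) -> Literal:
    hits = space.match("services", subject=subject, predicate=predicate)
    if len(hits) != 1 or not isinstance(hits[0].object, Literal):
        raise DescriptorError({predicate: f"expected exactly one literal on {subject}, got {len(hits)}"})
    return hits[0].object


def _indexed_nodes(space: KnowledgeSpace, subject: str, predicate: str) -> list[str]:
    nodes = [t.object for t in space.match("services", subject=subject, predicate=predicate)]
    def idx(node: str) -> int:
        lit = _literal_of(space, node, "hasIndex")
        return int(lit.value)
    return sorted((str(n) for n in nodes), key=idx)


def descriptor_from_triples(space: KnowledgeSpace, name: str) -> ServiceDescriptor:
    s = _subject(name)
    if not space.match("services", subject=s, predicate="hasName"):
        raise UnknownServiceError(name)
    deps = []
    for node in _indexed_nodes(space, s, "hasDependency"):
        deps.append(
            Dependency(
                str(_literal_of(space, node, "hasId").value),
                str(_literal_of(space, node, "hasInstallUri").value),
                str(_literal_of(space, node, "hasVersion").value),
            )
        )
    def ports(pred: str) -> tuple[PortSpec, ...]:
        out = []
        for node in _indexed_nodes(space, s, pred):
            out.append(
                PortSpec(
                    str(_literal_of(space, node, "hasPortName").value),
                    str(_literal_of(space, node, "hasDataKind").value),
                )
            )
        return tuple(out)

    return ServiceDescriptor(
        name=str(_literal_of(space, s, "hasName").value),
        description=str(_literal_of(space, s, "hasDescription").value),
        framework=str(_literal_of(space, s, "hasFramework").value),
        dependencies=tuple(deps),
        inputs=ports("hasInputPort"),
        outputs=ports("hasOutputPort"),
        category=str(_literal_of(space, s, "hasCategory").value),
        license=str(_literal_of(space, s, "hasLicense").value),
        invoke_path=str(_literal_of(space, s, "hasInvokePath").value),
    )


def register(space: KnowledgeSpace, record: Mapping) -> tuple[KnowledgeSpace, ServiceDescriptor]:
    """Validate and add a descriptor. Atomic: on any failure the space is
    untouched; duplicate names are rejected."""
    descriptor = validate_descriptor(record) if not isinstance(record, ServiceDescriptor) else record
    if space.match("services", subject=_subject(descriptor.name), predicate="hasName"):
        raise DuplicateServiceError(descriptor.name)
    space.add("services", descriptor_to_triples(descriptor))
    return space, descriptor


class Registry:
    """Name -> descriptor view over the ``services`` partition."""

    def __init__(self, space: KnowledgeSpace):
        self.space = space

    def names(self) -> list[str]:
        subs = {
            t.subject
            for t in self.space.match("services", predicate="hasName")
        }
        return sorted(s.split(":", 1)[1] for s in subs)

    def __len__(self) -> int:
        return len(self.names())

    def __contains__(self, name: str) -> bool:
        return bool(self.space.match("services", subject=_subject(name), predicate="hasName"))

    def get(self, name: str) -> ServiceDescriptor:
        return descriptor_from_triples(self.space, name)

    def descriptors(self) -> list[ServiceDescriptor]:
        return [self.get(n) for n in self.names()]

    def find(
        self,
        input_kind: Optional[str] = None,
        output_kind: Optional[str] = None,
        category: Optional[str] = None,
    ) -> list[ServiceDescriptor]:
        """Filter descriptors by primary input kind, output kind, and/or
        category (case-insensitive). At least one filter must be bound.
        Result sorted by name."""
        if input_kind is None and output_kind is None and category is None:
            raise ValueError("at least one filter must be bound")
        out = []
        for d in self.descriptors():
            if input_kind is not None and d.input_kind != input_kind:
                continue
            if output_kind is not None and d.output_kind != output_kind:
                continue
            if category is not None and d.category.lower() != category.lower():
                continue
            out.append(d)
        return out


def find_services(
    registry: Registry,
    input_kind: Optional[str] = None,
    output_kind: Optional[str] = None,
    category: Optional[str] = None,
) -> list[ServiceDescriptor]:
    return registry.find(input_kind=input_kind, output_kind=output_kind, category=category)
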