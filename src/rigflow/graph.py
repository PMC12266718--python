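"""Pipeline graph model: parse, validate, serialize.

A pipeline is a *graph* of named nodes — sources (only emit), transforms
(receive and emit) and sinks (only receive) — joined by directed links from
named output ports to named input ports.  Graphs are authored as JSON files
with an explicit ``schema_version``; unknown keys are rejected so a run
definition never silently means something else under a newer reader.

Two deliberate departures from DAG-style dataflow tools:

* Cycles are legal and load-bearing.  Request/response node pairs (a trial
  generator and a trial controller feeding each other) form a 2-cycle, so no
  acyclicity check exists anywhere.
* Start order is authoring order, not topological order.  The engine starts
  nodes exactly in the order they appear in the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, List, Optional

SCHEMA_VERSION = "1"

NODE_TYPES = ("source", "transform", "sink")


class GraphError(ValueError):
    """Base class for graph file problems."""


class GraphParseError(GraphError):
    """Malformed graph text; the message names the offending JSON path."""


class GraphValidationError(GraphError):
    """Raised by operations that require a valid graph."""


@dataclass(frozen=True)
class PortSpec:
    name: str
    direction: str  # "input" | "output"


@dataclass
class ParameterSpec:
    name: str
    value: Any
    updatable: bool = True


@dataclass
class NodeSpec:
    base_name: str
    instance_index: int
    node_type: str
    inputs: List[PortSpec] = field(default_factory=list)
    outputs: List[PortSpec] = field(default_factory=list)
    parameters: List[ParameterSpec] = field(default_factory=list)
    worker_ref: str = ""
    placement: str = "local"
    cpu_pin: Optional[int] = None
    com_log_path: Optional[str] = None

    @property
    def display_name(self) -> str:
        return f"{self.base_name}##{self.instance_index}"

    def parameter(self, name: str) -> Optional[ParameterSpec]:
        for p in self.parameters:
            if p.name == name:
                return p
        return None

    def parameter_values(self) -> dict:
        return {p.name: p.value for p in self.parameters}


@dataclass(frozen=True)
class Edge:
    from_node: str
    from_output: str
    to_node: str
    to_input: str

    @property
    def link_id(self) -> str:
        return f"{self.from_node}:{self.from_output}->{self.to_node}:{self.to_input}"


@dataclass
class Graph:
    nodes: List[NodeSpec] = field(default_factory=list)
    edges: List[Edge] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def node(self, display_name: str) -> Optional[NodeSpec]:
        for n in self.nodes:
            if n.display_name == display_name:
                return n
        return None


@dataclass(frozen=True)
class Violation:
    """One violated graph invariant.  Violations are data, not exceptions."""

    code: str
    subject: str  # display name of the node or link involved
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.subject}: {self.message}"


# ---------------------------------------------------------------------------
# parsing

_NODE_KEYS = {
    "base_name",
    "instance_index",
    "node_type",
    "inputs",
    "outputs",
    "parameters",
    "worker_ref",
    "placement",
    "cpu_pin",
    "com_log_path",
}
_PARAM_KEYS = {"name", "value", "updatable"}
_EDGE_KEYS = {"from_node", "from_output", "to_node", "to_input"}
_TOP_KEYS = {"schema_version", "nodes", "edges"}


def _expect(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise GraphParseError(f"{path}: {msg}")


def _parse_ports(raw: Any, path: str, direction: str) -> List[PortSpec]:
    _expect(isinstance(raw, list), path, "must be a list of port names")
    ports = []
    for i, name in enumerate(raw):
        _expect(
            isinstance(name, str) and name != "",
            f"{path}[{i}]",
            "port name must be a non-empty string",
        )
        ports.append(PortSpec(name=name, direction=direction))
    return ports


def _parse_parameters(raw: Any, path: str) -> List[ParameterSpec]:
    _expect(isinstance(raw, list), path, "must be a list of parameter objects")
    out = []
    for i, p in enumerate(raw):
        ppath = f"{path}[{i}]"
        _expect(isinstance(p, dict), ppath, "must be an object")
        unknown = set(p) - _PARAM_KEYS
        _expect(not unknown, ppath, f"unknown keys {sorted(unknown)}")
        _expect("name" in p and "value" in p, ppath, "requires 'name' and 'value'")
        _expect(
            isinstance(p["name"], str) and p["name"] != "",
            f"{ppath}.name",
            "must be a non-empty string",
        )
        updatable = p.get("updatable", True)
        _expect(isinstance(updatable, bool), f"{ppath}.updatable", "must be a boolean")
        out.append(ParameterSpec(name=p["name"], value=p["value"], updatable=updatable))
    return out


def parse_graph(text: str) -> Graph:
    """Parse graph-file content into a :class:`Graph`.

    Structural problems (wrong types, unknown keys, edges referencing
    missing nodes or ports) raise :class:`GraphParseError` naming the
    offending path.  Semantic invariants (node-type port rules, display-name
    uniqueness) are the province of :func:`validate_graph`.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GraphParseError(f"not valid JSON: {exc}") from exc
    _expect(isinstance(raw, dict), "$", "top level must be an object")
    unknown = set(raw) - _TOP_KEYS
    _expect(not unknown, "$", f"unknown keys {sorted(unknown)}")
    _expect(
        raw.get("schema_version") == SCHEMA_VERSION,
        "$.schema_version",
        f"must be {SCHEMA_VERSION!r}",
    )
    _expect(isinstance(raw.get("nodes"), list), "$.nodes", "must be a list")
    _expect(isinstance(raw.get("edges", []), list), "$.edges", "must be a list")

    nodes: List[NodeSpec] = []
    auto_index: dict = {}
    for i, n in enumerate(raw["nodes"]):
        path = f"$.nodes[{i}]"
        _expect(isinstance(n, dict), path, "must be an object")
        unknown = set(n) - _NODE_KEYS
        _expect(not unknown, path, f"unknown keys {sorted(unknown)}")
        _expect(
            isinstance(n.get("base_name"), str) and n["base_name"] != "",
            f"{path}.base_name",
            "must be a non-empty string",
        )
        _expect(
            n.get("node_type") in NODE_TYPES,
            f"{path}.node_type",
            f"must be one of {list(NODE_TYPES)}",
        )
        if "instance_index" in n:
            idx = n["instance_index"]
            _expect(
                isinstance(idx, int) and not isinstance(idx, bool) and idx >= 0,
                f"{path}.instance_index",
                "must be a non-negative integer",
            )
        else:
            # auto-assign the next free index for this base name
            idx = auto_index.get(n["base_name"], 0)
        auto_index[n["base_name"]] = max(auto_index.get(n["base_name"], 0), idx + 1)
        cpu_pin = n.get("cpu_pin")
        if cpu_pin is not None:
            _expect(
                isinstance(cpu_pin, int) and not isinstance(cpu_pin, bool) and cpu_pin >= 0,
                f"{path}.cpu_pin",
                "must be a non-negative integer",
            )
        com_log_path = n.get("com_log_path")
        if com_log_path is not None:
            _expect(isinstance(com_log_path, str), f"{path}.com_log_path", "must be a string")
        placement = n.get("placement", "local")
        _expect(
            isinstance(placement, str) and placement != "",
            f"{path}.placement",
            "must be a non-empty string",
        )
        worker_ref = n.get("worker_ref", "")
        _expect(isinstance(worker_ref, str), f"{path}.worker_ref", "must be a string")
        nodes.append(
            NodeSpec(
                base_name=n["base_name"],
                instance_index=idx,
                node_type=n["node_type"],
                inputs=_parse_ports(n.get("inputs", []), f"{path}.inputs", "input"),
                outputs=_parse_ports(n.get("outputs", []), f"{path}.outputs", "output"),
                parameters=_parse_parameters(n.get("parameters", []), f"{path}.parameters"),
                worker_ref=worker_ref,
                placement=placement,
                cpu_pin=cpu_pin,
                com_log_path=com_log_path,
            )
        )

    by_name = {n.display_name: n for n in nodes}
    edges: List[Edge] = []
    for i, e in enumerate(raw.get("edges", [])):
        path = f"$.edges[{i}]"
        _expect(isinstance(e, dict), path, "must be an object")
        unknown = set(e) - _EDGE_KEYS
        _expect(not unknown, path, f"unknown keys {sorted(unknown)}")
        for k in _EDGE_KEYS:
            _expect(isinstance(e.get(k), str) and e[k] != "", f"{path}.{k}", "must be a non-empty string")
        src = by_name.get(e["from_node"])
        _expect(src is not None, f"{path}.from_node", f"unknown node {e['from_node']!r}")
        dst = by_name.get(e["to_node"])
        _expect(dst is not None, f"{path}.to_node", f"unknown node {e['to_node']!r}")
        _expect(
            any(p.name == e["from_output"] for p in src.outputs),
            f"{path}.from_output",
            f"node {src.display_name!r} has no output port {e['from_output']!r}",
        )
        _expect(
            any(p.name == e["to_input"] for p in dst.inputs),
            f"{path}.to_input",
            f"node {dst.display_name!r} has no input port {e['to_input']!r}",
        )
        edges.append(Edge(e["from_node"], e["from_output"], e["to_node"], e["to_input"]))

    return Graph(nodes=nodes, edges=edges, schema_version=raw["schema_version"])


def serialize_graph(g: Graph) -> str:
    """Serialize to canonical graph-file JSON (round-trips through parse)."""
    doc = {
        "schema_version": g.schema_version,
        "nodes": [
            {
                "base_name": n.base_name,
                "instance_index": n.instance_index,
                "node_type": n.node_type,
                "inputs": [p.name for p in n.inputs],
                "outputs": [p.name for p in n.outputs],
                "parameters": [
                    {"name": p.name, "value": p.value, "updatable": p.updatable}
                    for p in n.parameters
                ],
                "worker_ref": n.worker_ref,
                "placement": n.placement,
                **({"cpu_pin": n.cpu_pin} if n.cpu_pin is not None else {}),
                **({"com_log_path": n.com_log_path} if n.com_log_path is not None else {}),
            }
            for n in g.nodes
        ],
        "edges": [
            {
                "from_node": e.from_node,
                "from_output": e.from_output,
                "to_node": e.to_node,
                "to_input": e.to_input,
            }
            for e in g.edges
        ],
    }
    return json.dumps(doc, indent=1)


# ---------------------------------------------------------------------------
# validation

_PORT_RULES = {
    # node_type: (inputs allowed, outputs allowed, inputs required, outputs required)
    "source": (False, True, False, True),
    "transform": (True, True, True, True),
    "sink": (True, False, True, False),
}


def validate_graph(g: Graph) -> List[Violation]:
    """Check every graph invariant; return the (possibly empty) violation list.

    Validity is order-independent: reordering nodes or edges never changes
    the outcome.  Cycles are never a violation.
    """
    out: List[Violation] = []
    seen_names: set = set()
    for n in g.nodes:
        name = n.display_name
        if name in seen_names:
            out.append(Violation("duplicate-node-name", name, "display name used more than once"))
        seen_names.add(name)
        if n.node_type not in NODE_TYPES:
            out.append(Violation("bad-node-type", name, f"unknown node_type {n.node_type!r}"))
            continue
        in_ok, out_ok, in_req, out_req = _PORT_RULES[n.node_type]
        if n.inputs and not in_ok:
            out.append(
                Violation(
                    "forbidden-input",
                    name,
                    f"{n.node_type} nodes can only transmit, yet declares inputs "
                    f"{[p.name for p in n.inputs]}",
                )
            )
        if n.outputs and not out_ok:
            out.append(
                Violation(
                    "forbidden-output",
                    name,
                    f"{n.node_type} nodes can only receive, yet declares outputs "
                    f"{[p.name for p in n.outputs]}",
                )
            )
        if in_req and not n.inputs:
            out.append(Violation("missing-input", name, f"{n.node_type} requires at least one input"))
        if out_req and not n.outputs:
            out.append(Violation("missing-output", name, f"{n.node_type} requires at least one output"))
        for direction, ports in (("input", n.inputs), ("output", n.outputs)):
            names = [p.name for p in ports]
            for dup in sorted({x for x in names if names.count(x) > 1}):
                out.append(
                    Violation("duplicate-port", name, f"{direction} port {dup!r} declared twice")
                )
            for p in ports:
                if p.direction != direction:
                    out.append(
                        Violation(
                            "wrong-port-direction", name, f"port {p.name!r} has direction {p.direction!r}"
                        )
                    )
        pnames = [p.name for p in n.parameters]
        for dup in sorted({x for x in pnames if pnames.count(x) > 1}):
            out.append(Violation("duplicate-parameter", name, f"parameter {dup!r} declared twice"))

    by_name = {n.display_name: n for n in g.nodes}
    seen_edges: set = set()
    for e in g.edges:
        lid = e.link_id
        key = (e.from_node, e.from_output, e.to_node, e.to_input)
        if key in seen_edges:
            out.append(Violation("duplicate-edge", lid, "identical link declared twice"))
        seen_edges.add(key)
        src = by_name.get(e.from_node)
        dst = by_name.get(e.to_node)
        if src is None:
            out.append(Violation("unknown-node", lid, f"from_node {e.from_node!r} does not exist"))
        elif not any(p.name == e.from_output for p in src.outputs):
            out.append(
                Violation("unknown-port", lid, f"{e.from_node!r} has no output {e.from_output!r}")
            )
        if dst is None:
            out.append(Violation("unknown-node", lid, f"to_node {e.to_node!r} does not exist"))
        elif not any(p.name == e.to_input for p in dst.inputs):
            out.append(Violation("unknown-port", lid, f"{e.to_node!r} has no input {e.to_input!r}"))
    return out


def start_order(g: Graph) -> List[str]:
    """Node display names in authoring order — the order the engine starts them.

    Deliberately *not* a topological sort: cycles are legal, and the
    reference behaviour starts nodes in the order they were added.
    """
    violations = validate_graph(g)
    if violations:
        raise GraphValidationError(
            "graph is invalid: " + "; ".join(str(v) for v in violations)
        )
    return [n.display_name for n in g.nodes]
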