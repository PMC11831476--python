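"""Extraction of the layered aversive-olfactory-learning circuit.

Starting from a small seed set of learning-correlated neurons (sensory seeds,
interneuron seeds, motor seeds), the extractor keeps only the strongest
synaptic routes through the clustered connectome, tracing at most two steps,
and discards everything else. Retention follows three scenarios depending on
seed class:

sensory seed
    Rank the seed's outgoing connections by EW; among the top k, retain
    interneuron and motor targets with their edges. Each retained interneuron
    then extends one more step: among its top-k outgoing connections, retain
    motor targets.
interneuron seed
    Among the top-k incoming connections, retain sensory sources; among the
    top-k outgoing connections, retain motor targets.
motor seed
    Among the top-k incoming connections, retain sensory and interneuron
    sources; each retained interneuron extends upstream one more step to
    sensory sources among its own top-k incoming connections.

Directionality note: a neuron's "presynaptic connections" are its outgoing
edges (it is the presynaptic partner on them) and its "postsynaptic
connections" are its incoming edges.

By default the top-k ranking is computed over all neighbors first and the
class filter is applied to those k (rank slots can be consumed by
disallowed-class neighbors); ``filter_first=True`` restricts the ranking to
permitted classes before taking k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .connectome import Connectome, NeuronClass, ranked_neighbors
from .errors import ValidationError

__all__ = ["SeedSet", "Circuit", "trace_from_sensory", "trace_from_interneuron",
           "trace_to_motor", "extract_circuit", "sparseness"]

_LAYERS = ("sensory", "inter", "motor")
_ORDER = {("sensory", "inter"), ("sensory", "motor"), ("inter", "motor")}


@dataclass(frozen=True)
class SeedSet:
    """Learning-correlated seed neurons grouped by class."""

    sensory_seeds: tuple[str, ...] = ()
    inter_seeds: tuple[str, ...] = ()
    motor_seeds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        groups = (self.sensory_seeds, self.inter_seeds, self.motor_seeds)
        names = [n for g in groups for n in g]
        if len(set(names)) != len(names):
            raise ValidationError("seed groups must be disjoint")

    @property
    def all(self) -> tuple[str, ...]:
        return self.sensory_seeds + self.inter_seeds + self.motor_seeds

    def __len__(self) -> int:
        return len(self.all)

    def validate_against(self, conn: Connectome) -> None:
        for group, cls in ((self.sensory_seeds, NeuronClass.SENSORY),
                           (self.inter_seeds, NeuronClass.INTER),
                           (self.motor_seeds, NeuronClass.MOTOR)):
            for name in group:
                if name not in conn:
                    raise LookupError(f"seed {name!r} is not in the connectome")
                if conn.class_of(name) is not cls:
                    raise ValidationError(
                        f"seed {name!r} is {conn.class_of(name).value}, "
                        f"expected {cls.value}"
                    )


class Circuit:
    """Layered directed subgraph retained by the extraction procedure.

    Nodes carry a layer (sensory/inter/motor); edges carry the EW of the
    source connectome edge plus a provenance record listing which seed and
    scenario step retained them.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, str] = {}           # name -> layer
        self.edges: dict[tuple[str, str], int] = {}   # (pre, post) -> EW
        self.provenance: dict[tuple[str, str], list[str]] = {}

    # -- construction -------------------------------------------------
    def add_node(self, name: str, layer: str) -> None:
        if layer not in _LAYERS:
            raise ValidationError(f"invalid layer {layer!r} for node {name!r}")
        if self.nodes.get(name, layer) != layer:
            raise ValidationError(f"conflicting layers for node {name!r}")
        self.nodes[name] = layer

    def add_edge(self, pre: str, post: str, ew: int, tag: str = "") -> None:
        if pre not in self.nodes or post not in self.nodes:
            raise ValidationError(f"edge {pre}->{post} references unknown node")
        if (self.nodes[pre], self.nodes[post]) not in _ORDER:
            raise ValidationError(
                f"edge {pre}->{post} violates layer ordering "
                f"({self.nodes[pre]} -> {self.nodes[post]})"
            )
        self.edges[(pre, post)] = ew
        if tag:
            self.provenance.setdefault((pre, post), []).append(tag)

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def layer_counts(self) -> dict[str, int]:
        out = {layer: 0 for layer in _LAYERS}
        for layer in self.nodes.values():
            out[layer] += 1
        return out

    def nodes_in_layer(self, layer: str) -> list[str]:
        return sorted(n for n, l in self.nodes.items() if l == layer)

    def predecessors(self, name: str) -> list[str]:
        return sorted(p for (p, q) in self.edges if q == name)

    def successors(self, name: str) -> list[str]:
        return sorted(q for (p, q) in self.edges if p == name)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name, layer in self.nodes.items():
            g.add_node(name, layer=layer)
        for (p, q), ew in self.edges.items():
            g.add_edge(p, q, EW=ew)
        return g

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [{"name": n, "layer": l}
                      for n, l in sorted(self.nodes.items())],
            "edges": [{"pre": p, "post": q, "EW": ew,
                       "provenance": self.provenance.get((p, q), [])}
                      for (p, q), ew in sorted(self.edges.items())],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "Circuit":
        c = cls()
        for node in payload["nodes"]:
            c.add_node(node["name"], node["layer"])
        for e in payload["edges"]:
            c.add_edge(e["pre"], e["post"], int(e["EW"]))
            if e.get("provenance"):
                c.provenance[(e["pre"], e["post"])] = list(e["provenance"])
        return c

    @classmethod
    def from_json(cls, path: str | Path) -> "Circuit":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def _top_k(conn: Connectome, node: str, direction: str, k: int,
           allowed: set[NeuronClass], filter_first: bool) -> list[tuple[str, int]]:
    """Neighbors retained by the rank-then-filter (default) or
    filter-then-rank reading of 'the k strongest connections'."""
    if filter_first:
        if direction == "downstream":
            pairs = [(e.post, e.EW) for e in conn.out_edges(node)
                     if conn.class_of(e.post) in allowed]
        else:
            pairs = [(e.pre, e.EW) for e in conn.in_edges(node)
                     if conn.class_of(e.pre) in allowed]
        pairs.sort(key=lambda t: (-t[1], t[0]))
        return pairs[:k]
    ranked = ranked_neighbors(conn, node, direction, k)
    return [(n, ew) for n, ew in ranked if conn.class_of(n) in allowed]


def _require_class(conn: Connectome, seed: str, cls: NeuronClass) -> None:
    actual = conn.class_of(seed)   # raises LookupError for unknown names
    if actual is not cls:
        raise ValidationError(
            f"seed {seed!r} is a {actual.value} neuron, expected {cls.value}"
        )


def trace_from_sensory(conn: Connectome, seed: str, k: int = 3,
                       filter_first: bool = False) -> Circuit:
    """Scenario with a sensory neuron as the starting point (two steps down)."""
    _require_class(conn, seed, NeuronClass.SENSORY)
    c = Circuit()
    c.add_node(seed, "sensory")
    step1 = _top_k(conn, seed, "downstream", k,
                   {NeuronClass.INTER, NeuronClass.MOTOR}, filter_first)
    for target, ew in step1:
        layer = "inter" if conn.class_of(target) is NeuronClass.INTER else "motor"
        c.add_node(target, layer)
        c.add_edge(seed, target, ew, f"sensory:{seed}:step1")
    for target, _ in step1:
        if conn.class_of(target) is not NeuronClass.INTER:
            continue  # motor targets terminate their branch
        step2 = _top_k(conn, target, "downstream", k,
                       {NeuronClass.MOTOR}, filter_first)
        for motor, ew in step2:
            c.add_node(motor, "motor")
            c.add_edge(target, motor, ew, f"sensory:{seed}:step2")
    return c


def trace_from_interneuron(conn: Connectome, seed: str, k: int = 3,
                           filter_first: bool = False) -> Circuit:
    """Scenario with an interneuron as intermediary (one step each way)."""
    _require_class(conn, seed, NeuronClass.INTER)
    c = Circuit()
    c.add_node(seed, "inter")
    for source, ew in _top_k(conn, seed, "upstream", k,
                             {NeuronClass.SENSORY}, filter_first):
        c.add_node(source, "sensory")
        c.add_edge(source, seed, ew, f"inter:{seed}:upstream")
    for target, ew in _top_k(conn, seed, "downstream", k,
                             {NeuronClass.MOTOR}, filter_first):
        c.add_node(target, "motor")
        c.add_edge(seed, target, ew, f"inter:{seed}:downstream")
    return c


def trace_to_motor(conn: Connectome, seed: str, k: int = 3,
                   filter_first: bool = False) -> Circuit:
    """Scenario with a motor neuron as terminal (two steps upstream)."""
    _require_class(conn, seed, NeuronClass.MOTOR)
    c = Circuit()
    c.add_node(seed, "motor")
    step1 = _top_k(conn, seed, "upstream", k,
                   {NeuronClass.SENSORY, NeuronClass.INTER}, filter_first)
    for source, ew in step1:
        layer = "inter" if conn.class_of(source) is NeuronClass.INTER else "sensory"
        c.add_node(source, layer)
        c.add_edge(source, seed, ew, f"motor:{seed}:step1")
    for source, _ in step1:
        if conn.class_of(source) is not NeuronClass.INTER:
            continue
        for sens, ew in _top_k(conn, source, "upstream", k,
                               {NeuronClass.SENSORY}, filter_first):
            c.add_node(sens, "sensory")
            c.add_edge(sens, source, ew, f"motor:{seed}:step2")
    return c


_SEED_LAYER = {NeuronClass.SENSORY: "sensory", NeuronClass.INTER: "inter",
               NeuronClass.MOTOR: "motor"}


def extract_circuit(conn: Connectome, seeds: SeedSet, k: int = 3,
                    filter_first: bool = False) -> Circuit:
    """Union of the per-seed traces; all seeds are retained unconditionally."""
    if not conn.clustered:
        raise ValidationError("extraction expects a functionally clustered connectome")
    if len(seeds) == 0:
        raise ValidationError("seed set is empty")
    seeds.validate_against(conn)
    out = Circuit()
    for name in seeds.all:
        out.add_node(name, _SEED_LAYER[conn.class_of(name)])
    traces = (
        [trace_from_sensory(conn, s, k, filter_first) for s in seeds.sensory_seeds]
        + [trace_from_interneuron(conn, s, k, filter_first) for s in seeds.inter_seeds]
        + [trace_to_motor(conn, s, k, filter_first) for s in seeds.motor_seeds]
    )
    for tr in traces:
        for name, layer in tr.nodes.items():
            out.add_node(name, layer)
        for (p, q), ew in tr.edges.items():
            out.add_edge(p, q, ew)
            for tag in tr.provenance.get((p, q), []):
                out.provenance.setdefault((p, q), []).append(tag)
    return out


def sparseness(circuit: Circuit) -> tuple[float, int]:
    """Realized connections as a percent of all ordered node pairs (n^2,
    self-pairs included). Returns (exact percent, nearest-integer percent)."""
    n = circuit.n_nodes
    if n < 1:
        raise ValidationError("sparseness needs at least one node")
    exact = 100.0 * circuit.n_edges / (n * n)
    return exact, round(exact)
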