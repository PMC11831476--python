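"""Connectome data model and I/O.

A connectome is a directed multigraph of named neurons. Each directed edge
(pre, post) carries two nonnegative integer counts: ``C``, the number of
chemical synapses (directional, generally asymmetric), and ``E``, the number
of electrical gap junctions (bidirectional, so ``E_ij == E_ji``). The edge
weight used everywhere downstream is their sum ``EW = C + E``, the total
number of synaptic contacts on the connection.

Functional clustering merges bilateral (or otherwise functionally analogous)
neuron pairs such as ADAL/ADAR into a single functional unit (ADA), summing
their synapse counts; neurons with distinct roles (e.g. ASEL vs ASER) keep
separate identities under an identity mapping.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

__all__ = [
    "NeuronClass",
    "NeuronRecord",
    "SynapseEdge",
    "Connectome",
    "edge_weight",
    "read_connectome",
    "write_connectome",
    "cluster_functional",
    "ranked_neighbors",
]


class NeuronClass(str, Enum):
    SENSORY = "sensory"
    INTER = "inter"
    MOTOR = "motor"
    PHARYNGEAL = "pharyngeal"
    OTHER = "other"


@dataclass(frozen=True)
class NeuronRecord:
    """A neuron (raw or functional unit) in the wiring diagram."""

    name: str
    neuron_class: NeuronClass = NeuronClass.OTHER
    functional_group: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("neuron name must be nonempty")
        if not self.functional_group:
            object.__setattr__(self, "functional_group", self.name)


@dataclass(frozen=True)
class SynapseEdge:
    """Directed connection with chemical count C and electrical count E."""

    pre: str
    post: str
    C: int
    E: int

    def __post_init__(self) -> None:
        if self.C < 0 or self.E < 0:
            raise ValidationError(
                f"negative synapse count on edge {self.pre}->{self.post}"
            )

    @property
    def EW(self) -> int:
        return edge_weight(self.C, self.E)


def edge_weight(C: int, E: int) -> int:
    """Total synaptic contact count ``EW = C + E`` of a directed connection."""
    if C < 0 or E < 0:
        raise ValidationError(f"synapse counts must be nonnegative, got C={C} E={E}")
    return C + E


class Connectome:
    """Directed graph of neurons with per-edge chemical/electrical counts.

    Zero-weight edges are never stored; adding rows with an existing
    (pre, post) key accumulates the counts.
    """

    def __init__(self, clustered: bool = False) -> None:
        self.neurons: dict[str, NeuronRecord] = {}
        self.edges: dict[tuple[str, str], SynapseEdge] = {}
        self.clustered = clustered

    # -- construction -------------------------------------------------
    def add_neuron(self, rec: NeuronRecord | str,
                   neuron_class: NeuronClass | str = NeuronClass.OTHER) -> None:
        if isinstance(rec, str):
            rec = NeuronRecord(rec, NeuronClass(neuron_class))
        existing = self.neurons.get(rec.name)
        if existing is not None and existing != rec:
            # metadata upgrade is allowed, silent duplicates of same record ok
            if existing.neuron_class is NeuronClass.OTHER:
                self.neurons[rec.name] = rec
                return
            if rec.neuron_class is not NeuronClass.OTHER:
                raise ValidationError(f"conflicting records for neuron {rec.name}")
            return
        self.neurons[rec.name] = rec

    def add_edge(self, pre: str, post: str, C: int = 0, E: int = 0) -> None:
        if C < 0 or E < 0:
            raise ValidationError(f"negative count on edge {pre}->{post}")
        for name in (pre, post):
            if name not in self.neurons:
                self.add_neuron(name)
        key = (pre, post)
        if key in self.edges:
            old = self.edges[key]
            C, E = old.C + C, old.E + E
        if C + E == 0:
            return
        self.edges[key] = SynapseEdge(pre, post, C, E)

    # -- queries ------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self.neurons

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def class_of(self, name: str) -> NeuronClass:
        try:
            return self.neurons[name].neuron_class
        except KeyError:
            raise LookupError(f"unknown neuron {name!r}") from None

    def out_edges(self, name: str) -> list[SynapseEdge]:
        if name not in self.neurons:
            raise LookupError(f"unknown neuron {name!r}")
        return [e for (p, _), e in self.edges.items() if p == name]

    def in_edges(self, name: str) -> list[SynapseEdge]:
        if name not in self.neurons:
            raise LookupError(f"unknown neuron {name!r}")
        return [e for (_, q), e in self.edges.items() if q == name]

    def total_synapses(self) -> int:
        return sum(e.EW for e in self.edges.values())

    def check_electrical_symmetry(self) -> None:
        """Gap junctions couple both directions: require E_ij == E_ji."""
        for (pre, post), e in self.edges.items():
            if e.E > 0:
                rev = self.edges.get((post, pre))
                if rev is None or rev.E != e.E:
                    raise ValidationError(
                        f"electrical asymmetry: E({pre}->{post})={e.E} but "
                        f"E({post}->{pre})={rev.E if rev else 'absent'}"
                    )

    # -- export -------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(clustered=self.clustered)
        for rec in self.neurons.values():
            g.add_node(rec.name, neuron_class=rec.neuron_class.value,
                       functional_group=rec.functional_group)
        for e in self.edges.values():
            g.add_edge(e.pre, e.post, C=e.C, E=e.E, EW=e.EW)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_connectome(path: str | Path,
                    neuron_meta: str | Path | None = None,
                    symmetrize_electrical: bool = False) -> Connectome:
    """Read a directed edge table with columns pre, post, C, E.

    Rows sharing a (pre, post) key are summed; rows with C+E == 0 are
    dropped. With ``symmetrize_electrical`` a table that lists each gap
    junction on a single orientation is mirrored so that E_ij == E_ji.
    ``neuron_meta`` optionally points to a two-column table (name, class)
    assigning neuron classes.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path))
    for col in ("pre", "post", "C", "E"):
        if col not in df.columns:
            raise FormatError(f"edge table {path} is missing column {col!r}")
    conn = Connectome()
    meta: dict[str, NeuronClass] = {}
    if neuron_meta is not None:
        meta_path = Path(neuron_meta)
        mdf = pd.read_csv(meta_path, sep=_delimiter_for(meta_path))
        for col in ("name", "class"):
            if col not in mdf.columns:
                raise FormatError(f"neuron metadata is missing column {col!r}")
        meta = {str(r["name"]): NeuronClass(str(r["class"]))
                for _, r in mdf.iterrows()}
    for i, row in df.iterrows():
        c, e = int(row["C"]), int(row["E"])
        if c < 0 or e < 0:
            raise ValidationError(f"negative synapse count at row {i + 1} of {path}")
        pre, post = str(row["pre"]), str(row["post"])
        conn.add_edge(pre, post, c, e)
        if symmetrize_electrical and e > 0:
            conn.add_edge(post, pre, 0, e)
    if symmetrize_electrical:
        # mirroring may have doubled E on pairs listed in both orientations;
        # reconcile to the max of the two accumulated values
        for (pre, post), edge in list(conn.edges.items()):
            rev = conn.edges.get((post, pre))
            if edge.E and rev is not None and rev.E != edge.E:
                target = max(edge.E, rev.E)
                conn.edges[(pre, post)] = SynapseEdge(pre, post, edge.C, target)
                conn.edges[(post, pre)] = SynapseEdge(post, pre, rev.C, target)
    for name, cls in meta.items():
        if name in conn.neurons:
            conn.neurons[name] = NeuronRecord(name, cls)
        else:
            conn.add_neuron(NeuronRecord(name, cls))
    return conn


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Write the edge table back out (pre, post, C, E; stable sort order)."""
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["pre", "post", "C", "E"])
        for key in sorted(conn.edges):
            e = conn.edges[key]
            w.writerow([e.pre, e.post, e.C, e.E])


def cluster_functional(conn: Connectome,
                       merge_map: Mapping[str, str]) -> Connectome:
    """Merge raw neurons into functional units and aggregate their synapses.

    Every raw name must appear in ``merge_map`` (identity entries allowed).
    Counts for each ordered pair of groups are the sums over constituent raw
    edges; self-edges created by a merge are dropped, since a unit's internal
    synapses carry no inter-unit information flow.
    """
    if conn.clustered:
        raise ValidationError("connectome is already clustered")
    missing = sorted(set(conn.neurons) - set(merge_map))
    if missing:
        raise ValidationError(f"merge map is missing neurons: {', '.join(missing)}")
    out = Connectome(clustered=True)
    for rec in conn.neurons.values():
        group = merge_map[rec.name]
        if group in out.neurons:
            prev = out.neurons[group]
            cls = prev.neuron_class
            if cls is NeuronClass.OTHER:
                cls = rec.neuron_class
            out.neurons[group] = NeuronRecord(group, cls, group)
        else:
            out.add_neuron(NeuronRecord(group, rec.neuron_class, group))
    for e in conn.edges.values():
        gp, gq = merge_map[e.pre], merge_map[e.post]
        if gp == gq:
            continue
        out.add_edge(gp, gq, e.C, e.E)
    return out


def ranked_neighbors(conn: Connectome, node: str, direction: str,
                     k: int) -> list[tuple[str, int]]:
    """The k strongest neighbors of ``node`` by edge weight EW.

    ``downstream`` ranks outgoing edges, ``upstream`` incoming ones. Sorting
    is by EW descending with ties broken by neighbor name ascending, which
    keeps extraction deterministic.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if direction == "downstream":
        pairs = [(e.post, e.EW) for e in conn.out_edges(node)]
    elif direction == "upstream":
        pairs = [(e.pre, e.EW) for e in conn.in_edges(node)]
    else:
        raise UsageError(f"direction must be downstream or upstream, got {direction!r}")
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return pairs[:k]
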