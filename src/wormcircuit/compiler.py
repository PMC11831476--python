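"""Compilation of a layered neural circuit into a convolutional classifier.

Each circuit neuron becomes a convolutional block and each synaptic
connection becomes an information-flow path between blocks. A stem
convolution feeds every source block (the sensory layer), the outputs of the
motor-layer blocks (plus any other sink) are aggregated into a head of one
convolution, pooling and a stack of fully connected layers, and a single
scale variable ``m`` multiplies every width that is marked scalable, sweeping
the model family across parameter budgets. Synaptic weights (EW) are carried
as metadata only; the compilation maps topology, not strength.

The shipped default widths were calibrated so that the analytic parameter
count of the 22-neuron worm circuit on 3x32x32/10-class input reproduces the
published model-size table exactly for m = 1..8 (151142 parameters at m = 1
up to 1416686 at m = 8). The calibration procedure — an exhaustive integer
search over stem/block/head widths, kernels and classifier sizes against the
printed counts — is documented in the methods note; the published source does
not print per-layer hyperparameters, so these values are a reconstruction,
not a transcription.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx

from .errors import UsageError, ValidationError
from .extraction import Circuit

__all__ = ["CompilerConfig", "ConvBlock", "ArchitectureSpec", "ParameterCount",
           "compile_architecture", "count_parameters", "randomize_circuit",
           "baseline_architecture", "scale_width"]


def scale_width(base: float, m: float) -> int:
    """Width after scaling: round(base * m), half away from zero, floor 1."""
    w = int(base * m + 0.5)
    if w < 1:
        warnings.warn(f"width {base}*{m} rounds below 1; clamped to 1")
        return 1
    return w


@dataclass
class CompilerConfig:
    """Layer hyperparameters of the compiled family.

    Defaults are the calibrated values reproducing the published parameter
    counts of the worm model (see module docstring). ``fc_hidden`` widths are
    fixed (not scaled by m); conv widths scale.
    """

    stem_width: int = 43
    block_width: int = 2
    head_width: int = 24
    stem_kernel: int = 3
    block_kernel: int = 3
    head_kernel: int = 3
    stem_pool: int = 2            # max-pool window after the stem
    head_pool_to: int = 2         # adaptive average-pool output size
    fc_hidden: tuple[int, ...] = (790, 78, 10)
    fc_hidden_bias: bool = False
    fc_activation: str = "leaky_relu"   # bias-free hidden units can recover
    fc_out_bias: bool = True
    conv_bias: bool = True
    aggregation: str = "concat"   # or "sum"

    @classmethod
    def from_json(cls, path: str | Path) -> "CompilerConfig":
        payload = json.loads(Path(path).read_text())
        payload["fc_hidden"] = tuple(payload.get("fc_hidden", cls.fc_hidden))
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["fc_hidden"] = list(self.fc_hidden)
        Path(path).write_text(json.dumps(d, indent=1) + "\n")


@dataclass
class ConvBlock:
    """One convolutional block compiled from a circuit neuron."""

    name: str
    in_channels: int
    out_channels: int
    kernel: int = 3
    bias: bool = True
    activation: str = "relu"

    def n_params(self) -> int:
        n = self.kernel * self.kernel * self.in_channels * self.out_channels
        if self.bias:
            n += self.out_channels
        return n


@dataclass
class ParameterCount:
    total: int
    per_block: dict[str, int]


class ArchitectureSpec:
    """DAG of convolution blocks plus stem and head, or a plain chain.

    Compiled circuit models populate ``stem``/``blocks``/``head``; baseline
    models populate ``sequential`` instead. Layer descriptors are dicts with a
    ``type`` key (conv, fc, maxpool, adaptive_avg_pool, flatten).
    """

    def __init__(self, input_shape: tuple[int, int, int], n_classes: int,
                 scale_m: float, aggregation: str = "concat") -> None:
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.scale_m = scale_m
        self.aggregation = aggregation
        self.stem: list[dict] = []
        self.blocks: dict[str, ConvBlock] = {}
        self.block_inputs: dict[str, list[str]] = {}
        self.block_edges: list[tuple[str, str]] = []
        self.head_inputs: list[str] = []
        self.head: list[dict] = []
        self.sequential: list[dict] | None = None
        self.metadata: dict = {}

    # -- structure ----------------------------------------------------
    def topological_blocks(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.blocks)
        g.add_edges_from(self.block_edges)
        return [n for n in nx.lexicographical_topological_sort(g)]

    def block_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.blocks)
        g.add_edges_from(self.block_edges)
        return g

    # -- shape propagation --------------------------------------------
    def propagate_shapes(self) -> int:
        """Symbolically push the input shape through to the classifier output.

        Returns the final feature count and raises if any stage is
        inconsistent (it must end at ``n_classes``).
        """
        c, h, w = self.input_shape
        if self.sequential is not None:
            c = self._run_chain(self.sequential, c, [h, w])
        else:
            hw = [h, w]
            c = self._run_chain(self.stem, c, hw)
            widths = {"stem": c}
            for name in self.topological_blocks():
                blk = self.blocks[name]
                ins = [widths[p] for p in self.block_inputs[name]]
                expect = sum(ins) if self.aggregation == "concat" else max(ins)
                if expect != blk.in_channels:
                    raise ValidationError(
                        f"block {name!r}: input channels {blk.in_channels} "
                        f"inconsistent with aggregated {expect}"
                    )
                widths[name] = blk.out_channels
            head_in = (sum(widths[p] for p in self.head_inputs)
                       if self.aggregation == "concat"
                       else max(widths[p] for p in self.head_inputs))
            c = self._run_chain(self.head, head_in, hw)
        if c != self.n_classes:
            raise ValidationError(
                f"classifier ends at {c} features, expected {self.n_classes}"
            )
        return c

    @staticmethod
    def _run_chain(layers: list[dict], c: int, hw: list[int]) -> int:
        flat = False
        for ly in layers:
            t = ly["type"]
            if t == "conv":
                if ly["in"] != c:
                    raise ValidationError(
                        f"conv expects {ly['in']} channels, got {c}"
                    )
                c = ly["out"]
            elif t == "maxpool":
                hw[0] //= ly["size"]
                hw[1] //= ly["size"]
                if hw[0] < 1 or hw[1] < 1:
                    raise ValidationError("pooling below 1x1")
            elif t == "adaptive_avg_pool":
                hw[0] = hw[1] = ly["size"]
            elif t == "flatten":
                c = c * hw[0] * hw[1]
                flat = True
            elif t == "fc":
                if not flat:
                    raise ValidationError("fc before flatten")
                if ly["in"] != c:
                    raise ValidationError(
                        f"fc expects {ly['in']} features, got {c}"
                    )
                c = ly["out"]
            else:
                raise UsageError(f"unknown layer type {t!r}")
        return c

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "scale_m": self.scale_m,
            "aggregation": self.aggregation,
            "stem": self.stem,
            "blocks": {k: asdict(v) for k, v in self.blocks.items()},
            "block_inputs": self.block_inputs,
            "block_edges": [list(e) for e in self.block_edges],
            "head_inputs": self.head_inputs,
            "head": self.head,
            "sequential": self.sequential,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        spec = cls(tuple(d["input_shape"]), d["n_classes"], d["scale_m"],
                   d.get("aggregation", "concat"))
        spec.stem = d.get("stem", [])
        spec.blocks = {k: ConvBlock(**v) for k, v in d.get("blocks", {}).items()}
        spec.block_inputs = {k: list(v) for k, v in d.get("block_inputs", {}).items()}
        spec.block_edges = [tuple(e) for e in d.get("block_edges", [])]
        spec.head_inputs = list(d.get("head_inputs", []))
        spec.head = d.get("head", [])
        spec.sequential = d.get("sequential")
        spec.metadata = d.get("metadata", {})
        return spec

    @classmethod
    def from_json(cls, path: str | Path) -> "ArchitectureSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compile_architecture(circuit: Circuit, m: float,
                         input_shape: tuple[int, int, int],
                         n_classes: int,
                         config: CompilerConfig | None = None) -> ArchitectureSpec:
    """Compile a layered circuit into a convolutional architecture.

    One block per neuron, one information-flow path per synapse. Source
    blocks (no upstream circuit edge) read the stem output; the motor layer
    and any other sink feed the head. Multi-input blocks aggregate by channel
    concatenation by default (``config.aggregation = "sum"`` adds instead,
    which requires equal input widths and is intended for parameter-count
    sensitivity studies).
    """
    cfg = config or CompilerConfig()
    if m <= 0:
        raise ValidationError(f"scale m must be positive, got {m}")
    if n_classes < 2:
        raise ValidationError("need at least two classes")
    g = circuit.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("circuit contains a cycle; cannot compile")

    spec = ArchitectureSpec(input_shape, n_classes, m, cfg.aggregation)
    stem_w = scale_width(cfg.stem_width, m)
    block_w = scale_width(cfg.block_width, m)
    head_w = scale_width(cfg.head_width, m)

    spec.stem = [
        {"type": "conv", "in": input_shape[0], "out": stem_w,
         "kernel": cfg.stem_kernel, "bias": cfg.conv_bias, "activation": "relu"},
        {"type": "maxpool", "size": cfg.stem_pool},
    ]

    order = sorted(circuit.nodes)
    widths = {"stem": stem_w}
    for name in order:
        preds = circuit.predecessors(name)
        inputs = preds if preds else ["stem"]
        if cfg.aggregation == "concat":
            in_ch = sum(widths.get(p, block_w) for p in inputs)
        else:
            in_set = {widths.get(p, block_w) for p in inputs}
            if len(in_set) > 1:
                raise ValidationError(
                    f"sum aggregation requires equal input widths at {name!r}"
                )
            in_ch = in_set.pop()
        spec.blocks[name] = ConvBlock(name, in_ch, block_w,
                                      kernel=cfg.block_kernel,
                                      bias=cfg.conv_bias)
        spec.block_inputs[name] = inputs
        widths[name] = block_w
    spec.block_edges = sorted(circuit.edges)

    sinks = {n for n in circuit.nodes if not circuit.successors(n)}
    head_in_names = sorted({n for n, l in circuit.nodes.items()
                            if l == "motor"} | sinks)
    spec.head_inputs = head_in_names
    if cfg.aggregation == "concat":
        head_in = block_w * len(head_in_names)
    else:
        head_in = block_w
    flat = head_w * cfg.head_pool_to ** 2
    spec.head = [
        {"type": "conv", "in": head_in, "out": head_w,
         "kernel": cfg.head_kernel, "bias": cfg.conv_bias, "activation": "relu"},
        {"type": "adaptive_avg_pool", "size": cfg.head_pool_to},
        {"type": "flatten"},
    ]
    prev = flat
    for width in cfg.fc_hidden:
        # leaky slope keeps narrow bias-free hidden units recoverable
        spec.head.append({"type": "fc", "in": prev, "out": width,
                          "bias": cfg.fc_hidden_bias,
                          "activation": cfg.fc_activation})
        prev = width
    spec.head.append({"type": "fc", "in": prev, "out": n_classes,
                      "bias": cfg.fc_out_bias, "activation": None})
    spec.metadata = {
        "edge_EW": {f"{p}->{q}": ew for (p, q), ew in sorted(circuit.edges.items())},
        "layers": {n: l for n, l in sorted(circuit.nodes.items())},
    }
    spec.propagate_shapes()
    return spec


def _chain_params(layers: list[dict]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i, ly in enumerate(layers):
        if ly["type"] == "conv":
            n = ly["kernel"] ** 2 * ly["in"] * ly["out"]
            if ly.get("bias", True):
                n += ly["out"]
            counts[f"{i}:conv"] = n
        elif ly["type"] == "fc":
            n = ly["in"] * ly["out"]
            if ly.get("bias", True):
                n += ly["out"]
            counts[f"{i}:fc"] = n
    return counts


def count_parameters(arch: ArchitectureSpec) -> ParameterCount:
    """Exact trainable-parameter count, computed analytically from the spec.

    Matches the instantiated model's count array-for-array (checked in the
    test suite against the runtime engine).
    """
    per: dict[str, int] = {}
    if arch.sequential is not None:
        for key, n in _chain_params(arch.sequential).items():
            per[key] = n
    else:
        per["stem"] = sum(_chain_params(arch.stem).values())
        for name, blk in arch.blocks.items():
            per[name] = blk.n_params()
        per["head"] = sum(_chain_params(arch.head).values())
    return ParameterCount(total=sum(per.values()), per_block=per)


def randomize_circuit(circuit: Circuit, seed: int,
                      preserve_layers: bool = True,
                      avoid_isolated: bool = True,
                      max_retries: int = 100) -> Circuit:
    """Degree-agnostic null model: same nodes, same edge count, random wiring.

    Edges are re-drawn uniformly at random among layer-respecting ordered
    pairs (sensory->inter, sensory->motor, inter->motor), without duplicates;
    acyclicity is automatic under the layer ordering. With
    ``preserve_layers=False`` the permitted pairs are all ordered pairs that
    follow a fixed topological order of the nodes (free-layer mode). When
    ``avoid_isolated`` is set, draws leaving any node with no incident edge
    are rejected and re-sampled up to ``max_retries`` times (then the last
    draw is kept), so the null stays close to uniform over permitted edge
    sets.
    """
    import numpy as np

    names = sorted(circuit.nodes)
    layers = dict(circuit.nodes)
    if preserve_layers:
        rank = {"sensory": 0, "inter": 1, "motor": 2}
        permitted = [(p, q) for p in names for q in names
                     if (layers[p], layers[q]) in
                     {("sensory", "inter"), ("sensory", "motor"),
                      ("inter", "motor")}]
    else:
        order = sorted(names, key=lambda n: ({"sensory": 0, "inter": 1,
                                              "motor": 2}[layers[n]], n))
        idx = {n: i for i, n in enumerate(order)}
        permitted = [(p, q) for p in names for q in names
                     if idx[p] < idx[q]]
    n_edges = circuit.n_edges
    if n_edges > len(permitted):
        raise ValidationError(
            f"cannot place {n_edges} edges among {len(permitted)} permitted pairs"
        )
    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    for attempt in range(max_retries + 1):
        pick = rng.choice(len(permitted), size=n_edges, replace=False)
        chosen = [permitted[i] for i in pick]
        if not avoid_isolated:
            break
        touched = {n for e in chosen for n in e}
        if len(touched) == len(names):
            break
    out = Circuit()
    for n in names:
        if preserve_layers:
            out.add_node(n, layers[n])
        else:
            out.nodes[n] = layers[n]   # free mode may break layer ordering
    for p, q in sorted(chosen):
        if preserve_layers:
            out.add_edge(p, q, 1, "randomized")
        else:
            out.edges[(p, q)] = 1
            out.provenance[(p, q)] = ["randomized"]
    return out


_BASELINES = {"lenet5", "alexnet"}


def baseline_architecture(name: str, m: float,
                          input_shape: tuple[int, int, int],
                          n_classes: int) -> ArchitectureSpec:
    """Classic sequential baselines with every width multiplied by m.

    ``lenet5``: conv 6@5x5 / pool / conv 16@5x5 / pool / FC 120 / FC 84.
    ``alexnet``: the common small-input adaptation with 3x3 convolutions
    (64, 192, 384, 256, 256) and two 4096-unit FC layers.
    """
    if name not in _BASELINES:
        raise UsageError(f"unsupported baseline {name!r}; choose from "
                         f"{sorted(_BASELINES)}")
    if m <= 0:
        raise ValidationError(f"scale m must be positive, got {m}")
    c, h, w = input_shape
    spec = ArchitectureSpec(input_shape, n_classes, m)
    sw = lambda base: scale_width(base, m)
    if name == "lenet5":
        w1, w2, f1, f2 = sw(6), sw(16), sw(120), sw(84)
        hh, ww = h // 2 // 2, w // 2 // 2
        spec.sequential = [
            {"type": "conv", "in": c, "out": w1, "kernel": 5, "bias": True,
             "activation": "relu"},
            {"type": "maxpool", "size": 2},
            {"type": "conv", "in": w1, "out": w2, "kernel": 5, "bias": True,
             "activation": "relu"},
            {"type": "maxpool", "size": 2},
            {"type": "flatten"},
            {"type": "fc", "in": w2 * hh * ww, "out": f1, "bias": True,
             "activation": "relu"},
            {"type": "fc", "in": f1, "out": f2, "bias": True,
             "activation": "relu"},
            {"type": "fc", "in": f2, "out": n_classes, "bias": True,
             "activation": None},
        ]
    else:
        widths = [sw(64), sw(192), sw(384), sw(256), sw(256)]
        f = sw(4096)
        hh, ww = h // 2 // 2 // 2, w // 2 // 2 // 2
        seq: list[dict] = []
        prev = c
        pool_after = {0, 1, 4}
        for i, out_w in enumerate(widths):
            seq.append({"type": "conv", "in": prev, "out": out_w, "kernel": 3,
                        "bias": True, "activation": "relu"})
            if i in pool_after:
                seq.append({"type": "maxpool", "size": 2})
            prev = out_w
        seq += [
            {"type": "flatten"},
            {"type": "fc", "in": prev * hh * ww, "out": f, "bias": True,
             "activation": "relu"},
            {"type": "fc", "in": f, "out": f, "bias": True,
             "activation": "relu"},
            {"type": "fc", "in": f, "out": n_classes, "bias": True,
             "activation": None},
        ]
        spec.sequential = seq
    spec.propagate_shapes()
    return spec
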