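"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's three input kinds, so the whole chain
is testable without any external download:

* :func:`gen_connectome` — a layered random digraph (sensory -> inter ->
  motor, with configurable within-layer and feedback wiring) with integer
  chemical counts and symmetric electrical counts, emulating the functional
  network's organization.
* :func:`gen_expression` — a gene x neuron proportion matrix with a planted
  subset of responsive neurons that soak up extra expression mass on the
  most strongly upregulated genes, plus the matching heavy-tailed fold-change
  vector. Ground truth is returned for parameter-recovery tests.
* :func:`gen_images` — class-conditional parametric images (distinct shape
  masks overlaid with class-specific grating textures, additive noise,
  optional spatial jitter and label noise) shaped like the small standard
  image-classification benchmarks.

:func:`load_published_fixtures` returns the packaged printed CRI table, the
11-neuron seed set, and the 22-node/21-edge circuit fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, NeuronClass, NeuronRecord
from .cri import (CRITable, ExpressionMatrix, FoldChangeVector,
                  _DATA_DIR, _verify_checksum, load_cri_fixture)
from .errors import ValidationError
from .extraction import Circuit, SeedSet

__all__ = ["SynthConnectomeParams", "SynthExpressionParams", "SynthImageParams",
           "gen_connectome", "gen_expression", "gen_images",
           "gen_image_arrays", "load_published_fixtures"]


# ------------------------------------------------------------- connectomes

_DEFAULT_DENSITIES = {
    ("sensory", "inter"): 0.20,
    ("sensory", "motor"): 0.05,
    ("inter", "motor"): 0.25,
    ("inter", "inter"): 0.10,
    ("sensory", "sensory"): 0.05,
    ("motor", "motor"): 0.05,
    ("inter", "sensory"): 0.03,
    ("motor", "inter"): 0.03,
    ("motor", "sensory"): 0.0,
}


@dataclass
class SynthConnectomeParams:
    """Layered random-connectome parameters.

    Default layer sizes mirror the 121-unit functional network's rough
    composition; chemical and electrical counts follow geometric
    distributions (integer, heavy-ish tail) resembling reported synapse-count
    dispersion, with electrical symmetry enforced.
    """

    n_sensory: int = 38
    n_inter: int = 45
    n_motor: int = 38
    densities: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    chemical_mean: float = 3.0
    electrical_density: float = 0.04
    electrical_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, d in self.densities.items():
            if not 0 <= d <= 1:
                raise ValidationError(f"density {d} for {pair} outside [0, 1]")
        if not 0 <= self.electrical_density <= 1:
            raise ValidationError("electrical density outside [0, 1]")
        if self.chemical_mean <= 0 or self.electrical_mean < 1:
            raise ValidationError("geometric means must be positive (E mean >= 1)")


def gen_connectome(p: SynthConnectomeParams) -> Connectome:
    """Seeded layered random digraph honoring connectome invariants."""
    rng = np.random.default_rng(p.seed)
    conn = Connectome(clustered=True)
    layers = {
        "sensory": [f"S{i:03d}" for i in range(p.n_sensory)],
        "inter": [f"I{i:03d}" for i in range(p.n_inter)],
        "motor": [f"M{i:03d}" for i in range(p.n_motor)],
    }
    cls = {"sensory": NeuronClass.SENSORY, "inter": NeuronClass.INTER,
           "motor": NeuronClass.MOTOR}
    for layer, names in layers.items():
        for n in names:
            conn.add_neuron(NeuronRecord(n, cls[layer]))
    all_names = [n for names in layers.values() for n in names]
    layer_of = {n: l for l, names in layers.items() for n in names}
    pc = min(1.0, 1.0 / p.chemical_mean)
    for pre in all_names:
        for post in all_names:
            if pre == post:
                continue
            d = p.densities.get((layer_of[pre], layer_of[post]), 0.0)
            if d and rng.random() < d:
                conn.add_edge(pre, post, int(rng.geometric(pc)), 0)
    pe = min(1.0, 1.0 / p.electrical_mean)
    for i, a in enumerate(all_names):
        for b in all_names[i + 1:]:
            if p.electrical_density and rng.random() < p.electrical_density:
                e = int(rng.geometric(pe))
                conn.add_edge(a, b, 0, e)
                conn.add_edge(b, a, 0, e)
    return conn


# ------------------------------------------------------------- expression

@dataclass
class SynthExpressionParams:
    """Parameters of the planted-neuron expression generator.

    Defaults mirror the study conditions: 338 differentially expressed genes
    scored over 121 functional neurons with 11 responsive units. Fold changes
    are heavy-tailed (Student-t, df 3, scale 10) and clipped to [-50, 50];
    the top ``responsive_frac`` of genes by fold change concentrate
    ``planted_effect`` times more expression mass in the planted neurons.
    """

    n_genes: int = 338
    n_neurons: int = 121
    n_planted: int = 11
    planted_effect: float = 10.0
    responsive_frac: float = 0.3
    t_df: float = 3.0
    t_scale: float = 10.0
    clip: tuple[float, float] = (-50.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_effect <= 0:
            raise ValidationError("planted_effect must be positive")
        if not 0 <= self.n_planted <= self.n_neurons:
            raise ValidationError("planted subset outside neuron range")
        if not 0 < self.responsive_frac <= 1:
            raise ValidationError("responsive_frac must be in (0, 1]")


def gen_expression(p: SynthExpressionParams
                   ) -> tuple[ExpressionMatrix, FoldChangeVector, list[str]]:
    """Planted-truth expression matrix, fold changes, and the planted set.

    Every row of W is a Dirichlet draw over neurons so rows sum to 1; for
    genes in the top ``responsive_frac`` by (signed) fold change, the planted
    neurons' Dirichlet weights are multiplied by ``planted_effect``. With
    effect 1 the planted set is statistically exchangeable with the rest.
    """
    rng = np.random.default_rng(p.seed)
    genes = [f"g{j:04d}" for j in range(p.n_genes)]
    neurons = [f"N{i:03d}" for i in range(p.n_neurons)]
    planted_idx = rng.choice(p.n_neurons, size=p.n_planted, replace=False)
    planted = sorted(neurons[i] for i in planted_idx)
    m = rng.standard_t(p.t_df, size=p.n_genes) * p.t_scale
    m = np.clip(m, *p.clip)
    cut = np.quantile(m, 1 - p.responsive_frac)
    responsive = m >= cut
    W = np.empty((p.n_genes, p.n_neurons))
    alpha0 = np.ones(p.n_neurons)
    alpha1 = alpha0.copy()
    alpha1[planted_idx] *= p.planted_effect
    for j in range(p.n_genes):
        W[j] = rng.dirichlet(alpha1 if responsive[j] else alpha0)
    wmat = ExpressionMatrix(pd.DataFrame(W, index=genes, columns=neurons))
    fold = FoldChangeVector(pd.Series(m, index=genes), clip_bounds=p.clip)
    return wmat, fold, planted


# ------------------------------------------------------------------ images

@dataclass
class SynthImageParams:
    """Class-conditional parametric image dataset parameters."""

    n_classes: int = 10
    train_per_class: int = 500
    test_per_class: int = 100
    size: int = 28
    channels: int = 1
    noise: float = 0.15
    jitter: int = 2
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if not 0 <= self.label_noise < 0.5:
            raise ValidationError("label noise must be in [0, 0.5)")


def _class_template(c: int, size: int) -> np.ndarray:
    """Deterministic shape-plus-texture template for class c, in [0, 1]."""
    y, x = np.mgrid[0:size, 0:size].astype(float) / (size - 1)
    cy, cx = y - 0.5, x - 0.5
    r = np.sqrt(cy ** 2 + cx ** 2)
    base = c % 10
    if base == 0:
        mask = (r < 0.33).astype(float)                      # disk
    elif base == 1:
        mask = ((np.abs(cy) < 0.33) & (np.abs(cx) < 0.33)).astype(float)
    elif base == 2:
        mask = ((np.abs(cy) < 0.10) | (np.abs(cx) < 0.10)).astype(float)
    elif base == 3:
        mask = ((r > 0.22) & (r < 0.40)).astype(float)       # ring
    elif base == 4:
        mask = (np.sin(2 * np.pi * 3 * y) > 0).astype(float)  # H stripes
    elif base == 5:
        mask = (np.sin(2 * np.pi * 3 * x) > 0).astype(float)  # V stripes
    elif base == 6:
        mask = (np.sin(2 * np.pi * 3 * (x + y)) > 0).astype(float)
    elif base == 7:
        mask = ((np.sin(2 * np.pi * 3 * x) > 0)
                ^ (np.sin(2 * np.pi * 3 * y) > 0)).astype(float)
    elif base == 8:
        mask = ((np.abs(cx + cy) < 0.12) | (r < 0.15)).astype(float)
    else:
        mask = ((np.abs(cy) > 0.36) | (np.abs(cx) > 0.36)).astype(float)
    theta = np.pi * c / 10.0
    freq = 3 + (c % 5)
    texture = 0.5 + 0.5 * np.sin(2 * np.pi * freq * (x * np.cos(theta)
                                                     + y * np.sin(theta)))
    return np.clip(0.1 + 0.55 * mask + 0.3 * texture, 0, 1)


def gen_image_arrays(p: SynthImageParams
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(X_train, y_train, X_test, y_test) arrays, NCHW float32 in [0, 1]."""
    rng = np.random.default_rng(p.seed)
    templates = [_class_template(c, p.size) for c in range(p.n_classes)]

    def make(n_per_class, rng):
        n = n_per_class * p.n_classes
        X = np.empty((n, p.channels, p.size, p.size), dtype=np.float32)
        y = np.repeat(np.arange(p.n_classes), n_per_class)
        for i, c in enumerate(y):
            img = templates[c]
            if p.jitter:
                dy, dx = rng.integers(-p.jitter, p.jitter + 1, size=2)
                img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            img = img + rng.normal(0, p.noise, img.shape) if p.noise else img
            X[i] = np.clip(img, 0, 1)[None, :, :]
        if p.label_noise:
            flip = rng.random(n) < p.label_noise
            y = y.copy()
            shift = rng.integers(1, p.n_classes, size=int(flip.sum()))
            y[flip] = (y[flip] + shift) % p.n_classes
        perm = rng.permutation(n)
        return X[perm], y[perm].astype(np.int64)

    X_tr, y_tr = make(p.train_per_class, rng)
    X_te, y_te = make(p.test_per_class, rng)
    return X_tr, y_tr, X_te, y_te


def gen_images(p: SynthImageParams, out_dir: str | Path) -> Path:
    """Write the dataset in directory layout (train/<class>/*.png etc.)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    X_tr, y_tr, X_te, y_te = gen_image_arrays(p)
    for split, X, y in (("train", X_tr, y_tr), ("test", X_te, y_te)):
        for i, (img, label) in enumerate(zip(X, y)):
            d = out / split / f"class_{label:03d}"
            d.mkdir(parents=True, exist_ok=True)
            arr = (img.transpose(1, 2, 0) * 255).astype(np.uint8)
            iio.imwrite(d / f"{i:06d}.png", arr.squeeze())
    return out


# ---------------------------------------------------------------- fixtures

def load_seed_fixture() -> SeedSet:
    """The 11 learning-correlated seed neurons (9 sensory + PVN + CAN)."""
    path = _DATA_DIR / "seed_neurons.txt"
    _verify_checksum(path)
    groups: dict[str, list[str]] = {"sensory": [], "inter": [], "motor": []}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, cls = line.split("\t")
        groups[cls].append(name)
    return SeedSet(tuple(groups["sensory"]), tuple(groups["inter"]),
                   tuple(groups["motor"]))


def load_circuit_fixture() -> Circuit:
    """The packaged 22-node / 21-edge aversive-learning circuit.

    The published wiring diagram is available only graphically; this fixture
    is a synthetic reconstruction that satisfies every printed constraint
    (22 nodes split 10 sensory / 5 inter / 7 motor, 21 layer-respecting
    edges, motors as sinks) and is interchangeable with a user-supplied
    transcription in the same JSON schema.
    """
    path = _DATA_DIR / "circuit_synthetic.json"
    _verify_checksum(path)
    return Circuit.from_json(path)


def load_published_fixtures() -> dict:
    """All packaged fixtures: {'cri_table', 'seed_set', 'circuit'}."""
    return {
        "cri_table": load_cri_fixture(),
        "seed_set": load_seed_fixture(),
        "circuit": load_circuit_fixture(),
    }
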