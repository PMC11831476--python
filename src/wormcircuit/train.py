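"""Training and evaluation of compiled architectures.

Three evaluation surfaces are reported per trained model: overall test
accuracy, the consistency of per-class accuracies (a dispersion statistic —
population standard deviation by default, lower meaning more consistent),
and the convergence behavior of the training-loss curve (steps to plateau
and an overfitting flag).

The training protocol defaults — cross-entropy loss, Adam at a fixed
learning rate of 1e-3, batch size 128, 30 epochs, no augmentation — are a
reproducible baseline configuration; they are recorded in every report's
``config_snapshot``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .compiler import ArchitectureSpec
from .errors import UsageError, ValidationError
from .nnengine import Adam, Model, softmax_cross_entropy

__all__ = ["DatasetSpec", "TrainConfig", "TrainingReport", "train",
           "evaluate", "consistency", "convergence_summary",
           "STANDARD_DATASETS"]

#: name -> (channels, height, width, n_classes, n_train, n_test)
STANDARD_DATASETS = {
    "mnist": (1, 28, 28, 10, 60000, 10000),
    "fashionmnist": (1, 28, 28, 10, 60000, 10000),
    "cifar10": (3, 32, 32, 10, 50000, 10000),
    "cifar100": (3, 32, 32, 100, 50000, 10000),
}


@dataclass
class DatasetSpec:
    name: str
    channels: int
    height: int
    width: int
    n_classes: int
    n_train: int
    n_test: int
    source: str = "synthetic"      # standard_download | directory | synthetic
    path: str | None = None
    noise: float = 0.15
    jitter: int = 2
    label_noise: float = 0.0
    normalize: bool = True         # center pixel values to [-0.5, 0.5]

    def __post_init__(self) -> None:
        if min(self.channels, self.height, self.width, self.n_classes) < 1:
            raise ValidationError("dataset dimensions must be positive")
        if self.name in STANDARD_DATASETS:
            expected = STANDARD_DATASETS[self.name]
            actual = (self.channels, self.height, self.width, self.n_classes,
                      self.n_train, self.n_test)
            if actual != expected:
                raise ValidationError(
                    f"{self.name} fields {actual} do not match the standard "
                    f"benchmark definition {expected}"
                )

    @classmethod
    def standard(cls, name: str, source: str = "standard_download") -> "DatasetSpec":
        if name not in STANDARD_DATASETS:
            raise UsageError(f"unknown standard dataset {name!r}")
        c, h, w, k, ntr, nte = STANDARD_DATASETS[name]
        return cls(name, c, h, w, k, ntr, nte, source=source)

    @classmethod
    def synthetic(cls, n_classes: int = 10, size: int = 28, channels: int = 1,
                  n_train: int = 5000, n_test: int = 1000,
                  **kw) -> "DatasetSpec":
        return cls("synthetic", channels, size, size, n_classes,
                   n_train, n_test, source="synthetic", **kw)

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return (self.channels, self.height, self.width)

    def load(self, seed: int = 0):
        """(X_train, y_train, X_test, y_test) as float32 NCHW / int64.

        With ``normalize`` (default) pixel values are centered to
        [-0.5, 0.5], the fixed preprocessing the training protocol assumes.
        """
        if self.source == "synthetic":
            from .synth import SynthImageParams, gen_image_arrays
            p = SynthImageParams(
                n_classes=self.n_classes,
                train_per_class=self.n_train // self.n_classes,
                test_per_class=self.n_test // self.n_classes,
                size=self.height, channels=self.channels,
                noise=self.noise, jitter=self.jitter,
                label_noise=self.label_noise, seed=seed,
            )
            return self._post(*gen_image_arrays(p))
        if self.source == "directory":
            return self._post(*_load_directory(Path(self.path), self.channels))
        raise UsageError(
            f"dataset source {self.source!r} is unavailable here: standard "
            "benchmark downloads require network access; use source="
            "'synthetic' or 'directory'"
        )

    def _post(self, X_tr, y_tr, X_te, y_te):
        if self.normalize:
            X_tr, X_te = X_tr - 0.5, X_te - 0.5
        return X_tr, y_tr, X_te, y_te


def _load_directory(root: Path, channels: int):
    import imageio.v3 as iio

    def split(name):
        classes = sorted(d.name for d in (root / name).iterdir() if d.is_dir())
        X, y = [], []
        for ci, cname in enumerate(classes):
            for f in sorted((root / name / cname).iterdir()):
                img = np.asarray(iio.imread(f), dtype=np.float32) / 255.0
                if img.ndim == 2:
                    img = img[None]
                else:
                    img = img.transpose(2, 0, 1)
                X.append(img[:channels])
                y.append(ci)
        return np.stack(X), np.asarray(y, dtype=np.int64)

    Xtr, ytr = split("train")
    Xte, yte = split("test")
    return Xtr, ytr, Xte, yte


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 30
    consistency_statistic: str = "sd"
    checkpoint: str | None = None


@dataclass
class TrainingReport:
    loss_curve: list[tuple[int, float]]
    test_accuracy: float
    per_class_accuracy: list[float]
    consistency: float
    config_snapshot: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        import json
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    def loss_curve_to_csv(self, path: str | Path) -> None:
        lines = ["step,loss"] + [f"{s},{l}" for s, l in self.loss_curve]
        Path(path).write_text("\n".join(lines) + "\n")


def train(arch: ArchitectureSpec, data: DatasetSpec,
          config: TrainConfig | None = None, seed: int = 0,
          return_model: bool = False):
    """Train an architecture and report the three evaluation surfaces.

    Deterministic given the seed (initialization and shuffling both derive
    from it). With ``epochs=0`` the report carries an empty loss curve and
    the untrained model's near-chance accuracy.
    """
    cfg = config or TrainConfig()
    if arch.input_shape != data.input_shape:
        raise ValidationError(
            f"architecture input {arch.input_shape} does not match dataset "
            f"{data.input_shape}"
        )
    if cfg.optimizer != "adam":
        raise UsageError(f"unsupported optimizer {cfg.optimizer!r}")
    X_tr, y_tr, X_te, y_te = data.load(seed=seed)
    model = Model(arch, seed=seed)
    opt = Adam(model, lr=cfg.learning_rate)
    rng = np.random.default_rng(seed + 1)
    curve: list[tuple[int, float]] = []
    step = 0
    for _ in range(cfg.epochs):
        perm = rng.permutation(len(X_tr))
        for i in range(0, len(X_tr), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            logits, caches, join = model.forward(X_tr[idx], want_cache=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            grads = model.backward(caches, join, dlogits)
            opt.step(grads)
            step += 1
            curve.append((step, loss))
    overall, per_class = evaluate(model, X_te, y_te)
    defined = [a for a in per_class if not np.isnan(a)]
    cons = consistency(np.asarray(defined), cfg.consistency_statistic)
    if cfg.checkpoint:
        model.save(cfg.checkpoint)
    report = TrainingReport(
        loss_curve=curve,
        test_accuracy=overall,
        per_class_accuracy=[float(a) for a in per_class],
        consistency=cons,
        config_snapshot=asdict(cfg),
        seed=seed,
    )
    return (report, model) if return_model else report


def evaluate(model, X_test, y_test) -> tuple[float, np.ndarray]:
    """Overall and per-class accuracy on a test split.

    ``model`` may be a Model or a checkpoint path. Classes absent from the
    split get NaN per-class accuracy (excluded from consistency).
    """
    if isinstance(model, (str, Path)):
        model = Model.load(model)
    pred = model.predict(np.asarray(X_test, dtype=np.float32))
    y = np.asarray(y_test)
    overall = float((pred == y).mean()) if len(y) else 0.0
    n_classes = model.spec.n_classes
    per = np.full(n_classes, np.nan)
    for c in range(n_classes):
        mask = y == c
        if mask.any():
            per[c] = float((pred[mask] == c).mean())
    return overall, per


def consistency(per_class_accuracy: np.ndarray, statistic: str = "sd") -> float:
    """Dispersion of per-class accuracies; lower means more consistent.

    ``sd`` (population standard deviation, the default), ``range``
    (max - min) and ``gini`` (mean absolute difference normalized by twice
    the mean) are available.
    """
    a = np.asarray(per_class_accuracy, dtype=float)
    a = a[~np.isnan(a)]
    if a.size < 2:
        raise ValidationError("consistency needs at least two defined entries")
    if statistic == "sd":
        return float(a.std(ddof=0))
    if statistic == "range":
        return float(a.max() - a.min())
    if statistic == "gini":
        mean = a.mean()
        if mean == 0:
            return 0.0
        mad = np.abs(a[:, None] - a[None, :]).mean()
        return float(mad / (2 * mean))
    raise UsageError(f"unknown consistency statistic {statistic!r}")


def convergence_summary(report: TrainingReport, window: int,
                        tol: float = 1e-3) -> tuple[int, float, bool]:
    """(steps_to_plateau, final_window_mean_loss, overfit_flag).

    The plateau is the first step at which the trailing windowed mean loss
    improves by less than ``tol`` relative to the previous windowed mean.
    The overfit flag is raised when the final windowed mean exceeds the
    global minimum windowed mean by more than ``tol`` (loss fell, then rose).
    """
    losses = np.asarray([l for _, l in report.loss_curve], dtype=float)
    steps = [s for s, _ in report.loss_curve]
    if window < 1 or window > losses.size:
        raise ValidationError(
            f"window {window} invalid for a curve of {losses.size} points"
        )
    kernel = np.ones(window) / window
    wmeans = np.convolve(losses, kernel, mode="valid")
    plateau = steps[-1]
    for i in range(1, wmeans.size):
        if wmeans[i - 1] - wmeans[i] < tol:
            plateau = steps[i + window - 1]
            break
    final = float(wmeans[-1])
    overfit = bool(final > wmeans.min() + tol)
    return plateau, final, overfit
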