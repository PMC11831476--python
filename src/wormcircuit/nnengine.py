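"""Minimal numpy execution engine for compiled architecture specs.

Implements exactly the layer vocabulary the compiler emits — stride-1
same-padded convolutions, ReLU, 2x2 max pooling, adaptive average pooling,
flatten, fully connected layers, channel concatenation / summation at
DAG joins — with reverse-mode gradients and an Adam optimizer. Tensors are
float32 in NCHW layout. The engine is deliberately small: it exists so the
compiled DAG models can be instantiated and trained deterministically from
an :class:`~wormcircuit.compiler.ArchitectureSpec` alone.
"""

from __future__ import annotations

import numpy as np

from .compiler import ArchitectureSpec
from .errors import ValidationError

__all__ = ["Model", "Adam", "softmax_cross_entropy"]


# ---------------------------------------------------------------- primitives

def _conv_forward(x, W, b):
    """Same-padded stride-1 convolution by shift-and-add: one thin matmul
    per kernel offset, which beats im2col for small channel counts."""
    n, c, h, w = x.shape
    o, _, k, _ = W.shape
    p = k // 2
    xp = np.pad(x.transpose(0, 2, 3, 1), ((0, 0), (p, p), (p, p), (0, 0)))
    acc = None
    for i in range(k):
        for j in range(k):
            part = xp[:, i:i + h, j:j + w, :] @ W[:, :, i, j].T
            acc = part if acc is None else acc + part
    if b is not None:
        acc += b
    out = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    return out, (xp, x.shape, k)


def _conv_backward(dout, W, cache):
    xp, xshape, k = cache
    n, c, h, w = xshape
    o = W.shape[0]
    p = k // 2
    dt = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))     # n,h,w,o
    db = dt.sum(axis=(0, 1, 2))
    dm = dt.reshape(n * h * w, o)
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            patch = xp[:, i:i + h, j:j + w, :].reshape(n * h * w, c)
            dW[:, :, i, j] = dm.T @ patch
            dxp[:, i:i + h, j:j + w, :] += (dm @ W[:, :, i, j]
                                            ).reshape(n, h, w, c)
    dx = np.ascontiguousarray(
        dxp[:, p:p + h, p:p + w, :].transpose(0, 3, 1, 2))
    return dx, dW, db


def _maxpool_forward(x, size):
    n, c, h, w = x.shape
    h2, w2 = h // size, w // size
    xc = x[:, :, :h2 * size, :w2 * size]
    r = xc.reshape(n, c, h2, size, w2, size).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h2, w2, size * size)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape, size)


def _maxpool_backward(dout, cache):
    idx, xshape, size = cache
    n, c, h, w = xshape
    h2, w2 = h // size, w // size
    dr = np.zeros((n, c, h2, w2, size * size), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(n, c, h2, w2, size, size).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, :, :h2 * size, :w2 * size] = dr.reshape(n, c, h2 * size, w2 * size)
    return dx


def _avgpool_forward(x, s):
    n, c, h, w = x.shape
    if h % s or w % s:
        raise ValidationError(
            f"adaptive average pool to {s}x{s} needs divisible input, got {h}x{w}"
        )
    kh, kw = h // s, w // s
    out = x.reshape(n, c, s, kh, s, kw).mean(axis=(3, 5))
    return out, (x.shape, s)


def _avgpool_backward(dout, cache):
    xshape, s = cache
    n, c, h, w = xshape
    kh, kw = h // s, w // s
    dx = np.repeat(np.repeat(dout, kh, axis=2), kw, axis=3) / (kh * kw)
    return dx.astype(dout.dtype)


def softmax_cross_entropy(logits, y):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


# ---------------------------------------------------------------- the model

class Model:
    """Instantiation of an ArchitectureSpec with float32 parameters."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        if spec.sequential is not None:
            self._init_chain("seq", spec.sequential, rng)
        else:
            self._init_chain("stem", spec.stem, rng)
            for name in spec.topological_blocks():
                self._init_chain(f"block:{name}", [self._block_layer(name)], rng)
            self._init_chain("head", spec.head, rng)

    # -- initialization ----------------------------------------------
    def _init_conv(self, key, cin, cout, k, bias, rng):
        std = np.sqrt(2.0 / (cin * k * k))
        self.params[f"{key}:W"] = (rng.standard_normal((cout, cin, k, k))
                                   * std).astype(np.float32)
        if bias:
            self.params[f"{key}:b"] = np.zeros(cout, dtype=np.float32)

    def _init_fc(self, key, fin, fout, bias, rng):
        std = np.sqrt(2.0 / fin)
        self.params[f"{key}:W"] = (rng.standard_normal((fin, fout))
                                   * std).astype(np.float32)
        if bias:
            self.params[f"{key}:b"] = np.zeros(fout, dtype=np.float32)

    def _init_chain(self, prefix, layers, rng):
        for i, ly in enumerate(layers):
            if ly["type"] == "conv":
                self._init_conv(f"{prefix}:{i}", ly["in"], ly["out"],
                                ly["kernel"], ly.get("bias", True), rng)
            elif ly["type"] == "fc":
                self._init_fc(f"{prefix}:{i}", ly["in"], ly["out"],
                              ly.get("bias", True), rng)

    def _block_layer(self, name: str) -> dict:
        blk = self.spec.blocks[name]
        return {"type": "conv", "in": blk.in_channels,
                "out": blk.out_channels, "kernel": blk.kernel,
                "bias": blk.bias, "activation": blk.activation}

    def n_parameters(self) -> int:
        """Framework-reported count: literally the sizes of the arrays."""
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward -------------------------------------------
    def _chain_forward(self, prefix, layers, x, cache):
        for i, ly in enumerate(layers):
            t = ly["type"]
            key = f"{prefix}:{i}"
            if t == "conv":
                x, c = _conv_forward(x, self.params[f"{key}:W"],
                                     self.params.get(f"{key}:b"))
                cache.append(("conv", key, c))
                act = ly.get("activation")
                if act in ("relu", "leaky_relu"):
                    slope = 0.01 if act == "leaky_relu" else 0.0
                    mask = np.where(x > 0, 1.0, slope).astype(x.dtype)
                    x = x * mask
                    cache.append(("act", None, mask))
            elif t == "fc":
                xin = x
                x = x @ self.params[f"{key}:W"]
                if f"{key}:b" in self.params:
                    x = x + self.params[f"{key}:b"]
                cache.append(("fc", key, xin))
                act = ly.get("activation")
                if act in ("relu", "leaky_relu"):
                    slope = 0.01 if act == "leaky_relu" else 0.0
                    mask = np.where(x > 0, 1.0, slope).astype(x.dtype)
                    x = x * mask
                    cache.append(("act", None, mask))
            elif t == "maxpool":
                x, c = _maxpool_forward(x, ly["size"])
                cache.append(("maxpool", None, c))
            elif t == "adaptive_avg_pool":
                x, c = _avgpool_forward(x, ly["size"])
                cache.append(("avgpool", None, c))
            elif t == "flatten":
                cache.append(("flatten", None, x.shape))
                x = x.reshape(x.shape[0], -1)
        return x

    def _chain_backward(self, cache, dout, grads):
        for kind, key, c in reversed(cache):
            if kind == "conv":
                dout, dW, db = _conv_backward(dout, self.params[f"{key}:W"], c)
                grads[f"{key}:W"] = grads.get(f"{key}:W", 0) + dW
                if f"{key}:b" in self.params:
                    grads[f"{key}:b"] = grads.get(f"{key}:b", 0) + db
            elif kind == "fc":
                xin = c
                grads[f"{key}:W"] = grads.get(f"{key}:W", 0) + xin.T @ dout
                if f"{key}:b" in self.params:
                    grads[f"{key}:b"] = grads.get(f"{key}:b", 0) + dout.sum(0)
                dout = dout @ self.params[f"{key}:W"].T
            elif kind == "act":
                dout = dout * c
            elif kind == "maxpool":
                dout = _maxpool_backward(dout, c)
            elif kind == "avgpool":
                dout = _avgpool_backward(dout, c)
            elif kind == "flatten":
                dout = dout.reshape(c)
        return dout

    def forward(self, x, want_cache: bool = False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        spec = self.spec
        caches: dict[str, list] = {}
        if spec.sequential is not None:
            caches["seq"] = []
            logits = self._chain_forward("seq", spec.sequential, x, caches["seq"])
            return (logits, caches, None) if want_cache else logits
        caches["stem"] = []
        outputs = {"stem": self._chain_forward("stem", spec.stem, x,
                                               caches["stem"])}
        join_info: dict[str, list[int]] = {}
        for name in spec.topological_blocks():
            ins = [outputs[p] for p in spec.block_inputs[name]]
            if spec.aggregation == "concat":
                xin = ins[0] if len(ins) == 1 else np.concatenate(ins, axis=1)
                join_info[name] = [t.shape[1] for t in ins]
            else:
                xin = ins[0] if len(ins) == 1 else np.sum(ins, axis=0)
            caches[name] = []
            outputs[name] = self._chain_forward(
                f"block:{name}", [self._block_layer(name)], xin, caches[name])
        head_ins = [outputs[p] for p in spec.head_inputs]
        if spec.aggregation == "concat":
            hin = (head_ins[0] if len(head_ins) == 1
                   else np.concatenate(head_ins, axis=1))
            join_info["head"] = [t.shape[1] for t in head_ins]
        else:
            hin = head_ins[0] if len(head_ins) == 1 else np.sum(head_ins, axis=0)
        caches["head"] = []
        logits = self._chain_forward("head", spec.head, hin, caches["head"])
        return (logits, caches, join_info) if want_cache else logits

    def backward(self, caches, join_info, dlogits):
        spec = self.spec
        grads: dict[str, np.ndarray] = {}
        if spec.sequential is not None:
            self._chain_backward(caches["seq"], dlogits, grads)
            return grads
        dtensors: dict[str, np.ndarray] = {}

        def accumulate(names, din, join_key):
            if spec.aggregation == "concat" and len(names) > 1:
                splits = np.cumsum(join_info[join_key][:-1])
                parts = np.split(din, splits, axis=1)
            else:
                parts = [din] * len(names)
            for nm, part in zip(names, parts):
                if nm in dtensors:
                    dtensors[nm] = dtensors[nm] + part
                else:
                    dtensors[nm] = part

        dhin = self._chain_backward(caches["head"], dlogits, grads)
        accumulate(spec.head_inputs, dhin, "head")
        for name in reversed(spec.topological_blocks()):
            if name not in dtensors:
                continue  # block whose output feeds nothing reachable
            din = self._chain_backward(caches[name], dtensors[name], grads)
            accumulate(spec.block_inputs[name], din, name)
        if "stem" in dtensors:
            self._chain_backward(caches["stem"], dtensors["stem"], grads)
        return grads

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size]).argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        import json
        np.savez(path, __spec__=json.dumps(self.spec.to_dict()),
                 **self.params)

    @classmethod
    def load(cls, path) -> "Model":
        import json
        data = np.load(path, allow_pickle=False)
        spec = ArchitectureSpec.from_dict(json.loads(str(data["__spec__"])))
        model = cls(spec, seed=0)
        for key in model.params:
            model.params[key] = data[key]
        return model


class Adam:
    """Adam optimizer over a Model's parameter dict."""

    def __init__(self, model: Model, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k, p in self.model.params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)
                  ).astype(p.dtype)
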