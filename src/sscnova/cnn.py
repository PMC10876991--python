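"""The 1-D convolutional classifier: architecture, training, scoring.

The network maps a length-``input_len`` annotation vector to a probability
of regulatory function through eight layers:

    conv(k=5, 32 maps) -> GELU -> maxpool(2)
    -> conv(k=5, 64 maps) -> GELU -> maxpool(2)
    -> flatten -> dense(16) -> GELU -> dropout(0.1)
    -> dense(1) -> sigmoid

Convolutions are valid (no padding), stride 1; max-pooling drops a
trailing odd element. With the default input length 141 the layer outputs
are (137, 32), (68, 32), (64, 64), (32, 64), 2048, 16, 1. GELU is the
exact Gaussian-CDF form x * Phi(x). Training minimizes binary
cross-entropy with Adam (learning rate 0.001) for 50 epochs by default;
initialization, mini-batch shuffling and dropout masks are all driven by
one seeded generator, so training is fully reproducible.

Everything here (forward pass, backpropagation, Adam) is implemented
directly on numpy arrays; mini-batch float32 matrix products carry the
heavy lifting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit, ndtr

from .features import AnnotationMatrix

try:  # optional fused C kernels for the float32 training path
    from . import _kernels
except ImportError:  # pragma: no cover - pure-numpy fallback
    _kernels = None

__all__ = [
    "ArchitectureSpec", "TrainConfig", "TrainedModel", "ArchitectureError",
    "trace_shapes", "gelu", "gelu_grad", "bce_loss", "train", "score",
    "choose_threshold",
]

_EPS = 1e-7  # probability clamp for the cross-entropy
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class ArchitectureError(ValueError):
    """The architecture is infeasible for the given input length."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the eight-layer network."""

    input_len: int = 141
    conv1_kernel: int = 5
    conv1_filters: int = 32
    pool1: int = 2
    conv2_kernel: int = 5
    conv2_filters: int = 64
    pool2: int = 2
    dense_units: int = 16
    dropout_p: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "input_len", "conv1_kernel", "conv1_filters", "pool1",
            "conv2_kernel", "conv2_filters", "pool2", "dense_units",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        trace_shapes(self)  # raises ArchitectureError if infeasible


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: BCE loss, Adam, seeded shuffling/dropout."""

    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def trace_shapes(spec: ArchitectureSpec | None = None) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes as (length, maps) / (units,) tuples.

    Raises :class:`ArchitectureError` naming the first layer whose output
    would be empty.
    """
    s = spec if spec is not None else ArchitectureSpec()
    shapes: list[tuple[str, tuple[int, ...]]] = []
    length = s.input_len
    for name, kernel, maps, pool in (
        ("conv1", s.conv1_kernel, s.conv1_filters, s.pool1),
        ("conv2", s.conv2_kernel, s.conv2_filters, s.pool2),
    ):
        length = length - kernel + 1
        if length < 1:
            raise ArchitectureError(
                f"layer {name}: kernel {kernel} does not fit input of "
                f"length {length + kernel - 1}"
            )
        shapes.append((name, (length, maps)))
        length = length // pool
        if length < 1:
            raise ArchitectureError(f"layer {name.replace('conv', 'pool')}: empty output")
        shapes.append((name.replace("conv", "pool"), (length, maps)))
    flat = length * (s.conv2_filters)
    shapes.append(("flatten", (flat,)))
    shapes.append(("dense", (s.dense_units,)))
    shapes.append(("output", (1,)))
    return shapes


# Abramowitz & Stegun 7.1.26 rational erf (|error| < 1.5e-7), used to
# evaluate Phi for float32 inputs: well below single precision, and much
# faster than the double-precision cephes routine on the training path.
_AS_P = 0.3275911
_AS_C = (0.254829592, -0.284496736, 1.421413741, -1.453152027, 1.061405429)


def _phi32(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Float32 Phi(x) plus the Gaussian factor exp(-x^2/2) as a byproduct.

    The erf approximation already needs exp(-x^2/2); returning it lets the
    backward pass form the normal pdf without a second exponential.
    """
    half = np.float32(0.5)
    gauss = np.exp(x * x * np.float32(-0.5))
    z = np.abs(x)
    z *= np.float32(np.sqrt(0.5))
    z *= np.float32(_AS_P)
    z += np.float32(1.0)
    t = np.reciprocal(z, out=z)
    c1, c2, c3, c4, c5 = (np.float32(c) for c in _AS_C)
    poly = t * c5
    poly += c4
    poly *= t
    poly += c3
    poly *= t
    poly += c2
    poly *= t
    poly += c1
    poly *= t
    poly *= gauss  # now 1 - |erf|
    # Phi = 0.5 * (1 + sign(x) * (1 - poly))
    phi = np.where(x >= 0, np.float32(1.0) - half * poly, half * poly)
    return phi, gauss


def _phi(x: np.ndarray) -> np.ndarray:
    """Standard normal CDF, evaluated to the precision of the input dtype."""
    if x.dtype != np.float32:
        return ndtr(x)
    return _phi32(x)[0]


def gelu(x):
    """Gaussian Error Linear Unit, x * Phi(x), elementwise.

    Uses the Gaussian-CDF form (not the tanh approximation); Phi is
    evaluated to the precision of the input dtype.
    """
    x = np.asarray(x)
    return x * _phi(x)


def gelu_grad(x, phi: np.ndarray | None = None):
    """d/dx [x * Phi(x)] = Phi(x) + x * phi(x).

    ``phi`` may pass a precomputed Phi(x) to avoid re-evaluating the CDF.
    """
    x = np.asarray(x)
    if phi is None:
        phi = _phi(x)
    # python-float scalars do not upcast float32 arrays (NEP 50)
    return phi + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def bce_loss(y, p) -> float:
    """Mean binary cross-entropy with probabilities clamped to [1e-7, 1-1e-7]."""
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if y.shape != p.shape or y.size == 0:
        raise ValueError(f"y and p must be equal-length non-empty, got {y.shape} vs {p.shape}")
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


# ---------------------------------------------------------------------------
# parameters and the forward/backward passes

_WEIGHT_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")


def weight_shapes(spec: ArchitectureSpec) -> dict[str, tuple[int, ...]]:
    shapes = dict(trace_shapes(spec))
    flat = shapes["flatten"][0]
    return {
        "W1": (spec.conv1_kernel, 1, spec.conv1_filters),
        "b1": (spec.conv1_filters,),
        "W2": (spec.conv2_kernel, spec.conv1_filters, spec.conv2_filters),
        "b2": (spec.conv2_filters,),
        "W3": (flat, spec.dense_units),
        "b3": (spec.dense_units,),
        "W4": (spec.dense_units, 1),
        "b4": (1,),
    }


def init_weights(
    spec: ArchitectureSpec, rng: np.random.Generator, dtype=np.float32
) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases."""
    out: dict[str, np.ndarray] = {}
    for name, shape in weight_shapes(spec).items():
        if name.startswith("b"):
            out[name] = np.zeros(shape, dtype=dtype)
            continue
        if name in ("W1", "W2"):
            k, cin, cout = shape
            fan_in, fan_out = k * cin, k * cout
        else:
            fan_in, fan_out = shape
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        out[name] = rng.uniform(-limit, limit, size=shape).astype(dtype)
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) patches, kernel-offset major."""
    b, l, c = x.shape
    if _use_kernels(x):
        col = np.empty((b, l - k + 1, k * c), dtype=np.float32)
        _kernels.im2col(x.ravel(), col.ravel(), b, l, c, k)
        return col
    win = sliding_window_view(x, k, axis=1)  # (B, L-k+1, C, k)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b, l - k + 1, k * c)


def _col2im(dcol: np.ndarray, k: int, l: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back."""
    b, lout, kc = dcol.shape
    c = kc // k
    if _use_kernels(dcol):
        dx = np.empty((b, l, c), dtype=np.float32)
        _kernels.col2im(dcol.ravel(), dx.ravel(), b, l, c, k)
        return dx
    d = dcol.reshape(b, lout, k, c)
    dx = np.zeros((b, l, c), dtype=dcol.dtype)
    for j in range(k):
        dx[:, j : j + lout, :] += d[:, :, j, :]
    return dx


def _pool_forward(h: np.ndarray, p: int):
    """Non-overlapping max-pool dropping the trailing remainder.

    Returns (pooled, aux, input_length); ``aux`` routes the gradient back
    to the argmax (first element wins ties, matching argmax).
    """
    b, l, c = h.shape
    lp = l // p
    if p == 2 and _use_kernels(h):  # fused C compare/select
        out = np.empty((b, lp, c), dtype=np.float32)
        mask = np.empty((b, lp, c), dtype=np.int8)
        _kernels.pool2_forward(h.ravel(), out.ravel(), mask.ravel(), b, l, c)
        return out, ("cmask2", mask), l
    if p == 2:  # compare the two lanes, no argmax
        left, right = h[:, : 2 * lp : 2, :], h[:, 1 : 2 * lp : 2, :]
        mask = left >= right
        return np.maximum(left, right), ("mask2", mask), l
    win = h[:, : lp * p, :].reshape(b, lp, p, c)
    idx = win.argmax(axis=2)
    return win.max(axis=2), ("argmax", idx), l


def _pool_backward(dout: np.ndarray, aux, l: int, p: int) -> np.ndarray:
    b, lp, c = dout.shape
    kind, data = aux
    if kind == "cmask2":
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        dh = np.empty((b, l, c), dtype=np.float32)
        _kernels.pool2_backward(dout.ravel(), data.ravel(), dh.ravel(), b, l, c)
        return dh
    dh = np.zeros((b, l, c), dtype=dout.dtype)
    if kind == "mask2":
        dleft = dout * data
        dh[:, : 2 * lp : 2, :] = dleft
        dh[:, 1 : 2 * lp : 2, :] = dout - dleft
    else:
        dwin = np.zeros((b, lp, p, c), dtype=dout.dtype)
        np.put_along_axis(dwin, data[:, :, None, :], dout[:, :, None, :], axis=2)
        dh[:, : lp * p, :] = dwin.reshape(b, lp * p, c)
    return dh


def _use_kernels(a: np.ndarray) -> bool:
    return (
        _kernels is not None
        and a.dtype == np.float32
        and a.flags.c_contiguous
    )


def _act(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gelu(a), Phi(a), exp(-a^2/2)) — forward value plus gradient factors."""
    if _use_kernels(a):
        h, phi, gauss = np.empty_like(a), np.empty_like(a), np.empty_like(a)
        _kernels.act_forward(a.ravel(), h.ravel(), phi.ravel(), gauss.ravel())
        return h, phi, gauss
    if a.dtype == np.float32:
        phi, gauss = _phi32(a)
    else:
        phi, gauss = ndtr(a), np.exp(-0.5 * a * a)
    return a * phi, phi, gauss


def _gelu_vjp(dh: np.ndarray, a: np.ndarray, phi: np.ndarray, gauss: np.ndarray):
    """dh * gelu'(a) using the cached Phi and Gaussian factors."""
    if _use_kernels(a) and dh.flags.c_contiguous:
        out = np.empty_like(a)
        _kernels.gelu_vjp(
            dh.ravel(), a.ravel(), phi.ravel(), gauss.ravel(), out.ravel()
        )
        return out
    t = a * gauss
    t *= _INV_SQRT_2PI
    t += phi
    t *= dh
    return t


def _forward(
    weights: dict[str, np.ndarray],
    spec: ArchitectureSpec,
    x: np.ndarray,
    dropout_mask: np.ndarray | None = None,
):
    """Run the network; returns (probabilities, cache for backprop)."""
    w1 = weights["W1"]
    dtype = w1.dtype
    x = np.asarray(x, dtype=dtype)
    b = x.shape[0]
    x3 = x[:, :, None]  # single input channel

    col1 = _im2col(x3, spec.conv1_kernel)
    a1 = col1 @ w1.reshape(-1, spec.conv1_filters) + weights["b1"]
    h1, phi1, gauss1 = _act(a1)
    p1, aux1, l1 = _pool_forward(h1, spec.pool1)

    col2 = _im2col(p1, spec.conv2_kernel)
    a2 = col2 @ weights["W2"].reshape(-1, spec.conv2_filters) + weights["b2"]
    h2, phi2, gauss2 = _act(a2)
    p2, aux2, l2 = _pool_forward(h2, spec.pool2)

    v = p2.reshape(b, -1)  # flatten index = position * maps + map
    a3 = v @ weights["W3"] + weights["b3"]
    h3, phi3, gauss3 = _act(a3)
    d3 = h3 if dropout_mask is None else h3 * dropout_mask
    a4 = d3 @ weights["W4"] + weights["b4"]
    prob = expit(a4[:, 0].astype(np.float64))
    cache = (
        col1, a1, phi1, gauss1, aux1, l1,
        col2, a2, phi2, gauss2, aux2, l2,
        v, a3, phi3, gauss3, d3, dropout_mask,
    )
    return prob, cache


def _backward(
    weights: dict[str, np.ndarray],
    spec: ArchitectureSpec,
    cache,
    prob: np.ndarray,
    y: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of mean BCE w.r.t. every parameter (sigmoid folded in)."""
    (col1, a1, phi1, gauss1, aux1, l1, col2, a2, phi2, gauss2, aux2, l2,
     v, a3, phi3, gauss3, d3, mask) = cache
    dtype = weights["W1"].dtype
    b = prob.shape[0]
    da4 = ((prob - y) / b).astype(dtype)[:, None]

    g: dict[str, np.ndarray] = {}
    g["W4"] = d3.T @ da4
    g["b4"] = da4.sum(axis=0)
    dd3 = da4 @ weights["W4"].T
    dh3 = dd3 if mask is None else dd3 * mask
    da3 = _gelu_vjp(dh3, a3, phi3, gauss3)
    g["W3"] = v.T @ da3
    g["b3"] = da3.sum(axis=0)
    dv = da3 @ weights["W3"].T

    dp2 = dv.reshape(b, -1, spec.conv2_filters)
    dh2 = _pool_backward(dp2, aux2, l2, spec.pool2)
    da2 = _gelu_vjp(dh2, a2, phi2, gauss2)
    kc2 = spec.conv2_kernel * spec.conv1_filters
    g["W2"] = (
        col2.reshape(-1, kc2).T @ da2.reshape(-1, spec.conv2_filters)
    ).reshape(weights["W2"].shape)
    g["b2"] = da2.sum(axis=(0, 1))
    dcol2 = da2 @ weights["W2"].reshape(kc2, -1).T
    dp1 = _col2im(dcol2, spec.conv2_kernel, l1 // spec.pool1)

    dh1 = _pool_backward(dp1, aux1, l1, spec.pool1)
    da1 = _gelu_vjp(dh1, a1, phi1, gauss1)
    kc1 = spec.conv1_kernel * 1
    g["W1"] = (
        col1.reshape(-1, kc1).T @ da1.reshape(-1, spec.conv1_filters)
    ).reshape(weights["W1"].shape)
    g["b1"] = da1.sum(axis=(0, 1))
    return g


@dataclass
class TrainedModel:
    """A fitted network: architecture, weights, loss history, provenance."""

    spec: ArchitectureSpec
    weights: dict[str, np.ndarray]
    training_history: list[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = weight_shapes(self.spec)
        for name, shape in expected.items():
            if name not in self.weights:
                raise ValueError(f"missing weight tensor {name}")
            if tuple(self.weights[name].shape) != shape:
                raise ValueError(
                    f"weight {name} has shape {self.weights[name].shape}, "
                    f"expected {shape}"
                )

    def predict(self, x: np.ndarray | AnnotationMatrix) -> np.ndarray:
        return score(self, x)

    def save(self, path) -> None:
        """Single-archive checkpoint: spec + provenance JSON and weights."""
        np.savez(
            path,
            spec_json=np.array(json.dumps(asdict(self.spec))),
            provenance_json=np.array(json.dumps(self.provenance)),
            history=np.asarray(self.training_history, dtype=float),
            **self.weights,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            spec = ArchitectureSpec(**json.loads(str(z["spec_json"])))
            provenance = json.loads(str(z["provenance_json"]))
            history = z["history"].tolist()
            weights = {n: z[n] for n in _WEIGHT_NAMES}
        return cls(spec, weights, history, provenance)


def _config_hash(spec: ArchitectureSpec, cfg: TrainConfig) -> str:
    blob = json.dumps({"spec": asdict(spec), "train": asdict(cfg)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_xy(m: AnnotationMatrix | np.ndarray, labels=None):
    if isinstance(m, AnnotationMatrix):
        x = m.values
        y = m.labels if labels is None else labels
    else:
        x, y = np.asarray(m, dtype=float), labels
    return x, None if y is None else np.asarray(y, dtype=float).ravel()


def train(
    m: AnnotationMatrix | np.ndarray,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    labels=None,
) -> TrainedModel:
    """Fit the network with Adam on mini-batches of BCE loss.

    ``m`` is a labeled :class:`AnnotationMatrix` (or a plain matrix with
    ``labels``). The per-epoch mean training loss is recorded in
    ``training_history``. Fully deterministic under ``cfg.seed``.
    """
    spec = spec or ArchitectureSpec()
    cfg = cfg or TrainConfig()
    x, y = _as_xy(m, labels)
    if y is None:
        raise ValueError("training requires labels")
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if x.shape[1] != spec.input_len:
        raise ValueError(
            f"matrix has {x.shape[1]} features but spec.input_len is {spec.input_len}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    weights = init_weights(spec, rng, dtype=np.float32)
    x32 = np.asarray(x, dtype=np.float32)
    adam_m = {k: np.zeros_like(v) for k, v in weights.items()}
    adam_v = {k: np.zeros_like(v) for k, v in weights.items()}
    t = 0
    keep = 1.0 - spec.dropout_p
    history: list[float] = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = x32[idx], y[idx]
            if spec.dropout_p > 0.0:
                mask = (
                    rng.random((len(idx), spec.dense_units)) >= spec.dropout_p
                ).astype(np.float32) / keep
            else:
                mask = None
            prob, cache = _forward(weights, spec, xb, dropout_mask=mask)
            total += bce_loss(yb, prob) * len(idx)
            grads = _backward(weights, spec, cache, prob, yb)
            t += 1
            # plain-float scalar: numpy scalars would promote float32 weights
            lr_t = float(
                cfg.learning_rate * np.sqrt(1.0 - cfg.beta2**t) / (1.0 - cfg.beta1**t)
            )
            for k in weights:
                gk = grads[k]
                if _kernels is not None and gk.flags.c_contiguous:
                    _kernels.adam_step(
                        weights[k].ravel(), gk.ravel(), adam_m[k].ravel(),
                        adam_v[k].ravel(), lr_t, cfg.beta1, cfg.beta2, cfg.eps,
                    )
                else:
                    adam_m[k] = cfg.beta1 * adam_m[k] + (1.0 - cfg.beta1) * gk
                    adam_v[k] = cfg.beta2 * adam_v[k] + (1.0 - cfg.beta2) * gk * gk
                    weights[k] = weights[k] - lr_t * adam_m[k] / (
                        np.sqrt(adam_v[k]) + cfg.eps
                    )
        history.append(total / n)
    provenance = {"config_hash": _config_hash(spec, cfg), "seed": cfg.seed, "n": n}
    return TrainedModel(spec, weights, history, provenance)


def score(
    model: TrainedModel,
    m: AnnotationMatrix | np.ndarray,
    batch_size: int = 1024,
) -> np.ndarray:
    """Predicted probability of the positive class, one value per row.

    Dropout is disabled; the result does not depend on ``batch_size`` or
    row order beyond reordering.
    """
    x = m.values if isinstance(m, AnnotationMatrix) else np.asarray(m, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.spec.input_len:
        raise ValueError(
            f"matrix has shape {x.shape}, expected (*, {model.spec.input_len})"
        )
    out = np.empty(x.shape[0], dtype=float)
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        prob, _ = _forward(model.weights, model.spec, xb, dropout_mask=None)
        out[start : start + len(xb)] = prob
    return out


def choose_threshold(scores, labels) -> float:
    """Cut point maximizing Youden's J for the rule ``score > threshold``.

    Candidate thresholds are midpoints between consecutive distinct
    scores (plus one below the minimum and one above the maximum), so the
    returned value for perfectly separated classes is the midpoint of the
    gap. Degenerate all-equal scores fall back to 0.5.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if s.shape != y.shape or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    if uniq.size == 1:
        return 0.5
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.r_[uniq[0] - 1.0, mids, uniq[-1] + 1.0]
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = s > t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t
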