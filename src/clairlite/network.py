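"""The multi-task convolutional network: build, initialise, forward, cost.

The network is a five-layer model: three convolution layers (SAME padding,
stride 1, each followed by SELU activation and a stride-1 valid max-pool)
and two fully connected layers.  Four output heads sit on top: the
alternative-allele head (4 sigmoid units, read off FC4 directly) and the
zygosity / variant-type / indel-length heads (2, 4 and 6 softmax units on
FC5).  The default configuration has 1,631,496 trainable parameters.

Hidden layers use SELU (self-normalising) activations, so no batch
normalisation is present anywhere.  Everything -- the forward pass, the
analytic gradients, Adam, dropout and L2 -- is implemented directly on
NumPy arrays in float64.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__network_version__ = "clairlite-net-1"

SELU_SCALE = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772

HEAD_SIZES = {"allele": 4, "zygosity": 2, "type": 4, "length": 6}
PROB_EPS = 1e-10  # clamp inside logs


@dataclass(frozen=True)
class ConvSpec:
    kernel: tuple[int, int]
    filters: int
    pool: tuple[int, int]


DEFAULT_CONVS = (
    ConvSpec((1, 4), 16, (5, 1)),
    ConvSpec((2, 4), 32, (4, 1)),
    ConvSpec((3, 4), 48, (3, 1)),
)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters; the defaults are the published ones."""

    input_shape: tuple[int, int, int] = (33, 4, 4)
    convs: tuple[ConvSpec, ...] = DEFAULT_CONVS
    fc4: int = 336
    fc5: int = 168
    dropout_fc4: float = 0.5
    #: fixed preconditioning factor applied to the raw count tensor before
    #: the first convolution, so typical activations start near unit scale
    #: at sequencing depths around 30; purely numerical, not data-dependent
    input_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.fc4 <= 0 or self.fc5 <= 0:
            raise ValueError("fully connected widths must be positive")
        if not 0 <= self.dropout_fc4 < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        h, w, _ = self.input_shape
        for spec in self.convs:
            if spec.filters <= 0:
                raise ValueError("filter count must be positive")
            h = h - spec.pool[0] + 1
            w = w - spec.pool[1] + 1
            if h <= 0 or w <= 0:
                raise ValueError("pooling shrinks a dimension below 1")

    def conv_stack_shape(self) -> tuple[int, int, int]:
        """(height, width, channels) after the last conv/pool block."""
        h, w, c = self.input_shape
        for spec in self.convs:
            c = spec.filters
            h = h - spec.pool[0] + 1
            w = w - spec.pool[1] + 1
        return h, w, c


@dataclass
class NetworkOutputs:
    """The four predicted probability groups for a batch of sites.

    ``z``/``t``/``l`` rows are softmax probability vectors; ``a`` rows are
    element-wise sigmoids in [0, 1] and need not sum to one.
    """

    a: np.ndarray
    z: np.ndarray
    t: np.ndarray
    l: np.ndarray

    def row(self, i: int) -> tuple[np.ndarray, ...]:
        return self.a[i], self.z[i], self.t[i], self.l[i]

    def __len__(self) -> int:
        return len(self.a)


class Network:
    """A parameter container plus its configuration.

    ``dtype`` selects the arithmetic precision: float32 (the default) for
    training speed, float64 where exactness matters (gradient checks).
    """

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self.in_degrees: dict[str, int] = {}
        h, w, c = config.input_shape
        for i, spec in enumerate(config.convs):
            kh, kw = spec.kernel
            self.params[f"conv{i}_W"] = np.zeros((kh, kw, c, spec.filters),
                                                 self.dtype)
            self.params[f"conv{i}_b"] = np.zeros(spec.filters, self.dtype)
            self.in_degrees[f"conv{i}_W"] = kh * kw * c
            c = spec.filters
        fh, fw, fc = config.conv_stack_shape()
        flat = fh * fw * fc
        dims = {"fc4": (flat, config.fc4), "fc5": (config.fc4, config.fc5),
                "allele": (config.fc4, HEAD_SIZES["allele"]),
                "zygosity": (config.fc5, HEAD_SIZES["zygosity"]),
                "type": (config.fc5, HEAD_SIZES["type"]),
                "length": (config.fc5, HEAD_SIZES["length"])}
        for name, (din, dout) in dims.items():
            self.params[f"{name}_W"] = np.zeros((din, dout), self.dtype)
            self.params[f"{name}_b"] = np.zeros(dout, self.dtype)
            self.in_degrees[f"{name}_W"] = din

    def weight_names(self) -> list[str]:
        return [k for k in self.params if k.endswith("_W")]

    def copy(self) -> "Network":
        m = Network(self.config, self.dtype)
        m.params = {k: v.copy() for k, v in self.params.items()}
        return m


def build(config: NetworkConfig | None = None, dtype=np.float32) -> Network:
    """Construct a network with zero-valued parameters."""
    return Network(config or NetworkConfig(), dtype)


def init_he(model: Network, seed: int = 0) -> Network:
    """He initialisation: weights ~ N(0, sigma^2), sigma = 1/sqrt(d_in/2).

    ``d_in`` is the in-degree of a node (kernel volume for convolutions,
    input width for dense layers).  Biases are zero.
    """
    rng = np.random.default_rng(seed)
    for name, p in model.params.items():
        if name.endswith("_W"):
            sigma = 1.0 / np.sqrt(model.in_degrees[name] / 2.0)
            model.params[name] = rng.normal(
                0.0, sigma, size=p.shape).astype(model.dtype)
        else:
            model.params[name] = np.zeros_like(p)
    return model


def he_sigma(d_in: int) -> float:
    return 1.0 / np.sqrt(d_in / 2.0)


def count_parameters(model: Network) -> int:
    """Total trainable parameter count (weights plus biases)."""
    return int(sum(p.size for p in model.params.values()))


# ---------------------------------------------------------------------------
# primitive layers


def _selu(x):
    neg = np.minimum(x, 0)  # avoid exp overflow on the positive branch
    return SELU_SCALE * np.where(x > 0, x, SELU_ALPHA * np.expm1(neg))


def _selu_grad(x):
    neg = np.minimum(x, 0)
    return SELU_SCALE * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(neg))


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softmax(x):
    m = x - x.max(axis=1, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=1, keepdims=True)


def _conv_forward(x, W, b):
    """SAME-padded stride-1 2D convolution via im2col."""
    kh, kw, cin, cout = W.shape
    n, h, w, _ = x.shape
    pt, pl = (kh - 1) // 2, (kw - 1) // 2
    pb, pr = kh - 1 - pt, kw - 1 - pl
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (n, h, w, cin, kh, kw) -> columns (n*h*w, cin*kh*kw)
    cols = np.ascontiguousarray(win).reshape(n * h * w, cin * kh * kw)
    Wr = W.transpose(2, 0, 1, 3).reshape(cin * kh * kw, cout)
    out = (cols @ Wr + b).reshape(n, h, w, cout)
    return out, (cols, W, (n, h, w, cin), (pt, pb, pl, pr))


def _conv_backward(dout, cache):
    cols, W, (n, h, w, cin), (pt, pb, pl, pr) = cache
    kh, kw, _, cout = W.shape
    Wr = W.transpose(2, 0, 1, 3).reshape(-1, cout)
    d2 = dout.reshape(-1, cout)
    dW = (cols.T @ d2).reshape(cin, kh, kw, cout).transpose(1, 2, 0, 3)
    db = d2.sum(axis=0)
    dcols = (d2 @ Wr.T).reshape(n, h, w, cin, kh, kw)
    dxp = np.zeros((n, h + pt + pb, w + pl + pr, cin), dtype=cols.dtype)
    for a in range(kh):
        for bb in range(kw):
            dxp[:, a:a + h, bb:bb + w, :] += dcols[:, :, :, :, a, bb]
    dx = dxp[:, pt:pt + h, pl:pl + w, :]
    return dx, dW, db


def _pool_forward(x, pool):
    ph, pw = pool
    n, h, w, c = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (ph, pw), axis=(1, 2))
    flat = np.ascontiguousarray(win).reshape(
        n, h - ph + 1, w - pw + 1, c, ph * pw)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape, pool)


def _pool_backward(dout, cache):
    idx, xshape, (ph, pw) = cache
    n, h, w, c = xshape
    ho, wo = h - ph + 1, w - pw + 1
    dx = np.zeros(xshape, dtype=dout.dtype)
    ni = np.arange(n)[:, None, None, None]
    hi = np.arange(ho)[None, :, None, None] + idx // pw
    wi = np.arange(wo)[None, None, :, None] + idx % pw
    ci = np.arange(c)[None, None, None, :]
    np.add.at(dx, (np.broadcast_to(ni, idx.shape), hi, wi,
                   np.broadcast_to(ci, idx.shape)), dout)
    return dx


# ---------------------------------------------------------------------------
# forward / cost / gradients


def forward(model: Network, X: np.ndarray, train: bool = False,
            rng: np.random.Generator | None = None,
            return_cache: bool = False):
    """Run a batch of (n, 33, 4, 4) tensors through the network.

    Inference mode (``train=False``) is deterministic: dropout is off.
    """
    X = np.asarray(X, dtype=model.dtype)
    if X.ndim == 3:
        X = X[None]
    if np.isnan(X).any():
        raise ValueError("NaN in input tensor batch")
    cfg = model.config
    cache: dict = {"X": X}
    h = X * model.dtype.type(cfg.input_scale)
    for i in range(len(cfg.convs)):
        u, ccache = _conv_forward(h, model.params[f"conv{i}_W"],
                                  model.params[f"conv{i}_b"])
        s = _selu(u)
        h, pcache = _pool_forward(s, cfg.convs[i].pool)
        cache[f"conv{i}"] = (u, ccache, pcache)
    flat = h.reshape(len(X), -1)
    cache["flat"] = flat
    u4 = flat @ model.params["fc4_W"] + model.params["fc4_b"]
    h4 = _selu(u4)
    if train and cfg.dropout_fc4 > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = 1.0 - cfg.dropout_fc4
        mask = ((rng.random(h4.shape) < keep) / keep).astype(model.dtype)
    else:
        mask = None
    h4d = h4 if mask is None else h4 * mask
    u5 = h4d @ model.params["fc5_W"] + model.params["fc5_b"]
    h5 = _selu(u5)
    ua = h4d @ model.params["allele_W"] + model.params["allele_b"]
    out = NetworkOutputs(
        a=_sigmoid(ua),
        z=_softmax(h5 @ model.params["zygosity_W"]
                   + model.params["zygosity_b"]),
        t=_softmax(h5 @ model.params["type_W"] + model.params["type_b"]),
        l=_softmax(h5 @ model.params["length_W"] + model.params["length_b"]),
    )
    if not return_cache:
        return out
    cache.update(u4=u4, mask=mask, h4d=h4d, u5=u5, h5=h5)
    return out, cache


def cost(outputs: NetworkOutputs, Y: np.ndarray) -> float:
    """Mean multi-task cost: squared error on the allele group plus
    cross-entropy (natural log) on the zygosity, type and length groups."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[None]
    if len(Y) == 0:
        raise ValueError("empty batch")
    a, z, t, l = Y[:, 0:4], Y[:, 4:6], Y[:, 6:10], Y[:, 10:16]
    se = ((outputs.a - a) ** 2).sum(axis=1)
    ce = -(z * np.log(np.clip(outputs.z, PROB_EPS, 1.0))).sum(axis=1)
    ce -= (t * np.log(np.clip(outputs.t, PROB_EPS, 1.0))).sum(axis=1)
    ce -= (l * np.log(np.clip(outputs.l, PROB_EPS, 1.0))).sum(axis=1)
    return float(np.mean(se + ce))


def loss_and_grads(model: Network, X: np.ndarray, Y: np.ndarray,
                   l2: float = 0.0, train: bool = True,
                   rng: np.random.Generator | None = None):
    """Cost and analytic gradients for one batch.

    Returns ``(data_cost, penalty, grads)`` where ``penalty`` is the L2
    term ``l2 * sum(w^2)`` over weight matrices (biases are not penalised)
    and ``grads`` maps parameter names to arrays.
    """
    Y = np.asarray(Y, dtype=model.dtype)
    if Y.ndim == 1:
        Y = Y[None]
    out, cache = forward(model, X, train=train, rng=rng, return_cache=True)
    n = len(Y)
    c = cost(out, Y)
    a, z, t, l = Y[:, 0:4], Y[:, 4:6], Y[:, 6:10], Y[:, 10:16]
    grads: dict[str, np.ndarray] = {}

    dua = 2.0 * (out.a - a) * out.a * (1.0 - out.a) / n
    duz = (out.z - z) / n
    dut = (out.t - t) / n
    dul = (out.l - l) / n

    h5, h4d, u5, u4 = cache["h5"], cache["h4d"], cache["u5"], cache["u4"]
    grads["zygosity_W"] = h5.T @ duz
    grads["zygosity_b"] = duz.sum(axis=0)
    grads["type_W"] = h5.T @ dut
    grads["type_b"] = dut.sum(axis=0)
    grads["length_W"] = h5.T @ dul
    grads["length_b"] = dul.sum(axis=0)
    dh5 = (duz @ model.params["zygosity_W"].T
           + dut @ model.params["type_W"].T
           + dul @ model.params["length_W"].T)
    du5 = dh5 * _selu_grad(u5)
    grads["fc5_W"] = h4d.T @ du5
    grads["fc5_b"] = du5.sum(axis=0)
    grads["allele_W"] = h4d.T @ dua
    grads["allele_b"] = dua.sum(axis=0)
    dh4d = du5 @ model.params["fc5_W"].T + dua @ model.params["allele_W"].T
    if cache["mask"] is not None:
        dh4d = dh4d * cache["mask"]
    du4 = dh4d * _selu_grad(u4)
    flat = cache["flat"]
    grads["fc4_W"] = flat.T @ du4
    grads["fc4_b"] = du4.sum(axis=0)
    dh = (du4 @ model.params["fc4_W"].T).reshape(
        (n,) + tuple(model.config.conv_stack_shape()))
    for i in range(len(model.config.convs) - 1, -1, -1):
        u, ccache, pcache = cache[f"conv{i}"]
        ds = _pool_backward(dh, pcache)
        du = ds * _selu_grad(u)
        dh, dW, db = _conv_backward(du, ccache)
        grads[f"conv{i}_W"] = dW
        grads[f"conv{i}_b"] = db

    penalty = 0.0
    if l2 > 0:
        for name in model.weight_names():
            w = model.params[name]
            penalty += l2 * float((w * w).sum())
            grads[name] = grads[name] + 2.0 * l2 * w
    return c, penalty, grads


# ---------------------------------------------------------------------------
# serialisation


def save_model(model: Network, path: str) -> None:
    """Single-file weight archive with the config and a version string."""
    cfg = model.config
    meta = {
        "version": __network_version__,
        "input_shape": list(cfg.input_shape),
        "convs": [[list(s.kernel), s.filters, list(s.pool)]
                  for s in cfg.convs],
        "fc4": cfg.fc4, "fc5": cfg.fc5, "dropout_fc4": cfg.dropout_fc4,
        "input_scale": cfg.input_scale, "dtype": model.dtype.name,
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_model(path: str) -> Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = NetworkConfig(
            input_shape=tuple(meta["input_shape"]),
            convs=tuple(ConvSpec(tuple(k), f, tuple(p))
                        for k, f, p in meta["convs"]),
            fc4=meta["fc4"], fc5=meta["fc5"],
            dropout_fc4=meta["dropout_fc4"],
            input_scale=meta.get("input_scale", 1.0),
        )
        model = Network(cfg, dtype=meta.get("dtype", "float32"))
        for name in model.params:
            model.params[name] = data[name]
    return model
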