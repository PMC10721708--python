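"""Two-pathway spatiotemporal convolutional classifier for cell clips.

The network follows the slow/fast two-pathway design for video
recognition: a *slow* pathway sees only every ``tau``-th frame of a clip
(default tau = 8) and carries most of the capacity, extracting the spatial
structure of the deforming cell; a *fast* pathway sees frames densely (a
frame-rate ratio ``alpha`` = 8 higher than the slow pathway) but with
channel widths reduced by ``beta`` = 1/8, capturing motion. At every block
group the fast features are fused into the slow pathway through a
time-strided lateral convolution; a single softmax head with dropout sits
on the concatenated pooled features of both pathways.

Everything — 3D convolutions (im2col + GEMM), batch normalisation, SGD with
momentum — is implemented here in numpy with analytic backward passes, so
the classifier is fully self-contained and deterministic given a seed. The
``tiny`` depth preset (two residual stages, slow widths 32/64) is sized for
CPU training on synthetic cohorts; deeper presets with the standard
four-stage layout are available in the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "SlowFastConfig",
    "SlowFastModel",
    "ModelOutput",
    "build_model",
    "predict",
    "SGD",
    "softmax_cross_entropy",
]

#: Depth presets: per-stage (slow) channel widths and residual block counts.
DEPTH_PRESETS = {
    "tiny": {"widths": (32, 64), "blocks": (1, 1)},
    "50": {"widths": (64, 128, 256, 512), "blocks": (3, 4, 6, 3)},
    "101": {"widths": (64, 128, 256, 512), "blocks": (3, 4, 23, 3)},
}


@dataclass(frozen=True)
class SlowFastConfig:
    """Pathway and head parameters of the two-pathway classifier.

    tau
        Temporal stride of the slow pathway: only every tau-th clip frame
        enters it.
    alpha
        Frame-rate ratio fast/slow: the fast pathway processes alpha frames
        per slow frame (its input stride is tau / alpha).
    beta
        Channel-width ratio fast/slow at every stage.
    """

    tau: int = 8
    alpha: int = 8
    beta: float = 1.0 / 8.0
    depth: str = "tiny"
    dropout: float = 0.5
    n_classes: int = 2
    clip_frames: int = 64
    clip_size: int = 50
    in_channels: int = 1
    spatial_pool: int = 1   # input average-pooling factor before the stems

    def __post_init__(self):
        if self.clip_frames % self.tau != 0:
            raise ValueError(
                f"clip_frames={self.clip_frames} must be divisible by tau={self.tau}")
        if self.alpha < 1 or int(self.alpha) != self.alpha:
            raise ValueError("alpha must be an integer >= 1")
        if self.tau % self.alpha != 0:
            raise ValueError("tau must be a multiple of alpha")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.depth not in DEPTH_PRESETS:
            raise ValueError(f"unknown depth preset {self.depth!r}")
        if self.spatial_pool < 1 or self.clip_size % self.spatial_pool:
            raise ValueError("spatial_pool must divide clip_size")

    @property
    def slow_frames(self) -> int:
        return self.clip_frames // self.tau

    @property
    def fast_frames(self) -> int:
        return self.clip_frames * self.alpha // self.tau

    @property
    def slow_widths(self) -> tuple[int, ...]:
        return DEPTH_PRESETS[self.depth]["widths"]

    @property
    def fast_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(self.beta * w)) for w in self.slow_widths)


@dataclass
class ModelOutput:
    """Per-clip class probabilities (non-negative, summing to 1)."""

    scores: np.ndarray          # (n_classes,)

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.scores))


# ---------------------------------------------------------------------------
# Layers (float32, analytic backward)
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Conv3d:
    """3D convolution via im2col + GEMM. Input (N, C, T, H, W)."""

    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), pad=None, rng=None):
        kt, kh, kw = kernel
        if pad is None:
            pad = (kt // 2, kh // 2, kw // 2)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.cin, self.cout = cin, cout
        fan_in = cin * kt * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kt, kh, kw))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size

    def _out_shape(self, T, H, W):
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.pad
        return ((T + 2 * pt - kt) // st + 1,
                (H + 2 * ph - kh) // sh + 1,
                (W + 2 * pw - kw) // sw + 1)

    def forward(self, x, train=True):
        N, C, T, H, W = x.shape
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.pad
        To, Ho, Wo = self._out_shape(T, H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        patches = np.empty((N, C, kt * kh * kw, To, Ho, Wo), dtype=np.float32)
        for idx, (dt, dh, dw) in enumerate(product(range(kt), range(kh), range(kw))):
            patches[:, :, idx] = xp[:, :,
                                    dt:dt + To * st:st,
                                    dh:dh + Ho * sh:sh,
                                    dw:dw + Wo * sw:sw]
        L = To * Ho * Wo
        CK = C * kt * kh * kw
        cols = patches.reshape(N, CK, L)      # view, contiguous per sample
        wmat = self.w.value.reshape(self.cout, CK)
        out = np.empty((N, self.cout, L), dtype=np.float32)
        for n in range(N):                    # per-sample GEMM, no transposes
            np.matmul(wmat, cols[n], out=out[n])
        out += self.b.value[None, :, None]
        self._cache = (cols, x.shape, (To, Ho, Wo))
        return out.reshape(N, self.cout, To, Ho, Wo)

    def backward(self, dout):
        cols, xshape, (To, Ho, Wo) = self._cache
        self._cache = None
        N, C, T, H, W = xshape
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.pad
        L = To * Ho * Wo
        CK = C * kt * kh * kw
        dmat = dout.reshape(N, self.cout, L)
        wmat = self.w.value.reshape(self.cout, CK)
        dw = np.zeros((self.cout, CK), dtype=np.float32)
        dcols = np.empty((N, CK, L), dtype=np.float32)
        for n in range(N):
            dw += dmat[n] @ cols[n].T
            np.matmul(wmat.T, dmat[n], out=dcols[n])
        self.w.grad += dw.reshape(self.w.value.shape)
        self.b.grad += dmat.sum(axis=(0, 2))
        dpatches = dcols.reshape(N, C, kt * kh * kw, To, Ho, Wo)
        dxp = np.zeros((N, C, T + 2 * pt, H + 2 * ph, W + 2 * pw),
                       dtype=np.float32)
        for idx, (dt, dh, dw_) in enumerate(product(range(kt), range(kh), range(kw))):
            dxp[:, :,
                dt:dt + To * st:st,
                dh:dh + Ho * sh:sh,
                dw_:dw_ + Wo * sw:sw] += dpatches[:, :, idx]
        return dxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W]


class BatchNorm3d:
    """Per-channel batch normalisation over (N, T, H, W)."""

    def __init__(self, channels, eps=1e-5, momentum=0.9):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def n_params(self) -> int:
        return self.gamma.value.size + self.beta.value.size

    def forward(self, x, train=True):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out = (self.gamma.value[None, :, None, None, None] * xhat
               + self.beta.value[None, :, None, None, None])
        if train:
            self._cache = (xhat, inv, x.shape)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv, shape = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        m = shape[0] * shape[2] * shape[3] * shape[4]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        dxhat = dout * g
        dx = (inv[None, :, None, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Linear:
    def __init__(self, cin, cout, rng):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class _ConvBnRelu:
    def __init__(self, cin, cout, kernel, stride, rng, relu=True):
        self.conv = Conv3d(cin, cout, kernel, stride, rng=rng)
        self.bn = BatchNorm3d(cout)
        self.relu = ReLU() if relu else None

    def params(self):
        return self.conv.params() + self.bn.params()

    def n_params(self):
        return self.conv.n_params() + self.bn.n_params()

    def forward(self, x, train=True):
        x = self.conv.forward(x, train)
        x = self.bn.forward(x, train)
        if self.relu is not None:
            x = self.relu.forward(x, train)
        return x

    def backward(self, dout):
        if self.relu is not None:
            dout = self.relu.backward(dout)
        dout = self.bn.backward(dout)
        return self.conv.backward(dout)


class ResidualBlock:
    """Basic 3x3x3 residual block with a projection shortcut when needed."""

    def __init__(self, cin, cout, spatial_stride, rng):
        stride = (1, spatial_stride, spatial_stride)
        self.c1 = _ConvBnRelu(cin, cout, (3, 3, 3), stride, rng)
        self.c2 = _ConvBnRelu(cout, cout, (3, 3, 3), (1, 1, 1), rng, relu=False)
        if cin != cout or spatial_stride != 1:
            self.short = _ConvBnRelu(cin, cout, (1, 1, 1), stride, rng, relu=False)
        else:
            self.short = None
        self.out_relu = ReLU()

    def params(self):
        ps = self.c1.params() + self.c2.params() + self.out_relu.params()
        if self.short is not None:
            ps += self.short.params()
        return ps

    def n_params(self):
        n = self.c1.n_params() + self.c2.n_params()
        if self.short is not None:
            n += self.short.n_params()
        return n

    def forward(self, x, train=True):
        main = self.c2.forward(self.c1.forward(x, train), train)
        skip = x if self.short is None else self.short.forward(x, train)
        return self.out_relu.forward(main + skip, train)

    def backward(self, dout):
        dout = self.out_relu.backward(dout)
        dmain = self.c1.backward(self.c2.backward(dout))
        dskip = dout if self.short is None else self.short.backward(dout)
        return dmain + dskip


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def n_params(self):
        return sum(l.n_params() for l in self.layers)

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# The two-pathway model
# ---------------------------------------------------------------------------

class SlowFastModel:
    """Two-pathway classifier. Build with :func:`build_model`.

    Forward input is a uint8 or float clip batch of shape (N, T, H, W); the
    model handles frame-rate subsampling into the two pathways internally.
    """

    def __init__(self, cfg: SlowFastConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths, blocks = cfg.slow_widths, DEPTH_PRESETS[cfg.depth]["blocks"]
        fwidths = cfg.fast_widths
        cin = cfg.in_channels
        t_ratio = cfg.fast_frames // cfg.slow_frames  # = alpha

        # stems: spatial stride 2, no temporal stride; the slow stem has no
        # temporal extent (spatial semantics), the fast stem has kernel 3.
        self.slow_stem = _ConvBnRelu(cin, widths[0], (1, 5, 5), (1, 2, 2), rng)
        self.fast_stem = _ConvBnRelu(cin, fwidths[0], (3, 5, 5), (1, 2, 2), rng)

        # lateral fusion after the stem and after every stage but the last:
        # time-strided conv fast -> 2*c_fast channels, concatenated to slow.
        self.laterals = []
        self.slow_stages = []
        self.fast_stages = []
        n_fusions = len(widths)  # stem + all stages except the last
        c_slow, c_fast = widths[0], fwidths[0]
        for si, (w, fw, nb) in enumerate(zip(widths, fwidths, blocks)):
            lat = _ConvBnRelu(c_fast, 2 * c_fast, (5, 1, 1),
                              (t_ratio, 1, 1), rng)
            self.laterals.append(lat)
            slow_blocks = []
            fast_blocks = []
            cin_s = c_slow + 2 * c_fast
            cin_f = c_fast
            for bi in range(nb):
                stride = 2 if bi == 0 else 1
                slow_blocks.append(ResidualBlock(cin_s, w, stride, rng))
                fast_blocks.append(ResidualBlock(cin_f, fw, stride, rng))
                cin_s, cin_f = w, fw
            self.slow_stages.append(_Sequential(slow_blocks))
            self.fast_stages.append(_Sequential(fast_blocks))
            c_slow, c_fast = w, fw

        # head features: spatial average, then temporal mean AND max per
        # pathway — deformation in the constriction is a transient event,
        # and a temporal max lets it survive pooling over the whole clip
        self.head = Linear(2 * (widths[-1] + fwidths[-1]), cfg.n_classes, rng)
        self._drop_rng = np.random.default_rng(seed + 1)
        self._cache = None

    # -- plumbing ----------------------------------------------------------

    def params(self):
        ps = self.slow_stem.params() + self.fast_stem.params()
        for lat, ss, fs in zip(self.laterals, self.slow_stages, self.fast_stages):
            ps += lat.params() + ss.params() + fs.params()
        ps += self.head.params()
        return ps

    def parameter_counts(self) -> dict:
        """Learnable parameter counts per component."""
        slow = self.slow_stem.n_params() + sum(s.n_params() for s in self.slow_stages)
        fast = self.fast_stem.n_params() + sum(s.n_params() for s in self.fast_stages)
        lateral = sum(l.n_params() for l in self.laterals)
        head = self.head.n_params()
        return {"slow": slow, "fast": fast, "lateral": lateral, "head": head,
                "total": slow + fast + lateral + head}

    def _preprocess(self, clips):
        x = np.asarray(clips, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError("clip batch must have shape (N, T, H, W)")
        N, T, H, W = x.shape
        cfg = self.cfg
        if T != cfg.clip_frames or H != cfg.clip_size or W != cfg.clip_size:
            raise ValueError(
                f"clip shape {(T, H, W)} does not match configured input "
                f"{(cfg.clip_frames, cfg.clip_size, cfg.clip_size)}")
        x = (x / 255.0 - 0.5) / 0.25
        if cfg.spatial_pool > 1:
            p = cfg.spatial_pool
            x = x.reshape(N, T, H // p, p, W // p, p).mean(axis=(3, 5))
        fast_stride = cfg.tau // cfg.alpha
        xs = x[:, ::cfg.tau][:, None]           # (N, 1, T/tau, H, W)
        xf = x[:, ::fast_stride][:, None]       # (N, 1, T*alpha/tau, H, W)
        return xs, xf

    # -- forward / backward ------------------------------------------------

    def forward(self, clips, train=True):
        """Logits of shape (N, n_classes)."""
        xs, xf = self._preprocess(clips)
        s = self.slow_stem.forward(xs, train)
        f = self.fast_stem.forward(xf, train)
        fusion_channels = []
        for lat, sstage, fstage in zip(self.laterals, self.slow_stages,
                                       self.fast_stages):
            l = lat.forward(f, train)
            fusion_channels.append((s.shape[1], l.shape[1]))
            s = sstage.forward(np.concatenate([s, l], axis=1), train)
            f = fstage.forward(f, train)
        s_t = s.mean(axis=(3, 4))           # (N, C, T)
        f_t = f.mean(axis=(3, 4))
        s_arg = s_t.argmax(axis=2)
        f_arg = f_t.argmax(axis=2)
        h = np.concatenate([s_t.mean(axis=2), s_t.max(axis=2),
                            f_t.mean(axis=2), f_t.max(axis=2)], axis=1)
        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (self._drop_rng.random(h.shape) < keep) / keep
            h = h * mask
        else:
            mask = None
        logits = self.head.forward(h.astype(np.float32), train)
        if train:
            self._cache = (s.shape, f.shape, fusion_channels, mask,
                           s_arg, f_arg)
        return logits

    @staticmethod
    def _head_grad(dmean, dmax, argmax, shape):
        """Gradient through spatial mean + temporal mean/max pooling."""
        N, C, T, H, W = shape
        d_t = np.repeat(dmean[:, :, None] / T, T, axis=2)    # (N, C, T)
        np.put_along_axis(
            d_t, argmax[:, :, None],
            np.take_along_axis(d_t, argmax[:, :, None], axis=2)
            + dmax[:, :, None], axis=2)
        return np.broadcast_to(d_t[:, :, :, None, None] / (H * W),
                               shape).astype(np.float32)

    def backward(self, dlogits):
        s_shape, f_shape, fusion_channels, mask, s_arg, f_arg = self._cache
        self._cache = None
        dh = self.head.backward(dlogits)
        if mask is not None:
            dh = dh * mask
        cs, cf = s_shape[1], f_shape[1]
        ds = self._head_grad(dh[:, :cs], dh[:, cs:2 * cs], s_arg, s_shape)
        df = self._head_grad(dh[:, 2 * cs:2 * cs + cf], dh[:, 2 * cs + cf:],
                             f_arg, f_shape)
        for lat, sstage, fstage, (n_s, n_l) in zip(
                reversed(self.laterals), reversed(self.slow_stages),
                reversed(self.fast_stages), reversed(fusion_channels)):
            df = fstage.backward(df)
            dcat = sstage.backward(ds)
            ds = dcat[:, :n_s]
            df = df + lat.backward(dcat[:, n_s:])
        self.slow_stem.backward(ds)
        self.fast_stem.backward(df)

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def predict_proba(self, clips, batch_size=16) -> np.ndarray:
        """Softmax class probabilities in evaluation mode (deterministic)."""
        clips = np.asarray(clips)
        if len(clips) == 0:
            return np.zeros((0, self.cfg.n_classes), dtype=np.float32)
        out = []
        for i in range(0, len(clips), batch_size):
            logits = self.forward(clips[i:i + batch_size], train=False)
            out.append(_softmax(logits))
        return np.concatenate(out, axis=0)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    ``labels`` may be integer class indices or an (n, k) matrix of soft
    target distributions (used by mixup)."""
    p = _softmax(logits)
    labels = np.asarray(labels)
    n = len(labels)
    if labels.ndim == 1:
        target = np.zeros_like(p)
        target[np.arange(n), labels] = 1.0
    else:
        target = labels
    loss = -np.mean(np.sum(target * np.log(p + 1e-12), axis=1))
    grad = (p - target) / n
    return float(loss), grad.astype(np.float32)


class SGD:
    """Stochastic gradient descent with momentum (default 0.9)."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v


def build_model(cfg: SlowFastConfig, seed: int = 0) -> SlowFastModel:
    """Construct the two-pathway model for a given configuration."""
    return SlowFastModel(cfg, seed=seed)


def save_model(model: SlowFastModel, path) -> None:
    """Checkpoint: config (JSON) + parameters + batch-norm running stats."""
    import json
    from dataclasses import asdict

    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    bn_stats = {}
    stack = [model.slow_stem, model.fast_stem, *model.laterals]
    for seq in (*model.slow_stages, *model.fast_stages):
        stack.extend(seq.layers)
    i = 0
    for layer in stack:
        for bn in _bn_modules(layer):
            bn_stats[f"bn{i}_mean"] = bn.running_mean
            bn_stats[f"bn{i}_var"] = bn.running_var
            i += 1
    np.savez_compressed(path, config=json.dumps(asdict(model.cfg)),
                        **arrays, **bn_stats)


def _bn_modules(layer):
    if isinstance(layer, _ConvBnRelu):
        return [layer.bn]
    if isinstance(layer, ResidualBlock):
        out = [layer.c1.bn, layer.c2.bn]
        if layer.short is not None:
            out.append(layer.short.bn)
        return out
    return []


def load_model(path) -> SlowFastModel:
    """Restore a checkpointed model (architecture rebuilt from the embedded
    config, weights and running statistics restored exactly)."""
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = SlowFastConfig(**json.loads(str(data["config"])))
        model = SlowFastModel(cfg, seed=0)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        stack = [model.slow_stem, model.fast_stem, *model.laterals]
        for seq in (*model.slow_stages, *model.fast_stages):
            stack.extend(seq.layers)
        i = 0
        for layer in stack:
            for bn in _bn_modules(layer):
                bn.running_mean = data[f"bn{i}_mean"].copy()
                bn.running_var = data[f"bn{i}_var"].copy()
                i += 1
    return model


def predict(model: SlowFastModel, clips) -> list[ModelOutput]:
    """Per-clip class scores in evaluation mode (dropout off)."""
    if hasattr(clips[0], "pixels"):
        batch = np.stack([c.pixels for c in clips])
    else:
        batch = np.asarray(clips)
    probs = model.predict_proba(batch)
    return [ModelOutput(scores=p) for p in probs]
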