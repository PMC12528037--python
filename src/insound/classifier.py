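"""The lightweight 11-stage spectrogram-image classifier.

The backbone interleaves five stride-2 3x3 convolutions (16-32-64-128-256
channels) with CSP-style dual-branch blocks: C3k2 blocks split the feature
map into a pass-through branch and a bottleneck-transformed branch (channel
reduction 0.25 at the early stages, residual connections at the late ones),
and a C2PSA block applies pyramid pooled-scale attention with per-channel
squeeze weighting and a spatial gate before the classification head
(1x1 embedding convolution, global average pooling, dropout, linear layer,
softmax).  All free internal widths are fixed once (head embedding 384,
squeeze hidden width 32, pyramid scales 1/2/4) which puts the trainable
parameter count at 1.54 million.

Everything runs on the in-package NumPy autograd (:mod:`insound.nn`);
training, initialization and augmentation are deterministic under explicit
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from . import nn
from .nn import Parameter, Tensor, conv2d, linear, batch_norm2d, softmax, softmax_cross_entropy

__all__ = [
    "AugmentConfig",
    "StageSpec",
    "ModelConfig",
    "TrainConfig",
    "FlopReport",
    "default_stage_table",
    "build_model",
    "count_parameters",
    "count_flops",
    "train",
    "set_freeze_policy",
    "predict",
    "augment",
    "eval_transform",
    "save_model",
    "load_model",
]

NUM_CLASSES = 12


# --------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time image augmentation: crop, rotate, jitter."""

    resize: int = 256
    crop_scale: tuple[float, float] = (0.8, 1.0)
    rotation_deg: float = 10.0
    jitter: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class StageSpec:
    operator: str  # conv | c3k2 | c2psa | classify
    filters: int
    kernel: int = 0
    stride: int = 0
    residual: bool = False
    channel_reduction: float = 0.0


def default_stage_table(num_classes: int = NUM_CLASSES) -> list[StageSpec]:
    """The reference 11-stage configuration of the architecture."""
    return [
        StageSpec("conv", 16, 3, 2),
        StageSpec("conv", 32, 3, 2),
        StageSpec("c3k2", 64, residual=False, channel_reduction=0.25),
        StageSpec("conv", 64, 3, 2),
        StageSpec("c3k2", 128, residual=False, channel_reduction=0.25),
        StageSpec("conv", 128, 3, 2),
        StageSpec("c3k2", 128, residual=True, channel_reduction=0.5),
        StageSpec("conv", 256, 3, 2),
        StageSpec("c3k2", 256, residual=True, channel_reduction=0.5),
        StageSpec("c2psa", 256),
        StageSpec("classify", num_classes),
    ]


@dataclass(frozen=True)
class ModelConfig:
    stages: tuple[StageSpec, ...] = tuple(default_stage_table())
    num_classes: int = NUM_CLASSES
    input_size: int = 256
    head_embed: int = 384
    pyramid_scales: tuple[int, ...] = (1, 2, 4)
    se_hidden: int = 32
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.stages) != 11:
            raise ValueError("the architecture table has exactly 11 stages")
        if self.stages[-1].operator != "classify":
            raise ValueError("stage 11 must be the classification head")
        if self.stages[-1].filters != self.num_classes:
            raise ValueError("classify stage width must equal num_classes")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol; reference settings are SGD at 0.1, batch 32,
    cross-entropy, no dropout and no early stopping."""

    optimizer: str = "sgd"
    lr: float = 0.1
    epochs: int = 150
    batch: int = 32
    momentum: float = 0.9
    early_stop_patience: int | None = None
    dropout: float = 0.0
    freeze_through_stage: int | None = None
    seed: int = 0
    augment: AugmentConfig | None = None

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be sgd or adam")


# --------------------------------------------------------------------------
# modules


class Module:
    def __init__(self) -> None:
        self.training = True
        self.frozen = False

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def parameters(self):
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Parameter):
                        yield u
        for child in self._children():
            yield from child.parameters()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self._children():
            child.set_training(flag)

    def set_frozen(self, flag: bool) -> None:
        self.frozen = flag
        for p in self.parameters():
            p.requires_grad = not flag
        for child in self._children():
            child.frozen = flag


def _he_conv(rng: np.random.Generator, out_c: int, in_c: int, k: int) -> Parameter:
    std = np.sqrt(2.0 / (in_c * k * k))
    return Parameter(rng.normal(0.0, std, size=(out_c, in_c, k, k)))


class ConvBN(Module):
    """Convolution (no bias) + batch norm + optional SiLU."""

    def __init__(self, rng, in_c, out_c, k=1, stride=1, act=True):
        super().__init__()
        self.weight = _he_conv(rng, out_c, in_c, k)
        self.gamma = Parameter(np.ones(out_c))
        self.beta = Parameter(np.zeros(out_c))
        self.running_mean = np.zeros(out_c, dtype=np.float32)
        self.running_var = np.ones(out_c, dtype=np.float32)
        self.k, self.stride, self.act = k, stride, act

    def __call__(self, x: Tensor) -> Tensor:
        pad = self.k // 2
        out = conv2d(x, self.weight, stride=self.stride, pad=pad)
        out = batch_norm2d(
            out,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training and not self.frozen,
            update_stats=self.training and not self.frozen,
        )
        return out.silu() if self.act else out


class Bottleneck(Module):
    """3x3 -> 3x3 at a reduced hidden width, optional residual add."""

    def __init__(self, rng, c, hidden, residual):
        super().__init__()
        self.cv1 = ConvBN(rng, c, hidden, k=3)
        self.cv2 = ConvBN(rng, hidden, c, k=3)
        self.residual = residual

    def __call__(self, x: Tensor) -> Tensor:
        out = self.cv2(self.cv1(x))
        return x + out if self.residual else out


class C3k2(Module):
    """Dual-branch CSP block: pass-through half + bottleneck-transformed half.

    The hidden width of the transform is ``filters * channel_reduction``; the
    two halves are concatenated and fused by a 1x1 convolution.  The residual
    connection (where the architecture table marks one) sits inside the
    bottleneck.
    """

    def __init__(self, rng, in_c, out_c, reduction, residual, n=1):
        super().__init__()
        half = out_c // 2
        hidden = max(1, int(round(out_c * reduction)))
        self.cv_a = ConvBN(rng, in_c, half)
        self.cv_b = ConvBN(rng, in_c, half)
        self.blocks = [Bottleneck(rng, half, hidden, residual) for _ in range(n)]
        self.fuse = ConvBN(rng, 2 * half, out_c)

    def __call__(self, x: Tensor) -> Tensor:
        a = self.cv_a(x)
        b = self.cv_b(x)
        for blk in self.blocks:
            b = blk(b)
        return self.fuse(Tensor.concat_channels([a, b]))


class C2PSA(Module):
    """CSP block with pyramid pooled-scale attention.

    One half passes through; the other is refined by (i) a pyramid of
    average-pooled contexts at scales 1/2/4 re-projected by 1x1 convolutions
    and summed back, (ii) a per-channel squeeze gate, (iii) a spatial gate
    from channel mean/max maps, and (iv) a 3x3 fuse convolution, before the
    halves are concatenated and mixed by a final 1x1 convolution.
    """

    def __init__(self, rng, c, scales=(1, 2, 4), se_hidden=32):
        super().__init__()
        half = c // 2
        self.cv1 = ConvBN(rng, c, c)
        self.pyramid = [ConvBN(rng, half, half) for _ in scales]
        self.scales = tuple(scales)
        self.se_w1 = Parameter(rng.normal(0.0, np.sqrt(2.0 / half), size=(half, se_hidden)))
        self.se_b1 = Parameter(np.zeros(se_hidden))
        self.se_w2 = Parameter(rng.normal(0.0, np.sqrt(1.0 / se_hidden), size=(se_hidden, half)))
        self.se_b2 = Parameter(np.zeros(half))
        self.spatial = Parameter(rng.normal(0.0, np.sqrt(2.0 / (2 * 49)), size=(1, 2, 7, 7)))
        self.spatial_b = Parameter(np.zeros(1))
        self.fuse = ConvBN(rng, half, half, k=3)
        self.cv2 = ConvBN(rng, c, c)
        self.half = half

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a = y.slice_channels(0, self.half)
        b = y.slice_channels(self.half, 2 * self.half)
        H, W = b.shape[2], b.shape[3]
        ctx = b
        for s, conv in zip(self.scales, self.pyramid):
            pooled = b.adaptive_avg_pool(min(s, H, W))
            proj = conv(pooled)
            ctx = ctx + proj.upsample_nearest((H, W))
        sq = ctx.global_avg_pool()  # (B, half)
        gate_c = linear(linear(sq, self.se_w1, self.se_b1).silu(), self.se_w2, self.se_b2).sigmoid()
        B = gate_c.shape[0]
        ctx = ctx * gate_c.reshape(B, self.half, 1, 1)
        sm = Tensor.concat_channels([ctx.channel_mean(), ctx.channel_max()])
        gate_s = conv2d(sm, self.spatial, stride=1, pad=3, bias=self.spatial_b).sigmoid()
        ctx = ctx * gate_s
        out = self.fuse(ctx)
        return self.cv2(Tensor.concat_channels([a, out]))


class Head(Module):
    """1x1 embedding conv -> global average pool -> dropout -> linear -> softmax."""

    def __init__(self, rng, in_c, embed, num_classes, dropout=0.0):
        super().__init__()
        self.embed = ConvBN(rng, in_c, embed)
        self.w = Parameter(rng.normal(0.0, np.sqrt(1.0 / embed), size=(embed, num_classes)))
        self.b = Parameter(np.zeros(num_classes))
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        feat = self.embed(x).global_avg_pool()
        if self.training and self.dropout > 0 and rng is not None:
            feat = feat.dropout(self.dropout, rng)
        return linear(feat, self.w, self.b)


class SpectrogramClassifier(Module):
    """The full 11-stage network; ``stages[i]`` is table stage ``i + 1``."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        stages: list[Module] = []
        in_c = 3
        for spec in config.stages[:-1]:
            if spec.operator == "conv":
                stages.append(ConvBN(rng, in_c, spec.filters, k=spec.kernel, stride=spec.stride))
            elif spec.operator == "c3k2":
                stages.append(C3k2(rng, in_c, spec.filters, spec.channel_reduction, spec.residual))
            elif spec.operator == "c2psa":
                stages.append(C2PSA(rng, spec.filters, config.pyramid_scales, config.se_hidden))
            else:
                raise ValueError(f"unknown operator {spec.operator!r}")
            in_c = spec.filters
        stages.append(Head(rng, in_c, config.head_embed, config.num_classes, config.dropout))
        self.stages = stages

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        t = Tensor(x)
        for stage in self.stages[:-1]:
            t = stage(t)
        return self.stages[-1](t, rng)

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        self.set_training(False)
        outs = []
        for i in range(0, len(x), batch):
            logits = self.forward(x[i : i + batch])
            outs.append(softmax(logits.data.astype(np.float64)))
        return np.concatenate(outs, axis=0)

    def stage_output_channels(self) -> list[int]:
        return [s.filters for s in self.config.stages]


# --------------------------------------------------------------------------
# public operations


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SpectrogramClassifier:
    """Instantiate the network with deterministic He initialization."""
    return SpectrogramClassifier(config or ModelConfig(), seed=seed)


def count_parameters(model: SpectrogramClassifier, as_millions: bool = True):
    """Trainable parameter count; frozen stages are excluded."""
    total = sum(p.data.size for p in model.parameters() if p.requires_grad)
    return round(total / 1e6, 2) if as_millions else int(total)


@dataclass(frozen=True)
class FlopReport:
    gflops: float
    macs: int
    convention: str


def count_flops(model: SpectrogramClassifier, input_size: int | None = None) -> FlopReport:
    """Static complexity: multiply-accumulates of one forward pass, x2 for FLOPs."""
    size = input_size or model.config.input_size
    was_training = model.training
    model.set_training(False)
    with nn.flop_counter() as fc:
        model.forward(np.zeros((1, 3, size, size), dtype=np.float32))
    model.set_training(was_training)
    return FlopReport(
        gflops=2.0 * fc.macs / 1e9,
        macs=fc.macs,
        convention=f"multiply-accumulate x 2, batch 1, input 3x{size}x{size}",
    )


def set_freeze_policy(model: SpectrogramClassifier, freeze_through_stage: int | None) -> SpectrogramClassifier:
    """Freeze table stages 1..freeze_through_stage (0 or None = all trainable)."""
    n = freeze_through_stage or 0
    if not 0 <= n <= 11:
        raise ValueError("freeze_through_stage must lie in [0, 11]")
    for i, stage in enumerate(model.stages, start=1):
        stage.set_frozen(i <= n)
    return model


class _SGD:
    def __init__(self, params, lr, momentum=0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def train(
    model: SpectrogramClassifier,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Minimize cross-entropy; returns per-epoch history (loss, val accuracy).

    ``X`` is (N, 3, H, W) float32 in [0, 1].  All randomness (shuffling,
    dropout, augmentation) flows from ``config.seed``.  History length equals
    the epoch count unless early stopping is configured and triggers.
    """
    if len(X) == 0:
        raise ValueError("empty training split")
    if config.freeze_through_stage is not None:
        set_freeze_policy(model, config.freeze_through_stage)
    model.set_training(True)
    for head in model.stages[-1:]:
        head.dropout = config.dropout
    params = [p for p in model.parameters() if p.requires_grad]
    opt = (_SGD(params, config.lr, config.momentum) if config.optimizer == "sgd"
           else _Adam(params, config.lr))
    rng = np.random.default_rng(config.seed)
    history = {"loss": [], "val_accuracy": []}
    best_val, since_best = -np.inf, 0
    for _epoch in range(config.epochs):
        model.set_training(True)
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(order), config.batch):
            idx = order[i : i + config.batch]
            xb = X[idx]
            if config.augment is not None:
                xb = np.stack([_augment_chw(img, config.augment, rng) for img in xb])
            opt.zero_grad()
            loss = softmax_cross_entropy(model.forward(xb, rng), y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        if X_val is not None and len(X_val):
            acc = float(np.mean(model.predict_proba(X_val).argmax(axis=1) == y_val))
        else:
            acc = np.nan
        history["val_accuracy"].append(acc)
        if config.early_stop_patience is not None and np.isfinite(acc):
            if acc > best_val:
                best_val, since_best = acc, 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break
    model.set_training(False)
    return history


def predict(model: SpectrogramClassifier, images: np.ndarray) -> np.ndarray:
    """Probability rows (softmax) for a batch of images.

    Accepts (B, 3, H, W) float arrays in [0, 1] or (B, H, W, 3) uint8 images.
    """
    x = _as_model_input(images)
    probs = model.predict_proba(x)
    return probs / probs.sum(axis=1, keepdims=True)


def _as_model_input(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images)
    if images.ndim != 4:
        raise ValueError("expected a batch of images")
    if images.shape[-1] == 3 and images.dtype == np.uint8:
        return (images.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)
    if images.shape[1] == 3:
        return images.astype(np.float32)
    raise ValueError("images must be (B, 3, H, W) float or (B, H, W, 3) uint8")


def _state_arrays(model: SpectrogramClassifier) -> dict[str, np.ndarray]:
    """Flat name -> array map of parameters and batch-norm running stats."""
    out: dict[str, np.ndarray] = {}

    def walk(mod: Module, prefix: str) -> None:
        for name, v in mod.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                walk(v, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    if isinstance(u, Module):
                        walk(u, f"{key}.{i}.")
                    elif isinstance(u, Parameter):
                        out[f"{key}.{i}"] = u.data

    walk(model, "")
    return out


def save_model(model: SpectrogramClassifier, path: str) -> str:
    """Checkpoint parameters + batch-norm statistics to an npz file."""
    np.savez_compressed(path, **_state_arrays(model))
    return path


def load_model(path: str, config: ModelConfig | None = None) -> SpectrogramClassifier:
    """Rebuild a model and load a checkpoint written by :func:`save_model`.

    This doubles as the transfer-learning entry point: load a pretrained
    checkpoint, then :func:`set_freeze_policy` the lower stages and fine-tune.
    """
    model = build_model(config, seed=0)
    with np.load(path) as data:
        state = _state_arrays(model)
        if set(data.files) != set(state):
            raise ValueError("checkpoint does not match the model architecture")
        for key, arr in state.items():
            loaded = data[key]
            if loaded.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}")
            arr[...] = loaded
    model.set_training(False)
    return model


# --------------------------------------------------------------------------
# augmentation


def eval_transform(image: np.ndarray, size: int = 256) -> np.ndarray:
    """Deterministic evaluation path: resize + scale to [0, 1], CHW float32."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    if img.shape[:2] != (size, size):
        img = _sk_resize(img, (size, size), order=1, mode="edge", anti_aliasing=False)
    return np.ascontiguousarray(img.transpose(2, 0, 1).astype(np.float32))


def augment(image: np.ndarray, config: AugmentConfig, seed: int | None = None) -> np.ndarray:
    """Seeded random crop -> resize -> rotation -> color jitter -> [0, 1] CHW."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chw = eval_transform(image, config.resize)
    return _augment_chw(chw, config, rng)


def _augment_chw(chw: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    img = chw.transpose(1, 2, 0)  # HWC float in [0, 1]
    size = config.resize
    # random area crop
    scale = rng.uniform(*config.crop_scale)
    side = max(1, int(round(size * np.sqrt(scale))))
    if side < size:
        y0 = int(rng.integers(0, size - side + 1))
        x0 = int(rng.integers(0, size - side + 1))
        img = img[y0 : y0 + side, x0 : x0 + side]
        img = _sk_resize(img, (size, size), order=1, mode="edge", anti_aliasing=False)
    # rotation
    angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg))
    if abs(angle) > 1e-3:
        img = _sk_rotate(img, angle, mode="edge", order=1)
    # color jitter: brightness/contrast/saturation
    j = config.jitter
    if j > 0:
        img = img * (1.0 + rng.uniform(-j, j))  # brightness
        mean = img.mean()
        img = (img - mean) * (1.0 + rng.uniform(-j, j)) + mean  # contrast
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (img - gray) * (1.0 + rng.uniform(-j, j))  # saturation
    return np.ascontiguousarray(np.clip(img, 0.0, 1.0).transpose(2, 0, 1).astype(np.float32))
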