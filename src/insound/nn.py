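"""A small reverse-mode automatic-differentiation engine over NumPy arrays.

Just enough machinery to express and train the convolutional classifier on a
CPU: tensors with a backward tape, 2-D convolution via im2col with a
col2im backward, batch normalization, SiLU/sigmoid nonlinearities, channel
concatenation/slicing, adaptive average pooling with nearest upsampling,
dropout, linear layers and a fused softmax cross-entropy.  Convolutions and
linear layers optionally report multiply-accumulate counts for complexity
accounting.

Everything is float32 and fully deterministic given explicit generators.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "flop_counter"]

_FLOP_COUNTER: list | None = None


class flop_counter:
    """Context manager accumulating multiply-accumulate counts of conv/linear ops."""

    def __init__(self) -> None:
        self.macs = 0

    def __enter__(self):
        global _FLOP_COUNTER
        self._prev = _FLOP_COUNTER
        _FLOP_COUNTER = [0]
        return self

    def __exit__(self, *exc):
        global _FLOP_COUNTER
        self.macs = _FLOP_COUNTER[0]
        _FLOP_COUNTER = self._prev
        return False


def _count_macs(n: int) -> None:
    if _FLOP_COUNTER is not None:
        _FLOP_COUNTER[0] += int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad over dimensions that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free the tape

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        # always copy on first store: g may alias a child's grad buffer
        if t.grad is None:
            t.grad = np.array(g, dtype=np.float32)
        else:
            t.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        data = a.data + b.data

        def backward(grad):
            if a.requires_grad:
                Tensor._accum(a, _unbroadcast(grad, a.data.shape))
            if b.requires_grad:
                Tensor._accum(b, _unbroadcast(grad, b.data.shape))

        return Tensor._make(data, (a, b), backward, a.requires_grad or b.requires_grad)

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        data = a.data * b.data

        def backward(grad):
            if a.requires_grad:
                Tensor._accum(a, _unbroadcast(grad * b.data, a.data.shape))
            if b.requires_grad:
                Tensor._accum(b, _unbroadcast(grad * a.data, b.data.shape))

        return Tensor._make(data, (a, b), backward, a.requires_grad or b.requires_grad)

    def scale(self, c: float) -> "Tensor":
        data = self.data * np.float32(c)
        src = self

        def backward(grad):
            Tensor._accum(src, grad * np.float32(c))

        return Tensor._make(data, (src,), backward, src.requires_grad)

    # -- activations -------------------------------------------------------
    def silu(self) -> "Tensor":
        src = self
        with np.errstate(over="ignore"):  # exp overflow saturates correctly
            sig = 1.0 / (1.0 + np.exp(-src.data))
        data = src.data * sig

        def backward(grad):
            Tensor._accum(src, grad * (sig * (1.0 + src.data * (1.0 - sig))))

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def sigmoid(self) -> "Tensor":
        src = self
        with np.errstate(over="ignore"):
            data = 1.0 / (1.0 + np.exp(-src.data))

        def backward(grad):
            Tensor._accum(src, grad * data * (1.0 - data))

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def relu(self) -> "Tensor":
        src = self
        mask = src.data > 0
        data = np.where(mask, src.data, 0.0)

        def backward(grad):
            Tensor._accum(src, grad * mask)

        return Tensor._make(data, (src,), backward, src.requires_grad)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        src = self
        data = src.data.reshape(*shape)

        def backward(grad):
            Tensor._accum(src, grad.reshape(src.data.shape))

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def slice_channels(self, start: int, stop: int) -> "Tensor":
        src = self
        data = src.data[:, start:stop]

        def backward(grad):
            full = np.zeros_like(src.data)
            full[:, start:stop] = grad
            Tensor._accum(src, full)

        return Tensor._make(data, (src,), backward, src.requires_grad)

    @staticmethod
    def concat_channels(tensors: list["Tensor"]) -> "Tensor":
        data = np.concatenate([t.data for t in tensors], axis=1)
        sizes = [t.data.shape[1] for t in tensors]

        def backward(grad):
            ofs = 0
            for t, c in zip(tensors, sizes):
                if t.requires_grad:
                    Tensor._accum(t, grad[:, ofs : ofs + c])
                ofs += c

        req = any(t.requires_grad for t in tensors)
        return Tensor._make(data, tuple(tensors), backward, req)

    # -- reductions over space/channels -----------------------------------
    def global_avg_pool(self) -> "Tensor":
        """(B, C, H, W) -> (B, C)."""
        src = self
        B, C, H, W = src.data.shape
        data = src.data.mean(axis=(2, 3))

        def backward(grad):
            g = np.broadcast_to(grad[:, :, None, None] / (H * W), src.data.shape)
            Tensor._accum(src, g)

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def adaptive_avg_pool(self, out_size: int) -> "Tensor":
        """Average pool (B, C, H, W) to (B, C, s, s); H must be a multiple of s."""
        src = self
        B, C, H, W = src.data.shape
        s = min(out_size, H, W)
        if H % s or W % s:
            raise ValueError("adaptive_avg_pool requires divisible sizes")
        kh, kw = H // s, W // s
        data = src.data.reshape(B, C, s, kh, s, kw).mean(axis=(3, 5))

        def backward(grad):
            g = grad[:, :, :, None, :, None] / (kh * kw)
            g = np.broadcast_to(g, (B, C, s, kh, s, kw)).reshape(B, C, H, W)
            Tensor._accum(src, g)

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def upsample_nearest(self, out_hw: tuple[int, int]) -> "Tensor":
        src = self
        B, C, H, W = src.data.shape
        oh, ow = out_hw
        if oh % H or ow % W:
            raise ValueError("upsample_nearest requires integer scale factors")
        rh, rw = oh // H, ow // W
        data = np.repeat(np.repeat(src.data, rh, axis=2), rw, axis=3)

        def backward(grad):
            g = grad.reshape(B, C, H, rh, W, rw).sum(axis=(3, 5))
            Tensor._accum(src, g)

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def channel_mean(self) -> "Tensor":
        """(B, C, H, W) -> (B, 1, H, W)."""
        src = self
        C = src.data.shape[1]
        data = src.data.mean(axis=1, keepdims=True)

        def backward(grad):
            Tensor._accum(src, np.broadcast_to(grad / C, src.data.shape))

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def channel_max(self) -> "Tensor":
        """(B, C, H, W) -> (B, 1, H, W); gradient routes to the argmax channel."""
        src = self
        idx = src.data.argmax(axis=1, keepdims=True)
        data = np.take_along_axis(src.data, idx, axis=1)

        def backward(grad):
            full = np.zeros_like(src.data)
            np.put_along_axis(full, idx, grad, axis=1)
            Tensor._accum(src, full)

        return Tensor._make(data, (src,), backward, src.requires_grad)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        if p <= 0:
            return self
        src = self
        keep = (rng.random(src.data.shape) >= p).astype(np.float32) / np.float32(1.0 - p)
        data = src.data * keep

        def backward(grad):
            Tensor._accum(src, grad * keep)

        return Tensor._make(data, (src,), backward, src.requires_grad)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- heavy ops -------------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Padded input (B, C, Hp, Wp) -> (B*ho*wo, C*k*k) patch matrix."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (B, C, ho, wo, k, k)
    col = view.transpose(0, 2, 3, 1, 4, 5).reshape(xp.shape[0] * ho * wo, -1)
    return np.ascontiguousarray(col)


def conv2d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0, bias: Tensor | None = None) -> Tensor:
    """2-D convolution (cross-correlation), NCHW x (O, C, k, k)."""
    B, C, H, W = x.data.shape
    O, _, k, _ = w.data.shape
    ho = (H + 2 * pad - k) // stride + 1
    wo = (W + 2 * pad - k) // stride + 1
    _count_macs(B * O * ho * wo * C * k * k)

    if k == 1 and stride == 1 and pad == 0:
        wm = w.data.reshape(O, C)
        data = np.einsum("bchw,oc->bohw", x.data, wm, optimize=True)
        if bias is not None:
            data = data + bias.data[None, :, None, None]

        def backward(grad):
            if x.requires_grad:
                Tensor._accum(x, np.einsum("bohw,oc->bchw", grad, wm, optimize=True))
            if w.requires_grad:
                gw = np.einsum("bohw,bchw->oc", grad, x.data, optimize=True)
                Tensor._accum(w, gw.reshape(w.data.shape))
            if bias is not None and bias.requires_grad:
                Tensor._accum(bias, grad.sum(axis=(0, 2, 3)))

        parents = (x, w) if bias is None else (x, w, bias)
        req = any(p.requires_grad for p in parents)
        return Tensor._make(data, parents, backward, req)

    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    col = _im2col(xp, k, stride, ho, wo)
    wf = w.data.reshape(O, -1)
    out = col @ wf.T  # (B*ho*wo, O)
    data = out.reshape(B, ho, wo, O).transpose(0, 3, 1, 2)
    if bias is not None:
        data = data + bias.data[None, :, None, None]

    def backward(grad):
        gflat = grad.transpose(0, 2, 3, 1).reshape(-1, O)
        if w.requires_grad:
            Tensor._accum(w, (gflat.T @ col).reshape(w.data.shape))
        if bias is not None and bias.requires_grad:
            Tensor._accum(bias, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = (gflat @ wf).reshape(B, ho, wo, C, k, k)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            gx = dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp
            Tensor._accum(x, gx)

    parents = (x, w) if bias is None else (x, w, bias)
    req = any(p.requires_grad for p in parents)
    return Tensor._make(data, parents, backward, req)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """(B, in) @ (in, out) + b."""
    _count_macs(x.data.shape[0] * w.data.shape[0] * w.data.shape[1])
    data = x.data @ w.data
    if b is not None:
        data = data + b.data

    def backward(grad):
        if x.requires_grad:
            Tensor._accum(x, grad @ w.data.T)
        if w.requires_grad:
            Tensor._accum(w, x.data.T @ grad)
        if b is not None and b.requires_grad:
            Tensor._accum(b, grad.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(data, parents, backward, any(p.requires_grad for p in parents))


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
    update_stats: bool = True,
) -> Tensor:
    """Per-channel batch normalization over (B, H, W)."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        if update_stats:
            running_mean *= 1.0 - momentum
            running_mean += momentum * mean
            running_var *= 1.0 - momentum
            running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(grad):
        if gamma.requires_grad:
            Tensor._accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            Tensor._accum(beta, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g = grad * gamma.data[None, :, None, None]
            if training:
                B, C, H, W = x.data.shape
                n = B * H * W
                sum_g = g.sum(axis=(0, 2, 3))
                sum_gx = (g * xhat).sum(axis=(0, 2, 3))
                gx = (
                    g
                    - sum_g[None, :, None, None] / n
                    - xhat * sum_gx[None, :, None, None] / n
                ) * inv_std[None, :, None, None]
            else:
                gx = g * inv_std[None, :, None, None]
            Tensor._accum(x, gx.astype(np.float32, copy=False))

    return Tensor._make(data, (x, gamma, beta), backward, x.requires_grad or gamma.requires_grad or beta.requires_grad)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch; fused softmax backward."""
    probs = softmax(logits.data.astype(np.float64)).astype(np.float32)
    B = logits.data.shape[0]
    eps = np.float32(1e-12)
    loss = -np.log(probs[np.arange(B), labels] + eps).mean()

    def backward(grad):
        g = probs.copy()
        g[np.arange(B), labels] -= 1.0
        Tensor._accum(logits, g * (grad / B))

    return Tensor._make(np.float32(loss), (logits,), backward, logits.requires_grad)
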