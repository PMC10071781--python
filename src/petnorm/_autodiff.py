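"""Minimal reverse-mode automatic differentiation over numpy arrays.

Exactly the operator set the displacement-field network needs: elementwise
arithmetic, reductions, leaky ReLU, same-padded 3x3x3 convolution,
2x average pooling / nearest upsampling, channel concatenation, trilinear
grid sampling (differentiable w.r.t. both source and coordinates), sliding
box sums for windowed cross-correlation, and forward differences for the
smoothness penalty. Arrays keep whatever float dtype they are given, so
gradient checks can run in float64 while training runs in float32.

Each :class:`Var` stores its value, accumulated gradient and a backward
closure; :func:`backward` runs the tape in reverse topological order.
Nodes that cannot reach a parameter (``needs_grad`` False) are skipped.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "Var", "const", "param", "backward",
    "add", "sub", "mul", "div", "neg", "sqrt", "maximum_const", "scale", "add_const",
    "vsum", "leaky_relu", "conv3d", "avgpool2", "upsample2", "concat",
    "grid_sample", "boxsum", "fdiff", "Adam", "clip_global_norm",
]


class Var:
    """A node in the tape: value, gradient slot and backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward", "needs_grad")

    def __init__(self, data, parents=(), backward=None, needs_grad=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        if needs_grad is None:
            needs_grad = any(p.needs_grad for p in self._parents)
        self.needs_grad = needs_grad

    @property
    def shape(self):
        return self.data.shape


def const(data) -> Var:
    return Var(data, needs_grad=False)


def param(data) -> Var:
    return Var(data, needs_grad=True)


def _accum(node: Var, g: np.ndarray) -> None:
    if not node.needs_grad:
        return
    if node.grad is None:
        node.grad = np.asarray(g, dtype=node.data.dtype).copy()
    else:
        node.grad += g


def backward(out: Var) -> None:
    """Accumulate d(out)/d(leaf) into every reachable ``needs_grad`` leaf."""
    order: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(out, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen and p.needs_grad:
                stack.append((p, False))
    out.grad = np.ones_like(out.data)
    for node in reversed(order):
        if node._backward is None or node.grad is None:
            continue
        node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise ------------------------------------------------------------

def add(a: Var, b: Var) -> Var:
    out = Var(a.data + b.data, (a, b))
    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    out._backward = bwd
    return out


def sub(a: Var, b: Var) -> Var:
    out = Var(a.data - b.data, (a, b))
    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))
    out._backward = bwd
    return out


def mul(a: Var, b: Var) -> Var:
    out = Var(a.data * b.data, (a, b))
    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    out._backward = bwd
    return out


def div(a: Var, b: Var) -> Var:
    out = Var(a.data / b.data, (a, b))
    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
    out._backward = bwd
    return out


def neg(a: Var) -> Var:
    return scale(a, -1.0)


def scale(a: Var, k: float) -> Var:
    out = Var(a.data * k, (a,))
    out._backward = lambda g: _accum(a, g * k)
    return out


def add_const(a: Var, c) -> Var:
    out = Var(a.data + c, (a,))
    out._backward = lambda g: _accum(a, _unbroadcast(g, a.data.shape))
    return out


def sqrt(a: Var) -> Var:
    root = np.sqrt(a.data)
    out = Var(root, (a,))
    out._backward = lambda g: _accum(a, g * (0.5 / root))
    return out


def maximum_const(a: Var, floor: float) -> Var:
    """Elementwise max with a constant; gradient flows where ``a > floor``."""
    out = Var(np.maximum(a.data, floor), (a,))
    out._backward = lambda g: _accum(a, g * (a.data > floor))
    return out


def vsum(a: Var) -> Var:
    """Sum of all elements (0-d result)."""
    out = Var(a.data.sum(), (a,))
    out._backward = lambda g: _accum(a, np.broadcast_to(g, a.data.shape))
    return out


def leaky_relu(a: Var, alpha: float = 0.2) -> Var:
    mask = a.data > 0
    out = Var(np.where(mask, a.data, alpha * a.data), (a,))
    out._backward = lambda g: _accum(a, g * np.where(mask, 1.0, alpha))
    return out


def concat(a: Var, b: Var) -> Var:
    """Concatenate along the channel (first) axis."""
    na = a.data.shape[0]
    out = Var(np.concatenate([a.data, b.data], axis=0), (a, b))
    def bwd(g):
        _accum(a, g[:na])
        _accum(b, g[na:])
    out._backward = bwd
    return out


# -- convolution and resolution changes -------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(Cin, D, H, W) -> (D*H*W, Cin*27) patch matrix, same padding."""
    cin = x.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
    # (Cin, D, H, W, 3,3,3) -> (D*H*W, Cin*27)
    n = win.shape[1] * win.shape[2] * win.shape[3]
    return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(n, cin * 27)


def conv3d(x: Var, w: Var, b: Var | None = None) -> Var:
    """3x3x3 convolution, stride 1, same (zero) padding.

    ``x``: (Cin, D, H, W); ``w``: (Cout, Cin, 3, 3, 3); ``b``: (Cout,).
    """
    cout, cin = w.data.shape[:2]
    spatial = x.data.shape[1:]
    cols = _im2col(x.data)
    y = cols @ w.data.reshape(cout, cin * 27).T
    y = y.T.reshape((cout,) + spatial)
    if b is not None:
        y = y + b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Var(y, parents)

    cached_cols = cols if (w.needs_grad or x.needs_grad) else None

    def bwd(g):
        gm = g.reshape(cout, -1)
        if w.needs_grad:
            _accum(w, (gm @ cached_cols).reshape(w.data.shape))
        if b is not None and b.needs_grad:
            _accum(b, gm.sum(axis=1))
        if x.needs_grad:
            # full correlation: conv of g with spatially flipped, channel-swapped w
            wt = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            gcols = _im2col(g)
            dx = (gcols @ wt.reshape(cin, cout * 27).T).T.reshape((cin,) + spatial)
            _accum(x, dx)
    out._backward = bwd
    return out


def avgpool2(x: Var) -> Var:
    """2x2x2 average pooling; spatial dims must be even."""
    c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {x.data.shape}")
    y = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
    out = Var(y, (x,))
    def bwd(g):
        gg = (g / 8.0)[:, :, None, :, None, :, None]
        _accum(x, np.broadcast_to(
            gg, (c, d // 2, 2, h // 2, 2, w // 2, 2)).reshape(x.data.shape))
    out._backward = bwd
    return out


def upsample2_linear(x: Var) -> Var:
    """Trilinear 2x upsampling (align with avgpool2 cell centers)."""
    c, d, h, w = x.data.shape
    coords = np.stack(np.meshgrid(*(np.arange(2 * n, dtype=x.data.dtype) for n in (d, h, w)),
                                  indexing="ij"))
    coords = (coords - 0.5) / 2.0
    return grid_sample_edge(x, const(coords))


def grid_sample_edge(src: Var, coords: Var) -> Var:
    """Trilinear sampling with edge clamping (for field upsampling)."""
    cl = [np.clip(coords.data[i], 0, src.data.shape[1 + i] - 1) for i in range(3)]
    return grid_sample(src, const(np.stack(cl))) if not coords.needs_grad else grid_sample(src, coords)


def upsample2(x: Var) -> Var:
    """Nearest-neighbour 2x upsampling of the three spatial axes."""
    y = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    c, d, h, w = x.data.shape
    out = Var(y, (x,))
    def bwd(g):
        _accum(x, g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)))
    out._backward = bwd
    return out


# -- sampling ---------------------------------------------------------------

def _corner_data(coords: np.ndarray):
    """Floor indices, fractional parts, per-axis corner index/weight tables."""
    base = np.floor(coords)
    frac = coords - base
    base = base.astype(np.int64)
    return base, frac


def grid_sample(src: Var, coords: Var) -> Var:
    """Trilinear sampling: out[c, v] = src[c] at coords[:, v], zero-padded.

    ``src``: (C, D, H, W); ``coords``: (3, d, h, w) absolute voxel
    coordinates. Differentiable w.r.t. both arguments; out-of-grid corners
    contribute zero value and zero gradient (constant padding).
    """
    srcd = src.data
    c_dim = srcd.shape[0]
    dims = srcd.shape[1:]
    sp = coords.data.shape[1:]
    nvox = int(np.prod(sp))
    base, frac = _corner_data(coords.data.reshape(3, nvox))
    flat = srcd.reshape(c_dim, -1)
    strides = (dims[1] * dims[2], dims[2], 1)

    out = np.zeros((c_dim, nvox), dtype=srcd.dtype)
    corner_cache = []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ii = base[0] + dx
                jj = base[1] + dy
                kk = base[2] + dz
                valid = ((ii >= 0) & (ii < dims[0]) & (jj >= 0) & (jj < dims[1])
                         & (kk >= 0) & (kk < dims[2]))
                idx = (np.clip(ii, 0, dims[0] - 1) * strides[0]
                       + np.clip(jj, 0, dims[1] - 1) * strides[1]
                       + np.clip(kk, 0, dims[2] - 1))
                wx = frac[0] if dx else 1.0 - frac[0]
                wy = frac[1] if dy else 1.0 - frac[1]
                wz = frac[2] if dz else 1.0 - frac[2]
                wgt = wx * wy * wz * valid
                out += flat[:, idx] * wgt
                corner_cache.append((dx, dy, dz, idx, valid, wx, wy, wz))
    result = Var(out.reshape((c_dim,) + sp), (src, coords))

    def bwd(g):
        gf = g.reshape(c_dim, nvox)
        if src.needs_grad:
            dsrc = np.zeros_like(flat)
            for dx, dy, dz, idx, valid, wx, wy, wz in corner_cache:
                contrib = gf * (wx * wy * wz * valid)
                for ch in range(c_dim):
                    np.add.at(dsrc[ch], idx, contrib[ch])
            _accum(src, dsrc.reshape(srcd.shape))
        if coords.needs_grad:
            dco = np.zeros((3, nvox), dtype=coords.data.dtype)
            for dx, dy, dz, idx, valid, wx, wy, wz in corner_cache:
                vals = (flat[:, idx] * gf).sum(axis=0) * valid
                sx = 1.0 if dx else -1.0
                sy = 1.0 if dy else -1.0
                sz = 1.0 if dz else -1.0
                dco[0] += vals * sx * wy * wz
                dco[1] += vals * wx * sy * wz
                dco[2] += vals * wx * wy * sz
            _accum(coords, dco.reshape(coords.data.shape))
    result._backward = bwd
    return result


# -- windowed sums and differences ------------------------------------------

def boxsum(x: Var, window: int) -> Var:
    """Sliding-window sum over a cubic window, zero padding (self-adjoint)."""
    n = window ** 3
    def op(arr):
        return ndimage.uniform_filter(arr, size=window, mode="constant", cval=0.0) * n
    out = Var(op(x.data), (x,))
    out._backward = lambda g: _accum(x, op(np.asarray(g, dtype=x.data.dtype)))
    return out


def fdiff(x: Var, axis: int) -> Var:
    """Forward difference along ``axis`` (same shape, trailing slice zero)."""
    y = np.zeros_like(x.data)
    head = [slice(None)] * x.data.ndim
    tail = [slice(None)] * x.data.ndim
    head[axis] = slice(None, -1)
    tail[axis] = slice(1, None)
    head_t, tail_t = tuple(head), tuple(tail)
    y[head_t] = x.data[tail_t] - x.data[head_t]
    out = Var(y, (x,))
    def bwd(g):
        dx = np.zeros_like(x.data)
        dx[head_t] -= g[head_t]
        dx[tail_t] += g[head_t]
        _accum(x, dx)
    out._backward = bwd
    return out


def clip_global_norm(params: list[Var], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


# -- optimizer --------------------------------------------------------------

class Adam:
    """Adam over a flat list of parameter :class:`Var` objects."""

    def __init__(self, params: list[Var], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 lr_mults: list[float] | None = None):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.lr_mults = list(lr_mults) if lr_mults is not None else [1.0] * len(self.params)
        if len(self.lr_mults) != len(self.params):
            raise ValueError("lr_mults length must match params")
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v, mult in zip(self.params, self.m, self.v, self.lr_mults):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data = p.data - (self.lr * mult) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
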