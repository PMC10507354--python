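"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the quantification and super-resolution
networks need: broadcasting arithmetic, matmul, elementwise nonlinear
maps, reductions, column gather, concatenation, and a custom
exponential-kernel convolution (the Tofts operator) with an analytic
adjoint. Gradients are checked against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_cols", "tofts_conv", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- ops ---------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return self._make(self.data[key], (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig)

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def gather_cols(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select columns ``idx`` from a (B, T) tensor -> (B, len(idx))."""
    idx = np.asarray(idx, dtype=int)

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (slice(None), idx), g)
            x._accum(full)

    return x._make(x.data[:, idx], (x,), backward)


def tofts_conv(cp: Tensor, ktrans: Tensor, kep: Tensor, dt_min: float) -> Tensor:
    """Batched standard-Tofts operator with analytic adjoint.

    ``cp``: (B, T) input-function curves; ``ktrans``/``kep``: (B,) rates
    in 1/min; ``dt_min``: grid step in minutes. Forward is the
    exponential-integrator recursion (exact convolution of the
    piecewise-linear interpolant of cp with the analytic kernel)

        y_i = a y_{i-1} + A cp_{i-1} + B cp_i,   out = ktrans * y

    with a = exp(-kep h), u = (1-a)/(kep h), Bc = (1-u)/kep,
    Ac = u h - Bc; matching :func:`roqdce.pk.tofts_forward`.
    """
    cp_d = cp.data if isinstance(cp, Tensor) else np.asarray(cp, float)
    kt_d = ktrans.data
    kep_d = kep.data
    B, T = cp_d.shape
    h = dt_min
    a = np.exp(-kep_d * h)  # (B,)
    u = (1.0 - a) / (kep_d * h)
    Bc = (1.0 - u) / kep_d
    Ac = u * h - Bc
    y = np.zeros((B, T))
    for i in range(1, T):
        y[:, i] = a * y[:, i - 1] + Ac * cp_d[:, i - 1] + Bc * cp_d[:, i]
    out_data = kt_d[:, None] * y

    parents = tuple(t for t in (cp, ktrans, kep) if isinstance(t, Tensor))

    def backward(g):
        # d out / d ktrans
        if isinstance(ktrans, Tensor) and ktrans.requires_grad:
            ktrans._accum(np.sum(g * y, axis=1))
        gy = g * kt_d[:, None]  # gradient wrt y
        need_cp = isinstance(cp, Tensor) and cp.requires_grad
        need_kep = isinstance(kep, Tensor) and kep.requires_grad
        if not (need_cp or need_kep):
            return
        # adjoint of the linear recursion: lam_i = gy_i + a lam_{i+1}
        lam = np.zeros((B, T))
        lam[:, T - 1] = gy[:, T - 1]
        for i in range(T - 2, -1, -1):
            lam[:, i] = gy[:, i] + a * lam[:, i + 1]
        if need_cp:
            gcp = np.zeros((B, T))
            # cp_i appears in step i (coeff Bc) and step i+1 (coeff Ac)
            gcp[:, 1:] += Bc[:, None] * lam[:, 1:]
            gcp[:, :-1] += Ac[:, None] * lam[:, 1:]
            cp._accum(gcp)
        if need_kep:
            # chain rule through a(kep), Ac(kep), Bc(kep)
            da = -h * a
            du = (a * kep_d * h - (1.0 - a)) / (kep_d**2 * h)
            dB = -du / kep_d - Bc / kep_d
            dA = du * h - dB
            contrib = (
                np.sum(lam[:, 1:] * y[:, :-1], axis=1) * da
                + np.sum(lam[:, 1:] * cp_d[:, :-1], axis=1) * dA
                + np.sum(lam[:, 1:] * cp_d[:, 1:], axis=1) * dB
            )
            kep._accum(contrib)

    out = Tensor(out_data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._prev = parents
        out._backward = backward
    return out


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
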