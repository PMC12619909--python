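"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core behind the node classifiers: a small tensor
graph supporting exactly the operations the hybrid convolutional /
recurrent architecture needs (dense and convolutional layers, max
pooling, GRU gate arithmetic, attention fusion and a fused
softmax/cross-entropy head).  Gradients are accumulated by a topological
backward sweep; every operation is gradient-checked against central
finite differences in the test suite.

Arrays are kept in float64: the networks here are small, and exact
reproducibility plus tight gradient checks matter more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _needs_graph(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: GRU graphs are thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data + other.data
        if not self._needs_graph(other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __rsub__(self, scalar: float) -> "Tensor":
        return (self * -1.0) + _as_tensor(scalar)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data * other.data
        if not self._needs_graph(other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        """Matrix product; supports (..., m, n) @ (n, p)."""
        other = _as_tensor(other)
        out_data = self.data @ other.data
        if not self._needs_graph(other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                a2 = self.data.reshape(-1, self.data.shape[-1])
                g2 = g.reshape(-1, g.shape[-1])
                other._accumulate(a2.T @ g2)

        return Tensor(out_data, True, (self, other), bwd)

    __matmul__ = matmul

    # -- activations ---------------------------------------------------------

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, True, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        # clipped logistic: |x| > 60 saturates in float64 anyway
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), bwd)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        if not self.requires_grad:
            return Tensor(out_data)
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(out_data, True, (self,), bwd)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out_data = self.data.reshape(*shape)
        if not self.requires_grad:
            return Tensor(out_data)
        orig = self.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor(out_data, True, (self,), bwd)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accumulate(full)

        return Tensor(out_data, True, (self,), bwd)

    def sum(self, axis=None) -> "Tensor":
        out_data = self.data.sum(axis=axis)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
            else:
                self._accumulate(np.broadcast_to(np.expand_dims(g, axis), self.shape))

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- structured ops for the network ---------------------------------------

    def unfold_windows(self, width: int) -> "Tensor":
        """Extract sliding windows for 1-D convolution.

        Input (B, L, C) with symmetric zero padding so the output keeps
        length L; output (B, L, width*C) ready for a kernel matmul.
        """
        pad = (width - 1) // 2
        b, length, c = self.data.shape
        padded = np.pad(self.data, ((0, 0), (pad, width - 1 - pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(padded, width, axis=1)
        # win: (B, L, C, width) -> (B, L, width, C) -> flatten
        out_data = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            b, length, width * c
        )
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            g4 = g.reshape(b, length, width, c)
            full = np.zeros((b, length + width - 1, c))
            for w in range(width):
                full[:, w : w + length, :] += g4[:, :, w, :]
            self._accumulate(full[:, pad : pad + length, :])

        return Tensor(out_data, True, (self,), bwd)

    def maxpool1d(self, width: int = 2) -> "Tensor":
        """Non-overlapping max pooling along axis 1 of (B, L, C)."""
        b, length, c = self.data.shape
        trimmed = length - length % width
        x = self.data[:, :trimmed, :].reshape(b, trimmed // width, width, c)
        out_data = x.max(axis=2)
        if not self.requires_grad:
            return Tensor(out_data)
        argm = x.argmax(axis=2)

        def bwd(g):
            full = np.zeros((b, trimmed // width, width, c))
            np.put_along_axis(full, argm[:, :, None, :], g[:, :, None, :], axis=2)
            padded = np.zeros_like(self.data)
            padded[:, :trimmed, :] = full.reshape(b, trimmed, c)
            self._accumulate(padded)

        return Tensor(out_data, True, (self,), bwd)

    def softmax_cross_entropy(self, onehot: np.ndarray) -> tuple["Tensor", np.ndarray]:
        """Fused softmax + categorical cross-entropy, mean over the batch.

        Returns (loss tensor, probability matrix).
        """
        z = self.data - self.data.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=-1, keepdims=True)
        n = self.data.shape[0]
        loss_val = -np.sum(onehot * np.log(np.clip(probs, 1e-300, None))) / n
        if not self.requires_grad:
            return Tensor(loss_val), probs

        def bwd(g):
            self._accumulate(g * (probs - onehot) / n)

        return Tensor(loss_val, True, (self,), bwd), probs


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` (used to stack GRU step outputs)."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, True, tuple(tensors), bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
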