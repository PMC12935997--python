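"""Layers and modules built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, maxpool2d

__all__ = ["Module", "Conv2d", "Linear", "LSTM", "Dropout"]


class Module:
    """Base class: parameter discovery, train/eval mode, freezing."""

    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def set_training(self, flag: bool):
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False

    def state_arrays(self):
        """Flat list of parameter arrays (for checkpointing)."""
        return [p.data for p in self._all_tensors()]

    def load_state_arrays(self, arrays):
        tensors = self._all_tensors()
        if len(arrays) != len(tensors):
            raise ValueError("checkpoint does not match model architecture")
        for p, a in zip(tensors, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)

    def _all_tensors(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v._all_tensors())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item._all_tensors())
                    elif isinstance(item, Tensor):
                        out.append(item)
        return out


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, pad=None, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0, scale, (cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = (k // 2) if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, nin, nout, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / nin)
        self.weight = Tensor(rng.normal(0, scale, (nin, nout)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTM(Module):
    """Single-layer LSTM over one sequence; input (T, nin) -> (T, nhid)."""

    def __init__(self, nin, nhid, rng=None):
        rng = rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(nhid)
        self.nhid = nhid
        self.w_x = Tensor(rng.uniform(-s, s, (nin, 4 * nhid)),
                          requires_grad=True)
        self.w_h = Tensor(rng.uniform(-s, s, (nhid, 4 * nhid)),
                          requires_grad=True)
        b = np.zeros(4 * nhid)
        b[nhid:2 * nhid] = 1.0          # forget-gate bias starts open
        self.bias = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor):
        T = x.data.shape[0]
        nh = self.nhid
        h = Tensor(np.zeros((1, nh)))
        c = Tensor(np.zeros((1, nh)))
        hs = []
        for t in range(T):
            xt = x[t:t + 1]
            gates = xt @ self.w_x + h @ self.w_h + self.bias
            i = gates[:, 0:nh].sigmoid()
            f = gates[:, nh:2 * nh].sigmoid()
            o = gates[:, 2 * nh:3 * nh].sigmoid()
            g = gates[:, 3 * nh:4 * nh].tanh()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h)
        return concat(hs, axis=0), h


class Dropout(Module):
    def __init__(self, p=0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
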