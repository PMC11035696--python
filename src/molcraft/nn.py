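"""Neural layers on top of :mod:`molcraft.autodiff`.

Linear / MLP / Embedding / stacked LSTM cell plus an Adam optimizer — the
building blocks of the graph encoder and the sequence decoder.  Weight
initialization is Glorot-uniform from an explicit ``numpy.random.Generator``
so every model is reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, gather_rows

__all__ = ["Module", "Linear", "MLP", "Embedding", "LSTMCell", "Adam"]


class Module:
    """Base class: tracks parameters of attributes that are Tensors or Modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in + fan_out, 1))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.w = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Two-layer perceptron with tanh hidden activation (linear output)."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(in_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.normal(0.0, 0.1, size=(n_embeddings, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return gather_rows(self.table, idx)


class LSTMCell(Module):
    """One LSTM layer with the gate equations of the decoder.

    Gates use separate input and recurrent weights and *two* bias vectors
    (b_x and b_l), i.e. g = sigma(W_x k_t + b_x + W_l l_{t-1} + b_l); the four
    gates (input, forget, output, candidate) are fused into single matmuls.
    """

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.wx = Tensor(_glorot(rng, in_dim, hidden_dim, (in_dim, 4 * hidden_dim)), requires_grad=True)
        self.wl = Tensor(_glorot(rng, hidden_dim, hidden_dim, (hidden_dim, 4 * hidden_dim)), requires_grad=True)
        self.bx = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)
        self.bl = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)

    def __call__(self, k_t: Tensor, l_prev: Tensor, c_prev: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden_dim
        z = k_t @ self.wx + self.bx + l_prev @ self.wl + self.bl
        g_i = z[:, 0 * H:1 * H].sigmoid()
        g_f = z[:, 1 * H:2 * H].sigmoid()
        g_o = z[:, 2 * H:3 * H].sigmoid()
        c_tilde = z[:, 3 * H:4 * H].tanh()
        c_t = g_f * c_prev + g_i * c_tilde
        l_t = g_o * c_t
        return l_t, c_t

    def step_numpy(self, k_t: np.ndarray, l_prev: np.ndarray, c_prev: np.ndarray):
        """Gradient-free fast path for sampling."""
        H = self.hidden_dim
        z = k_t @ self.wx.data + self.bx.data + l_prev @ self.wl.data + self.bl.data
        sig = lambda a: 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))
        g_i = sig(z[:, :H])
        g_f = sig(z[:, H:2 * H])
        g_o = sig(z[:, 2 * H:3 * H])
        c_tilde = np.tanh(z[:, 3 * H:])
        c_t = g_f * c_prev + g_i * c_tilde
        return g_o * c_t, c_t


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
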