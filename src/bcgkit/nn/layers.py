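"""Neural network building blocks over the autodiff core.

Initialisation follows the common uniform fan-in convention
U(-1/sqrt(fan_in), 1/sqrt(fan_in)) for linear and recurrent weights, with an
explicit numpy Generator so every build is reproducible from a seed.
"""

from __future__ import annotations

import math

import numpy as np

from bcgkit.nn.autograd import Tensor


class Module:
    """Base class: parameter discovery plus a train/eval mode flag."""

    def __init__(self):
        self.training = True

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

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value._set_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(training)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _uniform(rng: np.random.Generator, bound: float, shape: tuple) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    """Affine map ``y = x @ W + b`` with W of shape (in_features, out_features)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.W = _uniform(rng, bound, (in_features, out_features))
        self.b = _uniform(rng, bound, (out_features,))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout: active only in train mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class LSTM(Module):
    """Stacked LSTM; returns the final hidden state of the top layer.

    Input is ``(batch, seq, input_size)``. Gate order in the packed weight
    matrices is input, forget, cell, output. Initial hidden and cell states
    are zero.
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        bound = 1.0 / math.sqrt(hidden_size)
        self.weights: list[Tensor] = []
        for layer in range(num_layers):
            in_size = input_size if layer == 0 else hidden_size
            self.weights.extend(
                [
                    _uniform(rng, bound, (in_size, 4 * hidden_size)),   # W_ih
                    _uniform(rng, bound, (hidden_size, 4 * hidden_size)),  # W_hh
                    _uniform(rng, bound, (4 * hidden_size,)),           # b_ih
                    _uniform(rng, bound, (4 * hidden_size,)),           # b_hh
                ]
            )

    def __call__(self, x: Tensor) -> Tensor:
        batch, seq, _ = x.shape
        H = self.hidden_size
        layer_input = [x[:, t, :] for t in range(seq)]
        h = None
        for layer in range(self.num_layers):
            W_ih, W_hh, b_ih, b_hh = self.weights[4 * layer : 4 * layer + 4]
            h = Tensor(np.zeros((batch, H)))
            c = Tensor(np.zeros((batch, H)))
            outputs = []
            for x_t in layer_input:
                gates = x_t @ W_ih + h @ W_hh + b_ih + b_hh
                i = gates[:, 0 * H : 1 * H].sigmoid()
                f = gates[:, 1 * H : 2 * H].sigmoid()
                g = gates[:, 2 * H : 3 * H].tanh()
                o = gates[:, 3 * H : 4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outputs.append(h)
            layer_input = outputs
        return h  # final hidden state of top layer


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` parallel heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, batch: int, seq: int) -> Tensor:
        # (B, T, D) -> (B, H, T, Dh)
        return x.reshape(batch, seq, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        batch, seq, _ = x.shape
        q = self._split(self.wq(x), batch, seq)
        k = self._split(self.wk(x), batch, seq)
        v = self._split(self.wv(x), batch, seq)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, H, T, Dh)
        out = out.transpose(0, 2, 1, 3).reshape(batch, seq, self.d_model)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: self-attention and position-wise feed-forward,
    each wrapped in residual + layer normalisation."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ff2(self.ff1(x).relu())))
        return x


def cross_entropy(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax of ``scores`` (B, C)."""
    labels = np.asarray(labels, dtype=int)
    logp = scores.log_softmax(axis=-1)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()


class Adam:
    """Adam optimizer with an externally adjustable learning rate."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class StepLR:
    """Multiply the learning rate by ``gamma`` every ``step_size`` epochs."""

    def __init__(self, optimizer: Adam, step_size: int = 10, gamma: float = 0.1):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.epoch = 0

    def step(self, loss: float | None = None) -> None:
        self.epoch += 1
        if self.epoch % self.step_size == 0:
            self.optimizer.lr *= self.gamma


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate after ``patience`` epochs
    without improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 3):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = math.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr *= self.factor
                self.bad_epochs = 0
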