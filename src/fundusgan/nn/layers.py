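"""Parameter initialisation and the Adam optimizer for the tape engine."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor


def he_conv(rng: np.random.Generator, out_ch: int, in_ch: int, k: int) -> Tensor:
    """He-normal conv kernel (O, C, k, k)."""
    fan_in = in_ch * k * k
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)), requires_grad=True)


def he_linear(rng: np.random.Generator, out_dim: int, in_dim: int) -> Tensor:
    std = np.sqrt(2.0 / in_dim)
    return Tensor(rng.normal(0.0, std, size=(in_dim, out_dim)), requires_grad=True)


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape, dtype=DTYPE), requires_grad=True)


class Adam:
    """Adam on a name->Tensor parameter dict.

    WGAN-GP training conventionally runs with a low first-moment decay;
    the defaults here follow that convention.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.0, 0.9), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = float(betas[0]), float(betas[1])
        self.eps = float(eps)
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    # -- checkpoint support ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"adam_t": np.array([self.t], dtype=np.float64)}
        for k in self.params:
            out[f"adam_m.{k}"] = self.m[k]
            out[f"adam_v.{k}"] = self.v[k]
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        self.t = int(arrays["adam_t"][0])
        for k in self.params:
            self.m[k] = np.array(arrays[f"adam_m.{k}"])
            self.v[k] = np.array(arrays[f"adam_v.{k}"])
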