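"""Adam optimizer and cosine learning-rate decay."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with the training defaults beta1=0.9, beta2=0.99."""

    def __init__(self, params: list[Parameter], lr: float = 3e-5,
                 betas: tuple[float, float] = (0.9, 0.99), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]


def cosine_lr(step: int, max_steps: int, lr0: float) -> float:
    """Cosine decay from lr0 at step 0 to 0 at max_steps."""
    frac = min(max(step / max(max_steps, 1), 0.0), 1.0)
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * frac))
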