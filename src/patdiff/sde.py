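"""Mean-reverting SDE diffusion engine for image restoration.

The forward process is an Ornstein-Uhlenbeck-type SDE

    dx = theta_t (mu - x) dt + sigma_t dw,      sigma_t^2 / theta_t = 2 lambda^2,

which pulls the clean image ``x(0)`` toward its degraded counterpart ``mu``
while injecting noise with stationary level ``lambda``.  The marginal at
time t is Gaussian with

    m_t = mu + (x0 - mu) exp(-theta_bar_t),
    v_t = lambda^2 (1 - exp(-2 theta_bar_t)),       theta_bar_t = int_0^t theta.

Restoration integrates the time-reversed SDE with Euler-Maruyama, replacing
the score by ``-eps_hat / sqrt(v_t)`` where ``eps_hat`` is the network's
noise estimate.  Defaults follow the training setup: 200 states, noise level
50 on the [0, 255] image scale.

The per-state rate shape ``theta_t`` is a free choice; the default is a
constant rate scaled so that ``exp(-2 theta_bar_T) = 1e-4`` (the marginal
has converged to ``N(mu, lambda^2)`` at the terminal state).  The constant
shape keeps the marginal variance well-scaled near t = 0, which conditions
both the noise-prediction target and the final reverse steps; a cosine-ramp
shape is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, DataError, DivergenceError, PatdiffError
from .image import DYNAMIC_RANGE

TERMINAL_DECAY = 1e-4
"""Target for exp(-2 theta_bar_T): terminal-marginal convergence tolerance."""


class NoisePredictor(Protocol):
    """Anything that estimates the injected standard-normal noise."""

    def __call__(self, x_t: np.ndarray, mu: np.ndarray, t: int) -> np.ndarray: ...


@dataclass(frozen=True)
class DiffusionSchedule:
    """Discretized rates and volatilities on the uniform grid t_i = i/T.

    Arrays have length ``T + 1`` (states 0..T inclusive); ``dt = 1/T``.
    """

    T: int
    lam: float
    times: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    theta_bar: np.ndarray

    @property
    def dt(self) -> float:
        return 1.0 / self.T

    def mean_decay(self, t: float | np.ndarray) -> np.ndarray:
        """exp(-theta_bar) at arbitrary continuous times via interpolation."""
        return np.exp(-np.interp(t, self.times, self.theta_bar))

    def variance(self, t: float | np.ndarray) -> np.ndarray:
        return self.lam**2 * (1.0 - self.mean_decay(t) ** 2)

    def rate(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.theta)


def build_schedule(T: int = 200, lam: float = 50.0, kind: str = "constant") -> DiffusionSchedule:
    """Construct a schedule with ``sigma_t^2 = 2 lam^2 theta_t`` identically.

    ``kind='constant'`` holds theta flat; ``kind='cosine'`` ramps it
    smoothly from 0.  Either way theta is scaled so the cumulative trapezoid of
    theta over [0, 1] equals ``-ln(TERMINAL_DECAY)/2``.
    """
    if T < 2:
        raise ConfigurationError("need at least 2 states")
    if lam <= 0:
        raise ConfigurationError("noise level lambda must be positive")
    times = np.linspace(0.0, 1.0, T + 1)
    if kind == "cosine":
        shape = 0.5 * (1.0 - np.cos(np.pi * times))
    elif kind == "constant":
        shape = np.ones_like(times)
    else:
        raise ConfigurationError(f"unknown schedule kind {kind!r}")
    target = -0.5 * np.log(TERMINAL_DECAY)
    integral = np.trapezoid(shape, times)
    theta = shape * (target / integral)
    theta_bar = cumulative_trapezoid(theta, times, initial=0.0)
    sigma = np.sqrt(2.0 * lam**2 * theta)
    return DiffusionSchedule(T, lam, times, theta, sigma, theta_bar)


def _check_state(t: int, T: int) -> None:
    if not (0 <= t <= T):
        raise PatdiffError(f"state index {t} outside [0, {T}]")


def marginal_params(
    x0: np.ndarray, mu: np.ndarray, t: int, sched: DiffusionSchedule
) -> tuple[np.ndarray, float]:
    """Closed-form Gaussian marginal (m_t, v_t) of the forward process."""
    x0, mu = np.asarray(x0, float), np.asarray(mu, float)
    if x0.shape != mu.shape:
        raise DataError(f"x0 shape {x0.shape} != mu shape {mu.shape}")
    _check_state(t, sched.T)
    decay = np.exp(-sched.theta_bar[t])
    m_t = mu + (x0 - mu) * decay
    v_t = sched.lam**2 * (1.0 - decay**2)
    return m_t, float(v_t)


@dataclass
class DiffusionState:
    """A forward sample x_t together with the Gaussian draw that made it."""

    x_t: np.ndarray
    t: int
    eps: np.ndarray


def sample_forward(
    x0: np.ndarray, mu: np.ndarray, t: int, sched: DiffusionSchedule,
    rng: np.random.Generator,
) -> DiffusionState:
    """Reparameterized forward draw ``x_t = m_t + sqrt(v_t) * eps``."""
    m_t, v_t = marginal_params(x0, mu, t, sched)
    eps = rng.standard_normal(np.shape(x0))
    return DiffusionState(m_t + np.sqrt(v_t) * eps, t, eps)


def score_from_noise(eps: np.ndarray, v_t: float) -> np.ndarray:
    """Score of the Gaussian marginal under the noise reparameterization.

    ``grad_x log N(x_t; m_t, v_t) = -(x_t - m_t)/v_t = -eps / sqrt(v_t)``.
    """
    if v_t <= 0:
        raise PatdiffError("score undefined at zero marginal variance (t = 0)")
    return -np.asarray(eps, float) / np.sqrt(v_t)


def training_loss(
    net: NoisePredictor,
    batch: Sequence[tuple[np.ndarray, np.ndarray]],
    sched: DiffusionSchedule,
    rng: np.random.Generator,
) -> float:
    """Mean per-pixel squared error of noise prediction over a batch.

    For each pair a state index is drawn uniformly from {1..T}, a forward
    sample is taken, and the network's estimate is compared with the true
    draw.  A perfect oracle scores 0; the zero predictor scores ~1.
    """
    if len(batch) == 0:
        raise DataError("empty batch")
    total, count = 0.0, 0
    for x0, mu in batch:
        t = int(rng.integers(1, sched.T + 1))
        state = sample_forward(x0, mu, t, sched, rng)
        pred = np.asarray(net(state.x_t, np.asarray(mu, float), t), float)
        if pred.shape != state.eps.shape:
            raise DataError(f"prediction shape {pred.shape} != noise shape {state.eps.shape}")
        total += float(np.sum((pred - state.eps) ** 2))
        count += state.eps.size
    return total / count


def reverse_sample(
    mu: np.ndarray,
    net: NoisePredictor | None,
    sched: DiffusionSchedule,
    rng: np.random.Generator,
    steps: int | None = None,
    score_fn: Callable[[np.ndarray, float], np.ndarray] | None = None,
    stochastic: bool = True,
    clip: bool = True,
) -> np.ndarray:
    """Restore an image by Euler-Maruyama integration of the reverse SDE.

    Starts from ``x_T ~ N(mu, v_T)`` and steps ``x`` backwards through

        x <- x - [theta_t (mu - x) - sigma_t^2 * score] dt + sigma_t sqrt(dt) z,

    with the score supplied either by ``score_fn(x, t)`` (analytic oracle)
    or via the network estimate ``-net(x, mu, round(t*T)) / sqrt(v_t)``.
    No noise is added on the final step; the output is clipped to [0, 255]
    unless ``clip=False``.
    """
    if (net is None) == (score_fn is None):
        raise ConfigurationError("provide exactly one of net or score_fn")
    mu = np.asarray(mu, float)
    steps = steps or sched.T
    dt = 1.0 / steps
    v_T = float(sched.variance(1.0))
    x = mu + np.sqrt(v_T) * rng.standard_normal(mu.shape)
    for k in range(steps, 0, -1):
        t = k / steps
        theta = float(sched.rate(t))
        sigma2 = 2.0 * sched.lam**2 * theta
        if score_fn is not None:
            score = score_fn(x, t)
        else:
            v_t = float(sched.variance(t))
            eps_hat = net(x, mu, int(round(t * sched.T)))  # type: ignore[misc]
            score = -np.asarray(eps_hat, float) / np.sqrt(v_t)
        x = x - (theta * (mu - x) - sigma2 * score) * dt
        if stochastic and k > 1:
            x = x + np.sqrt(sigma2 * dt) * rng.standard_normal(mu.shape)
        if not np.all(np.isfinite(x)):
            raise DivergenceError(f"non-finite state at reverse step {k}")
    return np.clip(x, 0.0, DYNAMIC_RANGE) if clip else x
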