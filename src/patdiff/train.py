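"""Training loop for the noise-estimation network.

Implements the reference training recipe: Adam (beta1=0.9, beta2=0.99),
initial learning rate 3e-5 with cosine decay to zero over the configured
number of steps, batch size 2.  Each step draws a batch of (clean, degraded)
pairs, a uniform state index per sample, forms the reparameterized forward
sample ``x_t = m_t + sqrt(v_t) eps`` and minimizes the per-pixel squared
error between the network output and ``eps``.

Checkpoints are a framework-native ``.npz`` of the parameter arrays plus a
JSON manifest (config, seed, step); training logs are JSON-lines.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, DivergenceError
from .nn.autodiff import Tensor, mse
from .nn.network import NetworkConfig, NoiseNetwork
from .nn.optim import Adam, cosine_lr
from .sde import DiffusionSchedule, build_schedule


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    max_steps: int = 2000
    batch_size: int = 2
    lr: float = 3e-5
    betas: tuple[float, float] = (0.9, 0.99)
    T: int = 200
    lam: float = 50.0
    schedule_kind: str = "constant"
    seed: int = 0
    log_every: int = 50
    checkpoint_every: int = 0  # 0 = only at the end


def training_step(
    net: NoiseNetwork,
    opt: Adam,
    x0s: np.ndarray,
    mus: np.ndarray,
    sched: DiffusionSchedule,
    rng: np.random.Generator,
    batch_size: int,
) -> float:
    """One optimizer step; returns the batch loss."""
    idx = rng.integers(0, x0s.shape[0], size=batch_size)
    t = rng.integers(1, sched.T + 1, size=batch_size)
    decay = np.exp(-sched.theta_bar[t])[:, None, None]
    m_t = mus[idx] + (x0s[idx] - mus[idx]) * decay
    v_t = sched.lam**2 * (1.0 - decay**2)
    eps = rng.standard_normal(m_t.shape)
    x_t = m_t + np.sqrt(v_t) * eps
    pred = net.forward_graph(x_t, mus[idx], t)
    loss = mse(pred, Tensor(eps[:, None].astype(pred.data.dtype)))
    opt.zero_grad()
    loss.backward()
    opt.step()
    value = float(loss.data)
    if not np.isfinite(value):
        raise DivergenceError(f"non-finite training loss at step {opt.t}")
    return value


def train(
    net: NoiseNetwork,
    pairs: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
    out_dir: str | Path | None = None,
    verbose: bool = False,
) -> list[dict]:
    """Train ``net`` on stacked (x0, mu) arrays of shape (N, H, W).

    Returns the loss log; if ``out_dir`` is given, writes ``log.jsonl`` and
    a final checkpoint there.
    """
    x0s, mus = (np.asarray(a, dtype=np.float64) for a in pairs)
    if x0s.shape != mus.shape or x0s.ndim != 3 or x0s.shape[0] == 0:
        raise DataError(f"bad training pair shapes {x0s.shape} / {mus.shape}")
    sched = build_schedule(config.T, config.lam, config.schedule_kind)
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), lr=config.lr, betas=config.betas)
    log: list[dict] = []
    out_path = Path(out_dir) if out_dir else None
    log_file = (out_path / "log.jsonl").open("w") if out_path else None
    t0 = time.time()
    for step in range(config.max_steps):
        opt.lr = cosine_lr(step, config.max_steps, config.lr)
        loss = training_step(net, opt, x0s, mus, sched, rng, config.batch_size)
        if step % config.log_every == 0 or step == config.max_steps - 1:
            entry = {"step": step, "loss": loss, "lr": opt.lr,
                     "wall_s": round(time.time() - t0, 3)}
            log.append(entry)
            if log_file:
                log_file.write(json.dumps(entry) + "\n")
            if verbose:
                print(f"step {step:6d}  loss {loss:.4f}  lr {opt.lr:.2e}")
        if out_path and config.checkpoint_every and step and step % config.checkpoint_every == 0:
            save_checkpoint(net, out_path / f"ckpt_{step}.npz", config, step)
    if log_file:
        log_file.close()
    if out_path:
        save_checkpoint(net, out_path / "ckpt_final.npz", config, config.max_steps)
    return log


def save_checkpoint(net: NoiseNetwork, path: str | Path, config: TrainConfig,
                    step: int) -> None:
    path = Path(path)
    np.savez(path, **net.state_dict())
    manifest = {
        "step": step,
        "seed": config.seed,
        "train": asdict(config),
        "network": asdict(net.config),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> tuple[NoiseNetwork, dict]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    net_cfg = manifest["network"]
    for key in ("blocks_per_level", "heads_per_level"):
        net_cfg[key] = tuple(net_cfg[key])
    net = NoiseNetwork(NetworkConfig(**net_cfg))
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net, manifest
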