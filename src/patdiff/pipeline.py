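"""End-to-end orchestration: dataset builds, training, restoration, evaluation.

The default study conditions mirror the acquisition being emulated: a
512-element ring of 40 mm radius sampled at 62.5 MHz, degraded by sparse
subsets (n in {32, 64, 128, 256}) or limited arcs (pi/4 .. pi), full-view
FBP images as references, an 80/10/10 train/validation/test split, and the
reference training recipe (Adam, lr 3e-5 cosine, batch 2, lambda=50).
Image grids default to desk scale (64 x 64) so a complete study runs on one
CPU; the grid, phantom count and step count are configuration, not code.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .fbp import FilterSpec, ReconGrid, make_training_pair
from .geometry import RingGeometry
from .image import PressureImage
from .metrics import EvalReport
from .nn.network import NetworkConfig, NoiseNetwork
from .phantoms import child_seed, generate_phantom, PhantomSpec, split_dataset
from .sde import build_schedule, reverse_sample
from .train import TrainConfig, train


@dataclass
class RunConfig:
    """Single-file configuration of a full study."""

    n_phantoms: int = 200
    phantom_kind: str = "disks"
    grid_px: int = 64
    spacing_mm: float = 0.3
    mode: str = "sparse"
    param: float = 64.0
    geometry: RingGeometry = field(default_factory=lambda: RingGeometry(n_elements=512))
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    sampling_steps: int = 0  # 0 = use the schedule's T
    sampling_stochastic: bool = False  # mean-path restoration by default
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "n_phantoms": self.n_phantoms, "phantom_kind": self.phantom_kind,
            "grid_px": self.grid_px, "spacing_mm": self.spacing_mm,
            "mode": self.mode, "param": self.param,
            "geometry": asdict(self.geometry),
            "filter": {"order": self.filter_spec.order, "band_mhz": list(self.filter_spec.band_mhz)},
            "network": asdict(self.network), "training": asdict(self.training),
            "fractions": list(self.fractions), "sampling_steps": self.sampling_steps,
            "sampling_stochastic": self.sampling_stochastic, "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "geometry" in raw:
            kwargs["geometry"] = RingGeometry(**raw["geometry"])
        if "filter" in raw:
            f = kwargs.pop("filter")
            kwargs["filter_spec"] = FilterSpec(f["order"], tuple(f["band_mhz"]))
        if "network" in raw:
            cfg = dict(raw["network"])
            for key in ("blocks_per_level", "heads_per_level"):
                cfg[key] = tuple(cfg[key])
            kwargs["network"] = NetworkConfig(**cfg)
        if "training" in raw:
            t = dict(raw["training"])
            t["betas"] = tuple(t.get("betas", (0.9, 0.99)))
            kwargs["training"] = TrainConfig(**t)
        if "fractions" in raw:
            kwargs["fractions"] = tuple(raw["fractions"])
        return cls(**kwargs)


def build_pair_dataset(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Phantoms -> forward simulation -> full-view / degraded FBP pairs.

    Returns stacked (x0s, mus) arrays of shape (N, H, W) on the [0, 255]
    scale, jointly normalized per pair by the full-view image.
    """
    grid = ReconGrid((config.grid_px, config.grid_px),
                     config.grid_px * config.spacing_mm)
    x0s, mus = [], []
    for i in range(config.n_phantoms):
        seed_i = int(np.random.default_rng(child_seed(config.seed, i)).integers(0, 2**31 - 1))
        spec = PhantomSpec(kind=config.phantom_kind, seed=seed_i)
        phantom = generate_phantom(spec, (config.grid_px, config.grid_px),
                                   config.spacing_mm)
        x0, mu = make_training_pair(phantom, config.geometry, config.mode,
                                    config.param, grid, config.filter_spec)
        x0s.append(x0.pixels)
        mus.append(mu.pixels)
    return np.stack(x0s), np.stack(mus)


def restore_images(
    net: NoiseNetwork,
    mus: np.ndarray,
    sched,
    seed: int = 0,
    steps: int | None = None,
    stochastic: bool = False,
) -> np.ndarray:
    """Reverse-sample a batch of degraded images in one pass.

    The whole batch is carried through the sampler together so each reverse
    step is a single network forward.  ``stochastic=False`` (the default for
    restoration) integrates the mean path of the reverse SDE, which avoids
    re-injecting noise a finitely-trained estimator cannot fully remove.
    """
    mus = np.asarray(mus, dtype=np.float64)
    rng = np.random.default_rng(seed)

    def batched_net(x_t, mu, t):
        return net(x_t, mu, t)

    return reverse_sample(mus, batched_net, sched, rng, steps=steps,
                          stochastic=stochastic)


def end_to_end(config: RunConfig, out_dir: str | Path | None = None,
               verbose: bool = False) -> dict:
    """Full study: build pairs, split, train, restore the test set, evaluate.

    Returns a report dict with degraded and restored metrics per test image;
    identical config + seed gives an identical report.
    """
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_path / "config.yaml")
    x0s, mus = build_pair_dataset(config)
    idx_train, idx_val, idx_test = split_dataset(
        list(range(config.n_phantoms)), config.fractions, seed=config.seed)
    net = NoiseNetwork(config.network, seed=config.seed)
    log = train(net, (x0s[idx_train], mus[idx_train]), config.training,
                out_dir=out_path, verbose=verbose)
    sched = build_schedule(config.training.T, config.training.lam,
                           config.training.schedule_kind)
    steps = config.sampling_steps or None
    restored = restore_images(net, mus[idx_test], sched,
                              seed=config.seed + 1, steps=steps,
                              stochastic=config.sampling_stochastic)
    degraded_report = EvalReport.from_pairs(x0s[idx_test], mus[idx_test])
    restored_report = EvalReport.from_pairs(x0s[idx_test], restored)
    report = {
        "n_train": len(idx_train), "n_val": len(idx_val), "n_test": len(idx_test),
        "final_loss": log[-1]["loss"] if log else float("nan"),
        "degraded": degraded_report.summary(),
        "restored": restored_report.summary(),
        "per_image": [
            {"degraded": d, "restored": r}
            for d, r in zip(degraded_report.rows(), restored_report.rows())
        ],
    }
    if out_path:
        (out_path / "report.json").write_text(json.dumps(report, indent=2))
    return report
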