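"""Seeded synthetic initial-pressure phantoms and dataset splitting.

Three phantom families stand in for biological absorbers imaged by a circular
photoacoustic array: single point sources, collections of soft-edged disks,
and branching vessel trees grown by a recursive random walk with decreasing
width.  All generation is driven by a master seed that fans out to
per-phantom child seeds by index, so datasets are reproducible and can be
generated in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np
from skimage.draw import disk as _draw_disk

from .errors import ConfigurationError
from .image import DYNAMIC_RANGE, PressureImage

T = TypeVar("T")

PHANTOM_KINDS = ("point", "disks", "vessels")


@dataclass
class PhantomSpec:
    """Configuration of one phantom draw.

    Ranges are inclusive ``(low, high)`` pairs; radii are in mm, intensities
    on the [0, 255] dataset scale.
    """

    kind: str = "disks"
    n_objects: tuple[int, int] = (3, 8)
    radius_mm: tuple[float, float] = (0.5, 3.0)
    intensity: tuple[float, float] = (100.0, 255.0)
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ConfigurationError(f"unknown phantom kind {self.kind!r}")
        for name, rng in (("n_objects", self.n_objects), ("radius_mm", self.radius_mm),
                          ("intensity", self.intensity)):
            lo, hi = rng
            if hi < lo or lo < 0:
                raise ConfigurationError(f"invalid {name} range {rng}")
        if self.background < 0:
            raise ConfigurationError("background must be non-negative")


def child_seed(master: int, index: int) -> np.random.SeedSequence:
    """Per-phantom seed derived from a master seed and the phantom index."""
    return np.random.SeedSequence(entropy=master, spawn_key=(index,))


def generate_phantom(
    spec: PhantomSpec,
    grid: tuple[int, int] = (64, 64),
    spacing_mm: float = 0.3,
) -> PressureImage:
    """Draw one phantom on an ``H x W`` grid.

    Deterministic for a fixed ``(spec, seed)``.  A ``point`` phantom has
    exactly one nonzero pixel; ``disks`` adds ``n_objects`` uniform disks;
    ``vessels`` grows a connected branching tree from a single root.
    """
    h, w = grid
    if h < 8 or w < 8:
        raise ConfigurationError(f"grid {grid} too small, need >= 8x8")
    rng = np.random.default_rng(child_seed(spec.seed, 0))
    img = np.full((h, w), float(spec.background))

    if spec.kind == "point":
        r = rng.integers(h // 4, h - h // 4)
        c = rng.integers(w // 4, w - w // 4)
        img[r, c] = rng.uniform(*spec.intensity)
    elif spec.kind == "disks":
        n = int(rng.integers(spec.n_objects[0], spec.n_objects[1] + 1))
        for _ in range(n):
            rad_px = max(1.0, rng.uniform(*spec.radius_mm) / spacing_mm)
            cy = rng.uniform(0.2 * h, 0.8 * h)
            cx = rng.uniform(0.2 * w, 0.8 * w)
            amp = rng.uniform(*spec.intensity)
            rr, cc = _draw_disk((cy, cx), rad_px, shape=img.shape)
            img[rr, cc] += amp
    else:  # vessels
        _grow_vessel_tree(img, rng, spec, spacing_mm)

    np.clip(img, 0.0, DYNAMIC_RANGE, out=img)
    return PressureImage(img, spacing_mm)


def _stamp_segment(img, p0, p1, width_px, amp):
    """Rasterize a thick segment as overlapping disks along its length."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(length / max(width_px * 0.5, 0.5)) + 1)
    for s in np.linspace(0.0, 1.0, n):
        c = p0 + s * (p1 - p0)
        rr, cc = _draw_disk((c[0], c[1]), max(width_px, 0.8), shape=img.shape)
        img[rr, cc] = np.maximum(img[rr, cc], amp)


def _grow_vessel_tree(img, rng, spec: PhantomSpec, spacing_mm: float) -> None:
    """Recursive branching random walk with decreasing width.

    Every branch starts where its parent left off, so the nonzero support is
    a single connected component.
    """
    h, w = img.shape
    amp = rng.uniform(*spec.intensity)
    root = np.array([rng.uniform(0.3 * h, 0.7 * h), rng.uniform(0.3 * w, 0.7 * w)])
    width0 = max(1.0, rng.uniform(*spec.radius_mm) / spacing_mm)
    max_branches = int(rng.integers(max(2, spec.n_objects[0]), spec.n_objects[1] + 2))
    stack = [(root, rng.uniform(0, 2 * np.pi), width0, 0)]
    n_branches = 0
    step = max(2.0, 0.06 * min(h, w))
    while stack and n_branches < max_branches:
        pos, ang, width, depth = stack.pop()
        n_branches += 1
        n_steps = int(rng.integers(4, 9))
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.45)
            nxt = pos + step * np.array([np.sin(ang), np.cos(ang)])
            nxt = np.clip(nxt, 1.0, [h - 2.0, w - 2.0])
            _stamp_segment(img, pos, nxt, width, amp)
            pos = nxt
            if depth < 4 and rng.uniform() < 0.35:
                stack.append((pos.copy(), ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2),
                              max(0.8, width * 0.7), depth + 1))
        # taper the continuing trunk
        if depth < 4:
            stack.append((pos.copy(), ang, max(0.8, width * 0.8), depth + 1))


def generate_dataset(
    n: int,
    kind: str = "disks",
    grid: tuple[int, int] = (64, 64),
    spacing_mm: float = 0.3,
    seed: int = 0,
    **spec_kwargs,
) -> list[PressureImage]:
    """Generate ``n`` phantoms with per-index child seeds of ``seed``."""
    out = []
    for i in range(n):
        spec = PhantomSpec(kind=kind, seed=int(np.random.default_rng(
            child_seed(seed, i)).integers(0, 2**31 - 1)), **spec_kwargs)
        out.append(generate_phantom(spec, grid, spacing_mm))
    return out


def split_dataset(
    items: Sequence[T],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[T], list[T], list[T]]:
    """Seeded shuffle then disjoint, exhaustive (train, val, test) partition.

    Validation and test sizes are floors of their fractions; the remainder
    goes to training.
    """
    if not items:
        raise ConfigurationError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions {fractions} must sum to 1")
    if any(f < 0 for f in fractions):
        raise ConfigurationError("fractions must be non-negative")
    n = len(items)
    n_val = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val:]]
    return train, val, test
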