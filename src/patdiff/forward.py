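"""Forward acoustic simulation and view subsampling.

The forward model is an idealized point-detector, lossless, homogeneous
medium circular-mean projector: the pressure trace at a detector is the time
derivative of the mean of the initial pressure over circles centred at the
detector with radius ``v*t``.  Each pixel is deposited linearly into the two
time bins bracketing its arrival, annulus sums are converted to circular
means, and a central finite difference forms the derivative.  The model is
exactly linear in the image and exactly covariant under the square grid's
symmetries (90-degree rotations, axis/diagonal reflections).

Because the image is pixelated, traces carry sub-pixel binning roughness on
top of the smooth circular-mean signal; the reconstruction band-pass removes
it, and it is precisely the pixel-scale content that lets filtered
back-projection recover pixelated structures.  Integrated traces (the
circular means themselves) are smooth and nearly isotropic.

Sparse-view subsets keep every ``(n_elements/n)``-th element starting at
index 0; limited-view subsets keep the contiguous block of elements starting
at the ring's start angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigurationError, DataError, GeometryError
from .geometry import RingGeometry, detector_positions
from .image import PressureImage


@dataclass
class Sinogram:
    """Detector-by-time pressure traces plus acquisition metadata.

    ``detector_mask`` records which of the full ring's elements are present;
    ``traces`` has one row per active element, in ring order.
    """

    traces: np.ndarray
    dt_us: float
    geometry: RingGeometry
    detector_mask: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        self.detector_mask = np.asarray(self.detector_mask, dtype=bool)
        if self.detector_mask.shape != (self.geometry.n_elements,):
            raise DataError("detector_mask length must equal n_elements")
        if self.traces.shape[0] != int(self.detector_mask.sum()):
            raise DataError("traces rows must equal number of active elements")
        if not np.all(np.isfinite(self.traces)):
            raise DataError("traces contain non-finite samples")

    @property
    def n_detectors(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    def active_positions(self) -> np.ndarray:
        return detector_positions(self.geometry)[self.detector_mask]


def simulate_signals(
    image: PressureImage, geom: RingGeometry, n_samples: int | None = None
) -> Sinogram:
    """Simulate ring-array pressure traces from an initial-pressure image.

    Raises :class:`GeometryError` if the image grid extends outside the ring.
    """
    max_r = image.max_radius_mm()
    if max_r >= geom.radius_mm:
        raise GeometryError(
            f"image radius {max_r:.2f} mm reaches outside the {geom.radius_mm:.2f} mm ring"
        )
    n_t = n_samples or geom.n_samples or geom.required_samples(max_r)
    if n_t < geom.required_samples(max_r):
        raise GeometryError(
            f"{n_t} samples truncate arrivals; need >= {geom.required_samples(max_r)}"
        )

    X, Y = image.pixel_coordinates()
    vals = image.pixels.ravel()
    x, y = X.ravel(), Y.ravel()
    nz = vals != 0.0
    x, y, vals = x[nz], y[nz], vals[nz]

    dr = geom.radial_step_mm
    radii = np.arange(n_t) * dr
    # circumference of each time-of-flight circle; r=0 is never hit because
    # detectors sit outside the image
    circ = 2.0 * np.pi * np.maximum(radii, dr) * dr
    weights = vals * image.spacing_mm**2

    pos = detector_positions(geom)
    traces = np.empty((geom.n_elements, n_t))
    for d, (dx, dy) in enumerate(pos):
        if vals.size == 0:
            traces[d] = 0.0
            continue
        s = np.hypot(x - dx, y - dy) / dr
        i0 = s.astype(np.int64)
        frac = s - i0
        acc = np.bincount(i0, weights=weights * (1.0 - frac), minlength=n_t + 1)[: n_t + 1]
        acc += np.bincount(i0 + 1, weights=weights * frac, minlength=n_t + 1)[: n_t + 1]
        traces[d] = np.gradient(acc[:n_t] / circ, geom.dt_us)
    return Sinogram(traces, geom.dt_us, geom, np.ones(geom.n_elements, dtype=bool))


def subsample_views(sino: Sinogram, mode: str, param: float) -> Sinogram:
    """Reduce a full acquisition to a sparse-view or limited-view subset.

    ``mode='sparse'``: keep ``param`` uniformly strided elements (``param``
    must divide the element count).  ``mode='limited'``: keep the contiguous
    ``floor(n_elements * omega / coverage)`` elements starting at the ring's
    start angle, where ``param`` is the retained arc ``omega`` in radians.
    Trace rows are passed through unmodified.
    """
    if not np.all(sino.detector_mask):
        raise ConfigurationError("subsampling expects a full-view sinogram")
    n_el = sino.geometry.n_elements
    mask = np.zeros(n_el, dtype=bool)
    if mode == "sparse":
        n = int(param)
        if n < 1 or n_el % n != 0:
            raise ConfigurationError(f"sparse count {n} must divide {n_el}")
        mask[:: n_el // n] = True
    elif mode == "limited":
        omega = float(param)
        if not (0.0 < omega <= sino.geometry.coverage_rad + 1e-12):
            raise ConfigurationError(f"limited-view arc {omega} outside (0, coverage]")
        keep = int(np.floor(n_el * omega / sino.geometry.coverage_rad))
        mask[:max(keep, 1)] = True
    else:
        raise ConfigurationError(f"unknown subsampling mode {mode!r}")
    return Sinogram(sino.traces[mask], sino.dt_us, sino.geometry, mask)


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    """HDF5 layout: float32 dataset ``traces`` + geometry JSON attributes."""
    g = sino.geometry
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("traces", data=sino.traces.astype(np.float32))
        ds.attrs["dt_us"] = sino.dt_us
        ds.attrs["geometry"] = json.dumps(
            {
                "radius_mm": g.radius_mm,
                "n_elements": g.n_elements,
                "coverage_rad": g.coverage_rad,
                "start_angle_rad": g.start_angle_rad,
                "speed_of_sound_m_s": g.speed_of_sound_m_s,
                "sampling_rate_mhz": g.sampling_rate_mhz,
            }
        )
        f.create_dataset("detector_mask", data=sino.detector_mask)


def load_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as f:
        ds = f["traces"]
        geom = RingGeometry(**json.loads(ds.attrs["geometry"]))
        return Sinogram(
            np.asarray(ds, dtype=np.float64),
            float(ds.attrs["dt_us"]),
            geom,
            np.asarray(f["detector_mask"], dtype=bool),
        )
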