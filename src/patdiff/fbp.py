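"""Filtered back-projection for circular-array photoacoustic tomography.

Reconstruction follows the classic back-projection form: each recorded trace
is band-pass filtered with a zero-phase third-order Butterworth window (0.5
to 10 MHz by default), combined with its ramp-filtered time derivative into
the back-projection term

    b(r_d, t) = 2 p_f(r_d, t) - derivative_weight * t * dp_f/dt,

and back-projected onto the image grid along time-of-flight circles
``t = |r_s - r_d| / v`` with uniform weights ``1/N_active`` and linear
interpolation in time.  ``derivative_weight`` defaults to 1 (the plain
``2p - t dp/dt`` form); the universal-back-projection variant ``2p - 2t
dp/dt`` is available by setting it to 2.  Both the filter window and the
derivative are applied in the Fourier domain.

Raw reconstructions keep their signed values; normalization onto [0, 255]
happens only when building training pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ReconstructionError
from .forward import Sinogram, simulate_signals, subsample_views
from .geometry import RingGeometry
from .image import PressureImage


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass window for trace preprocessing."""

    order: int = 3
    band_mhz: tuple[float, float] = (0.5, 10.0)

    def __post_init__(self) -> None:
        low, high = self.band_mhz
        if not (0.0 < low < high):
            raise ConfigurationError(f"invalid band {self.band_mhz}")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")

    def validate_for(self, sampling_rate_mhz: float) -> None:
        nyquist = sampling_rate_mhz / 2.0
        if self.band_mhz[1] >= nyquist:
            raise ConfigurationError(
                f"band edge {self.band_mhz[1]} MHz >= Nyquist {nyquist} MHz"
            )

    def response(self, freqs_mhz: np.ndarray) -> np.ndarray:
        """|W(f)| of the analog Butterworth band-pass at given frequencies."""
        b, a = signal.butter(self.order, [2 * np.pi * f for f in self.band_mhz],
                             btype="bandpass", analog=True)
        _, h = signal.freqs(b, a, worN=2 * np.pi * np.abs(np.asarray(freqs_mhz, float)))
        return np.abs(h)

    @classmethod
    def parse(cls, text: str) -> "FilterSpec":
        """Parse the CLI string format ``order:low_MHz:high_MHz``."""
        try:
            order, low, high = text.split(":")
            return cls(int(order), (float(low), float(high)))
        except ValueError as exc:
            raise ConfigurationError(f"bad filter spec {text!r}; want order:low:high") from exc


@dataclass(frozen=True)
class ReconGrid:
    """Square reconstruction grid centred on the ring centre."""

    shape: tuple[int, int] = (500, 500)
    extent_mm: float = 50.0

    @property
    def spacing_mm(self) -> float:
        return self.extent_mm / max(self.shape)

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.shape
        ys = (np.arange(h) - (h - 1) / 2.0) * self.spacing_mm
        xs = (np.arange(w) - (w - 1) / 2.0) * self.spacing_mm
        return np.meshgrid(xs, ys)

    def validate_inside(self, geom: RingGeometry) -> None:
        corner = np.hypot(*[(s - 1) / 2.0 * self.spacing_mm for s in self.shape])
        if corner >= geom.radius_mm:
            raise ConfigurationError(
                f"grid corner radius {corner:.2f} mm not inside ring {geom.radius_mm:.2f} mm"
            )


def backprojection_term(
    sino: Sinogram, filt: FilterSpec = FilterSpec(), derivative_weight: float = 1.0
) -> np.ndarray:
    """Filtered traces combined with their ramp derivative, per detector.

    Computed per trace via FFT: ``2 F^-1{W F p} - w_d * t * F^-1{j omega W F p}``
    with time in microseconds and angular frequency in rad/us (the product
    ``t * omega`` is dimensionless, so any consistent unit pair is valid).
    """
    filt.validate_for(1.0 / sino.dt_us)
    n_t = sino.n_samples
    f_mhz = np.fft.fftfreq(n_t, d=sino.dt_us)
    w_window = filt.response(f_mhz)
    omega = 2.0 * np.pi * f_mhz
    spec = np.fft.fft(sino.traces, axis=1) * w_window
    smooth = np.fft.ifft(spec, axis=1).real
    deriv = np.fft.ifft(1j * omega * spec, axis=1).real
    t_us = np.arange(n_t) * sino.dt_us
    return 2.0 * smooth - derivative_weight * t_us * deriv


def reconstruct(
    sino: Sinogram,
    grid: ReconGrid = ReconGrid(),
    filt: FilterSpec = FilterSpec(),
    derivative_weight: float = 1.0,
) -> PressureImage:
    """Back-project the filtered term onto the grid (signed output).

    Uses uniform weights ``1/N_active`` over the active detectors and linear
    interpolation of ``b`` at the per-pixel arrival time; an arrival beyond
    the recorded window raises :class:`ReconstructionError`.
    """
    grid.validate_inside(sino.geometry)
    b = backprojection_term(sino, filt, derivative_weight)
    X, Y = grid.pixel_coordinates()
    v = sino.geometry.speed_mm_us
    dt = sino.dt_us
    n_t = sino.n_samples
    out = np.zeros(grid.shape, dtype=np.float64)
    for d, (dx, dy) in enumerate(sino.active_positions()):
        s = np.hypot(X - dx, Y - dy) / (v * dt)
        i0 = s.astype(np.int64)
        if i0.max() + 1 >= n_t:
            bad = np.unravel_index(np.argmax(s), s.shape)
            raise ReconstructionError(
                f"arrival time for pixel {bad} at detector {d} exceeds the "
                f"recorded window ({n_t} samples)"
            )
        frac = s - i0
        out += (1.0 - frac) * b[d, i0] + frac * b[d, i0 + 1]
    out /= sino.n_detectors
    return PressureImage(out, grid.spacing_mm)


def make_training_pair(
    image: PressureImage,
    geom: RingGeometry,
    mode: str,
    param: float,
    grid: ReconGrid,
    filt: FilterSpec = FilterSpec(),
    derivative_weight: float = 1.0,
) -> tuple[PressureImage, PressureImage]:
    """Full-view reference and degraded reconstruction, jointly normalized.

    Both images are reconstructed on the same grid and mapped to [0, 255]
    using the full-view image's min/max, so degradation-induced intensity
    loss survives normalization.
    """
    full = simulate_signals(image, geom)
    x0_raw = reconstruct(full, grid, filt, derivative_weight)
    sub = subsample_views(full, mode, param)
    mu_raw = reconstruct(sub, grid, filt, derivative_weight)
    lo, hi = float(x0_raw.pixels.min()), float(x0_raw.pixels.max())
    return x0_raw.normalized(lo, hi), mu_raw.normalized(lo, hi)
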