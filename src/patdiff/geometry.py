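"""Circular transducer-array geometry.

The acquisition hardware modelled here is a ring of ideal point detectors:
by default 512 elements on a 40 mm radius circle sampling at 62.5 MHz, with
sound speed 1500 m/s (standard soft-tissue value; the array's physical 5 MHz
centre frequency is represented only by the reconstruction band-pass filter,
not in the forward model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class RingGeometry:
    """Detector ring: positions, timing and acoustic parameters.

    ``coverage`` is the angular extent of the arc carrying the ``n_elements``
    detectors; elements are uniformly spaced over the arc with the first one
    at ``start_angle`` and an angular pitch of ``coverage / n_elements`` (a
    full 2*pi ring therefore has no duplicated endpoint).
    """

    radius_mm: float = 40.0
    n_elements: int = 512
    coverage_rad: float = TWO_PI
    start_angle_rad: float = 0.0
    speed_of_sound_m_s: float = 1500.0
    sampling_rate_mhz: float = 62.5
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ConfigurationError("radius must be positive")
        if self.n_elements < 1:
            raise ConfigurationError("need at least one element")
        if not (0.0 < self.coverage_rad <= TWO_PI + 1e-12):
            raise ConfigurationError("coverage must lie in (0, 2*pi]")
        if self.speed_of_sound_m_s <= 0 or self.sampling_rate_mhz <= 0:
            raise ConfigurationError("speed of sound and sampling rate must be positive")

    @property
    def dt_us(self) -> float:
        """Sampling interval in microseconds."""
        return 1.0 / self.sampling_rate_mhz

    @property
    def speed_mm_us(self) -> float:
        """Speed of sound in mm per microsecond."""
        return self.speed_of_sound_m_s * 1e-3

    @property
    def radial_step_mm(self) -> float:
        """Distance travelled by sound in one sample: v / f_s."""
        return self.speed_mm_us * self.dt_us

    def required_samples(self, image_max_radius_mm: float) -> int:
        """Samples needed so no arrival from the image is truncated."""
        max_dist = self.radius_mm + image_max_radius_mm
        return int(np.ceil(max_dist / self.radial_step_mm)) + 4

    def angles(self) -> np.ndarray:
        return self.start_angle_rad + np.arange(self.n_elements) * (
            self.coverage_rad / self.n_elements
        )


def detector_positions(geom: RingGeometry) -> np.ndarray:
    """(n_elements, 2) array of detector (x, y) coordinates in mm."""
    ang = geom.angles()
    return np.stack([geom.radius_mm * np.cos(ang), geom.radius_mm * np.sin(ang)], axis=1)
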