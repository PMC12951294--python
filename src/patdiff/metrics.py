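"""Image-quality evaluation: PSNR, RMSE, SSIM and central line profiles.

PSNR and SSIM use the standard definitions (scikit-image) with the dataset
convention ``data_range=255``; SSIM uses the canonical stabilizers
K1=0.01, K2=0.03 and an 11-tap Gaussian window with sigma=1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .errors import DataError
from .image import DYNAMIC_RANGE


def rmse(ref: np.ndarray, test: np.ndarray) -> float:
    ref, test = _checked(ref, test)
    return float(np.sqrt(np.mean((ref - test) ** 2)))


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = DYNAMIC_RANGE) -> float:
    """20 log10(range) - 10 log10(MSE); identical images report infinity."""
    ref, test = _checked(ref, test)
    if data_range <= 0:
        raise DataError("data_range must be positive")
    if np.array_equal(ref, test):
        return float("inf")
    return float(peak_signal_noise_ratio(ref, test, data_range=data_range))


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float = DYNAMIC_RANGE) -> float:
    """Mean local SSIM, Gaussian-weighted 11x11 window, K1=0.01, K2=0.03."""
    ref, test = _checked(ref, test)
    if min(ref.shape) < 11:
        raise DataError(f"image {ref.shape} smaller than the 11-tap SSIM window")
    return float(structural_similarity(
        ref, test, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03,
    ))


def line_profiles(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central horizontal (row H//2) and vertical (column W//2) profiles."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    return image[h // 2, :].copy(), image[:, w // 2].copy()


def _checked(ref, test) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise DataError(f"shape mismatch {ref.shape} vs {test.shape}")
    return ref, test


@dataclass
class EvalReport:
    """Per-image metric lists with mean/std aggregates."""

    psnr: list[float]
    rmse: list[float]
    ssim: list[float]

    @classmethod
    def from_pairs(cls, refs, tests, data_range: float = DYNAMIC_RANGE) -> "EvalReport":
        p, r, s = [], [], []
        for ref, test in zip(refs, tests):
            p.append(psnr(ref, test, data_range))
            r.append(rmse(ref, test))
            s.append(ssim(ref, test, data_range))
        return cls(p, r, s)

    def summary(self) -> dict[str, float]:
        out = {}
        for name, vals in (("psnr", self.psnr), ("rmse", self.rmse), ("ssim", self.ssim)):
            finite = [v for v in vals if np.isfinite(v)]
            out[f"{name}_mean"] = float(np.mean(finite)) if finite else float("nan")
            out[f"{name}_std"] = float(np.std(finite)) if finite else float("nan")
        return out

    def rows(self) -> list[dict[str, float]]:
        return [
            {"index": i, "psnr": p, "rmse": r, "ssim": s}
            for i, (p, r, s) in enumerate(zip(self.psnr, self.rmse, self.ssim))
        ]
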