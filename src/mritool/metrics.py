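"""Image quality metrics: SNR (dB) and SSIM.

Conventions: the clean reference image is the reference for every
comparison (``snr(ref, test)``, ``ssim(ref, test)``), so "before" means
clean-vs-noisy and "after" means clean-vs-denoised. SNR is

    10 * log10( sum(ref^2) / sum((ref - test)^2) )

capped at 300 dB when the images are identical. SSIM is the standard
local-window index with an 11x11 Gaussian window (sigma 1.5), stability
constants C1 = (0.01 L)^2 and C2 = (0.03 L)^2, and dynamic range L
defaulting to the reference max - min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

from .errors import InputError
from .grid import ImageGrid

SNR_CAP_DB = 300.0


@dataclass
class QualityReport:
    snr_db: float
    ssim: float
    window: str
    dynamic_range: float
    identical: bool = False


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)


def snr(reference, test) -> float:
    """Signal-to-noise ratio of ``test`` against ``reference``, in dB."""
    ref = _values(reference)
    tst = _values(test)
    if ref.shape != tst.shape:
        raise InputError(f"shape mismatch {ref.shape} vs {tst.shape}")
    signal = float(np.sum(ref ** 2))
    if signal == 0:
        raise InputError("reference image is identically zero")
    noise = float(np.sum((ref - tst) ** 2))
    if noise == 0:
        return SNR_CAP_DB
    return float(10.0 * np.log10(signal / noise))


def ssim(reference, test, window_sigma: float = 1.5,
         dynamic_range: Optional[float] = None) -> float:
    """Mean structural similarity over Gaussian windows.

    ``dynamic_range`` defaults to reference max - min; it must be > 0.
    """
    ref = _values(reference)
    tst = _values(test)
    if ref.shape != tst.shape:
        raise InputError(f"shape mismatch {ref.shape} vs {tst.shape}")
    if min(ref.shape) < 11:
        raise InputError(
            f"image {ref.shape} smaller than the 11-pixel SSIM window"
        )
    if dynamic_range is None:
        dynamic_range = float(ref.max() - ref.min())
    if not (dynamic_range > 0):
        raise InputError(f"dynamic_range must be > 0, got {dynamic_range}")
    return float(structural_similarity(
        ref, tst,
        data_range=dynamic_range,
        gaussian_weights=True,
        sigma=window_sigma,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
    ))


def quality_report(reference, test) -> QualityReport:
    """SNR and SSIM of ``test`` against ``reference`` in one record."""
    ref = _values(reference)
    dr = float(ref.max() - ref.min())
    s = snr(reference, test)
    return QualityReport(
        snr_db=s,
        ssim=ssim(reference, test),
        window="gaussian 11x11 sigma=1.5",
        dynamic_range=dr,
        identical=s >= SNR_CAP_DB,
    )
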