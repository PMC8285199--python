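"""Synthetic anatomy-like phantoms.

Stand-ins for patient MR slices so every pipeline stage can be exercised
with a known ground truth. Intensities are in [0, 1]; every kind contains
at least two distinct intensity regions so that thresholding has work to do.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .grid import ImageGrid

KINDS = ("shepp_like", "blobs", "step_wedge")


def _base_grids(shape):
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _shepp_like(shape, rng):
    """A few nested ellipses: skull-like ring, brain, ventricle-like voids."""
    coords = _base_grids(shape)
    img = np.zeros(shape)

    def ellipse(center, radii, value):
        q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
        nonlocal img
        img = np.where(q <= 1.0, value, img)

    zeros = (0.0,) * len(shape)
    ellipse(zeros, (0.92,) * len(shape), 1.0)              # skull
    ellipse(zeros, (0.80,) * len(shape), 0.55)             # brain tissue
    c1 = tuple([-0.25, -0.2] + [0.0] * (len(shape) - 2))
    c2 = tuple([-0.25, 0.2] + [0.0] * (len(shape) - 2))
    ellipse(c1, (0.30, 0.12) + (0.3,) * (len(shape) - 2), 0.25)   # ventricle
    ellipse(c2, (0.30, 0.12) + (0.3,) * (len(shape) - 2), 0.25)   # ventricle
    c3 = tuple([0.35, 0.0] + [0.0] * (len(shape) - 2))
    ellipse(c3, (0.15,) * len(shape), 0.85)                # lesion-like blob
    # faint texture so the histogram is not purely discrete
    img = img + 0.02 * rng.standard_normal(shape)
    img = ndimage.gaussian_filter(img, 0.8)
    img = np.clip(img, 0.0, None)
    img = img / img.max()
    # dim positive background: a multiplicative noise model carries no
    # information on true-zero pixels, so the phantom floor is above zero
    return 0.05 + 0.95 * img


def _blobs(shape, rng):
    """Random smooth elliptical blobs over a dim background."""
    coords = _base_grids(shape)
    img = np.zeros(shape)
    for _ in range(6):
        center = [rng.uniform(-0.7, 0.7) for _ in shape]
        radii = [rng.uniform(0.12, 0.45) for _ in shape]
        amp = rng.uniform(0.3, 1.0)
        q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
        img = np.maximum(img, amp * (q <= 1.0))
    img = ndimage.gaussian_filter(img, 1.0) + 0.05
    return img / img.max()


def _step_wedge(shape, rng):
    """Left half one constant, right half another; exactly two gray levels."""
    img = np.full(shape, 0.25)
    half = shape[1] // 2
    img[:, half:] = 0.75
    return img


_BUILDERS = {"shepp_like": _shepp_like, "blobs": _blobs, "step_wedge": _step_wedge}


def make_phantom(shape, kind: str = "blobs", seed: int = 0) -> ImageGrid:
    """Build a deterministic synthetic phantom.

    Parameters
    ----------
    shape : tuple of int
        Axis sizes, each >= 8; two or three axes.
    kind : {"shepp_like", "blobs", "step_wedge"}
    seed : int
        Seed for the stochastic kinds; the same call always returns the
        same image bit for bit.
    """
    if kind not in _BUILDERS:
        raise ConfigurationError(
            f"unknown phantom kind {kind!r}; expected one of {KINDS}"
        )
    shape = tuple(int(n) for n in shape)
    if len(shape) not in (2, 3) or any(n < 8 for n in shape):
        raise InputError(f"phantom shape must be 2-D/3-D with axes >= 8, got {shape}")
    rng = np.random.default_rng(seed)
    values = _BUILDERS[kind](shape, rng)
    return ImageGrid(values=values, modality_tag="synthetic",
                     metadata={"phantom_kind": kind, "phantom_seed": seed})
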