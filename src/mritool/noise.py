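"""Multiplicative speckle model and Rayleigh density machinery.

The noise model is ``y = l * i + a``: a noise-free image ``l`` corrupted
by i.i.d. multiplicative speckle ``i`` with one-sided Rayleigh-distributed
amplitude (attenuation parameter ``d``) and a small additive term ``a``.
Taking logarithms turns the multiplicative part into an additive one,
``log y = log l + log i`` (written ``f = m + n``), which is the domain in
which the MAP denoiser operates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputError, ParameterError
from .grid import ImageGrid

# Mean of log R for R ~ Rayleigh(scale=1): (log 2 - gamma) / 2.
LOG_RAYLEIGH_MEAN = (np.log(2.0) - np.euler_gamma) / 2.0
# Standard deviation of log R, independent of the scale: pi / sqrt(24).
LOG_RAYLEIGH_STD = np.pi / np.sqrt(24.0)


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of the speckle corruption model.

    d : Rayleigh attenuation parameter of the multiplicative field (> 0).
    additive_sigma : standard deviation of the zero-mean Gaussian additive
        term (>= 0); intensities are clipped at 0 afterwards.
    seed : RNG seed; every corruption is reproducible from it.
    """

    d: float
    additive_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.d > 0):
            raise ParameterError(f"attenuation parameter d must be > 0, got {self.d}")
        if self.additive_sigma < 0:
            raise ParameterError(
                f"additive_sigma must be >= 0, got {self.additive_sigma}"
            )


@dataclass(frozen=True)
class RayleighDensity:
    """Rayleigh amplitude density with attenuation parameter ``d``.

    ``one_sided`` is the standard density (t/d^2) exp(-t^2 / 2 d^2) on
    t >= 0. ``two_sided_normalized`` extends it symmetrically to the whole
    line and divides by two so it remains a proper density:
    (|t| / 2 d^2) exp(-t^2 / 2 d^2).
    """

    d: float
    form: Literal["one_sided", "two_sided_normalized"] = "one_sided"

    def __post_init__(self):
        if not (self.d > 0):
            raise ParameterError(f"attenuation parameter d must be > 0, got {self.d}")
        if self.form not in ("one_sided", "two_sided_normalized"):
            raise ParameterError(f"unknown density form {self.form!r}")


@dataclass(frozen=True)
class LogDomainPair:
    """Log-domain decomposition f = m + n of a noisy image.

    f : log of the noisy image.
    m : log of the clean image (None when the clean image is unknown).
    n : log of the speckle field (None when the field is unknown).
    """

    f: np.ndarray
    m: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None


def step(t: float) -> int:
    """Unit step: 1 for t >= 0, 0 for t < 0."""
    t = float(t)
    if not np.isfinite(t):
        raise InputError(f"step() requires a finite argument, got {t}")
    return 1 if t >= 0 else 0


def rayleigh_pdf(t, density: RayleighDensity):
    """Evaluate the Rayleigh amplitude density at ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    d2 = density.d ** 2
    if density.form == "one_sided":
        out = np.where(t >= 0, t / d2 * np.exp(-np.square(t) / (2 * d2)), 0.0)
    else:
        out = np.abs(t) / (2 * d2) * np.exp(-np.square(t) / (2 * d2))
    return out if out.ndim else float(out)


def rayleigh_cdf(t, d: float):
    """CDF of the one-sided Rayleigh density: 1 - exp(-t^2 / 2 d^2) on t >= 0."""
    if not (d > 0):
        raise ParameterError(f"d must be > 0, got {d}")
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, 1.0 - np.exp(-np.square(t) / (2 * d ** 2)), 0.0)
    return out if out.ndim else float(out)


def sample_speckle_field(shape, params: SpeckleParams) -> np.ndarray:
    """Draw an i.i.d. one-sided Rayleigh multiplicative field of given shape."""
    rng = np.random.default_rng(params.seed)
    return rng.rayleigh(scale=params.d, size=tuple(shape))


def apply_speckle(
    clean: ImageGrid,
    params: SpeckleParams,
    field: Optional[np.ndarray] = None,
) -> ImageGrid:
    """Corrupt a clean image: y = l * i + a, clipped at zero.

    ``field`` may be supplied to force a specific multiplicative field
    (used by tests); otherwise it is drawn from ``params``. The additive
    term uses an independent substream of the same seed so that
    ``additive_sigma = 0`` reproduces the purely multiplicative regime
    bit-exactly.
    """
    if field is None:
        field = sample_speckle_field(clean.shape, params)
    else:
        field = np.asarray(field, dtype=float)
        if field.shape != clean.shape:
            raise InputError(
                f"field shape {field.shape} != image shape {clean.shape}"
            )
    noisy = clean.values * field
    if params.additive_sigma > 0:
        rng = np.random.default_rng((int(params.seed), 1))
        noisy = noisy + rng.normal(0.0, params.additive_sigma, size=clean.shape)
    noisy = np.clip(noisy, 0.0, None)
    out = clean.like(noisy)
    out.metadata["speckle_d"] = params.d
    out.metadata["additive_sigma"] = params.additive_sigma
    out.metadata["noise_seed"] = params.seed
    return out


def _epsilon_floor(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Floor non-positive pixels at 1e-6 * max before a log transform.

    Returns the floored array and the boolean mask of touched pixels.
    """
    peak = float(values.max())
    if peak <= 0:
        raise DegenerateInputError("cannot log-transform an all-zero image")
    eps = 1e-6 * peak
    mask = values < eps
    return np.maximum(values, eps), mask


def log_separate(
    noisy: ImageGrid,
    clean: Optional[ImageGrid] = None,
    field: Optional[np.ndarray] = None,
) -> LogDomainPair:
    """Homomorphic separation: f = log y, and m = log l, n = log i if known.

    Non-positive pixels are floored at 1e-6 times the image maximum before
    the log, so the additivity f = m + n holds exactly only on pixels the
    floor did not touch.
    """
    y, _ = _epsilon_floor(noisy.values)
    f = np.log(y)
    m = n = None
    if clean is not None:
        c, _ = _epsilon_floor(clean.values)
        m = np.log(c)
    if field is not None:
        field = np.asarray(field, dtype=float)
        if field.shape != noisy.shape:
            raise InputError(
                f"field shape {field.shape} != image shape {noisy.shape}"
            )
        fl, _ = _epsilon_floor(field)
        n = np.log(fl)
    return LogDomainPair(f=f, m=m, n=n)


def estimate_d(samples) -> float:
    """Rayleigh maximum-likelihood moment estimator d = sqrt(mean(t^2) / 2)."""
    t = np.asarray(samples, dtype=float).ravel()
    if t.size == 0:
        raise InputError("estimate_d requires at least one sample")
    if not np.all(np.isfinite(t)):
        raise InputError("estimate_d requires finite samples")
    return float(np.sqrt(np.mean(np.square(t)) / 2.0))


def ks_against_rayleigh(samples, d: float):
    """Kolmogorov-Smirnov statistic and p-value of samples vs Rayleigh(d)."""
    res = stats.kstest(np.asarray(samples, dtype=float).ravel(),
                       stats.rayleigh(scale=d).cdf)
    return float(res.statistic), float(res.pvalue)
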