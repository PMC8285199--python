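"""Weighted-observation reconstruction, enhancement, thresholding, edges.

The acquisition model states that each low-resolution pixel is a weighted
sum of high-resolution pixels plus an additive offset:

    A[m, n] = sum_s Q[m, n, s] * X[s] + l[m, n]

over frames m, low-res pixels n and high-res pixels s (all 0-based and
dense internally). Inversion is linear least squares on the stacked
system. Enhancement minimizes the restoration objective
``W(g) = || b - j (*) g ||^2`` (observed degraded image b, point-spread
function j, candidate g) by projected gradient descent with backtracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, InputError, NumericalError, ParameterError
from .grid import ImageGrid


@dataclass
class AcquisitionModel:
    """Weights and offsets of the low-resolution observation operator.

    weights : ndarray, shape (M, N, P)
        ``weights[m, n, s]`` is the contribution of high-res pixel ``s``
        to low-res pixel ``n`` of frame ``m``.
    offsets : ndarray, shape (M, N)
        Additive offsets l[m, n] per low-res pixel.
    high_res_size : int
        Number of high-resolution pixels P.
    """

    weights: np.ndarray
    offsets: np.ndarray
    high_res_size: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.weights.ndim != 3:
            raise InputError("weights must have shape (frames, lowres, highres)")
        if self.offsets.shape != self.weights.shape[:2]:
            raise InputError(
                f"offsets shape {self.offsets.shape} incompatible with "
                f"weights {self.weights.shape}"
            )
        if self.weights.shape[2] != self.high_res_size:
            raise InputError(
                f"weights last axis {self.weights.shape[2]} != P={self.high_res_size}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise InputError("weights contain non-finite entries")


def forward_observe(high_res: ImageGrid, model: AcquisitionModel) -> list[np.ndarray]:
    """Apply the observation operator; returns one 1-D frame per m."""
    x = high_res.values.ravel()
    if x.size != model.high_res_size:
        raise InputError(
            f"image has {x.size} pixels but model expects P={model.high_res_size}"
        )
    frames = model.weights @ x + model.offsets
    return [frames[m] for m in range(frames.shape[0])]


@dataclass
class ReconstructionResult:
    estimate: np.ndarray          # flat high-res estimate, length P
    residual_norm: float
    rank: int
    rank_deficient: bool


def reconstruct(frames, model: AcquisitionModel) -> ReconstructionResult:
    """Least-squares inversion of the stacked observation system.

    Minimizes ``sum (A[m,n] - sum_s Q[m,n,s] X[s] - l[m,n])^2``; returns
    the minimum-norm solution (with a rank-deficiency flag) and the
    residual norm.
    """
    A = np.asarray(frames, dtype=float).ravel()
    Q = model.weights.reshape(-1, model.high_res_size)
    l = model.offsets.ravel()
    if A.size != Q.shape[0]:
        raise InputError(
            f"got {A.size} observations for a system with {Q.shape[0]} equations"
        )
    if Q.shape[0] < model.high_res_size:
        raise InputError(
            f"underdetermined system: {Q.shape[0]} equations < P={model.high_res_size}"
        )
    x, res, rank, _ = np.linalg.lstsq(Q, A - l, rcond=None)
    residual = float(np.linalg.norm(Q @ x - (A - l)))
    return ReconstructionResult(
        estimate=x,
        residual_norm=residual,
        rank=int(rank),
        rank_deficient=bool(rank < model.high_res_size),
    )


@dataclass
class EnhancementProblem:
    """Restoration objective data: observed image b, PSF j, candidate g."""

    degraded: np.ndarray
    psf: np.ndarray
    candidate: np.ndarray

    def __post_init__(self):
        self.degraded = np.asarray(self.degraded, dtype=float)
        self.psf = np.asarray(self.psf, dtype=float)
        self.candidate = np.asarray(self.candidate, dtype=float)
        if self.psf.size == 0:
            raise InputError("empty PSF")
        if not np.all(np.isfinite(self.psf)):
            raise InputError("PSF contains non-finite entries")
        if self.candidate.shape != self.degraded.shape:
            raise InputError(
                f"candidate shape {self.candidate.shape} != degraded "
                f"shape {self.degraded.shape}"
            )


def _convolve_same(image: np.ndarray, psf: np.ndarray) -> np.ndarray:
    """'Same'-size convolution, kernel centred, replicate padding."""
    return ndimage.convolve(image, psf, mode="nearest")


def enhancement_cost(problem: EnhancementProblem) -> float:
    """Squared residual ``|| b - j (*) g ||^2`` of a candidate restoration."""
    resid = problem.degraded - _convolve_same(problem.candidate, problem.psf)
    return float(np.sum(resid ** 2))


def enhance(degraded, psf, iterations: int = 50, step: float = None) -> np.ndarray:
    """Minimize the restoration objective by projected gradient descent.

    Starts from the degraded image itself, takes gradient steps with
    backtracking (halving the step on any cost increase; a step is only
    accepted if the cost does not increase), and clips negatives to keep
    the restored image a valid intensity image. Deterministic.
    """
    degraded = np.asarray(degraded, dtype=float)
    psf = np.asarray(psf, dtype=float)
    if psf.size == 0:
        raise InputError("empty PSF")
    if iterations < 1:
        raise ParameterError("iterations must be >= 1")
    if step is not None and not (step > 0):
        raise ParameterError("step must be > 0")
    if step is None:
        # 1 / Lipschitz bound of the quadratic: L <= (sum |j|)^2 for the
        # normal operator of a convolution.
        step = 1.0 / (2.0 * float(np.sum(np.abs(psf))) ** 2 + 1e-12)

    g = degraded.copy()
    cost = enhancement_cost(EnhancementProblem(degraded, psf, g))
    for _ in range(iterations):
        resid = _convolve_same(g, psf) - degraded
        grad = 2.0 * ndimage.correlate(resid, psf, mode="nearest")
        s = step
        for _ in range(30):
            cand = np.clip(g - s * grad, 0.0, None)
            c = enhancement_cost(EnhancementProblem(degraded, psf, cand))
            if c <= cost:
                g, cost = cand, c
                break
            s *= 0.5
        else:
            raise NumericalError("enhancement diverged: backtracking exhausted")
    return g


@dataclass
class SegmentationResult:
    """Best-threshold segmentation outcome.

    mask is exactly ``image >= threshold``; criterion_value is the
    between-class variance achieved at the chosen threshold.
    """

    threshold: float
    mask: np.ndarray
    criterion_value: float


def between_class_variance(values: np.ndarray, threshold: float) -> float:
    """Between-class variance of the split at ``values >= threshold``."""
    hi = values >= threshold
    n = values.size
    n1 = int(hi.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        return 0.0
    mu0 = float(values[~hi].mean())
    mu1 = float(values[hi].mean())
    w0, w1 = n0 / n, n1 / n
    return w0 * w1 * (mu1 - mu0) ** 2


def best_threshold_segment(image: ImageGrid, levels: int = 256) -> SegmentationResult:
    """Threshold at the gray level maximizing the between-class variance.

    Candidate thresholds are ``levels`` gray levels spanning the image
    range (Otsu's criterion over a uniform quantization); the lowest
    level wins ties. The mask is ``image >= threshold``.
    """
    if levels < 2:
        raise ParameterError(f"levels must be >= 2, got {levels}")
    values = image.values
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateInputError("cannot threshold a constant image")
    # Candidate thresholds strictly inside (lo, hi]: edges of the
    # quantization bins; a threshold at or below lo would put everything
    # in one class.
    candidates = np.linspace(lo, hi, levels + 1)[1:-1]
    best_t, best_v = None, -1.0
    for t in candidates:
        v = between_class_variance(values, float(t))
        if v > best_v:            # strict: lowest level wins ties
            best_t, best_v = float(t), v
    return SegmentationResult(
        threshold=best_t,
        mask=values >= best_t,
        criterion_value=best_v,
    )


def gradient_magnitude(values: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude with replicated borders."""
    padded = np.pad(values, 1, mode="edge")
    total = np.zeros_like(values, dtype=float)
    inner = tuple(slice(1, -1) for _ in values.shape)
    for axis in range(values.ndim):
        hi = list(inner)
        lo = list(inner)
        hi[axis] = slice(2, None)
        lo[axis] = slice(None, -2)
        total += np.square((padded[tuple(hi)] - padded[tuple(lo)]) / 2.0)
    return np.sqrt(total)


def edge_detect(image: ImageGrid, threshold: Optional[float] = None) -> np.ndarray:
    """Binary edge map: gradient magnitude strictly above ``threshold``.

    When ``threshold`` is omitted it defaults to the between-class-variance
    (Otsu) threshold of the gradient-magnitude image.
    """
    mag = gradient_magnitude(image.values)
    if threshold is None:
        if mag.min() == mag.max():
            return np.zeros(image.shape, dtype=bool)
        threshold = best_threshold_segment(image.like(mag)).threshold
    if threshold < 0:
        raise ParameterError(f"edge threshold must be >= 0, got {threshold}")
    return mag > threshold


def run_length_encode(mask: np.ndarray) -> list[tuple[int, int]]:
    """Run-length code of a flattened binary mask: (start, length) runs of 1s."""
    flat = np.asarray(mask).ravel().astype(bool)
    padded = np.concatenate([[False], flat, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]
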