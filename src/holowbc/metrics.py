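"""Scalar quality metrics for holographic reconstructions and masks.

Notation: I_ref is the reference (target) intensity, I_rec a numerically
reconstructed intensity, I_or an observed reconstruction.  Intensities are
compared after least-squares scaling because a phase-only reconstruction is
only defined up to an overall intensity factor.

The intensity error is the mean of squared intensity differences (no square
root); its square root is also exposed since the quantity is conventionally
reported as an RMSE.  The scaled signal-to-noise ratio removes the overall
intensity factor through the norm-ratio beta, which makes it invariant to
positive rescaling of the observed image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "eq1_error",
    "least_squares_scale",
    "speckle_contrast",
    "scaled_snr",
    "psnr",
    "jaccard",
    "QualityReport",
    "quality_report",
]


def _check_same_shape(a: np.ndarray, b: np.ndarray, op: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{op}: shape mismatch {a.shape} vs {b.shape}")


def eq1_error(i_ref: np.ndarray, i_rec: np.ndarray) -> float:
    """Mean over pixels of the squared intensity difference.

    Inputs are expected to be on a common intensity scale already (see
    :func:`least_squares_scale`).
    """
    i_ref = np.asarray(i_ref, dtype=float)
    i_rec = np.asarray(i_rec, dtype=float)
    _check_same_shape(i_ref, i_rec, "eq1_error")
    diff = i_ref - i_rec
    return float(np.mean(diff * diff))


def least_squares_scale(i_ref: np.ndarray, i_rec: np.ndarray) -> float:
    """The factor s minimizing ||i_ref - s * i_rec||."""
    i_ref = np.asarray(i_ref, dtype=float)
    i_rec = np.asarray(i_rec, dtype=float)
    _check_same_shape(i_ref, i_rec, "least_squares_scale")
    denom = float(np.sum(i_rec * i_rec))
    if denom == 0:
        raise ValueError("least_squares_scale: reconstruction is identically zero")
    return float(np.sum(i_ref * i_rec)) / denom


def speckle_contrast(
    image: np.ndarray, region: np.ndarray | None = None
) -> tuple[float, float, float]:
    """(sigma, mu, C) over a region; C = sigma / mu.

    sigma is the population standard deviation.  ``region`` restricts the
    statistics to a mask (e.g. the bright support of the target, since
    contrast over dark background is undefined).
    """
    image = np.asarray(image, dtype=float)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        _check_same_shape(image, region, "speckle_contrast")
        values = image[region]
    else:
        values = image.ravel()
    if values.size == 0:
        raise ValueError("speckle_contrast: empty region")
    mu = float(values.mean())
    if mu == 0:
        raise ValueError("speckle_contrast: zero mean intensity")
    sigma = float(values.std())
    return sigma, mu, sigma / mu


def scaled_snr(i_ref: np.ndarray, i_or: np.ndarray) -> tuple[float, float]:
    """Scale-invariant SNR = ||I_ref||^2 / ||I_ref - beta * I_or||^2.

    beta is the positive root of ||I_ref||^2 / ||I_or||^2, which removes
    any overall intensity factor of the observation.  A perfect (up to
    scale) observation yields +inf.
    """
    i_ref = np.asarray(i_ref, dtype=float)
    i_or = np.asarray(i_or, dtype=float)
    _check_same_shape(i_ref, i_or, "scaled_snr")
    ref_sq = float(np.sum(i_ref * i_ref))
    or_sq = float(np.sum(i_or * i_or))
    if or_sq == 0:
        raise ValueError("scaled_snr: observed image is identically zero")
    beta = float(np.sqrt(ref_sq / or_sq))
    denom = float(np.sum((i_ref - beta * i_or) ** 2))
    if denom == 0:
        return float("inf"), beta
    return ref_sq / denom, beta


def psnr(i_ref: np.ndarray, i_rec: np.ndarray) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE) in dB; peak = max(i_ref)."""
    i_ref = np.asarray(i_ref, dtype=float)
    i_rec = np.asarray(i_rec, dtype=float)
    _check_same_shape(i_ref, i_rec, "psnr")
    mse = float(np.mean((i_ref - i_rec) ** 2))
    if mse == 0:
        return float("inf")
    peak = float(i_ref.max())
    return 10.0 * np.log10(peak * peak / mse)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A intersect B| / |A union B|; two empty masks compare as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    _check_same_shape(a, b, "jaccard")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class QualityReport:
    eq1_error: float
    rmse: float  # square root of eq1_error
    sigma: float
    mu: float
    contrast: float
    snr: float
    beta_scale: float
    psnr_db: float
    jaccard: float | None = None


def quality_report(
    i_ref: np.ndarray,
    i_rec: np.ndarray,
    region: np.ndarray | None = None,
    mask_pair: tuple[np.ndarray, np.ndarray] | None = None,
) -> QualityReport:
    """All scalar metrics for one reference/reconstruction pair.

    The reconstruction is least-squares-scaled to the reference before the
    error metrics; speckle statistics use ``region`` if given.
    """
    scale = least_squares_scale(i_ref, i_rec)
    scaled = scale * np.asarray(i_rec, dtype=float)
    err = eq1_error(i_ref, scaled)
    sigma, mu, contrast = speckle_contrast(scaled, region)
    snr, beta = scaled_snr(i_ref, i_rec)
    return QualityReport(
        eq1_error=err,
        rmse=float(np.sqrt(err)),
        sigma=sigma,
        mu=mu,
        contrast=contrast,
        snr=snr,
        beta_scale=beta,
        psnr_db=psnr(i_ref, scaled),
        jaccard=None if mask_pair is None else jaccard(*mask_pair),
    )
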