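"""Threshold-based extraction of a white blood cell from a blood-film image.

The stained cell is darker than the film background, and the green channel
separates the stain from the background most strongly.  The pipeline is:

1. take the green channel and stretch its histogram (1st..99th percentile
   to the full range);
2. optionally crop to a region of interest;
3. binarize at ``threshold_fraction`` (default 70%) of the bright-area
   intensity I_B, keeping pixels *below* the threshold (the cell);
4. remove small connected components and fill interior holes;
5. smooth the mask boundary with a Gaussian window re-binarized at 50%;
6. trace the edges with the fixed 3x3 Sobel kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "SOBEL_GX",
    "SOBEL_GY",
    "SegmentationConfig",
    "SegmentationResult",
    "SegmentationError",
    "extract_green_enhanced",
    "binarize",
    "clean_mask",
    "smooth_mask",
    "detect_edges",
    "segment_wbc",
]

# The horizontal/vertical gradient kernels used for edge detection.
SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_GY = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


class SegmentationError(RuntimeError):
    """Raised when a stage cannot produce a valid mask; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the thresholding segmentation.

    ``min_component_px`` defaults to 50000, appropriate for full-resolution
    microscope frames; scaled-down fixtures must scale it accordingly.
    ``dark_foreground`` selects which side of the threshold is the cell
    (stained cells are darker than the background).
    ``nucleus_threshold_fraction`` is a second, lower threshold used to
    isolate the nucleus (the darkest stained region) inside the cell mask.
    """

    threshold_fraction: float = 0.70
    bright_percentile: float = 99.0
    min_component_px: int = 50000
    gaussian_window: int = 15
    smooth_threshold: float = 0.50
    dark_foreground: bool = True
    nucleus_threshold_fraction: float = 0.40

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if not 0.0 < self.bright_percentile <= 100.0:
            raise ValueError("bright_percentile must lie in (0, 100]")
        if self.gaussian_window < 3 or self.gaussian_window % 2 == 0:
            raise ValueError("gaussian_window must be an odd integer >= 3")
        if not 0.0 < self.smooth_threshold < 1.0:
            raise ValueError("smooth_threshold must lie in (0, 1)")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be non-negative")

    def rescaled(self, factor: float) -> "SegmentationConfig":
        """Config for an image scaled by ``factor`` (areas scale quadratically)."""
        return replace(self, min_component_px=max(1, int(self.min_component_px * factor**2)))


@dataclass
class SegmentationResult:
    cell_mask: np.ndarray
    edge_map: np.ndarray
    green_enhanced: np.ndarray
    i_b: float
    roi: tuple[int, int, int, int]  # (row, col, height, width) in image coordinates


def extract_green_enhanced(image: np.ndarray) -> np.ndarray:
    """Green channel, contrast-stretched to [0, 1].

    The 1st and 99th intensity percentiles are mapped to 0 and 1 (values
    outside are clipped).  A degenerate histogram (constant image) is passed
    through unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] < 3:
        raise SegmentationError(
            "extract_green_enhanced",
            f"expected an RGB image with 3 channels, got shape {image.shape}",
        )
    green = image[:, :, 1]
    lo, hi = np.percentile(green, [1.0, 99.0])
    # a (near-)degenerate histogram carries no cell/background contrast to
    # stretch; pass through rather than amplify sensor noise to full range
    if hi - lo < 0.05:
        return green.copy()
    return np.clip((green - lo) / (hi - lo), 0.0, 1.0)


def binarize(gray: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> tuple[np.ndarray, float]:
    """Threshold at ``threshold_fraction`` of the bright-area intensity I_B.

    I_B is the ``bright_percentile`` intensity of the image (robust to hot
    pixels).  With ``dark_foreground`` the mask is the set of pixels strictly
    below ``threshold_fraction * I_B``.  Returns ``(mask, i_b)``.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.size == 0:
        raise SegmentationError("binarize", "empty image")
    i_b = float(np.percentile(gray, cfg.bright_percentile))
    if i_b <= 0:
        raise SegmentationError("binarize", "bright-area intensity I_B is zero")
    thr = cfg.threshold_fraction * i_b
    mask = gray < thr if cfg.dark_foreground else gray > thr
    return mask, i_b


def clean_mask(mask: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Drop 8-connected components below ``min_component_px``; fill interior holes."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    kept = np.zeros_like(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep_ids = np.flatnonzero(sizes >= cfg.min_component_px) + 1
        kept = np.isin(labels, keep_ids)
    if not kept.any():
        raise SegmentationError(
            "clean_mask", f"no cell found: no component reaches {cfg.min_component_px} pixels"
        )
    # 8-connected background flood: only fully enclosed holes are filled
    return ndimage.binary_fill_holes(kept, structure=np.ones((3, 3), bool))


def smooth_mask(mask: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Gaussian-smooth the mask and re-binarize at ``smooth_threshold``.

    The kernel side equals ``gaussian_window`` with sigma = window / 6, so
    the Gaussian is effectively supported by the window.  Border handling is
    reflective.
    """
    mask = np.asarray(mask, dtype=float)
    sigma = cfg.gaussian_window / 6.0
    radius = (cfg.gaussian_window - 1) // 2
    blurred = ndimage.gaussian_filter(mask, sigma=sigma, mode="reflect", truncate=radius / sigma)
    return blurred > cfg.smooth_threshold


def detect_edges(mask: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Edge map: pixels with nonzero Sobel gradient magnitude sqrt(Gx^2 + Gy^2)."""
    mask = np.asarray(mask, dtype=float)
    gx = ndimage.convolve(mask, SOBEL_GX, mode="reflect")
    gy = ndimage.convolve(mask, SOBEL_GY, mode="reflect")
    magnitude = np.hypot(gx, gy)
    return magnitude > 1e-12


def segment_wbc(
    image: np.ndarray,
    cfg: SegmentationConfig = SegmentationConfig(),
    roi: tuple[int, int, int, int] | None = None,
) -> SegmentationResult:
    """Full segmentation chain on an RGB blood-film image.

    ``roi`` is ``(row, col, height, width)``; masks are returned in ROI
    coordinates.  If several components survive cleaning, the largest one is
    kept so the result holds a single cell.
    """
    green = extract_green_enhanced(image)
    if roi is None:
        r0, c0, rh, rw = 0, 0, green.shape[0], green.shape[1]
    else:
        r0, c0, rh, rw = roi
        if r0 < 0 or c0 < 0 or rh <= 0 or rw <= 0 or r0 + rh > green.shape[0] or c0 + rw > green.shape[1]:
            raise SegmentationError("crop", f"roi {roi} outside image of shape {green.shape}")
    green_roi = green[r0 : r0 + rh, c0 : c0 + rw]

    raw, i_b = binarize(green_roi, cfg)
    cleaned = clean_mask(raw, cfg)
    labels, n = ndimage.label(cleaned, structure=np.ones((3, 3), int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        cleaned = labels == (1 + int(np.argmax(sizes)))
    smoothed = smooth_mask(cleaned, cfg)
    if not smoothed.any():
        raise SegmentationError("smooth_mask", "mask vanished during smoothing")
    edges = detect_edges(smoothed, cfg)
    return SegmentationResult(
        cell_mask=smoothed,
        edge_map=edges,
        green_enhanced=green_roi,
        i_b=i_b,
        roi=(r0, c0, rh, rw),
    )
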