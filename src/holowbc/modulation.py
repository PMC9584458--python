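"""Hologram modulation: phase ramps, defocus chirps, and multi-plane display.

A single 2D phase hologram can carry several structural components of a
cell (whole body, edges plus nucleus, nucleus alone), each sent to its own
focal plane and lateral position.  Component m is modulated by

    ramp   R_m    = exp(i k [sin(alpha_m) nu_i + sin(beta_m) nu_j])
    chirp  chi_m  = exp(i pi lambda z_m |f|^2),   f = nu / (lambda F)

where nu is the SLM-plane coordinate (meters), F the Fourier-lens focal
length, and f the reconstruction-field spatial frequency that the SLM
coordinate addresses in a Fourier-lens geometry.  The ramp is a tilt that
laterally shifts the reconstruction (Fourier shift theorem); the chirp is
the standard Fresnel defocus transfer, so z = 0 is the in-focus identity
and chirps compose additively in z.  The modulated unit-modulus fields are
summed and the argument of the sum is the single displayed hologram.

Reconstructing with the conjugate chirp of a scanned distance z brings the
components whose z_m equals z into focus while defocusing the rest — the
selective-focus display used to tell structures (or a normal and a cancer
cell) apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cgh import PhaseHologram
from .optics import OpticalConfig, fft2c

__all__ = [
    "ModulationComponent",
    "FocalStack",
    "phase_ramp",
    "chirp",
    "combine",
    "reconstruct_at",
    "focus_score",
    "focal_stack",
    "predicted_shift_px",
    "annotate_target",
]


def phase_ramp(
    cfg: OpticalConfig, alpha: float, beta: float, shape: tuple[int, int]
) -> np.ndarray:
    """Unit-modulus tilt field exp(i k [sin(alpha) nu_i + sin(beta) nu_j]).

    alpha tilts along the row coordinate nu_i, beta along the column
    coordinate nu_j.
    """
    nu_i, nu_j = cfg.slm_coords(shape)
    k = 2.0 * np.pi / cfg.wavelength_m
    return np.exp(1j * k * (np.sin(alpha) * nu_i + np.sin(beta) * nu_j))


def chirp(cfg: OpticalConfig, z: float, shape: tuple[int, int]) -> np.ndarray:
    """Quadratic defocus phase exp(i pi lambda z |f|^2) with f = nu/(lambda F).

    z = 0 gives the all-ones identity field; chirp(z1) * chirp(z2) equals
    chirp(z1 + z2) pointwise.
    """
    nu_i, nu_j = cfg.slm_coords(shape)
    lam, foc = cfg.wavelength_m, cfg.focal_length_m
    f_sq = (nu_i**2 + nu_j**2) / (lam * foc) ** 2
    return np.exp(1j * np.pi * lam * z * f_sq)


def predicted_shift_px(cfg: OpticalConfig, sin_angle: float, n: int) -> float:
    """Reconstruction-pixel shift produced by a ramp of given sin(angle).

    Follows from the discrete Fourier shift theorem: a tilt advancing by
    sin(angle) * pitch / lambda cycles per SLM pixel moves the
    reconstruction by sin(angle) * n * pitch / lambda pixels along that
    axis (positive toward increasing index).
    """
    return sin_angle * n * cfg.slm_pitch_m / cfg.wavelength_m


@dataclass
class ModulationComponent:
    """One structure component: its hologram, focal offset and lateral shift.

    ``shift_u`` = (du_i, du_j) is the lateral separation at the component's
    reconstruction plane, in meters; the tilt angles follow the projection
    geometry sin(alpha) = du_i / z_m (an in-focus component, z_m = 0,
    cannot be shifted).
    """

    hologram: PhaseHologram
    z_m: float = 0.0
    shift_u: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        du_i, du_j = self.shift_u
        if self.z_m == 0.0:
            if du_i != 0.0 or du_j != 0.0:
                raise ValueError("a component at z_m = 0 must have zero lateral shift")
        else:
            if abs(du_i / self.z_m) > 1.0 or abs(du_j / self.z_m) > 1.0:
                raise ValueError("|shift / z_m| must not exceed 1 (sin of a real angle)")

    @property
    def sin_alpha(self) -> float:
        return 0.0 if self.z_m == 0.0 else self.shift_u[0] / self.z_m

    @property
    def sin_beta(self) -> float:
        return 0.0 if self.z_m == 0.0 else self.shift_u[1] / self.z_m

    def modulated_field(self, cfg: OpticalConfig) -> np.ndarray:
        shape = self.hologram.shape
        field = self.hologram.field()
        if self.sin_alpha != 0.0 or self.sin_beta != 0.0:
            field = field * phase_ramp(
                cfg, np.arcsin(self.sin_alpha), np.arcsin(self.sin_beta), shape
            )
        if self.z_m != 0.0:
            field = field * chirp(cfg, self.z_m, shape)
        return field


def combine(components: list[ModulationComponent], cfg: OpticalConfig) -> PhaseHologram:
    """Single hologram phi_all = arg(sum_m exp(i phi_m) R_m chi_m).

    Pixels where the sum is exactly zero get phase 0 (documented tie-break).
    """
    if not components:
        raise ValueError("need at least one component")
    shape = components[0].hologram.shape
    for c in components:
        if c.hologram.shape != shape:
            raise ValueError("all component holograms must share a shape")
    total = np.zeros(shape, dtype=complex)
    for c in components:
        total += c.modulated_field(cfg)
    return PhaseHologram(phase_of_sum(total))


def phase_of_sum(total: np.ndarray) -> np.ndarray:
    """Argument of a complex sum; exactly-zero pixels get phase 0 (tie-break)."""
    phase = np.angle(total)
    phase[total == 0] = 0.0
    return phase


def reconstruct_at(
    hologram: PhaseHologram,
    z: float,
    cfg: OpticalConfig,
    oversample: int = 1,
) -> np.ndarray:
    """Intensity |F(exp(i phi_all) chirp(-z))|^2 at scan distance z.

    Multiplying by the conjugate chirp cancels the defocus of every
    component whose z_m equals z, bringing it into focus.
    """
    field = hologram.field() * chirp(cfg, -z, hologram.shape)
    if oversample == 1:
        rec = fft2c(field)
        return rec.real**2 + rec.imag**2
    # embed the modulated field, not the bare phase, when oversampling
    h, w = hologram.shape
    frame = np.zeros((oversample * h, oversample * w), dtype=complex)
    frame[(oversample - 1) * h // 2 : (oversample - 1) * h // 2 + h,
          (oversample - 1) * w // 2 : (oversample - 1) * w // 2 + w] = field
    rec = fft2c(frame)
    return rec.real**2 + rec.imag**2


def focus_score(intensity: np.ndarray, roi: np.ndarray, smooth_sigma: float = 2.5) -> float:
    """Sharpness of an ROI: variance of the Sobel gradient magnitude.

    The intensity is Gaussian-smoothed first (default sigma 2.5 px) to
    suppress residual speckle, whose gradients would otherwise dominate the
    score at every plane; the score is normalized by the squared mean ROI
    intensity so it compares across planes of different brightness.
    """
    roi = np.asarray(roi, dtype=bool)
    smoothed = ndimage.gaussian_filter(np.asarray(intensity, dtype=float), smooth_sigma)
    grad = np.hypot(ndimage.sobel(smoothed, axis=1), ndimage.sobel(smoothed, axis=0))
    mean = smoothed[roi].mean()
    if mean == 0:
        return 0.0
    return float(grad[roi].var() / (mean * mean))


@dataclass
class FocalStack:
    distances: np.ndarray  # scanned z values (m)
    planes: list[np.ndarray]  # intensity per plane
    focus_scores: np.ndarray | None = None  # (n_planes, n_rois)


def focal_stack(
    hologram: PhaseHologram,
    distances: np.ndarray,
    cfg: OpticalConfig,
    rois: list[np.ndarray] | None = None,
    smooth_sigma: float = 2.5,
) -> FocalStack:
    """Reconstruct a z-scan and (optionally) score sharpness per ROI."""
    distances = np.asarray(distances, dtype=float)
    planes = [reconstruct_at(hologram, z, cfg) for z in distances]
    scores = None
    if rois is not None:
        scores = np.array(
            [[focus_score(p, roi, smooth_sigma) for roi in rois] for p in planes]
        )
    return FocalStack(distances=distances, planes=planes, focus_scores=scores)


def annotate_target(
    amplitude: np.ndarray,
    text_labels: list[tuple[str, tuple[int, int]]],
    scale: int = 1,
) -> np.ndarray:
    """Burn text labels into an amplitude image before hologram synthesis.

    Each label is ``(text, (row, col))`` with (row, col) the top-left corner
    of the rendered text.  Labeled pixels are set to the maximum amplitude,
    so the text appears bright in the reconstruction (e.g. "N"/"C" tags for
    normal/cancer cells, or the measured cell and nucleus areas).
    """
    from PIL import Image, ImageDraw

    out = np.array(amplitude, dtype=float, copy=True)
    if not text_labels:
        return out
    if scale < 1 or int(scale) != scale:
        raise ValueError("scale must be a positive integer")
    h, w = out.shape
    peak = out.max() if out.max() > 0 else 1.0
    for text, (row, col) in text_labels:
        canvas = Image.new("L", (w, h), 0)
        draw = ImageDraw.Draw(canvas)
        x0, y0, x1, y1 = draw.textbbox((0, 0), text)
        tw, th = (x1 - x0), (y1 - y0)
        if tw <= 0 or th <= 0:
            continue
        small = Image.new("L", (tw + 2, th + 2), 0)
        ImageDraw.Draw(small).text((-x0 + 1, -y0 + 1), text, fill=255)
        stencil = np.asarray(small) > 127
        if scale > 1:
            stencil = np.kron(stencil, np.ones((scale, scale), dtype=bool))
        sh, sw = stencil.shape
        if row < 0 or col < 0 or row + sh > h or col + sw > w:
            raise ValueError(f"label {text!r} does not fit at {(row, col)} in frame {(h, w)}")
        out[row : row + sh, col : col + sw][stencil] = peak
    return out
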