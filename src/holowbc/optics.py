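"""Optical constants and the centered unitary Fourier transforms.

The numerical model is a Fourier-lens geometry: a phase-only spatial light
modulator (SLM) sits in the front focal plane of a lens and the
reconstruction appears in the back focal plane, so SLM-to-image propagation
is a (scaled) two-dimensional Fourier transform.  All transforms in the
package are unitary ("ortho" normalization) with the zero frequency at the
grid center, which makes Parseval's theorem hold exactly and keeps hologram
files portable across conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as _fft

__all__ = [
    "OpticalConfig",
    "fft2c",
    "ifft2c",
    "DEFAULT_OPTICS",
]


def fft2c(field: np.ndarray) -> np.ndarray:
    """Centered unitary 2D Fourier transform (forward propagation)."""
    return _fft.fftshift(_fft.fft2(_fft.ifftshift(field), norm="ortho"))


def ifft2c(field: np.ndarray) -> np.ndarray:
    """Centered unitary 2D inverse Fourier transform (backward propagation)."""
    return _fft.fftshift(_fft.ifft2(_fft.ifftshift(field), norm="ortho"))


@dataclass(frozen=True)
class OpticalConfig:
    """Physical constants of the holographic projection bench.

    Parameters
    ----------
    wavelength_m:
        Illumination wavelength in meters.  Default 670 nm (red laser diode).
    slm_shape:
        (rows, cols) of the phase-only SLM.  Default 1080 x 1920.
    slm_pitch_m:
        SLM pixel pitch in meters.  Default 8 um.
    focal_length_m:
        Focal length of the Fourier lens in meters.  Default 125 mm.
    ccd_shape, ccd_pitch_m:
        Observation camera geometry; kept for reference and for choosing
        observation-plane oversampling.
    """

    wavelength_m: float = 670e-9
    slm_shape: tuple[int, int] = (1080, 1920)
    slm_pitch_m: float = 8e-6
    focal_length_m: float = 0.125
    ccd_shape: tuple[int, int] = (2054, 2452)
    ccd_pitch_m: float = 3.35e-6

    def __post_init__(self) -> None:
        for name in ("wavelength_m", "slm_pitch_m", "focal_length_m", "ccd_pitch_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("slm_shape", "ccd_shape"):
            shape = tuple(getattr(self, name))
            if len(shape) != 2 or any(int(s) <= 0 or int(s) != s for s in shape):
                raise ValueError(f"{name} must be two positive integers, got {shape}")
            object.__setattr__(self, name, (int(shape[0]), int(shape[1])))

    def slm_coords(self, shape: tuple[int, int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """SLM-plane coordinate grids (nu_i, nu_j) in meters.

        nu = (pixel index - center) * pitch, with the center at the same
        pixel the centered FFT uses (index N // 2).
        """
        h, w = shape if shape is not None else self.slm_shape
        nu_i = (np.arange(h) - h // 2) * self.slm_pitch_m
        nu_j = (np.arange(w) - w // 2) * self.slm_pitch_m
        return np.meshgrid(nu_i, nu_j, indexing="ij")

    def reconstruction_pitch_m(self, n: int) -> float:
        """Sample pitch lambda*f/(n*slm_pitch) of the reconstruction plane."""
        return self.wavelength_m * self.focal_length_m / (n * self.slm_pitch_m)

    def scaled(self, factor: float) -> "OpticalConfig":
        """A copy with the SLM pixel count scaled by ``factor`` (desk-scale runs)."""
        h, w = self.slm_shape
        return replace(self, slm_shape=(max(1, round(h * factor)), max(1, round(w * factor))))


DEFAULT_OPTICS = OpticalConfig()
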