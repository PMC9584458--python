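"""Phase-only computer-generated holograms by the iterative Fourier
transform algorithm (IFTA, Gerchberg-Saxton family).

Two planes are connected by a centered unitary Fourier transform: the SLM
plane (where the hologram phase lives, illuminated by a unit plane wave)
and the object/reconstruction plane.  Each iteration enforces the amplitude
constraint of both planes while keeping the propagated phase:

    object plane:  amplitude := target amplitude (sqrt of the intensity)
    SLM plane:     amplitude := 1

The run stops when the RMS wrapped change of the SLM phase between
consecutive iterations falls below ``epsilon_rad``, when the intensity
error (mean of squared intensity differences against the reference, after
least-squares intensity scaling) reaches ``error_floor``, or at
``max_iterations``.  The intensity-error trace is non-increasing — the
classic error-reduction property of alternating projections — and the
tests assert it to machine precision.

The converged phase is wrapped to [0, 2pi) and can be quantized to 8 bits
(0..255) for upload to the SLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import fft2c, ifft2c
from .metrics import eq1_error, least_squares_scale

__all__ = [
    "IFTAConfig",
    "PhaseHologram",
    "IFTAResult",
    "run_ifta",
    "quantize_phase",
    "dequantize_phase",
    "reconstruct_intensity",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class IFTAConfig:
    """Iteration controls.

    ``epsilon_rad`` is the phase-convergence bound (RMS wrapped phase change
    between consecutive SLM iterates, radians); ``error_floor`` is the
    intensity-error value at which the run may stop early.  Either criterion
    can be disabled by setting it to 0.  ``seed`` drives the uniform random
    initial object phase.
    """

    max_iterations: int = 200
    epsilon_rad: float = 0.2
    error_floor: float = 5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.epsilon_rad < 0 or self.error_floor < 0:
            raise ValueError("epsilon_rad and error_floor must be non-negative")


@dataclass
class PhaseHologram:
    """A 2D phase map in radians, wrapped to [0, 2pi)."""

    phase_rad: np.ndarray

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase_rad, dtype=float)
        if phase.ndim != 2:
            raise ValueError(f"phase map must be 2D, got shape {phase.shape}")
        self.phase_rad = np.mod(phase, _TWO_PI)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase_rad.shape

    @property
    def quantized_u8(self) -> np.ndarray:
        return quantize_phase(self.phase_rad)

    @classmethod
    def from_u8(cls, u8: np.ndarray) -> "PhaseHologram":
        return cls(dequantize_phase(u8))

    def field(self) -> np.ndarray:
        """The unit-modulus SLM field exp(i*phase)."""
        return np.exp(1j * self.phase_rad)


def quantize_phase(phase_rad: np.ndarray) -> np.ndarray:
    """Linear map of wrapped phase [0, 2pi) onto 8-bit levels {0..255}.

    Rounds half up, so phase pi maps to level 128.
    """
    wrapped = np.mod(np.asarray(phase_rad, dtype=float), _TWO_PI)
    return np.floor(wrapped * 255.0 / _TWO_PI + 0.5).astype(np.uint8)


def dequantize_phase(u8: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quantize_phase`; exact on the 256 levels."""
    return np.asarray(u8, dtype=float) * _TWO_PI / 255.0


@dataclass
class IFTAResult:
    hologram: PhaseHologram
    error_trace: np.ndarray  # intensity error per iteration
    phase_delta_trace: np.ndarray  # RMS wrapped phase change, from iteration 2 on
    iterations_run: int
    reconstruction: np.ndarray  # least-squares-scaled intensity |F(exp(i*phi))|^2
    stop_reason: str = "max_iterations"


def _rms_wrapped_delta(phi_new: np.ndarray, phi_old: np.ndarray) -> float:
    delta = phi_new - phi_old
    delta = np.mod(delta + np.pi, _TWO_PI) - np.pi  # wrap to (-pi, pi]
    return float(np.sqrt(np.mean(delta * delta)))


def run_ifta(target_amplitude: np.ndarray, cfg: IFTAConfig = IFTAConfig()) -> IFTAResult:
    """Compute a phase-only hologram whose reconstruction matches the target.

    Parameters
    ----------
    target_amplitude:
        Non-negative 2D amplitude image.  It is normalized so its maximum
        is 1; an all-zero target is rejected.  A float32 input runs the
        whole iteration in single precision (halves memory and time for
        SLM-scale frames).

    Returns
    -------
    IFTAResult with the wrapped hologram phase, the per-iteration intensity
    error and phase-change traces, and the numerically reconstructed
    intensity scaled to the reference by the least-squares factor.
    """
    target = np.asarray(target_amplitude)
    if target.ndim != 2:
        raise ValueError(f"target must be 2D, got shape {target.shape}")
    if np.any(target < 0):
        raise ValueError("target amplitude must be non-negative")
    peak = float(target.max())
    if peak == 0:
        raise ValueError("all-zero target amplitude")

    single = target.dtype == np.float32
    real_t = np.float32 if single else np.float64
    cplx_t = np.complex64 if single else np.complex128

    amp = (target / peak).astype(real_t)
    i_ref = amp * amp

    rng = np.random.default_rng(cfg.seed)
    phi0 = rng.uniform(0.0, _TWO_PI, size=amp.shape)
    obj = (amp * np.exp(1j * phi0)).astype(cplx_t)

    errors: list[float] = []
    deltas: list[float] = []
    phi_prev: np.ndarray | None = None
    phi_slm = np.zeros_like(amp)
    recon = i_ref
    stop = "max_iterations"

    for n in range(1, cfg.max_iterations + 1):
        slm = ifft2c(obj)
        phi_slm = np.angle(slm)

        if phi_prev is not None:
            deltas.append(_rms_wrapped_delta(phi_slm, phi_prev))
        phi_prev = phi_slm

        rec = fft2c(np.exp(1j * phi_slm).astype(cplx_t))
        i_rec = (rec.real * rec.real + rec.imag * rec.imag).astype(real_t)
        scale = least_squares_scale(i_ref, i_rec)
        recon = scale * i_rec
        errors.append(eq1_error(i_ref, recon))

        if deltas and cfg.epsilon_rad > 0 and deltas[-1] < cfg.epsilon_rad:
            stop = "phase_converged"
            break
        if cfg.error_floor > 0 and errors[-1] <= cfg.error_floor:
            stop = "error_floor"
            break

        obj = (amp * np.exp(1j * np.angle(rec))).astype(cplx_t)

    return IFTAResult(
        hologram=PhaseHologram(np.mod(phi_slm.astype(float), _TWO_PI)),
        error_trace=np.asarray(errors),
        phase_delta_trace=np.asarray(deltas),
        iterations_run=len(errors),
        reconstruction=recon,
        stop_reason=stop,
    )


def reconstruct_intensity(hologram: PhaseHologram | np.ndarray, oversample: int = 1) -> np.ndarray:
    """Numerically reconstructed intensity |F(exp(i*phi))|^2.

    ``oversample`` embeds the unit-modulus SLM field centered in a frame
    ``oversample`` times larger before transforming, sampling the
    observation plane on a correspondingly finer grid — the numerical
    analogue of a camera that resolves the speckle between the hologram's
    design samples.
    """
    phase = hologram.phase_rad if isinstance(hologram, PhaseHologram) else np.asarray(hologram)
    if oversample < 1 or int(oversample) != oversample:
        raise ValueError("oversample must be a positive integer")
    field_slm = np.exp(1j * phase)
    if oversample > 1:
        h, w = phase.shape
        frame = np.zeros((oversample * h, oversample * w), dtype=field_slm.dtype)
        y0 = (frame.shape[0] - h) // 2
        x0 = (frame.shape[1] - w) // 2
        frame[y0 : y0 + h, x0 : x0 + w] = field_slm
        field_slm = frame
    rec = fft2c(field_slm)
    return rec.real * rec.real + rec.imag * rec.imag
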