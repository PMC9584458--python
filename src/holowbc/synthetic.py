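"""Synthetic stained-blood-film scenes with exact ground truth.

Generates microscope-like images of white blood cells (WBCs) on a bright
background, emulating the appearance of a Romanowsky-stained peripheral
blood film: dark purple nucleus, pink cytoplasm, near-white background,
optional cytoplasmic granules.  Every rendered cell carries an exact
rasterized ground-truth mask, so segmentation, morphometry and the
holographic pipeline are all testable without microscope data.

The five normal WBC kinds are distinguished by nucleus geometry:
basophils and eosinophils carry a two-lobed nucleus, neutrophils a
four-lobed one, monocytes a kidney-shaped nucleus, and lymphocytes a round
nucleus that becomes an enlarged, irregular oval in the cancer phenotype.

The color palette is chosen so that the *green* channel separates nucleus
from background more strongly than red or blue, which is the property the
segmentation stage relies on.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "CellKind",
    "NucleusShape",
    "Palette",
    "CellSpec",
    "SyntheticScene",
    "render_scene",
    "render_amplitude_target",
    "save_scene",
    "CANCER_MAJOR_SCALE",
    "CANCER_MINOR_SCALE",
]

# Default axis scaling of a cancer lymphocyte relative to a normal one,
# matching the reported mean enlargement of the major/minor axes.
CANCER_MAJOR_SCALE = 1.42
CANCER_MINOR_SCALE = 1.33


class CellKind(str, enum.Enum):
    BASOPHIL = "basophil"
    EOSINOPHIL = "eosinophil"
    LYMPHOCYTE = "lymphocyte"
    MONOCYTE = "monocyte"
    NEUTROPHIL = "neutrophil"


class NucleusShape(str, enum.Enum):
    ROUND = "round"
    BILOBED = "bilobed"
    MULTILOBED = "multilobed"
    KIDNEY = "kidney"
    IRREGULAR_OVAL = "irregular-oval"


# kind -> (nucleus shape, lobe count) for the normal phenotype
_KIND_NUCLEUS: dict[CellKind, tuple[NucleusShape, int]] = {
    CellKind.BASOPHIL: (NucleusShape.BILOBED, 2),
    CellKind.EOSINOPHIL: (NucleusShape.BILOBED, 2),
    CellKind.NEUTROPHIL: (NucleusShape.MULTILOBED, 4),
    CellKind.MONOCYTE: (NucleusShape.KIDNEY, 1),
    CellKind.LYMPHOCYTE: (NucleusShape.ROUND, 1),
}

# Typical full axis lengths (major, minor) in pixels at 0.1 um/px,
# consistent with the measured normal-cell axes.
_KIND_AXES_PX: dict[CellKind, tuple[float, float]] = {
    CellKind.BASOPHIL: (102.0, 96.0),
    CellKind.EOSINOPHIL: (128.0, 117.0),
    CellKind.LYMPHOCYTE: (69.0, 65.0),
    CellKind.MONOCYTE: (120.0, 97.0),
    CellKind.NEUTROPHIL: (163.0, 112.0),
}

# granulocytes get granules by default
_KIND_GRANULARITY: dict[CellKind, float] = {
    CellKind.BASOPHIL: 0.5,
    CellKind.EOSINOPHIL: 0.6,
    CellKind.NEUTROPHIL: 0.3,
    CellKind.MONOCYTE: 0.0,
    CellKind.LYMPHOCYTE: 0.0,
}


@dataclass(frozen=True)
class Palette:
    """RGB colors (floats in [0, 1]) of the rendered stain.

    The nucleus green value is deliberately the lowest of all green values
    so the green channel carries the strongest nucleus/background contrast.
    """

    background: tuple[float, float, float] = (0.95, 0.93, 0.90)
    cytoplasm: tuple[float, float, float] = (0.95, 0.65, 0.75)
    nucleus: tuple[float, float, float] = (0.45, 0.20, 0.55)
    granule_amplitude: float = 0.15


@dataclass(frozen=True)
class CellSpec:
    """Geometry and phenotype of one rendered WBC.

    ``cell_axes`` are full (major, minor) axis lengths in pixels; the
    rendered cell is the ellipse with semi-axes ``cell_axes / 2`` rotated by
    ``rotation`` radians about ``center`` (row, col).
    """

    kind: CellKind
    center: tuple[float, float]
    cell_axes: tuple[float, float]
    nucleus_shape: NucleusShape
    nucleus_lobes: int = 1
    cancer: bool = False
    granularity: float = 0.0
    rotation: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CellKind(self.kind))
        object.__setattr__(self, "nucleus_shape", NucleusShape(self.nucleus_shape))
        major, minor = self.cell_axes
        if not (major >= minor > 0):
            raise ValueError(f"cell_axes must satisfy major >= minor > 0, got {self.cell_axes}")
        if not 0.0 <= self.granularity <= 1.0:
            raise ValueError("granularity must lie in [0, 1]")
        expected_shape, expected_lobes = _KIND_NUCLEUS[self.kind]
        if self.kind is CellKind.LYMPHOCYTE:
            expected_shape = NucleusShape.IRREGULAR_OVAL if self.cancer else NucleusShape.ROUND
        if self.nucleus_shape is not expected_shape:
            raise ValueError(
                f"{self.kind.value} ({'cancer' if self.cancer else 'normal'}) requires a "
                f"{expected_shape.value} nucleus, got {self.nucleus_shape.value}"
            )
        if self.nucleus_lobes != expected_lobes:
            raise ValueError(
                f"{self.kind.value} requires {expected_lobes} nucleus lobe(s), got {self.nucleus_lobes}"
            )

    @classmethod
    def for_kind(
        cls,
        kind: CellKind | str,
        center: tuple[float, float],
        *,
        cancer: bool = False,
        scale: float = 1.0,
        rotation: float = 0.0,
        granularity: float | None = None,
    ) -> "CellSpec":
        """A kind-consistent spec with typical axes (optionally scaled)."""
        kind = CellKind(kind)
        major, minor = _KIND_AXES_PX[kind]
        shape, lobes = _KIND_NUCLEUS[kind]
        if cancer:
            if kind is not CellKind.LYMPHOCYTE:
                raise ValueError("the cancer phenotype is modeled for lymphocytes only")
            major *= CANCER_MAJOR_SCALE
            minor *= CANCER_MINOR_SCALE
            shape = NucleusShape.IRREGULAR_OVAL
        if granularity is None:
            granularity = _KIND_GRANULARITY[kind]
        return cls(
            kind=kind,
            center=center,
            cell_axes=(major * scale, minor * scale),
            nucleus_shape=shape,
            nucleus_lobes=lobes,
            cancer=cancer,
            granularity=granularity,
            rotation=rotation,
        )


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    cell_masks: list[np.ndarray]
    nucleus_masks: list[np.ndarray]
    specs: list[CellSpec]
    noise_sigma: float
    seed: int
    um_per_px: float = 0.1  # declared calibration of the synthetic microscope


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    rotation: float,
    radial_perturbation=None,
) -> np.ndarray:
    """Rasterize a (possibly radially perturbed) rotated ellipse.

    ``radial_perturbation(theta)`` multiplies the boundary radius at polar
    angle ``theta`` measured in the ellipse frame.
    """
    h, w = shape
    cy, cx = center
    a, b = semi_axes  # a along the major (rotated-x) direction
    yy, xx = np.mgrid[:h, :w]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(rotation), np.sin(rotation)
    u = c * dx + s * dy  # along major axis
    v = -s * dx + c * dy
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if radial_perturbation is None:
        return rho <= 1.0
    theta = np.arctan2(v / b, u / a)
    return rho <= radial_perturbation(theta)


def _nucleus_masks(spec: CellSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Rasterize the nucleus of one cell as a union of lobes."""
    a, b = spec.cell_axes[0] / 2.0, spec.cell_axes[1] / 2.0
    cy, cx = spec.center
    rot = spec.rotation
    c, s = np.cos(rot), np.sin(rot)

    def offset(du: float, dv: float) -> tuple[float, float]:
        # (du, dv) in the ellipse frame -> (row, col) in the image
        return (cy + s * du + c * dv, cx + c * du - s * dv)

    ns = spec.nucleus_shape
    if ns is NucleusShape.ROUND:
        # lymphocyte: nucleus nearly fills the cell
        return _ellipse_mask(shape, (cy, cx), (0.94 * a, 0.94 * b), rot)
    if ns is NucleusShape.BILOBED:
        lobes = [
            _ellipse_mask(shape, offset(sign * 0.38 * a, 0.0), (0.34 * a, 0.44 * b), rot)
            for sign in (-1.0, 1.0)
        ]
        return np.logical_or.reduce(lobes)
    if ns is NucleusShape.MULTILOBED:
        lobes = []
        for ang in (0.25, 0.75, 1.25, 1.75):
            du = 0.42 * a * np.cos(np.pi * ang)
            dv = 0.42 * b * np.sin(np.pi * ang)
            lobes.append(_ellipse_mask(shape, offset(du, dv), (0.30 * a, 0.30 * b), rot))
        return np.logical_or.reduce(lobes)
    if ns is NucleusShape.KIDNEY:
        body = _ellipse_mask(shape, (cy, cx), (0.66 * a, 0.66 * b), rot)
        bite = _ellipse_mask(shape, offset(0.45 * a, 0.0), (0.42 * a, 0.50 * b), rot)
        return body & ~bite
    if ns is NucleusShape.IRREGULAR_OVAL:
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)

        def perturb(theta):
            return 0.80 * (1.0 + 0.12 * np.sin(3 * theta + p1) + 0.08 * np.sin(5 * theta + p2))

        return _ellipse_mask(shape, (cy, cx), (0.92 * a, 0.88 * b), rot, radial_perturbation=perturb)
    raise ValueError(f"unknown nucleus shape {ns}")  # pragma: no cover


def render_scene(
    specs: list[CellSpec],
    size: tuple[int, int] = (512, 512),
    noise_sigma: float = 0.01,
    seed: int = 0,
    palette: Palette = Palette(),
    um_per_px: float = 0.1,
) -> SyntheticScene:
    """Render a stained-blood-film scene with exact ground-truth masks.

    Cells must fit fully inside the frame and must not overlap one another
    (overlap would make the per-cell ground truth ambiguous); violations
    raise ``ValueError``.  Identical ``specs`` and ``seed`` produce a
    bit-identical scene.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError(f"scene must be at least 64x64, got {size}")
    rng = np.random.default_rng(seed)

    image = np.empty((h, w, 3), dtype=float)
    image[:] = np.asarray(palette.background)

    cell_masks: list[np.ndarray] = []
    nucleus_masks: list[np.ndarray] = []
    occupied = np.zeros((h, w), dtype=bool)

    for i, spec in enumerate(specs):
        cell = _ellipse_mask((h, w), spec.center, (spec.cell_axes[0] / 2, spec.cell_axes[1] / 2), spec.rotation)
        if not cell.any():
            raise ValueError(f"cell {i} rasterizes to an empty mask")
        # reject cells touching the frame border (the analytic ellipse must fit)
        if cell[0, :].any() or cell[-1, :].any() or cell[:, 0].any() or cell[:, -1].any():
            raise ValueError(f"cell {i} extends outside the frame")
        cy, cx = spec.center
        half = max(spec.cell_axes) / 2
        if not (half <= cy <= h - 1 - half and half <= cx <= w - 1 - half):
            raise ValueError(f"cell {i} extends outside the frame")
        if (cell & occupied).any():
            raise ValueError(f"cell {i} overlaps a previously placed cell")
        occupied |= cell

        nucleus = _nucleus_masks(spec, (h, w), rng) & cell
        if not nucleus.any():
            raise ValueError(f"cell {i} has an empty nucleus")

        cytoplasm = cell & ~nucleus
        image[cytoplasm] = np.asarray(palette.cytoplasm)
        image[nucleus] = np.asarray(palette.nucleus)

        if spec.granularity > 0 and cytoplasm.any():
            # granules: small speckles sprinkled over the cytoplasm
            n_gran = int(spec.granularity * cytoplasm.sum() / 40)
            idx = np.flatnonzero(cytoplasm)
            picks = rng.choice(idx, size=min(n_gran, idx.size), replace=False)
            signs = rng.choice([-1.0, 1.0], size=picks.size)
            gy, gx = np.unravel_index(picks, (h, w))
            for yy0, xx0, sg in zip(gy, gx, signs):
                y0, y1 = max(0, yy0 - 1), min(h, yy0 + 2)
                x0, x1 = max(0, xx0 - 1), min(w, xx0 + 2)
                patch = cytoplasm[y0:y1, x0:x1]
                image[y0:y1, x0:x1][patch] += sg * palette.granule_amplitude

        cell_masks.append(cell)
        nucleus_masks.append(nucleus)

    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return SyntheticScene(
        image=image,
        cell_masks=cell_masks,
        nucleus_masks=nucleus_masks,
        specs=list(specs),
        noise_sigma=noise_sigma,
        seed=seed,
        um_per_px=um_per_px,
    )


def render_amplitude_target(
    image: np.ndarray,
    pad_factor: int = 4,
    slm_shape: tuple[int, int] = (1080, 1920),
) -> np.ndarray:
    """Center an amplitude image in a zero frame of ``pad_factor`` x SLM size.

    Zero padding the hologram's design frame is the first step of the
    speckle-reduction chain: the padded frame is later synthesized as one
    large hologram and split into SLM-sized tiles.  The input is normalized
    to [0, 1] by its maximum (an all-zero input stays zero); zero padding
    adds no energy.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"amplitude target must be 2D, got shape {arr.shape}")
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError("pad_factor must be a positive integer")
    out_h, out_w = int(pad_factor) * slm_shape[0], int(pad_factor) * slm_shape[1]
    h, w = arr.shape
    if h > out_h or w > out_w:
        raise ValueError(f"input {arr.shape} larger than padded frame {(out_h, out_w)}")
    peak = arr.max()
    if peak > 0:
        arr = arr / peak
    out = np.zeros((out_h, out_w), dtype=float)
    y0, x0 = (out_h - h) // 2, (out_w - w) // 2
    out[y0 : y0 + h, x0 : x0 + w] = arr
    return out


def save_scene(scene: SyntheticScene, out_prefix: str | Path) -> dict:
    """Write scene image, masks (0/255 PNG) and a JSON sidecar; return the manifest."""
    import imageio.v3 as iio

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    files = {}
    img_path = out_prefix.with_suffix(".png")
    iio.imwrite(img_path, (scene.image * 255).round().astype(np.uint8))
    files["image"] = str(img_path)
    for i, (cm, nm) in enumerate(zip(scene.cell_masks, scene.nucleus_masks)):
        for tag, m in (("cell", cm), ("nucleus", nm)):
            p = out_prefix.parent / f"{out_prefix.name}_{tag}{i}.png"
            iio.imwrite(p, (m.astype(np.uint8) * 255))
            files[f"{tag}_mask_{i}"] = str(p)
    sidecar = {
        "seed": scene.seed,
        "noise_sigma": scene.noise_sigma,
        "um_per_px": scene.um_per_px,
        "specs": [
            {**asdict(s), "kind": s.kind.value, "nucleus_shape": s.nucleus_shape.value}
            for s in scene.specs
        ],
        "files": files,
    }
    sidecar_path = out_prefix.parent / f"{out_prefix.name}_scene.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    files["sidecar"] = str(sidecar_path)
    return files
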