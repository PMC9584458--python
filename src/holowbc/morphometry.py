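"""Cell morphometry: axis lengths, areas, and normal-vs-cancer comparisons.

Axis lengths follow the standard region-properties convention: the major
and minor axes of the ellipse having the same normalized second central
moments as the mask.  Areas are pixel counts scaled by the square of the
micrometer-per-pixel calibration.  Percent increases are reported to two
decimals, matching the precision of the reference measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "MorphometryRecord",
    "GroupComparison",
    "measure_cell",
    "percent_increase",
    "compare_groups",
    "records_to_frame",
    "WBC_REFERENCE_MEASUREMENTS",
]

# Reference morphometry of segmented WBCs (normal cells, and three
# lymphocytes from a cancer blood film), used by the worked examples:
# label -> (major axis um, minor axis um, nucleus area um2, cell area um2)
WBC_REFERENCE_MEASUREMENTS: dict[str, tuple[float, float, float, float]] = {
    "basophil": (10.22, 9.57, 29.01, 76.60),
    "eosinophil": (12.76, 11.74, 31.72, 117.48),
    "lymphocyte": (6.94, 6.48, 35.19, 35.19),
    "monocyte": (12.00, 9.66, 84.39, 89.18),
    "neutrophil": (16.26, 11.15, 50.70, 141.86),
    "cancer_lymphocyte_1": (9.23, 7.71, 49.83, 101.05),
    "cancer_lymphocyte_2": (9.17, 8.46, 59.11, 59.11),
    "cancer_lymphocyte_3": (11.10, 9.68, 73.72, 79.19),
}


@dataclass(frozen=True)
class MorphometryRecord:
    label: str
    major_axis_um: float
    minor_axis_um: float
    nucleus_area_um2: float
    cell_area_um2: float
    calibration_um_per_px: float

    def __post_init__(self) -> None:
        if not self.major_axis_um >= self.minor_axis_um > 0:
            raise ValueError("axes must satisfy major >= minor > 0")
        if self.nucleus_area_um2 > self.cell_area_um2 + 1e-9:
            raise ValueError("nucleus area cannot exceed cell area")

    @classmethod
    def from_reference(cls, label: str) -> "MorphometryRecord":
        major, minor, nuc, cell = WBC_REFERENCE_MEASUREMENTS[label]
        return cls(label, major, minor, nuc, cell, calibration_um_per_px=float("nan"))


def measure_cell(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    calibration_um_per_px: float,
    label: str = "",
) -> MorphometryRecord:
    """Measure one cell from its mask and its nucleus mask.

    The nucleus mask is intersected with the cell mask before measuring, so
    the nucleus-inside-cell invariant holds by construction.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool) & cell_mask
    if cell_mask.shape != nucleus_mask.shape:
        raise ValueError("cell and nucleus masks must share a shape")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    if calibration_um_per_px <= 0:
        raise ValueError("calibration must be positive")

    props = measure.regionprops(cell_mask.astype(np.uint8))[0]
    cal = calibration_um_per_px
    return MorphometryRecord(
        label=label,
        major_axis_um=props.axis_major_length * cal,
        minor_axis_um=props.axis_minor_length * cal,
        nucleus_area_um2=float(nucleus_mask.sum()) * cal**2,
        cell_area_um2=float(cell_mask.sum()) * cal**2,
        calibration_um_per_px=cal,
    )


def percent_increase(value: float, baseline: float) -> float:
    """100 * (value / baseline - 1), rounded to two decimals."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return round(100.0 * (value / baseline - 1.0), 2)


@dataclass
class GroupComparison:
    field: str
    baseline: float
    per_cell_increase_pct: list[float]
    mean_increase_pct: float


def _field_values(records, field: str) -> list[float]:
    out = []
    for r in records:
        out.append(float(getattr(r, field)) if hasattr(r, field) else float(r))
    return out


def compare_groups(records_normal, records_cancer, field: str) -> GroupComparison:
    """Percent increase of each cancer cell over the normal-group mean.

    ``records_normal`` / ``records_cancer`` may hold ``MorphometryRecord``
    objects or plain numbers.  The group-mean increase is the mean of the
    per-cell increases, rounded to two decimals.
    """
    normal = _field_values(records_normal, field)
    cancer = _field_values(records_cancer, field)
    if not normal or not cancer:
        raise ValueError("both groups must be non-empty")
    baseline = float(np.mean(normal))
    per_cell = [percent_increase(v, baseline) for v in cancer]
    return GroupComparison(
        field=field,
        baseline=baseline,
        per_cell_increase_pct=per_cell,
        mean_increase_pct=round(float(np.mean([100.0 * (v / baseline - 1.0) for v in cancer])), 2),
    )


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    """Records as a table mirroring the reference measurement columns."""
    return pd.DataFrame([asdict(r) for r in records])
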