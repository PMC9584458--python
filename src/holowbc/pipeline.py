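"""End-to-end orchestration: raw image -> segmentation -> morphometry ->
hologram synthesis -> tiling/multiplexing -> quality metrics, with a JSON
manifest tying every artifact to its seed and configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fileio
from .cgh import IFTAConfig
from .metrics import jaccard
from .morphometry import measure_cell, records_to_frame
from .optics import OpticalConfig
from .segmentation import SegmentationConfig, SegmentationError, binarize, clean_mask, segment_wbc, smooth_mask
from .speckle import speckle_pipeline

__all__ = ["PipelineConfig", "load_config", "save_config", "run_pipeline"]

log = logging.getLogger("holowbc")


@dataclass
class PipelineConfig:
    """All knobs of the full pipeline; one master seed feeds every stage."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    ifta: IFTAConfig = field(default_factory=IFTAConfig)
    calibration_um_per_px: float = 0.1
    output_dir: str = "holowbc_out"
    log_level: str = "INFO"
    pad_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibration_um_per_px <= 0:
            raise ValueError("calibration_um_per_px must be positive")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log_level {self.log_level!r}")


_SECTIONS = {"optical": OpticalConfig, "segmentation": SegmentationConfig, "ifta": IFTAConfig}


def _build_section(cls, payload: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    for key in payload:
        if key not in known:
            raise ValueError(f"unknown config key {path}.{key}")
    fixed = {
        k: tuple(v) if isinstance(v, list) else v  # JSON has no tuples
        for k, v in payload.items()
    }
    return cls(**fixed)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from JSON; unknown keys are rejected with their path."""
    payload = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for key, value in payload.items():
        if key not in known:
            raise ValueError(f"unknown config key {key}")
        if key in _SECTIONS:
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2))


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(
    image_path: str | Path,
    cfg: PipelineConfig,
    roi: tuple[int, int, int, int] | None = None,
    ground_truth_mask: np.ndarray | None = None,
) -> dict:
    """Run the full chain on one blood-film image and write every artifact.

    Stages: segmentation (cell, nucleus, edges), morphometry, hologram
    synthesis of the segmented cell (padded), tiling + temporal
    multiplexing, and quality metrics for the single-hologram baseline vs
    the multiplexed reconstruction.  Returns the manifest (also written to
    ``manifest.json``); stage failures are reported with the stage name and
    a partial manifest on the exception.
    """
    logging.basicConfig()
    log.setLevel(cfg.log_level.upper())
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "input": str(image_path),
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "files": {},
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        fileio.write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    image = fileio.read_image(image_path)

    # ---- segmentation
    try:
        seg = segment_wbc(image, cfg.segmentation, roi=roi)
        nucleus_raw = seg.green_enhanced < cfg.segmentation.nucleus_threshold_fraction * seg.i_b
        nucleus_raw &= seg.cell_mask
        nuc_cfg = dataclasses.replace(
            cfg.segmentation, min_component_px=max(1, cfg.segmentation.min_component_px // 20)
        )
        nucleus = smooth_mask(clean_mask(nucleus_raw, nuc_cfg), nuc_cfg) & seg.cell_mask
    except SegmentationError as exc:
        fail(f"segmentation:{exc.stage}", exc)
    fileio.write_mask(out / "cell_mask.png", seg.cell_mask)
    fileio.write_mask(out / "nucleus_mask.png", nucleus)
    fileio.write_mask(out / "edges.png", seg.edge_map)
    manifest["files"].update(
        cell_mask="cell_mask.png", nucleus_mask="nucleus_mask.png", edges="edges.png"
    )
    manifest["stages"]["segmentation"] = {"i_b": seg.i_b, "roi": list(seg.roi)}
    if ground_truth_mask is not None:
        manifest["stages"]["segmentation"]["jaccard_vs_truth"] = jaccard(
            seg.cell_mask, ground_truth_mask
        )
    log.info("segmentation done: I_B=%.4f, cell area %d px", seg.i_b, int(seg.cell_mask.sum()))

    # ---- morphometry
    try:
        record = measure_cell(seg.cell_mask, nucleus, cfg.calibration_um_per_px, label="cell")
    except ValueError as exc:
        fail("morphometry", exc)
    records_to_frame([record]).to_csv(out / "morphometry.csv", index=False)
    manifest["files"]["morphometry"] = "morphometry.csv"
    manifest["stages"]["morphometry"] = dataclasses.asdict(record)

    # ---- hologram synthesis + speckle reduction
    # amplitude: inverted stain intensity inside the cell (nucleus brightest)
    amplitude = (1.0 - seg.green_enhanced) * seg.cell_mask
    # crop to the cell's bounding box (plus margin) before SLM placement
    rows = np.flatnonzero(seg.cell_mask.any(axis=1))
    cols = np.flatnonzero(seg.cell_mask.any(axis=0))
    margin = 4
    r0, r1 = max(0, rows[0] - margin), min(amplitude.shape[0], rows[-1] + 1 + margin)
    c0, c1 = max(0, cols[0] - margin), min(amplitude.shape[1], cols[-1] + 1 + margin)
    amplitude = amplitude[r0:r1, c0:c1]
    # all stage randomness flows from the one master seed
    ifta_cfg = dataclasses.replace(
        cfg.ifta, seed=int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    )
    try:
        report = speckle_pipeline(
            amplitude,
            ifta_cfg,
            slm_shape=cfg.optical.slm_shape,
            pad_factor=cfg.pad_factor,
            keep_arrays=True,
        )
    except ValueError as exc:
        fail("speckle_pipeline", exc)
    for idx, tile in enumerate(report.tiled.tiles):
        name = f"tile_{idx:02d}.png"
        fileio.write_hologram(out / name, tile)
        manifest["files"][f"tile_{idx:02d}"] = name
    fileio.write_hologram(out / "hologram_full.png", report.tiled.full)
    fileio.write_gray_u8(out / "reconstruction.png", report.multiplexed_intensity)
    manifest["files"]["hologram_full"] = "hologram_full.png"
    manifest["files"]["reconstruction"] = "reconstruction.png"
    np.savetxt(
        out / "error_trace.csv",
        np.column_stack([np.arange(1, report.baseline.iterations_run + 1), report.baseline.error_trace]),
        delimiter=",",
        header="iteration,intensity_error",
        comments="",
    )
    manifest["files"]["error_trace"] = "error_trace.csv"
    manifest["stages"]["quality"] = {
        "before": dataclasses.asdict(report.before),
        "after": dataclasses.asdict(report.after),
        "contrast_reduction": report.contrast_reduction,
        "sigma_reduction": report.sigma_reduction,
        "n_tiles": report.n_tiles,
    }
    log.info(
        "speckle reduction: C %.3f -> %.3f, sigma %.4f -> %.4f",
        report.before.contrast,
        report.after.contrast,
        report.before.sigma,
        report.after.sigma,
    )

    fileio.write_json(out / "manifest.json", manifest)
    return manifest
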