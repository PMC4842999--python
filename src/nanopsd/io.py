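"""File formats and pipeline configuration.

Images travel as single-channel TIFF with the pixel size recorded in the
X/Y resolution tags (pixels per cm) and mirrored in a sidecar JSON;
localisations as CSV with an ``x_nm, y_nm, frame[, precision_nm, intensity,
truth_nc_id]`` header; ground truth, provenance and summaries as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import RenderedImage
from .palm import PalmParams
from .segmentation import (STED_NC_PARAMS, STED_PSD_PARAMS, PSDRecord,
                           SegmentationParams)
from .simulate import SimulationConfig

__all__ = [
    "PipelineConfig",
    "read_image",
    "write_image",
    "read_localisations",
    "write_localisations",
    "records_to_frame",
    "write_records",
    "run_pipeline",
]

_REQUIRED_LOC_COLUMNS = ("x_nm", "y_nm", "frame")
_DEFAULT_PRECISION_NM = 40.0


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def write_image(image: RenderedImage, path: str | Path,
                dtype: str = "uint16") -> Path:
    """Write a single-channel grayscale TIFF plus a sidecar JSON.

    Float data are scaled into the 16-bit range; the scale factor and the
    pixel size are stored in the sidecar so a round trip restores both array
    and geometry.  Integer data are written unchanged.
    """
    path = Path(path)
    data = image.data
    scale = 1.0
    if np.issubdtype(data.dtype, np.floating) and dtype == "uint16":
        peak = float(data.max())
        scale = 65535.0 / peak if peak > 0 else 1.0
        out = np.round(np.clip(data * scale, 0, 65535)).astype(np.uint16)
    else:
        out = data.astype(np.uint16 if dtype == "uint16" else data.dtype)
    # resolution tags: pixels per cm (1 cm = 1e7 nm)
    ppcm = 1e7 / image.pixel_size
    tifffile.imwrite(path, out, resolution=(ppcm, ppcm),
                     resolutionunit="CENTIMETER")
    sidecar = {"pixel_size_nm": image.pixel_size, "channel": image.channel,
               "intensity_scale": scale}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> RenderedImage:
    """Read a single-channel 8/16-bit TIFF.

    The pixel size comes from the sidecar JSON if present, else from the TIFF
    resolution tags; if neither is available it must be supplied via
    ``pixel_size_nm`` (the CLI flag ``--pixel-nm``).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        n_pages = max(len(tf.pages),
                      data.shape[0] if data.ndim == 3 else 1)
        if n_pages > 1:
            raise ValueError(
                f"{path} has {n_pages} pages; the single-image reader "
                "expects one page — split the stack first")
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        tag_px = None
        if res is not None and unit is not None:
            num, den = res.value
            if num > 0 and den > 0:
                ppu = num / den
                unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit.value))
                if unit_nm:
                    tag_px = unit_nm / ppu
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, "
                         f"got shape {data.shape}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    channel = ""
    scale = 1.0
    side_px = None
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        side_px = side.get("pixel_size_nm")
        channel = side.get("channel", "")
        scale = side.get("intensity_scale", 1.0)
    px = pixel_size_nm or side_px or tag_px
    if px is None:
        raise ValueError(
            f"{path} carries no pixel size (no sidecar JSON, no usable "
            "resolution tags); pass --pixel-nm / pixel_size_nm explicitly")
    arr = data.astype(np.float64) / scale if scale != 1.0 else data
    return RenderedImage(data=arr, pixel_size=float(px), channel=channel)


# --------------------------------------------------------------------------
# localisation tables
# --------------------------------------------------------------------------

def write_localisations(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_localisations(path: str | Path,
                       default_precision_nm: float = _DEFAULT_PRECISION_NM,
                       ) -> pd.DataFrame:
    """Read and validate a localisation CSV.

    Requires columns ``x_nm, y_nm, frame``; a missing ``precision_nm`` column
    is filled with the configured default (40 nm, the typical fitting
    precision) and flagged in ``DataFrame.attrs['precision_defaulted']``.
    Non-numeric cells raise with the offending row number.
    """
    path = Path(path)
    table = pd.read_csv(path)
    for col in _REQUIRED_LOC_COLUMNS:
        if col not in table.columns:
            raise ValueError(
                f"{path}: missing required column '{col}' "
                f"(header must contain {', '.join(_REQUIRED_LOC_COLUMNS)})")
    for col in table.columns:
        if col in ("x_nm", "y_nm", "frame", "precision_nm", "intensity"):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise ValueError(
                    f"{path}: non-numeric value in column '{col}' at data row "
                    f"{row} (value {table[col].iloc[row]!r})")
            table[col] = coerced
    table.attrs["precision_defaulted"] = False
    if "precision_nm" not in table.columns:
        table["precision_nm"] = default_precision_nm
        table.attrs["precision_defaulted"] = True
    return table


# --------------------------------------------------------------------------
# record tables
# --------------------------------------------------------------------------

def records_to_frame(records: list[PSDRecord], **extra) -> pd.DataFrame:
    """Flatten PSD records to one NC per row with parent PSD morphometry."""
    rows = []
    for i, rec in enumerate(records):
        for nc in rec.nanoclusters:
            row = {
                "psd_id": i,
                "psd_label": rec.psd.label,
                "nc_label": nc.label,
                "nc_count": rec.nc_count,
                "subtype": rec.subtype,
                "psd_equivalent_diameter": rec.psd.equivalent_diameter,
                "psd_area": rec.psd.area,
                "psd_mean_intensity": rec.psd.mean_intensity,
                "psd_integrated_intensity": rec.psd.integrated_intensity,
                "nc_equivalent_diameter": nc.equivalent_diameter,
                "nc_area": nc.area,
                "nc_long_axis": nc.long_axis,
                "nc_short_axis": nc.short_axis,
                "nc_aspect_ratio": nc.aspect_ratio,
                "nc_mean_intensity": nc.mean_intensity,
                "nc_integrated_intensity": nc.integrated_intensity,
                "nc_x_nm": nc.centroid[0],
                "nc_y_nm": nc.centroid[1],
            }
            row.update(extra)
            rows.append(row)
    return pd.DataFrame(rows)


def write_records(records: list[PSDRecord], summary: dict,
                  out_dir: str | Path, stem: str = "field", **extra) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records, **extra)
    frame.to_csv(out_dir / f"{stem}_records.csv", index=False)
    (out_dir / f"{stem}_summary.json").write_text(json.dumps(summary, indent=1,
                                                             default=str))
    return out_dir / f"{stem}_records.csv"


# --------------------------------------------------------------------------
# pipeline configuration and orchestration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Complete run configuration; round-trips losslessly through YAML."""

    modality: str = "sted"                   # "sted" or "palm"
    seed: int = 0
    output_dir: str = "out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    psd_segmentation: SegmentationParams = field(
        default_factory=lambda: dataclasses.replace(STED_PSD_PARAMS))
    nc_segmentation: SegmentationParams = field(
        default_factory=lambda: dataclasses.replace(STED_NC_PARAMS))
    palm: PalmParams = field(default_factory=PalmParams)

    def __post_init__(self) -> None:
        if self.modality not in ("sted", "palm"):
            raise ValueError("modality must be 'sted' or 'palm'")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "simulation": dataclasses.asdict(self.simulation),
            "psd_segmentation": dataclasses.asdict(self.psd_segmentation),
            "nc_segmentation": dataclasses.asdict(self.nc_segmentation),
            "palm": dataclasses.asdict(self.palm),
        }

    def to_yaml(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return yaml.safe_dump(_clean(self.to_dict()), sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            for key in ("subtype_mixture", "nc_axis_medians", "spacing_interval"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulation"] = SimulationConfig(**sim)
        for key in ("psd_segmentation", "nc_segmentation"):
            if key in kwargs:
                kwargs[key] = SegmentationParams(**kwargs[key])
        if "palm" in kwargs:
            kwargs["palm"] = PalmParams(**kwargs["palm"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate a field, segment it per the configured modality, and write
    records, summaries and full parameter provenance.

    Returns the summary dict (also written to ``summary.json``).  Every
    numeric threshold used is echoed into the provenance block.
    """
    from . import segmentation as seg
    from . import palm as palm_mod
    from . import simulate as sim

    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.simulation
    scene = sim.sample_scene(cfg, seed=config.seed)
    (out / "scene_truth.json").write_text(sim.scene_to_json(scene))
    stage_counts = {"n_psds_truth": len(scene.psds),
                    "n_ncs_truth": len(scene.nanoclusters)}
    if config.modality == "sted":
        confocal, sted = sim.render_scene_pair(scene, cfg, seed=config.seed)
        write_image(confocal, out / "confocal.tif")
        write_image(sted, out / "sted.tif")
        records, summary = seg.run_sted_workflow(
            confocal, sted, config.psd_segmentation, config.nc_segmentation)
    else:
        table = sim.simulate_palm(scene, cfg, seed=config.seed)
        write_localisations(table, out / "localisations.csv")
        records, summary = palm_mod.run_palm_workflow(
            table, config.palm, cfg.field_width_nm, cfg.field_height_nm)
    summary.update(stage_counts)
    write_records(records, summary, out, stem=config.modality)
    provenance = {"config": config.to_dict(), "summary": summary}
    (out / "summary.json").write_text(json.dumps(provenance, indent=1, default=str))
    return provenance
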