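"""TIFF/OME-TIFF image I/O, YAML run configuration and the end-to-end
pipeline that ties simulation, quantification and statistics together.

All tabular outputs are UTF-8 CSV with a header row; the run manifest is a
JSON file recording the configuration, its hash and every seed used, so a
re-run with the same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .confocal import (
    CellClassifierConfig,
    SegmentationConfig,
    classify_cells,
    segment_gvb_cores,
)
from .highcontent import (
    PunctaCriteria,
    WellObservation,
    background_subtract,
    measure_well,
    normalize_minmax,
)
from .image import ChannelError, MultiChannelImage
from .stats import StatResult, select_and_run
from .synth import (
    GroundTruth,
    OpticsParams,
    PopulationParams,
    dose_ladder_params,
    generate_dose_response,
)

logger = logging.getLogger("gvbquant")

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class DataError(RuntimeError):
    """Unreadable or inconsistent input data."""


# ---------------------------------------------------------------------------
# Image files
# ---------------------------------------------------------------------------

def write_image(path, image: MultiChannelImage, ome: bool = False) -> None:
    """Write a multi-page TIFF (one page per channel) or OME-TIFF.

    Channel roles and the pixel size travel in the file: as a JSON image
    description for plain TIFF, or as OME channel names and physical pixel
    sizes for OME-TIFF.
    """
    path = Path(path)
    roles = list(image.roles())
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    if ome:
        tifffile.imwrite(
            path,
            stack,
            ome=True,
            metadata={
                "axes": "CYX",
                "Channel": {"Name": roles},
                "PhysicalSizeX": image.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": image.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
            },
        )
    else:
        description = json.dumps(
            {"channels": roles, "pixel_size_um": image.pixel_size_um}
        )
        tifffile.imwrite(path, stack, description=description)


def read_image(
    path,
    channel_names: Optional[Sequence[str]] = None,
    pixel_size_um: Optional[float] = None,
) -> MultiChannelImage:
    """Read a (OME-)TIFF into a :class:`MultiChannelImage`.

    Channel names and pixel size come from the file metadata; values passed
    explicitly win over metadata (and the override is logged).  Raises
    :class:`DataError` when the file is unreadable and
    :class:`ConfigError` when channels cannot be mapped or no pixel size is
    available from either source.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            array = tif.asarray()
            meta_names = None
            meta_px = None
            if tif.ome_metadata:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tif.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                pixels = root.find(".//ome:Pixels", ns)
                if pixels is not None:
                    if pixels.get("PhysicalSizeX"):
                        meta_px = float(pixels.get("PhysicalSizeX"))
                    names = [
                        ch.get("Name")
                        for ch in pixels.findall("ome:Channel", ns)
                    ]
                    if names and all(names):
                        meta_names = names
            else:
                desc = tif.pages[0].description
                if desc:
                    try:
                        info = json.loads(desc)
                        meta_names = info.get("channels")
                        meta_px = info.get("pixel_size_um")
                    except (ValueError, AttributeError):
                        pass
    except (OSError, tifffile.TiffFileError) as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc

    if array.ndim == 2:
        array = array[None]
    if array.ndim != 3:
        raise DataError(f"{path}: expected a 2D multi-channel image, got {array.shape}")

    if channel_names is not None and meta_names and list(channel_names) != list(
        meta_names
    ):
        logger.info("%s: channel names overridden by configuration", path.name)
    names = list(channel_names) if channel_names is not None else meta_names
    if not names:
        raise ConfigError(f"{path}: no channel names in metadata or configuration")
    if len(names) != array.shape[0]:
        raise ConfigError(
            f"{path}: {len(names)} channel names for {array.shape[0]} pages"
        )
    if pixel_size_um is not None and meta_px and pixel_size_um != meta_px:
        logger.info("%s: pixel size overridden by configuration", path.name)
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise ConfigError(f"{path}: pixel size missing from metadata and configuration")
    return MultiChannelImage(
        channels={name: array[i] for i, name in enumerate(names)},
        pixel_size_um=float(px),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured pipeline configuration (see ``load_config``)."""

    seed: int = 1
    doses: List[float] = field(default_factory=lambda: [0.0, 40.0, 80.0, 160.0])
    wells_per_dose: int = 3
    population: PopulationParams = field(default_factory=PopulationParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    puncta: PunctaCriteria = field(default_factory=PunctaCriteria)
    classifier: CellClassifierConfig = field(default_factory=CellClassifierConfig)
    channel_role_map: Optional[Dict[str, str]] = None
    save_images: bool = False
    schema_version: int = SCHEMA_VERSION

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(_config_to_dict(self), sort_keys=True).encode()
        ).hexdigest()


def _build(cls, block: dict, tuple_fields=()):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {
        k: (tuple(v) if k in tuple_fields and v is not None else v)
        for k, v in block.items()
    }
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot load config {path}: {exc}") from exc
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    try:
        cfg = RunConfig(
            seed=int(raw.get("seed", 1)),
            doses=[float(d) for d in raw.get("doses", [0.0, 40.0, 80.0, 160.0])],
            wells_per_dose=int(raw.get("wells_per_dose", 3)),
            population=_build(
                PopulationParams,
                raw.get("population", {}),
                tuple_fields={"tau_intensity_levels", "morphology_probs"},
            ),
            optics=_build(
                OpticsParams, raw.get("optics", {}), tuple_fields={"image_shape"}
            ),
            segmentation=_build(SegmentationConfig, raw.get("segmentation", {})),
            puncta=_build(
                PunctaCriteria, raw.get("puncta", {}),
                tuple_fields={"area_range_um2"},
            ),
            classifier=_build(
                CellClassifierConfig,
                {
                    k: v
                    for k, v in raw.get("classifier", {}).items()
                    if k != "segmentation"
                },
            ),
            channel_role_map=raw.get("channel_role_map"),
            save_images=bool(raw.get("save_images", False)),
        )
        cfg.population.validate()
        cfg.optics.validate()
        cfg.puncta.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    cfg.classifier.segmentation = cfg.segmentation
    return cfg


def _config_to_dict(cfg: RunConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        return obj

    return plain(cfg)


# ---------------------------------------------------------------------------
# Ground-truth and result tables
# ---------------------------------------------------------------------------

def truth_to_tables(truth: GroundTruth, well_id: str = "W001"):
    """Ground truth as (cells, gvbs) DataFrames keyed by cell_id."""
    cell_rows = []
    gvb_rows = []
    for cell in truth.cells:
        cell_rows.append(
            {
                "well_id": well_id,
                "cell_id": cell.cell_id,
                "row": cell.center[0],
                "col": cell.center[1],
                "soma_area_um2": cell.soma_area_um2,
                "tau_status": cell.tau_status,
                "tau_intensity": cell.tau_intensity,
                "gvb_status": cell.gvb_status,
                "n_gvbs": len(cell.gvb_list),
            }
        )
        for k, gvb in enumerate(cell.gvb_list, start=1):
            gvb_rows.append(
                {
                    "well_id": well_id,
                    "cell_id": cell.cell_id,
                    "gvb_index": k,
                    "row": gvb.center[0],
                    "col": gvb.center[1],
                    "core_area_um2": gvb.core_area_um2,
                    "has_ring": gvb.has_ring,
                    "n_cores_in_ring": gvb.n_cores_in_ring,
                    "morphology": gvb.morphology,
                    "dqbsa_ratio_true": gvb.dqbsa_ratio_true,
                }
            )
    columns_g = [
        "well_id", "cell_id", "gvb_index", "row", "col", "core_area_um2",
        "has_ring", "n_cores_in_ring", "morphology", "dqbsa_ratio_true",
    ]
    return (
        pd.DataFrame(cell_rows),
        pd.DataFrame(gvb_rows, columns=columns_g),
    )


def _concat(frames: List[pd.DataFrame]) -> pd.DataFrame:
    nonempty = [f for f in frames if not f.empty]
    return pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]


def _stat_to_dict(result: StatResult) -> dict:
    return {
        "test_name": result.test_name,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "normality_pass": result.normality_pass,
        "posthoc": result.posthoc,
        "alpha": result.alpha,
        "significant": result.significant,
    }


def run_pipeline(cfg: RunConfig, outdir) -> Dict[str, Path]:
    """Simulate a dose ladder, quantify every well and write result tables.

    Outputs in ``outdir``: ``cells.csv`` (per-cell records),
    ``structures.csv`` (segmented cores), ``wells.csv`` (per-well loads, raw
    through normalized), ``truth_cells.csv``/``truth_gvbs.csv`` (generator
    ground truth), ``stats.json`` (load comparison across doses) and
    ``manifest.json``.  Identical config and seed give identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ladder = dose_ladder_params(cfg.population, cfg.doses)
    try:
        wells = generate_dose_response(
            ladder, cfg.wells_per_dose, cfg.optics, cfg.seed
        )
    except Exception as exc:
        raise DataError(f"simulate stage failed: {exc}") from exc

    cell_frames, truth_cells, truth_gvbs = [], [], []
    structure_rows = []
    observations: List[WellObservation] = []
    for i, (image, truth) in enumerate(wells):
        well_id = f"W{i + 1:03d}"
        dose = cfg.doses[i // cfg.wells_per_dose]
        tc, tg = truth_to_tables(truth, well_id)
        truth_cells.append(tc)
        truth_gvbs.append(tg)
        try:
            records = classify_cells(image, cfg.classifier)
            cores = segment_gvb_cores(image, "gvb", cfg.segmentation)
        except Exception as exc:
            raise DataError(f"segment stage failed on {well_id}: {exc}") from exc
        cell_frames.append(
            pd.DataFrame(
                [
                    {
                        "well_id": well_id,
                        "cell_id": r.cell_id,
                        "soma_area_um2": r.soma_area_um2,
                        "tau_intensity_au": r.tau_intensity_au,
                        "tau_positive": r.tau_positive,
                        "n_gvb_cores": len(r.gvb_cores),
                        "gvb_positive": r.gvb_positive,
                    }
                    for r in records
                ]
            )
        )
        for core in cores:
            structure_rows.append(
                {
                    "well_id": well_id,
                    "label": core.label,
                    "row": core.centroid_px[0],
                    "col": core.centroid_px[1],
                    "area_um2": core.area_um2,
                    **{
                        f"mean_{role}": v
                        for role, v in sorted(core.mean_intensity.items())
                    },
                }
            )
        obs = measure_well(
            image,
            well_id,
            criteria=cfg.puncta,
            dose_nM=dose,
            control=(dose == 0),
        )
        observations.append(obs)
        if cfg.save_images:
            write_image(outdir / f"{well_id}.ome.tif", image, ome=True)

    background_subtract(observations)
    try:
        normalize_minmax(observations, "tau")
        normalize_minmax(observations, "gvb")
    except ValueError:
        logger.warning("degenerate load range; normalized columns left empty")

    wells_df = pd.DataFrame([dataclasses.asdict(o) for o in observations])
    cells_df = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else pd.DataFrame()
    )
    columns_s = ["well_id", "label", "row", "col", "area_um2"]
    structures_df = pd.DataFrame(structure_rows)
    if structures_df.empty:
        structures_df = pd.DataFrame(columns=columns_s)

    stats_out = {}
    by_dose: Dict[float, List[WellObservation]] = {}
    for obs in observations:
        by_dose.setdefault(obs.dose_nM, []).append(obs)
    if len(by_dose) >= 2 and min(len(v) for v in by_dose.values()) >= 3:
        for field_name in ("tau", "gvb"):
            groups = [
                [o.corrected(field_name) for o in by_dose[d]]
                for d in sorted(by_dose)
            ]
            stats_out[f"{field_name}_load"] = _stat_to_dict(select_and_run(groups))
    else:
        logger.info("fewer than 3 wells per dose; skipping group statistics")

    paths = {}
    for name, frame in [
        ("cells", cells_df),
        ("structures", structures_df),
        ("wells", wells_df),
        ("truth_cells", _concat(truth_cells)),
        ("truth_gvbs", _concat(truth_gvbs)),
    ]:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    stats_path = outdir / "stats.json"
    stats_path.write_text(json.dumps(stats_out, indent=2))
    paths["stats"] = stats_path
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "gvbquant_version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg.digest(),
        "config": _config_to_dict(cfg),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
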