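"""Per-cell confocal quantification: GVB core segmentation and sizing,
tau/GVB co-classification, masked intensities and signal/background ratios.

The measurements follow the conventions of interactive confocal analysis —
threshold, watershed-split, measure particle areas in µm²; draw a
somatodendritic ROI and quantify marker intensity inside it with a nuclear
exclusion mask; express reporter signal as a structure/background ratio —
but replace every manual step with a seeded, reproducible surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import segmentation as skseg

from .image import MultiChannelImage

__all__ = [
    "SegmentationConfig",
    "CellClassifierConfig",
    "GVBCore",
    "CellRecord",
    "RatioRecord",
    "LineProfile",
    "NoCellError",
    "EmptyMaskError",
    "InsufficientBackgroundError",
    "NoGVBError",
    "segment_gvb_cores",
    "segment_ring_interiors",
    "measure_soma_area",
    "classify_cells",
    "tau_threshold_from_controls",
    "quantify_masked_intensity",
    "normalize_to_control",
    "dqbsa_ratio",
    "frequency_distribution",
    "gvb_cytosol_ratio",
    "line_profile",
    "classify_gvb_morphology",
]


class NoCellError(ValueError):
    """Seed point does not fall on a thresholded cell."""


class EmptyMaskError(ValueError):
    """Effective measurement mask has no pixels."""


class InsufficientBackgroundError(ValueError):
    """Not enough eligible cytosol to place the background ROIs."""


class NoGVBError(ValueError):
    """No GVB ROI was detected for this cell."""


@dataclass
class SegmentationConfig:
    """Configuration of puncta/core segmentation.

    threshold_method
        ``"mean_sd"`` (mean + k·SD of the thresholding region, robust to
        smooth background) or ``"otsu"``.
    threshold_k
        k of the mean + k·SD rule.
    watershed
        Split touching objects on the Euclidean distance transform with
        h-maxima seeding (h in pixels).
    refine_half_max
        Re-threshold each detected object at background + half of its peak
        above background.  This FWHM sizing criterion makes the area of a
        sharp object exact and keeps blurred-disk areas close to truth.
    """

    threshold_method: str = "mean_sd"
    threshold_k: float = 3.0
    watershed: bool = True
    h_maxima: float = 1.0
    min_area_um2: float = 0.15
    exclude_border: bool = True
    refine_half_max: bool = True
    # compute threshold statistics within the thresholded soma mask when a
    # soma channel is present (robust when cores dominate the dynamic range)
    stats_in_soma: bool = True
    # objects must peak at least min_peak_k SDs above the statistics-region
    # mean: GVB cores are tens of SDs above cytosol, noise clumps are not
    min_peak_k: float = 8.0


@dataclass
class GVBCore:
    """One segmented GVB core."""

    label: int
    centroid_px: Tuple[float, float]
    area_um2: float
    n_pixels: int
    mean_intensity: Dict[str, float]
    parent_cell: Optional[int] = None


@dataclass
class CellRecord:
    """One neuron's measurements from a classified field."""

    cell_id: int
    offset: Tuple[int, int]
    soma_mask: np.ndarray        # bool, cropped to the cell bbox
    nucleus_mask: np.ndarray     # bool, same crop
    soma_area_um2: float
    tau_intensity_au: float      # background-corrected somatic mean
    tau_positive: bool
    gvb_cores: List[GVBCore] = field(default_factory=list)

    @property
    def gvb_positive(self) -> bool:
        return bool(self.gvb_cores)


@dataclass
class RatioRecord:
    """Signal/background ratio of one structure."""

    structure_id: int
    marker_positive: bool
    signal_au: float
    background_au: float

    @property
    def ratio(self) -> float:
        return self.signal_au / self.background_au


@dataclass
class LineProfile:
    """Bilinear-interpolated intensities along a line segment."""

    endpoints_px: Tuple[Tuple[float, float], Tuple[float, float]]
    sample_positions_um: np.ndarray
    intensity: Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Thresholding and object splitting
# ---------------------------------------------------------------------------

def _threshold_value(
    raster: np.ndarray,
    method: str,
    k: float,
    mask: Optional[np.ndarray] = None,
) -> float:
    vals = raster[mask] if mask is not None else raster.ravel()
    if vals.size == 0:
        raise EmptyMaskError("thresholding region is empty")
    if method == "otsu":
        return float(skfilters.threshold_otsu(vals))
    if method == "mean_sd":
        return float(vals.mean() + k * vals.std())
    raise ValueError(f"unknown threshold method {method!r}")


def _split_objects(binary: np.ndarray, h: float) -> np.ndarray:
    """Label a binary mask, splitting merged objects by watershed on the
    distance transform with h-maxima seeding."""
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    peaks = skmorph.h_maxima(distance, h)
    markers, n = ndi.label(peaks)
    if n == 0:
        markers, _ = ndi.label(binary)
        return markers.astype(np.int32)
    return skseg.watershed(-distance, markers=markers, mask=binary).astype(np.int32)


def segment_gvb_cores(
    image: MultiChannelImage,
    channel: str = "gvb",
    cfg: Optional[SegmentationConfig] = None,
) -> List[GVBCore]:
    """Threshold + watershed segmentation of GVB cores with areas in µm².

    Connected regions above the threshold are split by distance-transform
    watershed, objects touching the image border are excluded, objects
    smaller than ``cfg.min_area_um2`` are discarded, and (by default) each
    object is re-sized at half of its peak above background so that blur
    does not inflate the reported area.
    """
    cfg = cfg or SegmentationConfig()
    raster = image.get(channel)
    stats_mask = None
    if cfg.stats_in_soma and "soma" in image.channels:
        soma = image.get("soma")
        candidate = soma > _threshold_value(soma, "otsu", 0.0)
        if candidate.any():
            stats_mask = candidate
    stats_vals = raster[stats_mask] if stats_mask is not None else raster.ravel()
    thr = _threshold_value(raster, cfg.threshold_method, cfg.threshold_k, stats_mask)
    peak_floor = float(stats_vals.mean() + cfg.min_peak_k * stats_vals.std())
    binary = raster > thr
    if not binary.any():
        return []
    background = float(raster[~binary].mean()) if (~binary).any() else 0.0

    if cfg.watershed:
        labels = _split_objects(binary, cfg.h_maxima)
    else:
        labels, _ = ndi.label(binary)
        labels = labels.astype(np.int32)
    if cfg.exclude_border:
        labels = skseg.clear_border(labels)

    px_area = image.pixel_area_um2
    cores: List[GVBCore] = []
    out_label = 0
    for region in skmeasure.regionprops(labels, intensity_image=raster):
        sl = region.slice
        region_mask = labels[sl] == region.label
        local = raster[sl]
        peak = local[region_mask].max()
        if peak < peak_floor:
            continue
        if cfg.refine_half_max:
            cut = background + 0.5 * (peak - background)
            refined = region_mask & (local >= cut)
            # keep the component containing the peak
            comp, _ = ndi.label(refined)
            peak_idx = np.unravel_index(
                np.argmax(np.where(region_mask, local, -np.inf)), local.shape
            )
            peak_lbl = comp[peak_idx]
            refined = comp == peak_lbl if peak_lbl else region_mask
        else:
            refined = region_mask
        n_px = int(refined.sum())
        area = n_px * px_area
        if area < cfg.min_area_um2 or n_px == 0:
            continue
        rr, cc = np.nonzero(refined)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        out_label += 1
        cores.append(
            GVBCore(
                label=out_label,
                centroid_px=(float(rr.mean()), float(cc.mean())),
                area_um2=float(area),
                n_pixels=n_px,
                mean_intensity={
                    role: float(image.channels[role][rr, cc].mean())
                    for role in image.roles()
                },
            )
        )
    return cores


def segment_ring_interiors(
    image: MultiChannelImage,
    channel: str = "membrane",
    cfg: Optional[SegmentationConfig] = None,
    min_interior_area_um2: float = 0.1,
) -> List[np.ndarray]:
    """Interior masks of ring-shaped membrane signal.

    The membrane channel is thresholded, small gaps are closed, holes are
    filled and the interiors (filled minus ring) are returned as full-frame
    boolean masks, one per ring.
    """
    cfg = cfg or SegmentationConfig()
    raster = image.get(channel)
    thr = _threshold_value(raster, cfg.threshold_method, cfg.threshold_k)
    ring = raster > thr
    if not ring.any():
        return []
    closed = skmorph.closing(ring, skmorph.disk(2))
    filled = ndi.binary_fill_holes(closed)
    # subtract the raw (not the closed) ring: closing thickens the membrane
    # and would eat into small interiors, inflating fill fractions
    interiors = filled & ~ring
    labels, n = ndi.label(interiors)
    out = []
    px_area = image.pixel_area_um2
    for lbl in range(1, n + 1):
        mask = labels == lbl
        if mask.sum() * px_area >= min_interior_area_um2:
            out.append(mask)
    return out


def measure_soma_area(
    image: MultiChannelImage,
    soma_channel: str = "soma",
    cell_seed: Tuple[float, float] = (0.0, 0.0),
    threshold_method: str = "otsu",
    threshold_k: float = 3.0,
) -> float:
    """Area (µm²) of the thresholded soma component containing a seed point.

    An automated surrogate for a hand-drawn somatic ROI: the soma channel is
    thresholded and the connected component under ``cell_seed`` is measured.
    """
    raster = image.get(soma_channel)
    thr = _threshold_value(raster, threshold_method, threshold_k)
    binary = raster > thr
    labels, _ = ndi.label(binary)
    seed = (int(round(cell_seed[0])), int(round(cell_seed[1])))
    if not (0 <= seed[0] < binary.shape[0] and 0 <= seed[1] < binary.shape[1]):
        raise NoCellError(f"seed {cell_seed} outside image")
    lbl = labels[seed]
    if lbl == 0:
        raise NoCellError(f"seed {cell_seed} falls on background")
    return float((labels == lbl).sum()) * image.pixel_area_um2


# ---------------------------------------------------------------------------
# Per-cell classification
# ---------------------------------------------------------------------------

@dataclass
class CellClassifierConfig:
    """Configuration for nuclei-seeded per-cell tau/GVB classification."""

    tau_threshold_au: float = 4.0     # background-corrected somatic mean cutoff
    min_puncta: int = 1
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    nuclei_min_area_um2: float = 8.0
    nuclei_split_h: float = 2.0


def _detect_nuclei(image: MultiChannelImage, cfg: CellClassifierConfig) -> np.ndarray:
    raster = image.get("nuclei")
    thr = _threshold_value(raster, "otsu", 0.0)
    binary = ndi.binary_fill_holes(raster > thr)
    labels = _split_objects(binary, cfg.nuclei_split_h)
    min_px = cfg.nuclei_min_area_um2 / image.pixel_area_um2
    counts = np.bincount(labels.ravel())
    too_small = np.nonzero(counts < min_px)[0]
    labels[np.isin(labels, too_small)] = 0
    return labels


def classify_cells(
    image: MultiChannelImage,
    cfg: Optional[CellClassifierConfig] = None,
) -> List[CellRecord]:
    """Detect nuclei, assign somata and classify each cell's tau/GVB status.

    Nuclei are detected in the nuclei channel (threshold + watershed split of
    touching nuclei) and used as seeds to partition the thresholded
    somatodendritic mask into per-cell territories.  A cell is tau-positive
    when its background-corrected somatic tau mean exceeds
    ``cfg.tau_threshold_au`` and GVB-positive when at least
    ``cfg.min_puncta`` segmented cores lie within its soma.  The full
    records allow any single/double-positive percentage downstream.
    """
    cfg = cfg or CellClassifierConfig()
    nuclei_labels = _detect_nuclei(image, cfg)
    if nuclei_labels.max() == 0:
        return []
    soma_raster = image.get("soma")
    soma_thr = _threshold_value(soma_raster, "otsu", 0.0)
    soma_binary = soma_raster > soma_thr
    # every nucleus belongs to a cell even if its soma pixels dip under the
    # threshold locally
    soma_binary |= nuclei_labels > 0
    cell_labels = skseg.watershed(
        -soma_raster, markers=nuclei_labels, mask=soma_binary
    )

    tau_raster = image.get("tau")
    tau_background = float(np.median(tau_raster[~soma_binary])) if (
        ~soma_binary
    ).any() else 0.0

    cores = segment_gvb_cores(image, "gvb", cfg.segmentation)
    cores_by_cell: Dict[int, List[GVBCore]] = {}
    for core in cores:
        r, c = (int(round(core.centroid_px[0])), int(round(core.centroid_px[1])))
        lbl = int(cell_labels[r, c])
        if lbl:
            core.parent_cell = lbl
            cores_by_cell.setdefault(lbl, []).append(core)

    records: List[CellRecord] = []
    px_area = image.pixel_area_um2
    for region in skmeasure.regionprops(cell_labels):
        sl = region.slice
        mask = cell_labels[sl] == region.label
        nucleus = nuclei_labels[sl] == region.label
        cell_tau = float(tau_raster[sl][mask & ~nucleus].mean()) - tau_background
        cell_cores = cores_by_cell.get(region.label, [])
        records.append(
            CellRecord(
                cell_id=int(region.label),
                offset=(sl[0].start, sl[1].start),
                soma_mask=mask,
                nucleus_mask=nucleus,
                soma_area_um2=float(mask.sum()) * px_area,
                tau_intensity_au=cell_tau,
                tau_positive=cell_tau > cfg.tau_threshold_au,
                gvb_cores=cell_cores if len(cell_cores) >= cfg.min_puncta else [],
            )
        )
    return records


def tau_threshold_from_controls(
    control_records: Sequence[CellRecord], k: float = 2.0
) -> float:
    """Tau-positivity cutoff from a control (buffer) population.

    mean + k·SD of the background-corrected somatic tau means of control
    cells — the conventional way to set a positivity threshold when no
    absolute cutoff exists.
    """
    vals = np.array([r.tau_intensity_au for r in control_records], dtype=float)
    if vals.size == 0:
        raise ValueError("no control records")
    return float(vals.mean() + k * vals.std())


# ---------------------------------------------------------------------------
# Masked intensities and ratios
# ---------------------------------------------------------------------------

def quantify_masked_intensity(
    image: MultiChannelImage,
    signal_channel: str,
    roi_mask: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
) -> Tuple[float, int]:
    """Mean signal over ``roi_mask AND NOT exclusion_mask``.

    Returns ``(mean, n_pixels)``; raises :class:`EmptyMaskError` when the
    effective mask is empty.
    """
    raster = image.get(signal_channel)
    if roi_mask.shape != raster.shape:
        raise ValueError("roi_mask shape does not match image")
    effective = roi_mask.astype(bool)
    if exclusion_mask is not None:
        if exclusion_mask.shape != raster.shape:
            raise ValueError("exclusion_mask shape does not match image")
        effective = effective & ~exclusion_mask.astype(bool)
    n = int(effective.sum())
    if n == 0:
        raise EmptyMaskError("effective mask is empty")
    return float(raster[effective].mean()), n


def normalize_to_control(
    values: Sequence[float], control_values: Sequence[float]
) -> List[float]:
    """Divide values by the control mean; the control condition becomes 1."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0 or control.mean() <= 0:
        raise ValueError("control mean must be > 0")
    scale = control.mean()
    return [float(v) / scale for v in np.asarray(values, dtype=float)]


def dqbsa_ratio(
    image: MultiChannelImage,
    reporter_channel: str,
    structure_masks: Sequence[np.ndarray],
    marker_flags: Sequence[bool],
    cytosol_mask: np.ndarray,
    n_background_rois: int = 4,
    rng_seed: int = 0,
) -> List[RatioRecord]:
    """Structure/background ratios of a proteolysis reporter.

    Per cell, the background is the mean reporter intensity of
    ``n_background_rois`` square ROIs sampled (seeded, reproducible) from
    the cytosol outside every structure; each structure's ratio is its mean
    reporter signal over that background.  ``marker_flags`` mark which
    structures are GVB-marker positive so the two ratio populations can be
    compared downstream.
    """
    if len(structure_masks) != len(marker_flags):
        raise ValueError("structure_masks and marker_flags lengths differ")
    raster = image.get(reporter_channel)
    occupied = np.zeros(raster.shape, dtype=bool)
    diameters = []
    for mask in structure_masks:
        occupied |= mask.astype(bool)
        diameters.append(2.0 * math.sqrt(mask.sum() / math.pi))
    eligible = cytosol_mask.astype(bool) & ~ndi.binary_dilation(
        occupied, iterations=2
    )
    side = max(int(round(np.median(diameters))) if diameters else 3, 2)
    # positions where a side x side square fits entirely in eligible cytosol
    fits = ndi.minimum_filter(eligible, size=side, mode="constant", cval=False)
    valid = np.argwhere(fits)
    if len(valid) < n_background_rois:
        raise InsufficientBackgroundError(
            f"only {len(valid)} candidate background positions for "
            f"{n_background_rois} ROIs"
        )
    rng = np.random.default_rng(rng_seed)
    picks = valid[rng.choice(len(valid), size=n_background_rois, replace=False)]
    half = side // 2
    roi_means = []
    for r, c in picks:
        sl = (
            slice(r - half, r - half + side),
            slice(c - half, c - half + side),
        )
        roi_means.append(raster[sl].mean())
    background = float(np.mean(roi_means))
    if background <= 0:
        raise InsufficientBackgroundError("background mean is not positive")
    records = []
    for idx, (mask, flag) in enumerate(zip(structure_masks, marker_flags), start=1):
        records.append(
            RatioRecord(
                structure_id=idx,
                marker_positive=bool(flag),
                signal_au=float(raster[mask.astype(bool)].mean()),
                background_au=background,
            )
        )
    return records


def frequency_distribution(
    ratios: Sequence[float], bin_width: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of ratios as percentages in half-open bins [k·w, (k+1)·w).

    Returns ``(bin_edges, percentages)``; percentages sum to 100.  A value
    exactly on the top data value still falls in a half-open bin because the
    edge grid always extends one bin past the maximum.
    """
    vals = np.asarray(ratios, dtype=float)
    if vals.size == 0:
        raise ValueError("ratio list is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(math.floor(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts * (100.0 / vals.size)


def gvb_cytosol_ratio(
    image: MultiChannelImage,
    reporter_channel: str,
    gvb_marker_channel: str = "gvb",
    soma_channel: str = "soma",
    cfg: Optional[SegmentationConfig] = None,
) -> float:
    """Reporter GVB/cytosol intensity ratio for one cell's field.

    GVB ROIs come from a threshold in the GVB-marker channel; the cytosolic
    background ROI is the thresholded soma mask excluding (dilated) GVB
    ROIs.  Raises :class:`NoGVBError` when no GVB ROI is detected, so the
    caller can skip the cell with a logged reason.
    """
    cfg = cfg or SegmentationConfig()
    marker = image.get(gvb_marker_channel)
    thr = _threshold_value(marker, cfg.threshold_method, cfg.threshold_k)
    detected = marker > thr
    peak_floor = marker.mean() + cfg.min_peak_k * marker.std()
    if not detected.any() or marker[detected].max() < peak_floor:
        raise NoGVBError("no GVB ROI detected")
    # refine each detected object at half of its peak above background so
    # the ROI covers the bright structure, not its blur skirt
    background = float(marker[~detected].mean()) if (~detected).any() else 0.0
    labels, n = ndi.label(detected)
    gvb_roi = np.zeros_like(detected)
    for lbl in range(1, n + 1):
        piece = labels == lbl
        peak = marker[piece].max()
        if peak < peak_floor:
            continue
        cut = background + 0.5 * (peak - background)
        gvb_roi |= piece & (marker >= cut)
    if not gvb_roi.any():
        raise NoGVBError("no GVB ROI detected")
    soma_raster = image.get(soma_channel)
    soma_mask = soma_raster > _threshold_value(soma_raster, "otsu", 0.0)
    cytosol = soma_mask & ~ndi.binary_dilation(detected, iterations=2)
    if not cytosol.any():
        raise EmptyMaskError("no cytosol outside GVB ROIs")
    reporter = image.get(reporter_channel)
    return float(reporter[gvb_roi].mean() / reporter[cytosol].mean())


def line_profile(
    image: MultiChannelImage,
    p0: Tuple[float, float],
    p1: Tuple[float, float],
    n_samples: int = 100,
) -> LineProfile:
    """Bilinear-interpolated intensity profile along a line segment."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("zero-length segment")
    shape = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= shape[0] - 1 and 0 <= p[1] <= shape[1] - 1):
            raise ValueError(f"endpoint {tuple(p)} outside image")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    distances = t * np.hypot(*(p1 - p0)) * image.pixel_size_um
    intensity = {
        role: ndi.map_coordinates(
            image.channels[role], np.vstack([rows, cols]), order=1
        )
        for role in image.roles()
    }
    return LineProfile(
        endpoints_px=(tuple(p0), tuple(p1)),
        sample_positions_um=distances,
        intensity=intensity,
    )


def classify_gvb_morphology(
    cores: Sequence[GVBCore],
    ring_masks: Sequence[np.ndarray],
    pixel_size_um: float,
    fill_fraction_threshold: float = 0.8,
) -> Dict[str, object]:
    """Tally GVB morphology classes: single, multiple or filling core.

    Per ring interior: ``multiple`` when two or more cores lie inside;
    otherwise ``filling`` when the core covers at least
    ``fill_fraction_threshold`` of the interior area; otherwise ``single``.
    Cores enclosed by no ring are counted separately as ``unenclosed`` and
    excluded from the percentages.
    """
    counts = {"single": 0, "multiple": 0, "filling": 0}
    assigned = set()
    px_area = pixel_size_um ** 2
    for mask in ring_masks:
        inside = []
        for i, core in enumerate(cores):
            r, c = int(round(core.centroid_px[0])), int(round(core.centroid_px[1]))
            if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
                inside.append(i)
        if not inside:
            continue
        assigned.update(inside)
        if len(inside) >= 2:
            counts["multiple"] += 1
        else:
            interior_area = mask.sum() * px_area
            core_area = cores[inside[0]].area_um2
            if core_area >= fill_fraction_threshold * interior_area:
                counts["filling"] += 1
            else:
                counts["single"] += 1
    n_rings = sum(counts.values())
    percentages = {
        k: (100.0 * v / n_rings if n_rings else float("nan"))
        for k, v in counts.items()
    }
    return {
        **counts,
        "unenclosed": len(cores) - len(assigned),
        "percentages": percentages,
    }
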