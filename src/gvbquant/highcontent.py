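"""Automated (high-content) microscopy pipeline: per-well tau-pathology and
GVB loads with background subtraction and the three normalization schemes
used for plate-based experiments.

GVB load is measured by detecting bright puncta in a background-removed GVB
marker channel, filtering them on intensity, area and circularity, and
clustering puncta within a soma-scale distance into one object per neuron.
Tau pathology load is the summed pathological-tau signal within the
somatodendritic-marker mask.  Per-well observations are then corrected
against control wells and rescaled with one of three schemes: normalization
to the control condition, mean-of-top-two = 100, or per-experiment
min–max to a 0–100% scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import measure as skmeasure

from .confocal import SegmentationConfig, _split_objects, _threshold_value
from .image import MultiChannelImage

__all__ = [
    "PunctaCriteria",
    "Punctum",
    "WellObservation",
    "count_nuclei",
    "remove_background",
    "detect_puncta",
    "cluster_puncta",
    "tau_pathology_load",
    "measure_well",
    "background_subtract",
    "normalize_top2",
    "normalize_minmax",
    "load_ratio",
]


@dataclass
class PunctaCriteria:
    """Intensity and morphology criteria for accepting a punctum.

    Defaults: area 0.1–2.0 µm² (GVB cores average ~0.45 µm²), circularity
    (4πA/P²) at least 0.6, peak at least ``min_intensity`` AU above the
    removed background, puncta within ``cluster_distance_um`` merged into
    one neuron-level object (≈ a soma radius, ~8 µm for mouse hippocampal
    neurons at the generator's soma size).
    """

    min_intensity: float = 5.0
    area_range_um2: Tuple[float, float] = (0.1, 2.0)
    min_circularity: float = 0.6
    cluster_distance_um: float = 8.0
    smooth_sigma_um: float = 0.2   # punctum-scale denoising before threshold

    def validate(self) -> None:
        lo, hi = self.area_range_um2
        if not (0 < lo < hi):
            raise ValueError("area_range_um2 must be positive and ordered")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must be in [0, 1]")
        if self.cluster_distance_um <= 0:
            raise ValueError("cluster_distance_um must be > 0")


@dataclass
class Punctum:
    centroid_px: Tuple[float, float]
    area_um2: float
    peak_au: float
    circularity: float


@dataclass
class WellObservation:
    """One well's observation: counts and loads, raw through normalized."""

    well_id: str
    tau_expression: bool = True
    dose_nM: float = 0.0
    control: bool = False
    region: str = "hippocampus"
    n_nuclei: int = 0
    tau_load_raw: float = 0.0
    gvb_load_raw: float = 0.0
    tau_load_corrected: Optional[float] = None
    gvb_load_corrected: Optional[float] = None
    tau_load_norm: Optional[float] = None
    gvb_load_norm: Optional[float] = None
    experiment: str = "exp1"

    def corrected(self, field_name: str) -> float:
        value = getattr(self, f"{field_name}_load_corrected")
        if value is None:
            raise ValueError(
                f"{field_name} load not background-subtracted yet for {self.well_id}"
            )
        return value


# ---------------------------------------------------------------------------
# Image-level measurements
# ---------------------------------------------------------------------------

def count_nuclei(
    image: MultiChannelImage,
    nuclei_channel: str = "nuclei",
    min_area_um2: float = 8.0,
    split_h: float = 2.0,
) -> int:
    """Count nuclei: threshold the DNA stain, watershed-split touching
    nuclei, reject sub-nuclear specks.  A blank image counts zero."""
    raster = image.get(nuclei_channel)
    thr = _threshold_value(raster, "mean_sd", 3.0)
    binary = ndi.binary_fill_holes(raster > thr)
    if not binary.any():
        return 0
    labels = _split_objects(binary, split_h)
    min_px = min_area_um2 / image.pixel_area_um2
    counts = np.bincount(labels.ravel())[1:]
    return int((counts >= min_px).sum())


def remove_background(
    image: MultiChannelImage, channel: str, scale_um: float
) -> np.ndarray:
    """Subtract a morphological-opening estimate of smooth background.

    A grey opening with a flat square structuring element of side
    ``2·scale_um`` erases structures smaller than the element while
    following smooth, continuous background; the residual keeps puncta
    amplitudes within ~10% and maps a constant image to ~0.  ``scale_um``
    must exceed the largest punctum diameter (and the pixel size).
    """
    if scale_um < image.pixel_size_um:
        raise ValueError("scale_um must be at least one pixel")
    raster = image.get(channel)
    size = 2 * int(round(scale_um / image.pixel_size_um)) + 1
    # opening of the raw raster would track the lower noise envelope and
    # bias the residual positive; estimate the background on a lightly
    # smoothed copy and re-center the residual at its median
    smooth = ndi.gaussian_filter(raster, 1.0)
    background = ndi.grey_opening(smooth, size=(size, size), mode="nearest")
    residual = raster - background
    return residual - np.median(residual)


def detect_puncta(
    residual: np.ndarray,
    pixel_size_um: float,
    criteria: Optional[PunctaCriteria] = None,
) -> List[Punctum]:
    """Select bright punctate signal from a background-removed raster.

    Connected regions above ``criteria.min_intensity`` are kept when their
    area lies in ``area_range_um2`` and their circularity 4πA/P² reaches
    ``min_circularity`` (clipped at 1 for few-pixel regions whose discrete
    perimeter underestimates a circle).
    """
    criteria = criteria or PunctaCriteria()
    criteria.validate()
    work = residual
    if criteria.smooth_sigma_um > 0:
        # matched-filter-like denoising at the punctum scale suppresses
        # single-pixel noise excursions without moving punctum peaks; the
        # smoothed raster only *detects* regions — each punctum is then
        # re-masked on the raw residual so its area is not blurred outward
        work = ndi.gaussian_filter(residual, criteria.smooth_sigma_um / pixel_size_um)
    detected = work > criteria.min_intensity
    if not detected.any():
        return []
    labels, _ = ndi.label(detected)
    refined = np.where(residual > criteria.min_intensity, labels, 0)
    px_area = pixel_size_um ** 2
    lo, hi = criteria.area_range_um2
    puncta = []
    for region in skmeasure.regionprops(refined, intensity_image=residual):
        area = region.area * px_area
        if not (lo <= area <= hi):
            continue
        perimeter = region.perimeter
        circ = 1.0 if perimeter == 0 else min(
            4 * math.pi * region.area / perimeter ** 2, 1.0
        )
        if circ < criteria.min_circularity:
            continue
        puncta.append(
            Punctum(
                centroid_px=tuple(region.centroid),
                area_um2=float(area),
                peak_au=float(region.intensity_max),
                circularity=float(circ),
            )
        )
    return puncta


def cluster_puncta(
    puncta: Sequence, cluster_distance_um: float, pixel_size_um: float = 1.0
) -> int:
    """Number of neuron-level objects after single-linkage clustering.

    Puncta whose centroids lie within ``cluster_distance_um`` of each other
    are merged transitively (single linkage); the cluster count estimates
    the number of GVB-positive neurons.  Accepts :class:`Punctum` objects
    or raw coordinate pairs (then ``pixel_size_um`` converts px to µm).
    """
    if cluster_distance_um <= 0:
        raise ValueError("cluster_distance_um must be > 0")
    if len(puncta) == 0:
        return 0
    pts = np.array(
        [
            (p.centroid_px if hasattr(p, "centroid_px") else tuple(p))
            for p in puncta
        ],
        dtype=float,
    ) * pixel_size_um
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cluster_distance_um, output_type="ndarray")
    n = len(pts)
    graph = csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_components, _ = connected_components(graph, directed=False)
    return int(n_components)


def tau_pathology_load(
    image: MultiChannelImage,
    tau_channel: str = "tau",
    soma_channel: str = "soma",
) -> float:
    """Summed tau signal within the somatodendritic mask, per image µm².

    The soma/dendrite marker is thresholded (Otsu) to delineate the
    neuronal ROI; tau intensity above the off-mask background level is
    summed inside it and divided by the image area so loads are comparable
    across fields.  An empty mask yields a zero load.
    """
    tau = image.get(tau_channel)
    soma = image.get(soma_channel)
    thr = _threshold_value(soma, "otsu", 0.0)
    mask = soma > thr
    if not mask.any():
        return 0.0
    background = float(np.median(tau[~mask])) if (~mask).any() else 0.0
    signal = tau[mask] - background
    image_area = tau.size * image.pixel_area_um2
    return float(np.clip(signal, 0, None).sum() / image_area)


def measure_well(
    image: MultiChannelImage,
    well_id: str,
    criteria: Optional[PunctaCriteria] = None,
    background_scale_um: float = 1.5,
    gvb_channel: str = "gvb",
    **condition,
) -> WellObservation:
    """Raw per-well observation from one field: nuclei count, tau load and
    GVB load (clustered puncta count)."""
    criteria = criteria or PunctaCriteria()
    residual = remove_background(image, gvb_channel, background_scale_um)
    puncta = detect_puncta(residual, image.pixel_size_um, criteria)
    gvb_load = cluster_puncta(
        puncta, criteria.cluster_distance_um, image.pixel_size_um
    )
    return WellObservation(
        well_id=well_id,
        n_nuclei=count_nuclei(image),
        tau_load_raw=tau_pathology_load(image),
        gvb_load_raw=float(gvb_load),
        **condition,
    )


# ---------------------------------------------------------------------------
# Well-level corrections and normalizations
# ---------------------------------------------------------------------------

def background_subtract(
    observations: Sequence[WellObservation], clip_at_zero: bool = False
) -> List[WellObservation]:
    """Subtract the control-condition mean from every well's loads.

    The mean raw load over wells flagged ``control`` is subtracted from the
    tau and GVB loads of all wells (separately per read-out), making the
    control's mean corrected load exactly 0.  Corrected loads may dip below
    zero by noise and are not clipped unless requested.
    """
    controls = [o for o in observations if o.control]
    if not controls:
        raise ValueError("no control wells present")
    tau_bg = float(np.mean([o.tau_load_raw for o in controls]))
    gvb_bg = float(np.mean([o.gvb_load_raw for o in controls]))
    for obs in observations:
        tau_c = obs.tau_load_raw - tau_bg
        gvb_c = obs.gvb_load_raw - gvb_bg
        if clip_at_zero:
            tau_c, gvb_c = max(tau_c, 0.0), max(gvb_c, 0.0)
        obs.tau_load_corrected = tau_c
        obs.gvb_load_corrected = gvb_c
    return list(observations)


def normalize_top2(
    observations: Sequence[WellObservation], field_name: str
) -> np.ndarray:
    """Rescale so the mean of the two largest corrected loads is 100.

    ``field_name`` is ``"tau"`` or ``"gvb"``.  The scale factor is
    100 / mean(two largest values); ranks are preserved.  Sets the
    ``*_load_norm`` fields and returns the normalized values.
    """
    values = np.array([o.corrected(field_name) for o in observations])
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    top2 = np.sort(values)[-2:]
    if top2.mean() <= 0:
        raise ValueError("top-two mean must be > 0")
    scaled = values * (100.0 / top2.mean())
    for obs, v in zip(observations, scaled):
        setattr(obs, f"{field_name}_load_norm", float(v))
    return scaled


def normalize_minmax(
    observations: Sequence[WellObservation], field_name: str
) -> np.ndarray:
    """Per-experiment min–max rescaling to a 0–100% scale.

    Within each experiment group the lowest corrected load maps to 0% and
    the highest to 100%; invariant to positive affine transforms of the
    input.  Sets the ``*_load_norm`` fields and returns the values in input
    order.
    """
    out = np.empty(len(observations))
    by_exp: Dict[str, List[int]] = {}
    for i, obs in enumerate(observations):
        by_exp.setdefault(obs.experiment, []).append(i)
    for indices in by_exp.values():
        values = np.array([observations[i].corrected(field_name) for i in indices])
        lo, hi = values.min(), values.max()
        if hi == lo:
            raise ValueError("degenerate range: max == min within experiment")
        scaled = 100.0 * (values - lo) / (hi - lo)
        for i, v in zip(indices, scaled):
            out[i] = v
            setattr(observations[i], f"{field_name}_load_norm", float(v))
    return out


def load_ratio(
    observations: Sequence[WellObservation],
    reference_region: str = "hippocampus",
) -> Tuple[Dict[str, float], int]:
    """Per-well GVB/tau load ratio, scaled so the reference-region mean is 1.

    Wells with non-positive corrected tau load cannot yield a meaningful
    ratio and are excluded; their count is returned alongside the ratios.
    """
    raw: Dict[str, float] = {}
    excluded = 0
    for obs in observations:
        tau = obs.corrected("tau")
        if tau <= 0:
            excluded += 1
            continue
        raw[obs.well_id] = obs.corrected("gvb") / tau
    reference = [
        v
        for obs in observations
        if obs.region == reference_region and obs.well_id in raw
        for v in [raw[obs.well_id]]
    ]
    if not reference:
        raise ValueError(f"no usable wells in reference region {reference_region!r}")
    scale = float(np.mean(reference))
    return {well: v / scale for well, v in raw.items()}, excluded
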