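"""Synthetic fluorescence-microscopy generator with per-cell ground truth.

The generator emulates the two imaging regimes of a tau-seeding GVB
(granulovacuolar degeneration body) experiment:

* confocal fields of cultured neurons — DAPI nuclei, MAP2-like somata with
  dendrites, bright somatic GVB-core puncta, LIMP2-like membrane rings
  around the cores, diffuse versus aggregated tau, and a DQ-BSA proteolysis
  reporter;
* high-content screening wells — the same scene at lower magnification.

Every rendered structure is recorded in a :class:`GroundTruth` object so
downstream segmentation, classification and load measurements can be scored
against known answers.  The per-cell status model is the joint distribution

    tau+  ~ Bernoulli(p_tau)
    GVB+ | tau+  ~ Bernoulli(p_gvb_given_tau)
    GVB+ | tau-  ~ Bernoulli(p_gvb_given_no_tau)

whose defaults are calibrated so that P(GVB+ | tau+) = 0.35 and
P(tau+ | GVB+) = 0.80, the co-occurrence reported for PFF-seeded
hippocampus.  All intensities are in arbitrary units (AU) on a documented
but arbitrary scale; fluorescence acquisition gain is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .image import MultiChannelImage

__all__ = [
    "PopulationParams",
    "OpticsParams",
    "GVBTruth",
    "LysosomeTruth",
    "CellTruth",
    "GroundTruth",
    "PlacementError",
    "generate_population",
    "render_image",
    "render_stack",
    "generate_dose_response",
    "dose_ladder_params",
    "generate_well_loads",
    "lattice_disk_pixels",
    "confocal_optics",
    "hcs_optics",
    "survey_optics",
]


# Rendering amplitudes (AU).  The absolute scale is arbitrary; only the
# relations matter: cores and aggregates are bright, cytosolic fills are
# moderate, read noise (default SD 1) is small against all of them.
NUCLEUS_AMP = 40.0
SOMA_AMP = 20.0
DENDRITE_AMP = 12.0
GVB_CYTO_AMP = 3.0
CORE_AMP = 60.0
MEMBRANE_AMP = 30.0
DQBSA_CYTO_AMP = 40.0
BACKGROUND_OFFSET = 2.0

# Log-normal parameters of the true DQ-BSA structure/background ratio,
# chosen as the unique log-normal with P(ratio > 1) = 0.91 and
# P(ratio > 2) = 0.46 — the measured exceedance fractions for GVBs.
DQBSA_LOGNORM_MU = 0.6447
DQBSA_LOGNORM_SIGMA = 0.4812

# Morphology mix of GVB structures (single / multiple / filling core),
# matching the super-resolution tally: 59% / 12% / 29%.
MORPHOLOGY_PROBS = (0.59, 0.12, 0.29)


class PlacementError(RuntimeError):
    """Raised when somata cannot be placed without overlap."""


@dataclass
class PopulationParams:
    """Generating parameters of one condition's neuron population.

    Defaults are the in vitro PFF-seeding study conditions: co-occurrence
    probabilities that reproduce P(GVB+|tau+) = 0.35 together with
    P(tau+|GVB+) = 0.80, and a mean GVB core area of 0.45 µm².
    """

    n_cells: int = 100
    p_tau: float = 0.5
    p_gvb_given_tau: float = 0.35
    p_gvb_given_no_tau: float = 0.0875
    gvb_count_mean: float = 3.0       # GVB structures per GVB+ cell (>= 1)
    core_area_mean_um2: float = 0.45
    core_area_sd_um2: float = 0.15
    soma_area_mean_um2: float = 160.0
    tau_intensity_levels: Tuple[float, float, float] = (1.0, 8.0, 25.0)
    dose: Optional[float] = None      # seed concentration label, nM
    lysosomes_per_cell_mean: float = 4.0
    morphology_probs: Tuple[float, float, float] = MORPHOLOGY_PROBS
    dqbsa_lognorm_mu: float = DQBSA_LOGNORM_MU
    dqbsa_lognorm_sigma: float = DQBSA_LOGNORM_SIGMA
    # where the reporter accumulates inside a GVB: "lumen" for an endocytic
    # proteolysis reporter filling the vacuole, "core" for a cytosolic cargo
    # that concentrates in the dense core
    reporter_target: str = "lumen"

    def validate(self) -> None:
        for name in ("p_tau", "p_gvb_given_tau", "p_gvb_given_no_tau"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in (
            "gvb_count_mean",
            "core_area_mean_um2",
            "core_area_sd_um2",
            "soma_area_mean_um2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(level < 0 for level in self.tau_intensity_levels):
            raise ValueError("tau_intensity_levels must be >= 0")
        if abs(sum(self.morphology_probs) - 1.0) > 1e-9:
            raise ValueError("morphology_probs must sum to 1")


@dataclass
class OpticsParams:
    """Forward-model optics: sampling, blur, background and noise.

    Stands in for the study's 60x/NA 1.4 confocal (``confocal_optics``) and
    20x high-content platform (``hcs_optics``); not a physical PSF model.
    """

    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.1
    background_gradient_amp: float = 3.0
    gaussian_sd: float = 1.0
    poisson_scaling: float = 0.0      # photons per AU; 0 disables shot noise
    image_shape: Tuple[int, int] = (512, 512)
    n_z: int = 1

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if min(self.image_shape) < 64:
            raise ValueError("image_shape must be at least 64x64")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um


def confocal_optics(**overrides) -> OpticsParams:
    """High-magnification optics (0.1 µm/px) for per-cell quantification."""
    return replace(OpticsParams(), **overrides)


def survey_optics(**overrides) -> OpticsParams:
    """Large-field optics (0.25 µm/px, 1536 px) for population surveys."""
    base = OpticsParams(
        pixel_size_um=0.25, psf_sigma_um=0.2, image_shape=(1536, 1536)
    )
    return replace(base, **overrides)


def hcs_optics(**overrides) -> OpticsParams:
    """High-content screening optics (20x-like, 0.325 µm/px)."""
    base = OpticsParams(
        pixel_size_um=0.325, psf_sigma_um=0.3, image_shape=(640, 640)
    )
    return replace(base, **overrides)


@dataclass
class GVBTruth:
    """One GVB structure: core(s) plus, usually, a delineating membrane."""

    center: Tuple[float, float]                  # (row, col), px
    core_area_um2: float                         # per-core area
    has_ring: bool
    n_cores_in_ring: int
    ring_inner_radius_px: float                  # interior radius of the ring
    core_centers: List[Tuple[float, float]]
    dqbsa_ratio_true: float
    morphology: str                              # "single" | "multiple" | "filling"

    def ring_interior_area_um2(self, pixel_size_um: float) -> float:
        return math.pi * self.ring_inner_radius_px ** 2 * pixel_size_um ** 2


@dataclass
class LysosomeTruth:
    """A non-GVB lysosomal structure: membrane ring, no GVB-marker core."""

    center: Tuple[float, float]
    interior_radius_px: float
    dqbsa_ratio_true: float


@dataclass
class CellTruth:
    """Ground truth for one neuron."""

    cell_id: int
    center: Tuple[float, float]
    nucleus_center: Tuple[float, float]
    offset: Tuple[int, int]              # top-left of the cropped masks
    soma_mask: np.ndarray                # bool, cropped to the soma bbox
    nucleus_mask: np.ndarray             # bool, same crop as soma_mask
    soma_area_um2: float
    tau_status: bool
    tau_intensity: float                 # diffuse AU level of this cell
    gvb_status: bool
    gvb_list: List[GVBTruth] = field(default_factory=list)
    lysosomes: List[LysosomeTruth] = field(default_factory=list)
    aggregates: List[Tuple[float, float, float]] = field(default_factory=list)
    # aggregates: (row, col, radius_px)

    def soma_pixels(self) -> Tuple[np.ndarray, np.ndarray]:
        rr, cc = np.nonzero(self.soma_mask)
        return rr + self.offset[0], cc + self.offset[1]

    def nucleus_pixels(self) -> Tuple[np.ndarray, np.ndarray]:
        rr, cc = np.nonzero(self.nucleus_mask)
        return rr + self.offset[0], cc + self.offset[1]


@dataclass
class GroundTruth:
    """Ground truth for one rendered field of view."""

    cells: List[CellTruth]
    condition: str
    seed: int
    image_shape: Tuple[int, int]
    pixel_size_um: float
    reporter_target: str = "lumen"

    def soma_label_image(self) -> np.ndarray:
        labels = np.zeros(self.image_shape, dtype=np.int32)
        for cell in self.cells:
            rr, cc = cell.soma_pixels()
            labels[rr, cc] = cell.cell_id
        return labels

    @property
    def n_tau_positive(self) -> int:
        return sum(c.tau_status for c in self.cells)

    @property
    def n_gvb_positive(self) -> int:
        return sum(c.gvb_status for c in self.cells)

    @property
    def n_double_positive(self) -> int:
        return sum(c.tau_status and c.gvb_status for c in self.cells)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def lattice_disk_pixels(
    center: Tuple[float, float], area_px: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Pixels of a rasterized disk of a requested area.

    The disk is the union of complete lattice-distance shells around
    ``center``, truncated at the shell whose cumulative pixel count is
    closest to ``area_px``.  For an integer center this reproduces the
    lattice-point count of an integer-radius disk (e.g. a 0.50 µm² request
    at 0.1 µm/px yields the 49 pixels within radius 4), and it makes the
    rendered area an exact, countable quantity for segmentation oracles.
    """
    if area_px < 1:
        area_px = 1.0
    r_max = math.sqrt(area_px / math.pi) + 3.0
    cr, cc = center
    r0, c0 = int(round(cr)), int(round(cc))
    extent = int(math.ceil(r_max))
    rows = np.arange(r0 - extent, r0 + extent + 1)
    cols = np.arange(c0 - extent, c0 + extent + 1)
    rr, cc2 = np.meshgrid(rows, cols, indexing="ij")
    d2 = (rr - cr) ** 2 + (cc2 - cc) ** 2
    flat_r = rr.ravel()
    flat_c = cc2.ravel()
    flat_d2 = np.round(d2.ravel(), 9)
    order = np.argsort(flat_d2, kind="stable")
    flat_r, flat_c, flat_d2 = flat_r[order], flat_c[order], flat_d2[order]
    # complete shells: cut only where the distance value changes
    boundaries = np.nonzero(np.diff(flat_d2))[0] + 1
    cumulative = np.concatenate([boundaries, [flat_d2.size]])
    best = cumulative[np.argmin(np.abs(cumulative - area_px))]
    return flat_r[:best], flat_c[:best]


def _smooth_blob_mask(
    rng: np.random.Generator, radius_px: float
) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Random convex-ish blob as a cropped boolean mask plus local center.

    Radial profile is 1 plus a few low-order Fourier modes, clipped to
    [0.75, 1.25] so the blob stays within 1.25x the nominal radius.
    """
    n_vert = 48
    theta = np.linspace(0, 2 * math.pi, n_vert, endpoint=False)
    wobble = np.zeros(n_vert)
    for k in range(2, 6):
        amp = rng.normal(0.0, 0.05)
        phase = rng.uniform(0, 2 * math.pi)
        wobble += amp * np.cos(k * theta + phase)
    radii = radius_px * np.clip(1.0 + wobble, 0.75, 1.25)
    size = int(math.ceil(radius_px * 1.3)) * 2 + 3
    c = size // 2
    rr = c + radii * np.sin(theta)
    cc = c + radii * np.cos(theta)
    mask = np.zeros((size, size), dtype=bool)
    pr, pc = skdraw.polygon(rr, cc, shape=mask.shape)
    mask[pr, pc] = True
    return mask, (c, c)


def _nucleus_mask_like(
    rng: np.random.Generator, soma_mask: np.ndarray, local_center: Tuple[int, int],
    soma_radius_px: float,
) -> np.ndarray:
    """Elliptical nucleus mask in the soma's crop frame."""
    a = soma_radius_px * rng.uniform(0.42, 0.52)
    b = soma_radius_px * rng.uniform(0.32, 0.42)
    angle = rng.uniform(0, math.pi)
    rr, cc = skdraw.ellipse(
        local_center[0], local_center[1], a, b, shape=soma_mask.shape, rotation=angle
    )
    mask = np.zeros_like(soma_mask)
    mask[rr, cc] = True
    return mask & soma_mask


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def generate_population(
    params: PopulationParams,
    optics: OpticsParams,
    rng_seed: int,
) -> GroundTruth:
    """Draw a neuron population with per-cell tau/GVB ground truth.

    Cell statuses are drawn independently per cell from the joint model in
    the module docstring.  Somata are placed by rejection sampling (500
    retries per cell) so that no two masks overlap; a :class:`PlacementError`
    is raised when ``params.n_cells`` exceeds the field's capacity.
    Deterministic for fixed ``(params, optics, rng_seed)``.
    """
    params.validate()
    optics.validate()
    rng = np.random.default_rng(rng_seed)
    px = optics.pixel_size_um
    shape = optics.image_shape
    r0_nominal = math.sqrt(params.soma_area_mean_um2 / math.pi) / px

    centers: List[Tuple[float, float]] = []
    radii: List[float] = []
    cells: List[CellTruth] = []
    for cell_id in range(1, params.n_cells + 1):
        r0 = r0_nominal * rng.uniform(0.85, 1.15)
        margin = 1.3 * r0 + 2
        if 2 * margin >= min(shape):
            raise PlacementError(
                f"soma radius {r0:.1f} px does not fit image shape {shape}"
            )
        placed = False
        for _ in range(500):
            cand = (
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            )
            ok = True
            for (pr, pc), pradius in zip(centers, radii):
                if (cand[0] - pr) ** 2 + (cand[1] - pc) ** 2 < (
                    1.3 * (r0 + pradius) + 2
                ) ** 2:
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {cell_id}/{params.n_cells} after 500 "
                f"retries; reduce n_cells or enlarge image_shape"
            )
        centers.append(cand)
        radii.append(r0)

        blob, local_center = _smooth_blob_mask(rng, r0)
        offset = (
            int(round(cand[0])) - local_center[0],
            int(round(cand[1])) - local_center[1],
        )
        nucleus = _nucleus_mask_like(rng, blob, local_center, r0)

        tau_status = bool(rng.random() < params.p_tau)
        p_gvb = params.p_gvb_given_tau if tau_status else params.p_gvb_given_no_tau
        gvb_status = bool(rng.random() < p_gvb)
        tau_intensity = (
            params.tau_intensity_levels[1] if tau_status
            else params.tau_intensity_levels[0]
        )

        cell = CellTruth(
            cell_id=cell_id,
            center=cand,
            nucleus_center=(float(cand[0]), float(cand[1])),
            offset=offset,
            soma_mask=blob,
            nucleus_mask=nucleus,
            soma_area_um2=float(blob.sum()) * px ** 2,
            tau_status=tau_status,
            tau_intensity=tau_intensity,
            gvb_status=gvb_status,
        )
        _populate_structures(cell, params, px, rng)
        if tau_status:
            _populate_aggregates(cell, params, px, rng)
        cells.append(cell)

    condition = "buffer" if not params.dose else f"{params.dose:g}nM"
    return GroundTruth(
        cells=cells,
        condition=condition,
        seed=int(rng_seed),
        image_shape=tuple(shape),
        pixel_size_um=px,
        reporter_target=params.reporter_target,
    )


def _interior_coords(cell: CellTruth, margin_px: float) -> np.ndarray:
    """Coordinates (local frame) at least margin_px inside the soma."""
    dist = ndi.distance_transform_edt(cell.soma_mask)
    rr, cc = np.nonzero(dist > margin_px)
    return np.column_stack([rr, cc])


def _populate_structures(
    cell: CellTruth, params: PopulationParams, px: float, rng: np.random.Generator
) -> None:
    """Draw GVB structures (if GVB+) and plain lysosomes for one cell."""
    core_radius_nominal = math.sqrt(params.core_area_mean_um2 / math.pi) / px

    def draw_ratio() -> float:
        return float(
            rng.lognormal(params.dqbsa_lognorm_mu, params.dqbsa_lognorm_sigma)
        )

    taken: List[Tuple[float, float, float]] = []  # (row, col, radius) local frame

    def place(margin: float) -> Optional[Tuple[float, float]]:
        coords = _interior_coords(cell, margin)
        if coords.size == 0:
            return None
        for _ in range(50):
            r, c = coords[rng.integers(len(coords))]
            jitter = rng.uniform(-0.5, 0.5, size=2)
            cand = (float(r) + jitter[0], float(c) + jitter[1])
            if all(
                (cand[0] - tr) ** 2 + (cand[1] - tc) ** 2 > (margin + tradius) ** 2
                for tr, tc, tradius in taken
            ):
                return cand
        return None

    if cell.gvb_status:
        n_structures = 1 + int(rng.poisson(max(params.gvb_count_mean - 1.0, 0.0)))
        for _ in range(n_structures):
            area = max(
                rng.normal(params.core_area_mean_um2, params.core_area_sd_um2),
                0.05,
            )
            core_r = math.sqrt(area / math.pi) / px
            morph = ("single", "multiple", "filling")[
                rng.choice(3, p=params.morphology_probs)
            ]
            if morph == "single":
                fill = rng.uniform(0.2, 0.45)
                ring_r = core_r / math.sqrt(fill)
                n_cores = 1
            elif morph == "filling":
                fill = rng.uniform(0.85, 0.95)
                ring_r = core_r / math.sqrt(fill)
                n_cores = 1
            else:
                # a wider vacuole holding 2-3 cores of the same size class
                n_cores = int(rng.integers(2, 4))
                ring_r = 3.2 * core_r
            center = place(ring_r + 3.5)
            if center is None:
                continue
            if n_cores == 1:
                core_centers = [center]
            else:
                core_centers = []
                base_ang = rng.uniform(0, 2 * math.pi)
                sector = 2 * math.pi / n_cores
                for k in range(n_cores):
                    ang = base_ang + k * sector + rng.uniform(-0.2, 0.2) * sector
                    rad = (ring_r - core_r - 0.5) * rng.uniform(0.8, 0.95)
                    core_centers.append(
                        (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
                    )
            taken.append((center[0], center[1], ring_r + 2.5))
            off = cell.offset
            cell.gvb_list.append(
                GVBTruth(
                    center=(center[0] + off[0], center[1] + off[1]),
                    core_area_um2=float(area),
                    has_ring=True,
                    n_cores_in_ring=n_cores,
                    ring_inner_radius_px=float(ring_r),
                    core_centers=[(r + off[0], c + off[1]) for r, c in core_centers],
                    dqbsa_ratio_true=draw_ratio(),
                    morphology=morph,
                )
            )
        if not cell.gvb_list:
            # rejection placement failed for every structure: fall back to
            # the deepest interior point so the drawn status is never lost
            dist = ndi.distance_transform_edt(cell.soma_mask)
            r, c = np.unravel_index(np.argmax(dist), dist.shape)
            area = params.core_area_mean_um2
            core_r = math.sqrt(area / math.pi) / px
            ring_r = core_r / math.sqrt(0.4)
            off = cell.offset
            cell.gvb_list.append(
                GVBTruth(
                    center=(float(r) + off[0], float(c) + off[1]),
                    core_area_um2=float(area),
                    has_ring=True,
                    n_cores_in_ring=1,
                    ring_inner_radius_px=float(ring_r),
                    core_centers=[(float(r) + off[0], float(c) + off[1])],
                    dqbsa_ratio_true=draw_ratio(),
                    morphology="single",
                )
            )

    n_lyso = int(rng.poisson(params.lysosomes_per_cell_mean))
    lyso_r = max(core_radius_nominal * 0.8, 1.2)
    for _ in range(n_lyso):
        center = place(lyso_r + 3.0)
        if center is None:
            break
        taken.append((center[0], center[1], lyso_r + 2.5))
        off = cell.offset
        cell.lysosomes.append(
            LysosomeTruth(
                center=(center[0] + off[0], center[1] + off[1]),
                interior_radius_px=float(lyso_r),
                dqbsa_ratio_true=draw_ratio(),
            )
        )


def _populate_aggregates(
    cell: CellTruth, params: PopulationParams, px: float, rng: np.random.Generator
) -> None:
    n_agg = 1 + int(rng.poisson(2.0))
    for _ in range(n_agg):
        area_um2 = rng.uniform(2.0, 6.0)
        radius = math.sqrt(area_um2 / math.pi) / px
        coords = _interior_coords(cell, radius * 0.5 + 1)
        if coords.size == 0:
            continue
        r, c = coords[rng.integers(len(coords))]
        cell.aggregates.append(
            (float(r) + cell.offset[0], float(c) + cell.offset[1], float(radius))
        )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _paint_disk(canvas: np.ndarray, center, area_px: float, value: float) -> None:
    rr, cc = lattice_disk_pixels(center, area_px)
    keep = (
        (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    )
    canvas[rr[keep], cc[keep]] += value


def _paint_annulus(
    canvas: np.ndarray, center, inner_r: float, width: float, value: float
) -> None:
    extent = int(math.ceil(inner_r + width)) + 1
    r0 = int(round(center[0]))
    c0 = int(round(center[1]))
    rows = np.arange(max(r0 - extent, 0), min(r0 + extent + 1, canvas.shape[0]))
    cols = np.arange(max(c0 - extent, 0), min(c0 + extent + 1, canvas.shape[1]))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    ring = (d > inner_r) & (d <= inner_r + width)
    canvas[rr[ring], cc[ring]] += value


def _background(shape, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth tilted-plane background plus constant offset."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    angle = rng.uniform(0, 2 * math.pi)
    ramp = np.cos(angle) * xx / max(shape[1] - 1, 1) + np.sin(angle) * yy / max(
        shape[0] - 1, 1
    )
    ramp = ramp - ramp.min()
    if ramp.max() > 0:
        ramp = ramp / ramp.max()
    return BACKGROUND_OFFSET + amp * ramp


def _render_objects(truth: GroundTruth) -> dict:
    """Noise- and background-free object rasters per channel role."""
    shape = truth.image_shape
    px = truth.pixel_size_um
    chans = {
        role: np.zeros(shape, dtype=np.float64)
        for role in ("nuclei", "soma", "gvb", "membrane", "tau", "dqbsa")
    }
    dendrites = np.zeros(shape, dtype=bool)

    for cell in truth.cells:
        rr, cc = cell.soma_pixels()
        inside = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        rr, cc = rr[inside], cc[inside]
        nrr, ncc = cell.nucleus_pixels()
        chans["nuclei"][nrr, ncc] += NUCLEUS_AMP
        chans["soma"][rr, cc] += SOMA_AMP
        chans["gvb"][rr, cc] += GVB_CYTO_AMP
        chans["tau"][rr, cc] += cell.tau_intensity
        chans["dqbsa"][rr, cc] += DQBSA_CYTO_AMP

        # thin dendrite strokes leaving the soma
        r0 = math.sqrt(cell.soma_mask.sum() / math.pi)
        rng_d = np.random.default_rng(
            (truth.seed * 1_000_003 + cell.cell_id) % (2**31)
        )
        for _ in range(int(rng_d.integers(2, 5))):
            ang = rng_d.uniform(0, 2 * math.pi)
            length = r0 * rng_d.uniform(1.5, 2.5)
            start = (
                cell.center[0] + 0.9 * r0 * math.sin(ang),
                cell.center[1] + 0.9 * r0 * math.cos(ang),
            )
            end = (
                start[0] + length * math.sin(ang),
                start[1] + length * math.cos(ang),
            )
            lr, lc = skdraw.line(
                int(round(start[0])), int(round(start[1])),
                int(round(end[0])), int(round(end[1])),
            )
            keep = (lr >= 0) & (lr < shape[0]) & (lc >= 0) & (lc < shape[1])
            dendrites[lr[keep], lc[keep]] = True

        for row, col, radius in cell.aggregates:
            _paint_disk(
                chans["tau"], (row, col), math.pi * radius ** 2,
                truth_aggregate_amp(cell),
            )

        for gvb in cell.gvb_list:
            area_px = gvb.core_area_um2 / px ** 2
            for core_center in gvb.core_centers:
                _paint_disk(chans["gvb"], core_center, area_px, CORE_AMP)
            if gvb.has_ring:
                _paint_annulus(
                    chans["membrane"], gvb.center, gvb.ring_inner_radius_px, 2.0,
                    MEMBRANE_AMP,
                )
            if truth.reporter_target == "core":
                for core_center in gvb.core_centers:
                    _paint_disk(
                        chans["dqbsa"], core_center, area_px,
                        DQBSA_CYTO_AMP * (gvb.dqbsa_ratio_true - 1.0),
                    )
            else:
                _paint_disk(
                    chans["dqbsa"], gvb.center,
                    math.pi * gvb.ring_inner_radius_px ** 2,
                    DQBSA_CYTO_AMP * (gvb.dqbsa_ratio_true - 1.0),
                )
        for lyso in cell.lysosomes:
            _paint_annulus(
                chans["membrane"], lyso.center, lyso.interior_radius_px, 2.0,
                MEMBRANE_AMP,
            )
            _paint_disk(
                chans["dqbsa"], lyso.center,
                math.pi * lyso.interior_radius_px ** 2,
                DQBSA_CYTO_AMP * (lyso.dqbsa_ratio_true - 1.0),
            )

    dendrites = ndi.binary_dilation(dendrites) & (chans["soma"] == 0)
    chans["soma"][dendrites] += DENDRITE_AMP
    return chans


def truth_aggregate_amp(cell: CellTruth) -> float:
    """Aggregate amplitude: the cell's diffuse level scaled to aggregate AU."""
    # aggregates are drawn only for tau+ cells, whose diffuse level is
    # tau_intensity_levels[1]; the aggregate adds up to ~levels[2]
    return cell.tau_intensity * 2.2


def render_stack(
    truth: GroundTruth, optics: OpticsParams, rng_seed: int
) -> List[MultiChannelImage]:
    """Render a Z-stack of ``optics.n_z`` slices.

    Slice k scales all object signal by a Gaussian focus weight centred on
    the middle slice; background and noise are drawn independently per
    slice.  With ``n_z == 1`` this is a single in-focus image.
    """
    optics.validate()
    if truth.pixel_size_um != optics.pixel_size_um or tuple(
        truth.image_shape
    ) != tuple(optics.image_shape):
        raise ValueError("truth and optics geometry are inconsistent")
    rng = np.random.default_rng(rng_seed)
    objects = _render_objects(truth)
    sigma = optics.psf_sigma_px
    mid = (optics.n_z - 1) / 2.0
    slices = []
    for k in range(optics.n_z):
        weight = math.exp(-((k - mid) ** 2) / (2 * max(optics.n_z / 4.0, 0.5) ** 2))
        chans = {}
        for role, raster in objects.items():
            img = raster * weight + _background(
                truth.image_shape, optics.background_gradient_amp, rng
            )
            if sigma > 0:
                img = ndi.gaussian_filter(img, sigma)
            if optics.poisson_scaling > 0:
                img = rng.poisson(
                    np.clip(img, 0, None) * optics.poisson_scaling
                ) / optics.poisson_scaling
            if optics.gaussian_sd > 0:
                img = img + rng.normal(0.0, optics.gaussian_sd, size=img.shape)
            chans[role] = img
        slices.append(
            MultiChannelImage(
                channels=chans,
                pixel_size_um=optics.pixel_size_um,
                z_index=k,
                metadata={"condition": truth.condition, "seed": truth.seed},
            )
        )
    return slices


def render_image(
    truth: GroundTruth, optics: OpticsParams, rng_seed: int
) -> MultiChannelImage:
    """Render the in-focus image (single slice) of a ground-truth scene.

    Channels rendered: nuclei, soma (+dendrites), GVB cores, membrane rings,
    tau (diffuse + aggregates), DQ-BSA reporter; then a smooth background
    gradient is added, PSF blur applied and read noise drawn.  Blurring
    conserves each interior object's total flux within 1%.
    """
    stack = render_stack(truth, replace(optics, n_z=1), rng_seed)
    return stack[0]


# ---------------------------------------------------------------------------
# Dose ladders
# ---------------------------------------------------------------------------

def dose_ladder_params(
    base: PopulationParams,
    doses: Sequence[float] = (0.0, 40.0, 80.0, 160.0),
) -> List[PopulationParams]:
    """Per-dose population parameters for a seed dose–response experiment.

    Tau-pathology prevalence scales linearly with dose up to the base
    parameters at the top dose; the zero-dose (buffer) condition has no tau
    aggregates and no GVBs, mirroring the control wells.
    """
    if not doses:
        raise ValueError("doses must be non-empty")
    if list(doses) != sorted(doses):
        raise ValueError("doses must be ordered")
    top = max(doses)
    out = []
    for dose in doses:
        if dose == 0:
            out.append(
                replace(base, p_tau=0.0, p_gvb_given_no_tau=0.0, dose=None)
            )
        else:
            out.append(replace(base, p_tau=base.p_tau * dose / top, dose=dose))
    return out


def generate_dose_response(
    doses: Sequence[PopulationParams],
    wells_per_dose: int,
    optics: OpticsParams,
    rng_seed: int,
) -> List[Tuple[MultiChannelImage, GroundTruth]]:
    """Render ``wells_per_dose`` annotated wells for each dose condition."""
    if not doses:
        raise ValueError("dose list is empty")
    if wells_per_dose < 1:
        raise ValueError("wells_per_dose must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).generate_state(
        len(doses) * wells_per_dose
    ) % (2**31)
    out = []
    idx = 0
    for params in doses:
        for _ in range(wells_per_dose):
            truth = generate_population(params, optics, int(seeds[idx]))
            image = render_image(truth, optics, int(seeds[idx]) + 1)
            out.append((image, truth))
            idx += 1
    return out


def generate_well_loads(
    doses: Sequence[float] = (0.0, 40.0, 80.0, 160.0),
    wells_per_dose: int = 6,
    cv: float = 0.15,
    rng_seed: int = 0,
    tau_load_per_nm: float = 1.0,
    gvb_per_tau: float = 0.6,
    background_tau: float = 2.0,
    background_gvb: float = 1.0,
):
    """Well-level load generator for dose–response statistics.

    Each well's true tau-pathology load is proportional to dose; its GVB
    load is proportional to the realized tau load; both measurements carry
    independent multiplicative log-normal noise of coefficient of variation
    ``cv``, plus an additive condition-independent background (what the
    control wells measure).  Returns a list of
    :class:`gvbquant.highcontent.WellObservation` with raw fields set.
    """
    from .highcontent import WellObservation  # deferred to avoid a cycle

    rng = np.random.default_rng(rng_seed)
    sigma = math.sqrt(math.log(1 + cv**2))
    mu = -(sigma**2) / 2  # unit-mean multiplicative noise
    observations = []
    well = 0
    for dose in doses:
        for _ in range(wells_per_dose):
            well += 1
            tau_true = tau_load_per_nm * dose * rng.lognormal(mu, sigma)
            gvb_true = gvb_per_tau * tau_true * rng.lognormal(mu, sigma)
            observations.append(
                WellObservation(
                    well_id=f"W{well:03d}",
                    tau_expression=True,
                    dose_nM=float(dose),
                    control=(dose == 0),
                    region="hippocampus",
                    n_nuclei=int(rng.normal(6000, 300)),
                    tau_load_raw=tau_true + background_tau,
                    gvb_load_raw=gvb_true + background_gvb,
                )
            )
    return observations
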