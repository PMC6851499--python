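"""Multi-channel image container used throughout the pipeline.

Channels are keyed by *role* — what the stain reports, not the fluorophore.
The roles the pipeline understands:

``nuclei``
    DNA counterstain (DAPI-like); used for counting and nuclear masks.
``soma``
    Somatodendritic marker (MAP2-like); its thresholded mask defines the
    neuronal region of interest.
``gvb``
    GVB core marker (CK1δ/pPERK-like); bright somatic puncta.
``membrane``
    Late endo-lysosomal membrane marker (LIMP2/LAMP1-like); ring-shaped
    signal around GVB cores.
``tau``
    Phospho-tau signal (AT8/AT100-like) or insoluble tagged tau; diffuse
    plus aggregate signal in cells with tau pathology.
``dqbsa``
    Endocytosed proteolysis reporter; bright where degradation occurs.

Coordinates are 0-based ``(row, col)`` with pixel centers on the integer
lattice.  Areas are always ``pixel_count * pixel_size_um ** 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

#: Channel roles the renderer and quantifiers know about.
KNOWN_ROLES = ("nuclei", "soma", "gvb", "membrane", "tau", "dqbsa")


class ChannelError(KeyError):
    """Raised when a required channel role is missing or unknown."""


@dataclass
class MultiChannelImage:
    """A 2D multi-channel fluorescence image with physical pixel size.

    Parameters
    ----------
    channels
        Mapping from channel role to a 2D float array in arbitrary
        fluorescence units (AU).  All rasters must share one shape.
    pixel_size_um
        Pixel edge length in micrometres per pixel; must be positive.
    z_index
        Index of the focal plane within a stack, if applicable.
    is_projection
        True if this image is a maximum-intensity projection.
    """

    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    z_index: Optional[int] = None
    is_projection: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.channels:
            raise ValueError("image must have at least one channel")
        shapes = {np.asarray(arr).shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D, got shape {shape}")
        self.channels = {
            role: np.asarray(arr, dtype=np.float64) for role, arr in self.channels.items()
        }

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def get(self, role: str) -> np.ndarray:
        """Return the raster for a channel role, raising ChannelError if absent."""
        try:
            return self.channels[role]
        except KeyError:
            raise ChannelError(
                f"channel role {role!r} not present; available: {sorted(self.channels)}"
            ) from None

    def roles(self) -> Iterable[str]:
        return self.channels.keys()


def max_project(stack: list) -> MultiChannelImage:
    """Maximum-intensity projection of a Z-stack.

    Per pixel and per channel the maximum across slices is taken; the
    standard way to collapse a confocal stack before 2D quantification.

    Parameters
    ----------
    stack
        Non-empty list of :class:`MultiChannelImage`, all with identical
        shape, channel roles and pixel size.
    """
    if not stack:
        raise ValueError("cannot project an empty stack")
    first = stack[0]
    roles = set(first.channels)
    for img in stack[1:]:
        if set(img.channels) != roles:
            raise ValueError("channel roles differ across slices")
        if img.shape != first.shape:
            raise ValueError("slice shapes differ")
        if img.pixel_size_um != first.pixel_size_um:
            raise ValueError("pixel sizes differ across slices")
    projected = {
        role: np.maximum.reduce([img.channels[role] for img in stack]) for role in roles
    }
    return MultiChannelImage(
        channels=projected,
        pixel_size_um=first.pixel_size_um,
        is_projection=True,
        metadata=dict(first.metadata),
    )
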