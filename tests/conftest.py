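"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest

import gvbquant as gq
from gvbquant.image import MultiChannelImage


@pytest.fixture(scope="session")
def survey_scene():
    """A 160-cell survey field with its rendered image and ground truth."""
    optics = gq.survey_optics(image_shape=(1536, 1536))
    params = gq.PopulationParams(n_cells=160)
    truth = gq.generate_population(params, optics, 42)
    image = gq.render_image(truth, optics, 43)
    return params, optics, truth, image


@pytest.fixture(scope="session")
def confocal_cell_scene():
    """A one-cell confocal field, every structure type represented."""
    optics = gq.confocal_optics(image_shape=(256, 256))
    params = gq.PopulationParams(
        n_cells=1, p_tau=1.0, p_gvb_given_tau=1.0, gvb_count_mean=3.0,
        soma_area_mean_um2=120.0,
    )
    truth = gq.generate_population(params, optics, 11)
    image = gq.render_image(truth, optics, 12)
    return optics, truth, image


@pytest.fixture(scope="session")
def buffer_wells():
    """Sixteen buffer (no tau, no GVB) wells measured with the HCS path."""
    from gvbquant.highcontent import measure_well

    optics = gq.hcs_optics()
    params = gq.PopulationParams(n_cells=40, p_tau=0.0, p_gvb_given_no_tau=0.0)
    observations = []
    for w in range(16):
        truth = gq.generate_population(params, optics, 300 + w)
        image = gq.render_image(truth, optics, 400 + w)
        observations.append(
            measure_well(image, f"W{w:03d}", control=True)
        )
    return observations


def flat_image(value: float, shape=(64, 64), roles=("gvb",), pixel_size_um=0.1):
    """Uniform single- or multi-channel image helper."""
    return MultiChannelImage(
        channels={r: np.full(shape, float(value)) for r in roles},
        pixel_size_um=pixel_size_um,
    )


def brute_force_single_linkage(points: np.ndarray, distance: float) -> int:
    """O(n^2) union-find single-linkage cluster count (test oracle)."""
    n = len(points)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= distance:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    return len({find(i) for i in range(n)})
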