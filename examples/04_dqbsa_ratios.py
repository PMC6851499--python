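"""Proteolytic activity of GVBs: DQ-BSA signal/background ratios.

Renders a confocal scene, measures the DQ-BSA reporter inside every
membrane-delineated structure against seeded cytosolic background ROIs, and
prints the fraction of GVBs whose reporter signal exceeds background (and
exceeds it twofold), plus the binned frequency distribution.
"""

import numpy as np

import gvbquant as gq
from gvbquant.confocal import dqbsa_ratio, frequency_distribution
from gvbquant.synth import lattice_disk_pixels

optics = gq.confocal_optics(image_shape=(640, 640))
params = gq.PopulationParams(
    n_cells=2, p_tau=1.0, p_gvb_given_tau=1.0, gvb_count_mean=5.0,
    soma_area_mean_um2=140.0,
)

ratios = []
for k in range(6):
    truth = gq.generate_population(params, optics, rng_seed=30 + k)
    image = gq.render_image(truth, optics, rng_seed=40 + k)
    for cell in truth.cells:
        masks, flags = [], []
        for gvb in cell.gvb_list:
            mask = np.zeros(image.shape, bool)
            rr, cc = lattice_disk_pixels(
                gvb.center, np.pi * max(gvb.ring_inner_radius_px - 1, 1) ** 2
            )
            mask[rr, cc] = True
            masks.append(mask)
            flags.append(True)
        if not masks:
            continue
        cytosol = np.zeros(image.shape, bool)
        rr, cc = cell.soma_pixels()
        cytosol[rr, cc] = True
        try:
            records = dqbsa_ratio(image, "dqbsa", masks, flags, cytosol, rng_seed=k)
        except ValueError:
            continue
        ratios.extend(r.ratio for r in records)

ratios = np.array(ratios)
edges, pct = frequency_distribution(ratios, bin_width=0.5)
print(f"GVBs measured: {len(ratios)}")
print(f"above cytosolic background: {100 * (ratios > 1).mean():.0f}%")
print(f"more than twofold above:    {100 * (ratios > 2).mean():.0f}%")
print("frequency distribution (bin -> %):")
for lo, p in zip(edges[:-1], pct):
    print(f"  [{lo:.1f}, {lo + 0.5:.1f}): {p:5.1f}%")
# Most GVBs contain hydrolysed (dequenched) reporter: they are
# proteolytically active compartments, not inert inclusions.
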