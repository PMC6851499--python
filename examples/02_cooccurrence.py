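"""Tau/GVB co-occurrence: classify cells and count double positives.

Generates a population in which 35% of tau-pathology neurons form GVBs and
80% of GVB-bearing neurons have tau pathology (the generator's default
joint model), classifies every cell from the rendered image, and prints the
recovered conditional percentages.
"""

import gvbquant as gq

optics = gq.survey_optics(image_shape=(1536, 1536))
params = gq.PopulationParams(n_cells=160)

n_tau = n_gvb = n_double = 0
for tile in range(3):
    truth = gq.generate_population(params, optics, rng_seed=10 + tile)
    image = gq.render_image(truth, optics, rng_seed=20 + tile)
    records = gq.classify_cells(image)
    n_tau += sum(r.tau_positive for r in records)
    n_gvb += sum(r.gvb_positive for r in records)
    n_double += sum(r.tau_positive and r.gvb_positive for r in records)

print(f"tau+ neurons: {n_tau}, GVB+ neurons: {n_gvb}, double positive: {n_double}")
print(f"P(tau+ | GVB+) = {100 * n_double / n_gvb:.1f}%  (generating: 80%)")
print(f"P(GVB+ | tau+) = {100 * n_double / n_tau:.1f}%  (generating: 35%)")
# With only ~480 cells the estimates scatter by a few percentage points
# around the generating probabilities (binomial sampling).
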