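"""The normality-gated statistics decision tree on per-well loads.

Builds three groups of per-well GVB loads (control, low dose, high dose),
lets the selector pick the test route (Shapiro-Wilk gate, then parametric
or rank-based branch), and prints the route, p-values and post hoc table.
"""

import numpy as np

import gvbquant as gq

rng = np.random.default_rng(0)
control = rng.normal(0.0, 1.0, 16)
low = rng.normal(2.0, 1.0, 16)
high = np.exp(rng.normal(1.6, 1.2, 16))  # skewed: fails the normality gate

result = gq.select_and_run([control, low, high])
print(f"route taken: {result.test_name}")
print(f"normality per group: {result.normality_pass}")
print(f"omnibus statistic = {result.statistic:.3f}, p = {result.p_value:.2e}")
for row in result.posthoc:
    print(f"  groups {row['pair']}: adjusted p = {row['p_adjusted']:.4f}")

r = gq.correlate([1.0, 2.0, 3.0, 4.0], [2.1, 3.9, 6.2, 8.1])
print(f"Pearson r = {r['r']:.3f}, slope = {r['slope']:.2f}")
# One skewed group routes the whole comparison to Kruskal-Wallis with
# Dunn's Bonferroni-adjusted pairwise tests, exactly as the gate dictates.
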