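"""Normality-gated statistical decision tree for group comparisons.

The procedure mirrors standard practice in cell-biology quantification:
Shapiro–Wilk per group at α = 0.05; if every group passes, the parametric
branch is used (Student's t for two groups, one-way ANOVA with Tukey's HSD
post hoc for more); if any group fails, the non-parametric branch is used
(Mann–Whitney U for two groups, Kruskal–Wallis with Dunn's post hoc and
Bonferroni adjustment for more).  One-sample t against zero and Pearson
correlation with a least-squares line complete the toolkit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "select_and_run",
    "one_sample_vs_zero",
    "correlate",
    "dunn_posthoc",
]

ALPHA = 0.05


@dataclass
class StatResult:
    """Outcome of one statistical comparison, with the route taken."""

    test_name: str
    statistic: float
    p_value: float
    normality_pass: List[bool] = field(default_factory=list)
    posthoc: Optional[List[Dict]] = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _as_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(out):
        if g.size < 3:
            raise ValueError(f"group {i} has n={g.size} < 3: insufficient data")
    return out


def dunn_posthoc(
    groups: Sequence[np.ndarray], adjust: str = "bonferroni"
) -> List[Dict]:
    """Dunn's multiple-comparison test on pooled ranks.

    For groups i, j the statistic is

        z = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) )

    with N the pooled size, R̄ the mean pooled mid-ranks and
    T = Σ(t³ − t)/(12(N − 1)) the tie correction over tied values of
    multiplicity t.  Two-sided normal p-values, Bonferroni-adjusted by the
    number of pairs (adjusted p never below the unadjusted one).
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = math.sqrt(
            variance_base * (1.0 / groups[i].size + 1.0 / groups[j].size)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(p * m, 1.0) if adjust == "bonferroni" else p
        out.append(
            {"pair": (i, j), "statistic": float(z), "p_unadjusted": float(p),
             "p_adjusted": float(p_adj)}
        )
    return out


def select_and_run(groups: Sequence[Sequence[float]]) -> StatResult:
    """Run the normality-gated comparison appropriate for the groups.

    Shapiro–Wilk is applied per group at α = 0.05; a single failing group
    routes the whole comparison to the non-parametric branch.  Student's t
    is the classical equal-variance form.
    """
    gs = _as_groups(groups)
    normality = [bool(sps.shapiro(g).pvalue > ALPHA) for g in gs]
    parametric = all(normality)
    if len(gs) == 2:
        if parametric:
            stat, p = sps.ttest_ind(gs[0], gs[1], equal_var=True)
            return StatResult("student_t", float(stat), float(p), normality)
        stat, p = sps.mannwhitneyu(gs[0], gs[1], alternative="two-sided")
        return StatResult("mann_whitney_u", float(stat), float(p), normality)
    if parametric:
        stat, p = sps.f_oneway(*gs)
        tukey = sps.tukey_hsd(*gs)
        posthoc = []
        for i, j in itertools.combinations(range(len(gs)), 2):
            posthoc.append(
                {
                    "pair": (i, j),
                    "statistic": float(tukey.statistic[i, j]),
                    "p_adjusted": float(tukey.pvalue[i, j]),
                }
            )
        return StatResult(
            "anova_tukey", float(stat), float(p), normality, posthoc
        )
    stat, p = sps.kruskal(*gs)
    return StatResult(
        "kruskal_dunn", float(stat), float(p), normality, dunn_posthoc(gs)
    )


def one_sample_vs_zero(values: Sequence[float]) -> StatResult:
    """Two-sided one-sample t test of the mean against 0 (df = n − 1)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(vals) == 0:
        raise ValueError("zero variance: one-sample t test undefined")
    stat, p = sps.ttest_1samp(vals, popmean=0.0)
    return StatResult("one_sample_t", float(stat), float(p), [True])


def correlate(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Pearson correlation plus the least-squares regression line.

    Returns ``{"r", "p", "slope", "intercept"}``; symmetric in (x, y) for r
    and p, and invariant to positive affine rescaling of either variable.
    """
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.size != ys.size or xs.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in x or y")
    fit = sps.linregress(xs, ys)
    return {
        "r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }
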