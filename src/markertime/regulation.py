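"""Bayesian gene regulation-timing comparisons.

Each gene carries a posterior over its regulation time — the switch time t0
for switch-like genes, the peak time p for transient genes.  For a pair
(A, B) the posterior of the difference t0_A - t0_B is formed draw-by-draw
(draws are paired by posterior sample index, preserving their correlation),
and the genes are declared regulated at significantly different times when
the credible interval of the difference excludes zero.  Switch-vs-transient
comparisons use t0 against p directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .inference import PosteriorSamples, _interval

__all__ = [
    "RegulationTestResult",
    "regulation_time_draws",
    "pairwise_regulation_test",
    "all_pairwise_tests",
    "order_genes_by_regulation",
]


@dataclass(frozen=True)
class RegulationTestResult:
    """Posterior summary of the timing difference between two genes."""

    gene_a: str
    gene_b: str
    diff_mean: float
    ci_lower: float
    ci_upper: float
    significant: bool
    direction: str  # A_before_B | B_before_A | indeterminate
    level: float = 0.95


def regulation_time_draws(samples: PosteriorSamples, gene) -> np.ndarray:
    """Pooled draws of the gene's regulation time (t0 or p by behaviour)."""
    j = samples.gene_index(gene)
    return samples.flat("time")[:, j]


def pairwise_regulation_test(samples: PosteriorSamples, gene_a, gene_b,
                             level=0.95, interval="central") -> RegulationTestResult:
    """Credible-interval test of whether gene_a is regulated before gene_b.

    The default interval on the difference is equal-tailed (central), since
    the decision rule is a sign test on the interval endpoints; an HPD
    interval is available via ``interval="hpd"``.
    """
    if gene_a == gene_b:
        raise ValueError("cannot compare a gene with itself")
    diff = regulation_time_draws(samples, gene_a) - regulation_time_draws(
        samples, gene_b
    )
    lo, hi = _interval(diff, level, interval)
    significant = bool(lo > 0.0 or hi < 0.0)
    if not significant:
        direction = "indeterminate"
    elif hi < 0.0:
        direction = "A_before_B"
    else:
        direction = "B_before_A"
    return RegulationTestResult(
        gene_a=gene_a, gene_b=gene_b, diff_mean=float(diff.mean()),
        ci_lower=float(lo), ci_upper=float(hi), significant=significant,
        direction=direction, level=level,
    )


def all_pairwise_tests(samples: PosteriorSamples, level=0.95,
                       interval="central", simultaneous=False) -> pd.DataFrame:
    """Timing test for every unordered gene pair: G*(G-1)/2 rows.

    Intervals are raw (unadjusted) by default, matching the original test;
    ``simultaneous=True`` applies a Bonferroni-style adjustment of the level
    across pairs (clearly more conservative).
    """
    genes = list(samples.gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    pairs = list(combinations(genes, 2))
    lvl = level
    if simultaneous:
        lvl = 1.0 - (1.0 - level) / len(pairs)
    rows = []
    for a, b in pairs:
        res = pairwise_regulation_test(samples, a, b, level=lvl, interval=interval)
        rows.append(dict(
            gene_a=a, gene_b=b, diff_mean=res.diff_mean, lower=res.ci_lower,
            upper=res.ci_upper, significant=res.significant,
            direction=res.direction,
        ))
    out = pd.DataFrame(rows)
    out.attrs["level"] = level
    out.attrs["simultaneous"] = simultaneous
    return out


def order_genes_by_regulation(samples: PosteriorSamples) -> list:
    """Gene ids sorted by posterior-mean regulation time; ties lexicographic."""
    means = samples.flat("time").mean(axis=0)
    return [g for _, g in sorted(zip(means, samples.gene_ids),
                                 key=lambda mg: (mg[0], mg[1]))]
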