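"""Downstream statistics: Fisher exact concordance, Poisson-Binomial
oncogene enrichment, and exponential tail fits on log-scaled histograms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]]
    (probability-mass method)."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Poisson-Binomial enrichment


@dataclass
class EnrichmentInput:
    """One (tumor type, gene) enrichment test.

    ``interval_lengths``: per-sample lists of amplicon interval lengths l_a;
    ``gene_length``: l_g; ``genome_length``: G; ``k``: number of samples
    whose amplicons hit the gene.
    """

    interval_lengths: list  # list of per-sample lists
    gene_length: float
    genome_length: float
    k: int

    def __post_init__(self):
        if self.gene_length <= 0 or self.genome_length <= 0:
            raise ValueError("lengths must be positive")
        if not (0 <= self.k <= len(self.interval_lengths)):
            raise ValueError("k out of range")


def intersect_probability(l_a: float, l_g: float, g: float) -> float:
    """Null probability that a random interval of length l_a intersects a
    gene of length l_g on a genome of length g: (l_a + l_g) / g."""
    return (l_a + l_g) / g


def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact Poisson-Binomial pmf by O(n^2) dynamic programming."""
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * (1.0 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def poisson_binomial_tail(probs, k: int) -> float:
    """P(X >= k) for independent Bernoulli trials with given probabilities."""
    if k <= 0:
        return 1.0
    pmf = poisson_binomial_pmf(probs)
    if k >= len(pmf):
        return 0.0
    return float(np.sum(pmf[k:]))


def poibin_enrichment(inp: EnrichmentInput, alpha: float = 0.05):
    """Bonferroni-corrected Poisson-Binomial enrichment test.

    Per-sample success probability B = 1 - prod(1 - A) over the sample's
    intervals, A = (l_a + l_g)/G (clamped below 1 with a warning if
    violated); tail P(X >= k); correction factor G / l_g.
    Returns (corrected_p, enriched).
    """
    bs = []
    for lengths in inp.interval_lengths:
        prod = 1.0
        for l_a in lengths:
            a = intersect_probability(l_a, inp.gene_length, inp.genome_length)
            if a >= 1.0:
                import warnings

                warnings.warn("interval covers the genome; A clamped to 1")
                a = 1.0
            prod *= 1.0 - a
        bs.append(1.0 - prod)
    p = poisson_binomial_tail(bs, inp.k)
    corrected = min(p * inp.genome_length / inp.gene_length, 1.0)
    return corrected, corrected < alpha


# ---------------------------------------------------------------------------
# exponential fit on a log-scaled histogram


def exp_fit(values, bin_width: float, fit_range: tuple) -> float:
    """Estimate an exponential mean as -1/slope of the best-fit line to
    log bin counts over ``fit_range``; empty bins are skipped."""
    values = np.asarray(values, dtype=float)
    if len(values) < 100:
        raise ValueError("need at least 100 values for a tail fit")
    lo, hi = fit_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    if keep.sum() < 2:
        raise ValueError("fewer than two non-empty bins in the fit range")
    slope, _intercept = np.polyfit(centers[keep], np.log(counts[keep]), 1)
    if slope >= 0:
        raise ValueError("non-decaying histogram; no exponential fit")
    return -1.0 / slope
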