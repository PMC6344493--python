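"""Meanshift copy-number boundary detection and segment coverage ratios.

The gradient of a Gaussian kernel density over (window index, coverage)
is evaluated per window; boundaries are negative-to-positive sign changes.
A coarse 10 kbp pass is refined by a local 300 bp pass around each accepted
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .records import StartIndex
from .seqstats import SeqStats

NEIGHBORS = 50  # j iterates over 50 windows on either side
HB_SWEEP = (2, 5, 10, 50, 100)


@dataclass
class CoverageProfile:
    chrom: str
    start: int
    ws: int
    values: np.ndarray  # per-window coverage, windows tile [start, ...)

    @property
    def end(self) -> int:
        return self.start + len(self.values) * self.ws

    def window_pos(self, idx: int) -> int:
        return self.start + idx * self.ws


def profile_from_index(
    index: StartIndex, tid: int, chrom: str, start: int, end: int,
    ws: int, read_len: float,
) -> CoverageProfile:
    n = max((end - start) // ws, 1)
    counts = index.window_counts(tid, start, start + n * ws, ws)
    return CoverageProfile(chrom, start, ws, counts * read_len / ws)


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    mean_coverage: float  # C_s
    coverage_ratio: float  # CR_s = 2 C_s / mu_ws


def bandwidth_r(values: np.ndarray, stats: SeqStats, ws: int) -> np.ndarray:
    """Per-window coverage bandwidth H_r = max(2, sqrt(c_i/theta)) * sigma."""
    theta = max(stats.theta(ws), 1e-9)
    return np.maximum(2.0, np.sqrt(np.maximum(values, 0) / theta)) * stats.sigma(ws)


def meanshift_gradient(
    values: np.ndarray, hb: float, hr: np.ndarray, neighbors: int = NEIGHBORS
) -> np.ndarray:
    """Gradient component of the kernel density along the window axis.

    (grad F)_i = (1/Hb^2) sum_{j != i} (j - i) exp(-(j-i)^2 / 2 Hb^2)
                 * exp(-(r_i - r_j)^2 / 2 Hr_i^2)
    with j over ``neighbors`` windows each side (truncated at the edges).
    The normalization constant is irrelevant to sign changes and omitted.
    """
    values = np.asarray(values, dtype=float)
    hr = np.broadcast_to(np.asarray(hr, dtype=float), values.shape)
    n = len(values)
    grad = np.zeros(n)
    offsets = np.arange(-neighbors, neighbors + 1)
    offsets = offsets[offsets != 0]
    kernel_b = offsets * np.exp(-(offsets ** 2) / (2.0 * hb ** 2))
    for i in range(n):
        js = i + offsets
        ok = (js >= 0) & (js < n)
        dv = values[i] - values[js[ok]]
        w = np.exp(-(dv ** 2) / (2.0 * max(hr[i], 1e-9) ** 2))
        grad[i] = np.sum(kernel_b[ok] * w) / hb ** 2
    return grad


def _crossings(grad: np.ndarray):
    """Boundary indices: window i starts a new segment when the gradient
    flips from negative (at i-1) to non-negative (at i)."""
    return [
        i + 1
        for i in range(len(grad) - 1)
        if grad[i] < 0 <= grad[i + 1]
    ]


def _segment_means(values, bounds):
    """bounds: sorted interior boundary indices; returns per-segment means."""
    edges = [0] + list(bounds) + [len(values)]
    return [
        (edges[k], edges[k + 1], float(np.mean(values[edges[k]:edges[k + 1]])))
        for k in range(len(edges) - 1)
    ]


def _significant(c1, n1, c2, n2, stats: SeqStats, ws: int) -> bool:
    """Coverage-difference significance between adjacent segments.

    Under 15 windows the raw inequality applies; for larger segments the same
    inequality with a mean standard error (sigma / sqrt(min n)).
    """
    sigma = stats.sigma(ws)
    theta = max(stats.theta(ws), 1e-9)
    nmin = min(n1, n2)
    if nmin >= 15:
        sigma = sigma / np.sqrt(nmin)
    return abs(c1 - c2) > 3.0 * sigma * max(c1, c2) / theta


def meanshift_boundaries(
    profile: CoverageProfile,
    stats: SeqStats,
    hb_sweep=HB_SWEEP,
    neighbors: int = NEIGHBORS,
):
    """Multi-scale meanshift boundary detection (window-index resolution).

    Sweeps the index bandwidth over ``hb_sweep``, freezing boundaries found
    significant at each stage.
    """
    values = profile.values
    if len(values) < 2:
        return []
    hr = bandwidth_r(values, stats, profile.ws)
    frozen: set[int] = set()
    for hb in hb_sweep:
        grad = meanshift_gradient(values, hb, hr, neighbors)
        cand = [b for b in _crossings(grad) if b not in frozen]
        if not cand:
            continue
        allb = sorted(frozen | set(cand))
        segs = _segment_means(values, allb)
        seg_by_start = {s[0]: k for k, s in enumerate(segs)}
        for b in cand:
            k = seg_by_start[b]
            s1, s2 = segs[k - 1], segs[k]
            if _significant(
                s1[2], s1[1] - s1[0], s2[2], s2[1] - s2[0], stats, profile.ws
            ):
                frozen.add(b)
    return sorted(frozen)


def _mode_filter(values, bounds, stats, ws, mode):
    """Iteratively drop boundaries failing the mode's CR / t-test rule."""
    mu = max(stats.mu(ws), 1e-9)
    bounds = sorted(bounds)
    while bounds:
        segs = _segment_means(values, bounds)
        worst, worst_key = None, None
        for k in range(len(segs) - 1):
            (a1, b1, c1), (a2, b2, c2) = segs[k], segs[k + 1]
            cr1, cr2 = 2 * c1 / mu, 2 * c2 / mu
            if mode == "default":
                bad = abs(cr1 - cr2) < max(1.0, np.sqrt(cr1), np.sqrt(cr2))
                key = abs(cr1 - cr2)
            else:  # sensitive: Welch two-sample test on window coverages
                v1, v2 = values[a1:b1], values[a2:b2]
                if len(v1) < 2 or len(v2) < 2:
                    p = 0.0
                elif np.ptp(v1) == 0 and np.ptp(v2) == 0:
                    p = 1.0 if v1[0] == v2[0] else 0.0
                else:
                    p = sps.ttest_ind(v1, v2, equal_var=False).pvalue
                bad = not (p < 0.05)
                key = p if np.isfinite(p) else 1.0
            if not bad:
                continue
            better = worst is None or (
                key < worst if mode == "default" else key > worst
            )
            if better:
                worst, worst_key = key, bounds[k]
        if worst_key is None:
            break
        bounds.remove(worst_key)
    return bounds


def refine_boundary(
    coarse_pos: int,
    direction: float,
    fine_profile: CoverageProfile,
    stats: SeqStats,
    hb_sweep=(2, 5, 10),
):
    """Pick the 300 bp boundary with matching direction and largest coverage
    difference inside the local fine profile; ties break to the lower
    coordinate; falls back to the coarse position."""
    values = fine_profile.values
    if len(values) < 4:
        return coarse_pos
    hr = bandwidth_r(values, stats, fine_profile.ws)
    best = None
    cands = set()
    for hb in hb_sweep:
        grad = meanshift_gradient(values, hb, hr)
        cands.update(_crossings(grad))
    for b in sorted(cands):
        left = float(np.mean(values[:b]))
        right = float(np.mean(values[b:]))
        delta = right - left
        if delta * direction <= 0:
            continue
        if best is None or abs(delta) > best[0]:
            best = (abs(delta), fine_profile.window_pos(b))
    return best[1] if best else coarse_pos


def meanshift_segments(
    profile: CoverageProfile,
    stats: SeqStats,
    mode: str = "default",
    fine_profile_fn=None,
    hb_sweep=HB_SWEEP,
):
    """Full segmentation of one interval.

    Returns (segments, boundary_positions). ``fine_profile_fn(start, end)``
    supplies a 300 bp profile for local boundary refinement; when None the
    coarse positions are kept.
    """
    if mode not in ("default", "sensitive"):
        raise ValueError(mode)
    values = profile.values
    ws = profile.ws
    if len(values) < 2:
        seg = Segment(
            profile.chrom, profile.start, profile.end,
            float(np.mean(values)) if len(values) else 0.0,
            2 * float(np.mean(values)) / max(stats.mu(ws), 1e-9) if len(values) else 0.0,
        )
        return [seg], []
    bounds = meanshift_boundaries(profile, stats, hb_sweep)
    bounds = _mode_filter(values, bounds, stats, ws, mode)
    segs = _segment_means(values, bounds)

    positions = []
    for k, b in enumerate(bounds):
        pos = profile.window_pos(b)
        if fine_profile_fn is not None:
            direction = segs[k + 1][2] - segs[k][2]
            fine = fine_profile_fn(max(pos - ws, profile.start), min(pos + ws, profile.end))
            refined = refine_boundary(pos, direction, fine, stats)
            if not positions or refined > positions[-1]:
                pos = refined
        positions.append(pos)

    mu = max(stats.mu(ws), 1e-9)
    out = []
    edges = [profile.start] + positions + [profile.end]
    for k, (a, b, c) in enumerate(segs):
        out.append(
            Segment(profile.chrom, edges[k], edges[k + 1], c, 2 * c / mu)
        )
    return out, positions
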