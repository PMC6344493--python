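"""Discordant read-pair detection and bicluster clustering.

A bicluster is a pair of co-located, co-oriented discordant read clusters
whose mates group together; it supports one rearrangement junction.  The
breakpoint coordinate of a cluster is the extremal aligned end in the
cluster's orientation (the junction-proximal edge); the breakpoint
orientation equals the read strand ('+' = retained sequence left of the
position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import FWD, ReadPairs
from .seqstats import SeqStats

MAPQ_MIN = 6  # reads with MAPQ <= 5 are dropped
DEFAULT_D = 20.0


@dataclass(frozen=True)
class ThresholdPolicy:
    mode: str = "coverage"  # fixed | coverage | CR | deltaCR
    fixed: float = 2.0
    downscale: float = DEFAULT_D

    def __post_init__(self):
        if self.downscale <= 0:
            raise ValueError("downscale factor must be positive")
        if self.mode not in ("fixed", "coverage", "CR", "deltaCR"):
            raise ValueError(self.mode)


def s_cr(stats: SeqStats, cr: float, downscale: float = DEFAULT_D) -> float:
    """Minimum supporting pairs for a junction at coverage ratio ``cr``:
    S = P * CR * mu_300 * (I - R) / (2R) / D."""
    if cr < 0:
        raise ValueError("negative coverage ratio")
    p = stats.proper_fraction
    mu300 = stats.mu(300)
    i, r = stats.insert_mean, stats.read_length
    return p * cr * mu300 * (i - r) / (2.0 * r) / downscale


def threshold(
    policy: ThresholdPolicy, stats: SeqStats,
    cr: float | None = None, delta_cr: float | None = None,
) -> float:
    if policy.mode == "fixed":
        return policy.fixed
    if policy.mode == "coverage":
        return s_cr(stats, 2.0, policy.downscale)
    if policy.mode == "CR":
        return s_cr(stats, float(cr), policy.downscale)
    return s_cr(stats, float(delta_cr), policy.downscale)


def find_discordant(pairs: ReadPairs, stats: SeqStats) -> np.ndarray:
    """Mask of pairs that are discordant: inter-contig, unexpected
    orientation, or outer distance outside (mu_I - 3 sigma, mu_I + 3 sigma)."""
    inter = pairs.tid1 != pairs.tid2
    same_strand = pairs.strand1 == pairs.strand2
    # forward read must be the leftmost of an FR pair
    fwd_pos = np.where(pairs.strand1 == FWD, pairs.pos1, pairs.pos2)
    rev_pos = np.where(pairs.strand1 == FWD, pairs.pos2, pairs.pos1)
    rf = ~same_strand & (fwd_pos > rev_pos)
    span = pairs.outer_span()
    lo = stats.insert_mean - 3 * stats.insert_sd
    hi = stats.insert_mean + 3 * stats.insert_sd
    bad_span = (span < lo) | (span > hi)
    return inter | (~inter & (same_strand | rf | bad_span))


def strong_discordant(pairs: ReadPairs, stats: SeqStats,
                      span_sigma: float = 6.0) -> np.ndarray:
    """Discordant pairs excluding mild same-contig FR span outliers.

    The Gaussian tail of normal inserts puts ~0.3% of proper-geometry pairs
    just past the 3-sigma cut; at high amplicon depth those scattered pairs
    chain distinct junction clusters together under single linkage.  Real
    deletion junctions carry span >= insert + deleted length, so requiring
    FR pairs to exceed ``span_sigma`` keeps them while dropping the glue.
    """
    mask = find_discordant(pairs, stats)
    inter = pairs.tid1 != pairs.tid2
    same_strand = pairs.strand1 == pairs.strand2
    fwd_pos = np.where(pairs.strand1 == FWD, pairs.pos1, pairs.pos2)
    rev_pos = np.where(pairs.strand1 == FWD, pairs.pos2, pairs.pos1)
    fr_ok = ~inter & ~same_strand & (fwd_pos <= rev_pos)
    span = pairs.outer_span()
    lo = stats.insert_mean - span_sigma * stats.insert_sd
    hi = stats.insert_mean + span_sigma * stats.insert_sd
    mild = fr_ok & (span >= lo) & (span <= hi)
    return mask & ~mild


@dataclass
class Bicluster:
    breakpoint1: tuple  # (chrom-id, pos, orient)
    breakpoint2: tuple
    support: int        # unique read pairs
    n_pairs: int        # all member pairs
    pair_indices: np.ndarray

    def ends(self):
        return (self.breakpoint1, self.breakpoint2)


def _side_arrays(pairs: ReadPairs, idx: np.ndarray):
    """Canonically ordered pair ends (low side by (tid, pos) first)."""
    t1, p1 = pairs.tid1[idx], pairs.pos1[idx]
    t2, p2 = pairs.tid2[idx], pairs.pos2[idx]
    swap = (t1 > t2) | ((t1 == t2) & (p1 > p2))
    def pick(a1, a2):
        return np.where(swap, a2, a1), np.where(swap, a1, a2)
    tl, th = pick(t1, t2)
    pl, ph = pick(p1, p2)
    sl, sh = pick(pairs.strand1[idx], pairs.strand2[idx])
    al, ah = pick(pairs.alen1[idx], pairs.alen2[idx])
    return (tl, pl, sl, al), (th, ph, sh, ah)


def _split_clusters(order, tid, strand, pos, gap):
    """Single-linkage grouping along sorted order."""
    groups = []
    cur = [order[0]]
    for prev, nxt in zip(order[:-1], order[1:]):
        if (
            tid[nxt] != tid[prev]
            or strand[nxt] != strand[prev]
            or pos[nxt] - pos[prev] > gap
        ):
            groups.append(cur)
            cur = []
        cur.append(nxt)
    groups.append(cur)
    return groups


def _cluster_breakpoint(tid, pos, strand, alen, members):
    t = int(tid[members[0]])
    orient = "+" if strand[members[0]] == FWD else "-"
    if orient == "+":
        p = int(max(pos[m] + alen[m] for m in members))
    else:
        p = int(min(pos[m] for m in members))
    return (t, p, orient)


def cluster_biclusters(
    pairs: ReadPairs,
    discordant: np.ndarray,
    stats: SeqStats,
    policy: ThresholdPolicy = ThresholdPolicy("fixed", 2.0),
    cr_lookup=None,
    min_support: int = 2,
) -> list:
    """Cluster discordant pairs into biclusters and filter by support.

    ``discordant`` is a boolean mask or index array over ``pairs``.
    ``cr_lookup(chrom_tid, pos) -> CR`` supplies the local coverage ratio
    for CR / deltaCR threshold modes (defaults to CR=2 when absent).
    Reads with MAPQ <= 5 are removed before clustering.
    """
    idx = np.nonzero(discordant)[0] if discordant.dtype == bool else np.asarray(discordant)
    if len(idx) == 0:
        return []
    ok = (pairs.mapq1[idx] >= MAPQ_MIN) & (pairs.mapq2[idx] >= MAPQ_MIN)
    idx = idx[ok]
    if len(idx) == 0:
        return []
    (tl, pl, sl, al), (th, ph, sh, ah) = _side_arrays(pairs, idx)
    gap = stats.max_discordant_span
    order = np.lexsort((pl, sl, tl))
    out = []
    for grp in _split_clusters(order, tl, sl, pl, gap):
        sub = np.asarray(grp)
        order2 = sub[np.lexsort((ph[sub], sh[sub], th[sub]))]
        for members in _split_clusters(order2, th, sh, ph, gap):
            members = list(members)
            uniq = {(int(pl[m]), int(ph[m])) for m in members}
            support = len(uniq)
            bp1 = _cluster_breakpoint(tl, pl, sl, al, members)
            bp2 = _cluster_breakpoint(th, ph, sh, ah, members)
            if cr_lookup is not None and policy.mode in ("CR", "deltaCR"):
                cr = max(cr_lookup(bp1[0], bp1[1]), cr_lookup(bp2[0], bp2[1]))
                s = threshold(policy, stats, cr=cr, delta_cr=cr)
            else:
                s = threshold(policy, stats, cr=2.0, delta_cr=2.0)
            s = max(s, float(min_support))
            if support < s:
                continue
            out.append(
                Bicluster(bp1, bp2, support, len(members), idx[np.asarray(members)])
            )
    return out


def write_bedpe(path: str, biclusters, contigs) -> None:
    with open(path, "w") as fh:
        for b in biclusters:
            (t1, p1, o1), (t2, p2, o2) = b.ends()
            fh.write(
                f"{contigs.names[t1]}\t{p1}\t{p1 + 1}\t"
                f"{contigs.names[t2]}\t{p2}\t{p2 + 1}\t{b.support}\t{o1}\t{o2}\n"
            )
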