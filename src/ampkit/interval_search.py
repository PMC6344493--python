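"""Amplicon interval discovery from a seed by following amplified,
discordantly connected regions."""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .records import ContigTable, ReadPairs, StartIndex
from .seqstats import SeqStats
from . import svdetect

EXT_START = 10_000
EXT_CAP = 10_000_000
PAD = 100_000
MAX_ITER = 10
AMPLIFIED_FRACTION = 0.2
SMALL_INTERVAL = 20_000


@dataclass
class IntervalSet:
    intervals: list = field(default_factory=list)  # (tid, start, end)
    warning: str | None = None

    def add(self, tid: int, start: int, end: int) -> None:
        self.intervals.append((tid, start, end))
        self._normalize()

    def _normalize(self) -> None:
        merged = []
        for tid, s, e in sorted(self.intervals):
            if merged and merged[-1][0] == tid and s <= merged[-1][2]:
                merged[-1] = (tid, merged[-1][1], max(merged[-1][2], e))
            else:
                merged.append((tid, s, e))
        self.intervals = merged

    def contains(self, tid: int, pos: int) -> bool:
        return any(t == tid and s <= pos < e for t, s, e in self.intervals)

    def overlaps(self, tid: int, start: int, end: int) -> bool:
        return any(t == tid and s < end and e > start for t, s, e in self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


def is_amplified(
    tid: int, start: int, end: int,
    index: StartIndex, stats: SeqStats,
    n_discordant_edges: int = 0,
    ws: int = 10_000,
) -> bool:
    """Amplified iff >= 20% of ws windows exceed theta + 3 sigma, or the
    interval is under 20 kbp and carries at least two discordant edges."""
    if end <= start:
        return False
    if end - start < SMALL_INTERVAL and n_discordant_edges >= 2:
        return True
    length = end - start
    if length < ws:
        cov = index.count(tid, start, end) * stats.read_length / length
        counts = np.array([cov])
    else:
        counts = (
            index.window_counts(tid, start, start + (length // ws) * ws, ws)
            * stats.read_length / ws
        )
    thresh = stats.theta(ws) + 3 * stats.sigma(ws)
    return float(np.mean(counts > thresh)) >= AMPLIFIED_FRACTION


def _directional_extent(tid, pos, direction, index, stats, contig_len):
    """Maximal amplified extent from ``pos`` going left (-1) or right (+1),
    by doubling then binary refinement."""
    def amplified(e):
        if direction > 0:
            return is_amplified(tid, pos, min(pos + e, contig_len), index, stats)
        return is_amplified(tid, max(pos - e, 0), pos, index, stats)

    e = EXT_START
    if not amplified(e):
        return 0
    while e < EXT_CAP and amplified(e * 2):
        if (direction > 0 and pos + e >= contig_len) or (direction < 0 and pos - e <= 0):
            break
        e *= 2
    lo, hi = e, min(e * 2, EXT_CAP)
    while hi - lo > EXT_START:
        mid = (lo + hi) // 2
        if amplified(mid):
            lo = mid
        else:
            hi = mid
    # the >=20% rule can overrun the amplified core by up to 5x; trim the
    # extent back to the farthest amplified window
    ws = 10_000
    if direction > 0:
        start, end = pos, min(pos + lo, contig_len)
    else:
        start, end = max(pos - lo, 0), pos
    n = max((end - start) // ws, 1)
    counts = (
        index.window_counts(tid, start, start + n * ws, ws)
        * stats.read_length / ws
    )
    thresh = stats.theta(ws) + 3 * stats.sigma(ws)
    amped = np.nonzero(counts > thresh)[0]
    if len(amped) == 0:
        return lo
    if direction > 0:
        return min(int((amped[-1] + 1) * ws), lo)
    return min(int(lo - amped[0] * ws), lo)


def search_intervals(
    seed: tuple,
    pairs: ReadPairs,
    stats: SeqStats,
    contigs: ContigTable,
    max_iterations: int = MAX_ITER,
    pad: int = PAD,
) -> IntervalSet:
    """Grow the amplicon interval set from a seed ``(tid, start, end)``.

    A max-heap ordered by discordant-pair connectivity to previously seen
    intervals drives the search; each mate cluster outside the seen set is
    extended to its amplified extent (doubling + binary refinement), padded
    by 100 kbp and enqueued.  Terminates when the heap empties or after 10
    dequeues.
    """
    tid0, s0, e0 = seed
    index = StartIndex(pairs)
    disc_mask = svdetect.strong_discordant(pairs, stats)
    disc_idx = np.nonzero(disc_mask)[0]

    result = IntervalSet()
    seed_disc = _count_ends_in(pairs, disc_idx, tid0, s0, e0)
    if not is_amplified(tid0, s0, e0, index, stats, n_discordant_edges=seed_disc):
        result.add(tid0, s0, e0)
        result.warning = "seed interval is not amplified"
        return result

    counter = 0
    heap = []  # (-connectivity, counter, interval)
    heapq.heappush(heap, (-np.inf, counter, seed))
    seen = IntervalSet()
    for _ in range(max_iterations):
        if not heap:
            break
        _, _, (tid, s, e) = heapq.heappop(heap)
        pieces = _uncovered(seen, tid, s, e)
        if not pieces:
            continue
        in_iv = np.zeros(len(disc_idx), dtype=bool)
        for ps, pe in pieces:
            seen.add(tid, ps, pe)
            in_iv |= _ends_in_mask(pairs, disc_idx, tid, ps, pe)
        if not in_iv.any():
            continue
        bics = svdetect.cluster_biclusters(
            pairs, disc_idx[in_iv], stats,
            svdetect.ThresholdPolicy("coverage"),
        )
        for b in bics:
            for (mt, mp, _), other in ((b.breakpoint1, b.breakpoint2),
                                       (b.breakpoint2, b.breakpoint1)):
                if seen.contains(mt, mp) or result.overlaps(mt, mp, mp + 1):
                    continue
                clen = contigs.lengths[mt]
                left = _directional_extent(mt, mp, -1, index, stats, clen)
                right = _directional_extent(mt, mp, +1, index, stats, clen)
                if left == 0 and right == 0:
                    small = (mt, max(mp - SMALL_INTERVAL // 2, 0),
                             min(mp + SMALL_INTERVAL // 2, clen))
                    n_edges = _count_ends_in(pairs, disc_idx, *small)
                    if not is_amplified(*small, index, stats, n_discordant_edges=n_edges):
                        continue
                    ext = small
                else:
                    ext = (mt, max(mp - left - pad, 0),
                           min(mp + right + pad, clen))
                counter += 1
                heapq.heappush(heap, (-b.support, counter, ext))
    for tid, s, e in seen:
        result.add(tid, s, e)
    result._normalize()
    return result


def _uncovered(seen: IntervalSet, tid, start, end, min_size=1000):
    """Portions of [start, end) not already in the seen set."""
    pieces = [(start, end)]
    for t, s, e in seen:
        if t != tid:
            continue
        nxt = []
        for a, b in pieces:
            if e <= a or s >= b:
                nxt.append((a, b))
            else:
                if a < s:
                    nxt.append((a, s))
                if e < b:
                    nxt.append((e, b))
        pieces = nxt
    return [(a, b) for a, b in pieces if b - a >= min_size]


def _ends_in_mask(pairs, idx, tid, start, end):
    in1 = (pairs.tid1[idx] == tid) & (pairs.pos1[idx] >= start) & (pairs.pos1[idx] < end)
    in2 = (pairs.tid2[idx] == tid) & (pairs.pos2[idx] >= start) & (pairs.pos2[idx] < end)
    return in1 | in2


def _count_ends_in(pairs, idx, tid, start, end):
    return int(_ends_in_mask(pairs, idx, tid, start, end).sum())


def read_bed(path: str, contigs: ContigTable):
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            out.append((contigs.tid(f[0]), int(f[1]), int(f[2])))
    return out


def write_bed(path: str, intervals, contigs: ContigTable) -> None:
    with open(path, "w") as fh:
        for tid, s, e in intervals:
            fh.write(f"{contigs.names[tid]}\t{s}\t{e}\n")
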