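"""Seed interval selection from CNV calls: merging and track-based filters."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

CN_THRESHOLD = 5.0
SIZE_THRESHOLD = 100_000
MERGE_GAP = 300_000
BLACKLIST_PAD = 1_000_000
DUKE35_MAX = 2.5
ARM_DELTA = 3.0


@dataclass
class AmplifiedInterval:
    chrom: str
    start: int
    end: int
    size: int   # sum of amplified-segment sizes (not end - start)
    cn: float   # size-weighted mean CN of the amplified segments


@dataclass
class AnnotationTracks:
    """Optional annotation tracks; a missing (None) track skips its filter."""

    blacklist: list | None = None          # [(chrom, start, end)]
    mappability: list | None = None        # [(chrom, start, end, score)]
    segdups: list | None = None            # [(chrom, start, end)]
    arm_medians: dict | None = None        # {(chrom, arm_start, arm_end): cn}


def merge_amplified(
    cnv_calls,
    cn_threshold: float = CN_THRESHOLD,
    size_threshold: int = SIZE_THRESHOLD,
    gap: int = MERGE_GAP,
):
    """Merge consecutive amplified CNV segments within ``gap`` bp.

    ``cnv_calls``: iterable of (chrom, start, end, cn).  Interval size is
    the sum of its amplified-segment sizes and its CN the size-weighted
    mean; intervals below ``size_threshold`` are dropped.
    """
    amplified = sorted(
        (c for c in cnv_calls if c[3] > cn_threshold),
        key=lambda c: (c[0], c[1]),
    )
    out = []
    group = []
    for call in amplified:
        if group and (call[0] != group[-1][0] or call[1] - group[-1][2] > gap):
            out.append(_collapse(group))
            group = []
        group.append(call)
    if group:
        out.append(_collapse(group))
    return [iv for iv in out if iv.size >= size_threshold]


def _collapse(group):
    size = sum(e - s for _c, s, e, _cn in group)
    cn = sum((e - s) * cn for _c, s, e, cn in group) / size
    return AmplifiedInterval(
        group[0][0], group[0][1], group[-1][2], size, cn
    )


def _overlap_len(start, end, regions, chrom, pad=0):
    total = 0
    for c, s, e, *rest in regions:
        if c == chrom:
            total += max(0, min(end, e + pad) - max(start, s - pad))
    return total


def _subtract_padded(iv: AmplifiedInterval, regions, pad):
    """Remove portions of the interval within ``pad`` of any region."""
    pieces = [(iv.start, iv.end)]
    for c, s, e in regions:
        if c != iv.chrom:
            continue
        s, e = s - pad, e + pad
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
    return [
        AmplifiedInterval(iv.chrom, a, b, min(iv.size, b - a), iv.cn)
        for a, b in pieces
        if b > a
    ]


def sd_adjusted_cn(iv: AmplifiedInterval, segdups) -> float:
    """CN downscaled by assumed segmental-duplication repeat count of 2:
    CN / (1 + SD-overlap-length / interval-length)."""
    ov = _overlap_len(iv.start, iv.end, segdups, iv.chrom)
    return iv.cn / (1.0 + ov / max(iv.end - iv.start, 1))


def filter_seeds(
    intervals,
    tracks: AnnotationTracks,
    cn_threshold: float = CN_THRESHOLD,
    size_threshold: int = SIZE_THRESHOLD,
):
    """Apply the blacklist / mappability / SD / arm-ploidy seed filters."""
    out = []
    for iv in intervals:
        pieces = [iv]
        if tracks.blacklist is not None:
            pieces = _subtract_padded(iv, tracks.blacklist, BLACKLIST_PAD)
        else:
            log.warning("blacklist track missing; trim filter skipped")
        for piece in pieces:
            if piece.size < size_threshold:
                continue
            if tracks.mappability is not None:
                score = _mean_score(piece, tracks.mappability)
                if score > DUKE35_MAX:
                    continue
            else:
                log.warning("mappability track missing; filter skipped")
            if tracks.segdups is not None:
                if sd_adjusted_cn(piece, tracks.segdups) <= cn_threshold:
                    continue
            else:
                log.warning("segdup track missing; filter skipped")
            if tracks.arm_medians is not None:
                med = _arm_median(piece, tracks.arm_medians)
                if med is not None and piece.cn - med < ARM_DELTA:
                    continue
            else:
                log.warning("arm-median track missing; filter skipped")
            out.append(piece)
    return out


def _mean_score(iv, mappability):
    total_len = 0
    total = 0.0
    for c, s, e, score in mappability:
        if c != iv.chrom:
            continue
        ov = max(0, min(iv.end, e) - max(iv.start, s))
        total += ov * score
        total_len += ov
    if total_len == 0:
        return 1.0  # unannotated: assume unique
    return total / total_len


def _arm_median(iv, arm_medians):
    for (chrom, s, e), med in arm_medians.items():
        if chrom == iv.chrom and s <= iv.start < e:
            return med
    return None


def blacklist_from_normals(normal_call_sets, min_recurrence: int = 2,
                           cn_threshold: float = CN_THRESHOLD):
    """Utility: regions amplified in >= ``min_recurrence`` normal samples."""
    hits = {}
    for calls in normal_call_sets:
        seen = set()
        for chrom, s, e, cn in calls:
            if cn > cn_threshold:
                key = (chrom, s, e)
                if key not in seen:
                    hits[key] = hits.get(key, 0) + 1
                    seen.add(key)
    return [k for k, v in hits.items() if v >= min_recurrence]


def read_cnv_bed(path: str):
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            out.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return out


def write_seeds_bed(path: str, seeds) -> None:
    with open(path, "w") as fh:
        for iv in seeds:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.cn:.3f}\n")
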