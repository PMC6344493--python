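"""Ground-truth amplicon simulator.

Builds circular (and linear) amplicon structures carrying an integrated
viral genome, applies iterative rearrangements, and synthesises paired-end
alignment records directly (no FASTQ / external aligner): sequencing noise
is modelled only as an optional uniform MAPQ-0 fraction, and reads that
cross a structure junction are clipped at the junction like an aligner
would soft-clip them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .records import FWD, REV, ContigTable, ReadPairs, synthetic_reference

DEFAULT_READ_LEN = 100
DEFAULT_INSERT_MEAN = 300
DEFAULT_INSERT_SD = 30
# relaxation floor for the min-segment redraw rule: kept above the
# fragment-skip resolution limit (insert - 2*(R - clip)) so a fragment can
# never step over a whole segment and fake a junction
MIN_SEGMENT_FLOOR = 600


@dataclass
class OrientedSegment:
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def reversed(self) -> "OrientedSegment":
        return OrientedSegment(
            self.chrom, self.start, self.end, "-" if self.strand == "+" else "+"
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "OrientedSegment":
        loc, strand = text.rsplit(":", 1)
        chrom, span = loc.rsplit(":", 1)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass
class AmpliconStructure:
    segments: list
    topology: str = "circular"  # or 'linear'
    copy_number: float = 1.0
    viral_chrom: str | None = None
    operations: list = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def viral_length(self) -> int:
        return sum(
            s.length for s in self.segments if s.chrom == self.viral_chrom
        )

    def is_viral(self, seg: OrientedSegment) -> bool:
        return seg.chrom == self.viral_chrom

    def junctions(self):
        """Adjacent segment-end pairs that are not reference-contiguous.

        Returns ``[((chrom, pos, orient), (chrom, pos, orient)), ...]`` where
        orient '+' means the retained sequence lies left of pos (a segment
        head) and '-' means it lies right of pos (a segment tail).
        """
        out = []
        segs = self.segments
        n = len(segs)
        last = n if self.topology == "circular" else n - 1
        for i in range(last):
            a, b = segs[i], segs[(i + 1) % n]
            if _contiguous(a, b):
                continue
            out.append((_exit_end(a), _entry_end(b)))
        return out

    def truth_line(self) -> str:
        segs = " ".join(str(s) for s in self.segments)
        return f"{self.topology} {self.copy_number:g} {segs}"

    @classmethod
    def from_truth_line(cls, line: str, viral_chrom: str | None = None):
        parts = line.split()
        return cls(
            segments=[OrientedSegment.parse(p) for p in parts[2:]],
            topology=parts[0],
            copy_number=float(parts[1]),
            viral_chrom=viral_chrom,
        )


def _exit_end(seg: OrientedSegment):
    """Breakpoint endpoint left behind when a walk exits ``seg``."""
    if seg.strand == "+":
        return (seg.chrom, seg.end, "+")
    return (seg.chrom, seg.start, "-")


def _entry_end(seg: OrientedSegment):
    if seg.strand == "+":
        return (seg.chrom, seg.start, "-")
    return (seg.chrom, seg.end, "+")


def _contiguous(a: OrientedSegment, b: OrientedSegment) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.strand == "+":
        return a.end == b.start
    return a.start == b.end


def _merge_adjacent(segments, circular: bool):
    if not segments:
        return segments
    out = [segments[0]]
    for seg in segments[1:]:
        if _contiguous(out[-1], seg):
            prev = out.pop()
            if prev.strand == "+":
                seg = OrientedSegment(prev.chrom, prev.start, seg.end, "+")
            else:
                seg = OrientedSegment(prev.chrom, seg.start, prev.end, "-")
        out.append(seg)
    if circular and len(out) > 1 and _contiguous(out[-1], out[0]):
        last, first = out[-1], out[0]
        if last.strand == "+":
            merged = OrientedSegment(last.chrom, last.start, first.end, "+")
        else:
            merged = OrientedSegment(last.chrom, first.start, last.end, "-")
        out = [merged] + out[1:-1]
    return out


def write_truth(path: str, structures) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(s.truth_line() + "\n")


def read_truth(path: str, viral_chrom: str | None = None):
    with open(path) as fh:
        return [
            AmpliconStructure.from_truth_line(ln, viral_chrom)
            for ln in fh
            if ln.strip()
        ]


# ---------------------------------------------------------------------------
# structure-space arc operations


def _split_at(segments, p: int):
    """Split the segment list at structure offset p (0 < p < total)."""
    out = []
    off = 0
    for seg in segments:
        if off < p < off + seg.length:
            d = p - off
            if seg.strand == "+":
                out.append(OrientedSegment(seg.chrom, seg.start, seg.start + d, "+"))
                out.append(OrientedSegment(seg.chrom, seg.start + d, seg.end, "+"))
            else:
                out.append(OrientedSegment(seg.chrom, seg.end - d, seg.end, "-"))
                out.append(OrientedSegment(seg.chrom, seg.start, seg.end - d, "-"))
        else:
            out.append(seg)
        off += seg.length
    return out


def _extract_arc(segments, p1: int, p2: int, circular: bool):
    """Return (arc, rest) for the arc running forward from p1 to p2."""
    total = sum(s.length for s in segments)
    segs = _split_at(segments, p1 % total if circular else p1)
    segs = _split_at(segs, p2 % total if circular else p2)
    rest = []
    head, tail = [], []  # arc pieces (tail wraps through the origin)
    for seg, off in zip_offsets(segs):
        if circular and p1 > p2:
            if off >= p1:
                head.append(seg)
            elif off < p2:
                tail.append(seg)
            else:
                rest.append(seg)
        else:
            (head if p1 <= off < p2 else rest).append(seg)
    return head + tail, rest


def zip_offsets(segments):
    off = 0
    for seg in segments:
        yield seg, off
        off += seg.length


def _insert_at(segments, arc, p: int):
    segs = _split_at(segments, p)
    out = []
    off = 0
    placed = p == 0
    if placed:
        out.extend(arc)
    for seg in segs:
        out.append(seg)
        off += seg.length
        if not placed and off == p:
            out.extend(arc)
            placed = True
    if not placed:
        out.extend(arc)
    return out


def apply_operation(structure: AmpliconStructure, op) -> AmpliconStructure:
    """Apply one logged rearrangement ``(type, p1, p2, p3)`` (p3 may be None).

    Positions are structure offsets *at the time of application*; this is the
    replay contract used by the truth/oracle tests.
    """
    kind, p1, p2, p3 = op
    circular = structure.topology == "circular"
    segs = structure.segments
    arc, rest = _extract_arc(segs, p1, p2, circular)
    if kind == "deletion":
        new = rest
    elif kind == "inversion":
        inv = [s.reversed() for s in reversed(arc)]
        new = _reassemble(segs, p1, p2, inv, circular)
    elif kind == "tandem_duplication":
        new = _reassemble(segs, p1, p2, arc + arc, circular)
    elif kind == "inverted_duplication":
        inv = [s.reversed() for s in reversed(arc)]
        new = _reassemble(segs, p1, p2, arc + inv, circular)
    elif kind in ("translocation", "translocated_duplication"):
        # p3 is an offset into `rest`
        keep = kind == "translocated_duplication"
        base = _reassemble(segs, p1, p2, arc, circular) if keep else rest
        new = _insert_at(base, [copy.copy(s) for s in arc], p3)
    else:
        raise ValueError(f"unknown rearrangement type {kind!r}")
    new = _merge_adjacent(new, circular)
    out = AmpliconStructure(
        segments=new,
        topology=structure.topology,
        copy_number=structure.copy_number,
        viral_chrom=structure.viral_chrom,
        operations=structure.operations + [op],
    )
    return out


def _reassemble(segments, p1, p2, replacement, circular):
    """Replace the arc (p1, p2) by ``replacement`` in place."""
    arc, rest = _extract_arc(segments, p1, p2, circular)
    if circular and p1 > p2:
        # rest runs from p2 to p1; replacement goes after it
        return rest + replacement
    # rest = prefix + suffix; insert replacement at offset p1 within rest
    out, off = [], 0
    placed = False
    for seg in rest:
        if not placed and off >= p1:
            out.extend(replacement)
            placed = True
        out.append(seg)
        off += seg.length
    if not placed:
        out.extend(replacement)
    return out


# ---------------------------------------------------------------------------
# SimConfig + simulate_structure


@dataclass(frozen=True)
class SimConfig:
    interval_size: int
    copy_number: float
    n_rearrangements: int
    p_duplication: float
    coverage: float
    seed: int = 0
    read_len: int = DEFAULT_READ_LEN
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD

    def __post_init__(self):
        if not (0.0 <= self.p_duplication <= 1.0):
            raise ValueError("p_duplication outside [0, 1]")


_NONDUP = ("deletion", "inversion", "translocation")


def simulate_structure(
    cfg: SimConfig,
    reference: ContigTable,
    rng,
    viral_contig: str = "hpv16",
    human_contig: str | None = None,
    min_segment: int = 1000,
    max_total: int | None = None,
    max_growth: float = 16.0,
) -> AmpliconStructure:
    """Simulate one circular viral-hybrid amplicon via iterative rearrangement.

    The viral contig is integrated at a uniform-random human site; an
    ``interval_size`` window at the site is circularized with the virus at
    the wrap junction (so the unrearranged circle is exactly two segments);
    then ``n_rearrangements`` arc operations are applied, each a duplication
    with probability ``p_duplication`` and otherwise uniform over deletion,
    inversion and translocation. Operations that would delete every viral
    base, create a segment shorter than ``min_segment`` or shrink the
    structure below 5 kbp are redrawn.
    """
    if viral_contig not in reference:
        raise ValueError(f"reference lacks viral contig {viral_contig!r}")
    vlen = reference.length(viral_contig)
    if cfg.interval_size < vlen:
        raise ValueError("interval_size smaller than the viral contig")
    if human_contig is None:
        human_contig = next(n for n in reference.names if n != viral_contig)
    hlen = reference.length(human_contig)
    if cfg.interval_size >= hlen:
        raise ValueError("interval_size exceeds human contig")
    if max_total is None:
        # keep final sizes inside the envelope the source material reports
        # for simulated amplicons (40 kbp - 10 Mbp) instead of letting
        # repeated whole-arc duplications blow a small window up 300-fold
        max_total = min(12_000_000, int(max_growth * (cfg.interval_size + vlen)))
    site = int(rng.integers(0, hlen - cfg.interval_size))
    segments = [
        OrientedSegment(human_contig, site, site + cfg.interval_size, "+"),
        OrientedSegment(viral_contig, 0, vlen, "+"),
    ]
    structure = AmpliconStructure(
        segments=segments,
        topology="circular",
        copy_number=cfg.copy_number,
        viral_chrom=viral_contig,
    )
    min_total = 10_000
    for _ in range(cfg.n_rearrangements):
        structure = _draw_op(
            structure, rng, cfg.p_duplication, min_segment, min_total,
            max_total=max_total,
        )
    return structure


def _draw_positions(total: int, rng, circular: bool):
    """Two uniform breakpoints; on a circle the arc may wrap the origin."""
    p1, p2 = (int(rng.integers(1, total)) for _ in range(2))
    if not circular and p1 > p2:
        p1, p2 = p2, p1
    return p1, p2


def _draw_op(structure, rng, p_dup, min_segment, min_total,
             max_total=None, max_tries=300):
    # constraints must not outlaw the *current* state (earlier relaxed draws
    # may have left shorter segments or a smaller structure)
    floor = min(min_segment, min(s.length for s in structure.segments))
    min_total = min(min_total, structure.total_length)
    gap = JUNCTION_GAP_FLOOR
    for attempt in range(max_tries * 6):
        if attempt and attempt % max_tries == 0:
            # progressively relax the constraints rather than fail
            floor = max(MIN_SEGMENT_FLOOR // 2, floor // 2)
            min_total = max(3000, min_total // 2)
            if attempt >= max_tries * 3:
                gap = 0  # crowded corner: drop the resolution guard
        if rng.random() < p_dup:
            kind = "tandem_duplication"
        else:
            kind = _NONDUP[int(rng.integers(0, len(_NONDUP)))]
        total = structure.total_length
        p1, p2 = _draw_positions(total, rng, structure.topology == "circular")
        if p1 == p2:
            continue
        p3 = None
        if kind in ("translocation", "translocated_duplication"):
            arc_len = (p2 - p1) % total
            rest_len = total - arc_len if kind == "translocation" else total
            if rest_len <= 1:
                continue
            p3 = int(rng.integers(0, rest_len + 1))
        op = (kind, p1, p2, p3)
        cand = apply_operation(structure, op)
        if _valid_structure(cand, floor, min_total, max_total,
                            junction_gap=min(gap, floor)):
            return cand
    raise RuntimeError("could not draw a valid rearrangement")


JUNCTION_GAP_FLOOR = 400  # read-pair clustering resolution (~mu_I + 3 sigma)


def _valid_structure(s: AmpliconStructure, min_segment, min_total,
                     max_total=None, junction_gap=JUNCTION_GAP_FLOOR) -> bool:
    if not s.segments or s.total_length < min_total:
        return False
    if max_total is not None and s.total_length > max_total:
        return False
    if s.viral_chrom and s.viral_length() == 0:
        return False
    if any(seg.length < min_segment for seg in s.segments):
        return False
    if junction_gap:
        # distinct junction coordinates below the read-pair clustering
        # resolution are irresolvable without split reads; identical
        # coordinates (repeated copies of the same junction) are fine
        by_chrom = {}
        for j in s.junctions():
            for chrom, pos, _o in j:
                by_chrom.setdefault(chrom, set()).add(pos)
        for positions in by_chrom.values():
            ps = sorted(positions)
            if any(b - a < junction_gap for a, b in zip(ps[:-1], ps[1:])):
                return False
    return True


# ---------------------------------------------------------------------------
# parameter grids (base 960 + 24 large structures -> 1248 instances)

INTERVAL_SIZES = (40_000, 160_000, 640_000, 2_400_000)
COPY_NUMBERS = (4, 16, 32)
N_REARRANGEMENTS = (0, 4, 8, 16, 32)
P_DUPLICATIONS = (0.0, 0.25, 0.5, 0.75)
COVERAGES = (1, 4, 16, 32)
LARGE_SIZES = (5_000_000, 10_000_000)
LARGE_REARRANGEMENTS = (0, 8, 32)


def base_grid():
    """The 960-config cross product of the base simulation parameters."""
    return [
        SimConfig(sz, cn, nr, pd, cov, seed=i)
        for i, (sz, cn, nr, pd, cov) in enumerate(
            product(
                INTERVAL_SIZES, COPY_NUMBERS, N_REARRANGEMENTS,
                P_DUPLICATIONS, COVERAGES,
            )
        )
    ]


def large_grid():
    """The 24 large-amplicon structures (CN 32, coverage 32)."""
    return [
        SimConfig(sz, 32, nr, pd, 32, seed=10_000 + i)
        for i, (sz, nr, pd) in enumerate(
            product(LARGE_SIZES, LARGE_REARRANGEMENTS, P_DUPLICATIONS)
        )
    ]


def build_grid():
    """All 1248 simulation instances: the 960 base configs plus the 24
    large structures expanded over the downsampling grid CN x coverage."""
    base = base_grid()
    large = large_grid()
    instances = list(base)
    for cfg in large:
        for cn, cov in product(COPY_NUMBERS, COVERAGES):
            instances.append(
                SimConfig(
                    cfg.interval_size, cn, cfg.n_rearrangements,
                    cfg.p_duplication, cov, seed=cfg.seed,
                )
            )
    return base, large, instances


# ---------------------------------------------------------------------------
# alignment-record generation


def simulate_alignments(
    structure: AmpliconStructure,
    coverage: float,
    reference: ContigTable,
    rng,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    background_ploidy: int = 2,
    with_background: bool = True,
    mapq: int = 60,
    mapq0_fraction: float = 0.0,
) -> ReadPairs:
    """Synthesize aligned read pairs for a structure plus genome background.

    ``coverage`` is the diploid background depth; the amplicon is sequenced
    at ``coverage * copy_number / 2``.  Fragments are drawn uniformly along
    the (circular) structure with Normal(insert_mean, insert_sd) inserts;
    each read end is mapped back to reference coordinates of the segment
    holding the majority of the read and clipped at junctions.
    """
    if not structure.segments:
        raise ValueError("empty structure")
    if any(s.length < read_len for s in structure.segments):
        raise ValueError("segment shorter than the read length")
    if coverage < 0:
        raise ValueError("negative coverage")
    parts = []
    total = structure.total_length
    amp_depth = coverage * structure.copy_number / 2.0
    n_amp = int(round(total * amp_depth / (2 * read_len)))
    if n_amp > 0:
        parts.append(
            _structure_pairs(
                structure, n_amp, reference, rng, read_len,
                insert_mean, insert_sd, mapq,
            )
        )
    if with_background and coverage > 0:
        depth = coverage * background_ploidy / 2.0
        for name, length in zip(reference.names, reference.lengths):
            if structure.viral_chrom is not None and name == structure.viral_chrom:
                continue  # no germline viral background
            n_bg = int(round(length * depth / (2 * read_len)))
            if n_bg:
                parts.append(
                    _background_pairs(
                        reference.tid(name), length, n_bg, rng,
                        read_len, insert_mean, insert_sd, mapq,
                    )
                )
    pairs = ReadPairs.concat(parts)
    if mapq0_fraction > 0 and len(pairs):
        hit = rng.random(len(pairs)) < mapq0_fraction
        pairs.mapq1[hit] = 0
        pairs.mapq2[hit] = 0
    return pairs


def _structure_pairs(structure, n, reference, rng, read_len, mu, sd, mapq):
    total = structure.total_length
    circular = structure.topology == "circular"
    starts = rng.integers(0, total, size=n)
    inserts = np.maximum(
        np.round(rng.normal(mu, sd, size=n)).astype(np.int64), read_len + 10
    )
    if not circular:
        starts = np.minimum(starts, np.maximum(total - inserts, 0))
        inserts = np.minimum(inserts, total - starts)
    r1 = starts
    r2 = starts + inserts - read_len
    if circular:
        r2 = r2 % total
    tid1, pos1, strand1, alen1 = _map_reads(structure, reference, r1, read_len, forward=True)
    tid2, pos2, strand2, alen2 = _map_reads(structure, reference, r2, read_len, forward=False)
    span = np.maximum(pos1 + alen1, pos2 + alen2) - np.minimum(pos1, pos2)
    fr = (
        (tid1 == tid2)
        & (strand1 != strand2)
        & (
            np.where(strand1 == FWD, pos1, pos2)
            <= np.where(strand1 == FWD, pos2, pos1)
        )
    )
    proper = fr & (span >= read_len) & (span <= mu + 4 * sd)
    m = np.full(n, mapq, dtype=np.int64)
    return ReadPairs(
        tid1=tid1, pos1=pos1, strand1=strand1, alen1=alen1, mapq1=m,
        tid2=tid2, pos2=pos2, strand2=strand2, alen2=alen2, mapq2=m.copy(),
        proper=proper, read_len=np.full(n, read_len, dtype=np.int64),
    )


def _map_reads(structure, reference, xs, read_len, forward):
    """Map structure-space read intervals [x, x+R) to reference coordinates.

    Returns (tid, pos, strand, alen); reads spanning a junction are clipped
    to the segment holding the majority of the read.
    """
    segs = structure.segments
    total = structure.total_length
    bounds = np.cumsum([0] + [s.length for s in segs])
    seg_tid = np.array([reference.tid(s.chrom) for s in segs])
    seg_start = np.array([s.start for s in segs])
    seg_end = np.array([s.end for s in segs])
    seg_rev = np.array([s.strand == "-" for s in segs])

    n = len(xs)
    xs = np.asarray(xs, dtype=np.int64)
    ends = xs + read_len
    wrap = ends > total
    tid = np.zeros(n, dtype=np.int64)
    pos = np.zeros(n, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int64)
    alen = np.zeros(n, dtype=np.int64)

    core = ~wrap
    xi = xs[core]
    ei = ends[core]
    i1 = np.searchsorted(bounds, xi, side="right") - 1
    i2 = np.searchsorted(bounds, ei - 1, side="right") - 1
    same = i1 == i2
    # straddling reads: pick the segment with the larger overlap (tie -> left)
    ov1 = bounds[i1 + 1] - xi
    ov2 = ei - bounds[np.minimum(i2, len(segs) - 1)]
    pick = np.where(same | (ov1 >= ov2), i1, i2)
    # reads spanning >2 segments are impossible when min segment >= R
    cs = np.maximum(xi, bounds[pick])
    ce = np.minimum(ei, bounds[pick + 1])
    off = cs - bounds[pick]
    ln = ce - cs
    rev = seg_rev[pick]
    p = np.where(rev, seg_end[pick] - off - ln, seg_start[pick] + off)
    s = rev.astype(np.int64) if forward else (~rev).astype(np.int64)
    tid[core] = seg_tid[pick]
    pos[core] = p
    strand[core] = s
    alen[core] = ln

    for idx in np.nonzero(wrap)[0]:  # rare: read crosses the circle origin
        x = int(xs[idx])
        len_a = total - x
        if len_a >= read_len - len_a:
            k, cs_, ce_ = len(segs) - 1, x, total
            # may span inner boundary too; clamp into final segment
            k = int(np.searchsorted(bounds, cs_, side="right") - 1)
            ce_ = min(ce_, int(bounds[k + 1]))
        else:
            k, cs_, ce_ = 0, 0, read_len - len_a
            ce_ = min(ce_, int(bounds[1]))
        off_ = cs_ - int(bounds[k])
        ln_ = ce_ - cs_
        seg = segs[k]
        if seg.strand == "-":
            p_ = seg.end - off_ - ln_
            s_ = FWD if not forward else REV
        else:
            p_ = seg.start + off_
            s_ = FWD if forward else REV
        tid[idx], pos[idx], strand[idx], alen[idx] = (
            reference.tid(seg.chrom), p_, s_, ln_,
        )
    return tid, pos, strand, alen


def _background_pairs(tid, length, n, rng, read_len, mu, sd, mapq):
    inserts = np.clip(
        np.round(rng.normal(mu, sd, size=n)).astype(np.int64),
        2 * read_len, None,
    )
    starts = rng.integers(0, np.maximum(length - inserts, 1))
    pos1 = starts
    pos2 = starts + inserts - read_len
    t = np.full(n, tid, dtype=np.int64)
    m = np.full(n, mapq, dtype=np.int64)
    rl = np.full(n, read_len, dtype=np.int64)
    return ReadPairs(
        tid1=t, pos1=pos1, strand1=np.zeros(n, dtype=np.int64), alen1=rl.copy(),
        mapq1=m,
        tid2=t.copy(), pos2=pos2, strand2=np.ones(n, dtype=np.int64),
        alen2=rl.copy(), mapq2=m.copy(),
        proper=np.ones(n, dtype=bool), read_len=rl,
    )


# ---------------------------------------------------------------------------
# viral-integration simulation sets (unifocal / bifocal)

VIRAL_OP_TYPES = (
    "translocated_duplication", "tandem_duplication", "inverted_duplication",
    "translocation", "inversion", "deletion",
)
VIRAL_OP_PROBS = (0.19, 0.19, 0.19, 0.19, 0.19, 0.05)


def draw_amplicon_length(rng, mean=155_000, minimum=3_000) -> int:
    ln = 0
    while ln < minimum:
        ln = int(rng.exponential(mean))
    return ln


def simulate_viral_set(
    kind: str,
    topology: str,
    rng,
    n: int = 40,
    n_iterations: int = 20,
    reference: ContigTable | None = None,
    viral_contig: str = "hpv16",
    mean_length: float = 155_000,
    min_segment: int = 200,
):
    """Simulate ``n`` viral-integration amplicons with per-iteration snapshots.

    kind 'unifocal' starts from (BVC)/BVC and 'bifocal' from (BV)/BVB;
    amplicon lengths are Exponential(mean 155 kbp); each of the 20 iterations
    applies one rearrangement drawn from the six types at probabilities
    {0.19 x5, 0.05}, never deleting the virus entirely.  Returns a list of
    snapshot lists (iteration 0 .. n_iterations).
    """
    if kind not in ("unifocal", "bifocal"):
        raise ValueError(kind)
    if topology not in ("circular", "linear"):
        raise ValueError(topology)
    if reference is None:
        reference = synthetic_reference()
    human = next(nm for nm in reference.names if nm != viral_contig)
    hlen = reference.length(human)
    vlen = reference.length(viral_contig)
    results = []
    for _ in range(n):
        ln = draw_amplicon_length(rng, mean_length, minimum=3 * min_segment)
        a = int(rng.integers(0, hlen - ln))
        virus = OrientedSegment(viral_contig, 0, vlen, "+")
        if kind == "unifocal":
            u = int(rng.integers(min_segment, ln - min_segment))
            b = OrientedSegment(human, a, a + u, "+")
            c = OrientedSegment(human, a + u, a + ln, "+")
            segs = [b, virus, c]
        else:
            b = OrientedSegment(human, a, a + ln, "+")
            segs = [b, virus] if topology == "circular" else [b, virus, copy.copy(b)]
        structure = AmpliconStructure(
            segments=segs, topology=topology, copy_number=1.0,
            viral_chrom=viral_contig,
        )
        snapshots = [structure]
        for _ in range(n_iterations):
            structure = _draw_viral_op(structure, rng, min_segment)
            snapshots.append(structure)
        results.append(snapshots)
    return results


def _draw_viral_op(structure, rng, min_segment, max_tries=400):
    for _ in range(max_tries):
        kind = VIRAL_OP_TYPES[
            int(rng.choice(len(VIRAL_OP_TYPES), p=VIRAL_OP_PROBS))
        ]
        total = structure.total_length
        if total < 3 * min_segment:
            min_segment = max(50, total // 10)
        p1, p2 = _draw_positions(total, rng, structure.topology == "circular")
        if p1 == p2:
            continue
        p3 = None
        if kind in ("translocation", "translocated_duplication"):
            arc_len = (p2 - p1) % total
            rest_len = total - arc_len if kind == "translocation" else total
            if rest_len <= 1:
                continue
            p3 = int(rng.integers(0, rest_len + 1))
        cand = apply_operation(structure, (kind, p1, p2, p3))
        # signature tests read exact truth geometry, so the read-pair
        # resolution (junction-gap) guard does not apply here
        if _valid_structure(cand, min_segment, 3 * min_segment,
                            junction_gap=0):
            return cand
    raise RuntimeError("could not draw a valid viral rearrangement")
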