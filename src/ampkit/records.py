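"""Columnar paired-end alignment records, contig tables and SAM round-trip.

Alignment records are stored one *pair* per row in parallel numpy arrays;
this keeps million-pair simulated libraries cheap to generate, sort and
query.  ``AlignmentRecord`` offers a per-read dataclass view, and
:func:`write_sam` / :func:`read_sam` convert to and from standard SAM via
pysam (text SAM only — the deliverable stays plain text).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

FWD = 0
REV = 1

_STRAND = {0: "+", 1: "-"}


@dataclass(frozen=True)
class ContigTable:
    """Ordered reference contig names and lengths."""

    names: tuple
    lengths: tuple

    def __post_init__(self):
        if len(self.names) != len(self.lengths):
            raise ValueError("names/lengths size mismatch")

    def tid(self, name: str) -> int:
        return self.names.index(name)

    def length(self, name: str) -> int:
        return self.lengths[self.tid(name)]

    def __contains__(self, name) -> bool:
        return name in self.names

    def to_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [
                    {"SN": n, "LN": int(ln)}
                    for n, ln in zip(self.names, self.lengths)
                ],
            }
        )

    @classmethod
    def from_header(cls, header: pysam.AlignmentHeader) -> "ContigTable":
        d = header.to_dict()
        return cls(
            names=tuple(sq["SN"] for sq in d["SQ"]),
            lengths=tuple(int(sq["LN"]) for sq in d["SQ"]),
        )


def synthetic_reference(
    human_length: int = 12_000_000,
    viral_length: int = 7_904,
    human_name: str = "chr1",
    viral_name: str = "hpv16",
) -> ContigTable:
    """Desk-scale reference: one human contig plus a viral contig.

    7904 bp is the HPV16 genome length; the viral contig acts as the
    de-facto seed interval for simulated hybrid amplicons.
    """
    return ContigTable((human_name, viral_name), (human_length, viral_length))


@dataclass
class AlignmentRecord:
    """Single-read view of one end of a pair."""

    read_id: int
    contig: str
    pos: int
    strand: str
    mapq: int
    mate_contig: str
    mate_pos: int
    mate_strand: str
    template_length: int
    read_length: int
    aligned_length: int
    is_proper: bool
    is_read1: bool


class ReadPairs:
    """One read pair per row, columnar.

    Fields (all numpy arrays of equal length): ``tid1, pos1, strand1, alen1,
    mapq1`` and the ``2`` twins, plus ``proper`` (aligner-style proper-pair
    flag) and ``read_len`` (full read length; ``alen`` may be shorter when a
    simulated read was clipped at an amplicon junction).
    """

    FIELDS = (
        "tid1", "pos1", "strand1", "alen1", "mapq1",
        "tid2", "pos2", "strand2", "alen2", "mapq2",
        "proper", "read_len",
    )

    def __init__(self, **arrays):
        n = None
        for f in self.FIELDS:
            a = np.asarray(arrays[f])
            if n is None:
                n = len(a)
            elif len(a) != n:
                raise ValueError(f"field {f} length mismatch")
            setattr(self, f, a)
        self._n = n or 0
        self._start_index = None

    def __len__(self) -> int:
        return self._n

    @classmethod
    def empty(cls) -> "ReadPairs":
        z = np.zeros(0, dtype=np.int64)
        return cls(
            tid1=z, pos1=z, strand1=z, alen1=z, mapq1=z,
            tid2=z, pos2=z, strand2=z, alen2=z, mapq2=z,
            proper=np.zeros(0, dtype=bool), read_len=z,
        )

    @classmethod
    def concat(cls, parts) -> "ReadPairs":
        parts = [p for p in parts if len(p) > 0]
        if not parts:
            return cls.empty()
        return cls(**{
            f: np.concatenate([getattr(p, f) for p in parts])
            for f in cls.FIELDS
        })

    def subset(self, sel) -> "ReadPairs":
        return ReadPairs(**{f: getattr(self, f)[sel] for f in self.FIELDS})

    def thin(self, fraction: float, rng) -> "ReadPairs":
        """Uniform read-pair downsampling (coverage capping)."""
        if fraction >= 1.0:
            return self
        keep = rng.random(len(self)) < fraction
        return self.subset(keep)

    # -- span helpers -------------------------------------------------
    def outer_span(self) -> np.ndarray:
        """Outermost mapping distance for same-contig pairs (else -1)."""
        left = np.minimum(self.pos1, self.pos2)
        right = np.maximum(self.pos1 + self.alen1, self.pos2 + self.alen2)
        span = right - left
        return np.where(self.tid1 == self.tid2, span, -1)

    def record(self, i: int, contigs: ContigTable, end: int) -> AlignmentRecord:
        a, b = (1, 2) if end == 1 else (2, 1)
        g = lambda f, e: getattr(self, f"{f}{e}")[i]
        return AlignmentRecord(
            read_id=i,
            contig=contigs.names[g("tid", a)],
            pos=int(g("pos", a)),
            strand=_STRAND[int(g("strand", a))],
            mapq=int(g("mapq", a)),
            mate_contig=contigs.names[g("tid", b)],
            mate_pos=int(g("pos", b)),
            mate_strand=_STRAND[int(g("strand", b))],
            template_length=int(self.outer_span()[i]),
            read_length=int(self.read_len[i]),
            aligned_length=int(g("alen", a)),
            is_proper=bool(self.proper[i]),
            is_read1=end == 1,
        )


class StartIndex:
    """Per-contig sorted alignment-start positions for coverage queries.

    Counts *alignment starts* — the single coverage convention used across
    the package (coverage of a window = starts * R / ws).
    """

    def __init__(self, pairs: ReadPairs, mapq_min: int = 0):
        self._starts = {}
        tids = np.concatenate([pairs.tid1, pairs.tid2])
        poss = np.concatenate([pairs.pos1, pairs.pos2])
        if mapq_min > 0:
            mq = np.concatenate([pairs.mapq1, pairs.mapq2])
            keep = mq >= mapq_min
            tids, poss = tids[keep], poss[keep]
        for tid in np.unique(tids):
            self._starts[int(tid)] = np.sort(poss[tids == tid])

    def starts(self, tid: int) -> np.ndarray:
        return self._starts.get(int(tid), np.zeros(0, dtype=np.int64))

    def count(self, tid: int, start: int, end: int) -> int:
        s = self.starts(tid)
        return int(np.searchsorted(s, end) - np.searchsorted(s, start))

    def window_counts(self, tid: int, start: int, end: int, ws: int) -> np.ndarray:
        """Start counts for windows tiling [start, end) with size ws."""
        edges = np.arange(start, end + ws, ws)
        edges[-1] = min(edges[-1], end) if edges[-1] > end else edges[-1]
        s = self.starts(tid)
        idx = np.searchsorted(s, edges)
        return np.diff(idx)


# ---------------------------------------------------------------------------
# SAM round trip


def write_sam(path: str, pairs: ReadPairs, contigs: ContigTable) -> None:
    header = contigs.to_header()
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in range(len(pairs)):
            for end in (1, 2):
                out.write(_to_segment(pairs, i, end, header))


def _to_segment(pairs: ReadPairs, i: int, end: int, header) -> pysam.AlignedSegment:
    a, b = (1, 2) if end == 1 else (2, 1)
    g = lambda f, e: int(getattr(pairs, f"{f}{e}")[i])
    seg = pysam.AlignedSegment(header)
    seg.query_name = f"p{i}"
    rl, alen = int(pairs.read_len[i]), g("alen", a)
    flag = 0x1  # paired
    if pairs.proper[i]:
        flag |= 0x2
    if g("strand", a) == REV:
        flag |= 0x10
    if g("strand", b) == REV:
        flag |= 0x20
    flag |= 0x40 if end == 1 else 0x80
    seg.flag = flag
    seg.reference_id = g("tid", a)
    seg.reference_start = g("pos", a)
    seg.mapping_quality = g("mapq", a)
    clip = rl - alen
    if clip > 0:
        # clip on the 3' side in reference orientation for forward reads
        cig = [(0, alen), (4, clip)] if g("strand", a) == FWD else [(4, clip), (0, alen)]
    else:
        cig = [(0, alen)]
    seg.cigartuples = cig
    seg.next_reference_id = g("tid", b)
    seg.next_reference_start = g("pos", b)
    if g("tid", a) == g("tid", b):
        left = min(g("pos", a), g("pos", b))
        right = max(g("pos", a) + g("alen", a), g("pos", b) + g("alen", b))
        tlen = right - left
        seg.template_length = tlen if g("pos", a) <= g("pos", b) else -tlen
    seg.query_sequence = "N" * rl
    seg.query_qualities = pysam.qualitystring_to_array("I" * rl)
    return seg


def read_sam(path: str):
    """Read a (queryname-pairable) SAM file -> (ReadPairs, ContigTable)."""
    cols = {f: [] for f in ReadPairs.FIELDS}
    pending = {}
    with pysam.AlignmentFile(path, "r") as fh:
        contigs = ContigTable.from_header(fh.header)
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.query_name in pending:
                first = pending.pop(seg.query_name)
                r1, r2 = (first, seg) if first.is_read1 else (seg, first)
                for e, s in ((1, r1), (2, r2)):
                    cols[f"tid{e}"].append(s.reference_id)
                    cols[f"pos{e}"].append(s.reference_start)
                    cols[f"strand{e}"].append(REV if s.is_reverse else FWD)
                    cols[f"alen{e}"].append(s.reference_length or s.query_length)
                    cols[f"mapq{e}"].append(s.mapping_quality)
                cols["proper"].append(bool(r1.is_proper_pair))
                cols["read_len"].append(r1.query_length or r1.infer_read_length() or 0)
            else:
                pending[seg.query_name] = seg
    arrays = {
        f: np.asarray(v, dtype=bool if f == "proper" else np.int64)
        for f, v in cols.items()
    }
    return ReadPairs(**arrays), contigs
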