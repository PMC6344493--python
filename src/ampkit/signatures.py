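"""Human-viral fusion amplicon selection and integration-signature calls.

Signatures over chimeric (human-viral) junctions:

* unifocal — two reciprocal chimeric edges, opposite strands on both
  genomes, human positions within 1 kbp: a single insertion point;
* strong bifocal — an opposite-orientation chimeric pair flanking the
  entire amplified human region (virus on both ends, suggesting circular
  hybrid ecDNA);
* weak bifocal — the flanked segments all exceed every other segment's
  copy number (strict).

Precedence: unifocal > strong bifocal > weak bifocal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bpgraph import SOURCE, BreakpointGraph
from .simgen import AmpliconStructure

UNIFOCAL_TOL = 1_000
FLANK_TOL = 1_000
MERGE_GAP = 5_000_000
AMP_CN = 2.5
MEAN_CN = 3.0


@dataclass
class ChimericEdge:
    chrom: str
    human_pos: int
    human_orient: str  # '+': human sequence continues left of pos
    viral_pos: int
    viral_orient: str


@dataclass
class HumanSegment:
    chrom: str
    start: int
    end: int
    cn: float


@dataclass
class SignatureCall:
    label: str  # unifocal | strong_bifocal | weak_bifocal | none
    evidence: list = field(default_factory=list)


def classify_signature(
    junctions,
    human_segments,
    tol: int = UNIFOCAL_TOL,
    flank_tol: int = FLANK_TOL,
    amp_cn: float = AMP_CN,
) -> SignatureCall:
    """Classify one amplicon from its chimeric junctions and human segments."""
    junctions = list(junctions)
    segments = list(human_segments)
    # unifocal: reciprocal pair at one human locus
    for a in junctions:
        for b in junctions:
            if a is b or a.chrom != b.chrom:
                continue
            if (
                a.human_orient != b.human_orient
                and a.viral_orient != b.viral_orient
                and abs(a.human_pos - b.human_pos) <= tol
            ):
                return SignatureCall("unifocal", [a, b])

    amplified = [s for s in segments if s.cn > amp_cn] or segments
    if amplified:
        # evaluate flanking on the chromosome of the highest-CN segment
        top_chrom = max(amplified, key=lambda s: s.cn).chrom
        chrom_segs = [s for s in amplified if s.chrom == top_chrom]
        hmin = min(s.start for s in chrom_segs)
        hmax = max(s.end for s in chrom_segs)
        left = [
            j for j in junctions
            if j.chrom == top_chrom and j.human_orient == "-"
            and abs(j.human_pos - hmin) <= flank_tol
        ]
        right = [
            j for j in junctions
            if j.chrom == top_chrom and j.human_orient == "+"
            and abs(j.human_pos - hmax) <= flank_tol
        ]
        if left and right:
            return SignatureCall("strong_bifocal", [left[0], right[0]])

    # weak bifocal: opposite-orientation pair whose flanked segments beat
    # every other segment's CN (strict)
    for a in junctions:
        for b in junctions:
            if a.chrom != b.chrom:
                continue
            if a.human_orient == "-" and b.human_orient == "+" and a.human_pos < b.human_pos:
                inside = [
                    s for s in segments
                    if s.chrom == a.chrom
                    and s.start >= a.human_pos - flank_tol
                    and s.end <= b.human_pos + flank_tol
                ]
                outside = [s for s in segments if s not in inside]
                if inside and outside:
                    if min(s.cn for s in inside) > max(s.cn for s in outside):
                        return SignatureCall("weak_bifocal", [a, b])
    return SignatureCall("none")


# ---------------------------------------------------------------------------
# inputs from truth structures (simulation replay) or breakpoint graphs


def structure_signature_inputs(structure: AmpliconStructure):
    """Chimeric junctions + human segment copy profile of a truth structure.

    Human segment copy numbers are occurrence multiplicities (scaled by the
    structure copy number), merged over identical reference intervals.
    """
    viral = structure.viral_chrom
    junctions = []
    for (c1, p1, o1), (c2, p2, o2) in structure.junctions():
        first_viral = c1 == viral
        second_viral = c2 == viral
        if first_viral == second_viral:
            continue
        if first_viral:
            junctions.append(ChimericEdge(c2, p2, o2, p1, o1))
        else:
            junctions.append(ChimericEdge(c1, p1, o1, p2, o2))
    counts = {}
    for s in structure.segments:
        if s.chrom == viral:
            continue
        key = (s.chrom, s.start, s.end)
        counts[key] = counts.get(key, 0) + 1
    segments = [
        HumanSegment(c, s, e, n * structure.copy_number)
        for (c, s, e), n in counts.items()
    ]
    return junctions, segments


def graph_signature_inputs(g: BreakpointGraph, viral_chrom: str):
    viral_tid = g.contigs.tid(viral_chrom)
    junctions = []
    for e in g.edges:
        if e.kind != "discordant":
            continue
        (t1, p1, o1), (t2, p2, o2) = e.v1, e.v2
        if (t1 == viral_tid) == (t2 == viral_tid):
            continue
        if t1 == viral_tid:
            t1, p1, o1, t2, p2, o2 = t2, p2, o2, t1, p1, o1
        junctions.append(
            ChimericEdge(g.contigs.names[t1], p1, o1, p2, o2)
        )
    segments = [
        HumanSegment(g.contigs.names[e.v1[0]], e.v1[1], e.v2[1], e.cn)
        for e in g.sequence_edges()
        if e.v1[0] != viral_tid
    ]
    return junctions, segments


def classify_structure(structure: AmpliconStructure, **kw) -> SignatureCall:
    junctions, segments = structure_signature_inputs(structure)
    return classify_signature(junctions, segments, **kw)


def classify_graph(g: BreakpointGraph, viral_chrom: str, **kw) -> SignatureCall:
    junctions, segments = graph_signature_inputs(g, viral_chrom)
    return classify_signature(junctions, segments, **kw)


# ---------------------------------------------------------------------------
# fusion amplicon selection (graph level)


@dataclass
class FusionAmplicon:
    human_intervals: list  # [(chrom, start, end)]
    junctions: list
    mean_cn: float
    size: int


def select_fusion_amplicons(
    g: BreakpointGraph,
    viral_chrom: str,
    merge_gap: int = MERGE_GAP,
    amp_cn: float = AMP_CN,
    mean_cn: float = MEAN_CN,
):
    """Split virus-connected human clusters into amplicons and keep those
    whose length-weighted mean CN over amplified human edges exceeds 3.0."""
    junctions, segments = graph_signature_inputs(g, viral_chrom)
    if not junctions:
        return []
    # merge human intervals within merge_gap, per chromosome
    clusters = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if (
            clusters
            and clusters[-1][0][0].chrom == seg.chrom
            and seg.start - max(s.end for s in clusters[-1][0]) <= merge_gap
        ):
            clusters[-1][0].append(seg)
        else:
            clusters.append(([seg], []))
    for j in junctions:
        for segs, js in clusters:
            if any(
                s.chrom == j.chrom and s.start - 1 <= j.human_pos <= s.end + 1
                for s in segs
            ):
                js.append(j)
                break
    # clusters without direct inter-cluster discordant links are separate
    # amplicons; only virus-connected clusters qualify
    linked = _linked_components(g, clusters, viral_chrom)
    out = []
    for group in linked:
        segs = [s for ci in group for s in clusters[ci][0]]
        js = [j for ci in group for j in clusters[ci][1]]
        if not js:
            continue
        amped = [s for s in segs if s.cn > amp_cn]
        if not amped:
            continue
        wsum = sum((s.end - s.start) * s.cn for s in amped)
        lsum = sum(s.end - s.start for s in amped)
        mcn = wsum / lsum if lsum else 0.0
        if mcn > mean_cn:
            out.append(
                FusionAmplicon(
                    [(s.chrom, s.start, s.end) for s in segs],
                    js, mcn, sum(s.end - s.start for s in segs),
                )
            )
    return out


def _linked_components(g, clusters, viral_chrom):
    """Union clusters joined by human-human discordant edges."""
    viral_tid = g.contigs.tid(viral_chrom)
    parent = list(range(len(clusters)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def locate(tid, pos):
        chrom = g.contigs.names[tid]
        for ci, (segs, _js) in enumerate(clusters):
            if any(s.chrom == chrom and s.start <= pos <= s.end for s in segs):
                return ci
        return None

    for e in g.edges:
        if e.kind != "discordant":
            continue
        (t1, p1, _), (t2, p2, _) = e.v1, e.v2
        if t1 == viral_tid or t2 == viral_tid:
            continue
        c1, c2 = locate(t1, p1), locate(t2, p2)
        if c1 is not None and c2 is not None and c1 != c2:
            parent[find(c1)] = find(c2)
    groups = {}
    for i in range(len(clusters)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def write_signature_report(path: str, rows) -> None:
    """rows: iterable of (name, SignatureCall, mean_cn, size)."""
    with open(path, "w") as fh:
        fh.write("amplicon\tlabel\tjunctions\tmean_cn\tsize\n")
        for name, call, mcn, size in rows:
            ev = ";".join(
                f"{j.chrom}:{j.human_pos}{j.human_orient}~v:{j.viral_pos}{j.viral_orient}"
                for j in call.evidence
            )
            fh.write(f"{name}\t{call.label}\t{ev}\t{mcn:.3f}\t{size}\n")
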