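"""Breakpoint graph construction and balanced-flow copy-number assignment.

Vertices sit at segment endpoints: ``(tid, pos, '-')`` faces left at a
segment start, ``(tid, pos, '+')`` faces right at a segment end; a single
source vertex absorbs unexplained boundaries and interval endpoints.  Copy
numbers are assigned by minimizing a Poisson negative log-likelihood under
per-vertex flow conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .records import ContigTable, ReadPairs, StartIndex
from .seqstats import SeqStats

SOURCE = ("source", -1, ".")
EPS_CN = 1e-4
SNAP = 500  # merge meanshift boundaries into bicluster breakpoints within this


@dataclass
class Edge:
    kind: str  # sequence | concordant | discordant | source
    v1: tuple
    v2: tuple
    count: float = 0.0
    cn: float = 0.0
    length: int = 0  # sequence edges only

    def vertices(self):
        return (self.v1, self.v2)


@dataclass
class BreakpointGraph:
    contigs: ContigTable
    segments: list = field(default_factory=list)  # (tid, start, end)
    edges: list = field(default_factory=list)

    def sequence_edges(self):
        return [e for e in self.edges if e.kind == "sequence"]

    def breakpoint_edges(self):
        return [e for e in self.edges if e.kind != "sequence"]

    def vertex_edges(self):
        """vertex -> list of (edge, multiplicity at that vertex)."""
        out = {}
        for e in self.edges:
            if e.kind == "sequence":
                continue
            for v in set(e.vertices()):
                mult = sum(1 for u in e.vertices() if u == v)
                out.setdefault(v, []).append((e, mult))
        return out

    def seq_edge_at(self, v):
        for e in self.sequence_edges():
            if v in e.vertices():
                return e
        return None

    def flow_residuals(self):
        """Per-vertex |CN_seq - sum CN_bp| (source excluded)."""
        ve = self.vertex_edges()
        res = {}
        for e in self.sequence_edges():
            for v in e.vertices():
                bp = sum(edge.cn * m for edge, m in ve.get(v, []))
                res[v] = abs(e.cn - bp)
        return res


def _segment_vertices(tid, start, end):
    return (tid, start, "-"), (tid, end, "+")


def build_graph(
    intervals,
    boundaries: dict,
    biclusters,
    pairs: ReadPairs,
    stats: SeqStats,
    contigs: ContigTable,
    snap: int = SNAP,
) -> BreakpointGraph:
    """Assemble the breakpoint graph.

    ``intervals``: iterable of (tid, start, end); ``boundaries``: mapping
    interval -> list of refined meanshift boundary positions.  Bicluster
    breakpoints inside the interval set partition the intervals together
    with the meanshift boundaries (boundaries within ``snap`` bp of a
    bicluster breakpoint are merged into it — the read evidence is more
    precise).  Meanshift boundaries without a matching bicluster get source
    edges, as do interval endpoints and biclusters with one side outside.
    """
    intervals = list(intervals)
    g = BreakpointGraph(contigs=contigs)
    index = StartIndex(pairs, mapq_min=1)

    def in_intervals(tid, pos):
        return any(t == tid and s <= pos <= e for t, s, e in intervals)

    bp_positions = {}
    for b in biclusters:
        for (tid, pos, _o) in b.ends():
            if in_intervals(tid, pos):
                bp_positions.setdefault(tid, set()).add(pos)

    # per-interval partition positions
    partitions = {}
    unexplained = {}
    for iv in intervals:
        tid, s, e = iv
        cuts = set()
        unexp = []
        for pos in boundaries.get(iv, []):
            if not (s < pos < e):
                continue
            near = [
                q for q in bp_positions.get(tid, ())
                if abs(q - pos) <= snap and s < q < e
            ]
            if near:
                cuts.add(min(near, key=lambda q: abs(q - pos)))
            else:
                cuts.add(pos)
                unexp.append(pos)
        for q in bp_positions.get(tid, ()):
            if s < q < e:
                cuts.add(q)
        partitions[iv] = sorted(cuts)
        unexplained[iv] = unexp

    # concordant-crossing counters (proper pairs spanning a position)
    proper = pairs.subset(pairs.proper.astype(bool))
    span_left, span_right = {}, {}
    for tid in np.unique(proper.tid1):
        m = proper.tid1 == tid
        left = np.minimum(proper.pos1[m], proper.pos2[m])
        right = np.maximum(
            proper.pos1[m] + proper.alen1[m], proper.pos2[m] + proper.alen2[m]
        )
        span_left[int(tid)] = np.sort(left)
        span_right[int(tid)] = np.sort(right)

    def crossing(tid, pos):
        if tid not in span_left:
            return 0
        n_started = np.searchsorted(span_left[tid], pos)
        n_ended = np.searchsorted(span_right[tid], pos, side="right")
        return int(max(n_started - n_ended, 0))

    vertex_set = set()
    for iv in intervals:
        tid, s, e = iv
        edges_pos = [s] + partitions[iv] + [e]
        prev_end_vertex = None
        for a, b in zip(edges_pos[:-1], edges_pos[1:]):
            if b <= a:
                continue
            g.segments.append((tid, a, b))
            v1, v2 = _segment_vertices(tid, a, b)
            vertex_set.update((v1, v2))
            k = index.count(tid, a, b)
            g.edges.append(
                Edge("sequence", v1, v2, count=k, length=b - a)
            )
            if prev_end_vertex is not None:
                g.edges.append(
                    Edge("concordant", prev_end_vertex, v1, count=crossing(tid, a))
                )
            prev_end_vertex = v2
        # interval endpoints -> source
        sv1 = (tid, s, "-")
        sv2 = (tid, e, "+")
        g.edges.append(Edge("source", sv1, SOURCE, count=crossing(tid, s)))
        g.edges.append(Edge("source", sv2, SOURCE, count=crossing(tid, e)))

    overlaps = _check_partition(g.segments)
    if overlaps:
        raise ValueError(f"overlapping segments: {overlaps}")

    def snap_vertex(tid, pos, orient):
        """Snap a breakpoint to the nearest matching partition vertex."""
        best = None
        for v in vertex_set:
            if v[0] == tid and v[2] == orient:
                d = abs(v[1] - pos)
                if d <= snap and (best is None or d < abs(best[1] - pos)):
                    best = v
        return best

    for b in biclusters:
        (t1, p1, o1), (t2, p2, o2) = b.ends()
        v1 = snap_vertex(t1, p1, o1) if in_intervals(t1, p1) else None
        v2 = snap_vertex(t2, p2, o2) if in_intervals(t2, p2) else None
        if v1 is not None and v2 is not None:
            g.edges.append(Edge("discordant", v1, v2, count=b.support))
        elif v1 is not None or v2 is not None:
            v = v1 if v1 is not None else v2
            g.edges.append(Edge("source", v, SOURCE, count=b.support))

    # unexplained meanshift boundaries: source edges on both flanking vertices
    ve = {}
    for e in g.edges:
        if e.kind in ("discordant",):
            for v in e.vertices():
                ve.setdefault(v, 0)
                ve[v] += 1
    for iv, positions in unexplained.items():
        tid = iv[0]
        for pos in positions:
            for orient in ("+", "-"):
                v = (tid, pos, orient)
                if v in vertex_set and ve.get(v, 0) == 0:
                    g.edges.append(Edge("source", v, SOURCE, count=0))
    return g


def _check_partition(segments):
    bad = []
    by_tid = {}
    for tid, s, e in segments:
        by_tid.setdefault(tid, []).append((s, e))
    for tid, ivs in by_tid.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
            if s2 < e1:
                bad.append((tid, (s1, e1), (s2, e2)))
    return bad


# ---------------------------------------------------------------------------
# balanced flow


def edge_rate(edge: Edge, stats: SeqStats) -> float:
    """Expected read (pair) count per structure copy for an edge.

    Sequence edges: mu_10000 * L / (2R) expected alignment starts per copy.
    Breakpoint edges: P * mu_300 * (I - R) / (4R) expected junction-spanning
    pairs per copy: per-copy depth is mu/2 and a fragment crossing the
    junction leaves both reads clear of it over an (I - R) window, at
    (depth / 2R) fragments per base.
    """
    r = stats.read_length
    if edge.kind == "sequence":
        return max(stats.mu(10_000) * edge.length / (2.0 * r), 1e-9)
    return max(
        stats.proper_fraction
        * stats.mu(300)
        * (stats.insert_mean - r)
        / (4.0 * r),
        1e-9,
    )


def balance_flow(
    g: BreakpointGraph,
    stats: SeqStats,
    eps: float = EPS_CN,
    tol: float = 1e-8,
) -> BreakpointGraph:
    """Assign copy numbers by convex Poisson-NLL balanced-flow optimization.

    Minimizes sum(lambda_e * CN_e - k_e * ln(lambda_e * CN_e)) subject to
    CN_seq(v) = sum of incident breakpoint-edge CNs at every breakpoint
    vertex; CN >= eps.  The flow residual is asserted < 1e-6 after solving.
    """
    if not g.edges:
        return g
    # vertices lacking any breakpoint edge get an implicit source edge
    ve = g.vertex_edges()
    for e in list(g.sequence_edges()):
        for v in e.vertices():
            if not ve.get(v):
                imp = Edge("source", v, SOURCE, count=0)
                g.edges.append(imp)
                ve[v] = [(imp, 1)]
    edges = g.edges
    n = len(edges)
    lam = np.array([edge_rate(e, stats) for e in edges])
    k = np.array([e.count for e in edges], dtype=float)

    # flow-conservation rows: one per breakpoint vertex
    eidx = {id(e): i for i, e in enumerate(edges)}
    rows = []
    for e in edges:
        if e.kind != "sequence":
            continue
        for v in e.vertices():
            row = np.zeros(n)
            row[eidx[id(e)]] = 1.0
            for bp, mult in ve[v]:
                row[eidx[id(bp)]] -= mult
            rows.append(row)
    a_mat = np.vstack(rows) if rows else np.zeros((0, n))

    scale = max(k.sum(), 1.0)
    pos = k > 0

    def fun(x):
        xs = np.maximum(x, 1e-12)
        return (np.sum(lam * x) - np.sum(k[pos] * np.log(xs[pos]))) / scale

    def jac(x):
        xs = np.maximum(x, 1e-12)
        g = lam.copy()
        g[pos] -= k[pos] / xs[pos]
        return g / scale

    x0 = np.maximum(k / lam, 10 * eps)
    bounds = [(eps, None)] * n
    res = minimize(
        fun, x0, jac=jac, bounds=bounds, method="SLSQP",
        constraints=[{"type": "eq", "fun": lambda x: a_mat @ x,
                      "jac": lambda x: a_mat}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    x = res.x
    resid0 = float(np.max(np.abs(a_mat @ x))) if len(rows) else 0.0
    if (not res.success) or resid0 > 1e-6 or np.any(x < eps / 2):
        res = minimize(
            fun, np.maximum(x, eps), jac=jac, bounds=bounds,
            method="trust-constr",
            constraints=[LinearConstraint(a_mat, 0.0, 0.0)],
            options={"maxiter": 2000, "gtol": 1e-10, "xtol": 1e-12},
        )
        x = res.x
    x = np.maximum(x, eps)
    if len(rows):
        resid = float(np.max(np.abs(a_mat @ x)))
        if resid > 1e-6:
            raise RuntimeError(f"balanced flow residual {resid:.2e} > 1e-6")
    for e, cn in zip(edges, x):
        e.cn = float(cn)
    return g


# ---------------------------------------------------------------------------
# text round trip


def _fmt_vertex(v, contigs):
    if v == SOURCE:
        return "source"
    tid, pos, orient = v
    return f"{contigs.names[tid]}:{pos}({orient})"


def _parse_vertex(text, contigs):
    if text == "source":
        return SOURCE
    loc, orient = text[:-1].rsplit("(", 1)
    chrom, pos = loc.rsplit(":", 1)
    return (contigs.tid(chrom), int(pos), orient)


def write_graph(path: str, g: BreakpointGraph) -> None:
    contigs = g.contigs
    with open(path, "w") as fh:
        for e in g.edges:
            if e.kind == "sequence":
                tid, s, _ = e.v1
                _, ee, _ = e.v2
                fh.write(
                    f"sequence\t{contigs.names[tid]}:{s}-{ee}\t{e.cn:.6g}\t{e.count:g}\n"
                )
            else:
                fh.write(
                    f"{e.kind}\t{_fmt_vertex(e.v1, contigs)}->"
                    f"{_fmt_vertex(e.v2, contigs)}\t{e.cn:.6g}\t{e.count:g}\n"
                )


def read_graph(path: str, contigs: ContigTable) -> BreakpointGraph:
    g = BreakpointGraph(contigs=contigs)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            kind, desc, cn, count = line.rstrip("\n").split("\t")
            if kind == "sequence":
                chrom, span = desc.rsplit(":", 1)
                s, e = (int(x) for x in span.split("-"))
                tid = contigs.tid(chrom)
                v1, v2 = _segment_vertices(tid, s, e)
                g.segments.append((tid, s, e))
                g.edges.append(
                    Edge("sequence", v1, v2, count=float(count),
                         cn=float(cn), length=e - s)
                )
            else:
                t1, t2 = desc.split("->")
                g.edges.append(
                    Edge(kind, _parse_vertex(t1, contigs),
                         _parse_vertex(t2, contigs),
                         count=float(count), cn=float(cn))
                )
    return g


def plot_graph(path: str, g: BreakpointGraph, index=None, stats=None) -> None:
    """Minimal static SV view: per-segment copy numbers as bars with
    discordant-edge arcs (one panel per contig carrying segments)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tids = sorted({tid for tid, _s, _e in g.segments})
    fig, axes = plt.subplots(
        len(tids), 1, figsize=(10, 2.5 * max(len(tids), 1)), squeeze=False
    )
    ax_by_tid = {tid: axes[k][0] for k, tid in enumerate(tids)}
    for e in g.sequence_edges():
        (tid, a, _), (_t, b, _) = e.v1, e.v2
        ax = ax_by_tid[tid]
        ax.fill_between([a, b], [e.cn, e.cn], step="mid", alpha=0.5)
    for e in g.edges:
        if e.kind != "discordant":
            continue
        (t1, p1, _), (t2, p2, _) = e.v1, e.v2
        if t1 != t2:
            continue  # inter-contig edges are listed, not drawn
        ax = ax_by_tid.get(t1)
        if ax is None:
            continue
        mid, span = (p1 + p2) / 2, abs(p2 - p1)
        height = max(ed.cn for ed in g.sequence_edges()) * 1.1
        theta = np.linspace(0, np.pi, 50)
        ax.plot(mid + span / 2 * np.cos(theta), height * np.sin(theta) * 0.3
                + height, lw=0.8, color="crimson")
    for tid, ax in ax_by_tid.items():
        ax.set_ylabel("copy number")
        ax.set_title(g.contigs.names[tid])
    axes[-1][0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
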