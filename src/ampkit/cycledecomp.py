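"""Decomposition of a balanced breakpoint graph into simple cycles.

A simple cycle is an alternating closed walk traversing each sequence edge
at most once per direction; a walk may pass through the source vertex
(two consecutive breakpoint edges) at most once and is then reported with
topology 'linear'.  Cycles are extracted greedily by maximum bottleneck
residual copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import ContigTable
from .bpgraph import SOURCE, BreakpointGraph

MIN_CN = 1e-3
BALANCE_TOL = 1e-5


@dataclass
class SimpleCycle:
    segments: list  # [(segment_index, '+'/'-')], 0-based into graph segments
    cn: float
    is_source: bool = False

    @property
    def topology(self) -> str:
        return "linear" if self.is_source else "circular"


@dataclass
class _Arena:
    """Residual-graph view used by the DFS."""
    seq_edges: list
    bp_edges: list
    seq_res: list
    bp_res: list
    partner: dict      # vertex -> (seq index, direction, other vertex)
    incident: dict     # vertex -> [(bp index, other vertex)]


def _build_arena(g: BreakpointGraph) -> _Arena:
    seq_edges = g.sequence_edges()
    bp_edges = g.breakpoint_edges()
    partner = {}
    for i, e in enumerate(seq_edges):
        v1, v2 = e.v1, e.v2  # v1 = start ('-'), v2 = end ('+')
        partner[v1] = (i, "+", v2)
        partner[v2] = (i, "-", v1)
    incident = {}
    for j, e in enumerate(bp_edges):
        a, b = e.vertices()
        incident.setdefault(a, []).append((j, b))
        if b != a:
            incident.setdefault(b, []).append((j, a))
    return _Arena(
        seq_edges, bp_edges,
        [e.cn for e in seq_edges], [e.cn for e in bp_edges],
        partner, incident,
    )


def _candidate_thresholds(arena, min_cn):
    vals = set()
    for r in arena.seq_res + arena.bp_res:
        for t in (r, r / 2.0):
            if t >= min_cn:
                # shave an epsilon so a cycle whose bottleneck is exactly t
                # survives the residual >= uses * t check
                vals.add(t * (1.0 - 1e-9))
    return sorted(vals, reverse=True)


class _Budget:
    """Backtracking-step budget so dense graphs cannot stall the DFS."""

    def __init__(self, steps: int):
        self.steps = steps

    def spend(self) -> bool:
        self.steps -= 1
        return self.steps >= 0


def _find_cycle(arena: _Arena, t: float, budget_steps: int = 200_000):
    """DFS for an alternating closed walk whose edges all have residual
    >= (uses * t).  Deterministic ordering; returns (seq_uses, bp_uses,
    ordered segment walk) or None."""
    order = sorted(
        range(len(arena.seq_edges)),
        key=lambda i: (-arena.seq_res[i], i),
    )
    budget = _Budget(budget_steps)
    for start in order:
        if arena.seq_res[start] < t:
            continue
        for direction in ("+", "-"):
            e = arena.seq_edges[start]
            v_in = e.v1 if direction == "+" else e.v2
            v_out = e.v2 if direction == "+" else e.v1
            walk = [(start, direction)]
            found = _dfs(
                arena, t, v_in, v_out, {(start, direction): 1}, {}, walk,
                source_used=False, depth_cap=2 * len(arena.seq_edges) + 2,
                budget=budget,
            )
            if found is not None:
                return found
            if budget.steps < 0:
                return None
    return None


def _dfs(arena, t, v_home, v_cur, seq_uses, bp_uses, walk, source_used,
         depth_cap, budget=None):
    if len(walk) > depth_cap:
        return None
    if budget is not None and not budget.spend():
        return None
    nbrs = sorted(
        arena.incident.get(v_cur, []),
        key=lambda jn: (-arena.bp_res[jn[0]], jn[0]),
    )
    for j, v_next in nbrs:
        uses = bp_uses.get(j, 0) + 1
        if arena.bp_res[j] < uses * t:
            continue
        bp_uses[j] = uses
        if v_next == v_home:
            return (dict(seq_uses), dict(bp_uses), list(walk))
        if v_next == SOURCE:
            if not source_used:
                res = _via_source(
                    arena, t, v_home, seq_uses, bp_uses, walk, depth_cap, j,
                    budget,
                )
                if res is not None:
                    return res
        elif v_next in arena.partner:
            si, sdir, v_exit = arena.partner[v_next]
            if seq_uses.get((si, sdir), 0) < 1 and arena.seq_res[si] >= (
                seq_uses.get((si, "+"), 0) + seq_uses.get((si, "-"), 0) + 1
            ) * t:
                seq_uses[(si, sdir)] = 1
                walk.append((si, sdir))
                res = _dfs(
                    arena, t, v_home, v_exit, seq_uses, bp_uses, walk,
                    source_used, depth_cap, budget,
                )
                if res is not None:
                    return res
                walk.pop()
                del seq_uses[(si, sdir)]
        bp_uses[j] -= 1
        if bp_uses[j] == 0:
            del bp_uses[j]
    return None


def _via_source(arena, t, v_home, seq_uses, bp_uses, walk, depth_cap, j_in,
                budget=None):
    """Continue the walk through the source: pick a second source edge."""
    nbrs = sorted(
        (jn for jn in arena.incident.get(SOURCE, [])),
        key=lambda jn: (-arena.bp_res[jn[0]], jn[0]),
    )
    for j, v_next in nbrs:
        uses = bp_uses.get(j, 0) + 1
        if arena.bp_res[j] < uses * t:
            continue
        if v_next == SOURCE:
            continue
        bp_uses[j] = uses
        if v_next == v_home:
            return (dict(seq_uses), dict(bp_uses), list(walk))
        if v_next in arena.partner:
            si, sdir, v_exit = arena.partner[v_next]
            if seq_uses.get((si, sdir), 0) < 1 and arena.seq_res[si] >= (
                seq_uses.get((si, "+"), 0) + seq_uses.get((si, "-"), 0) + 1
            ) * t:
                seq_uses[(si, sdir)] = 1
                walk.append((si, sdir))
                res = _dfs(
                    arena, t, v_home, v_exit, seq_uses, bp_uses, walk,
                    source_used=True, depth_cap=depth_cap, budget=budget,
                )
                if res is not None:
                    return res
                walk.pop()
                del seq_uses[(si, sdir)]
        bp_uses[j] -= 1
        if bp_uses[j] == 0:
            del bp_uses[j]
    return None


def decompose(
    g: BreakpointGraph,
    content_target: float = 0.8,
    min_cn: float = MIN_CN,
    max_cycles: int = 200,
    peel_background: bool = True,
) -> list:
    """Greedy max-bottleneck simple-cycle decomposition.

    When ``peel_background`` is set, the chromosomal pass-through flow of
    each interval (the source-bounded walk along its concordant chain,
    carrying the diploid background) is extracted first; without this the
    background stacks onto amplicon flow and the max-bottleneck cycle can
    mix the two, skipping true junctions at low amplification.  Then the
    simple cycle with the highest bottleneck residual CN is iteratively
    extracted and decremented, stopping once the explained genomic content
    reaches ``content_target`` or no cycle with CN >= ``min_cn`` remains.
    """
    res = g.flow_residuals()
    if res and max(res.values()) > BALANCE_TOL:
        raise ValueError("graph is not balanced; run balance_flow first")
    arena = _build_arena(g)
    denom = sum(e.cn * e.length for e in arena.seq_edges)
    cycles = []
    explained = 0.0
    if peel_background:
        for walk, cn in _background_walks(arena, min_cn):
            for i, _d in walk:
                arena.seq_res[i] -= cn
            for j in _chain_bp_indices(arena, walk):
                arena.bp_res[j] -= cn
            cycles.append(SimpleCycle(list(walk), cn, is_source=True))
        # the content target judges the greedy extraction of what remains:
        # a tiny amplicon must not be skipped because the background walk
        # already covers most raw content
        denom = sum(
            r * e.length for r, e in zip(arena.seq_res, arena.seq_edges)
        )
    for _ in range(max_cycles):
        if denom > 0 and explained / denom >= content_target:
            break
        found = None
        for t in _candidate_thresholds(arena, min_cn):
            found = _find_cycle(arena, t)
            if found is not None:
                break
        if found is None:
            break
        seq_uses, bp_uses, walk = found
        bottleneck = min(
            [
                arena.seq_res[i] / (
                    seq_uses.get((i, "+"), 0) + seq_uses.get((i, "-"), 0)
                )
                for i in {i for i, _d in walk}
            ]
            + [arena.bp_res[j] / u for j, u in bp_uses.items()]
        )
        for i, _d in walk:
            arena.seq_res[i] -= bottleneck
        for j, u in bp_uses.items():
            arena.bp_res[j] -= bottleneck * u
        is_source = any(
            SOURCE in arena.bp_edges[j].vertices() for j in bp_uses
        )
        cycles.append(SimpleCycle(list(walk), bottleneck, is_source))
        explained += bottleneck * sum(
            arena.seq_edges[i].length for i, _d in walk
        )
    return cycles


def _interval_chains(arena):
    """Maximal runs of sequence edges linked by concordant edges, with the
    bounding source edges; yields (walk, conc_bp_idx, src_bp_idx)."""
    by_vertex_bp = {}
    for j, e in enumerate(arena.bp_edges):
        for v in set(e.vertices()):
            by_vertex_bp.setdefault(v, []).append(j)

    def find_edge(kind, v1, v2=None):
        for j in by_vertex_bp.get(v1, []):
            e = arena.bp_edges[j]
            if e.kind != kind:
                continue
            if v2 is None or v2 in e.vertices():
                return j
        return None

    seqs = sorted(
        range(len(arena.seq_edges)),
        key=lambda i: (arena.seq_edges[i].v1[0], arena.seq_edges[i].v1[1]),
    )
    chain, conc = [], []
    for i in seqs:
        e = arena.seq_edges[i]
        if chain:
            prev = arena.seq_edges[chain[-1]]
            j = find_edge("concordant", prev.v2, e.v1)
            if prev.v2[0] == e.v1[0] and prev.v2[1] == e.v1[1] and j is not None:
                chain.append(i)
                conc.append(j)
                continue
            yield chain, conc
            chain, conc = [], []
        chain.append(i)
    if chain:
        yield chain, conc


def _background_walks(arena, min_cn):
    """Source-bounded pass-through walks along each interval chain."""
    out = []
    for chain, conc in _interval_chains(arena):
        first, last = arena.seq_edges[chain[0]], arena.seq_edges[chain[-1]]
        src1 = _find_source(arena, first.v1)
        src2 = _find_source(arena, last.v2)
        if src1 is None or src2 is None:
            continue
        cn = min(
            [arena.bp_res[src1], arena.bp_res[src2]]
            + [arena.seq_res[i] for i in chain]
            + [arena.bp_res[j] for j in conc]
        )
        if cn >= min_cn:
            out.append(([(i, "+") for i in chain], cn))
    return out


def _find_source(arena, v):
    for j, e in enumerate(arena.bp_edges):
        if e.kind == "source" and v in e.vertices():
            return j
    return None


def _chain_bp_indices(arena, walk):
    """Concordant + bounding source edges of a pass-through walk."""
    idxs = []
    chain = [i for i, _d in walk]
    first, last = arena.seq_edges[chain[0]], arena.seq_edges[chain[-1]]
    idxs.append(_find_source(arena, first.v1))
    idxs.append(_find_source(arena, last.v2))
    by_vertex = {}
    for j, e in enumerate(arena.bp_edges):
        if e.kind == "concordant":
            for v in e.vertices():
                by_vertex.setdefault(v, []).append(j)
    for a, b in zip(chain[:-1], chain[1:]):
        v2 = arena.seq_edges[a].v2
        v1 = arena.seq_edges[b].v1
        for j in by_vertex.get(v2, []):
            if v1 in arena.bp_edges[j].vertices():
                idxs.append(j)
                break
    return [j for j in idxs if j is not None]


def explained_content(g: BreakpointGraph, cycles) -> float:
    """Fraction of amplicon genomic content explained by the cycles."""
    seq_edges = g.sequence_edges()
    denom = sum(e.cn * e.length for e in seq_edges)
    if denom == 0:
        return 1.0
    num = sum(
        c.cn * sum(seq_edges[i].length for i, _d in c.segments)
        for c in cycles
    )
    return num / denom


def merge_cycles(c1: SimpleCycle, c2: SimpleCycle, segment_index: int) -> SimpleCycle:
    """Splice two cycles at a shared segment: (A,B) + (B,C) -> (A,B,C,B)."""
    def rotate_to(cycle, si):
        for k, (i, d) in enumerate(cycle.segments):
            if i == si:
                return cycle.segments[k:] + cycle.segments[:k], d
        return None, None

    s1, d1 = rotate_to(c1, segment_index)
    s2, d2 = rotate_to(c2, segment_index)
    if s1 is None or s2 is None:
        raise ValueError("cycles do not share the segment")
    if d1 != d2:
        s2 = [(i, "+" if d == "-" else "-") for i, d in reversed(s2)]
        s2, _ = rotate_to(SimpleCycle(s2, 0), segment_index)
    merged = [s1[0]] + s2[1:] + [s2[0]] + s1[1:]
    return SimpleCycle(
        merged, min(c1.cn, c2.cn), c1.is_source or c2.is_source
    )


# ---------------------------------------------------------------------------
# cycles file round trip


def write_cycles(path: str, g: BreakpointGraph, cycles) -> None:
    contigs = g.contigs
    with open(path, "w") as fh:
        for i, (tid, s, e) in enumerate(g.segments, start=1):
            fh.write(f"Segment\t{i}\t{contigs.names[tid]}\t{s}\t{e}\n")
        for n, c in enumerate(cycles, start=1):
            ids = ",".join(f"{i + 1}{d}" for i, d in c.segments)
            if c.is_source:
                ids = "0+," + ids
            fh.write(f"Cycle={n};Copy_count={c.cn:.6g};Segments={ids}\n")


def read_cycles(path: str, contigs: ContigTable):
    """Returns (segments [(tid,start,end)], cycles [SimpleCycle])."""
    segments = []
    cycles = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("Segment"):
                _tag, _sid, chrom, s, e = line.split("\t")
                segments.append((contigs.tid(chrom), int(s), int(e)))
            elif line.startswith("Cycle="):
                fields = dict(p.split("=", 1) for p in line.split(";"))
                cn = float(fields["Copy_count"])
                walk = []
                is_source = False
                for token in fields["Segments"].split(","):
                    sid, d = int(token[:-1]), token[-1]
                    if sid == 0:
                        is_source = True
                        continue
                    walk.append((sid - 1, d))
                cycles.append(SimpleCycle(walk, cn, is_source))
    return segments, cycles
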