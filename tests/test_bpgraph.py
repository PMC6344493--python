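import numpy as np
import pytest

from ampkit import bpgraph, records
from ampkit.bpgraph import SOURCE, BreakpointGraph, Edge, balance_flow, build_graph
from ampkit.seqstats import SeqStats


def make_stats(mu=10.0):
    s = SeqStats(read_length=100, insert_mean=300, insert_sd=30,
                 proper_fraction=1.0)
    for ws in (300, 10_000):
        s.cov_mean[ws] = mu
        s.cov_median[ws] = mu
        s.cov_sd[ws] = 0.5
    return s


def single_circle_graph(contigs, cn=10.0, length=100_000, noise=1.0):
    """One segment whose head joins its tail (pure ecDNA circle)."""
    stats = make_stats()
    g = BreakpointGraph(contigs=contigs)
    v1, v2 = (0, 0, "-"), (0, length, "+")
    seq = Edge("sequence", v1, v2, length=length)
    disc = Edge("discordant", v2, v1)
    s1 = Edge("source", v1, SOURCE, count=0)
    s2 = Edge("source", v2, SOURCE, count=0)
    seq.count = cn * bpgraph.edge_rate(seq, stats) * noise
    disc.count = cn * bpgraph.edge_rate(disc, stats) * noise
    g.segments = [(0, 0, length)]
    g.edges = [seq, disc, s1, s2]
    return g, stats


class TestBuildGraph:
    def test_single_segment_with_circle_edge(self, small_reference):
        from ampkit.svdetect import Bicluster

        stats = make_stats()
        iv = (0, 100_000, 200_000)
        b = Bicluster((0, 200_000, "+"), (0, 100_000, "-"), 20, 20,
                      np.arange(20))
        g = build_graph([iv], {iv: []}, [b], records.ReadPairs.empty(),
                        stats, small_reference)
        kinds = sorted(e.kind for e in g.edges)
        assert kinds == ["discordant", "sequence", "source", "source"]
        assert len(g.segments) == 1

    def test_k_segments_k_minus_1_concordant(self, small_reference):
        stats = make_stats()
        iv = (0, 0, 100_000)
        bounds = [20_000, 40_000, 70_000]
        g = build_graph([iv], {iv: bounds}, [], records.ReadPairs.empty(),
                        stats, small_reference)
        assert len(g.segments) == 4
        assert sum(1 for e in g.edges if e.kind == "concordant") == 3
        # unexplained boundaries get source edges on both sides
        n_src = sum(1 for e in g.edges if e.kind == "source")
        assert n_src == 2 + 2 * 3

    def test_overlapping_segments_rejected(self, small_reference):
        stats = make_stats()
        ivs = [(0, 0, 100_000), (0, 50_000, 150_000)]
        with pytest.raises(ValueError, match="overlap"):
            build_graph(ivs, {iv: [] for iv in ivs}, [],
                        records.ReadPairs.empty(), stats, small_reference)


class TestBalanceFlow:
    def test_single_circle_matches_poisson_mle(self, small_reference):
        g, stats = single_circle_graph(small_reference, cn=10.0)
        balance_flow(g, stats)
        seq = g.sequence_edges()[0]
        disc = next(e for e in g.edges if e.kind == "discordant")
        assert seq.cn == pytest.approx(10.0, rel=0.02)
        assert disc.cn == pytest.approx(10.0, rel=0.02)

    def test_flow_conservation_residual(self, small_reference):
        g, stats = single_circle_graph(small_reference, cn=25.0, noise=1.13)
        balance_flow(g, stats)
        assert max(g.flow_residuals().values()) < 1e-6

    def test_all_zero_counts_floor(self, small_reference):
        g, stats = single_circle_graph(small_reference, cn=0.0)
        for e in g.edges:
            e.count = 0.0
        balance_flow(g, stats)
        for e in g.edges:
            assert e.cn <= 10 * bpgraph.EPS_CN

    def test_degenerate_single_edge_closed_form(self, small_reference):
        """With only a sequence edge (implicit sources added), CN -> k/lam."""
        stats = make_stats()
        g = BreakpointGraph(contigs=small_reference)
        v1, v2 = (0, 0, "-"), (0, 50_000, "+")
        seq = Edge("sequence", v1, v2, length=50_000)
        lam = bpgraph.edge_rate(seq, stats)
        seq.count = 7.5 * lam
        g.segments = [(0, 0, 50_000)]
        g.edges = [seq]
        balance_flow(g, stats)
        assert seq.cn == pytest.approx(7.5, rel=0.05)

    def test_optimum_independent_of_noise_seed(self, small_reference):
        g1, stats = single_circle_graph(small_reference, cn=16.0, noise=1.05)
        g2, _ = single_circle_graph(small_reference, cn=16.0, noise=1.05)
        balance_flow(g1, stats)
        balance_flow(g2, stats)
        for e1, e2 in zip(g1.edges, g2.edges):
            assert e1.cn == pytest.approx(e2.cn, rel=1e-6)


def test_simulated_graph_contains_truth_junctions(
    reconstruction, simulated_instance, small_reference
):
    """The reconstructed graph holds a matching discordant edge for every
    truth junction (within 300 bp, matching orientations)."""
    _cfg, structure, _pairs = simulated_instance
    g = reconstruction.graph
    disc = [e for e in g.edges if e.kind == "discordant"]

    def matches(vertex, end):
        tid = small_reference.tid(end[0])
        return (
            vertex[0] == tid and vertex[2] == end[2]
            and abs(vertex[1] - end[1]) <= 300
        )

    missed = []
    for e1, e2 in structure.junctions():
        ok = any(
            (matches(d.v1, e1) and matches(d.v2, e2))
            or (matches(d.v1, e2) and matches(d.v2, e1))
            for d in disc
        )
        if not ok:
            missed.append((e1, e2))
    assert len(missed) <= max(1, len(structure.junctions()) // 10)


def test_simulated_cn_accuracy(reconstruction, simulated_instance,
                               small_reference):
    """Per-segment CN within 20% of truth (+2 chromosomal background) for
    most amplified segments."""
    _cfg, structure, _pairs = simulated_instance
    tid = small_reference.tid("chr1")
    depth = {}
    for seg in structure.segments:
        if seg.chrom != "chr1":
            continue
        depth[(seg.start, seg.end)] = depth.get((seg.start, seg.end), 0) + 1
    ok = total = 0
    for e in reconstruction.graph.sequence_edges():
        (t, a, _), (_, b, _) = e.v1, e.v2
        if t != tid:
            continue
        mult = sum(
            m for (s, ee), m in depth.items() if s <= a and ee >= b
        )
        if mult == 0:
            continue
        truth_cn = mult * structure.copy_number + 2
        total += 1
        if abs(e.cn - truth_cn) / truth_cn <= 0.2:
            ok += 1
    assert total > 0 and ok / total >= 0.9


def test_graph_round_trip(tmp_path, reconstruction):
    path = tmp_path / "graph.txt"
    bpgraph.write_graph(str(path), reconstruction.graph)
    back = bpgraph.read_graph(str(path), reconstruction.graph.contigs)
    assert len(back.edges) == len(reconstruction.graph.edges)
    for e1, e2 in zip(reconstruction.graph.edges, back.edges):
        assert e1.kind == e2.kind
        assert e1.cn == pytest.approx(e2.cn, rel=1e-4)
        assert e1.v1 == e2.v1 and e1.v2 == e2.v2


def test_plot_graph_writes_figure(tmp_path, reconstruction):
    out = tmp_path / "sv_view.png"
    bpgraph.plot_graph(str(out), reconstruction.graph)
    assert out.stat().st_size > 0
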