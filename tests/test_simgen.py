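import numpy as np
import pytest

from ampkit import simgen
from ampkit.simgen import (
    AmpliconStructure,
    OrientedSegment,
    SimConfig,
    apply_operation,
    build_grid,
    simulate_alignments,
    simulate_structure,
    simulate_viral_set,
)


class TestSimulateStructure:
    def test_no_rearrangement_is_two_segment_circle(self, small_reference, rng):
        cfg = SimConfig(40_000, 8.0, 0, 0.0, 4, seed=1)
        s = simulate_structure(cfg, small_reference, rng)
        assert s.topology == "circular"
        assert len(s.segments) == 2
        chroms = {seg.chrom for seg in s.segments}
        assert chroms == {"chr1", "hpv16"}
        human = next(seg for seg in s.segments if seg.chrom == "chr1")
        assert human.length == 40_000
        assert s.copy_number == 8.0

    def test_non_duplicating_ops_never_grow(self, small_reference, rng):
        cfg = SimConfig(80_000, 4.0, 4, 0.0, 4, seed=2)
        s = simulate_structure(cfg, small_reference, rng)
        assert s.total_length <= 80_000 + small_reference.length("hpv16")

    def test_replay_oracle_segment_count(self, small_reference):
        """Re-applying the logged operations to the initial circle must give
        the same segment list (independent replay)."""
        rng = np.random.default_rng(9)
        cfg = SimConfig(60_000, 4.0, 8, 0.5, 4, seed=9)
        s = simulate_structure(cfg, small_reference, rng)
        assert len(s.operations) == 8
        human = None
        # rebuild initial structure from the final one's operations: the
        # first human window is recoverable from op replay invariance --
        # instead replay from a fresh initial built with the same seed
        rng2 = np.random.default_rng(9)
        initial = simulate_structure(
            SimConfig(60_000, 4.0, 0, 0.5, 4, seed=9), small_reference, rng2
        )
        replayed = initial
        for op in s.operations:
            replayed = apply_operation(replayed, op)
        assert [str(x) for x in replayed.segments] == [str(x) for x in s.segments]

    def test_viral_content_never_deleted(self, small_reference):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cfg = SimConfig(40_000, 4.0, 16, 0.0, 4, seed=seed)
            s = simulate_structure(cfg, small_reference, rng)
            assert s.viral_length() > 0

    def test_rejects_interval_smaller_than_virus(self, small_reference, rng):
        cfg = SimConfig(5_000, 4.0, 0, 0.0, 4, seed=1)
        with pytest.raises(ValueError, match="viral"):
            simulate_structure(cfg, small_reference, rng)

    def test_rejects_bad_duplication_probability(self):
        with pytest.raises(ValueError, match="p_duplication"):
            SimConfig(40_000, 4.0, 0, 1.5, 4)


class TestBaseConservation:
    def test_base_multiset_conserved_by_non_dup_ops(self, small_reference):
        rng = np.random.default_rng(4)
        cfg = SimConfig(50_000, 4.0, 0, 0.0, 4, seed=4)
        s = simulate_structure(cfg, small_reference, rng)

        def base_multiset(structure):
            out = {}
            for seg in structure.segments:
                key = (seg.chrom,)
                out[seg.chrom] = out.get(seg.chrom, 0) + seg.length
            return out

        inv = apply_operation(s, ("inversion", 10_000, 30_000, None))
        assert base_multiset(inv) == base_multiset(s)
        dup = apply_operation(s, ("tandem_duplication", 10_000, 30_000, None))
        assert dup.total_length == s.total_length + 20_000
        dele = apply_operation(s, ("deletion", 10_000, 30_000, None))
        assert dele.total_length == s.total_length - 20_000


class TestGrid:
    def test_base_grid_is_960(self):
        base, large, instances = build_grid()
        assert len(base) == 960

    def test_large_grid_is_24(self):
        _base, large, _instances = build_grid()
        assert len(large) == 24

    def test_total_instances_1248(self):
        _base, _large, instances = build_grid()
        assert len(instances) == 1248

    def test_grid_values_cover_declared_ranges(self):
        base, _large, _ = build_grid()
        assert {c.interval_size for c in base} == set(simgen.INTERVAL_SIZES)
        assert {c.coverage for c in base} == set(simgen.COVERAGES)


class TestSimulateAlignments:
    def test_zero_coverage_empty_stream(self, small_reference, rng):
        cfg = SimConfig(40_000, 4.0, 0, 0.0, 0, seed=1)
        s = simulate_structure(cfg, small_reference, rng)
        pairs = simulate_alignments(s, 0, small_reference, rng)
        assert len(pairs) == 0

    def test_unrearranged_circle_single_discordant_geometry(
        self, small_reference, rng
    ):
        cfg = SimConfig(40_000, 8.0, 0, 0.0, 4, seed=2)
        s = simulate_structure(cfg, small_reference, rng)
        assert len(s.junctions()) == 2  # human->virus and virus->human wrap

    def test_read_count_matches_poisson_oracle(self, small_reference):
        rng = np.random.default_rng(11)
        cfg = SimConfig(40_000, 8.0, 0, 0.0, 4, seed=11)
        s = simulate_structure(cfg, small_reference, rng)
        pairs = simulate_alignments(s, 4, small_reference, rng,
                                    with_background=False)
        human = next(seg for seg in s.segments if seg.chrom == "chr1")
        tid = small_reference.tid("chr1")
        starts = np.concatenate([
            pairs.pos1[pairs.tid1 == tid], pairs.pos2[pairs.tid2 == tid]
        ])
        observed = int(np.sum((starts >= human.start) & (starts < human.end)))
        # expected = CN/2 x coverage x L / R, within 3 Poisson SD
        expected = 8.0 / 2 * 4 * human.length / 100
        assert abs(observed - expected) <= 3 * np.sqrt(expected)

    def test_segment_shorter_than_read_raises(self, small_reference, rng):
        s = AmpliconStructure(
            [OrientedSegment("chr1", 0, 50, "+")], "circular", 4.0
        )
        with pytest.raises(ValueError, match="read length"):
            simulate_alignments(s, 4, small_reference, rng)


class TestViralSets:
    def test_bifocal_circular_initial_structure(self, small_reference, rng):
        sets = simulate_viral_set(
            "bifocal", "circular", rng, n=2, n_iterations=0,
            reference=small_reference,
        )
        for snapshots in sets:
            s0 = snapshots[0]
            assert len(s0.segments) == 2
            assert {seg.chrom for seg in s0.segments} == {"chr1", "hpv16"}

    def test_unifocal_reciprocal_junctions(self, small_reference, rng):
        sets = simulate_viral_set(
            "unifocal", "circular", rng, n=2, n_iterations=0,
            reference=small_reference,
        )
        for snapshots in sets:
            s0 = snapshots[0]
            chimeric = [
                (a, b) for a, b in s0.junctions()
                if (a[0] == "hpv16") != (b[0] == "hpv16")
            ]
            human_pos = [
                (a if a[0] != "hpv16" else b)[1] for a, b in chimeric
            ]
            # one reciprocal pair at the integration site (< 1 kbp apart)
            assert len(human_pos) == 2
            assert abs(human_pos[0] - human_pos[1]) < 1000

    def test_amplicon_length_mean(self, rng):
        draws = [simgen.draw_amplicon_length(rng) for _ in range(10_000)]
        assert abs(np.mean(draws) - 155_000) / 155_000 < 0.05

    def test_snapshots_and_viral_retention(self, small_reference, rng):
        sets = simulate_viral_set(
            "bifocal", "linear", rng, n=2, n_iterations=5,
            reference=small_reference,
        )
        for snapshots in sets:
            assert len(snapshots) == 6
            for s in snapshots:
                assert s.viral_length() > 0
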