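import heapq
import itertools

import numpy as np
import pytest

from ampkit import rdcj
from ampkit.rdcj import (
    RDCJResult,
    error_rate,
    permutation_predictor,
    rdcj_distance,
    switch_cost,
)
from ampkit.simgen import AmpliconStructure, OrientedSegment


def circle(*segs, cn=1.0):
    return AmpliconStructure(
        [OrientedSegment(c, s, e, st) for c, s, e, st in segs],
        topology="circular", copy_number=cn,
    )


A = ("chr1", 0, 10_000, "+")
B = ("chr1", 20_000, 30_000, "+")
C = ("chr1", 40_000, 50_000, "+")
D = ("chr1", 60_000, 70_000, "+")


class TestIdentityAndBasics:
    def test_identity_zero(self):
        t = circle(A, B, C)
        r = rdcj_distance(t, [circle(A, B, C)])
        assert (r.errors, r.swaps) == (0, 0)

    def test_rotation_and_reflection_invariant(self):
        t = circle(A, B, C)
        rotated = circle(B, C, A)
        assert rdcj_distance(t, [rotated]).errors == 0
        reflected = circle(
            ("chr1", 40_000, 50_000, "-"),
            ("chr1", 20_000, 30_000, "-"),
            ("chr1", 0, 10_000, "-"),
        )
        r = rdcj_distance(t, [reflected])
        assert (r.errors, r.swaps) == (0, 0)

    def test_single_segment_truth(self):
        t = circle(A)
        r = rdcj_distance(t, [circle(A)])
        assert r.errors == 0 and r.n_segments == 1

    def test_missing_breakpoint_edge_costs_two(self):
        """Pred linearized through the source at one junction."""
        t = circle(A, B)
        pred = AmpliconStructure(
            [OrientedSegment(*A), OrientedSegment(*B)],
            topology="linear", copy_number=1.0,
        )
        r = rdcj_distance(t, [pred])
        assert r.errors == 2

    def test_swapped_adjacency_order(self):
        """Two cycles whose merge equals truth: 0 errors, 1 swap."""
        t = circle(A, B, A, C)  # truth traverses A twice
        preds = [circle(A, B), circle(A, C)]
        r = rdcj_distance(t, preds)
        assert (r.errors, r.swaps) == (0, 1)

    def test_empty_prediction_all_errors(self):
        t = circle(A, B, C)
        r = rdcj_distance(t, [])
        assert r.errors == 2 * 3
        assert r.error_rate == 100.0


class TestPermutationPredictor:
    def test_single_segment_identity(self, rng):
        t = circle(A)
        p = permutation_predictor(t, rng)
        assert rdcj_distance(t, [p]).errors == 0

    def test_reproducible(self):
        t = circle(A, B, C, D)
        p1 = permutation_predictor(t, np.random.default_rng(5))
        p2 = permutation_predictor(t, np.random.default_rng(5))
        assert [str(s) for s in p1.segments] == [str(s) for s in p2.segments]

    def test_mean_errors_near_two_per_segment(self, rng):
        """Average permutation errors approach 2 x segments (minus chance)."""
        segs = [("chr1", i * 20_000, i * 20_000 + 10_000, "+") for i in range(8)]
        t = circle(*segs)
        rates = []
        for _ in range(40):
            p = permutation_predictor(t, rng)
            rates.append(rdcj_distance(t, [p]).error_rate)
        assert 60 < np.mean(rates) <= 100


class TestErrorRate:
    def test_all_perfect_zero(self):
        rs = [RDCJResult(0, 0, 5), RDCJResult(0, 1, 3)]
        assert error_rate(rs) == 0.0

    def test_arithmetic(self):
        assert error_rate([RDCJResult(2, 0, 5)]) == 20.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_rate([])

    def test_invariant_under_relabeling(self):
        t1 = circle(A, B, C)
        t2 = circle(
            ("chr1", 100_000, 110_000, "+"),
            ("chr1", 120_000, 130_000, "+"),
            ("chr1", 140_000, 150_000, "+"),
        )
        p1 = circle(B, C, A)
        p2 = circle(
            ("chr1", 120_000, 130_000, "+"),
            ("chr1", 140_000, 150_000, "+"),
            ("chr1", 100_000, 110_000, "+"),
        )
        assert rdcj_distance(t1, [p1]).error_rate == rdcj_distance(t2, [p2]).error_rate


# ---------------------------------------------------------------------------
# independent BFS oracle over matching states


BLANK = rdcj.BLANK


def oracle_switch_cost(p_pairs, t_pairs):
    """Dijkstra over matching states with unit-cost vertex ops and swaps,
    minimizing (errors, swaps) lexicographically.  Independent of the
    production implementation."""
    labels_t = sorted({x for pair in t_pairs for x in pair} | {BLANK},
                      key=repr)
    m = max(len(p_pairs), len(t_pairs))
    pad = lambda lst: tuple(sorted(
        list(lst) + [(BLANK, BLANK)] * (m - len(lst)), key=repr
    ))
    start = pad(p_pairs)
    goal = pad(t_pairs)

    def neighbors(state):
        state = list(state)
        # reassignment of one endpoint (1 error)
        for i, (a, b) in enumerate(state):
            for lab in labels_t:
                if lab != a:
                    yield (1, 0), tuple(sorted(
                        state[:i] + [(lab, b)] + state[i + 1:], key=repr))
                if lab != b:
                    yield (1, 0), tuple(sorted(
                        state[:i] + [(a, lab)] + state[i + 1:], key=repr))
        # swap: exchange head partners of two edges (1 swap)
        for i, j in itertools.combinations(range(len(state)), 2):
            (a, b), (c, d) = state[i], state[j]
            yield (0, 1), tuple(sorted(
                state[:i] + [(a, d)] + state[i + 1:j] + [(c, b)] + state[j + 1:],
                key=repr))

    dist = {start: (0, 0)}
    heap = [((0, 0), 0, start)]
    tie = 0
    while heap:
        cost, _t, state = heapq.heappop(heap)
        if state == goal:
            return cost
        if dist.get(state, (99, 99)) < cost:
            continue
        for (de, ds), nxt in neighbors(state):
            ncost = (cost[0] + de, cost[1] + ds)
            if ncost < dist.get(nxt, (99, 99)):
                dist[nxt] = ncost
                tie += 1
                heapq.heappush(heap, (ncost, tie, nxt))
    raise AssertionError("oracle failed to reach goal")


LABELS = [(0, "h"), (0, "t"), (1, "h"), "src"]


@pytest.mark.parametrize("seed", range(30))
def test_switch_cost_matches_bfs_oracle(seed):
    rng = np.random.default_rng(seed)
    def rand_pairs(k):
        return [
            (LABELS[rng.integers(0, len(LABELS))],
             LABELS[rng.integers(0, len(LABELS))])
            for _ in range(k)
        ]
    p = rand_pairs(int(rng.integers(0, 4)))
    t = rand_pairs(int(rng.integers(1, 4)))
    got = switch_cost(p, t)
    want = oracle_switch_cost(p, t)
    assert got == want, f"{p} vs {t}: got {got}, oracle {want}"


def test_switch_cost_exhaustive_two_by_two():
    """All 2x2 switches over a tiny label alphabet match the oracle."""
    labs = [(0, "h"), (1, "t")]
    pairs2 = list(itertools.product(labs, labs))
    for p in itertools.combinations_with_replacement(pairs2, 2):
        for t in itertools.combinations_with_replacement(pairs2, 2):
            assert switch_cost(list(p), list(t)) == oracle_switch_cost(
                list(p), list(t)
            )


def test_report_round_trip(tmp_path):
    rows = [("sim0", RDCJResult(2, 1, 5)), ("sim1", RDCJResult(0, 0, 3))]
    path = tmp_path / "rdcj.tsv"
    rdcj.write_report(str(path), rows)
    lines = open(path).read().strip().splitlines()
    assert lines[0].startswith("simulation")
    assert lines[1].split("\t") == ["sim0", "2", "1", "5", "20.000"]
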