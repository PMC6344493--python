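"""Repeat-DCJ edit distance between amplicon structures.

Each common atomic segment is a *switch*: a bipartite gadget whose two
shores are the segment's tail (reference start) and head (reference end).
A traversal of the segment in a structure contributes one match edge
pairing the adjacency labels seen at its two ends.  The distance between a
predicted and a true structure is the per-switch sum of the minimum number
of operations transforming the predicted matching into the true one:

* a reconstruction error adds, deletes or reassigns exactly one vertex of a
  match edge;
* a repeat branch swap replaces match edges (V1,V2),(V3,V4) by
  (V1,V4),(V3,V2) — copy-number neutral, it re-routes traversals across a
  repeat.

Errors are minimized first, then swaps (lexicographic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .simgen import AmpliconStructure, OrientedSegment

SRC = "src"
BLANK = "."
SNAP_TOL = 500
MAX_EXACT = 5


@dataclass
class RDCJResult:
    errors: int
    swaps: int
    n_segments: int  # truth traversal count over the common atoms

    @property
    def error_rate(self) -> float:
        if self.n_segments == 0:
            return 0.0
        return 100.0 * self.errors / (2.0 * self.n_segments)


# ---------------------------------------------------------------------------
# structures -> cyclic element walks over common atoms


def _structure_walk(structure: AmpliconStructure):
    """Cyclic element list; linear structures get one SRC element at the wrap."""
    elements = [("seg", s) for s in structure.segments]
    if structure.topology == "linear":
        elements.append((SRC, None))
    return elements


def _snap_segments(segments, truth_bps, tol):
    out = []
    for s in segments:
        bps = truth_bps.get(s.chrom)
        start, end = s.start, s.end
        if bps is not None and len(bps):
            for attr, val in (("start", start), ("end", end)):
                j = int(np.searchsorted(bps, val))
                best = min(
                    (b for b in bps[max(j - 1, 0):j + 1]),
                    key=lambda b: abs(int(b) - val),
                    default=None,
                )
                if best is not None and abs(int(best) - val) <= tol:
                    if attr == "start":
                        start = int(best)
                    else:
                        end = int(best)
        if end > start:
            out.append(OrientedSegment(s.chrom, start, end, s.strand))
    return out


def _atomize(walks):
    """Build the common atomic partition and re-express walks over atom ids.

    ``walks``: list of cyclic element lists with ('seg', OrientedSegment)
    and (SRC, None) entries. Returns (atom table, atomized walks) where an
    atomized walk is a cyclic list of ('seg', atom_id, strand) / (SRC,)
    entries.
    """
    cuts = {}
    for walk in walks:
        for kind, seg in walk:
            if kind == "seg":
                cuts.setdefault(seg.chrom, set()).update((seg.start, seg.end))
    positions = {c: sorted(v) for c, v in cuts.items()}
    atom_id = {}
    atoms = []

    def atoms_in(seg):
        ps = positions[seg.chrom]
        lo = ps.index(seg.start)
        hi = ps.index(seg.end)
        ids = []
        for a, b in zip(ps[lo:hi], ps[lo + 1:hi + 1]):
            key = (seg.chrom, a, b)
            if key not in atom_id:
                atom_id[key] = len(atoms)
                atoms.append(key)
            ids.append(atom_id[key])
        return ids

    out = []
    for walk in walks:
        aw = []
        for kind, seg in walk:
            if kind == SRC:
                aw.append((SRC,))
                continue
            ids = atoms_in(seg)
            if seg.strand == "-":
                ids = ids[::-1]
            for i in ids:
                aw.append(("seg", i, seg.strand))
        out.append(aw)
    return atoms, out


def _entry_label(el):
    if el[0] == SRC:
        return SRC
    _k, i, strand = el
    return (i, "t" if strand == "+" else "h")


def _exit_label(el):
    if el[0] == SRC:
        return SRC
    _k, i, strand = el
    return (i, "h" if strand == "+" else "t")


def _switch_pairs(atom_walks, n_atoms):
    """Per-atom multiset of (tail_label, head_label) match edges."""
    pairs = [[] for _ in range(n_atoms)]
    for walk in atom_walks:
        n = len(walk)
        if n == 0:
            continue
        for k, el in enumerate(walk):
            if el[0] == SRC:
                continue
            prev = walk[(k - 1) % n]
            nxt = walk[(k + 1) % n]
            if n == 1:
                prev = nxt = el  # single-element circle adjoins itself
            _kind, i, strand = el
            if strand == "+":
                tail, head = _exit_label(prev), _entry_label(nxt)
            else:
                tail, head = _entry_label(nxt), _exit_label(prev)
            pairs[i].append((tail, head))
    return pairs


# ---------------------------------------------------------------------------
# per-switch minimization


def _shore_errors(p_labels, t_labels):
    pc, tc = Counter(p_labels), Counter(t_labels)
    common = sum((pc & tc).values())
    return max(len(p_labels), len(t_labels)) - common


def switch_cost(p_pairs, t_pairs, max_exact: int = MAX_EXACT):
    """Minimum (errors, swaps), lexicographic, for one switch.

    Pads the smaller matching with blank edges; enumerates tail/head shore
    slot assignments exactly up to multiplicity ``max_exact``, above which
    errors stay exact (shore-wise multiset edit) and swaps use a greedy
    upper bound.
    """
    m = max(len(p_pairs), len(t_pairs))
    if m == 0:
        return 0, 0
    pad = lambda lst: list(lst) + [(BLANK, BLANK)] * (m - len(lst))
    P, T = pad(p_pairs), pad(t_pairs)
    pt = [x[0] for x in P]
    ph = [x[1] for x in P]
    tt = [x[0] for x in T]
    th = [x[1] for x in T]
    lower = _shore_errors(pt, tt) + _shore_errors(ph, th)
    if m > max_exact:
        return lower, _greedy_swaps(P, T)
    best = None
    perms = list(permutations(range(m)))
    for p_t in perms:
        e_t = sum(pt[i] != tt[p_t[i]] for i in range(m))
        if best is not None and e_t > best[0]:
            continue
        for p_h in perms:
            errors = e_t + sum(ph[i] != th[p_h[i]] for i in range(m))
            if best is not None and errors > best[0]:
                continue
            # slot permutation: tail slot a -> head slot of the P edge in a
            inv = [0] * m
            for i in range(m):
                inv[p_t[i]] = i
            f = [p_h[inv[a]] for a in range(m)]
            swaps = m - _count_cycles(f)
            cand = (errors, swaps)
            if best is None or cand < best:
                best = cand
                if best == (lower, 0):
                    return best
    return best


def _count_cycles(f):
    seen = [False] * len(f)
    n = 0
    for i in range(len(f)):
        if not seen[i]:
            n += 1
            j = i
            while not seen[j]:
                seen[j] = True
                j = f[j]
    return n


def _greedy_swaps(P, T):
    """Upper bound on swaps: fix identical edges first, chain the rest."""
    tc = Counter(T)
    rest = []
    for p in P:
        if tc[p] > 0:
            tc[p] -= 1
        else:
            rest.append(p)
    # every unfixed edge may require one swap except one per chain
    return max(len(rest) - 1, 0) if rest else 0


# ---------------------------------------------------------------------------
# public API


def rdcj_distance(
    truth: AmpliconStructure,
    predictions,
    snap_tol: int = SNAP_TOL,
) -> RDCJResult:
    """RDCJ distance between a true structure and predicted structure(s).

    ``predictions`` is a list of AmpliconStructure (cycles from a
    decomposition; topology 'linear' marks source walks).  Predicted
    segment endpoints are snapped to truth breakpoints within ``snap_tol``
    before refinement to the common atomic partition.  Irreconcilable
    segment content is counted as errors, never raised.
    """
    truth_bps = {}
    for s in truth.segments:
        truth_bps.setdefault(s.chrom, set()).update((s.start, s.end))
    truth_bps = {c: np.array(sorted(v)) for c, v in truth_bps.items()}

    walks = [_structure_walk(truth)]
    for p in predictions:
        segs = _snap_segments(p.segments, truth_bps, snap_tol)
        if not segs:
            continue
        walks.append(
            _structure_walk(
                AmpliconStructure(segs, p.topology, p.copy_number)
            )
        )
    atoms, atom_walks = _atomize(walks)
    truth_pairs = _switch_pairs(atom_walks[:1], len(atoms))
    pred_pairs = _switch_pairs(atom_walks[1:], len(atoms))
    errors = swaps = 0
    for i in range(len(atoms)):
        e, s = switch_cost(pred_pairs[i], truth_pairs[i])
        errors += e
        swaps += s
    # normalization counts the truth structure's own segments (with
    # multiplicity), not the refined atoms
    return RDCJResult(errors, swaps, len(truth.segments))


def permutation_predictor(truth: AmpliconStructure, rng) -> AmpliconStructure:
    """Uniform random shuffle of the truth segment multiset (orientations
    kept), circularized — the naive baseline predictor."""
    order = list(rng.permutation(len(truth.segments)))
    return AmpliconStructure(
        [truth.segments[i] for i in order],
        topology="circular",
        copy_number=truth.copy_number,
        viral_chrom=truth.viral_chrom,
    )


def error_rate(results) -> float:
    """Aggregate normalized error rate (percent) over RDCJResults."""
    results = list(results)
    if not results:
        raise ValueError("empty result set")
    total_err = sum(r.errors for r in results)
    total_seg = sum(r.n_segments for r in results)
    if total_seg == 0:
        return 0.0
    return 100.0 * total_err / (2.0 * total_seg)


def write_report(path: str, rows) -> None:
    """rows: iterable of (name, RDCJResult)."""
    with open(path, "w") as fh:
        fh.write("simulation\terrors\tswaps\tsegments\terror_rate\n")
        for name, r in rows:
            fh.write(
                f"{name}\t{r.errors}\t{r.swaps}\t{r.n_segments}\t"
                f"{r.error_rate:.3f}\n"
            )
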