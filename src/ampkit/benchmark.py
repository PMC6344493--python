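"""Reduced-grid benchmark: simulate -> reconstruct -> score.

Drives the evaluation experiment used by the acceptance suite: a reduced
version of the simulation grid (sizes <= 640 kbp, CN {4,16,32},
rearrangements {0,4,8,16}, duplication probability {0,0.25,0.5}, coverage
alternating over {4,16}), the full reconstruction pipeline, the RDCJ score
against truth, and the random permutation-predictor baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from . import cli, rdcj, records, simgen

REDUCED_SIZES = (40_000, 160_000, 640_000)
REDUCED_CNS = (4, 16, 32)
REDUCED_REARRANGEMENTS = (0, 4, 8, 16)
REDUCED_PDUP = (0.0, 0.25, 0.5)
REDUCED_COVERAGES = (4, 16)


def reduced_grid():
    """The 108 evaluation cells; coverage alternates by cell parity."""
    cells = list(
        product(REDUCED_SIZES, REDUCED_CNS, REDUCED_REARRANGEMENTS, REDUCED_PDUP)
    )
    return [
        (sz, cn, nr, pd, REDUCED_COVERAGES[i % len(REDUCED_COVERAGES)])
        for i, (sz, cn, nr, pd) in enumerate(cells)
    ]


@dataclass
class BenchmarkRun:
    config: simgen.SimConfig
    result: rdcj.RDCJResult
    permutation: rdcj.RDCJResult
    explained: float
    runtime: float
    dna_content: float


def run_cell(cell, seed: int, reference=None,
             content_target: float = 0.9) -> BenchmarkRun:
    sz, cn, nr, pd, cov = cell
    if reference is None:
        reference = records.synthetic_reference()
    rng = np.random.default_rng(seed)
    cfg = simgen.SimConfig(sz, cn, nr, pd, cov, seed=seed)
    structure = simgen.simulate_structure(cfg, reference, rng)
    pairs = simgen.simulate_alignments(structure, cov, reference, rng)
    seed_iv = (reference.tid("hpv16"), 0, reference.length("hpv16"))
    res = cli.reconstruct_amplicon(
        pairs, reference, seed_iv, seed_rng=seed,
        content_target=content_target,
    )
    score = cli.evaluate_reconstruction(structure, res)
    perm = rdcj.rdcj_distance(
        structure, [rdcj.permutation_predictor(structure, rng)]
    )
    return BenchmarkRun(
        cfg, score, perm, res.explained, res.runtime,
        cli.dna_content(structure, cov),
    )


def run_reduced_grid(seed: int = 0, stride: int = 1, reference=None,
                     content_target: float = 0.9):
    """Run every ``stride``-th cell of the reduced grid (stride > 1 gives a
    deterministic subsample for tighter time budgets)."""
    if reference is None:
        reference = records.synthetic_reference()
    runs = []
    for i, cell in enumerate(reduced_grid()):
        if i % stride:
            continue
        runs.append(run_cell(cell, seed * 100_000 + i, reference,
                             content_target))
    return runs
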