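import numpy as np
import pytest

from ampkit import cli, records, seqstats, simgen


@pytest.fixture(scope="session")
def reference():
    return records.synthetic_reference()


@pytest.fixture(scope="session")
def small_reference():
    """3 Mbp human contig + viral contig: enough windows for seqstats."""
    return records.synthetic_reference(human_length=3_000_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simulated_instance(small_reference):
    """One mid-difficulty simulated amplicon shared across tests."""
    rng = np.random.default_rng(77)
    cfg = simgen.SimConfig(
        interval_size=80_000, copy_number=16, n_rearrangements=8,
        p_duplication=0.25, coverage=10, seed=77,
    )
    structure = simgen.simulate_structure(cfg, small_reference, rng)
    pairs = simgen.simulate_alignments(structure, 10, small_reference, rng)
    return cfg, structure, pairs


@pytest.fixture(scope="session")
def simulated_stats(simulated_instance, small_reference):
    _cfg, _structure, pairs = simulated_instance
    return seqstats.estimate_stats(pairs, small_reference, seed=1, n_windows=280)


@pytest.fixture(scope="session")
def reconstruction(simulated_instance, simulated_stats, small_reference):
    _cfg, _structure, pairs = simulated_instance
    seed = (small_reference.tid("hpv16"), 0, small_reference.length("hpv16"))
    return cli.reconstruct_amplicon(
        pairs, small_reference, seed, stats=simulated_stats,
    )
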