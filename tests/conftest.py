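import numpy as np
import pytest

from srnavirome.synthetic_data import default_specs, simulate_virome


@pytest.fixture(scope="session")
def default_virome():
    """One moderately deep synthetic virome shared across tests."""
    return simulate_virome(default_specs(), depth=4000, seed=11, n_eve_decoys=2)


@pytest.fixture(scope="session")
def virome_alignments_by_contig(default_virome):
    by = {c.id: [] for c in default_virome.contigs}
    for rec in default_virome.alignments:
        by[rec.contig_id].append(rec)
    return by


@pytest.fixture(scope="session")
def virome_reads_by_id(default_virome):
    return {
        r.id: r.sequence
        for reads in default_virome.reads_by_library.values()
        for r in reads
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
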