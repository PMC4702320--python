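import numpy as np
import pytest

from sspred import AlignedMotifSet, default_donor_spec, simulate_motifs

BASES = "ATGC"


def random_motifs(rng, n, p, label=None):
    """Uniform random aligned motif set (test helper, not the generator)."""
    codes = rng.integers(0, 4, size=(n, p))
    motifs = tuple("".join(BASES[c] for c in row) for row in codes)
    return AlignedMotifSet(motifs, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def donor_sets():
    """One seeded donor-like TSS/FSS draw shared across tests."""
    return simulate_motifs(default_donor_spec(n_tss=400, n_fss=400, seed=101))
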