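import numpy as np
import pytest

from relaxev import poolseq


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_sync(rng):
    """A small random 10-population sync table (counts on all four bases)."""
    n, npop = 200, 10
    counts = rng.integers(0, 40, size=(n, npop, 6))
    counts[:, :, 4:] = 0
    pos = np.sort(rng.choice(1_000_000, size=n, replace=False)) + 1
    return poolseq.SyncTable(
        chrom=np.array(["2L"] * n, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n, dtype=object),
        counts=counts,
    )


def make_snp_table(minor_freqs, coverage=50):
    """Build an SNPTable directly from per-population minor-allele
    frequencies (n_sites, n_pops), with exact (rounded) counts."""
    f = np.atleast_2d(np.asarray(minor_freqs, dtype=float))
    n, npop = f.shape
    minor = np.rint(f * coverage).astype(np.int64)
    return poolseq.SNPTable(
        chrom=np.array(["2L"] * n, dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64) * 100,
        major=np.array(["A"] * n, dtype=object),
        minor=np.array(["T"] * n, dtype=object),
        major_counts=coverage - minor,
        minor_counts=minor,
    )
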