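import numpy as np
import pytest

from granatum.variant_io import MISSING, GenomeLayout, GenotypeMatrix


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout((("chr1", 100_000), ("chr2", 50_000)))


def random_matrix(
    seed: int,
    n_samples: int = 20,
    n_sites: int = 200,
    missing_frac: float = 0.05,
    layout: GenomeLayout | None = None,
) -> GenotypeMatrix:
    """Random dosage matrix with uniform allele frequencies and missingness."""
    rng = np.random.default_rng(seed)
    layout = layout or GenomeLayout((("chr1", 1_000_000), ("chr2", 500_000)))
    lengths = np.array([c[1] for c in layout.chromosomes], dtype=float)
    ci = np.sort(rng.choice(len(lengths), n_sites, p=lengths / lengths.sum()))
    pos = np.sort(rng.integers(0, 1_000_000, n_sites))
    for i in range(1, n_sites):  # keep (chrom,pos) strictly increasing
        if ci[i] == ci[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    chrom = np.array([layout.chromosomes[i][0] for i in ci], dtype=object)
    p = rng.uniform(0.05, 0.95, n_sites)
    codes = rng.binomial(2, np.broadcast_to(p, (n_samples, n_sites))).astype(np.int8)
    if missing_frac:
        mask = rng.random(codes.shape) < missing_frac
        codes[mask] = MISSING
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "T", dtype=object)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, chrom, pos, ref, alt, codes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
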