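import numpy as np
import pytest

from hapld.alignment_io import HaplotypeAlignment


def make_alignment(seqs, gene="g", species="sp", cds=None, names=None):
    if names is None:
        names = tuple(f"h{i}" for i in range(len(seqs)))
    return HaplotypeAlignment(
        gene_id=gene, species_id=species, names=tuple(names),
        sequences=tuple(seqs), cds_intervals=cds,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20100915)


@pytest.fixture
def toy_alignment():
    # 4 haplotypes, 8 columns; sites 1 and 5 usable biallelic in perfect LD
    return make_alignment(
        ["AAGGTTCA", "ACGGTTCA", "AAGGTCCA", "ACGGTTCA"][:4]
    )


def random_2x2(rng, n_max=64):
    """Random two-locus haplotype counts with both margins polymorphic."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        cuts = sorted(rng.integers(0, n + 1, size=3))
        n11, n12, n21 = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
        n22 = n - cuts[2]
        if 0 < n11 + n12 < n and 0 < n11 + n21 < n:
            return n11, n12, n21, n22


def table_to_vectors(n11, n12, n21, n22):
    x = [1] * n11 + [1] * n12 + [0] * n21 + [0] * n22
    y = [1] * n11 + [0] * n12 + [1] * n21 + [0] * n22
    return np.array(x, float), np.array(y, float)
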