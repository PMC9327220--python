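import numpy as np
import pytest

from machkit.mach_io import DoseBlock, SampleId, SnpInfoRecord

ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def make_snps(m, chrom="1"):
    return [
        SnpInfoRecord(
            name=f"{chrom}:{100 * (j + 1)}",
            al1=ALLELE_PAIRS[j % 4][0],
            al2=ALLELE_PAIRS[j % 4][1],
            freq1=0.5,
            maf=0.5,
            quality=0.9,
            rsq=0.8,
        )
        for j in range(m)
    ]


def make_block(n, m, rng=None, chrom="1", dosages=None):
    """A small valid DoseBlock with FID->IID samples and chr:pos SNP names."""
    if dosages is None:
        rng = rng or np.random.default_rng(0)
        dosages = rng.uniform(0, 2, size=(n, m))
    samples = [SampleId.from_token(f"F{i}->I{i}") for i in range(n)]
    return DoseBlock(samples=samples, snps=make_snps(m, chrom), dosages=dosages, chrom_label=chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
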