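import numpy as np
import pytest

from sanderpop import GenotypeMatrix
from sanderpop.ancestry import ParentalFreqs

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t./.\t0/0
"""

VCF_TRIALLELIC = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1
chr1\t150\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t1/2
chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t1/1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(VCF_TEXT)
    return p


@pytest.fixture
def triallelic_vcf(tmp_path):
    p = tmp_path / "tri.vcf"
    p.write_text(VCF_TRIALLELIC)
    return p


@pytest.fixture
def tiny_gm():
    """3 samples x 2 loci matching VCF_TEXT."""
    return GenotypeMatrix(
        samples=["s1", "s2", "s3"],
        chrom=["chr1", "chr1"],
        pos=[100, 200],
        gt=np.array([[0, 1], [1, -1], [2, 0]], dtype=np.int8),
    )


@pytest.fixture
def diagnostic_freqs():
    """Fully diagnostic parental panel: species A fixed ref, B fixed alt."""
    L = 200
    return ParentalFreqs(np.zeros(L), np.ones(L))


def make_gm(gt, chrom=None, pos=None, samples=None):
    gt = np.asarray(gt, dtype=np.int8)
    n, L = gt.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        chrom=chrom if chrom is not None else ["chr1"] * L,
        pos=pos if pos is not None else np.arange(1, L + 1),
        gt=gt,
    )
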