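import numpy as np
import pytest

from gdmfuse import AlleleFrequencyTable, LabeledDistanceMatrix


@pytest.fixture
def toy_vcf(tmp_path):
    """4 biallelic SNPs x 3 pooled samples with AD/DP FORMAT fields.

    chr1:400 is missing (DP below threshold) in 2 of 3 samples, so it is
    the locus the 5% missingness filter removes.
    """
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
    )
    rows = [
        # S1 f=0.8, S2 f=0.5, S3 f=1.0
        "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD:DP\t0/1:8,2:10\t0/1:5,5:10\t0/0:10,0:10",
        "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:AD:DP\t0/1:6,2:8\t0/1:4,2:6\t0/1:4,4:8",
        "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:AD:DP\t0/1:3,7:10\t0/1:2,8:10\t0/1:1,9:10",
        # S1 below depth; S2 at DP=5 exactly (missing under the strict rule)
        "chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT:AD:DP\t0/1:1,1:2\t0/1:3,2:5\t0/1:5,5:10",
    ]
    path = tmp_path / "toy.vcf"
    path.write_text(header + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def square5():
    """A complete Euclidean-embeddable 5x5 matrix from planar points."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(5, 2))
    from scipy.spatial.distance import pdist, squareform

    return LabeledDistanceMatrix(
        [f"p{i}" for i in range(5)], squareform(pdist(pts))
    )


@pytest.fixture
def freq_table():
    return AlleleFrequencyTable(
        ["x", "y", "z"],
        ["l1", "l2", "l3"],
        np.array([
            [0.2, 0.8, 0.5],
            [0.2, np.nan, 0.5],
            [0.9, 0.1, np.nan],
        ]),
    )
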