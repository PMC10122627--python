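import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from varburden import (  # noqa: E402
    CaseCohort,
    CaseVariant,
    GeneModel,
)


@pytest.fixture
def gene_one() -> GeneModel:
    """Single gene, two exons, default 5-bp pad."""
    return GeneModel(gene="G1", chrom="1", exons=[(100, 200), (300, 400)])


@pytest.fixture
def tiny_cohort() -> CaseCohort:
    """Three samples, two missense SNVs inside gene_one's exons."""
    return CaseCohort(
        samples=["S1", "S2", "S3"],
        variants=[
            CaseVariant(
                chrom="1", pos=150, ref="A", alt="G",
                consequences={"missense_variant"},
                dosages=np.array([1, 0, 1], dtype=np.int8),
            ),
            CaseVariant(
                chrom="1", pos=350, ref="C", alt="T",
                consequences={"missense_variant"},
                dosages=np.array([0, 2, 1], dtype=np.int8),
            ),
        ],
    )


def write_vcf(path, body: str, samples=("S1", "S2", "S3"), extra_header=""):
    """Write a minimal but valid multi-sample VCF v4.2."""
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        "##contig=<ID=2>\n"
        '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Allele|Consequence">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
        + extra_header
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)
    return str(path)
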