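import numpy as np
import pytest

from pstfst.types import GenotypeMatrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=ctg1>\n##contig=<ID=ctg2>\n"
)


def write_vcf(path, samples, records):
    """records: list of (chrom, pos, ref, alt, [gt strings])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_popmap(path, mapping):
    with open(path, "w") as fh:
        for s, p in mapping.items():
            fh.write(f"{s}\t{p}\n")


@pytest.fixture
def tiny_vcf(tmp_path):
    vcf = tmp_path / "tiny.vcf"
    popmap = tmp_path / "popmap.tsv"
    write_vcf(vcf, ["s1", "s2", "s3"], [
        ("ctg1", 100, "A", "T", ["0/0", "0/1", "1/1"]),
        ("ctg2", 50, "G", "C", ["0|1", "./.", "1/1"]),
    ])
    write_popmap(popmap, {"s1": "A", "s2": "A", "s3": "B"})
    return vcf, popmap


def genotypes_from_dosages(dosages, populations, loci=None):
    dosages = np.asarray(dosages)
    n, L = dosages.shape
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        populations=list(populations),
        dosages=dosages,
        loci=loci or [f"ctg{j}:1" for j in range(L)],
    )
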