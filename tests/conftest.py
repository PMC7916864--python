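import numpy as np
import pytest

from popgenkit.genotypes import GenotypeMatrix, SampleMetadata


def make_matrix(dosages, positions=None, scaffolds=None, samples=None, qual=None):
    """Build a small GenotypeMatrix from a nested list of dosages."""
    d = np.asarray(dosages, dtype=np.int8)
    n_s, n_v = d.shape
    if positions is None:
        positions = (np.arange(n_v) + 1) * 10_000
    if scaffolds is None:
        scaffolds = ["chr1"] * n_v
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_s)]
    return GenotypeMatrix(
        dosages=d,
        scaffolds=np.array(scaffolds, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_v, dtype=object),
        alt=np.array(["G"] * n_v, dtype=object),
        samples=list(samples),
        qual=qual,
    )


def write_test_vcf(path, records, samples):
    """Write a small plain-text VCF.

    ``records`` is a list of (chrom, pos, ref, alt, qual, genotype strings).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {r[0] for r in records}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c},length=100000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, qual, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


@pytest.fixture
def two_group_meta():
    return SampleMetadata(
        {
            "s1": ("blue", "farmA"),
            "s2": ("blue", "farmA"),
            "s3": ("red", "farmA"),
            "s4": ("red", "farmA"),
        }
    )
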