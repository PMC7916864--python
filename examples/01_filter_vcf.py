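"""Filter a multi-sample VCF on MAF, missingness and site quality.

Builds a small VCF in a temporary directory, reads it into a genotype
matrix, applies the standard resequencing filters (MAF > 0.05, missing
fraction < 0.1, QUAL > 30) and prints what survived.
"""

import tempfile
from pathlib import Path

import numpy as np

from popgenkit import FilterSpec, apply_filters, read_vcf, write_vcf
from popgenkit.genotypes import GenotypeMatrix

rng = np.random.default_rng(0)
n_samples, n_variants = 20, 200
freqs = rng.uniform(0.0, 0.5, n_variants)
dosages = rng.binomial(2, freqs, size=(n_samples, n_variants)).astype(np.int8)
gm = GenotypeMatrix(
    dosages=dosages,
    scaffolds=np.array(["scaffold_1"] * n_variants, dtype=object),
    positions=(np.arange(n_variants, dtype=np.int64) + 1) * 10_000,
    ref=np.array(["A"] * n_variants, dtype=object),
    alt=np.array(["G"] * n_variants, dtype=object),
    samples=[f"mink_{i}" for i in range(n_samples)],
    qual=rng.uniform(10, 100, n_variants),
)

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "cohort.vcf"
    write_vcf(gm, vcf)
    loaded = read_vcf(vcf)
    filtered = apply_filters(loaded, spec=FilterSpec(min_maf=0.05, max_missing=0.1,
                                                     min_qual=30))

print(f"variants read:      {loaded.n_variants}")
print(f"variants retained:  {filtered.n_variants}")
print(f"post-filter MAF range: {filtered.maf().min():.3f}-{filtered.maf().max():.3f}")
# Retained sites all have minor allele frequency above 0.05 and QUAL above 30;
# low-frequency and low-confidence sites were removed before analysis.
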