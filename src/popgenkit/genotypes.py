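"""Genotype containers, VCF/metadata I/O and variant filtering.

The central in-memory object is :class:`GenotypeMatrix`: a samples x variants
matrix of alternate-allele dosages (0, 1, 2; missing calls are stored as -1)
together with the scaffold/position map of each variant.  Only bi-allelic
SNPs are represented; multi-allelic records and non-SNP variants are dropped
at read time.

Variant filtering follows the conventional whole-genome-resequencing recipe:
minor allele frequency strictly above a floor, per-site missing-call fraction
strictly below a ceiling, and site QUAL strictly above a phred threshold.
MAF and missingness are computed jointly over all samples; per-group
statistics in :mod:`popgenkit.diversity` recompute frequencies descriptively
within groups without re-filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel used for missing genotype calls in dosage matrices.
MISSING = -1

UNASSIGNED = "unassigned"


class EmptyFilterError(ValueError):
    """Raised when a filter removes every variant."""


@dataclass
class GenotypeMatrix:
    """Bi-allelic SNP dosages for a set of samples.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` integer array with values 0, 1, 2 or
        :data:`MISSING`.
    scaffolds, positions, ref, alt
        Per-variant arrays; positions are 1-based and strictly increasing
        within each scaffold.
    samples
        Ordered sample identifiers (rows of ``dosages``).
    qual
        Optional per-variant phred site quality (populated by
        :func:`read_vcf`).
    """

    dosages: np.ndarray
    scaffolds: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        n_s, n_v = self.dosages.shape
        if len(self.samples) != n_s:
            raise ValueError("sample list does not match dosage rows")
        for arr, name in ((self.scaffolds, "scaffolds"), (self.positions, "positions"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_v:
                raise ValueError(f"{name} does not match dosage columns")
        vals = np.unique(self.dosages)
        bad = set(vals.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid dosage values: {sorted(bad)}")
        # positions strictly increasing within each scaffold (in file order)
        for scaf in pd.unique(self.scaffolds):
            pos = self.positions[self.scaffolds == scaf]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample: {sample}") from None

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to the variants selected by index array or boolean mask."""
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            scaffolds=self.scaffolds[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            samples=list(self.samples),
            qual=None if self.qual is None else self.qual[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            scaffolds=self.scaffolds,
            positions=self.positions,
            ref=self.ref,
            alt=self.alt,
            samples=[self.samples[i] for i in idx],
            qual=self.qual,
        )

    # ------------------------------------------------------------------ #
    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls.

        Variants with no non-missing call yield ``nan``.
        """
        d = self.dosages if sample_idx is None else self.dosages[sample_idx, :]
        obs = d != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_freq(sample_idx)
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def scaffold_spans(self) -> dict[str, tuple[int, int]]:
        """First/last observed position per scaffold (proxy for length)."""
        out: dict[str, tuple[int, int]] = {}
        for scaf in pd.unique(self.scaffolds):
            pos = self.positions[self.scaffolds == scaf]
            out[scaf] = (int(pos.min()), int(pos.max()))
        return out

    def callable_length(self) -> int:
        """Total span of analysed scaffolds, the default denominator of F_ROH."""
        return sum(hi - lo + 1 for lo, hi in self.scaffold_spans().values())


@dataclass
class SampleMetadata:
    """Maps each sample to a group (e.g. color-type) and supergroup (e.g. farm)."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample", "group", "supergroup"}
        if not required.issubset(df.columns):
            raise ValueError(f"metadata must have columns {sorted(required)}")
        return cls({r["sample"]: (r["group"], r["supergroup"]) for _, r in df.iterrows()})

    def group_of(self, sample: str) -> str:
        return self.assignments[sample][0]

    def supergroup_of(self, sample: str) -> str:
        return self.assignments[sample][1]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(g for g, _ in self.assignments.values()))

    @property
    def supergroups(self) -> list[str]:
        return list(dict.fromkeys(s for _, s in self.assignments.values()))

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s, (g, _) in self.assignments.items() if g == group]
        if not out:
            raise KeyError(f"unknown or empty group: {group}")
        return out

    def group_indices(self, gm: GenotypeMatrix, group: str) -> np.ndarray:
        members = set(self.samples_in_group(group))
        idx = np.array([i for i, s in enumerate(gm.samples) if s in members], dtype=int)
        if idx.size == 0:
            raise KeyError(f"group {group} has no samples in the matrix")
        return idx

    def ensure_samples(self, samples: list[str]) -> None:
        """Register unknown samples as unassigned (with a warning)."""
        for s in samples:
            if s not in self.assignments:
                logger.warning("sample %s absent from metadata; group set to %r", s, UNASSIGNED)
                self.assignments[s] = (UNASSIGNED, UNASSIGNED)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(s, g, sg) for s, (g, sg) in self.assignments.items()]
        pd.DataFrame(rows, columns=["sample", "group", "supergroup"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class FilterSpec:
    """Site-level variant filter thresholds (all inequalities are strict)."""

    min_maf: float = 0.05
    max_missing: float = 0.1
    min_qual: float | None = 30.0
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


# ---------------------------------------------------------------------- #
# VCF / tabular I/O
# ---------------------------------------------------------------------- #

def read_vcf(path: str | Path, metadata: SampleMetadata | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and non-SNP variants are dropped (the count is
    logged).  Sample order follows the VCF header.  Samples missing from
    ``metadata`` are registered as unassigned with a warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if metadata is not None:
        metadata.ensure_samples(samples)

    cols, scafs, pos, ref, alt, qual = [], [], [], [], [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = v.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(dos.astype(np.int8))
        scafs.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)
    if not cols:
        raise ValueError(f"no usable bi-allelic SNP records in {path}")

    gm = GenotypeMatrix(
        dosages=np.column_stack(cols),
        scaffolds=np.array(scafs, dtype=object),
        positions=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        samples=samples,
        qual=np.array(qual, dtype=float),
    )
    gm.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return gm


def apply_filters(
    gm: GenotypeMatrix,
    qual: np.ndarray | None = None,
    spec: FilterSpec | None = None,
) -> GenotypeMatrix:
    """Retain variants passing the :class:`FilterSpec` thresholds.

    MAF is computed over non-missing calls across *all* samples.  Quality is
    taken from ``qual`` if given, else from ``gm.qual``; if neither is
    available the quality criterion is skipped.  Raises
    :class:`EmptyFilterError` when nothing survives.
    """
    spec = spec or FilterSpec()
    keep = np.ones(gm.n_variants, dtype=bool)

    maf = gm.maf()
    keep &= np.where(np.isnan(maf), False, maf > spec.min_maf)
    keep &= gm.missing_rate() < spec.max_missing

    q = qual if qual is not None else gm.qual
    if spec.min_qual is not None and q is not None:
        q = np.asarray(q, dtype=float)
        keep &= np.where(np.isnan(q), True, q > spec.min_qual)

    if not keep.any():
        raise EmptyFilterError("all variants removed by filters")
    return gm.take_variants(keep)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal plain-text VCF v4.2."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf, (_, hi) in gm.scaffold_spans().items():
            fh.write(f"##contig=<ID={scaf},length={hi}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        qual = gm.qual
        for j in range(gm.n_variants):
            q = "." if qual is None or np.isnan(qual[j]) else f"{qual[j]:g}"
            gts = "\t".join(code[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{gm.scaffolds[j]}\t{gm.positions[j]}\t.\t{gm.ref[j]}\t"
                     f"{gm.alt[j]}\t{q}\tPASS\t.\tGT\t{gts}\n")


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a samples-as-rows dosage table (missing as -1)."""
    cols = [f"{s}:{p}" for s, p in zip(gm.scaffolds, gm.positions)]
    pd.DataFrame(gm.dosages, index=gm.samples, columns=cols).to_csv(path, sep="\t")


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a pedigree TSV with columns individual, sire, dam.

    ``0`` or empty parent fields denote founders and are mapped to ``None``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree must have columns {sorted(required)}")
    for col in ("sire", "dam"):
        df[col] = df[col].where(~df[col].isin(["0", "", "nan"]) & df[col].notna(), None)
    return df[["individual", "sire", "dam"]]


def write_pedigree(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("0")
    out.to_csv(path, sep="\t", index=False)
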