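"""Per-group diversity and individual inbreeding statistics.

Covers average minor allele frequency and observed heterozygosity per group,
the excess-homozygosity inbreeding coefficient F_HOM per sample, Wright's
pedigree inbreeding coefficient F_PED via the recursive tabular method, and
Pearson correlations among inbreeding measures.

F_HOM is the method-of-moments form

    F = (O_hom - E_hom) / (m - E_hom),

where over a sample's m non-missing variants O_hom counts observed
homozygotes and E_hom sums the Hardy-Weinberg expectation
1 - 2 p_j (1 - p_j) * 2N_j / (2N_j - 1) with the small-sample correction;
p_j is by default the alternate-allele frequency over *all* samples (the
pooled reference set), with an optional per-group frequency mode.  Data at
Hardy-Weinberg give F near 0 and heterozygote excess gives F < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SampleMetadata

__all__ = [
    "GroupDiversitySummary",
    "group_maf_het",
    "f_hom",
    "f_hom_all",
    "f_ped",
    "inbreeding_correlations",
    "diversity_table",
]


@dataclass
class GroupDiversitySummary:
    group: str
    n_animals: int
    mean_maf: float
    observed_het_pct: float
    mean_f_hom: float
    mean_f_ped: float | None = None


def group_maf_het(
    gm: GenotypeMatrix, metadata: SampleMetadata, group: str
) -> tuple[float, float]:
    """Mean MAF and observed heterozygosity (%) within one group.

    MAF is recomputed per variant over the group's non-missing calls
    (variants with no call in the group are skipped); heterozygosity is the
    percentage of non-missing genotype calls that are heterozygous.
    """
    idx = metadata.group_indices(gm, group)
    maf = gm.maf(idx)
    d = gm.dosages[idx, :]
    obs = d != MISSING
    if obs.sum() == 0:
        raise ValueError(f"group {group} has no genotype calls")
    het_pct = 100.0 * (d == 1).sum() / obs.sum()
    return float(np.nanmean(maf)), float(het_pct)


def _expected_hom(gm: GenotypeMatrix, freq_idx: np.ndarray | None) -> np.ndarray:
    """Per-variant expected homozygote probability with 2N/(2N-1) correction."""
    d = gm.dosages if freq_idx is None else gm.dosages[freq_idx, :]
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)
    p = gm.alt_freq(freq_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = 2.0 * n / (2.0 * n - 1.0)
    return 1.0 - 2.0 * p * (1.0 - p) * corr


def f_hom(
    gm: GenotypeMatrix,
    sample: str,
    freq_samples: np.ndarray | None = None,
) -> float:
    """Excess-of-homozygosity inbreeding coefficient of one sample.

    ``freq_samples`` optionally restricts the reference allele frequencies to
    a subset of sample indices (e.g. one group); by default frequencies come
    from the full sample set.
    """
    si = gm.sample_index(sample)
    d = gm.dosages[si, :]
    called = d != MISSING
    e_hom = _expected_hom(gm, freq_samples)
    use = called & ~np.isnan(e_hom)
    m = int(use.sum())
    if m == 0:
        raise ValueError(f"sample {sample} has no usable calls")
    o = float(((d == 0) | (d == 2))[use].sum())
    e = float(e_hom[use].sum())
    denom = m - e
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("expected homozygosity equals variant count; F undefined")
    return (o - e) / denom


def f_hom_all(
    gm: GenotypeMatrix, freq_samples: np.ndarray | None = None
) -> pd.Series:
    """F_HOM for every sample (vectorized across samples)."""
    d = gm.dosages
    called = d != MISSING
    e_hom = _expected_hom(gm, freq_samples)
    valid = ~np.isnan(e_hom)
    use = called & valid[None, :]
    m = use.sum(axis=1).astype(float)
    o = (((d == 0) | (d == 2)) & use).sum(axis=1).astype(float)
    e = (np.where(valid, e_hom, 0.0)[None, :] * use).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o - e) / (m - e)
    return pd.Series(f, index=gm.samples, name="f_hom")


# ---------------------------------------------------------------------- #
# Pedigree inbreeding (tabular / recursive kinship method)
# ---------------------------------------------------------------------- #

def _kinship_table(pedigree: pd.DataFrame):
    parent = {r.individual: (r.sire, r.dam) for r in pedigree.itertuples()}

    # depth (generation number) with cycle detection
    depth: dict[str, int] = {}

    def depth_of(ind, stack=()):
        if ind is None:
            return -1
        if ind in depth:
            return depth[ind]
        if ind in stack:
            raise ValueError("pedigree contains a cycle")
        s, d = parent.get(ind, (None, None))
        depth[ind] = 1 + max(depth_of(s, stack + (ind,)), depth_of(d, stack + (ind,)))
        return depth[ind]

    for ind in parent:
        depth_of(ind)

    memo: dict[frozenset, float] = {}

    def phi(a, b) -> float:
        """Coefficient of kinship between a and b (None = unknown founder parent)."""
        if a is None or b is None:
            return 0.0
        key = frozenset((a, b)) if a != b else frozenset((a,))
        if key in memo:
            return memo[key]
        if a == b:
            s, d = parent.get(a, (None, None))
            val = 0.5 * (1.0 + phi(s, d))
        else:
            # recurse on the individual farther from the founders
            if depth.get(a, 0) < depth.get(b, 0):
                a, b = b, a
            s, d = parent.get(a, (None, None))
            val = 0.5 * (phi(s, b) + phi(d, b))
        memo[key] = val
        return val

    return parent, phi


def f_ped(pedigree: pd.DataFrame, individual: str) -> float:
    """Wright's inbreeding coefficient from a pedigree table.

    Computed as the kinship between the individual's parents via the
    recursive tabular (additive-relationship) method; founders get F = 0.
    Raises on cycles or unknown individuals.
    """
    parent, phi = _kinship_table(pedigree)
    if individual not in parent:
        raise KeyError(f"individual {individual} not in pedigree")
    sire, dam = parent[individual]
    return phi(sire, dam)


def f_ped_all(pedigree: pd.DataFrame) -> pd.Series:
    parent, phi = _kinship_table(pedigree)
    vals = {ind: phi(*parent[ind]) for ind in parent}
    return pd.Series(vals, name="f_ped")


# ---------------------------------------------------------------------- #

def inbreeding_correlations(measures: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among per-sample inbreeding measures.

    ``measures`` has one row per sample and one column per measure (e.g.
    f_hom, f_roh, f_ped); missing entries are handled pairwise-complete.
    Measures with zero variance yield NaN correlations (flagged by pandas).
    """
    if len(measures) < 3:
        raise ValueError("need at least 3 samples for correlations")
    return measures.corr(method="pearson", min_periods=3)


def diversity_table(
    gm: GenotypeMatrix,
    metadata: SampleMetadata,
    f_ped_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-group summary (plus supergroup and pooled rows) of MAF, het%, F_HOM, F_PED."""
    fh = f_hom_all(gm)
    rows = []

    def one(label: str, idx: np.ndarray):
        sub_samples = [gm.samples[i] for i in idx]
        maf = gm.maf(idx)
        d = gm.dosages[idx, :]
        obs = d != MISSING
        het = 100.0 * (d == 1).sum() / obs.sum()
        fp = None
        if f_ped_values is not None:
            hits = f_ped_values.reindex(sub_samples).dropna()
            fp = float(hits.mean()) if len(hits) else None
        rows.append(
            GroupDiversitySummary(
                group=label,
                n_animals=len(idx),
                mean_maf=float(np.nanmean(maf)),
                observed_het_pct=float(het),
                mean_f_hom=float(fh.iloc[idx].mean()),
                mean_f_ped=fp,
            )
        )

    for g in metadata.groups:
        one(g, metadata.group_indices(gm, g))
    if len(metadata.supergroups) > 1:
        for sg in metadata.supergroups:
            idx = np.array(
                [i for i, s in enumerate(gm.samples) if metadata.supergroup_of(s) == sg],
                dtype=int,
            )
            if idx.size:
                one(sg, idx)
    one("Total", np.arange(gm.n_samples))
    return pd.DataFrame([r.__dict__ for r in rows])
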