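"""Composite-genotype linkage disequilibrium and LD-based Ne estimation.

Because genotypes are unphased, the gametic disequilibrium D is estimated by
the Burrows composite estimator, which needs no haplotype reconstruction:

    D = [N/(N-1)] * ( (2*N_AABB + N_AABb + N_AaBB + N_AaBb/2) / N
                      - 2 * p_A * p_B )

with N the samples non-missing at both loci and p the allele frequencies over
those samples.  Writing X, Y for the two dosage vectors this equals the
sample covariance of (X, Y) divided by two.  The squared correlation is

    r^2 = D^2 / (p_A * p_a * p_B * p_b),

followed by the small-sample correction for unphased data

    r^2_corrected = (r^2 - 1/n) / (1 - 1/n),  n = number of sampled
    haplotypes = 2 * N,

clamped to [0, 1] (the correction can produce small negatives at low true
LD, and negative mass would bias the Ne inversion upward).

Ne trajectories invert Sved's expectation E[r^2] = 1 / (1 + 4*Ne*c) at the
recombination distance c (Morgans) of each distance bin, and date each
estimate to 1/(2c) generations ago; at the conventional 1 cM/Mb, a bin at
10 Mb reflects Ne five generations ago and a bin at 250 kb reflects 200
generations ago.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "LdConfig",
    "LDBin",
    "NePoint",
    "composite_d",
    "pair_r2",
    "adjacent_r2",
    "ld_decay",
    "sved_expected_r2",
    "ne_from_bin",
    "ne_trajectory",
    "marker_density",
    "decay_distance",
]


@dataclass
class LdConfig:
    """Settings for genome-wide LD scans and Ne dating.

    ``n_snps`` SNPs are randomly subsampled (seeded, without replacement)
    from scaffolds whose observed span is at least ``min_scaffold_length``
    before pairs are formed.  ``cm_per_mb`` converts base pairs to Morgans.
    """

    n_snps: int = 100_000
    min_scaffold_length: int = 10_000_000
    cm_per_mb: float = 1.0
    seed: int = 0
    generations: tuple[int, ...] = (200, 150, 100, 50, 10, 5)

    @property
    def morgans_per_bp(self) -> float:
        return self.cm_per_mb * 1e-8


@dataclass
class LDBin:
    low: int
    high: int
    n_pairs: int
    mean_r2: float
    sd_r2: float
    median_distance: float


@dataclass
class NePoint:
    generations_ago: float
    c_morgans: float
    mean_r2: float
    ne: float


# ---------------------------------------------------------------------- #
# Pair-level estimators
# ---------------------------------------------------------------------- #

def composite_d(table: np.ndarray) -> float:
    """Burrows composite D from a 3x3 joint dosage table.

    ``table[i, j]`` counts samples with dosage i at the first locus and j at
    the second.  Raises when either locus is monomorphic among the tabled
    samples or fewer than two samples are present.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("expected a 3x3 joint genotype table")
    n = t.sum()
    if n < 2:
        raise ValueError("need at least 2 samples")
    i = np.arange(3)
    x_mean = (t.sum(axis=1) * i).sum() / n
    y_mean = (t.sum(axis=0) * i).sum() / n
    p_a, p_b = x_mean / 2.0, y_mean / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic locus; composite D undefined")
    xy = (t * np.outer(i, i)).sum() / n
    return float(n / (n - 1.0) * (xy / 2.0 - 2.0 * p_a * p_b))


def _cross_stats(z1, w1, z2, w2):
    """Corrected r^2 for every column pair of two dosage blocks.

    ``z`` holds dosages with missing as 0, ``w`` the non-missing masks;
    shapes (S, V1) and (S, V2).  Returns an array (V1, V2) with NaN where a
    pair has < 2 shared samples or a monomorphic locus among them.
    """
    n = w1.T @ w2
    sxy = z1.T @ z2
    sx = z1.T @ w2
    sy = w1.T @ z2
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = sx / (2.0 * n)
        pb = sy / (2.0 * n)
        inner = sxy / (2.0 * n) - 2.0 * pa * pb
        d = n / (n - 1.0) * inner
        denom = pa * (1.0 - pa) * pb * (1.0 - pb)
        r2 = d * d / denom
        nh = 2.0 * n
        r2c = (r2 - 1.0 / nh) / (1.0 - 1.0 / nh)
    bad = (n < 2) | ~np.isfinite(r2c) | (denom <= 0)
    r2c = np.clip(r2c, 0.0, 1.0)
    r2c[bad] = np.nan
    return r2c


def _prepare(dosages: np.ndarray):
    w = (dosages != MISSING).astype(np.float64)
    z = np.where(dosages != MISSING, dosages, 0).astype(np.float64)
    return z, w


def pair_r2(gm: GenotypeMatrix, i: int, j: int, sample_idx: np.ndarray | None = None) -> float:
    """Sample-size-corrected composite r^2 between two variants.

    Both variants must sit on the same scaffold.  Returns NaN when either
    locus is monomorphic among the shared samples; raises when fewer than two
    samples are non-missing at both.
    """
    if gm.scaffolds[i] != gm.scaffolds[j]:
        raise ValueError("r^2 pairs are restricted to one scaffold")
    d = gm.dosages if sample_idx is None else gm.dosages[sample_idx, :]
    z, w = _prepare(d[:, [i, j]])
    if float(w[:, 0] @ w[:, 1]) < 2:
        raise ValueError("fewer than 2 shared non-missing samples")
    return float(_cross_stats(z[:, :1], w[:, :1], z[:, 1:], w[:, 1:])[0, 0])


def correct_r2(r2_computed: float | np.ndarray, n_haplotypes: float) -> float | np.ndarray:
    """Sample-size correction for unphased data, clamped to [0, 1]."""
    out = (r2_computed - 1.0 / n_haplotypes) / (1.0 - 1.0 / n_haplotypes)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------- #
# Genome scans
# ---------------------------------------------------------------------- #

def _elementwise_pairs(z1, w1, z2, w2):
    """Corrected r^2 for P pre-matched pairs, shapes (S, P)."""
    n = (w1 * w2).sum(axis=0)
    sxy = (z1 * z2).sum(axis=0)
    sx = (z1 * w2).sum(axis=0)
    sy = (w1 * z2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = sx / (2.0 * n)
        pb = sy / (2.0 * n)
        d = n / (n - 1.0) * (sxy / (2.0 * n) - 2.0 * pa * pb)
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2 = d * d / denom
        r2c = (r2 - 1.0 / (2 * n)) / (1.0 - 1.0 / (2 * n))
    bad = (n < 2) | ~np.isfinite(r2c) | (denom <= 0)
    r2c = np.clip(r2c, 0.0, 1.0)
    r2c[bad] = np.nan
    return r2c


def adjacent_r2(
    gm: GenotypeMatrix,
    metadata: SampleMetadata | None = None,
    group: str | None = None,
) -> tuple[float, float, float]:
    """Mean/SD of r^2 between consecutive SNPs and mean adjacent distance (bp).

    Uses only the group's samples when ``group`` is given; pairs monomorphic
    within the group are skipped.
    """
    idx = None
    if group is not None:
        if metadata is None:
            raise ValueError("metadata required to select a group")
        idx = metadata.group_indices(gm, group)
    d = gm.dosages if idx is None else gm.dosages[idx, :]

    r2s, dists = [], []
    for scaf in pd.unique(gm.scaffolds):
        cols = np.flatnonzero(gm.scaffolds == scaf)
        if cols.size < 2:
            continue
        z, w = _prepare(d[:, cols])
        r2 = _elementwise_pairs(z[:, :-1], w[:, :-1], z[:, 1:], w[:, 1:])
        dist = np.diff(gm.positions[cols]).astype(float)
        ok = ~np.isnan(r2)
        r2s.append(r2[ok])
        dists.append(dist[ok])
    r2s = np.concatenate(r2s) if r2s else np.array([])
    dists = np.concatenate(dists) if dists else np.array([])
    if r2s.size < 2:
        raise ValueError("fewer than 2 usable adjacent SNP pairs")
    return float(r2s.mean()), float(r2s.std(ddof=1)), float(dists.mean())


def _subsample_columns(gm: GenotypeMatrix, config: LdConfig) -> np.ndarray:
    spans = gm.scaffold_spans()
    keep_scafs = {s for s, (lo, hi) in spans.items() if hi >= config.min_scaffold_length}
    eligible = np.flatnonzero(np.isin(gm.scaffolds, list(keep_scafs)))
    if eligible.size == 0:
        raise ValueError("no scaffold reaches the minimum length for LD analysis")
    if config.n_snps < eligible.size:
        rng = np.random.default_rng(config.seed)
        eligible = np.sort(rng.choice(eligible, size=config.n_snps, replace=False))
    return eligible


def ld_decay(
    gm: GenotypeMatrix,
    metadata: SampleMetadata | None = None,
    group: str | None = None,
    max_distance: int = 100_000,
    bin_size: int = 10_000,
    config: LdConfig | None = None,
    block: int = 1024,
) -> list[LDBin]:
    """Distance-binned r^2 decay curve.

    SNPs are subsampled per the config, then r^2 is computed for every
    same-scaffold pair closer than ``max_distance`` and pairs are assigned to
    half-open bins ``[k*bin_size, (k+1)*bin_size)``.  Empty bins are retained
    with ``n_pairs = 0``, NaN mean and the bin midpoint as fallback median.
    """
    config = config or LdConfig()
    if max_distance % bin_size != 0:
        raise ValueError("bin size must divide max distance")
    n_bins = max_distance // bin_size

    sample_idx = None
    if group is not None:
        if metadata is None:
            raise ValueError("metadata required to select a group")
        sample_idx = metadata.group_indices(gm, group)
    d = gm.dosages if sample_idx is None else gm.dosages[sample_idx, :]

    cols = _subsample_columns(gm, config)
    r2_chunks = [[] for _ in range(n_bins)]
    dist_chunks = [[] for _ in range(n_bins)]

    for scaf in pd.unique(gm.scaffolds[cols]):
        sc_cols = cols[gm.scaffolds[cols] == scaf]
        pos = gm.positions[sc_cols]
        z, w = _prepare(d[:, sc_cols])
        V = sc_cols.size
        for b1 in range(0, V, block):
            e1 = min(b1 + block, V)
            for b2 in range(b1, V, block):
                e2 = min(b2 + block, V)
                if pos[b2] - pos[e1 - 1] >= max_distance:
                    break
                r2 = _cross_stats(z[:, b1:e1], w[:, b1:e1], z[:, b2:e2], w[:, b2:e2])
                dist = pos[b2:e2][None, :] - pos[b1:e1][:, None]
                mask = (dist > 0) & (dist < max_distance) & ~np.isnan(r2)
                if not mask.any():
                    continue
                dv = dist[mask]
                rv = r2[mask]
                bins = dv // bin_size
                for b in np.unique(bins):
                    sel = bins == b
                    r2_chunks[int(b)].append(rv[sel])
                    dist_chunks[int(b)].append(dv[sel])

    out = []
    for k in range(n_bins):
        lo, hi = k * bin_size, (k + 1) * bin_size
        if r2_chunks[k]:
            rv = np.concatenate(r2_chunks[k])
            dv = np.concatenate(dist_chunks[k])
            out.append(
                LDBin(lo, hi, rv.size, float(rv.mean()),
                      float(rv.std(ddof=1)) if rv.size > 1 else 0.0,
                      float(np.median(dv)))
            )
        else:
            out.append(LDBin(lo, hi, 0, float("nan"), float("nan"), (lo + hi) / 2.0))
    return out


# ---------------------------------------------------------------------- #
# Ne estimation (Sved inversion)
# ---------------------------------------------------------------------- #

def sved_expected_r2(ne: float, c: float) -> float:
    """Sved's drift expectation E[r^2] = 1 / (1 + 4*Ne*c)."""
    return 1.0 / (1.0 + 4.0 * ne * c)


def ne_from_bin(mean_r2: float, c: float) -> float:
    """Invert Sved's expectation: Ne = (1/r^2 - 1) / (4c).

    ``mean_r2`` is the sample-size-corrected bin mean; ``c`` the bin's
    recombination distance in Morgans.
    """
    if c <= 0:
        raise ValueError("recombination distance must be positive")
    if mean_r2 <= 0:
        raise ValueError("mean r^2 must be positive; Ne undefined")
    if mean_r2 >= 1:
        raise ValueError("mean r^2 >= 1 gives the Ne = 0 bound")
    return (1.0 / mean_r2 - 1.0) / (4.0 * c)


def ne_trajectory(bins: list[LDBin], config: LdConfig | None = None) -> list[NePoint]:
    """Sved Ne at each requested number of generations ago.

    A generation count t targets the recombination distance c = 1/(2t)
    Morgans; the bin whose realized median pair distance is nearest the
    corresponding physical distance supplies the mean r^2, and its own median
    distance supplies the c used in the inversion.  Targets with no bin
    within a factor of two of the requested distance are omitted with a
    warning.
    """
    config = config or LdConfig()
    if not bins:
        raise ValueError("no LD bins supplied")
    usable = [b for b in bins if b.n_pairs > 0 and 0 < b.mean_r2 < 1]
    if not usable:
        raise ValueError("no usable LD bin (all empty or degenerate mean r^2)")
    med = np.array([b.median_distance for b in usable])
    out = []
    for t in config.generations:
        c_target = 1.0 / (2.0 * t)
        d_target = c_target / config.morgans_per_bp
        k = int(np.argmin(np.abs(med - d_target)))
        if not (d_target / 2.0 <= med[k] <= d_target * 2.0):
            logger.warning(
                "no bin within a factor of 2 of %d bp (t=%s); point omitted",
                int(d_target), t,
            )
            continue
        b = usable[k]
        c_real = b.median_distance * config.morgans_per_bp
        out.append(
            NePoint(
                generations_ago=float(t),
                c_morgans=float(c_real),
                mean_r2=b.mean_r2,
                ne=ne_from_bin(b.mean_r2, c_real),
            )
        )
    return out


def marker_density(genome_size: float, decay_distance: float) -> int:
    """SNP count needed for one marker per LD-decay distance: floor(G / d)."""
    if genome_size <= 0 or decay_distance <= 0:
        raise ValueError("genome size and decay distance must be positive")
    return int(genome_size // decay_distance)


def decay_distance(bins: list[LDBin], r2_threshold: float) -> float | None:
    """Distance (bp) at which the binned mean r^2 drops below a threshold.

    Returns the upper edge of the last bin (scanning outward) whose mean r^2
    is still >= the threshold, or None if already below it in the first bin
    (or above it everywhere).
    """
    last = None
    for b in sorted(bins, key=lambda b: b.low):
        if np.isnan(b.mean_r2):
            continue
        if b.mean_r2 >= r2_threshold:
            last = b.high
        else:
            return float(last) if last is not None else None
    return None  # never dropped below within the scanned range
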