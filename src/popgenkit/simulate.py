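"""Synthetic genotype data with known ground truth.

Four generators cover the quantities the analysis modules estimate, so each
estimator can be validated by parameter recovery:

* :func:`simulate_structured` — K ancestral populations at target Fst values
  under the Balding–Nichols model, with per-individual admixture proportions.
  Population allele frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around an
  ancestral frequency p, so Weir–Cockerham theta should recover F.
* :func:`simulate_wright_fisher` — a forward diploid Wright–Fisher population
  with per-generation recombination, the ground truth for LD decay and for
  Ne estimation from Sved's E[r^2] = 1/(1 + 4*Ne*c).
* :func:`plant_roh` — forces chosen tracts of a genotype matrix autozygous,
  the fixture for run-of-homozygosity detection and F_ROH.
* :func:`simulate_pedigree` / :func:`gene_drop` — small designed pedigrees
  with textbook inbreeding coefficients, and Mendelian gene dropping through
  them, linking pedigree F to genomic homozygosity.

All generators take an explicit integer seed and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SampleMetadata

__all__ = [
    "StructureSimConfig",
    "WrightFisherConfig",
    "RohTract",
    "simulate_structured",
    "simulate_wright_fisher",
    "plant_roh",
    "simulate_pedigree",
    "gene_drop",
]


# ---------------------------------------------------------------------- #
# Structured populations (Balding–Nichols + admixture)
# ---------------------------------------------------------------------- #

@dataclass
class StructureSimConfig:
    """Parameters of the Balding–Nichols structured-population generator.

    ``fst`` holds one target Fst per ancestral population.  The ancestral
    minor-allele-frequency sampler is uniform on ``maf_range``; the default
    (0.1, 0.5) keeps the simulated MAF spectrum inside the post-filter
    regime (MAF > 0.05) so little is lost to filtering.  Loci are unlinked:
    genotypes are independent across loci even though nominal scaffold
    positions are assigned for container validity.
    """

    k: int
    fst: list[float] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_loci: int = 10_000
    seed: int = 0
    n_scaffolds: int = 10
    spacing_bp: int = 50_000

    def __post_init__(self) -> None:
        if not self.fst:
            self.fst = [0.1] * self.k
        if len(self.fst) != self.k:
            raise ValueError("need one target Fst per population")
        if any(not 0.0 <= f < 1.0 for f in self.fst):
            raise ValueError("target Fst must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")


def _nominal_positions(n_loci: int, n_scaffolds: int, spacing: int):
    """Spread loci over scaffolds with regular spacing (container plumbing)."""
    per = int(np.ceil(n_loci / n_scaffolds))
    scafs, pos = [], []
    for j in range(n_loci):
        s, k = divmod(j, per)
        scafs.append(f"scaffold_{s + 1}")
        pos.append((k + 1) * spacing)
    return np.array(scafs, dtype=object), np.array(pos, dtype=np.int64)


def simulate_structured(
    config: StructureSimConfig,
    samples_per_group: dict[str, int],
    group_admixture: dict[str, np.ndarray] | None = None,
    group_supergroup: dict[str, str] | None = None,
    max_resample_rounds: int = 20,
) -> tuple[GenotypeMatrix, SampleMetadata, dict]:
    """Draw unlinked genotypes from K Balding–Nichols populations.

    Each group is given an admixture vector q on the K-simplex (default: the
    i-th group is pure population ``i mod K``); every individual's genotype at
    a locus is Binomial(2, sum_k q_k * p_kj).  Loci at which every population
    ends up fixed for the same allele are redrawn (up to
    ``max_resample_rounds``; an error is raised if fixed loci persist, which
    only happens for degenerate samplers such as ``maf_range=(0, 0)``).

    Returns the genotype matrix, sample metadata and a truth record holding
    the ancestral frequencies, population frequencies and admixture vectors.
    """
    rng = np.random.default_rng(config.seed)
    groups = list(samples_per_group)
    if group_admixture is None:
        group_admixture = {}
        for i, g in enumerate(groups):
            q = np.zeros(config.k)
            q[i % config.k] = 1.0
            group_admixture[g] = q
    for g, q in group_admixture.items():
        q = np.asarray(q, dtype=float)
        if q.shape != (config.k,) or not np.isclose(q.sum(), 1.0):
            raise ValueError(f"admixture vector for {g} must be a {config.k}-simplex point")
        group_admixture[g] = q
    group_supergroup = group_supergroup or {g: "farm_1" for g in groups}

    L = config.n_loci
    lo, hi = config.maf_range

    def draw(n: int):
        p = rng.uniform(lo, hi, size=n)
        flip = rng.random(n) < 0.5          # ancestral ALT may be major or minor
        p = np.where(flip, 1.0 - p, p)
        pk = np.empty((config.k, n))
        for k in range(config.k):
            f = config.fst[k]
            if f < 1e-9:
                pk[k] = p
            else:
                a = p * (1.0 - f) / f
                b = (1.0 - p) * (1.0 - f) / f
                pk[k] = rng.beta(a, b)
        return p, pk

    p_anc, pop_freq = draw(L)
    for _ in range(max_resample_rounds):
        degenerate = np.all(pop_freq <= 0.0, axis=0) | np.all(pop_freq >= 1.0, axis=0)
        if not degenerate.any():
            break
        p_new, pk_new = draw(int(degenerate.sum()))
        p_anc[degenerate] = p_new
        pop_freq[:, degenerate] = pk_new
    else:
        raise RuntimeError(
            "sampler keeps producing loci fixed in every population; "
            "widen maf_range or lower target Fst"
        )

    samples, grp_rows, q_rows = [], [], []
    for g in groups:
        for i in range(samples_per_group[g]):
            samples.append(f"{g}_{i + 1}")
            grp_rows.append(g)
            q_rows.append(group_admixture[g])
    Q = np.array(q_rows)                      # (n_samples, K)
    mean_p = Q @ pop_freq                     # per-individual expected frequency
    dosages = rng.binomial(2, np.clip(mean_p, 0.0, 1.0)).astype(np.int8)

    scafs, pos = _nominal_positions(L, config.n_scaffolds, config.spacing_bp)
    gm = GenotypeMatrix(
        dosages=dosages,
        scaffolds=scafs,
        positions=pos,
        ref=np.array(["A"] * L, dtype=object),
        alt=np.array(["G"] * L, dtype=object),
        samples=samples,
    )
    meta = SampleMetadata(
        {s: (g, group_supergroup[g]) for s, g in zip(samples, grp_rows)}
    )
    truth = {
        "config": config,
        "ancestral_freq": p_anc,
        "pop_freq": pop_freq,
        "admixture": {s: Q[i] for i, s in enumerate(samples)},
    }
    return gm, meta, truth


# ---------------------------------------------------------------------- #
# Forward Wright–Fisher with recombination
# ---------------------------------------------------------------------- #

@dataclass
class WrightFisherConfig:
    """Forward diploid Wright–Fisher simulation on one chromosome.

    ``recomb_rate`` is in Morgans per base pair (1e-8 corresponds to the
    standard 1 cM/Mb assumption).  Initial haplotypes carry independent loci
    whose allele-1 frequencies are uniform on ``init_freq_range``; the default
    (0.1, 0.9) keeps an appreciable fraction of loci segregating after
    hundreds of generations of drift.
    """

    ne: int
    n_generations: int
    chrom_length: int = 10_000_000
    recomb_rate: float = 1e-8
    sample_size: int = 50
    n_start_loci: int = 2_000
    init_freq_range: tuple[float, float] = (0.1, 0.9)
    scaffold: str = "sim_1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.recomb_rate < 0:
            raise ValueError("recombination rate must be >= 0")
        if self.sample_size > self.ne:
            raise ValueError("cannot sample more diploids than exist")


def simulate_wright_fisher(config: WrightFisherConfig) -> tuple[GenotypeMatrix, dict]:
    """Run the forward simulation and sample diploids from the last generation.

    Each offspring haplotype is a recombinant of the two haplotypes of a
    random parent, with a Poisson(length * rate) crossover count and uniform
    crossover positions; gametes unite at random (selfing permitted, as in
    the neutral Wright–Fisher model).  Raises if every locus fixes before
    sampling.
    """
    rng = np.random.default_rng(config.seed)
    N, L = config.ne, config.n_start_loci
    positions = np.sort(rng.choice(config.chrom_length, size=L, replace=False)) + 1
    lo, hi = config.init_freq_range
    p0 = rng.uniform(lo, hi, size=L)
    H = rng.random((2 * N, L)) < p0          # haplotypes as boolean rows
    realized_p0 = H.mean(axis=0)
    total_morgans = config.chrom_length * config.recomb_rate

    for _ in range(config.n_generations):
        parents = rng.integers(0, N, size=(N, 2))
        n_cross = rng.poisson(total_morgans, size=2 * N)
        start_hap = rng.integers(0, 2, size=2 * N)
        new = np.empty_like(H)
        for g in range(2 * N):
            par = parents[g // 2, g % 2]
            h0 = H[2 * par + start_hap[g]]
            if n_cross[g] == 0:
                new[g] = h0
            else:
                h1 = H[2 * par + 1 - start_hap[g]]
                cuts = np.sort(rng.uniform(0, config.chrom_length, size=n_cross[g]))
                seg = np.searchsorted(cuts, positions) % 2
                new[g] = np.where(seg == 0, h0, h1)
        H = new

    freq = H.mean(axis=0)
    if not np.any((freq > 0) & (freq < 1)):
        raise RuntimeError(
            "all loci fixed before sampling; increase n_start_loci or "
            "reduce n_generations"
        )

    chosen = rng.choice(N, size=config.sample_size, replace=False)
    dosages = (H[2 * chosen].astype(np.int8) + H[2 * chosen + 1].astype(np.int8))
    gm = GenotypeMatrix(
        dosages=dosages,
        scaffolds=np.array([config.scaffold] * L, dtype=object),
        positions=positions,
        ref=np.array(["A"] * L, dtype=object),
        alt=np.array(["G"] * L, dtype=object),
        samples=[f"wf_{i + 1}" for i in range(config.sample_size)],
    )
    truth = {
        "config": config,
        "init_freq": p0,                 # sampler targets
        "init_realized_freq": realized_p0,  # frequencies actually seeded
        "final_pop_freq": freq,
        "ne": N,
    }
    return gm, truth


# ---------------------------------------------------------------------- #
# Planted autozygous tracts
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class RohTract:
    """One tract to force autozygous: sample, scaffold, start/end (bp, inclusive)."""

    sample: str
    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def plant_roh(
    gm: GenotypeMatrix,
    tracts: list[RohTract],
    error_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Force the given tracts homozygous, returning a new matrix.

    Within a tract, genotypes that are heterozygous or missing are set to the
    homozygote of the per-variant major allele (already-homozygous calls are
    left untouched), which keeps site allele frequencies close to the
    original.  With ``error_rate`` > 0, each in-tract SNP is independently
    flipped back to heterozygous with that probability, emulating genotyping
    error inside true autozygous runs.
    """
    by_sample: dict[str, list[RohTract]] = {}
    for t in tracts:
        for u in by_sample.get(t.sample, []):
            if u.scaffold == t.scaffold and not (t.end < u.start or t.start > u.end):
                raise ValueError(f"overlapping tracts for sample {t.sample}")
        by_sample.setdefault(t.sample, []).append(t)

    spans = gm.scaffold_spans()
    for t in tracts:
        if t.scaffold not in spans:
            raise ValueError(f"unknown scaffold {t.scaffold}")
        lo, hi = spans[t.scaffold]
        if t.start < 1 or t.end > hi or t.start > t.end:
            raise ValueError(f"tract {t} outside scaffold bounds (1..{hi})")

    rng = np.random.default_rng(seed)
    out = gm.dosages.copy()
    major_hom = np.where(gm.alt_freq() >= 0.5, 2, 0).astype(np.int8)
    for t in tracts:
        si = gm.sample_index(t.sample)
        mask = (gm.scaffolds == t.scaffold) & (gm.positions >= t.start) & (gm.positions <= t.end)
        cols = np.flatnonzero(mask)
        row = out[si, cols]
        row = np.where((row == 1) | (row == MISSING), major_hom[cols], row)
        if error_rate > 0:
            err = rng.random(cols.size) < error_rate
            row = np.where(err, 1, row)
        out[si, cols] = row
    new = GenotypeMatrix(
        dosages=out,
        scaffolds=gm.scaffolds,
        positions=gm.positions,
        ref=gm.ref,
        alt=gm.alt,
        samples=list(gm.samples),
        qual=gm.qual,
    )
    return new


# ---------------------------------------------------------------------- #
# Pedigrees
# ---------------------------------------------------------------------- #

def simulate_pedigree(
    depth: int,
    founders: int,
    scheme: str,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Build a small pedigree with analytically known inbreeding coefficients.

    Schemes
    -------
    ``full-sib``
        Founder pairs produce two full sibs, which are mated: offspring
        F = 1/4.
    ``half-sib``
        One sire with two dams produces two paternal half sibs, which are
        mated: offspring F = 1/8.
    ``parent-offspring``
        A founder pair produce a daughter, who is backcrossed to her sire:
        offspring F = 1/4.
    ``random``
        ``depth`` generations of random mating among distinct parents
        (founders F = 0; deeper coefficients are whatever the realized
        matings imply).

    Returns the pedigree table (individual, sire, dam) and a dict of the
    designed, analytically known coefficients.
    """
    if founders < 2:
        raise ValueError("need at least 2 founders")
    rows: list[tuple[str, str | None, str | None]] = []
    known: dict[str, float] = {}
    counter = iter(range(1, 10_000))

    def new_id(prefix: str) -> str:
        return f"{prefix}{next(counter)}"

    if scheme == "full-sib":
        for _ in range(max(1, founders // 2)):
            f1, f2 = new_id("F"), new_id("F")
            rows += [(f1, None, None), (f2, None, None)]
            known[f1] = known[f2] = 0.0
            s1, s2 = new_id("S"), new_id("S")
            rows += [(s1, f1, f2), (s2, f1, f2)]
            known[s1] = known[s2] = 0.0
            off = new_id("X")
            rows.append((off, s1, s2))
            known[off] = 0.25
    elif scheme == "half-sib":
        for _ in range(max(1, founders // 3)):
            sire, d1, d2 = new_id("F"), new_id("F"), new_id("F")
            rows += [(sire, None, None), (d1, None, None), (d2, None, None)]
            known.update({sire: 0.0, d1: 0.0, d2: 0.0})
            h1, h2 = new_id("S"), new_id("S")
            rows += [(h1, sire, d1), (h2, sire, d2)]
            known[h1] = known[h2] = 0.0
            off = new_id("X")
            rows.append((off, h1, h2))
            known[off] = 0.125
    elif scheme == "parent-offspring":
        f1, f2 = new_id("F"), new_id("F")
        rows += [(f1, None, None), (f2, None, None)]
        known[f1] = known[f2] = 0.0
        child = new_id("S")
        rows.append((child, f1, f2))
        known[child] = 0.0
        off = new_id("X")
        rows.append((off, f1, child))
        known[off] = 0.25
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        gen = [new_id("F") for _ in range(founders)]
        for g in gen:
            rows.append((g, None, None))
            known[g] = 0.0
        for _ in range(depth):
            nxt = []
            for _ in range(max(2, founders)):
                sire, dam = rng.choice(gen, size=2, replace=False)
                child = new_id("R")
                rows.append((child, sire, dam))
                nxt.append(child)
            gen = nxt
    else:
        raise ValueError(f"unknown mating scheme: {scheme}")

    ped = pd.DataFrame(rows, columns=["individual", "sire", "dam"])
    return ped, known


def gene_drop(
    pedigree: pd.DataFrame,
    n_loci: int = 5_000,
    founder_freq_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    spacing_bp: int = 10_000,
) -> GenotypeMatrix:
    """Drop unlinked Mendelian genotypes through a pedigree.

    Founder haplotype alleles are Bernoulli draws at per-locus frequencies;
    each offspring inherits one random allele from each parent per locus
    (loci unlinked).  Positions are nominal — the output is meant for
    frequency/inbreeding statistics, not LD.
    """
    rng = np.random.default_rng(seed)
    lo, hi = founder_freq_range
    p = rng.uniform(lo, hi, size=n_loci)
    haplos: dict[str, np.ndarray] = {}       # individual -> (2, L) bool

    parent = {r.individual: (r.sire, r.dam) for r in pedigree.itertuples()}

    def resolve(ind: str, stack: tuple = ()) -> np.ndarray:
        if ind in haplos:
            return haplos[ind]
        if ind in stack:
            raise ValueError("pedigree contains a cycle")
        sire, dam = parent.get(ind, (None, None))
        h = np.empty((2, n_loci), dtype=bool)
        for slot, par in enumerate((sire, dam)):
            if par is None:
                h[slot] = rng.random(n_loci) < p
            else:
                ph = resolve(par, stack + (ind,))
                pick = rng.integers(0, 2, size=n_loci)
                h[slot] = ph[pick, np.arange(n_loci)]
        haplos[ind] = h
        return h

    inds = list(pedigree["individual"])
    for ind in inds:
        resolve(ind)
    dosages = np.array([haplos[i].sum(axis=0) for i in inds], dtype=np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        scaffolds=np.array(["ped_1"] * n_loci, dtype=object),
        positions=(np.arange(n_loci, dtype=np.int64) + 1) * spacing_bp,
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["G"] * n_loci, dtype=object),
        samples=inds,
    )
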