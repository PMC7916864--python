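"""Population differentiation: Nei's distance, Weir–Cockerham Fst, AMOVA.

Nei's (1972) standard genetic distance is D = -ln I with the normalized gene
identity I = J_AB / sqrt(J_A * J_B), where the J terms are averages over
loci of sums of squared (or cross-multiplied) allele frequencies; loci
monomorphic in both populations legitimately contribute identity 1.

Weir & Cockerham's theta is computed from the standard two-level variance
components a (among populations), b (among individuals within populations)
and c (within individuals), using observed heterozygosities, and combined
across loci as a ratio of sums — the estimator's recommended multi-locus
form.  Theta can be slightly negative when populations are effectively
undifferentiated.

AMOVA follows the Excoffier, Smouse & Quattro decomposition of a matrix of
squared inter-individual distances into among-supergroup (e.g. farm),
among-group-within-supergroup (e.g. color-type) and within-group sums of
squares, converts mean squares to variance components with the unequal
sample-size coefficients, and attaches permutation p-values (groups permuted
across supergroups for the top level; samples permuted across groups within
supergroups for the middle level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SampleMetadata

__all__ = [
    "nei_distance",
    "wc_fst",
    "pairwise_distances",
    "dosage_sq_distance",
    "AmovaResult",
    "amova",
]


def _group_freq_stats(gm: GenotypeMatrix, idx: np.ndarray):
    """(n called, alt freq, observed het fraction) per variant for one group."""
    d = gm.dosages[idx, :]
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, (d == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def nei_distance(
    gm: GenotypeMatrix, metadata: SampleMetadata, group_a: str, group_b: str
) -> float:
    """Nei (1972) standard genetic distance between two groups.

    Returns ``inf`` when the normalized identity is zero (completely disjoint
    allele pools at every locus).
    """
    ia = metadata.group_indices(gm, group_a)
    ib = metadata.group_indices(gm, group_b)
    _, pa, _ = _group_freq_stats(gm, ia)
    _, pb, _ = _group_freq_stats(gm, ib)
    use = ~np.isnan(pa) & ~np.isnan(pb)
    if not use.any():
        raise ValueError("no locus typed in both groups")
    pa, pb = pa[use], pb[use]
    j_a = np.mean(pa**2 + (1 - pa) ** 2)
    j_b = np.mean(pb**2 + (1 - pb) ** 2)
    j_ab = np.mean(pa * pb + (1 - pa) * (1 - pb))
    identity = j_ab / np.sqrt(j_a * j_b)
    if identity <= 0:
        return float("inf")
    return float(-np.log(identity))


def wc_fst(
    gm: GenotypeMatrix,
    metadata: SampleMetadata,
    groups: list[str] | tuple[str, str] | None = None,
) -> float:
    """Multi-locus Weir–Cockerham theta for two (or more) groups.

    Computed as sum(a) / sum(a+b+c) over loci typed in every group, with
    loci monomorphic across the pooled groups excluded (they contribute zero
    to both sums).  Raises when the denominator is empty.
    """
    groups = list(groups) if groups is not None else metadata.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    idxs = [metadata.group_indices(gm, g) for g in groups]
    for g, idx in zip(groups, idxs):
        if idx.size < 2:
            raise ValueError(f"group {g} needs >= 2 samples")
    r = len(groups)
    stats = [_group_freq_stats(gm, idx) for idx in idxs]
    n_i = np.vstack([s[0] for s in stats])          # (r, L)
    p_i = np.vstack([s[1] for s in stats])
    h_i = np.vstack([s[2] for s in stats])

    ok = np.all(n_i >= 1, axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]

    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    poly = (p_bar > 0) & (p_bar < 1) & (n_bar > 1) & (n_c > 0)
    n_bar, n_c, p_bar, s2, h_bar = (
        arr[poly] for arr in (n_bar, n_c, p_bar, s2, h_bar)
    )
    if n_bar.size == 0:
        raise ValueError("all loci monomorphic across the chosen groups; theta undefined")

    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - s2 * (r - 1) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("zero total variance; theta undefined")
    return float(a.sum() / denom)


def pairwise_distances(gm: GenotypeMatrix, metadata: SampleMetadata) -> pd.DataFrame:
    """Square table with Nei's D above and Weir–Cockerham Fst below the diagonal."""
    groups = metadata.groups
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            out.loc[ga, gb] = nei_distance(gm, metadata, ga, gb)
            out.loc[gb, ga] = wc_fst(gm, metadata, (ga, gb))
    return out


def dosage_sq_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Mean squared dosage difference over shared non-missing loci, per sample pair.

    This is the squared-distance matrix fed to :func:`amova`.
    """
    d = gm.dosages.astype(float)
    w = (gm.dosages != MISSING).astype(float)
    z = np.where(w > 0, d, 0.0)
    n_shared = w @ w.T
    sq = (z**2 * 1.0) @ w.T + w @ (z**2).T - 2.0 * (z @ z.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_shared > 0, sq / n_shared, np.nan)
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------- #
# AMOVA
# ---------------------------------------------------------------------- #

@dataclass
class AmovaResult:
    """Hierarchical variance decomposition with permutation p-values.

    ``table`` has one row per stratum (among_supergroups, among_groups,
    within_groups) with df, SS, MS, the raw variance component, the
    zero-truncated component used for percentages, the percent of total and
    the permutation p-value (None where not applicable).
    """

    table: pd.DataFrame
    n_permutations: int
    notes: list[str] = field(default_factory=list)

    def percent(self, stratum: str) -> float:
        return float(self.table.set_index("stratum").loc[stratum, "percent"])

    def p_value(self, stratum: str) -> float | None:
        v = self.table.set_index("stratum").loc[stratum, "p_value"]
        return None if pd.isna(v) else float(v)


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _components(d2, groups, supergroups):
    """Raw AMOVA variance components (sigma_a, sigma_b, sigma_c) and SS/df."""
    N = len(groups)
    glabels = pd.unique(groups)
    slabels = pd.unique(supergroups)
    G, S = len(glabels), len(slabels)

    ss_total = d2.sum() / (2.0 * N)
    ss_wg = _ss_within(d2, groups)
    ss_ws = _ss_within(d2, supergroups)
    ssd_ag = ss_ws - ss_wg           # among groups within supergroups
    ssd_as = ss_total - ss_ws        # among supergroups

    df_wg = N - G
    df_ag = G - S
    df_as = S - 1

    n_g = np.array([(groups == g).sum() for g in glabels], dtype=float)
    sg_of_group = {}
    for g in glabels:
        sgs = pd.unique(supergroups[groups == g])
        if len(sgs) != 1:
            raise ValueError(f"group {g} spans multiple supergroups")
        sg_of_group[g] = sgs[0]
    n_s = np.array([(supergroups == s).sum() for s in slabels], dtype=float)

    sum_gsq_over_s = 0.0
    for s, ns in zip(slabels, n_s):
        gsq = sum(n_g[i] ** 2 for i, g in enumerate(glabels) if sg_of_group[g] == s)
        sum_gsq_over_s += gsq / ns

    sigma_c = ss_wg / df_wg if df_wg > 0 else np.nan
    if df_ag > 0:
        n1 = (N - sum_gsq_over_s) / df_ag
        sigma_b = (ssd_ag / df_ag - sigma_c) / n1
    else:
        sigma_b = np.nan
    if df_as > 0 and df_ag >= 0 and S > 1:
        n2 = (sum_gsq_over_s - (n_g**2).sum() / N) / df_as
        n3 = (N - (n_s**2).sum() / N) / df_as
        ms_as = ssd_as / df_as
        sb = 0.0 if np.isnan(sigma_b) else sigma_b
        sigma_a = (ms_as - sigma_c - n2 * sb) / n3
    else:
        sigma_a = np.nan
    return {
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
        "ss": (ssd_as, ssd_ag, ss_wg, ss_total),
        "df": (df_as, df_ag, df_wg),
    }


def amova(
    d2: np.ndarray,
    gm_samples: list[str],
    metadata: SampleMetadata,
    n_permutations: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA on a squared-distance matrix over samples.

    When the design has a single supergroup, the among-supergroup stratum is
    reported as undefined and the "among groups" stratum is the top level.
    Negative variance components are reported raw and truncated to zero for
    the percentage breakdown.
    """
    d2 = np.asarray(d2, dtype=float)
    N = len(gm_samples)
    if d2.shape != (N, N):
        raise ValueError("distance matrix does not match sample list")
    if not np.allclose(d2, d2.T, equal_nan=True) or not np.allclose(np.diag(d2), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    groups = np.array([metadata.group_of(s) for s in gm_samples], dtype=object)
    supergroups = np.array([metadata.supergroup_of(s) for s in gm_samples], dtype=object)

    obs = _components(d2, groups, supergroups)
    rng = np.random.default_rng(seed)
    notes: list[str] = []

    S = len(pd.unique(supergroups))
    glabels = pd.unique(groups)

    # middle level: permute samples across groups within supergroups
    p_b = np.nan
    if not np.isnan(obs["sigma_b"]):
        count = 0
        for _ in range(n_permutations):
            perm_groups = groups.copy()
            for s in pd.unique(supergroups):
                idx = np.flatnonzero(supergroups == s)
                perm_groups[idx] = perm_groups[rng.permutation(idx)]
            c = _components(d2, perm_groups, supergroups)
            if c["sigma_b"] >= obs["sigma_b"]:
                count += 1
        p_b = (count + 1) / (n_permutations + 1)

    # top level: permute whole groups across supergroups
    p_a = np.nan
    if S > 1 and not np.isnan(obs["sigma_a"]):
        sg_of_group = {g: supergroups[groups == g][0] for g in glabels}
        sg_slots = [sg_of_group[g] for g in glabels]
        count = 0
        for _ in range(n_permutations):
            perm_slots = rng.permutation(sg_slots)
            mapping = dict(zip(glabels, perm_slots))
            perm_sg = np.array([mapping[g] for g in groups], dtype=object)
            c = _components(d2, groups, perm_sg)
            if c["sigma_a"] >= obs["sigma_a"]:
                count += 1
        p_a = (count + 1) / (n_permutations + 1)
    elif S == 1:
        notes.append("single supergroup: among-supergroup component undefined")

    ssd_as, ssd_ag, ss_wg, ss_total = obs["ss"]
    df_as, df_ag, df_wg = obs["df"]
    sigmas = np.array([obs["sigma_a"], obs["sigma_b"], obs["sigma_c"]])
    trunc = np.where(np.isnan(sigmas), np.nan, np.maximum(sigmas, 0.0))
    total_trunc = np.nansum(trunc)
    percent = 100.0 * trunc / total_trunc if total_trunc > 0 else trunc * np.nan

    table = pd.DataFrame(
        {
            "stratum": ["among_supergroups", "among_groups", "within_groups"],
            "df": [df_as if S > 1 else np.nan, df_ag, df_wg],
            "ss": [ssd_as if S > 1 else np.nan, ssd_ag, ss_wg],
            "ms": [
                ssd_as / df_as if S > 1 and df_as > 0 else np.nan,
                ssd_ag / df_ag if df_ag > 0 else np.nan,
                ss_wg / df_wg if df_wg > 0 else np.nan,
            ],
            "sigma": sigmas,
            "sigma_truncated": trunc,
            "percent": percent,
            "p_value": [p_a, p_b, np.nan],
        }
    )
    return AmovaResult(table=table, n_permutations=n_permutations, notes=notes)
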