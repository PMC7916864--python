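"""End-to-end orchestration: VCF + metadata -> report tables.

``run_all`` executes every analysis stage (diversity, ROH/F_ROH, pairwise
Nei/Fst, AMOVA, adjacent-SNP r^2, LD-decay curves at three distance sets, Ne
trajectory, marker-density recommendations) and writes one TSV per table into
the output directory, each with a header comment carrying the package
version and a parameter hash.  ``simulate_and_run`` generates a synthetic
dataset from a named preset, runs the full pipeline on it and appends a
truth-versus-estimate comparison table.  Outputs are deterministic for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    FilterSpec,
    GenotypeMatrix,
    SampleMetadata,
    apply_filters,
    read_pedigree,
    read_vcf,
)
from .diversity import diversity_table, f_ped_all
from .differentiation import amova, dosage_sq_distance, pairwise_distances
from .ld import LdConfig, adjacent_r2, decay_distance, ld_decay, marker_density, ne_trajectory
from .roh import RohParams, froh_table
from . import simulate as sim

logger = logging.getLogger(__name__)

#: The three LD-decay distance sets: (label, max distance, bin size).
DECAY_SETS = (
    ("100kb", 100_000, 10_000),
    ("1000kb", 1_000_000, 100_000),
    ("10mb", 10_000_000, 1_000_000),
)


@dataclass
class RunConfig:
    vcf: str | None = None
    metadata: str | None = None
    pedigree: str | None = None
    outdir: str = "popgenkit_out"
    seed: int = 0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    roh_params: RohParams = field(default_factory=RohParams)
    roh_thresholds: tuple[int, ...] = (500_000, 1_000_000, 2_000_000)
    ld_config: LdConfig = field(default_factory=LdConfig)
    amova_permutations: int = 999
    genome_size: float | None = None       # default: total span of scaffolds
    r2_thresholds: tuple[float, ...] = (0.2, 0.3)
    do_diversity: bool = True
    do_roh: bool = True
    do_differentiation: bool = True
    do_amova: bool = True
    do_ld: bool = True
    make_plots: bool = False


def _param_hash(config: RunConfig) -> str:
    d = _config_dict(config)
    d.pop("outdir", None)  # analysis parameters only, not where they land
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _config_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def _write(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# popgenkit v{__version__} params={_param_hash(config)} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_all(
    config: RunConfig,
    gm: GenotypeMatrix | None = None,
    metadata: SampleMetadata | None = None,
    pedigree: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the configured stages and write report tables; returns them by name."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if gm is None:
        if config.vcf is None or config.metadata is None:
            raise ValueError("either pass a genotype matrix or set vcf/metadata paths")
        metadata = SampleMetadata.from_tsv(config.metadata)
        gm = read_vcf(config.vcf, metadata)
        gm = apply_filters(gm, spec=config.filter_spec)
    if metadata is None:
        raise ValueError("metadata required")
    if pedigree is None and config.pedigree:
        pedigree = read_pedigree(config.pedigree)

    tables: dict[str, pd.DataFrame] = {}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    if config.do_diversity:
        stage("diversity")
        try:
            fped = f_ped_all(pedigree) if pedigree is not None else None
            tables["diversity"] = diversity_table(gm, metadata, fped)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"diversity stage failed: {exc}") from exc

    if config.do_roh:
        stage("roh")
        try:
            per_sample = froh_table(
                gm, metadata, list(config.roh_thresholds), config.roh_params
            )
            tables["froh_samples"] = per_sample
            tables["froh_groups"] = (
                per_sample.groupby(["group", "threshold_bp"])
                .agg(
                    n_animals=("sample", "nunique"),
                    mean_n_segments=("n_segments", "mean"),
                    sd_n_segments=("n_segments", "std"),
                    mean_froh=("froh", "mean"),
                    sd_froh=("froh", "std"),
                )
                .reset_index()
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"roh stage failed: {exc}") from exc

    if config.do_differentiation and len(metadata.groups) > 1:
        stage("differentiation")
        try:
            dist = pairwise_distances(gm, metadata)
            tables["distances"] = dist.reset_index(names="group")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"differentiation stage failed: {exc}") from exc

    if config.do_amova and len(metadata.groups) > 1:
        stage("amova")
        try:
            d2 = dosage_sq_distance(gm)
            res = amova(d2, gm.samples, metadata,
                        n_permutations=config.amova_permutations, seed=config.seed)
            tables["amova"] = res.table
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"amova stage failed: {exc}") from exc

    if config.do_ld:
        stage("ld")
        try:
            tables.update(_ld_stage(gm, metadata, config))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"ld stage failed: {exc}") from exc

    for name, df in tables.items():
        _write(df, outdir / f"{name}.tsv", config)
    manifest = {
        "package": "popgenkit",
        "version": __version__,
        "seed": config.seed,
        "param_hash": _param_hash(config),
        "config": _config_dict(config),
        "n_samples": gm.n_samples,
        "n_variants": gm.n_variants,
        "tables": sorted(tables),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return tables


def _ld_stage(gm, metadata, config: RunConfig) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    units = ["ALL"] + (metadata.groups if len(metadata.groups) > 1 else [])

    adj_rows = []
    for unit in units:
        grp = None if unit == "ALL" else unit
        try:
            mean, sd, dist = adjacent_r2(gm, metadata, grp)
            adj_rows.append({"group": unit, "mean_r2": mean, "sd_r2": sd,
                             "mean_distance_bp": dist})
        except ValueError as exc:
            logger.warning("adjacent r2 skipped for %s: %s", unit, exc)
    out["adjacent_r2"] = pd.DataFrame(adj_rows)

    genome = config.genome_size or float(gm.callable_length())
    density_rows = []
    ne_rows = []
    for label, max_d, bin_s in DECAY_SETS:
        decay_rows = []
        for unit in units:
            grp = None if unit == "ALL" else unit
            bins = ld_decay(gm, metadata, grp, max_d, bin_s, config.ld_config)
            for b in bins:
                decay_rows.append({"group": unit, "bin_low": b.low, "bin_high": b.high,
                                   "n_pairs": b.n_pairs, "mean_r2": b.mean_r2,
                                   "sd_r2": b.sd_r2, "median_distance": b.median_distance})
            if label == "100kb":
                for thr in config.r2_thresholds:
                    d = decay_distance(bins, thr)
                    density_rows.append({
                        "group": unit, "r2_threshold": thr,
                        "decay_distance_bp": d,
                        "recommended_snps": marker_density(genome, d) if d else np.nan,
                    })
            if label == "10mb":
                try:
                    points = ne_trajectory(bins, config.ld_config)
                except ValueError as exc:
                    logger.warning("Ne trajectory skipped for %s: %s", unit, exc)
                    points = []
                for pt in points:
                    ne_rows.append({"group": unit,
                                    "generations_ago": pt.generations_ago,
                                    "c_morgans": pt.c_morgans,
                                    "mean_r2": pt.mean_r2, "ne": pt.ne})
        out[f"ld_decay_{label}"] = pd.DataFrame(decay_rows)
    out["marker_density"] = pd.DataFrame(density_rows)
    out["ne_trajectory"] = pd.DataFrame(ne_rows)
    return out


def plot_ld_decay(bins_by_group: dict[str, list], path: str) -> None:
    """Plot binned mean r^2 against median bin distance (one line per group)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for grp, bins in bins_by_group.items():
        xs = [b.median_distance / 1e3 for b in bins if b.n_pairs > 0]
        ys = [b.mean_r2 for b in bins if b.n_pairs > 0]
        ax.plot(xs, ys, marker="o", ms=3, label=grp)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------- #
# Simulation presets
# ---------------------------------------------------------------------- #

PRESETS = ("structured-3pop", "constant-ne", "planted-roh")


def simulate_and_run(preset: str, seed: int, outdir: str) -> dict[str, pd.DataFrame]:
    """Generate a preset synthetic dataset, run the pipeline, compare to truth."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    outdir_p = Path(outdir)
    outdir_p.mkdir(parents=True, exist_ok=True)

    if preset == "structured-3pop":
        cfg = sim.StructureSimConfig(k=3, fst=[0.08, 0.10, 0.12], n_loci=3_000, seed=seed)
        gm, meta, truth = sim.simulate_structured(
            cfg, {"popA": 20, "popB": 20, "popC": 20},
            group_supergroup={"popA": "farm_1", "popB": "farm_1", "popC": "farm_2"},
        )
        run = RunConfig(outdir=outdir, seed=seed, do_ld=False, amova_permutations=199)
        tables = run_all(run, gm=gm, metadata=meta)
        from .differentiation import wc_fst

        rows = []
        for a, fa in (("popA", 0.08), ("popB", 0.10), ("popC", 0.12)):
            for b, fb in (("popA", 0.08), ("popB", 0.10), ("popC", 0.12)):
                if a < b:
                    # independent BN draws: pairwise theta ~ mean of the two F's
                    rows.append({"pair": f"{a}-{b}",
                                 "target_fst": (fa + fb) / 2.0,
                                 "estimated_theta": wc_fst(gm, meta, (a, b))})
        comparison = pd.DataFrame(rows)

    elif preset == "constant-ne":
        cfg = sim.WrightFisherConfig(ne=100, n_generations=200, chrom_length=10_000_000,
                                     sample_size=50, n_start_loci=1_500, seed=seed)
        gm, truth = sim.simulate_wright_fisher(cfg)
        meta = SampleMetadata({s: ("wf", "sim") for s in gm.samples})
        ldc = LdConfig(n_snps=10**6, min_scaffold_length=5_000_000, seed=seed)
        run = RunConfig(outdir=outdir, seed=seed, ld_config=ldc,
                        do_amova=False, do_differentiation=False, do_roh=False)
        tables = run_all(run, gm=gm, metadata=meta)
        traj = tables["ne_trajectory"]
        comparison = traj.assign(true_ne=float(truth["ne"]))

    else:  # planted-roh
        cfg = sim.StructureSimConfig(k=1, fst=[0.0], maf_range=(0.2, 0.5), n_loci=3_000,
                                     seed=seed, n_scaffolds=1, spacing_bp=10_000)
        gm, meta, _ = sim.simulate_structured(cfg, {"popA": 10})
        tracts = [
            sim.RohTract("popA_1", "scaffold_1", 1_000_000, 3_000_000),
            sim.RohTract("popA_2", "scaffold_1", 5_000_000, 6_000_000),
        ]
        gm = sim.plant_roh(gm, tracts)
        run = RunConfig(outdir=outdir, seed=seed, do_ld=False, do_amova=False,
                        do_differentiation=False)
        tables = run_all(run, gm=gm, metadata=meta)
        L = gm.callable_length()
        planted = {t.sample: 0 for t in tracts}
        for t in tracts:
            planted[t.sample] += t.length
        per = tables["froh_samples"]
        rows = []
        for s in gm.samples:
            det = per[(per["sample"] == s) & (per["threshold_bp"] == 500_000)]["froh"]
            rows.append({"sample": s,
                         "planted_froh": planted.get(s, 0) / L,
                         "detected_froh": float(det.iloc[0]) if len(det) else np.nan})
        comparison = pd.DataFrame(rows)

    run_cfg = RunConfig(outdir=outdir, seed=seed)
    _write(comparison, outdir_p / "truth_comparison.tsv", run_cfg)
    tables["truth_comparison"] = comparison
    return tables
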