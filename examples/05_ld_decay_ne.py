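"""LD decay and the Ne trajectory from a constant-size population.

Runs a forward Wright-Fisher simulation (true Ne = 100) on a 10 Mb
chromosome at 1 cM/Mb, computes the composite-r^2 decay curve, inverts
Sved's E[r^2] = 1/(1+4*Ne*c) at the bin nearest each dated distance, and
prints the marker density the observed decay would recommend.
"""

from popgenkit import (
    LdConfig,
    WrightFisherConfig,
    adjacent_r2,
    ld_decay,
    marker_density,
    ne_trajectory,
    simulate_wright_fisher,
)
from popgenkit.ld import decay_distance

cfg = WrightFisherConfig(ne=100, n_generations=200, chrom_length=10_000_000,
                         recomb_rate=1e-8, sample_size=50, n_start_loci=3_000, seed=4)
gm, truth = simulate_wright_fisher(cfg)
gm = gm.take_variants(gm.maf() > 0.05)
print(f"{gm.n_variants} segregating SNPs in a sample of {gm.n_samples} diploids")

mean, sd, dist = adjacent_r2(gm)
print(f"adjacent-SNP r^2: {mean:.3f} +/- {sd:.3f} at mean spacing {dist/1e3:.1f} kb")

ldc = LdConfig(n_snps=10**6, min_scaffold_length=5_000_000, seed=0)
bins = ld_decay(gm, None, None, 10_000_000, 100_000, ldc)
for b in bins[:5]:
    print(f"  bin {b.low//1000:5d}-{b.high//1000:5d} kb: mean r^2 = {b.mean_r2:.3f} "
          f"({b.n_pairs} pairs)")

print("\nNe trajectory (true Ne = 100):")
for p in ne_trajectory(bins, ldc):
    print(f"  t = {p.generations_ago:5.0f} generations ago "
          f"(c = {p.c_morgans:.4f} M): Ne = {p.ne:7.1f}")

d02 = decay_distance(bins, 0.2)
if d02:
    print(f"\nmean r^2 drops below 0.2 by {d02/1e3:.0f} kb -> "
          f"{marker_density(2.4e9, d02):,} SNPs for a 2.4 Gb genome")
# Estimates at intermediate dates sit near the simulated Ne of 100; the
# shortest-distance bins look further back in time than the 200 simulated
# generations and the 10 Mb bin (t = 5) is limited by the chromosome length.
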