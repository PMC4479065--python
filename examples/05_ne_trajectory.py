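"""Ancestral effective population size from binned LD.

Under the drift-recombination equilibrium without mutation,
E(r2) = 1/(1 + 4 Ne c) at genetic distance c Morgans, and LD at c
reflects Ne about t = 1/(2c) generations ago.  Here a population whose
true history is Ne 300 -> 60 (bottleneck 40 generations ago) is
simulated and the trajectory read back from its LD alone.
"""

import breedld as bl

cfg = bl.SimConfig(n_chromosomes=6, chrom_length_mb=25, n_markers_per_chrom=500,
                   ne_trajectory=[(500, 300), (40, 60)],
                   sample_sizes={"P": 120}, seed=23)
pop = bl.simulate(cfg)["P"]
geno = bl.to_genotypes(pop)
geno, markers, _ = bl.apply_qc(geno, pop.markers, bl.QCConfig(maf_min=0.05))
pairs = bl.ld_pairs(geno, markers, max_dist_mb=12.0)

traj = bl.ne_trajectory(pairs, time_points=[5, 10, 20, 50, 100, 250, 500],
                        cm_per_mb=1.0)
print(traj[["t", "c_morgan", "n_pairs", "mean_r2", "ne"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))

# Recent points (t <= 20, long-range LD) sit near the post-bottleneck
# size of 60; older points climb towards the ancestral 300.  The
# Mb->Morgan conversion (cm_per_mb) is the one assumption the data do
# not constrain -- report it with any Ne trajectory.
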