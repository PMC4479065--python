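"""Population structure via the genomic relationship matrix.

Builds the VanRaden G = (M-2P)(M-2P)'/(2*sum p(1-p)) over two
populations that diverged 150 generations ago (missing doses imputed
with twice the within-population allele frequency) and projects the
individuals on the leading principal components.
"""

import numpy as np

import breedld as bl

cfg = bl.SimConfig(n_chromosomes=5, chrom_length_mb=15, n_markers_per_chrom=400,
                   ne_trajectory=[(250, 100)], split_events=[(150, "P", "Q")],
                   sample_sizes={"P": 40, "Q": 40}, missing_rate=0.02, seed=29)
pops = bl.simulate(cfg)

data = {}
for label, pop in pops.items():
    geno = bl.to_genotypes(pop, missing_rate=0.02, seed=3)
    geno, markers, _ = bl.apply_qc(geno, pop.markers, bl.QCConfig(maf_min=0.05))
    data[label] = (geno, markers)

joint, joint_markers = bl.merge_populations(data)
gmat = bl.build_G(joint, joint_markers.name)
res = bl.pca(gmat, k=4)

print(f"{gmat.n} individuals x {len(joint_markers)} shared markers")
print("variance explained:",
      ", ".join(f"PC{k + 1} {v:.1%}" for k, v in enumerate(res.variance_ratio)))
pc1_p = res.scores[res.populations == "P", 0]
pc1_q = res.scores[res.populations == "Q", 0]
for label, pc1 in (("P", pc1_p), ("Q", pc1_q)):
    print(f"{label}: PC1 in [{pc1.min():+.3f}, {pc1.max():+.3f}]")
gap = max(pc1_q.min() - pc1_p.max(), pc1_p.min() - pc1_q.max())
print(f"PC1 separates the populations: {gap > 0} (gap {gap:.3f})")

# After 150 generations of independent drift the two samples occupy
# disjoint PC1 ranges; PC2 captures within-population family structure.
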