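# Methods

## Statistics

### Composite disequilibrium and r²

Unphased diploid genotypes do not identify gametes, so the gametic
disequilibrium D = f(AB) − f(A)f(B) is estimated with the Burrows-type
composite estimator from the two-locus genotype classes:

    D̂ = N/(N−1) · [ (4·N_AABB + 2·(N_AABb + N_AaBB) + N_AaBb)/(2N) − 2·f(A)·f(B) ]

where N is the number of individuals complete at both loci.  The
numerator term equals Σᵢ xᵢyᵢ over the dose columns x, y ∈ {0,1,2}, so
D̂ = cov(x, y)/2 with the (N−1)-denominator sample covariance; the
vectorised pair-table builder uses this identity.  Then
r² = D̂²/(f(A)f(a)f(B)f(b)) and signed r = sign(D̂)·√r².

The composite estimator sums the gametic and non-gametic (between an
individual's two haplotypes) disequilibria.  Under random mating the
non-gametic part has expectation zero, and the estimator tracks the
true haplotype r²; this is verified against the simulator's phased
haplotypes (oracle-agreement experiment).  Because of the N/(N−1)
factor and non-HWE sampled configurations the ratio can exceed 1; since
the statistic's range is 0–1 by definition, values are capped at 1 and
the cap is flagged per pair (pairs capped contribute signed r = ±1).
Whether >1 values should instead be discarded is a convention choice;
the flag lets either be recomputed.

Missing genotypes are handled pairwise-complete: each pair uses exactly
the individuals called at both markers and N is that count.  Pairs with
N < 2 or a locus monomorphic within the complete subset are undefined
and skipped (scalar API raises; table builders drop and can report).

### Small-sample correction

r²_corr = (r² − 1/N)/(1 − 1/N) with N the number of haplotypes, i.e.
twice the number of individuals, floored at 0.  Uncorrected r² is the
primary output everywhere; the correction is an optional parallel
column and an optional input to the Ne inversion (`use_corrected`).

### Distance bins

The default scheme has exactly 20 bins: (0, 0.02) Mb, 0.01-Mb bins from
0.02 to 0.1, 0.1-Mb bins from 0.1 to 1, [1, 1.2), and an open bin above
1.2 Mb.  Assignment is half-open [lo, hi) with ties going to the upper
bin and zero distances excluded; the convention is arbitrary but fixed,
so bin counts are reproducible.  Pairs are enumerated within
chromosome, by default out to 15 Mb — far beyond the last bin edge
because the Ne analysis needs long-range pairs (t = 5 generations ⇒
c = 0.1 Morgans ⇒ 10 Mb at 1 cM/Mb).

### Consistency of gametic phase

For two populations, marker pairs are matched by (name_i, name_j) on
the shared map and the Pearson correlation of their signed r values is
computed per distance bin (undefined and flagged when fewer than three
shared pairs or zero variance on either side).  Signed r flips with
dose orientation, so a per-marker registry of the counted allele is
carried with every genotype matrix; comparing tables whose registries
disagree at any shared marker is a hard error rather than a silent sign
corruption.  The square consistency matrix reports a pooled correlation
over distances below 0.20 Mb above the diagonal and over the
0.02–0.03 Mb bin below it; pooling the pairs (rather than averaging
per-bin correlations) is the chosen convention for the coarse windows.

### Ancestral effective population size

Sved's drift–recombination expectation without mutation,
E(r²) = 1/(1 + 4·Ne·c), is inverted at a set of time points: for each t
the target distance is c = 1/(2t) Morgans, pairs within ±10% of c (in
genetic distance) are averaged, and Ne = (1/r̄² − 1)/(4c).  Defaults:

* time grid — 21 log-spaced points from 5 to 1500 generations;
* window — ±10% of the target c;
* physical→genetic conversion — 1 cM/Mb, uniform.

The cM/Mb conversion is the single largest assumption: the data do not
constrain it, it rescales the whole time axis, and it is therefore a
required, logged parameter recorded in every output.  r̄² ≥ 1 maps to
Ne = 0; r̄² ≤ 0 or an empty window yields a flagged NaN point.

### Genomic relationship matrix and PCA

G = (M − 2P)(M − 2P)′ / (2·Σᵢ pᵢ(1−pᵢ)) over the markers passing QC in
every included population.  Two frequency conventions deliberately
coexist: centering and the denominator use the pooled (all-population)
frequency of the counted allele, while missing doses are imputed as
twice the frequency *within the individual's own population* (falling
back to pooled if a population has no call at a marker).  Markers
monomorphic in the pooled sample are dropped (zero denominator
contribution).  PCA is the symmetric eigendecomposition of G; scores
are eigenvectors scaled by √λ, with each component's sign fixed so its
largest-magnitude loading is positive, making output bit-reproducible.

## Quality control

Per population (frequencies and HWE are meaningless across structure),
in a fixed order: (1) individuals with call rate < 0.90 are removed;
(2) non-autosomal or unmapped markers (chromosome code outside
1..max_autosome, default 29 for goat, or position 0) are removed;
(3) SNP statistics are computed on the remaining individuals and SNPs
failing MAF (< 0.05 or 0.15 by sample size), call rate (< 0.90), the
1-df χ² HWE test without continuity correction (p < 10⁻⁶) or
heterozygosity excess (Ho − He > 0.15, He = 2pq from the observed
frequency) are removed.  Running individual QC first prevents bad
samples from distorting SNP statistics; the report counts failures per
criterion on the post-step-2 set, so one SNP may appear under several
criteria while the bookkeeping identity
`remaining = input − non-autosomal − distinct failures` always holds.
Missing genotypes are never imputed during QC or LD; the only
imputation in the package is the 2p rule inside G.

## Simulator

The generator emulates multi-population SNP-chip data: discrete
non-overlapping generations of diploid random mating (selfing allowed),
per-epoch diploid Ne, population splits that copy the parent at the
stated generation, and single-generation admixture pulses that draw a
fraction of one generation's parents from a source population.

* **Initialisation/burn-in.**  Founder haplotypes are site-wise
  independent draws at frequencies ~ Uniform(0.1, 0.9) — linkage
  equilibrium.  Equilibrium LD is built by running a burn-in as part of
  the configured epochs; ≥ 4·Ne generations is the recommendation used
  by the validation experiments.  There is no mutation after
  initialisation, matching the no-mutation expectation used for Ne.
* **Recombination.**  A uniform genetic map (cm_per_mb per chromosome)
  with Poisson crossovers and no interference.  Transmission is exact
  at marker loci: the parental-haplotype indicator along a gamete is a
  two-state Markov chain with switch probability (1 − e^(−2d))/2 per
  adjacent-marker interval of d Morgans (the Haldane probability of an
  odd crossover count); chromosome boundaries switch at ½.  This is
  fully vectorised per generation, which is what makes burn-ins of
  hundreds of generations over 10⁴ markers affordable.
* **Markers.**  A jittered grid per chromosome (uniform offset within
  each spacing interval), giving strictly increasing positions with
  realistic gap variation at the configured mean spacing.
* **Sampling.**  At generation 0, n individuals are taken without
  replacement when n ≤ N; when a larger genotyped sample than the
  breeding population is requested (as in the Ne-recovery design:
  200 diploids from Ne = 100) the sample consists of offspring gametes
  drawn from the final parental pool, i.e. one extra meiosis.

What the simulator does **not** emulate: mutation, selection,
overlapping generations, pedigree structure, sex chromosomes,
ascertainment bias of array SNP discovery, genotyping error other than
uniform missingness, and non-uniform recombination maps.  Passing
tests therefore demonstrate correctness of the estimators under
neutral random-mating drift — not robustness to selection, pedigree
sampling or array ascertainment in real data.

## Validation experiment sizes

The ground-truthed experiments (shared by the test suite and
`scripts/acceptance.py`) use sizes chosen to keep per-window pair
genealogies near-independent while remaining desk-scale:

* oracle agreement — Ne 100, burn-in 400, 20 × 7.5 Mb chromosomes,
  3,000 markers, 100 diploids, 500 pairs alternating short (<0.1 Mb)
  and long (0.75–2 Mb) distances at MAF ≥ 0.15;
* constant-Ne recovery — Ne 100, burn-in 450, 20 × 30 Mb chromosomes,
  18,000 simulated sites so that ~2,000 polymorphic markers survive QC
  after drift, 200 diploids, windows at t ∈ {10, 20, 50};
* bottleneck — Ne 500 for 600 generations then 50 for the last 50;
  recent = mean Ne over t ∈ {5, 10, 20}, ancient over t ∈ {200, 500};
* phase divergence — splits at 0/20/100 generations, Ne 100, pooled
  consistency below 0.2 Mb;
* PCA separation — split 200 generations, 50 + 50 diploids.

Drift during burn-in fixes the majority of founder variants; panel
sizes above are inflated accordingly and the surviving marker counts
are reported alongside the results.

## Numerical conventions and edge cases

* Doses are int8 with −1 as the missing sentinel; positions are 1-based
  base pairs; distances in Mb are (pos_j − pos_i)/10⁶.
* The reference (counted) allele is the .bim A1 or the first allele
  encountered in a .ped; the text dialect additionally writes a `.ref`
  sidecar (marker, ref, alt) so a write/read cycle preserves dose
  orientation exactly — plain .ped/.map files carry no allele order.
* Monomorphic loci: MAF 0 (fails any positive MAF threshold), HWE
  χ² = 0 with p = 1 (never the reason for exclusion), heterozygosity
  excess 0, LD undefined.
* An all-missing column has call rate 0 and undefined frequencies; an
  input that filters down to nothing returns an explicit empty result.
* Self-consistency of phase is exactly 1; bins are reported (flagged
  NaN) rather than dropped throughout, so table shapes are stable.

## Design notes

The package is organised as a library plus `examples/`; the CLI is a
thin JSON-config front end over the pipeline because the end-to-end
QC → LD → phase → Ne → PCA run over PLINK filesets is the one workflow
users plausibly launch from a shell.  All report tables are CSV-first;
plots are conveniences and never the source of record.  Cross-population
stages operate on the intersection of per-population QC survivor sets,
computed after QC — per-population thresholds (e.g. different MAF
cut-offs by sample size) therefore shape the joint marker set, which is
recorded in the run manifest together with every threshold and seed.
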