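import numpy as np
import pytest

import breedld as bl
from breedld.sim import (MonomorphicError, SimConfigError, _switch_probabilities,
                         meiosis)


def _cfg(**kw):
    base = dict(n_chromosomes=2, chrom_length_mb=5, n_markers_per_chrom=50,
                ne_trajectory=[(30, 40)], sample_sizes={"P": 20}, seed=3)
    base.update(kw)
    return bl.SimConfig(**base)


def test_identical_seed_gives_bit_identical_output():
    a = bl.simulate(_cfg())["P"]
    b = bl.simulate(_cfg())["P"]
    np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
    np.testing.assert_array_equal(a.markers.pos, b.markers.pos)
    c = bl.simulate(_cfg(seed=4))["P"]
    assert not np.array_equal(a.haplotypes, c.haplotypes)


def test_one_generation_drift_variance_matches_wright_fisher():
    """Var of the per-generation frequency change is p(1-p)/(2Ne)."""
    ne, loci = 100, 500
    rng = np.random.default_rng(11)
    founders = np.zeros((2 * ne, loci), dtype=np.uint8)
    for j in range(loci):  # exact frequency 0.5 at every locus
        founders[rng.permutation(2 * ne)[:ne], j] = 1
    switch_p = np.full(loci - 1, 0.5)  # unlinked loci
    offspring = meiosis(founders, 2 * ne, switch_p, rng)
    dp = offspring.mean(axis=0) - 0.5
    expected_var = 0.25 / (2 * ne)
    observed_var = float(np.mean(dp ** 2))
    se = expected_var * np.sqrt(2.0 / loci)  # SE of a chi-square mean
    assert abs(observed_var - expected_var) < 3 * se


def test_zero_recombination_transmits_whole_founder_haplotypes():
    cfg = _cfg(n_chromosomes=1, cm_per_mb=0.0, ne_trajectory=[(20, 10)])
    rng = np.random.default_rng(0)
    markers = bl.simulate(cfg)["P"].markers
    switch_p = _switch_probabilities(markers, 0.0)
    assert np.all(switch_p == 0.0)
    founders = (np.random.default_rng(1).random((20, len(markers))) < 0.5).astype(np.uint8)
    out = founders
    for _ in range(15):
        out = meiosis(out, 20, switch_p, rng)
    founder_set = {f.tobytes() for f in founders}
    assert all(h.tobytes() in founder_set for h in out)


def test_dose_is_haplotype_sum_and_missing_rate_zero_is_clean(small_pop):
    geno = bl.to_genotypes(small_pop, missing_rate=0.0)
    expected = small_pop.haplotypes[0::2].astype(int) + small_pop.haplotypes[1::2]
    np.testing.assert_array_equal(geno.doses, expected)
    assert not (geno.doses == bl.MISSING).any()


def test_missing_fraction_within_binomial_interval(small_pop):
    geno = bl.to_genotypes(small_pop, missing_rate=0.05, seed=5)
    n = geno.doses.size
    k = int((geno.doses == bl.MISSING).sum())
    # binomial 99% interval around 0.05
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(k / n - 0.05) < 2.576 * se


def test_true_haplotype_r2_complete_ld_and_independence():
    markers = bl.MarkerMap(np.array(["1", "1"]), np.array([100, 200]),
                           np.array(["a", "b"]))
    coupled = np.array([[1, 1], [0, 0]] * 10, dtype=np.uint8)
    pop = bl.PhasedPopulation(coupled, markers, "P")
    assert bl.true_haplotype_r2(pop, 0, 1) == pytest.approx(1.0)
    balanced = np.array([[1, 1], [1, 0], [0, 1], [0, 0]] * 25, dtype=np.uint8)
    pop = bl.PhasedPopulation(balanced, markers, "P")
    assert bl.true_haplotype_r2(pop, 0, 1) == pytest.approx(0.0)


def test_true_haplotype_r2_matches_direct_count_oracle():
    rng = np.random.default_rng(17)
    markers = bl.MarkerMap(np.array(["1", "1"]), np.array([100, 200]),
                           np.array(["a", "b"]))
    haps = rng.integers(0, 2, size=(20, 2)).astype(np.uint8)
    pop = bl.PhasedPopulation(haps, markers, "P")
    f_ab = np.mean((haps[:, 0] == 1) & (haps[:, 1] == 1))
    f_a, f_b = haps[:, 0].mean(), haps[:, 1].mean()
    d = f_ab - f_a * f_b
    oracle = d * d / (f_a * (1 - f_a) * f_b * (1 - f_b))
    assert bl.true_haplotype_r2(pop, 0, 1) == pytest.approx(oracle)


def test_monomorphic_marker_raises():
    markers = bl.MarkerMap(np.array(["1", "1"]), np.array([100, 200]),
                           np.array(["a", "b"]))
    haps = np.array([[1, 1], [1, 0]] * 5, dtype=np.uint8)  # marker 0 fixed
    pop = bl.PhasedPopulation(haps, markers, "P")
    with pytest.raises(MonomorphicError):
        bl.true_haplotype_r2(pop, 0, 1)


def test_config_rejects_inconsistent_events():
    with pytest.raises(SimConfigError):  # child splits before parent exists
        _cfg(split_events=[(10, "A", "B"), (5, "P", "A")],
             sample_sizes={"P": 5, "A": 5, "B": 5})
    with pytest.raises(SimConfigError):  # two roots
        _cfg(sample_sizes={"P": 5, "Q": 5})
    with pytest.raises(SimConfigError):
        _cfg(admixture_events=[(5, "P", "P", 1.5)])
    with pytest.raises(SimConfigError):
        _cfg(missing_rate=1.0)
    with pytest.raises(SimConfigError):
        _cfg(ne_trajectory=[(10, 1)])


def test_split_produces_identical_then_diverging_populations():
    cfg = _cfg(split_events=[(0, "P", "Q")], sample_sizes={"P": 10, "Q": 10})
    pops = bl.simulate(cfg)
    # a zero-generations-ago split shares the final gamete pool: allele
    # frequencies nearly identical, and every Q haplotype occurs in the pool
    fa = pops["P"].allele_frequencies()
    fb = pops["Q"].allele_frequencies()
    assert np.corrcoef(fa, fb)[0, 1] > 0.9


def test_admixture_pulse_moves_allele_frequencies():
    """A 100% pulse replaces the target's gene pool with the source's."""
    cfg = _cfg(n_chromosomes=1, n_markers_per_chrom=200,
               ne_trajectory=[(60, 50)],
               split_events=[(50, "P", "Q")],
               admixture_events=[(5, "Q", "P", 1.0)],
               sample_sizes={"P": 30, "Q": 30}, seed=21)
    cfg_no = _cfg(n_chromosomes=1, n_markers_per_chrom=200,
                  ne_trajectory=[(60, 50)],
                  split_events=[(50, "P", "Q")],
                  sample_sizes={"P": 30, "Q": 30}, seed=21)
    with_pulse = bl.simulate(cfg)
    without = bl.simulate(cfg_no)
    d_with = np.abs(with_pulse["P"].allele_frequencies()
                    - with_pulse["Q"].allele_frequencies()).mean()
    d_without = np.abs(without["P"].allele_frequencies()
                       - without["Q"].allele_frequencies()).mean()
    assert d_with < d_without


def test_write_populations_emits_readable_plink(tmp_path):
    pops = bl.simulate(_cfg())
    bl.sim.write_populations(pops, str(tmp_path), missing_rate=0.02, seed=3)
    geno, markers, samples = bl.read_plink(str(tmp_path / "P"))
    assert geno.n_individuals == 20
    assert len(markers) == 100
    assert (tmp_path / "simulation.json").exists()
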