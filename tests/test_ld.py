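import numpy as np
import pytest
from hypothesis import given, strategies as st

import breedld as bl
from breedld.ld import LDUndefinedError


def _independence_counts():
    # N = 16 individuals with both loci in HWE at p = 0.5 and no association
    c = np.zeros((3, 3))
    c[2, 2], c[2, 1], c[2, 0] = 1, 2, 1
    c[1, 2], c[1, 1], c[1, 0] = 2, 4, 2
    c[0, 2], c[0, 1], c[0, 0] = 1, 2, 1
    return c


def test_composite_d_independence_fixture_is_zero():
    assert bl.composite_D(_independence_counts()) == pytest.approx(0.0)


def test_composite_d_coupling_fixture_is_one_third():
    c = np.zeros((3, 3))
    c[2, 2], c[1, 1], c[0, 0] = 1, 2, 1
    assert bl.composite_D(c) == pytest.approx(1.0 / 3.0)


def test_composite_d_negates_under_single_locus_relabel():
    rng = np.random.default_rng(3)
    c = rng.integers(0, 5, (3, 3)).astype(float)
    c[1, 1] += 2  # keep both loci polymorphic
    d = bl.composite_D(c)
    assert bl.composite_D(c[::-1, :]) == pytest.approx(-d)
    assert bl.composite_D(c[:, ::-1]) == pytest.approx(-d)
    assert bl.composite_D(c[::-1, ::-1]) == pytest.approx(d)


def test_composite_d_error_conditions():
    with pytest.raises(LDUndefinedError):
        bl.composite_D(np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 0]]))
    mono = np.zeros((3, 3))
    mono[2, 1], mono[2, 0] = 3, 3  # locus A fixed for the reference allele
    with pytest.raises(LDUndefinedError):
        bl.composite_D(mono)


def test_pair_r2_independence_and_cap():
    # independence fixture written out as dose columns
    xi = np.array([2] * 4 + [1] * 8 + [0] * 4)
    yi = np.array([2, 1, 1, 0] * 4)
    d, r, r2 = bl.pair_r2(xi, yi)
    assert d == pytest.approx(0.0)
    assert r2 == pytest.approx(0.0)
    # N=4 perfect coupling in HWE: raw composite ratio exceeds 1, capped
    xc = np.array([2, 1, 1, 0])
    d, r, r2 = bl.pair_r2(xc, xc.copy())
    assert d == pytest.approx(1.0 / 3.0)
    assert r2 == 1.0
    assert r == 1.0


def test_pair_r2_uses_pairwise_complete_subset():
    x = np.array([2, 1, 0, 2, bl.MISSING, 1], dtype=np.int8)
    y = np.array([2, 1, 0, bl.MISSING, 2, 1], dtype=np.int8)
    d, r, r2 = bl.pair_r2(x, y)
    ok = (x >= 0) & (y >= 0)
    d2, r2_, r22 = bl.pair_r2(x[ok], y[ok])
    assert (d, r, r2) == (d2, r2_, r22)


def test_pair_r2_error_conditions():
    with pytest.raises(LDUndefinedError):
        bl.pair_r2(np.array([2]), np.array([1]))
    with pytest.raises(LDUndefinedError):  # monomorphic after missing removal
        bl.pair_r2(np.array([2, 2, bl.MISSING], dtype=np.int8),
                   np.array([1, 0, 1], dtype=np.int8))


@given(st.integers(0, 2 ** 31 - 1))
def test_orientation_invariance(seed):
    """Recoding alleles flips D and signed r but never changes r²."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, 40)
    y = rng.integers(0, 3, 40)
    try:
        d, r, r2 = bl.pair_r2(x, y)
    except LDUndefinedError:
        return
    d1, r1, r21 = bl.pair_r2(2 - x, y)
    assert d1 == pytest.approx(-d)
    assert r1 == pytest.approx(-r)
    assert r21 == pytest.approx(r2)
    d2, _, r22 = bl.pair_r2(2 - x, 2 - y)
    assert d2 == pytest.approx(d)
    assert r22 == pytest.approx(r2)


def test_correct_r2_fixed_points_and_small_sample_shift():
    assert bl.correct_r2(1.0 / 96, 48) == pytest.approx(0.0)
    assert bl.correct_r2(1.0, 48) == pytest.approx(1.0)
    corrected = bl.correct_r2(0.25, 48)
    assert corrected == pytest.approx((0.25 - 1 / 96) / (1 - 1 / 96))
    assert 0.25 - corrected == pytest.approx(0.008, abs=2e-3)
    assert bl.correct_r2(0.001, 48) == 0.0  # floored


def test_default_bin_scheme_has_twenty_bins_and_half_open_edges():
    bins = bl.BinScheme.default()
    assert bins.n_bins == 20
    idx = bins.assign(np.array([0.025, 0.02, 0.0199, 1.19, 1.2, 5.0, 0.0]))
    labels = [bins.labels[i] if i >= 0 else None for i in idx]
    assert labels[0] == "0.02-0.03"     # inside second bin
    assert labels[1] == "0.02-0.03"     # tie at the edge goes up
    assert labels[2] == "0-0.02"
    assert labels[3] == "1-1.2"
    assert labels[4] == ">1.2"          # tie at 1.2 goes to the open bin
    assert labels[5] == ">1.2"
    assert labels[6] is None            # zero distance excluded


def test_ld_pairs_matches_scalar_estimator(small_geno, small_pop):
    pairs = bl.ld_pairs(small_geno, small_pop.markers, max_dist_mb=2.0)
    assert len(pairs) > 100
    rng = np.random.default_rng(5)
    name_to_col = {n: j for j, n in enumerate(small_pop.markers.name)}
    for _, row in pairs.sample(40, random_state=rng.integers(1 << 16)).iterrows():
        i, j = name_to_col[row["name_i"]], name_to_col[row["name_j"]]
        d, r, r2 = bl.pair_r2(small_geno.doses[:, i], small_geno.doses[:, j])
        assert row["D"] == pytest.approx(d, abs=1e-12)
        assert row["r"] == pytest.approx(r, abs=1e-12)
        assert row["r2"] == pytest.approx(r2, abs=1e-12)


def test_ld_pairs_skips_undefined_pairs():
    doses = np.array([[2, 2, 0], [2, 1, 1], [2, 0, 2]], dtype=np.int8)  # col 0 fixed
    samples = bl.SampleTable(np.array(["a", "b", "c"]), np.array(["P"] * 3))
    geno = bl.GenotypeMatrix(doses, samples, np.array(["A"] * 3), np.array(["B"] * 3))
    markers = bl.MarkerMap(np.array(["1"] * 3), np.array([100, 200, 300]),
                           np.array(["x", "y", "z"]))
    pairs = bl.ld_pairs(geno, markers, max_dist_mb=1.0)
    assert set(zip(pairs["name_i"], pairs["name_j"])) == {("y", "z")}


def test_adjacent_ld_distance_arithmetic_and_recount(small_geno, small_pop):
    markers = bl.MarkerMap(np.array(["1"] * 3),
                           np.array([1_000_001, 1_060_001, 1_090_001]),
                           np.array(["a", "b", "c"]))
    rng = np.random.default_rng(2)
    doses = rng.integers(0, 3, (50, 3)).astype(np.int8)
    samples = bl.SampleTable(np.array([f"i{k}" for k in range(50)]),
                             np.array(["P"] * 50))
    geno = bl.GenotypeMatrix(doses, samples, np.array(["A"] * 3), np.array(["B"] * 3))
    adj = bl.adjacent_ld(geno, markers).set_index("chrom")
    assert adj.loc["1", "mean_dist_mb"] == pytest.approx(0.045)
    # full recount oracle on simulated data
    adj2 = bl.adjacent_ld(small_geno, small_pop.markers).set_index("chrom")
    for c in small_pop.markers.chromosomes():
        idx = small_pop.markers.indices_of(c)
        r2s = []
        for a in range(len(idx) - 1):
            try:
                _, _, r2 = bl.pair_r2(small_geno.doses[:, idx[a]],
                                      small_geno.doses[:, idx[a + 1]])
                r2s.append(r2)
            except LDUndefinedError:
                pass
        assert adj2.loc[c, "mean_r2"] == pytest.approx(np.mean(r2s))


def test_unlinked_markers_have_low_mean_adjacent_r2():
    rng = np.random.default_rng(9)
    doses = rng.binomial(2, 0.5, size=(500, 3)).astype(np.int8)
    samples = bl.SampleTable(np.array([f"i{k}" for k in range(500)]),
                             np.array(["P"] * 500))
    geno = bl.GenotypeMatrix(doses, samples, np.array(["A"] * 3), np.array(["B"] * 3))
    markers = bl.MarkerMap(np.array(["1"] * 3), np.array([100, 200, 300]),
                           np.array(["x", "y", "z"]))
    adj = bl.adjacent_ld(geno, markers).set_index("chrom")
    assert adj.loc["overall", "mean_r2"] < 0.02


def test_ld_decay_binning_matches_brute_force(small_geno, small_pop):
    bins = bl.BinScheme.default()
    decay = bl.ld_decay(small_geno, small_pop.markers, bins, max_dist_mb=5.0)
    pairs = bl.ld_pairs(small_geno, small_pop.markers, max_dist_mb=5.0)
    assert decay["n_pairs"].sum() == len(pairs)
    idx = bins.assign(pairs["dist_mb"].to_numpy())
    for b, row in decay.iterrows():
        sel = pairs.loc[idx == b, "r2"]
        assert row["n_pairs"] == len(sel)
        if len(sel):
            assert row["mean_r2"] == pytest.approx(sel.mean())
        else:
            assert np.isnan(row["mean_r2"])


def test_single_pair_lands_in_one_bin():
    rng = np.random.default_rng(4)
    doses = rng.integers(0, 3, (30, 2)).astype(np.int8)
    samples = bl.SampleTable(np.array([f"i{k}" for k in range(30)]),
                             np.array(["P"] * 30))
    geno = bl.GenotypeMatrix(doses, samples, np.array(["A"] * 2), np.array(["B"] * 2))
    markers = bl.MarkerMap(np.array(["1", "1"]), np.array([100_000, 125_000]),
                           np.array(["x", "y"]))
    decay = bl.ld_decay(geno, markers)
    assert decay["n_pairs"].sum() == 1
    assert decay.set_index("bin").loc["0.02-0.03", "n_pairs"] == 1


def test_decay_is_monotone_on_equilibrium_population():
    """Mean r² per bin decreases with distance, up to sampling noise."""
    cfg = bl.SimConfig(n_chromosomes=4, chrom_length_mb=10, n_markers_per_chrom=250,
                       ne_trajectory=[(400, 100)], sample_sizes={"P": 100}, seed=31)
    pop = bl.simulate(cfg)["P"]
    geno = bl.to_genotypes(pop)
    gq, mq, _ = bl.apply_qc(geno, pop.markers, bl.QCConfig(maf_min=0.05))
    decay = bl.ld_decay(gq, mq, max_dist_mb=5.0)
    dense = decay[decay["n_pairs"] >= 200]
    means = dense["mean_r2"].to_numpy()
    # trend test: each bin mean below the mean of bins two places earlier
    assert np.all(means[2:] < means[:-2])
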