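import numpy as np
import pytest

import breedld as bl
from breedld.genotype_io import PlinkParseError


@pytest.mark.parametrize("dialect", ["ped", "bed"])
def test_round_trip_preserves_everything(toy_triplet, tmp_path, dialect):
    geno, markers, samples = toy_triplet
    prefix = str(tmp_path / "toy")
    bl.write_plink(geno, markers, samples, prefix, dialect=dialect)
    geno2, markers2, samples2 = bl.read_plink(prefix)
    np.testing.assert_array_equal(geno2.doses, geno.doses)
    np.testing.assert_array_equal(markers2.pos, markers.pos)
    np.testing.assert_array_equal(markers2.name, markers.name)
    np.testing.assert_array_equal(markers2.chrom, markers.chrom)
    np.testing.assert_array_equal(samples2.iid, samples.iid)
    np.testing.assert_array_equal(samples2.population, samples.population)


def test_dialects_agree_on_same_data(toy_triplet, tmp_path):
    geno, markers, samples = toy_triplet
    bl.write_plink(geno, markers, samples, str(tmp_path / "t"), dialect="ped")
    bl.write_plink(geno, markers, samples, str(tmp_path / "b"), dialect="bed")
    g_ped, m_ped, _ = bl.read_plink(str(tmp_path / "t"))
    g_bed, m_bed, _ = bl.read_plink(str(tmp_path / "b"))
    np.testing.assert_array_equal(g_ped.doses, g_bed.doses)
    np.testing.assert_array_equal(m_ped.name, m_bed.name)


def test_ped_dose_counts_first_seen_allele(tmp_path):
    (tmp_path / "x.map").write_text("1 snpA 0 1000\n1 snpB 0 2000\n")
    (tmp_path / "x.ped").write_text(
        "F1 i1 0 0 0 -9 A A G G\n"
        "F1 i2 0 0 0 -9 A G G A\n")
    geno, markers, samples = bl.read_plink(str(tmp_path / "x"))
    # snpA: reference allele A -> doses 2 and 1; snpB: reference G -> 2 and 1
    np.testing.assert_array_equal(geno.doses, [[2, 2], [1, 1]])
    assert geno.ref_allele[0] == "A" and geno.ref_allele[1] == "G"


def test_third_allele_is_a_parse_error(tmp_path):
    (tmp_path / "x.map").write_text("1 snpA 0 1000\n")
    (tmp_path / "x.ped").write_text(
        "F1 i1 0 0 0 -9 A A\nF1 i2 0 0 0 -9 A G\nF1 i3 0 0 0 -9 A T\n")
    with pytest.raises(PlinkParseError, match="snpA"):
        bl.read_plink(str(tmp_path / "x"))


def test_bad_bed_magic_rejected(toy_triplet, tmp_path):
    geno, markers, samples = toy_triplet
    prefix = str(tmp_path / "toy")
    bl.write_plink(geno, markers, samples, prefix, dialect="bed")
    raw = bytearray((tmp_path / "toy.bed").read_bytes())
    raw[0] ^= 0xFF
    (tmp_path / "toy.bed").write_bytes(bytes(raw))
    with pytest.raises(PlinkParseError, match="magic"):
        bl.read_plink(prefix)


def test_refuses_empty_marker_set(tmp_path):
    samples = bl.SampleTable(np.array(["i1"]), np.array(["P"]))
    geno = bl.GenotypeMatrix(np.zeros((1, 0), dtype=np.int8), samples,
                             np.array([], dtype=str), np.array([], dtype=str))
    markers = bl.MarkerMap(np.array([], dtype=str), np.array([], dtype=np.int64),
                           np.array([], dtype=str))
    with pytest.raises(ValueError, match="no markers"):
        bl.write_plink(geno, markers, samples, str(tmp_path / "empty"))


def test_map_summary_gap_arithmetic():
    markers = bl.MarkerMap(np.array(["1", "1", "1"]),
                           np.array([1_000_001, 1_060_001, 1_090_001]),
                           np.array(["a", "b", "c"]))
    df = bl.summarize_map(markers).set_index("chrom")
    assert df.loc["1", "longest_gap_mb"] == pytest.approx(0.06)
    assert df.loc["1", "mean_gap_mb"] == pytest.approx(0.045)
    assert df.loc["1", "length_mb"] == pytest.approx(0.09)


def test_map_summary_equal_spacing_has_zero_sd():
    markers = bl.MarkerMap(np.array(["1"] * 5),
                           np.arange(1, 6) * 50_000,
                           np.array([f"m{k}" for k in range(5)]))
    df = bl.summarize_map(markers).set_index("chrom")
    assert df.loc["1", "sd_gap_mb"] == pytest.approx(0.0)


def test_map_summary_matches_brute_force(small_pop):
    markers = small_pop.markers
    df = bl.summarize_map(markers).set_index("chrom")
    total_len, total_n = 0.0, 0
    for c in markers.chromosomes():
        pos = np.sort(markers.pos[markers.indices_of(c)])
        gaps = np.diff(pos) / 1e6
        assert df.loc[c, "longest_gap_mb"] == pytest.approx(gaps.max())
        assert df.loc[c, "mean_gap_mb"] == pytest.approx(gaps.mean())
        assert df.loc[c, "n_snps"] == len(pos)
        total_len += (pos[-1] - pos[0]) / 1e6
        total_n += len(pos)
    assert df.loc["overall", "length_mb"] == pytest.approx(total_len)
    assert df.loc["overall", "n_snps"] == total_n


def test_single_marker_chromosome_flagged():
    markers = bl.MarkerMap(np.array(["1", "2", "2"]),
                           np.array([100, 100, 200]),
                           np.array(["a", "b", "c"]))
    df = bl.summarize_map(markers).set_index("chrom")
    assert df.loc["1", "length_mb"] == 0.0
    assert np.isnan(df.loc["1", "mean_gap_mb"])


def test_marker_map_rejects_duplicates_and_disorder():
    with pytest.raises(ValueError, match="duplicate"):
        bl.MarkerMap(np.array(["1", "1"]), np.array([1, 2]), np.array(["a", "a"]))
    mm = bl.MarkerMap(np.array(["1", "1"]), np.array([5, 2]), np.array(["a", "b"]))
    with pytest.raises(ValueError, match="increasing"):
        mm.validate_sorted()


def test_autosome_mask_excludes_sex_and_unmapped():
    mm = bl.MarkerMap(np.array(["1", "29", "30", "X", "0"]),
                      np.array([1, 1, 1, 1, 0]),
                      np.array(list("abcde")))
    np.testing.assert_array_equal(mm.is_autosomal(29),
                                  [True, True, False, False, False])
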