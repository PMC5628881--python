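"""Population-genetic estimators against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylokaryo import (
    MISSING,
    MaskSet,
    allele_frequencies,
    dissimilarity_matrix,
    euclidean_dissimilarity,
    locus_diversity,
    nei_gst,
    sample_heterozygosity,
    similarity_to_centroid,
    simple_matching_dissimilarity,
    taxon_centroid,
)

from conftest import make_gm


class TestAlleleFrequencies:
    def test_fixed_and_quarter(self):
        gm = make_gm([[2, 1], [2, 0]])
        f = allele_frequencies(gm, gm.samples)
        assert f.p_alt[0] == 1.0  # {alt/alt, alt/alt}
        assert f.p_alt[1] == 0.25  # {ref/alt, ref/ref}: 1 of 4 alleles

    def test_all_missing_flagged_undefined(self):
        gm = make_gm([[MISSING], [MISSING]])
        f = allele_frequencies(gm, gm.samples)
        assert np.isnan(f.p_alt[0]) and f.n_obs[0] == 0

    def test_mask_aware_equals_brute_force(self):
        rng = np.random.default_rng(21)
        d = rng.choice([0, 1, 2, MISSING], size=(11, 40))
        pos = list(range(100, 100 + 400, 10))
        gm = make_gm(d, positions=pos)
        mask = MaskSet()
        mask.add("s0", "1", 100, 200)  # covers first ~11 loci
        mask.add("s3", "1", 250, 480)
        f = allele_frequencies(gm, gm.samples, mask)
        covered = mask.cell_mask(gm)
        for j in range(40):
            alleles = []
            for i in range(11):
                if d[i, j] != MISSING and not covered[i, j]:
                    alleles += [d[i, j]]
            if alleles:
                assert f.p_alt[j] == pytest.approx(sum(alleles) / (2 * len(alleles)))
            else:
                assert np.isnan(f.p_alt[j])


class TestDiversity:
    def test_closed_forms(self):
        # all-het locus: Ho=1, He=0.5, Fw=-1; p=0.5 gives maximal He
        gm = make_gm([[1, 1], [1, 1]])
        div = locus_diversity(gm, gm.samples)
        assert list(div["Ho"]) == [1.0, 1.0]
        assert list(div["He"]) == [0.5, 0.5]
        assert list(div["Fw"]) == [-1.0, -1.0]

    def test_monomorphic_fw_undefined(self):
        gm = make_gm([[0], [0]])
        div = locus_diversity(gm, gm.samples)
        assert div["He"].iloc[0] == 0 and np.isnan(div["Fw"].iloc[0])

    def test_random_locus_hand_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.choice([0, 1, 2], size=(20, 5))
        gm = make_gm(d)
        div = locus_diversity(gm, gm.samples)
        for j in range(5):
            col = d[:, j]
            ho = (col == 1).mean()
            p = col.sum() / 40
            he = 1 - p**2 - (1 - p) ** 2
            assert div["Ho"].iloc[j] == pytest.approx(ho)
            assert div["He"].iloc[j] == pytest.approx(he)
            if he > 0:
                assert div["Fw"].iloc[j] == pytest.approx(1 - ho / he)

    def test_hwe_simulation_recovers_fw_zero(self):
        rng = np.random.default_rng(8)
        p = 0.3
        d = (rng.random((500, 50)) < p).astype(int) + (
            rng.random((500, 50)) < p
        ).astype(int)
        gm = make_gm(d)
        fw = locus_diversity(gm, gm.samples)["Fw"]
        assert abs(fw.mean()) < 0.05


class TestSampleHeterozygosity:
    def test_missing_excluded(self):
        gm = make_gm([[1, 0, 2, MISSING]])
        assert sample_heterozygosity(gm, "s0") == pytest.approx(1 / 3)

    def test_all_het(self):
        gm = make_gm([[1, 1, 1]])
        assert sample_heterozygosity(gm, "s0") == 1.0

    def test_all_missing_undefined(self):
        gm = make_gm([[MISSING, MISSING]])
        assert np.isnan(sample_heterozygosity(gm, "s0"))


class TestNeiGst:
    def test_closed_forms(self):
        assert nei_gst([1.0], [0.0])[0] == 1.0  # fixed alternative alleles
        assert nei_gst([0.3], [0.3])[0] == 0.0  # identical frequencies
        # hand evaluation: He_a = He_b = 0.18, He_tot = 0.5
        assert nei_gst([0.9], [0.1])[0] == pytest.approx(0.64)

    def test_undefined_when_monomorphic_pooled(self):
        assert np.isnan(nei_gst([0.0], [0.0])[0])
        assert np.isnan(nei_gst([np.nan], [0.5])[0])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_bounded_and_symmetric(self, pa, pb):
        g1 = nei_gst([pa], [pb])[0]
        g2 = nei_gst([pb], [pa])[0]
        if np.isnan(g1):
            assert np.isnan(g2)
        else:
            assert 0.0 <= g1 <= 1.0
            assert g1 == pytest.approx(g2)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.01, 0.99, allow_nan=False))
    def test_no_differentiation_is_zero(self, p):
        assert nei_gst([p], [p])[0] == pytest.approx(0.0, abs=1e-12)


class TestDissimilarity:
    def test_simple_matching_cases(self):
        gm = make_gm([[0, 0], [2, 2], [1, 0]])
        assert simple_matching_dissimilarity(gm, "s0", "s0") == 0.0
        assert simple_matching_dissimilarity(gm, "s0", "s1") == 1.0  # no shared allele
        # single differing locus ref/ref vs ref/alt -> m=1 -> contributes 0.5
        gm2 = make_gm([[0], [1]])
        assert simple_matching_dissimilarity(gm2, "s0", "s1") == 0.5

    def test_euclidean_cases_and_oracle(self):
        gm = make_gm([[0], [2]])
        assert euclidean_dissimilarity(gm, "s0", "s0") == 0.0
        assert euclidean_dissimilarity(gm, "s0", "s1") == 2.0
        rng = np.random.default_rng(9)
        d = rng.choice([0, 1, 2], size=(2, 5))
        gm = make_gm(d)
        exp = np.sqrt(((d[0] - d[1]) ** 2).sum())
        assert euclidean_dissimilarity(gm, "s0", "s1") == pytest.approx(exp)

    def test_no_pairwise_complete_loci_undefined(self):
        gm = make_gm([[MISSING, 1], [0, MISSING]])
        assert np.isnan(simple_matching_dissimilarity(gm, "s0", "s1"))

    def test_matrix_symmetric_zero_diagonal(self, tmp_path):
        rng = np.random.default_rng(10)
        gm = make_gm(rng.choice([0, 1, 2, MISSING], size=(5, 30)))
        dm = dissimilarity_matrix(gm, "SIMPLE_MATCHING")
        np.testing.assert_allclose(dm.d, dm.d.T)
        assert (np.diag(dm.d) == 0).all()
        dm.write_tsv(tmp_path / "d.tsv")
        assert (tmp_path / "d.tsv").read_text().startswith("sample\t")


class TestCentroidSimilarity:
    def test_single_sample_centroid_equals_dosage_half(self):
        gm = make_gm([[0, 1, 2]])
        c = taxon_centroid(gm, ["s0"])
        np.testing.assert_allclose(c.p_alt, [0.0, 0.5, 1.0])

    def test_two_sample_centroid(self):
        gm = make_gm([[0], [2]])
        assert taxon_centroid(gm, gm.samples).p_alt[0] == 0.5

    def test_centroid_equals_allele_frequencies_with_mask(self):
        rng = np.random.default_rng(11)
        gm = make_gm(rng.choice([0, 1, 2, MISSING], size=(6, 20)))
        mask = MaskSet()
        mask.add("s1", "1", 100, 180)
        c = taxon_centroid(gm, gm.samples, mask)
        f = allele_frequencies(gm, gm.samples, mask)
        np.testing.assert_array_equal(c.p_alt, f.p_alt)

    def test_similarity_values(self):
        gm = make_gm([[2, 2, 1]])
        c_perfect = taxon_centroid(make_gm([[2, 0, 1]]), ["s0"])
        s = similarity_to_centroid(gm, "s0", c_perfect)
        assert s[0] == 1.0  # alt/alt vs centroid p_alt=1
        assert s[1] == 0.0  # alt/alt vs centroid p_alt=0
        assert s[2] == 0.5  # het vs centroid p_alt=0.5

    def test_s_equals_one_minus_simple_matching_on_degenerate_centroid(self):
        # against a single homozygous genotype as centroid, S reduces to 1 - d
        # (a heterozygous centroid call gives expected matching 0.5, not the
        # identity matching 1, so the reduction is exact for hom calls only)
        rng = np.random.default_rng(12)
        d = rng.choice([0, 1, 2], size=(2, 25))
        d[1] = rng.choice([0, 2], size=25)
        gm = make_gm(d)
        c = taxon_centroid(gm, ["s1"])
        s = similarity_to_centroid(gm, "s0", c)
        dis = simple_matching_dissimilarity(gm, "s0", "s1")
        assert s.mean() == pytest.approx(1 - dis)

    def test_monomorphic_reference_identical_sample(self):
        gm = make_gm([[0, 2, 0], [0, 2, 0], [0, 2, 0]])
        c = taxon_centroid(gm, ["s0", "s1"])
        np.testing.assert_allclose(similarity_to_centroid(gm, "s2", c), 1.0)
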