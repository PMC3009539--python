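import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pol2prom.features import (
    FEATURE_NAMES,
    SequenceWindow,
    cage_feature,
    composition_features,
    count_kmers,
    extract_features,
    feature_matrix,
    pooled_tpm,
    property_feature,
    reverse_complement,
    signal_features,
    window_tpm_profile,
)
from pol2prom.scales import PropertyScale, all_kmers, builtin_scales, constant_scale

dna = st.text(alphabet="ACGTN", min_size=4, max_size=60)


def brute_force_kmers(seq, k):
    counts = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


class TestCountKmers:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AAA", 2, {"AA": 2}),
            ("CGCG", 2, {"CG": 2, "GC": 1}),
            ("ANA", 2, {}),  # both dinucleotide windows contain N
        ],
    )
    def test_examples(self, seq, k, expected):
        assert count_kmers(seq, k).counts == expected

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            count_kmers("AC", 3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(250):
            n = int(rng.integers(4, 40))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.23] * 4 + [0.08]))
            for k in (1, 2, 3, 4):
                assert count_kmers(seq, k).counts == brute_force_kmers(seq, k)


class TestComposition:
    def test_uniform_repeat(self):
        feats = composition_features("ACGT" * 125)
        for base in "acgt":
            assert feats[f"{base}_fraction"] == 0.25
        assert feats["purpyr_fraction"] == 0
        assert feats["amke_fraction"] == 0
        assert feats["west_fraction"] == 0

    def test_homopolymer(self):
        feats = composition_features("A" * 500)
        assert feats["a_fraction"] == 1.0
        assert feats["cpg1"] == feats["cpg2"] == feats["cpg3"] == 0.0

    def test_cpg1_hand_count(self):
        # "CGCG": nCG=2, nGC=1 -> (2*2 + 2*1)/3
        assert composition_features("CGCG")["cpg1"] == pytest.approx(2.0)

    def test_cpg2_single_window(self):
        # "ACG": the only trinucleotide is ACG with weight 1, L-2 = 1
        assert composition_features("ACG")["cpg2"] == pytest.approx(1.0)

    def test_cpg3_weighted_term(self):
        # "CAG" carries weight 4 in the 8-term sum
        assert composition_features("CAG")["cpg3"] == pytest.approx(4.0)

    @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=120))
    @settings(max_examples=60, deadline=None)
    def test_fraction_identities(self, seq):
        f = composition_features(seq)
        total = sum(f[f"{b}_fraction"] for b in "acgt")
        assert total == pytest.approx(1.0)
        assert f["purpyr_fraction"] + f["amke_fraction"] + f["west_fraction"] == (
            pytest.approx(4 * f["a_fraction"] - 1)
        )

    @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=120))
    @settings(max_examples=60, deadline=None)
    def test_reverse_complement_symmetries(self, seq):
        f, r = composition_features(seq), composition_features(reverse_complement(seq))
        assert r["west_fraction"] == pytest.approx(f["west_fraction"])
        assert r["cpg1"] == pytest.approx(f["cpg1"])
        assert r["purpyr_fraction"] == pytest.approx(-f["purpyr_fraction"])

    def test_n_counts_nothing_but_length_kept(self):
        f = composition_features("ANNNA")
        assert f["a_fraction"] == pytest.approx(2 / 5)


class TestPropertyFeature:
    def test_constant_scale_gives_constant(self):
        for k in (1, 2, 3):
            assert property_feature("ACGTACGTAC", constant_scale("c", k, 2.5)) == 2.5

    def test_hand_computed_dinucleotide_mean(self):
        values = {x: 0.0 for x in all_kmers(2)}
        values["AA"] = 1.0
        scale = PropertyScale("p", 2, values, synthetic=True)
        assert property_feature("AAA", scale) == pytest.approx(1.0)  # 2 AA / 2 windows

        values = {x: 0.0 for x in all_kmers(2)}
        values.update({"AC": 1.0, "CG": 2.0, "GT": 3.0})
        scale = PropertyScale("p", 2, values, synthetic=True)
        assert property_feature("ACGT", scale) == pytest.approx(2.0)

    def test_linearity_in_scale(self):
        rng = np.random.default_rng(3)
        values = {x: float(v) for x, v in zip(all_kmers(2), rng.normal(size=16))}
        scale = PropertyScale("p", 2, values, synthetic=True)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        assert property_feature(seq, scale.scaled(2.0)) == pytest.approx(
            2.0 * property_feature(seq, scale)
        )

    def test_all_n_window_is_zero(self):
        assert property_feature("NNNNN", constant_scale("c", 2, 9.0)) == 0.0

    def test_incomplete_scale_rejected(self):
        with pytest.raises(ValueError):
            PropertyScale("bad", 2, {"AA": 1.0})


class TestSignalFeatures:
    def test_uniform_coverage_ratio_one(self, uniform_track):
        track = uniform_track([7] * 500, library_size=10_000)
        tpm = track.tpm_profile("chr1", 0, 500)
        avg, mx, ratio = signal_features(tpm)
        assert ratio == pytest.approx(1.0)
        assert avg == pytest.approx(mx)

    def test_single_base_spike_closed_form(self, uniform_track):
        lib, h, L = 2_000_000, 40, 500
        cov = np.zeros(L, dtype=int)
        cov[123] = h
        track = uniform_track(cov, library_size=lib)
        avg, mx, ratio = signal_features(track.tpm_profile("chr1", 0, L))
        assert mx == pytest.approx(h * 1e6 / lib)
        assert avg == pytest.approx(h * 1e6 / (lib * L))
        assert ratio == pytest.approx(L)

    def test_zero_coverage_degenerate(self, uniform_track):
        track = uniform_track([0] * 100, library_size=10)
        assert signal_features(track.tpm_profile("chr1", 0, 100)) == (0.0, 0.0, 0.0)

    def test_cage_total(self, uniform_track):
        cov = np.zeros(600, dtype=int)
        cov[100:110] = 1  # 10 tags inside the window
        cov[550] = 99  # outside
        track = uniform_track(cov, library_size=1_000_000, assay="cage")
        assert cage_feature(track.tpm_profile("chr1", 0, 500)) == pytest.approx(10.0)
        assert cage_feature(track.tpm_profile("chr1", 200, 300)) == 0.0

    def test_missing_chromosome_errors(self, uniform_track):
        track = uniform_track([1] * 10)
        win = SequenceWindow(seq="A" * 10, chrom="chrX", start=0, end=10)
        with pytest.raises(KeyError):
            window_tpm_profile(win, track)

    def test_tpm_invariant_to_depth_scaling(self, uniform_track):
        cov = np.array([0, 3, 1, 0, 5, 2, 0, 0, 1, 4])
        a = uniform_track(cov, library_size=1000)
        b = uniform_track(cov * 3, library_size=3000)
        np.testing.assert_allclose(
            a.tpm_profile("chr1", 0, 10), b.tpm_profile("chr1", 0, 10)
        )


class TestExtractFeatures:
    @pytest.fixture()
    def scales(self):
        return [constant_scale(name, k, 1.0) for name, k in
                __import__("pol2prom.scales", fromlist=["PHYSCHEM_PROPERTIES"])
                .PHYSCHEM_PROPERTIES.items()]

    def test_componentwise_against_hand_values(self, scales, uniform_track):
        seq = "ACGT" * 125
        win = SequenceWindow(seq=seq, chrom="chr1", start=0, end=500)
        cov = np.zeros(500, dtype=int)
        cov[250] = 10
        polii = uniform_track(cov, library_size=1_000_000)
        h3k = uniform_track(np.ones(500, dtype=int), library_size=1_000_000,
                            assay="h3k4me3")
        cage = uniform_track(cov * 2, library_size=1_000_000, assay="cage")
        fv = extract_features(win, scales, [polii], [h3k], [cage])
        assert fv["a_fraction"] == 0.25
        assert fv["eiip"] == 1.0  # constant scale
        assert fv["cage_total_tpm"] == pytest.approx(20.0)
        assert fv["polII_max_tpm"] == pytest.approx(10.0)
        assert fv["polII_avg_tpm"] == pytest.approx(10.0 / 500)
        assert fv["polII_max_over_avg"] == pytest.approx(500.0)
        assert fv["h3k4me3_max_over_avg"] == pytest.approx(1.0)

    def test_all_n_window_with_empty_tracks(self, scales):
        win = SequenceWindow(seq="N" * 500, chrom="chr1", start=0, end=500)
        fv = extract_features(win, scales, allow_missing_assays=True)
        assert all(v == 0.0 for v in fv.values)

    def test_tpm_scale_invariance_in_vector(self, scales, uniform_track):
        win = SequenceWindow(seq="ACGT" * 125, chrom="chr1", start=0, end=500)
        cov = np.arange(500) % 5
        t1 = uniform_track(cov, library_size=1000)
        t2 = uniform_track(cov * 2, library_size=2000)
        fv1 = extract_features(win, scales, [t1], allow_missing_assays=True)
        fv2 = extract_features(win, scales, [t2], allow_missing_assays=True)
        assert fv1.values == fv2.values

    def test_missing_assay_errors_unless_allowed(self, scales):
        win = SequenceWindow(seq="ACGT" * 125, chrom="chr1", start=0, end=500)
        with pytest.raises(ValueError):
            extract_features(win, scales)

    def test_wrong_scale_set_rejected(self, uniform_track):
        win = SequenceWindow(seq="ACGT" * 125, chrom="chr1", start=0, end=500)
        with pytest.raises(ValueError):
            extract_features(win, [constant_scale("eiip", 1, 1.0)],
                             allow_missing_assays=True)

    def test_feature_matrix_column_order(self, scales):
        wins = [
            SequenceWindow(seq="ACGT" * 125, chrom="chr1", start=0, end=500),
            SequenceWindow(seq="A" * 500, chrom="chr1", start=600, end=1100),
        ]
        X = feature_matrix(wins, scales, allow_missing_assays=True)
        assert list(X.columns) == ["chrom", "start", "end", "strand"] + FEATURE_NAMES
        assert len(X) == 2


class TestSequenceWindow:
    def test_from_genome_minus_strand_revcomp(self):
        genome = {"chr1": "AACCGGTT"}
        win = SequenceWindow.from_genome(genome, "chr1", 2, 6, "-")
        assert win.seq == reverse_complement("CCGG")

    def test_padding_beyond_bounds(self):
        genome = {"chr1": "ACGT"}
        win = SequenceWindow.from_genome(genome, "chr1", -2, 6)
        assert win.seq == "NNACGTNN"
        assert win.L == 8

    def test_builtin_scales_complete(self):
        scales = builtin_scales()
        assert len(scales) == 22
        ks = {s.name: s.k for s in scales}
        assert ks["eiip"] == 1 and ks["trinuc_bendability"] == 3
        assert ks["tetranuc_flexibility"] == 4
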