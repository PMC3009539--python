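import numpy as np
import pytest

from pol2prom.dataset import (
    NONPROMOTER,
    PROMOTER,
    deduplicate_cross_tissue,
    gene_promoter_status,
    label_promoter_peaks,
    select_nonpromoter_peaks,
    split_train_test,
)
from pol2prom.genome_io import GeneModel, GenomicInterval, build_nonredundant_tss
from pol2prom.peaks import PeakCall


def peak(chrom, summit, half=150):
    return PeakCall(
        interval=GenomicInterval(chrom, summit - half, summit + half),
        summit=summit,
        tag_count=100,
        p_value=1e-9,
        fdr_q=1e-6,
    )


def gene(gid, chrom, start, end, strand, biotype="coding"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand), biotype)


@pytest.fixture()
def plus_catalog():
    return build_nonredundant_tss([gene("g", "chr1", 10_000, 20_000, "+")])


class TestPromoterLabeling:
    def test_summit_at_tss(self, plus_catalog):
        recs = label_promoter_peaks([peak("chr1", 10_000)], plus_catalog)
        assert len(recs) == 1
        w = recs[0].window
        assert (w.start, w.end, w.strand) == (9_700, 10_200, "+")
        assert recs[0].label == PROMOTER

    def test_summit_just_outside_upstream_bound(self, plus_catalog):
        assert label_promoter_peaks([peak("chr1", 9_699)], plus_catalog) == []
        assert len(label_promoter_peaks([peak("chr1", 9_700)], plus_catalog)) == 1

    def test_minus_strand_upstream_is_rightward(self):
        cat = build_nonredundant_tss([gene("g", "chr1", 5_000, 10_001, "-")])
        # TSS at 10,000; +250 rightward is upstream within -300
        recs = label_promoter_peaks([peak("chr1", 10_250)], cat)
        assert len(recs) == 1
        assert recs[0].window.strand == "-"

    def test_one_record_even_with_two_reachable_tss(self):
        cat = build_nonredundant_tss(
            [gene("a", "chr1", 10_000, 20_000, "+"), gene("b", "chr1", 10_100, 20_000, "+")]
        )
        recs = label_promoter_peaks([peak("chr1", 10_050)], cat)
        assert len(recs) == 1


class TestNonpromoterSelection:
    def setup_method(self):
        self.genes = [gene("g", "chr1", 10_000, 20_000, "+")]
        self.catalog = build_nonredundant_tss(self.genes)

    def test_internal_peak_of_bound_gene_selected(self):
        peaks = [peak("chr1", 10_000), peak("chr1", 15_000)]
        status = gene_promoter_status(self.genes, peaks)
        assert status["g"] is True
        recs = select_nonpromoter_peaks(peaks, self.genes, status,
                                        tss_catalog=self.catalog)
        assert len(recs) == 1
        assert recs[0].label == NONPROMOTER
        w = recs[0].window
        assert 10_000 <= w.start and w.end <= 20_000  # inside host gene

    def test_unbound_host_promoter_excludes_internal_peak(self):
        peaks = [peak("chr1", 15_000)]
        status = gene_promoter_status(self.genes, peaks)
        assert status["g"] is False
        assert select_nonpromoter_peaks(peaks, self.genes, status,
                                        tss_catalog=self.catalog) == []

    def test_exclusion_track_removes_peak(self):
        peaks = [peak("chr1", 10_000), peak("chr1", 15_000)]
        status = gene_promoter_status(self.genes, peaks)
        est_5prime = [GenomicInterval("chr1", 14_900, 15_100)]
        recs = select_nonpromoter_peaks(
            peaks, self.genes, status, exclusion_tracks=[est_5prime],
            tss_catalog=self.catalog,
        )
        assert recs == []

    def test_peak_overlapping_tss_window_excluded(self):
        peaks = [peak("chr1", 10_000), peak("chr1", 10_150)]
        status = gene_promoter_status(self.genes, peaks)
        recs = select_nonpromoter_peaks(peaks, self.genes, status,
                                        tss_catalog=self.catalog)
        assert recs == []  # 10,150 is still within TSS -300/+200

    def test_shrinking_exclusions_never_decreases_count(self):
        rng = np.random.default_rng(1)
        peaks = [peak("chr1", 10_000)] + [
            peak("chr1", int(s)) for s in rng.integers(11_000, 19_000, size=20)
        ]
        status = gene_promoter_status(self.genes, peaks)
        wide = [GenomicInterval("chr1", 12_000, 18_000)]
        narrow = [GenomicInterval("chr1", 14_000, 15_000)]
        n_wide = len(
            select_nonpromoter_peaks(peaks, self.genes, status, [wide],
                                     tss_catalog=self.catalog)
        )
        n_narrow = len(
            select_nonpromoter_peaks(peaks, self.genes, status, [narrow],
                                     tss_catalog=self.catalog)
        )
        n_none = len(
            select_nonpromoter_peaks(peaks, self.genes, status,
                                     tss_catalog=self.catalog)
        )
        assert n_wide <= n_narrow <= n_none


def rec(label, chrom, start, tissue="t1"):
    from pol2prom.dataset import LabeledRecord

    return LabeledRecord(
        window=GenomicInterval(chrom, start, start + 500, "+"),
        label=label,
        tissue=tissue,
    )


class TestCrossTissueDedup:
    def test_identical_window_conflict_drops_nonpromoter(self):
        prom = [rec(PROMOTER, "chr1", 1_000, "liver")]
        nonprom = [rec(NONPROMOTER, "chr1", 1_000, "lung")]
        p, n = deduplicate_cross_tissue(prom, nonprom)
        assert len(p) == 1 and n == []

    def test_one_bp_overlap_drops(self):
        prom = [rec(PROMOTER, "chr1", 1_000)]
        nonprom = [rec(NONPROMOTER, "chr1", 1_499)]  # overlaps by 1 bp
        _, n = deduplicate_cross_tissue(prom, nonprom)
        assert n == []

    def test_adjacent_windows_kept(self):
        prom = [rec(PROMOTER, "chr1", 1_000)]
        nonprom = [rec(NONPROMOTER, "chr1", 1_500)]  # touching, no overlap
        _, n = deduplicate_cross_tissue(prom, nonprom)
        assert len(n) == 1


class TestSplit:
    def make_records(self, n_prom, n_nonprom):
        return [rec(PROMOTER, "chr1", 1_000 * i) for i in range(1, n_prom + 1)] + [
            rec(NONPROMOTER, "chr2", 1_000 * i) for i in range(1, n_nonprom + 1)
        ]

    def test_stratified_arithmetic(self):
        split = split_train_test(self.make_records(100, 400), 0.75, seed=1)
        train_prom = sum(r.label == PROMOTER for r in split.train)
        test_prom = sum(r.label == PROMOTER for r in split.test)
        assert (train_prom, test_prom) == (75, 25)
        assert (len(split.train), len(split.test)) == (375, 125)

    def test_same_seed_reproducible(self):
        records = self.make_records(40, 60)
        a = split_train_test(records, seed=9)
        b = split_train_test(records, seed=9)
        assert a.train == b.train and a.test == b.test

    def test_partition_disjoint_and_complete(self):
        records = self.make_records(30, 50)
        split = split_train_test(records, seed=2)
        ids = lambda rs: {(r.window.chrom, r.window.start, r.label) for r in rs}
        assert ids(split.train) & ids(split.test) == set()
        assert ids(split.train) | ids(split.test) == ids(records)


class TestBenchmarkProperties:
    def test_label_sets_disjoint_by_overlap(self, small_bench):
        from intervaltree import IntervalTree

        trees = {}
        for r in small_bench.promoter_records:
            trees.setdefault(r.window.chrom, IntervalTree()).addi(
                r.window.start, r.window.end
            )
        for r in small_bench.nonpromoter_records:
            t = trees.get(r.window.chrom)
            assert not (t and t[r.window.start : r.window.end])

    def test_nonpromoter_windows_inside_host_genes(self, small_bench):
        gene_spans = {}
        for g in small_bench.sim.genes:
            gene_spans.setdefault(g.chrom, []).append(g.interval)
        for r in small_bench.nonpromoter_records:
            assert any(
                iv.start <= r.window.start and r.window.end <= iv.end
                for iv in gene_spans[r.window.chrom]
            )

    def test_all_windows_are_500bp(self, small_bench):
        for r in small_bench.promoter_records + small_bench.nonpromoter_records:
            assert len(r.window) == 500
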