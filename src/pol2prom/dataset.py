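"""Labeled promoter / non-promoter record construction and splitting.

Labeling rules (all offsets strand-aware, relative to transcription
direction):

* a peak whose summit lies within -300/+200 bp of a known TSS is a
  **promoter** record; the record window is the -300/+200 window anchored
  on the summit, oriented by the matched TSS strand;
* a peak strictly inside a gene body, not within -300/+200 bp of *any*
  TSS, whose host transcript's own promoter window contains a Pol-II peak,
  and not intersecting any exclusion track (homolog promoters, EST 5'
  ends), is a **non-promoter** record;
* after pooling tissues, any non-promoter record overlapping (>= 1 bp) any
  promoter record from any tissue is dropped.

The "falls within" test uses the peak summit by default (a peak's width is
caller-dependent; its summit is a point); ``mode="overlap"`` switches to
any-overlap of the peak interval.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import (
    GeneModel,
    GenomicInterval,
    TssCatalog,
    TssEntry,
    window_around,
)
from .peaks import PeakCall

PROMOTER = "promoter"
NONPROMOTER = "nonpromoter"

#: the promoter window, in bp upstream/downstream of the anchor
PROMOTER_UP, PROMOTER_DOWN = 300, 200

__all__ = [
    "LabeledRecord",
    "DatasetSplit",
    "label_promoter_peaks",
    "gene_promoter_status",
    "select_nonpromoter_peaks",
    "deduplicate_cross_tissue",
    "split_train_test",
    "anchors_to_windows",
    "records_to_frame",
]


@dataclass(frozen=True)
class LabeledRecord:
    window: GenomicInterval
    label: str
    tissue: str = ""
    source_peak: str = ""

    def __post_init__(self) -> None:
        if self.label not in (PROMOTER, NONPROMOTER):
            raise ValueError(f"bad label {self.label!r}")


@dataclass
class DatasetSplit:
    train: list[LabeledRecord]
    test: list[LabeledRecord]
    seed: int


def _tss_window_tree(
    catalog: TssCatalog, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for entry in catalog:
        _, s, e, _ = window_around(entry.chrom, entry.tss, entry.strand, up, down)
        trees[entry.chrom].addi(s, e, entry)
    return trees


def _peak_anchor(peak: PeakCall, mode: str) -> tuple[int, int]:
    """Half-open span tested against TSS windows: the summit point or the
    whole peak interval."""
    if mode == "summit":
        return peak.summit, peak.summit + 1
    if mode == "overlap":
        return peak.interval.start, peak.interval.end
    raise ValueError("mode must be 'summit' or 'overlap'")


def _record_window(summit: int, chrom: str, strand: str) -> GenomicInterval:
    c, s, e, st = window_around(chrom, summit, strand, PROMOTER_UP, PROMOTER_DOWN)
    return GenomicInterval(c, max(s, 0), e, st)


def label_promoter_peaks(
    peaks: Sequence[PeakCall],
    tss_catalog: TssCatalog,
    mode: str = "summit",
    tissue: str = "",
) -> list[LabeledRecord]:
    """Promoter records: one per peak whose summit (or interval, in
    ``mode="overlap"``) hits the -300/+200 window of a known TSS.  The
    record window is anchored on the summit and oriented by the nearest
    matching TSS, so a peak reachable from several TSSs still yields a
    single record."""
    trees = _tss_window_tree(tss_catalog)
    records = []
    for pk in peaks:
        lo, hi = _peak_anchor(pk, mode)
        hits = trees[pk.chrom][lo:hi] if pk.chrom in trees else ()
        if not hits:
            continue
        entry = min(hits, key=lambda h: (abs(h.data.tss - pk.summit), h.data.tss)).data
        records.append(
            LabeledRecord(
                window=_record_window(pk.summit, pk.chrom, entry.strand),
                label=PROMOTER,
                tissue=tissue,
                source_peak=f"{pk.chrom}:{pk.summit}",
            )
        )
    return records


def gene_promoter_status(
    genes: Sequence[GeneModel], peaks: Sequence[PeakCall], mode: str = "summit"
) -> dict[str, bool]:
    """For each gene id: does its own -300/+200 TSS window contain a peak?
    A gene with several transcripts is bound if any transcript's promoter
    window is."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for pk in peaks:
        lo, hi = _peak_anchor(pk, mode)
        trees[pk.chrom].addi(lo, hi, pk)
    status: dict[str, bool] = {}
    for g in genes:
        _, s, e, _ = window_around(g.chrom, g.tss, g.strand, PROMOTER_UP, PROMOTER_DOWN)
        hit = bool(trees[g.chrom][s:e]) if g.chrom in trees else False
        status[g.gene_id] = status.get(g.gene_id, False) or hit
    return status


def anchors_to_windows(
    anchors: Iterable[tuple[str, int, str]],
    up: int = PROMOTER_UP,
    down: int = PROMOTER_DOWN,
) -> list[GenomicInterval]:
    """Expand anchor points (e.g. homolog-promoter TSSs, EST 5' ends) into
    -300/+200 exclusion windows."""
    out = []
    for chrom, pos, strand in anchors:
        c, s, e, st = window_around(chrom, pos, strand, up, down)
        out.append(GenomicInterval(c, max(s, 0), e, st))
    return out


def select_nonpromoter_peaks(
    peaks: Sequence[PeakCall],
    genes: Sequence[GeneModel],
    promoter_status: Mapping[str, bool],
    exclusion_tracks: Sequence[Sequence[GenomicInterval]] = (),
    tss_catalog: TssCatalog | None = None,
    mode: str = "summit",
    tissue: str = "",
) -> list[LabeledRecord]:
    """Non-promoter records per the four rules in the module docstring.

    ``tss_catalog`` defaults to the TSSs of ``genes``; pass the full
    non-redundant catalog when it is richer than the gene list.  The record
    window must additionally lie entirely within the host gene.
    """
    if tss_catalog is None:
        from .genome_io import build_nonredundant_tss

        tss_catalog = build_nonredundant_tss(genes)
    tss_trees = _tss_window_tree(tss_catalog)

    gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        gene_trees[g.chrom].addi(g.interval.start, g.interval.end, g)

    excl_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for trk in exclusion_tracks:
        for iv in trk:
            excl_trees[iv.chrom].addi(iv.start, iv.end, iv)

    records = []
    for pk in peaks:
        lo, hi = _peak_anchor(pk, mode)
        chrom = pk.chrom
        if chrom in tss_trees and tss_trees[chrom][lo:hi]:
            continue  # overlaps a known TSS window
        if chrom in excl_trees and excl_trees[chrom][lo:hi]:
            continue  # homolog promoter / EST 5' exclusion
        candidates = [
            h.data
            for h in (gene_trees[chrom][pk.summit] if chrom in gene_trees else ())
            if promoter_status.get(h.data.gene_id, False)
        ]
        # the record window is oriented by the host gene and must lie
        # entirely within it
        viable = []
        for g in candidates:
            w = _record_window(pk.summit, chrom, g.strand)
            if g.interval.start <= w.start and w.end <= g.interval.end:
                viable.append((g, w))
        if not viable:
            continue
        host, window = min(viable, key=lambda gw: (gw[0].interval.start, gw[0].gene_id))
        records.append(
            LabeledRecord(
                window=window,
                label=NONPROMOTER,
                tissue=tissue,
                source_peak=f"{chrom}:{pk.summit}",
            )
        )
    return records


def deduplicate_cross_tissue(
    promoter_records: Sequence[LabeledRecord],
    nonpromoter_records: Sequence[LabeledRecord],
) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    """Drop every non-promoter record whose window overlaps (>= 1 bp) any
    promoter record from any tissue; the promoter set is untouched."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rec in promoter_records:
        trees[rec.window.chrom].addi(rec.window.start, rec.window.end)
    kept = [
        rec
        for rec in nonpromoter_records
        if not (
            rec.window.chrom in trees
            and trees[rec.window.chrom][rec.window.start : rec.window.end]
        )
    ]
    return list(promoter_records), kept


def split_train_test(
    records: Sequence[LabeledRecord],
    train_fraction: float = 0.75,
    seed: int = 0,
    train_counts: Mapping[str, int] | None = None,
) -> DatasetSplit:
    """Random stratified split.  ``train_counts`` (label -> n) overrides the
    fraction per class, for replaying a bookkeeping layout exactly."""
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[LabeledRecord]] = defaultdict(list)
    for rec in records:
        by_label[rec.label].append(rec)
    train: list[LabeledRecord] = []
    test: list[LabeledRecord] = []
    for label in sorted(by_label):
        group = by_label[label]
        idx = rng.permutation(len(group))
        if train_counts is not None:
            n_train = int(train_counts[label])
        else:
            n_train = int(round(train_fraction * len(group)))
        if not 0 <= n_train <= len(group):
            raise ValueError(f"train count {n_train} out of range for {label}")
        train.extend(group[i] for i in idx[:n_train])
        test.extend(group[i] for i in idx[n_train:])
    return DatasetSplit(train=train, test=test, seed=seed)


def records_to_frame(records: Sequence[LabeledRecord]) -> pd.DataFrame:
    """Manifest table (also the BED name payload): window, label, tissue,
    source peak."""
    return pd.DataFrame(
        {
            "chrom": [r.window.chrom for r in records],
            "start": [r.window.start for r in records],
            "end": [r.window.end for r in records],
            "strand": [r.window.strand for r in records],
            "label": [r.label for r in records],
            "tissue": [r.tissue for r in records],
            "source_peak": [r.source_peak for r in records],
        }
    )
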