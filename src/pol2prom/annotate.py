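"""Genome-wide promoter annotation from classified Pol-II peaks.

Every Pol-II peak is scored twice — the -300/+200 window around its summit
read on the forward strand, and the strand-mirrored window read on the
reverse complement.  Calls above threshold are kept; when both strands of
one peak are called, the two windows merge into a single promoter (union
interval, max score).  Promoters are then assigned to the nearest gene
whose TSS lies within -2 kb/+500 bp (strand-aware, boundaries inclusive)
of the peak summit; unassigned calls are potential novel promoters.
Finally, assigned calls from multiple samples are clustered per gene by
single-linkage >= 1 bp interval overlap, each cluster counting as one
distinct (possibly alternative) promoter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PROMOTER_DOWN, PROMOTER_UP
from .features import SequenceWindow, feature_matrix
from .genome_io import (
    GenomicInterval,
    TagTrack,
    TssCatalog,
    TssEntry,
    relative_offset,
    window_around,
)
from .peaks import PeakCall

__all__ = [
    "PromoterCall",
    "GenePromoterSummary",
    "scan_peaks",
    "merge_strand_calls",
    "assign_to_genes",
    "combine_samples",
    "summarize_alternative_promoters",
]


@dataclass(frozen=True)
class PromoterCall:
    interval: GenomicInterval
    score: float
    strands_supporting: frozenset
    sample_id: str
    peak_id: str
    summit: int


@dataclass(frozen=True)
class GenePromoterSummary:
    gene_id: str
    biotype: str
    promoter_count: int
    intervals: tuple[GenomicInterval, ...]


def _strand_windows(peak: PeakCall) -> dict[str, tuple[int, int]]:
    out = {}
    for strand in "+-":
        _, s, e, _ = window_around(
            peak.chrom, peak.summit, strand, PROMOTER_UP, PROMOTER_DOWN
        )
        out[strand] = (s, e)
    return out


def scan_peaks(
    peaks: Sequence[PeakCall],
    results,
    genome: Mapping[str, str],
    scales,
    tracks: Mapping[str, Sequence[TagTrack]],
    threshold: float = 0.5,
    sample_id: str = "",
    pooling: str = "sum",
    merge: bool = True,
) -> list[PromoterCall]:
    """Score the -300/+200 window around each peak summit on both strands
    with a fitted :class:`~pol2prom.classify.PromoterClassifierResults`.

    ``tracks`` maps assay name ('polII', 'h3k4me3', 'cage') to its track
    list.  Windows that cross chromosome ends are N-padded.  With
    ``merge=True`` (default) both-strand calls on one peak are collapsed
    via :func:`merge_strand_calls`.
    """
    windows, keys = [], []
    for i, pk in enumerate(peaks):
        for strand, (s, e) in _strand_windows(pk).items():
            windows.append(
                SequenceWindow.from_genome(genome, pk.chrom, s, e, strand)
            )
            keys.append((i, strand))
    if not windows:
        return []
    X = feature_matrix(
        windows,
        scales,
        polII_tracks=tracks.get("polII", ()),
        h3k4me3_tracks=tracks.get("h3k4me3", ()),
        cage_tracks=tracks.get("cage", ()),
        pooling=pooling,
        allow_missing_assays=True,
    )
    scores = results.predict_proba(X[results.feature_names])

    per_peak: dict[int, list[PromoterCall]] = defaultdict(list)
    for (i, strand), win, score in zip(keys, windows, scores):
        if score < threshold:
            continue
        pk = peaks[i]
        per_peak[i].append(
            PromoterCall(
                interval=GenomicInterval(win.chrom, max(win.start, 0), win.end, strand),
                score=float(score),
                strands_supporting=frozenset(strand),
                sample_id=sample_id,
                peak_id=f"{pk.chrom}:{pk.summit}",
                summit=pk.summit,
            )
        )
    calls = [c for i in sorted(per_peak) for c in per_peak[i]]
    return merge_strand_calls(calls) if merge else calls


def merge_strand_calls(calls: Sequence[PromoterCall]) -> list[PromoterCall]:
    """Collapse per-strand calls of the same source peak: when both the
    '+' and '-' windows were called, the merged promoter spans their
    union, carries the max score and both supporting strands."""
    by_peak: dict[tuple[str, str], list[PromoterCall]] = defaultdict(list)
    for c in calls:
        by_peak[(c.sample_id, c.peak_id)].append(c)
    merged = []
    for key in sorted(by_peak):
        grp = by_peak[key]
        if len(grp) == 1:
            merged.append(grp[0])
            continue
        iv = GenomicInterval(
            grp[0].interval.chrom,
            min(c.interval.start for c in grp),
            max(c.interval.end for c in grp),
            ".",
        )
        merged.append(
            PromoterCall(
                interval=iv,
                score=max(c.score for c in grp),
                strands_supporting=frozenset().union(*(c.strands_supporting for c in grp)),
                sample_id=grp[0].sample_id,
                peak_id=grp[0].peak_id,
                summit=grp[0].summit,
            )
        )
    return merged


def assign_to_genes(
    calls: Sequence[PromoterCall],
    tss_catalog: TssCatalog,
    up: int = 2000,
    down: int = 500,
) -> tuple[list[tuple[PromoterCall, TssEntry]], list[PromoterCall]]:
    """Assign each call to a gene iff its source-peak summit lies within
    -``up``/+``down`` bp (strand-aware, inclusive at both boundaries) of
    the gene's TSS; several candidates resolve to the nearest TSS, ties to
    the smaller coordinate.  Returns (assigned, unassigned)."""
    by_chrom: dict[str, list[TssEntry]] = defaultdict(list)
    for e in tss_catalog:
        by_chrom[e.chrom].append(e)
    for lst in by_chrom.values():
        lst.sort(key=lambda e: e.tss)
    tss_pos = {c: np.array([e.tss for e in lst]) for c, lst in by_chrom.items()}

    assigned, unassigned = [], []
    span = max(up, down)
    for call in calls:
        cands = []
        entries = by_chrom.get(call.interval.chrom, ())
        if entries:
            pos = tss_pos[call.interval.chrom]
            lo = int(np.searchsorted(pos, call.summit - span, side="left"))
            hi = int(np.searchsorted(pos, call.summit + span, side="right"))
            for e in entries[lo:hi]:
                d = relative_offset(call.summit, e.tss, e.strand)
                if -up <= d <= down:
                    cands.append((abs(d), e.tss, e))
        if cands:
            cands.sort(key=lambda t: (t[0], t[1]))
            assigned.append((call, cands[0][2]))
        else:
            unassigned.append(call)
    return assigned, unassigned


def combine_samples(
    assigned_per_sample: Sequence[Sequence[tuple[PromoterCall, TssEntry]]],
    biotypes: Mapping[str, str] | None = None,
) -> dict[str, GenePromoterSummary]:
    """Cluster assigned calls per gene across samples by single-linkage
    >= 1 bp interval overlap; each cluster is one distinct promoter.  The
    result is order-invariant in the sample list."""
    per_gene: dict[str, list[PromoterCall]] = defaultdict(list)
    gene_biotype: dict[str, str] = {}
    for sample in assigned_per_sample:
        for call, entry in sample:
            for gid in entry.gene_ids:
                per_gene[gid].append(call)
                gene_biotype.setdefault(gid, entry.biotype)
    if biotypes:
        gene_biotype.update(biotypes)

    out = {}
    for gid in sorted(per_gene):
        ivs = sorted(
            (c.interval for c in per_gene[gid]), key=lambda iv: (iv.start, iv.end)
        )
        clusters: list[GenomicInterval] = []
        cur_start, cur_end, chrom = ivs[0].start, ivs[0].end, ivs[0].chrom
        for iv in ivs[1:]:
            if iv.start < cur_end:  # >= 1 bp overlap -> same cluster
                cur_end = max(cur_end, iv.end)
            else:
                clusters.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        clusters.append(GenomicInterval(chrom, cur_start, cur_end))
        out[gid] = GenePromoterSummary(
            gene_id=gid,
            biotype=gene_biotype.get(gid, "coding"),
            promoter_count=len(clusters),
            intervals=tuple(clusters),
        )
    return out


def summarize_alternative_promoters(
    gene_summaries: Mapping[str, GenePromoterSummary] | Sequence[GenePromoterSummary],
) -> pd.DataFrame:
    """Per biotype: genes with 1, 2 and >= 3 distinct promoters and the
    fraction with >= 2 (alternative-promoter usage)."""
    if isinstance(gene_summaries, Mapping):
        gene_summaries = list(gene_summaries.values())
    rows = defaultdict(lambda: [0, 0, 0])
    for gs in gene_summaries:
        bucket = 0 if gs.promoter_count == 1 else (1 if gs.promoter_count == 2 else 2)
        rows[gs.biotype][bucket] += 1
    out = []
    for biotype in sorted(rows):
        one, two, three_plus = rows[biotype]
        total = one + two + three_plus
        out.append(
            {
                "biotype": biotype,
                "one_promoter": one,
                "two_promoters": two,
                "three_or_more": three_plus,
                "total_genes": total,
                "fraction_multi": (two + three_plus) / total if total else 0.0,
            }
        )
    return pd.DataFrame(out)
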