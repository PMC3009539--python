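"""Poisson-background peak calling at a target FDR.

Sliding windows (default 500 bp every 50 bp) are scored against a single
genome-wide background rate ``lambda = library_size * window_bp /
effective_genome_size`` with a Poisson upper-tail p-value.  p-values are
converted to q-values with Benjamini-Hochberg across all windows, windows
with q <= fdr are kept, and overlapping/adjacent significant windows are
merged into peaks.  Each peak carries its summit (position of maximum
coverage, leftmost on ties), total tag count, and the best window p/q.

Peaks may also be imported from an external BED, bypassing the caller
entirely — the downstream dataset and annotation stages only need
:class:`PeakCall` objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomicInterval, TagTrack

__all__ = [
    "PeakCall",
    "poisson_tail",
    "bh_qvalues",
    "call_peaks",
    "significant_region_mask",
    "write_peaks_bed",
    "read_peaks_bed",
]


@dataclass(frozen=True)
class PeakCall:
    interval: GenomicInterval
    summit: int
    tag_count: int
    p_value: float
    fdr_q: float

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError("summit must lie inside the peak interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def poisson_tail(count: int | np.ndarray, lam: float) -> float | np.ndarray:
    """Upper tail P(X >= count) for X ~ Poisson(lam), computed via the
    survival function for numerical stability; P(X >= 0) = 1."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    out = stats.poisson.sf(np.asarray(count) - 1, lam)
    return float(out) if np.isscalar(count) else out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up adjustment)."""
    p = np.asarray(p, dtype=np.float64)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(q, 1.0)


def call_peaks(
    track: TagTrack,
    window_bp: int = 500,
    step_bp: int = 50,
    fdr: float = 0.001,
    effective_genome_size: int | None = None,
) -> list[PeakCall]:
    """Identify tag-enriched regions at the target FDR (see module doc)."""
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    if track.total_tags() == 0:
        return []
    egs = effective_genome_size or sum(len(a) for a in track.coverage.values())
    lam = track.library_size * window_bp / egs

    win_chrom: list[str] = []
    win_start_all: list[np.ndarray] = []
    win_count_all: list[np.ndarray] = []
    for chrom in sorted(track.coverage):
        cov = track.coverage[chrom]
        if len(cov) < window_bp:
            continue
        cs = np.concatenate(([0], np.cumsum(cov, dtype=np.int64)))
        starts = np.arange(0, len(cov) - window_bp + 1, step_bp)
        counts = cs[starts + window_bp] - cs[starts]
        win_chrom.extend([chrom] * len(starts))
        win_start_all.append(starts)
        win_count_all.append(counts)
    if not win_start_all:
        return []
    starts = np.concatenate(win_start_all)
    counts = np.concatenate(win_count_all)
    chroms = np.array(win_chrom)

    # p-values via lookup on unique counts (counts are small integers)
    uniq, inv = np.unique(counts, return_inverse=True)
    pvals = poisson_tail(uniq, lam)[inv]
    qvals = bh_qvalues(pvals)
    sig = qvals <= fdr

    peaks: list[PeakCall] = []
    for chrom in sorted(set(chroms[sig])):
        m = sig & (chroms == chrom)
        s, p, q = starts[m], pvals[m], qvals[m]
        order = np.argsort(s)
        s, p, q = s[order], p[order], q[order]
        cov = track.coverage[chrom]
        i = 0
        while i < len(s):
            j = i
            end = s[i] + window_bp
            while j + 1 < len(s) and s[j + 1] <= end:
                j += 1
                end = max(end, s[j] + window_bp)
            region = cov[s[i] : end]
            summit = int(s[i] + int(np.argmax(region)))
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(chrom, int(s[i]), int(end)),
                    summit=summit,
                    tag_count=int(region.sum()),
                    p_value=float(p[i : j + 1].min()),
                    fdr_q=float(q[i : j + 1].min()),
                )
            )
            i = j + 1
    return peaks


def significant_region_mask(
    peaks: Sequence[PeakCall], chrom_sizes: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Boolean per-base mask, true exactly inside peak intervals."""
    mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for pk in peaks:
        iv = pk.interval
        if iv.chrom in mask:
            mask[iv.chrom][iv.start : min(iv.end, len(mask[iv.chrom]))] = True
    return mask


def write_peaks_bed(peaks: Sequence[PeakCall], path: str | Path) -> None:
    """BED6+ with summit offset, tag count, p-value and q-value columns."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{pk.tag_count}\t.\t"
                f"{pk.summit - iv.start}\t{pk.p_value:.6g}\t{pk.fdr_q:.6g}\n"
            )


def read_peaks_bed(path: str | Path) -> list[PeakCall]:
    """Read peaks written by :func:`write_peaks_bed`, or any BED where an
    optional 7th column gives the summit offset (default: interval midpoint)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            chrom, start, end = p[0], int(p[1]), int(p[2])
            count = int(float(p[4])) if len(p) > 4 else 0
            summit = start + (int(p[6]) if len(p) > 6 else (end - start) // 2)
            pval = float(p[7]) if len(p) > 7 else 1.0
            qval = float(p[8]) if len(p) > 8 else 1.0
            peaks.append(
                PeakCall(GenomicInterval(chrom, start, end), summit, count, pval, qval)
            )
    return peaks
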