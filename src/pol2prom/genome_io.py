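"""Coordinate types and plain-text genomics I/O.

All internal coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.  One-based table inputs are converted at the boundary by their
readers.  Strand-aware window arithmetic lives here so that every module
shares a single convention: "upstream" means smaller coordinates on ``+``
and larger coordinates on ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "TssEntry",
    "TssCatalog",
    "TagTrack",
    "window_around",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "build_nonredundant_tss",
    "read_tags",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def window_around(
    chrom: str, pos: int, strand: str, up: int, down: int
) -> tuple[str, int, int, str]:
    """Half-open window covering ``up`` bp upstream through ``down`` bp
    downstream of ``pos``, in transcription direction.

    On ``+`` (and ``.``) this is ``[pos - up, pos + down)``; on ``-`` the
    mirror image ``[pos - down + 1, pos + up + 1)``.  Returned as a plain
    tuple because the window may extend past chromosome bounds (callers pad
    with N or clip).
    """
    if strand == "-":
        return (chrom, pos - down + 1, pos + up + 1, strand)
    return (chrom, pos - up, pos + down, strand)


def relative_offset(pos: int, anchor: int, strand: str) -> int:
    """Signed offset of ``pos`` from ``anchor`` in transcription direction
    (negative = upstream)."""
    return anchor - pos if strand == "-" else pos - anchor


@dataclass(frozen=True)
class GeneModel:
    """One transcript/gene model; the TSS is the strand-aware 5' end."""

    gene_id: str
    interval: GenomicInterval
    biotype: str = "coding"
    source: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class TssEntry:
    gene_ids: tuple[str, ...]
    chrom: str
    tss: int
    strand: str
    biotype: str = "coding"
    sources: tuple[str, ...] = ()


@dataclass
class TssCatalog:
    """Non-redundant TSS list, deduplicated on (chrom, tss, strand)."""

    entries: list[TssEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [e.chrom for e in self.entries],
                "tss": [e.tss for e in self.entries],
                "strand": [e.strand for e in self.entries],
                "gene_ids": [";".join(e.gene_ids) for e in self.entries],
                "biotype": [e.biotype for e in self.entries],
                "sources": [";".join(e.sources) for e in self.entries],
            }
        )


def build_nonredundant_tss(*gene_lists: Iterable) -> TssCatalog:
    """Union of TSSs from one or more gene lists (or catalogs), collapsing
    entries identical on (chrom, tss, strand); gene ids and source labels
    accumulate.  Idempotent: feeding a catalog back in changes nothing.
    """
    merged: dict[tuple[str, int, str], dict] = {}
    n_in = 0
    for lst in gene_lists:
        items = lst.entries if isinstance(lst, TssCatalog) else lst
        for g in items:
            n_in += 1
            if isinstance(g, TssEntry):
                key = (g.chrom, g.tss, g.strand)
                ids, srcs, biotype = g.gene_ids, g.sources, g.biotype
            else:
                key = (g.chrom, g.tss, g.strand)
                ids, srcs, biotype = (g.gene_id,), (g.source,) if g.source else (), g.biotype
            slot = merged.setdefault(
                key, {"ids": set(), "sources": set(), "biotype": biotype}
            )
            slot["ids"].update(ids)
            slot["sources"].update(srcs)
    if n_in == 0 or not merged:
        raise ValueError("no TSS entries to merge")
    entries = [
        TssEntry(
            gene_ids=tuple(sorted(v["ids"])),
            chrom=k[0],
            tss=k[1],
            strand=k[2],
            biotype=v["biotype"],
            sources=tuple(sorted(v["sources"])),
        )
        for k, v in sorted(merged.items())
    ]
    return TssCatalog(entries)


# ---------------------------------------------------------------------------
# tag tracks
# ---------------------------------------------------------------------------


@dataclass
class TagTrack:
    """Per-base tag coverage for one sample with its library size.

    ``coverage`` maps chromosome -> integer array of tag counts per base.
    ``library_size`` is the total mapped tags used for TPM scaling; it is
    deliberately *not* recomputed when coverage is masked, so that TPM stays
    anchored to sequencing depth.
    """

    sample_id: str
    assay: str
    coverage: dict[str, np.ndarray]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for chrom, arr in self.coverage.items():
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")

    def total_tags(self) -> int:
        return int(sum(int(a.sum()) for a in self.coverage.values()))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.coverage.items()}

    def tpm_profile(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base TPM over ``[start, end)``; positions outside the
        chromosome contribute 0 (window padded, length preserved)."""
        if chrom not in self.coverage:
            raise KeyError(f"chromosome {chrom!r} absent from track {self.sample_id}")
        cov = self.coverage[chrom]
        out = np.zeros(end - start, dtype=np.float64)
        lo, hi = max(start, 0), min(end, len(cov))
        if lo < hi:
            out[lo - start : hi - start] = cov[lo:hi]
        return out * (1e6 / self.library_size)

    def masked(self, mask: Mapping[str, np.ndarray]) -> "TagTrack":
        """Zero coverage outside ``mask`` (per-chrom boolean arrays);
        library size is preserved."""
        cov = {}
        for chrom, arr in self.coverage.items():
            m = mask.get(chrom)
            cov[chrom] = arr * m.astype(arr.dtype) if m is not None else np.zeros_like(arr)
        return TagTrack(self.sample_id, self.assay, cov, self.library_size)


def read_tags(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "",
    assay: str = "polII",
    library_size: int | None = None,
    fmt: str | None = None,
) -> TagTrack:
    """Read a tag track from a BED of tag positions or a bedGraph of
    coverage.

    Format is inferred from the extension (``.bedgraph``/``.bdg`` =>
    coverage, else tag positions) unless ``fmt`` is given.  For tag-position
    BED each record adds one tag at its start base and ``library_size``
    defaults to the number of records; for bedGraph the 4th column is the
    per-base count over the interval and ``library_size`` defaults to the
    total coverage.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bedgraph" if path.suffix.lower() in (".bedgraph", ".bdg") else "bed"
    cov = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    total = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start = parts[0], int(parts[1])
            if chrom not in cov:
                continue
            if fmt == "bedgraph":
                end, value = int(parts[2]), float(parts[3])
                if value < 0:
                    raise ValueError(f"negative coverage in {path}: {line!r}")
                cov[chrom][start : min(end, len(cov[chrom]))] += int(round(value))
            else:
                if 0 <= start < len(cov[chrom]):
                    cov[chrom][start] += 1
                    total += 1
    if library_size is None:
        library_size = total if fmt == "bed" else int(sum(a.sum() for a in cov.values()))
    return TagTrack(sample_id or path.stem, assay, cov, library_size)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a dict keyed by record name; sequences are
    upper-cased, non-ACGT characters preserved as-is (typically N)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"chrom": 0, "strand": 1, "txStart": 2, "txEnd": 3, "name": 4, "biotype": 5}


def read_gene_table(
    path: str | Path,
    source_label: str = "",
    column_map: Mapping[str, int] | None = None,
    biotype: str = "coding",
    one_based: bool = False,
) -> list[GeneModel]:
    """Read a tab-delimited gene table into :class:`GeneModel` objects.

    Default column order is chrom, strand, txStart, txEnd, name[, biotype];
    override with ``column_map`` (field name -> 0-based column index) for
    UCSC-style layouts.  Malformed rows are skipped with a logged warning
    and the skip count is reported in the log.  Rows duplicated on
    (chrom, tss, strand, name) are collapsed.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    genes: dict[tuple, GeneModel] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                chrom = parts[cols["chrom"]]
                strand = parts[cols["strand"]]
                start = int(parts[cols["txStart"]]) - (1 if one_based else 0)
                end = int(parts[cols["txEnd"]])
                name = parts[cols["name"]]
                bt = (
                    parts[cols["biotype"]]
                    if cols.get("biotype") is not None and len(parts) > cols["biotype"]
                    else biotype
                )
                gene = GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    biotype=bt,
                    source=source_label,
                )
            except (IndexError, ValueError) as exc:
                skipped += 1
                log.warning("%s:%d skipped malformed row (%s)", path, lineno, exc)
                continue
            genes.setdefault((gene.chrom, gene.tss, gene.strand, gene.gene_id), gene)
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)
    return list(genes.values())


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write standard 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3-6 into a DataFrame with columns chrom, start, end, name,
    score, strand (missing columns filled with defaults)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            rows.append(
                {
                    "chrom": p[0],
                    "start": int(p[1]),
                    "end": int(p[2]),
                    "name": p[3] if len(p) > 3 else "",
                    "score": float(p[4]) if len(p) > 4 else 0.0,
                    "strand": p[5] if len(p) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def bed_intervals(frame: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in frame.itertuples()
    ]
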