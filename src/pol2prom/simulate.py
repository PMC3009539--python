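"""Fully synthetic genomes, gene catalogs and tag tracks.

The generator reproduces the statistical structure the classifier relies
on, so the whole pipeline can be exercised without any downloads:

* background sequence from a uniform base model; promoter windows
  (TSS -300/+200) resampled from a CpG-enriched first-order Markov model
  (the enrichment factor multiplies the odds of C->G and G->C steps);
* Pol-II tags Poisson-distributed around a background rate, with a strong
  bump over each promoter window, a weak linearly decaying 5'->3'
  gene-body component, and punctate "stalling" bumps inside gene bodies —
  the latter produce the distinct non-promoter peaks that elongating
  polymerase creates in real data;
* H3K4me3 enrichment over a -500/+1000 window at each TSS;
* CAGE tags concentrated within +-25 bp of each TSS;
* a configurable fraction of genes carries a second (alternative) TSS a
  few kb into the body, with its own promoter signal.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import PROMOTER_DOWN, PROMOTER_UP
from .genome_io import (
    GeneModel,
    GenomicInterval,
    TagTrack,
    TssCatalog,
    build_nonredundant_tss,
    window_around,
    write_bed,
    write_fasta,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Rates are Poisson means in tags per base.  The defaults are sized so
    that the end-to-end benchmark yields on the order of 500 promoter and
    2,000 non-promoter records — a desk-scale version of a multi-tissue
    Pol-II compendium — with peak power high enough that every true
    promoter is recovered by the 0.001-FDR caller.
    """

    seed: int = 0
    genome_length: int = 10_000_000
    n_chroms: int = 2
    n_genes: int = 420
    gene_length: tuple[int, int] = (8_000, 14_000)
    intergenic_gap: tuple[int, int] = (3_000, 13_000)
    edge_margin: int = 5_000
    alt_promoter_fraction: float = 0.25
    alt_tss_offset: tuple[int, int] = (2_500, 4_000)
    noncoding_fraction: float = 0.15
    # sequence model
    promoter_gc: float = 0.6
    cpg_enrichment: float = 3.0
    # Pol-II ChIP
    polII_background: float = 0.05
    polII_promoter: float = 0.8
    polII_body_5p: float = 0.03
    polII_body_3p: float = 0.0
    polII_stall_rate: float = 0.5
    polII_stall_width: int = 300
    polII_stalls_per_gene: float = 4.5
    polII_stall_spacing: int = 1_600
    # H3K4me3 ChIP
    h3k4me3_background: float = 0.05
    h3k4me3_promoter: float = 0.6
    # CAGE
    cage_background: float = 0.002
    cage_tss_tags: float = 150.0
    cage_tss_halfwidth: int = 25

    def __post_init__(self) -> None:
        for name in (
            "polII_background", "polII_promoter", "polII_body_5p", "polII_body_3p",
            "polII_stall_rate", "h3k4me3_background", "h3k4me3_promoter",
            "cage_background", "cage_tss_tags",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        min_span = self.gene_length[0] + self.intergenic_gap[0]
        if self.genome_length < self.n_genes * min_span:
            raise ValueError("genome too short for the requested gene count")


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    truth_promoters: list[GenomicInterval]  # TSS -300/+200 windows
    truth_tss: list[tuple[str, int, str, str]]  # chrom, pos, strand, gene_id
    config: SimulationConfig

    def catalog(self) -> TssCatalog:
        return build_nonredundant_tss(self.genes)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        rows = [
            (g.chrom, g.strand, g.interval.start, g.interval.end, g.gene_id, g.biotype)
            for g in self.genes
        ]
        pd.DataFrame(
            rows, columns=["chrom", "strand", "txStart", "txEnd", "name", "biotype"]
        ).to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
        write_bed(
            self.truth_promoters,
            outdir / "truth_promoters.bed",
            names=[f"tss_{i}" for i in range(len(self.truth_promoters))],
        )


def _markov_promoter(rng: np.random.Generator, length: int, gc: float,
                     enrichment: float) -> str:
    """First-order chain with stationary GC bias and CpG/GpC enrichment."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    trans = np.tile(p, (4, 1))
    trans[1, 2] *= enrichment  # C -> G
    trans[2, 1] *= enrichment  # G -> C
    trans /= trans.sum(axis=1, keepdims=True)
    # draw the whole chain with one uniform vector per step
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(4, p=p)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    for i in range(1, length):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return "".join(BASES[states])


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Place non-overlapping genes on random strands, embed CpG-enriched
    promoter sequence at every (primary and alternative) TSS, and record
    the truth promoter windows."""
    rng = rng or np.random.default_rng(config.seed)
    clen = config.genome_length // config.n_chroms
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]

    seqs = {c: rng.integers(0, 4, size=clen) for c in chrom_names}

    genes: list[GeneModel] = []
    truth_tss: list[tuple[str, int, str, str]] = []
    gi = 0
    for chrom in chrom_names:
        pos = config.edge_margin
        while gi < config.n_genes:
            length = int(rng.integers(*config.gene_length))
            if pos + length > clen - config.edge_margin:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (
                "noncoding" if rng.random() < config.noncoding_fraction else "coding"
            )
            gid = f"gene_{gi}"
            iv = GenomicInterval(chrom, pos, pos + length, strand)
            g = GeneModel(gene_id=gid, interval=iv, biotype=biotype, source="sim")
            genes.append(g)
            truth_tss.append((chrom, g.tss, strand, gid))
            if rng.random() < config.alt_promoter_fraction:
                off = int(rng.integers(*config.alt_tss_offset))
                if off < length - 2_000:
                    if strand == "+":
                        alt_iv = GenomicInterval(chrom, pos + off, pos + length, "+")
                    else:
                        alt_iv = GenomicInterval(chrom, pos, pos + length - off, "-")
                    alt = GeneModel(gene_id=gid, interval=alt_iv, biotype=biotype,
                                    source="sim")
                    genes.append(alt)
                    truth_tss.append((chrom, alt.tss, strand, gid))
            pos += length + int(rng.integers(*config.intergenic_gap))
            gi += 1

    if gi < config.n_genes:
        raise ValueError(
            f"could only place {gi} of {config.n_genes} genes; "
            "increase genome_length or shrink gaps"
        )

    truth_promoters = []
    for chrom, tss, strand, _ in truth_tss:
        _, s, e, _ = window_around(chrom, tss, strand, PROMOTER_UP, PROMOTER_DOWN)
        truth_promoters.append(GenomicInterval(chrom, s, e, strand))
        prom_seq = _markov_promoter(
            rng, e - s, config.promoter_gc, config.cpg_enrichment
        )
        seqs[chrom][s:e] = np.searchsorted(
            np.array(list("ACGT")), np.array(list(prom_seq))
        )

    genome = {c: "".join(BASES[v]) for c, v in seqs.items()}
    return SimulatedGenome(
        genome=genome,
        genes=genes,
        truth_promoters=truth_promoters,
        truth_tss=truth_tss,
        config=config,
    )


def simulate_tags(sim: SimulatedGenome, config: SimulationConfig | None = None,
                  rng: np.random.Generator | None = None) -> dict[str, TagTrack]:
    """Draw Poisson tag counts per base for the three assays."""
    config = config or sim.config
    rng = rng or np.random.default_rng(config.seed + 1)
    sizes = sim.chrom_sizes()
    rate = {
        "polII": {c: np.full(n, config.polII_background) for c, n in sizes.items()},
        "h3k4me3": {c: np.full(n, config.h3k4me3_background) for c, n in sizes.items()},
        "cage": {c: np.full(n, config.cage_background) for c, n in sizes.items()},
    }

    for iv in sim.truth_promoters:
        rate["polII"][iv.chrom][iv.start : iv.end] += config.polII_promoter
    for chrom, tss, strand, _ in sim.truth_tss:
        _, s, e, _ = window_around(chrom, tss, strand, 500, 1000)
        s, e = max(s, 0), min(e, sizes[chrom])
        rate["h3k4me3"][chrom][s:e] += config.h3k4me3_promoter
        hw = config.cage_tss_halfwidth
        cs, ce = max(tss - hw, 0), min(tss + hw + 1, sizes[chrom])
        rate["cage"][chrom][cs:ce] += config.cage_tss_tags / (2 * hw + 1)

    # gene bodies: weak linear 5'->3' decay plus punctate stalling bumps;
    # iterate primary transcripts only (one body per gene id)
    seen = set()
    stall_truth: list[GenomicInterval] = []
    for g in sim.genes:
        if g.gene_id in seen:
            continue
        seen.add(g.gene_id)
        iv = g.interval
        body = np.linspace(config.polII_body_5p, config.polII_body_3p, len(iv))
        if g.strand == "-":
            body = body[::-1]
        rate["polII"][iv.chrom][iv.start : iv.end] += body

        # stall sites: inside the body, clear of every TSS window
        if g.strand == "+":
            lo, hi = iv.start + 1_800, iv.end - 600
        else:
            lo, hi = iv.start + 600, iv.end - 1_800
        slots = np.arange(lo, hi, config.polII_stall_spacing)
        slots = np.array(
            [
                s
                for s in slots
                if all(
                    abs(s - t) > 1_200
                    for c, t, _, gid2 in sim.truth_tss
                    if c == iv.chrom and gid2 == g.gene_id
                )
            ]
        )
        if len(slots) == 0:
            continue
        k = min(int(rng.poisson(config.polII_stalls_per_gene)), len(slots))
        if k == 0:
            continue
        for s in rng.choice(slots, size=k, replace=False):
            w = config.polII_stall_width
            a, b = int(s - w // 2), int(s + w // 2)
            rate["polII"][iv.chrom][a:b] += config.polII_stall_rate
            stall_truth.append(GenomicInterval(iv.chrom, a, b))

    tracks = {}
    for assay, rates in rate.items():
        cov = {c: rng.poisson(r).astype(np.int64) for c, r in sorted(rates.items())}
        total = int(sum(a.sum() for a in cov.values()))
        tracks[assay] = TagTrack(
            sample_id=f"sim_{assay}", assay=assay, coverage=cov,
            library_size=max(total, 1),
        )
    tracks["polII"].stall_truth = stall_truth  # diagnostic attribute
    return tracks


@dataclass
class Benchmark:
    """Ready-to-train bundle produced by :func:`make_benchmark`."""

    sim: SimulatedGenome
    tracks: dict[str, TagTrack]
    peaks: dict[str, list]
    promoter_records: list
    nonpromoter_records: list
    X: pd.DataFrame  # 39 feature columns, rows aligned with y
    y: np.ndarray  # label strings
    split: "object"
    train_idx: np.ndarray  # row indices into X/y
    test_idx: np.ndarray
    catalog: TssCatalog


def make_benchmark(config: SimulationConfig | None = None,
                   mask_to_significant: bool = True,
                   fdr: float = 0.001,
                   scales=None) -> Benchmark:
    """Run the full chain on simulated data: simulate genome and tags,
    call peaks per assay, build the labeled promoter/non-promoter dataset,
    extract the 39 features (coverage masked to each assay's significant
    regions by default) and produce a stratified 3:1 split."""
    from .classify import POSITIVE_LABEL  # noqa: F401  (label constants)
    from .dataset import (
        deduplicate_cross_tissue,
        gene_promoter_status,
        label_promoter_peaks,
        select_nonpromoter_peaks,
    )
    from .features import SequenceWindow, feature_matrix
    from .peaks import call_peaks, significant_region_mask
    from .scales import builtin_scales

    config = config or SimulationConfig()
    sim = simulate_genome(config)
    tracks = simulate_tags(sim, config)
    sizes = sim.chrom_sizes()

    peaks = {assay: call_peaks(trk, fdr=fdr) for assay, trk in tracks.items()}
    if mask_to_significant:
        tracks = {
            assay: trk.masked(significant_region_mask(peaks[assay], sizes))
            for assay, trk in tracks.items()
        }

    catalog = sim.catalog()
    status = gene_promoter_status(sim.genes, peaks["polII"])
    promoters = label_promoter_peaks(peaks["polII"], catalog, tissue="sim")
    nonpromoters = select_nonpromoter_peaks(
        peaks["polII"], sim.genes, status, tss_catalog=catalog, tissue="sim"
    )
    promoters, nonpromoters = deduplicate_cross_tissue(promoters, nonpromoters)

    records = promoters + nonpromoters
    windows = [
        SequenceWindow.from_genome(
            sim.genome, r.window.chrom, r.window.start, r.window.end, r.window.strand
        )
        for r in records
    ]
    scales = scales or builtin_scales()
    X = feature_matrix(
        windows,
        scales,
        polII_tracks=[tracks["polII"]],
        h3k4me3_tracks=[tracks["h3k4me3"]],
        cage_tracks=[tracks["cage"]],
    )
    from .features import FEATURE_NAMES

    y = np.array([r.label for r in records])

    # stratified 3:1 split, keeping feature-row indices aligned
    from .dataset import DatasetSplit

    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = [], []
    for label in sorted(set(y)):
        idx = np.nonzero(y == label)[0]
        perm = rng.permutation(len(idx))
        n_train = int(round(0.75 * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train_idx, test_idx = np.array(sorted(train_idx)), np.array(sorted(test_idx))
    split = DatasetSplit(
        train=[records[i] for i in train_idx],
        test=[records[i] for i in test_idx],
        seed=config.seed,
    )
    return Benchmark(
        sim=sim,
        tracks=tracks,
        peaks=peaks,
        promoter_records=promoters,
        nonpromoter_records=nonpromoters,
        X=X[FEATURE_NAMES],
        y=y,
        split=split,
        train_idx=train_idx,
        test_idx=test_idx,
        catalog=catalog,
    )
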