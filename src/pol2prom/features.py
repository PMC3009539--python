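"""39-dimensional feature vectors for 500 bp genomic windows.

Each window is described by three feature groups:

* **composition (10)** — single-nucleotide fractions, purine/pyrimidine,
  amino/keto and weak/strong skews, and three CpG-island statistics built
  from di-/tri-nucleotide counts (CpG1-3).  Denominators are the fixed
  window length L, L-1 and L-2 even when the window contains N.
* **physico-chemical (22)** — for each property scale phi, the mean of
  phi(x) over all N-free k-mer windows, i.e. sum(n_x * phi(x)) divided by
  the number of valid k-mer positions.  This normalisation makes the
  feature length-independent and maps a constant scale to its constant.
* **experimental (7)** — CAGE total TPM in the window, and average TPM,
  maximum TPM and max/avg ratio for pooled Pol-II and pooled H3K4me3
  coverage.  TPM = tags per base * 1e6 / library size; samples of the same
  assay are converted to TPM independently and then pooled (sum by
  default) so that deeper libraries do not dominate.

k-mers containing N are skipped from every count.  ``max/avg`` is defined
as 0 when the average is 0 (no evidence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import TagTrack
from .scales import PHYSCHEM_PROPERTIES, PropertyScale, kmer_index

COMPOSITION_FEATURES = [
    "a_fraction",
    "c_fraction",
    "g_fraction",
    "t_fraction",
    "purpyr_fraction",
    "amke_fraction",
    "west_fraction",
    "cpg1",
    "cpg2",
    "cpg3",
]
PHYSCHEM_FEATURES = list(PHYSCHEM_PROPERTIES)
SIGNAL_FEATURES = [
    "cage_total_tpm",
    "polII_avg_tpm",
    "polII_max_tpm",
    "polII_max_over_avg",
    "h3k4me3_avg_tpm",
    "h3k4me3_max_tpm",
    "h3k4me3_max_over_avg",
]
FEATURE_NAMES = COMPOSITION_FEATURES + PHYSCHEM_FEATURES + SIGNAL_FEATURES
assert len(FEATURE_NAMES) == 39

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SequenceWindow:
    """A sequence window with its genomic origin.

    ``start``/``end`` are the *nominal* coordinates and may extend past
    chromosome bounds; in that case the sequence is N-padded so that
    ``len(seq) == end - start`` always holds.  For ``-`` strand windows the
    stored sequence is the reverse complement (transcription orientation).
    """

    seq: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValueError("sequence length does not match coordinates")

    @property
    def L(self) -> int:
        return len(self.seq)

    @classmethod
    def from_genome(
        cls,
        genome: Mapping[str, str],
        chrom: str,
        start: int,
        end: int,
        strand: str = ".",
    ) -> "SequenceWindow":
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        ref = genome[chrom]
        lo, hi = max(start, 0), min(end, len(ref))
        core = ref[lo:hi] if lo < hi else ""
        seq = "N" * (lo - start) + core + "N" * (end - hi)
        if strand == "-":
            seq = reverse_complement(seq)
        return cls(seq=seq.upper(), chrom=chrom, start=start, end=end, strand=strand)


@dataclass(frozen=True)
class KmerCounts:
    """Counts of overlapping k-mers (k-mers containing N are skipped)."""

    k: int
    counts: dict[str, int]
    n_valid: int  # number of N-free k-mer positions

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


def _kmer_count_array(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    n = len(codes)
    if n < k:
        raise ValueError(f"sequence shorter than k={k}")
    m = n - k + 1
    idx = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    c = codes.astype(np.int64)
    for j in range(k):
        idx = idx * 4 + c[j : j + m]
        ok &= codes[j : j + m] < 4
    counts = np.bincount(idx[ok], minlength=4**k)
    return counts, int(ok.sum())


_KMER_CACHE: dict[int, list[str]] = {}


def _kmers(k: int) -> list[str]:
    from .scales import all_kmers

    if k not in _KMER_CACHE:
        _KMER_CACHE[k] = all_kmers(k)
    return _KMER_CACHE[k]


def count_kmers(window: SequenceWindow | str, k: int) -> KmerCounts:
    """Overlapping k-mer counts for k in 1..4."""
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    seq = window if isinstance(window, str) else window.seq
    counts, n_valid = _kmer_count_array(encode_sequence(seq), k)
    names = _kmers(k)
    nz = np.nonzero(counts)[0]
    return KmerCounts(k=k, counts={names[i]: int(counts[i]) for i in nz}, n_valid=n_valid)


# indices into the k=2 / k=3 count arrays used by the CpG features
_CG, _GC = kmer_index("CG"), kmer_index("GC")
_CPG2_TERMS = {
    "ACG": 1, "AGC": 1, "CAG": 1, "CCG": 1, "CGA": 1, "CGC": 1, "CGG": 2,
    "CGT": 1, "CTG": 1, "GAC": 1, "GCA": 1, "GCC": 2, "GCG": 1, "GCT": 1,
    "GGC": 2, "GTC": 1, "TCG": 1, "TGC": 1,
}
_CPG3_TERMS = {
    "CAG": 4, "CCG": 1, "CGG": 1, "CTG": 4, "GAC": 4, "GCC": 1, "GGC": 1,
    "GTC": 4,
}
_CPG2_IDX = np.array([kmer_index(x) for x in _CPG2_TERMS])
_CPG2_W = np.array(list(_CPG2_TERMS.values()), dtype=np.float64)
_CPG3_IDX = np.array([kmer_index(x) for x in _CPG3_TERMS])
_CPG3_W = np.array(list(_CPG3_TERMS.values()), dtype=np.float64)


def composition_features(window: SequenceWindow | str) -> dict[str, float]:
    """The 10 composition/CpG features.

    Fractions use the full window length L as denominator; CpG1 uses L-1
    and CpG2/CpG3 use L-2.  N bases contribute nothing to any count.
    """
    seq = window if isinstance(window, str) else window.seq
    L = len(seq)
    if L < 3:
        raise ValueError("window must be at least 3 bp")
    codes = encode_sequence(seq)
    c1, _ = _kmer_count_array(codes, 1)
    c2, _ = _kmer_count_array(codes, 2)
    c3, _ = _kmer_count_array(codes, 3)
    nA, nC, nG, nT = (float(c1[i]) for i in range(4))
    return {
        "a_fraction": nA / L,
        "c_fraction": nC / L,
        "g_fraction": nG / L,
        "t_fraction": nT / L,
        "purpyr_fraction": (nA + nG - nC - nT) / L,
        "amke_fraction": (nA + nC - nG - nT) / L,
        "west_fraction": (nA + nT - nC - nG) / L,
        "cpg1": (2.0 * c2[_CG] + 2.0 * c2[_GC]) / (L - 1),
        "cpg2": float(c3[_CPG2_IDX] @ _CPG2_W) / (L - 2),
        "cpg3": float(c3[_CPG3_IDX] @ _CPG3_W) / (L - 2),
    }


def property_feature(window: SequenceWindow | str, scale: PropertyScale) -> float:
    """Mean property value per N-free k-mer position:
    ``sum(n_x * phi(x)) / n_valid``; 0 when the window has no valid k-mer."""
    seq = window if isinstance(window, str) else window.seq
    counts, n_valid = _kmer_count_array(encode_sequence(seq), scale.k)
    if n_valid == 0:
        return 0.0
    return float(counts @ scale.as_array()) / n_valid


# ---------------------------------------------------------------------------
# experimental-signal features
# ---------------------------------------------------------------------------


def window_tpm_profile(window: SequenceWindow, track: TagTrack) -> np.ndarray:
    """Per-base TPM over the window for a single track (length L)."""
    return track.tpm_profile(window.chrom, window.start, window.end)


def pooled_tpm(
    tracks: Sequence[TagTrack],
    chrom: str,
    start: int,
    end: int,
    pooling: str = "sum",
) -> np.ndarray:
    """Pool per-base TPM across samples of one assay (sum or mean)."""
    if pooling not in ("sum", "mean"):
        raise ValueError("pooling must be 'sum' or 'mean'")
    out = np.zeros(end - start, dtype=np.float64)
    for track in tracks:
        out += track.tpm_profile(chrom, start, end)
    if pooling == "mean" and tracks:
        out /= len(tracks)
    return out


def signal_features(tpm: np.ndarray) -> tuple[float, float, float]:
    """(average TPM, maximum TPM, max/avg) over the window; max/avg is 0
    when the average is 0."""
    avg = float(tpm.mean()) if len(tpm) else 0.0
    mx = float(tpm.max()) if len(tpm) else 0.0
    ratio = mx / avg if avg > 0 else 0.0
    return avg, mx, ratio


def cage_feature(tpm: np.ndarray) -> float:
    """Total TPM falling in the window."""
    return float(tpm.sum())


@dataclass(frozen=True)
class FeatureVector:
    """The 39 named feature values for one window."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError("expected 39 feature values")

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=FEATURE_NAMES)


def _check_scales(scales: Sequence[PropertyScale]) -> dict[str, PropertyScale]:
    by_name = {s.name: s for s in scales}
    if set(by_name) != set(PHYSCHEM_FEATURES) or len(scales) != 22:
        raise ValueError(
            "exactly the 22 canonical property scales are required; "
            f"got {sorted(by_name)}"
        )
    return by_name


def extract_features(
    window: SequenceWindow,
    scales: Sequence[PropertyScale],
    polII_tracks: Sequence[TagTrack] = (),
    h3k4me3_tracks: Sequence[TagTrack] = (),
    cage_tracks: Sequence[TagTrack] = (),
    pooling: str = "sum",
    allow_missing_assays: bool = False,
) -> FeatureVector:
    """Compute all 39 features for one window.

    Signal features are computed on genomic (unstranded) coordinates;
    sequence features are computed on the stored (orientation-respecting)
    sequence.  With ``allow_missing_assays`` an empty track group yields 0
    for its features instead of raising.
    """
    by_name = _check_scales(scales)
    if not allow_missing_assays:
        for label, grp in (
            ("polII", polII_tracks),
            ("h3k4me3", h3k4me3_tracks),
            ("cage", cage_tracks),
        ):
            if not grp:
                raise ValueError(
                    f"no {label} tracks supplied (pass allow_missing_assays=True "
                    "to emit zeros)"
                )
    comp = composition_features(window)
    values = [comp[name] for name in COMPOSITION_FEATURES]
    values += [property_feature(window, by_name[name]) for name in PHYSCHEM_FEATURES]

    def group_tpm(tracks):
        if not tracks:
            return np.zeros(window.L)
        return pooled_tpm(tracks, window.chrom, window.start, window.end, pooling)

    values.append(cage_feature(group_tpm(cage_tracks)))
    for tracks in (polII_tracks, h3k4me3_tracks):
        avg, mx, ratio = signal_features(group_tpm(tracks))
        values += [avg, mx, ratio]
    return FeatureVector(values=tuple(values))


def feature_matrix(
    windows: Iterable[SequenceWindow],
    scales: Sequence[PropertyScale],
    polII_tracks: Sequence[TagTrack] = (),
    h3k4me3_tracks: Sequence[TagTrack] = (),
    cage_tracks: Sequence[TagTrack] = (),
    pooling: str = "sum",
    allow_missing_assays: bool = False,
) -> pd.DataFrame:
    """Feature table: window identifier columns followed by the 39 features
    in fixed order.  Writable as TSV via ``DataFrame.to_csv(sep='\\t')``."""
    rows, meta = [], []
    for w in windows:
        fv = extract_features(
            w,
            scales,
            polII_tracks,
            h3k4me3_tracks,
            cage_tracks,
            pooling=pooling,
            allow_missing_assays=allow_missing_assays,
        )
        rows.append(fv.values)
        meta.append((w.chrom, w.start, w.end, w.strand))
    out = pd.DataFrame(
        meta, columns=["chrom", "start", "end", "strand"]
    )
    out[FEATURE_NAMES] = pd.DataFrame(rows, columns=FEATURE_NAMES)
    return out
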