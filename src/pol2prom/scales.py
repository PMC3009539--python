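"""Physico-chemical/structural property scales for DNA k-mers.

A :class:`PropertyScale` maps every k-mer over {A,C,G,T} (for a fixed k in
1..4) to a real number — stacking energies, twist angles, bendability and
the like.  The classifier uses 22 such scales; their canonical names and
k-mer orders are listed in :data:`PHYSCHEM_PROPERTIES`.

Two of the packaged tables carry real literature values (EIIP single-
nucleotide potentials; unified nearest-neighbour duplex free energies).
The remaining twenty ship as deterministic *synthetic stand-in* tables
(``*.synthetic.tsv``): they have the right shape and units-free magnitude
so that every pipeline mechanism — feature extraction, linearity,
classification — is fully exercised, but they are not the published
biophysical measurements.  Users with the published tables can drop in
replacements via :meth:`PropertyScale.from_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"

#: canonical property name -> k-mer size, in the classifier's fixed order
PHYSCHEM_PROPERTIES: dict[str, int] = {
    "a_philicity": 2,
    "base_stacking": 2,
    "bdna_twist": 2,
    "bending_stiffness": 2,
    "dinuc_flex_energy": 2,
    "denaturation": 2,
    "duplex_disrupt_energy": 2,
    "duplex_free_energy": 2,
    "helical_rise": 2,
    "helical_twist": 2,
    "helical_tilt": 2,
    "helical_roll": 2,
    "helical_shift": 2,
    "helical_slide": 2,
    "propeller_twist": 2,
    "protein_deformability": 2,
    "protein_dna_twist": 2,
    "zdna_energy": 2,
    "trinuc_bendability": 3,
    "nucleosome_preference": 3,
    "tetranuc_flexibility": 4,
    "eiip": 1,
}


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def kmer_index(kmer: str) -> int:
    """Base-4 index of a k-mer (A=0, C=1, G=2, T=3)."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + ALPHABET.index(ch)
    return idx


@dataclass(frozen=True)
class PropertyScale:
    """Total mapping k-mer -> value for one physico-chemical property."""

    name: str
    k: int
    values: dict[str, float]
    citation: str = ""
    synthetic: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 4:
            raise ValueError("k must be in 1..4")
        expected = set(all_kmers(self.k))
        missing = expected - set(self.values)
        if missing:
            raise ValueError(
                f"scale {self.name!r} incomplete: missing {sorted(missing)[:4]}..."
            )

    def as_array(self) -> np.ndarray:
        """Values ordered by base-4 k-mer index, for vectorised dot products."""
        arr = np.empty(4**self.k, dtype=np.float64)
        for kmer, v in self.values.items():
            arr[kmer_index(kmer)] = v
        return arr

    def scaled(self, factor: float) -> "PropertyScale":
        return PropertyScale(
            self.name, self.k, {x: v * factor for x, v in self.values.items()},
            self.citation, self.synthetic,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyScale":
        """Load a scale from TSV: ``# name:``/``# k:``/``# citation:``
        header comments, then ``kmer<TAB>value`` rows."""
        meta = {"name": Path(path).stem, "k": None, "citation": "", "synthetic": "false"}
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if ":" in body:
                        key, _, val = body.partition(":")
                        meta[key.strip()] = val.strip()
                    continue
                kmer, val = line.split("\t")
                values[kmer.upper()] = float(val)
        k = int(meta["k"]) if meta["k"] else len(next(iter(values)))
        return cls(
            name=meta["name"],
            k=k,
            values=values,
            citation=meta["citation"],
            synthetic=str(meta.get("synthetic", "false")).lower() == "true",
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# name: {self.name}\n# k: {self.k}\n")
            if self.citation:
                fh.write(f"# citation: {self.citation}\n")
            fh.write(f"# synthetic: {str(self.synthetic).lower()}\n")
            for kmer in all_kmers(self.k):
                fh.write(f"{kmer}\t{self.values[kmer]:.6g}\n")


def constant_scale(name: str, k: int, value: float) -> PropertyScale:
    """Scale mapping every k-mer to the same value; handy in tests."""
    return PropertyScale(name, k, {x: value for x in all_kmers(k)}, synthetic=True)


def _data_dir():
    return resources.files("pol2prom") / "data" / "scales"


def builtin_scales() -> list[PropertyScale]:
    """The 22 packaged scales in canonical order (see module docstring for
    which are literature values and which are synthetic stand-ins)."""
    out = []
    root = _data_dir()
    for name in PHYSCHEM_PROPERTIES:
        plain = root / f"{name}.tsv"
        synth = root / f"{name}.synthetic.tsv"
        path = plain if plain.is_file() else synth
        scale = PropertyScale.from_tsv(str(path))
        if scale.k != PHYSCHEM_PROPERTIES[name]:
            raise ValueError(f"packaged scale {name} has wrong k")
        out.append(scale)
    return out


def load_scales_dir(directory: str | Path) -> list[PropertyScale]:
    """Load user-supplied scale TSVs from a directory; must cover all 22
    canonical properties with the right k for each."""
    directory = Path(directory)
    found: dict[str, PropertyScale] = {}
    for path in sorted(directory.glob("*.tsv")):
        scale = PropertyScale.from_tsv(path)
        found[scale.name] = scale
    missing = set(PHYSCHEM_PROPERTIES) - set(found)
    if missing:
        raise ValueError(f"scale directory missing properties: {sorted(missing)}")
    return [found[name] for name in PHYSCHEM_PROPERTIES]
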