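"""Coordinate system, genome map, and ancestry-mosaic data model.

All coordinates are 0-based, half-open ``[start_bp, end_bp)`` integers in
base pairs; conversion to other conventions (e.g. the 1-based inclusive
columns of RFMix msp files) happens only in readers and writers.

A haploid genome is a tiling of each chromosome by maximal same-ancestry
tracts.  Internally tracts on one chromosome are stored as two parallel
arrays — tract end positions (the last entry equals the chromosome length)
and small-integer ancestry codes — which keeps meiosis and locus queries
fast; :class:`AncestryTract` objects are materialised on demand.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeMap",
    "AncestryTract",
    "HaploidGenome",
    "DiploidGenome",
    "MarkerGrid",
    "default_bovine_map",
    "ancestry_dosage",
    "validate_haploid",
]


class CoordinateError(ValueError):
    """A position or interval falls outside its chromosome."""


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosome lengths plus a uniform recombination rate.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.  Names must be unique and
        lengths positive.
    recomb_rate_per_mb
        Expected crossovers per megabase per meiosis.  The Poisson mean
        for a chromosome is ``length_bp / 1e6 * recomb_rate_per_mb``.
    """

    chromosomes: tuple[tuple[str, int], ...]
    recomb_rate_per_mb: float = 0.01

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in GenomeMap")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.recomb_rate_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([l for _, l in self.chromosomes], dtype=np.int64)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def lam(self, chrom: str) -> float:
        """Poisson crossover mean for one chromosome (length Mb x rate)."""
        return self.length(chrom) / 1e6 * self.recomb_rate_per_mb

    @property
    def lams(self) -> np.ndarray:
        return self.lengths / 1e6 * self.recomb_rate_per_mb

    @property
    def total_length_bp(self) -> int:
        return int(self.lengths.sum())

    def __len__(self) -> int:
        return len(self.chromosomes)

    @classmethod
    def from_tsv(cls, path, recomb_rate_per_mb: float = 0.01) -> "GenomeMap":
        """Read a two-column ``chrom<TAB>length_bp`` table (optional header)."""
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].lower() in ("chrom", "chr", "chromosome"):
                    continue
                chroms.append((fields[0], int(fields[1])))
        return cls(tuple(chroms), recomb_rate_per_mb)


def default_bovine_map(recomb_rate_per_mb: float = 0.01) -> GenomeMap:
    """The 29 bovine autosomes (ARS-UCD1.2 coordinates), ~2,489.39 Mb total.

    Chromosome 1 spans 158,532,931 bp, so at the default rate of 0.01
    crossovers/Mb its per-meiosis Poisson mean is 1.58532931.
    """
    ref = importlib.resources.files("admixscan.data") / "ars_ucd12_autosomes.tsv"
    with importlib.resources.as_file(ref) as path:
        return GenomeMap.from_tsv(path, recomb_rate_per_mb)


@dataclass(frozen=True)
class AncestryTract:
    """A maximal run of one ancestry on one homolog, ``[start_bp, end_bp)``."""

    chrom: str
    start_bp: int
    end_bp: int
    ancestry: str

    def __post_init__(self) -> None:
        if not 0 <= self.start_bp < self.end_bp:
            raise ValueError(
                f"invalid tract interval [{self.start_bp}, {self.end_bp}) on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


class HaploidGenome:
    """One gamete/homolog: per chromosome, a tiling by ancestry tracts.

    Parameters
    ----------
    labels
        The ordered ancestry set for this run; tract codes index into it.
    ends, codes
        Per chromosome, tract end positions (int64, strictly increasing,
        last equals the chromosome length) and ancestry codes (int8).
    """

    __slots__ = ("labels", "ends", "codes")

    def __init__(
        self,
        labels: Sequence[str],
        ends: dict[str, np.ndarray],
        codes: dict[str, np.ndarray],
    ) -> None:
        self.labels = tuple(labels)
        self.ends = ends
        self.codes = codes

    @classmethod
    def from_tracts(
        cls, labels: Sequence[str], tracts: Iterable[AncestryTract]
    ) -> "HaploidGenome":
        labels = tuple(labels)
        index = {a: i for i, a in enumerate(labels)}
        by_chrom: dict[str, list[AncestryTract]] = {}
        for t in tracts:
            by_chrom.setdefault(t.chrom, []).append(t)
        ends: dict[str, np.ndarray] = {}
        codes: dict[str, np.ndarray] = {}
        for chrom, ts in by_chrom.items():
            ts = sorted(ts, key=lambda t: t.start_bp)
            ends[chrom] = np.array([t.end_bp for t in ts], dtype=np.int64)
            codes[chrom] = np.array([index[t.ancestry] for t in ts], dtype=np.int8)
        return cls(labels, ends, codes)

    def tracts(self, chrom: str | None = None) -> Iterator[AncestryTract]:
        chroms = [chrom] if chrom is not None else list(self.ends)
        for c in chroms:
            start = 0
            for end, code in zip(self.ends[c].tolist(), self.codes[c].tolist()):
                yield AncestryTract(c, start, int(end), self.labels[code])
                start = int(end)

    def code_at(self, chrom: str, pos_bp: int) -> int:
        ends = self.ends[chrom]
        if not 0 <= pos_bp < ends[-1]:
            raise CoordinateError(f"position {pos_bp} outside chromosome {chrom!r}")
        return int(self.codes[chrom][np.searchsorted(ends, pos_bp, side="right")])

    def ancestry_at(self, chrom: str, pos_bp: int) -> str:
        return self.labels[self.code_at(chrom, pos_bp)]

    def codes_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised ancestry codes at sorted or unsorted positions."""
        idx = np.searchsorted(self.ends[chrom], positions, side="right")
        return self.codes[chrom][idx]

    def n_tracts(self) -> int:
        return sum(len(c) for c in self.codes.values())

    def bp_per_ancestry(self) -> np.ndarray:
        """Total bp covered by each ancestry label, ordered as ``labels``."""
        out = np.zeros(len(self.labels), dtype=np.int64)
        for chrom, ends in self.ends.items():
            lengths = np.diff(ends, prepend=np.int64(0))
            np.add.at(out, self.codes[chrom], lengths)
        return out

    def copy(self) -> "HaploidGenome":
        return HaploidGenome(
            self.labels,
            {c: e.copy() for c, e in self.ends.items()},
            {c: k.copy() for c, k in self.codes.items()},
        )


@dataclass
class DiploidGenome:
    """An individual: two haploid mosaics on the same genome map."""

    id: str
    hap1: HaploidGenome
    hap2: HaploidGenome

    @property
    def labels(self) -> tuple[str, ...]:
        return self.hap1.labels

    @property
    def haplotypes(self) -> tuple[HaploidGenome, HaploidGenome]:
        return (self.hap1, self.hap2)

    def n_tracts(self) -> int:
        return self.hap1.n_tracts() + self.hap2.n_tracts()

    def global_fraction(self, ancestry: str) -> float:
        code = self.labels.index(ancestry)
        bp = self.hap1.bp_per_ancestry() + self.hap2.bp_per_ancestry()
        return float(bp[code] / bp.sum())


def ancestry_dosage(genome: DiploidGenome, chrom: str, pos_bp: int, ancestry: str) -> int:
    """Number of the individual's two homologs carrying ``ancestry`` at a locus.

    Raises :class:`CoordinateError` if the position lies outside the
    chromosome, and ``ValueError`` for an ancestry not in the declared set.
    """
    if ancestry not in genome.labels:
        raise ValueError(f"unknown ancestry label {ancestry!r}")
    code = genome.labels.index(ancestry)
    return int(genome.hap1.code_at(chrom, pos_bp) == code) + int(
        genome.hap2.code_at(chrom, pos_bp) == code
    )


def validate_haploid(h: HaploidGenome, gmap: GenomeMap) -> list[str]:
    """Check the tiling and maximal-run invariants; return violations.

    An empty list means the haploid is valid: every chromosome of the map
    is tiled exactly (first tract starts at 0, ends strictly increase to
    the chromosome length) and no two adjacent tracts share an ancestry.
    """
    violations: list[str] = []
    for chrom in gmap.names:
        if chrom not in h.ends:
            violations.append(f"{chrom}: no tracts (gap over whole chromosome)")
            continue
        ends = h.ends[chrom]
        codes = h.codes[chrom]
        length = gmap.length(chrom)
        if len(ends) == 0:
            violations.append(f"{chrom}: no tracts (gap over whole chromosome)")
            continue
        if len(ends) != len(codes):
            violations.append(f"{chrom}: ends/codes length mismatch")
            continue
        if ends[0] <= 0:
            violations.append(f"{chrom}: empty first tract (end {ends[0]})")
        bad = np.nonzero(np.diff(ends) <= 0)[0]
        for i in bad:
            violations.append(
                f"{chrom}: non-increasing tract end at index {i + 1} (pos {ends[i + 1]})"
            )
        if ends[-1] < length:
            violations.append(f"{chrom}: gap from {ends[-1]} to chromosome end {length}")
        elif ends[-1] > length:
            violations.append(
                f"{chrom}: tract end {ends[-1]} overruns chromosome length {length}"
            )
        runs = np.nonzero(codes[1:] == codes[:-1])[0]
        for i in runs:
            violations.append(
                f"{chrom}: non-maximal run at {ends[i]} "
                f"(adjacent tracts both {h.labels[codes[i]]})"
            )
    for chrom in h.ends:
        if chrom not in gmap._lengths:
            violations.append(f"{chrom}: chromosome not in genome map")
    return violations


@dataclass(frozen=True)
class MarkerGrid:
    """Evaluation loci: per chromosome, strictly increasing positions (bp).

    Stands in for the dense SNP panel on which window calls and locus-wise
    ancestry frequencies are evaluated.
    """

    positions: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if len(pos) == 0:
                raise ValueError(f"empty marker set on chromosome {chrom!r}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom!r}")

    @classmethod
    def uniform(cls, gmap: GenomeMap, spacing_bp: int = 3000) -> "MarkerGrid":
        """Evenly spaced markers, ``spacing_bp`` apart, offset half a spacing.

        The 3 kb default yields ~830k markers on the bovine autosomes,
        comparable to the density of a large imputed SNP panel.
        """
        positions = {}
        for chrom, length in gmap.chromosomes:
            pos = np.arange(spacing_bp // 2, length, spacing_bp, dtype=np.int64)
            if len(pos) == 0:  # chromosome shorter than half a spacing
                pos = np.array([length // 2], dtype=np.int64)
            positions[chrom] = pos
        return cls(positions)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def __iter__(self):
        return iter(self.positions.items())
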