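"""Forward-in-time crossbreeding simulator on ancestry-tract genomes.

Simulates the founding and random-mating phases of composite cattle
breeds (e.g. 3/8 Brahman x 5/8 Angus Brangus; 1/2 x 1/2 Beefmaster) as
diploid ancestry mosaics.  Recombination per chromosome is Poisson with
mean lambda_c = chromosome length (Mb) x rate (crossovers/Mb, default
0.01), crossover positions uniform along the chromosome, no interference
and no obligate chiasma.  Populations are monoecious; a cross produces
one offspring from one meiosis of each parent.

Optional ancestry-biased viability selection provides a recoverable
signal for the divergence scans: an offspring is accepted with
probability prod_loci (1+s)^dosage / (1+s)^2 across the selected loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome import DiploidGenome, GenomeMap, HaploidGenome, MarkerGrid

__all__ = [
    "CrossingScheme",
    "FoundingStep",
    "SelectionSpec",
    "SelectedLocus",
    "SimCohort",
    "BRANGUS_SG",
    "BEEFMASTER",
    "founder",
    "meiosis",
    "cross",
    "next_generation",
    "run_scheme",
    "expected_tract_count",
    "simulate_design",
    "emit_window_calls",
]


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class FoundingStep:
    """One founding cross: mate population ``a`` x population ``b``.

    ``a``/``b`` name either a founder ancestry (an unlimited purebred
    pool) or the output of an earlier step.  The last step's output is
    the breed's generation-1 cohort.
    """

    name: str
    a: str
    b: str


@dataclass(frozen=True)
class CrossingScheme:
    """A named crossing design: founding steps then random mating.

    The two presets mirror the standard American Breed designs:

    * :data:`BRANGUS_SG` — 3/8 x 5/8: BC1 = F1 x taurine purebred, then
      generation 1 = BC1 x F1, then random mating.
    * :data:`BEEFMASTER` — 1/2 x 1/2: generation 1 = F1 x F1, then
      random mating.
    """

    name: str
    founders: tuple[str, ...]
    steps: tuple[FoundingStep, ...]
    n: int = 1000
    generations_random_mating: int = 8

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("population size must be positive")
        known = set(self.founders)
        for step in self.steps:
            for pop in (step.a, step.b):
                if pop not in known:
                    raise ValueError(
                        f"step {step.name!r} references undefined population {pop!r}"
                    )
            known.add(step.name)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.founders


BRANGUS_SG = CrossingScheme(
    name="brangus_sg",
    founders=("Angus", "Brahman"),
    steps=(
        FoundingStep("F1", "Angus", "Brahman"),
        FoundingStep("BC1", "F1", "Angus"),
        FoundingStep("gen1", "BC1", "F1"),
    ),
)

BEEFMASTER = CrossingScheme(
    name="beefmaster",
    founders=("Taurine", "Brahman"),
    steps=(
        FoundingStep("F1", "Taurine", "Brahman"),
        FoundingStep("gen1", "F1", "F1"),
    ),
)


@dataclass(frozen=True)
class SelectedLocus:
    chrom: str
    pos_bp: int
    favored: str
    s: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass(frozen=True)
class SelectionSpec:
    """Multiplicative viability selection at one or more loci."""

    loci: tuple[SelectedLocus, ...]
    mode: Literal["viability"] = "viability"

    @classmethod
    def single(cls, chrom: str, pos_bp: int, favored: str, s: float) -> "SelectionSpec":
        return cls((SelectedLocus(chrom, pos_bp, favored, s),))


@dataclass
class SimCohort:
    """A generation of simulated individuals plus provenance."""

    genomes: list[DiploidGenome]
    generation: int
    labels: tuple[str, ...]
    scheme: str = ""
    seed: int | None = None
    gmap: GenomeMap | None = field(default=None, repr=False)
    intermediates: dict | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.genomes)

    @property
    def generations(self) -> np.ndarray:
        """Generation index per individual (uniform within a cohort)."""
        return np.full(len(self.genomes), self.generation, dtype=np.int64)

    def mean_fraction(self, ancestry: str) -> float:
        return float(np.mean([g.global_fraction(ancestry) for g in self.genomes]))


# ---------------------------------------------------------------------------
# core operations


def founder(ancestry: str, gmap: GenomeMap, labels: Sequence[str], id: str = "") -> DiploidGenome:
    """A purebred individual: every homolog one full-length tract."""
    labels = tuple(labels)
    if ancestry not in labels:
        raise ValueError(f"unknown ancestry label {ancestry!r}")
    code = labels.index(ancestry)

    def hap() -> HaploidGenome:
        ends = {c: np.array([l], dtype=np.int64) for c, l in gmap.chromosomes}
        codes = {c: np.array([code], dtype=np.int8) for c, _ in gmap.chromosomes}
        return HaploidGenome(labels, ends, codes)

    return DiploidGenome(id or f"{ancestry}_founder", hap(), hap())


def _gamete_chrom(
    ends1: np.ndarray,
    codes1: np.ndarray,
    ends2: np.ndarray,
    codes2: np.ndarray,
    length: int,
    cuts: np.ndarray,
    start_homolog: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Build one gamete chromosome from two homologs and crossover cuts.

    Copies tract segments from the active homolog, switching at each cut,
    then merges adjacent same-ancestry tracts (maximal runs).
    """
    homologs = ((ends1, codes1), (ends2, codes2))
    if len(cuts) == 0:
        ends, codes = homologs[start_homolog]
        return ends.copy(), codes.copy()
    bounds = np.empty(len(cuts) + 2, dtype=np.int64)
    bounds[0] = 0
    bounds[1:-1] = cuts
    bounds[-1] = length
    parts_e: list[np.ndarray] = []
    parts_c: list[np.ndarray] = []
    h = start_homolog
    for i in range(len(bounds) - 1):
        a = bounds[i]
        b = bounds[i + 1]
        ends, codes = homologs[h]
        j0 = int(np.searchsorted(ends, a, side="right"))
        j1 = int(np.searchsorted(ends, b, side="left"))
        seg_e = np.append(ends[j0:j1], b)
        parts_e.append(seg_e)
        parts_c.append(codes[j0 : j1 + 1])
        h ^= 1
    out_e = np.concatenate(parts_e)
    out_c = np.concatenate(parts_c)
    keep = np.empty(len(out_c), dtype=bool)
    keep[-1] = True
    np.not_equal(out_c[1:], out_c[:-1], out=keep[:-1])
    return out_e[keep], out_c[keep].astype(np.int8, copy=False)


def meiosis(
    parent: DiploidGenome,
    gmap: GenomeMap,
    rng: np.random.Generator,
    lam: float | np.ndarray | None = None,
) -> HaploidGenome:
    """One gamete: per chromosome, Poisson(lambda_c) uniform crossovers.

    The starting homolog is a fair coin; the copy switches homolog at
    each crossover.  ``lam`` overrides the map-derived Poisson means
    (scalar or per-chromosome array), e.g. to force one crossover per
    chromosome on average.
    """
    names = gmap.names
    lengths = gmap.lengths
    lams = gmap.lams if lam is None else np.broadcast_to(np.asarray(lam, float), (len(names),))
    ks = rng.poisson(lams)
    starts = rng.integers(0, 2, size=len(names))
    total = int(ks.sum())
    if total:
        u = rng.random(total)
        rep_len = np.repeat(lengths, ks)
        all_cuts = 1 + (u * (rep_len - 1)).astype(np.int64)
        offsets = np.concatenate(([0], np.cumsum(ks)))
    ends: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    h1, h2 = parent.hap1, parent.hap2
    for i, chrom in enumerate(names):
        e1, c1 = h1.ends[chrom], h1.codes[chrom]
        k = int(ks[i])
        if k == 0:
            src_e, src_c = (e1, c1) if starts[i] == 0 else (h2.ends[chrom], h2.codes[chrom])
            ends[chrom] = src_e.copy()
            codes[chrom] = src_c.copy()
            continue
        cuts = np.unique(all_cuts[offsets[i] : offsets[i + 1]])
        ends[chrom], codes[chrom] = _gamete_chrom(
            e1, c1, h2.ends[chrom], h2.codes[chrom], int(lengths[i]), cuts, int(starts[i])
        )
    return HaploidGenome(parent.labels, ends, codes)


def cross(
    p1: DiploidGenome,
    p2: DiploidGenome,
    gmap: GenomeMap,
    rng: np.random.Generator,
    id: str = "",
    lam: float | np.ndarray | None = None,
) -> DiploidGenome:
    """One offspring: one meiosis from each parent."""
    return DiploidGenome(id, meiosis(p1, gmap, rng, lam), meiosis(p2, gmap, rng, lam))


def _acceptance_prob(g: DiploidGenome, selection: SelectionSpec) -> float:
    p = 1.0
    for locus in selection.loci:
        code = g.labels.index(locus.favored)
        d = int(g.hap1.code_at(locus.chrom, locus.pos_bp) == code) + int(
            g.hap2.code_at(locus.chrom, locus.pos_bp) == code
        )
        p *= (1.0 + locus.s) ** d / (1.0 + locus.s) ** 2
    return p


_MAX_REJECTION_DRAWS = 1000


def _offspring(
    p1: DiploidGenome,
    p2: DiploidGenome,
    gmap: GenomeMap,
    rng: np.random.Generator,
    id: str,
    selection: SelectionSpec | None,
) -> DiploidGenome:
    if selection is None:
        return cross(p1, p2, gmap, rng, id)
    for _ in range(_MAX_REJECTION_DRAWS):
        child = cross(p1, p2, gmap, rng, id)
        if rng.random() < _acceptance_prob(child, selection):
            return child
    raise RuntimeError(
        f"viability selection rejected {_MAX_REJECTION_DRAWS} consecutive offspring; "
        "selection coefficients may be inconsistent with the parental ancestries"
    )


def next_generation(
    parents: SimCohort,
    n: int,
    rng: np.random.Generator,
    mating_mode: Literal["pair_equal", "resample"] = "pair_equal",
    selection: SelectionSpec | None = None,
) -> SimCohort:
    """Random mating within a cohort.

    ``pair_equal`` (default): parents are randomly paired without
    replacement into pairs and each pair leaves exactly two offspring,
    so parental contributions are equal — the low-drift reading of
    "randomly mated".  ``resample``: each offspring draws two distinct
    parents uniformly with replacement across offspring.
    """
    if not len(parents):
        raise ValueError("empty parent cohort")
    if parents.gmap is None:
        raise ValueError("cohort has no genome map attached")
    gmap = parents.gmap
    genomes = parents.genomes
    gen = parents.generation + 1
    out: list[DiploidGenome] = []
    if mating_mode == "pair_equal":
        if n % 2:
            raise ValueError("pair_equal mating requires an even offspring count")
        if len(genomes) % 2:
            raise ValueError("pair_equal mating requires an even parent count")
        while len(out) < n:
            order = rng.permutation(len(genomes))
            for i in range(0, len(order) - 1, 2):
                if len(out) >= n:
                    break
                p1, p2 = genomes[order[i]], genomes[order[i + 1]]
                for _ in range(2):
                    if len(out) >= n:
                        break
                    out.append(
                        _offspring(p1, p2, gmap, rng, f"g{gen}_{len(out)}", selection)
                    )
    elif mating_mode == "resample":
        # viability selection samples from the joint (pair, child)
        # distribution: a rejected candidate redraws its parents too
        for i in range(n):
            for _ in range(_MAX_REJECTION_DRAWS):
                a = int(rng.integers(len(genomes)))
                b = int(rng.integers(len(genomes) - 1))
                if b >= a:
                    b += 1
                child = cross(genomes[a], genomes[b], gmap, rng, f"g{gen}_{i}")
                if selection is None or rng.random() < _acceptance_prob(child, selection):
                    out.append(child)
                    break
            else:
                raise RuntimeError(
                    f"viability selection rejected {_MAX_REJECTION_DRAWS} consecutive "
                    "offspring; selection coefficients may be inconsistent with the "
                    "parental ancestries"
                )
    else:
        raise ValueError(f"unknown mating mode {mating_mode!r}")
    return SimCohort(out, gen, parents.labels, parents.scheme, parents.seed, gmap=gmap)


def run_scheme(
    scheme: CrossingScheme,
    gmap: GenomeMap,
    rng: np.random.Generator,
    selection: SelectionSpec | None = None,
    mating_mode: Literal["pair_equal", "resample"] = "pair_equal",
    keep_intermediate: bool = False,
) -> SimCohort:
    """Run founding steps then random mating; return the final cohort.

    With ``keep_intermediate`` the returned cohort carries an
    ``intermediates`` dict mapping step/generation names to cohorts
    (founding steps by name, random-mating rounds as ``"gen<i>"``).
    """
    labels = scheme.labels
    n = scheme.n
    pools: dict[str, list[DiploidGenome]] = {}
    founders = {a: founder(a, gmap, labels) for a in labels}
    intermediates: dict[str, SimCohort] = {}

    def draw(pop: str, size: int) -> list[DiploidGenome]:
        if pop in founders:
            return [founders[pop]] * size
        members = pools[pop]
        if len(members) == size:
            return [members[i] for i in rng.permutation(size)]
        idx = rng.integers(0, len(members), size=size)
        return [members[i] for i in idx]

    for step in scheme.steps:
        pa = draw(step.a, n)
        pb = draw(step.b, n)
        pools[step.name] = [
            cross(pa[i], pb[i], gmap, rng, f"{step.name}_{i}") for i in range(n)
        ]
        if keep_intermediate:
            intermediates[step.name] = SimCohort(
                pools[step.name], 0, labels, scheme.name, gmap=gmap
            )

    cohort = SimCohort(pools[scheme.steps[-1].name], 1, labels, scheme.name, gmap=gmap)
    for _ in range(scheme.generations_random_mating):
        cohort = next_generation(cohort, n, rng, mating_mode, selection)
        if keep_intermediate:
            intermediates[f"gen{cohort.generation}"] = cohort
    if keep_intermediate:
        cohort.intermediates = intermediates
    return cohort


# ---------------------------------------------------------------------------
# drift-free (independent-pedigree) sampling
#
# A closed population of N=1,000 accumulates allele-frequency drift every
# generation of random mating, inflating the across-loci dispersion of the
# cohort ancestry proportion well beyond the founder-sampling value.  The
# infinite-population limit of random mating has no drift: every individual
# of the final generation is an independent draw whose pedigree shares no
# ancestors with any other individual.  Sampling such an individual naively
# costs 2^g founder lineages; instead each haplotype is generated lazily,
# simulating ancestral meioses only on the chromosome intervals that are
# actually inherited.


@dataclass(frozen=True)
class _Pure:
    """Base of the pedigree recursion: a founder haplotype of one ancestry."""

    code: int


@dataclass(frozen=True)
class _Mix:
    """A gamete of an individual whose homologs are drawn from ``a`` and ``b``."""

    a: "_Pure | _Mix"
    b: "_Pure | _Mix"


def _final_hap_kind(scheme: CrossingScheme) -> "_Pure | _Mix":
    """Gamete-kind of the final generation's haplotypes under i.i.d. mating."""
    index = {label: i for i, label in enumerate(scheme.labels)}
    ind_kind: dict[str, tuple] = {
        label: (_Pure(i), _Pure(i)) for label, i in index.items()
    }
    for step in scheme.steps:
        ha = _Mix(*ind_kind[step.a])
        hb = _Mix(*ind_kind[step.b])
        ind_kind[step.name] = (ha, hb)
    hap_a, hap_b = ind_kind[scheme.steps[-1].name]
    if scheme.generations_random_mating == 0:
        # final generation is the last founding step itself; both homolog
        # kinds occur, return them as an asymmetric pair via a Mix marker
        return _Mix(hap_a, hap_b)  # only used through _iid_individual below
    m = _Mix(hap_a, hap_b)
    for _ in range(scheme.generations_random_mating - 1):
        m = _Mix(m, m)
    return _Mix(m, m)


class _ChromRand:
    """Buffered per-chromosome randomness for the pedigree recursion.

    The recursion consumes many scalar draws (one Poisson count and one
    coin per ancestral meiosis); buffering them through the same seeded
    generator keeps runs reproducible while avoiding per-call overhead.
    """

    __slots__ = ("rng", "lam", "_ks", "_hs", "_i")
    _BATCH = 2048

    def __init__(self, rng: np.random.Generator, lam: float) -> None:
        self.rng = rng
        self.lam = lam
        self._refill()

    def _refill(self) -> None:
        self._ks = self.rng.poisson(self.lam, self._BATCH)
        self._hs = self.rng.integers(0, 2, self._BATCH)
        self._i = 0

    def meiosis_draw(self) -> tuple[int, int]:
        if self._i >= self._BATCH:
            self._refill()
        k, h = int(self._ks[self._i]), int(self._hs[self._i])
        self._i += 1
        return k, h

    def cuts(self, k: int, length: int) -> np.ndarray:
        return np.unique(1 + (self.rng.random(k) * (length - 1)).astype(np.int64))


def _sample_kind(kind, intervals, length, pool, out) -> None:
    """Simulate one gamete lineage on the requested intervals only.

    Each call is a fresh ancestor (infinite population: no pedigree
    collapse), drawing its own crossovers over the whole chromosome and
    recursing into the two parental haplotype kinds with the interval
    pieces each transmits.
    """
    while True:
        if isinstance(kind, _Pure):
            code = kind.code
            out.extend((a, b, code) for a, b in intervals)
            return
        k, h = pool.meiosis_draw()
        if k == 0:
            kind = kind.a if h == 0 else kind.b  # tail recursion
            continue
        cuts = pool.cuts(k, length)
        bounds = [0, *cuts.tolist(), length]
        ia: list[tuple[int, int]] = []
        ib: list[tuple[int, int]] = []
        for si in range(len(bounds) - 1):
            s0, s1 = bounds[si], bounds[si + 1]
            tgt = ia if (h + si) % 2 == 0 else ib
            for a, b in intervals:
                lo, hi = max(a, s0), min(b, s1)
                if lo < hi:
                    tgt.append((lo, hi))
        if ia:
            _sample_kind(kind.a, ia, length, pool, out)
        if not ib:
            return
        kind, intervals = kind.b, ib  # tail recursion


def _iid_haploid(
    kind, gmap: GenomeMap, pools: list["_ChromRand"], labels: tuple[str, ...]
) -> HaploidGenome:
    ends: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for i, (chrom, length) in enumerate(gmap.chromosomes):
        pieces: list[tuple[int, int, int]] = []
        _sample_kind(kind, [(0, length)], length, pools[i], pieces)
        pieces.sort()
        e = np.array([p[1] for p in pieces], dtype=np.int64)
        c = np.array([p[2] for p in pieces], dtype=np.int8)
        keep = np.empty(len(c), dtype=bool)
        keep[-1] = True
        np.not_equal(c[1:], c[:-1], out=keep[:-1])
        ends[chrom] = e[keep]
        codes[chrom] = c[keep]
    return HaploidGenome(labels, ends, codes)


def iid_cohort(
    scheme: CrossingScheme,
    n_individuals: int,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> SimCohort:
    """Final-generation individuals under drift-free random mating.

    Each individual is an independent draw from the infinite-population
    limit of the scheme's random-mating phase: its two haplotypes come
    from disjoint pedigrees, so cohort ancestry proportions carry founder
    sampling variance only, with no accumulated drift.  Ancestral
    recombination is simulated lazily on inherited intervals, so the cost
    is polynomial in the generation count, not exponential.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    kind = _final_hap_kind(scheme)
    labels = scheme.labels
    gen = 1 + scheme.generations_random_mating
    pools = [_ChromRand(rng, lam) for lam in gmap.lams]
    genomes = []
    for i in range(n_individuals):
        hap1 = _iid_haploid(kind.a, gmap, pools, labels)
        hap2 = _iid_haploid(kind.b, gmap, pools, labels)
        genomes.append(DiploidGenome(f"iid{gen}_{i}", hap1, hap2))
    return SimCohort(genomes, gen, labels, scheme.name, gmap=gmap)


def expected_tract_count(
    design: Literal["purebred", "F1", "BC1", "F2"], crossovers_per_chrom: float = 1.0
) -> float:
    """Closed-form expected diploid ancestry-tract count on 29 autosomes.

    Every crossover in an F1 meiosis switches ancestry, so an F1-derived
    gamete has 1 + c tracts per chromosome in expectation; purebred
    gametes always have one.  Purebred and F1 individuals carry 58
    full-length tracts; BC1 = 29 + 29(1+c) = 87 at c = 1; F2 =
    2 x 29(1+c) = 116 at c = 1.
    """
    c = crossovers_per_chrom
    n_chrom = 29
    if design in ("purebred", "F1"):
        return 2.0 * n_chrom
    if design == "BC1":
        return n_chrom + n_chrom * (1.0 + c)
    if design == "F2":
        return 2.0 * n_chrom * (1.0 + c)
    raise ValueError(f"unknown design {design!r}")


def simulate_design(
    design: Literal["purebred", "F1", "BC1", "F2"],
    n: int,
    gmap: GenomeMap,
    rng: np.random.Generator,
    labels: Sequence[str] = ("Taurine", "Brahman"),
    crossovers_per_chrom: float | None = None,
) -> list[DiploidGenome]:
    """Simulate ``n`` independent individuals of a simple cross design.

    ``crossovers_per_chrom`` overrides the map-derived Poisson means with
    a constant per-chromosome mean (e.g. 1.0 for the one-crossover-per-
    chromosome-pair accounting of the generation proxy).
    """
    labels = tuple(labels)
    taur = founder(labels[0], gmap, labels)
    brah = founder(labels[1], gmap, labels)
    lam = crossovers_per_chrom
    out = []
    for i in range(n):
        if design == "purebred":
            out.append(cross(taur, taur, gmap, rng, f"P_{i}", lam))
        elif design == "F1":
            out.append(cross(taur, brah, gmap, rng, f"F1_{i}", lam))
        elif design == "BC1":
            f1 = cross(taur, brah, gmap, rng, "", lam)
            out.append(cross(taur, f1, gmap, rng, f"BC1_{i}", lam))
        elif design == "F2":
            f1a = cross(taur, brah, gmap, rng, "", lam)
            f1b = cross(taur, brah, gmap, rng, "", lam)
            out.append(cross(f1a, f1b, gmap, rng, f"F2_{i}", lam))
        else:
            raise ValueError(f"unknown design {design!r}")
    return out


def emit_window_calls(cohort: SimCohort, grid: MarkerGrid, window_snps: int = 25):
    """RFMix-style most-likely window calls for a simulated cohort.

    Chromosomes are partitioned into consecutive windows of
    ``window_snps`` markers (the last window may be short).  A
    haplotype's call in a window is the ancestry covering the majority
    of the window's markers; ties go to the ancestry at the window's
    midpoint marker.  Returns a :class:`~admixscan.windows.WindowCalls`.
    """
    from .windows import WindowCalls  # local import to avoid a cycle

    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    genomes = cohort.genomes
    if not genomes:
        raise ValueError("empty cohort")
    labels = cohort.labels
    n_anc = len(labels)
    rows = []
    call_blocks = []
    for chrom, pos in grid:
        n_m = len(pos)
        n_w = (n_m + window_snps - 1) // window_snps
        bnd = np.arange(0, n_m, window_snps)
        # windows tile the chromosome: boundaries at each window's first marker
        starts = np.empty(n_w, dtype=np.int64)
        starts[0] = 0
        starts[1:] = pos[bnd[1:]]
        chrom_end = int(genomes[0].hap1.ends[chrom][-1])
        ends_bp = np.empty(n_w, dtype=np.int64)
        ends_bp[:-1] = starts[1:]
        ends_bp[-1] = chrom_end
        n_snps = np.diff(np.append(bnd, n_m))
        mid_idx = bnd + np.minimum(window_snps // 2, n_snps - 1)
        calls = np.empty((n_w, 2 * len(genomes)), dtype=np.int8)
        for si, g in enumerate(genomes):
            for hi, hap in enumerate((g.hap1, g.hap2)):
                anc = hap.codes_at(chrom, pos)
                onehot_counts = np.empty((n_w, n_anc), dtype=np.int32)
                for a in range(n_anc):
                    onehot_counts[:, a] = np.add.reduceat((anc == a).astype(np.int32), bnd)
                best = onehot_counts.argmax(axis=1)
                top = onehot_counts.max(axis=1)
                tied = (onehot_counts == top[:, None]).sum(axis=1) > 1
                if tied.any():
                    best[tied] = anc[mid_idx[tied]]
                calls[:, 2 * si + hi] = best
        for w in range(n_w):
            rows.append((chrom, int(starts[w]), int(ends_bp[w]), int(n_snps[w])))
        call_blocks.append(calls)
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
    return WindowCalls(
        windows=windows,
        calls=np.vstack(call_blocks),
        samples=[g.id for g in genomes],
        labels=labels,
    )
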