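"""Cohort window statistics: proportions, concatenation, generation proxy.

Works on per-window, per-haplotype most-likely ancestry calls (the msp
representation) or directly on tract-level truth from the simulator.
The per-individual total ancestry-tract ("haplotype") count is the
generation proxy: recombination increases it every generation, so
animals can be ranked by it when pedigree information is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import DiploidGenome, GenomeMap, MarkerGrid

__all__ = [
    "WindowCalls",
    "WindowTable",
    "window_proportions",
    "merge_identical_windows",
    "haplotype_metrics",
    "global_ancestry",
    "count_correlation",
    "tail_groups",
    "locus_frequencies",
]


@dataclass
class WindowCalls:
    """Per-window, per-haplotype ancestry codes across a cohort.

    ``calls[w, 2*i + h]`` is the ancestry code of haplotype ``h`` of
    sample ``i`` in window ``w``; codes index into ``labels``.
    """

    windows: pd.DataFrame  # columns: chrom, start, end, n_snps
    calls: np.ndarray
    samples: list[str]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.windows), 2 * len(self.samples)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.windows)} windows x 2*{len(self.samples)} haplotypes"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def hap_names(self) -> list[str]:
        return [f"{s}.{h}" for s in self.samples for h in (0, 1)]

    def sample_columns(self, ids: Sequence[str]) -> np.ndarray:
        """Haplotype column indices for a subset of sample ids."""
        pos = {s: i for i, s in enumerate(self.samples)}
        cols = []
        for s in ids:
            i = pos[s]
            cols.extend((2 * i, 2 * i + 1))
        return np.array(cols, dtype=np.intp)

    def subset(self, ids: Sequence[str]) -> "WindowCalls":
        cols = self.sample_columns(ids)
        return WindowCalls(self.windows.copy(), self.calls[:, cols], list(ids), self.labels)


@dataclass
class WindowTable:
    """Per-window haplotype counts and ancestry proportions p_i.

    ``frame`` columns: chrom, start, end, n_snps, n_hap, then
    ``count_<label>`` and ``p_<label>`` per ancestry.
    """

    frame: pd.DataFrame
    labels: tuple[str, ...]

    def p(self, ancestry: str) -> np.ndarray:
        return self.frame[f"p_{ancestry}"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def window_proportions(calls: "WindowCalls") -> WindowTable:
    """Exact haplotype counting per window: p_i = count / (2 n_samples)."""
    if calls.n_samples < 1:
        raise ValueError("need at least one sample")
    n_hap = 2 * calls.n_samples
    frame = calls.windows.copy()
    frame["n_hap"] = n_hap
    for a, label in enumerate(calls.labels):
        cnt = (calls.calls == a).sum(axis=1)
        frame[f"count_{label}"] = cnt
        frame[f"p_{label}"] = cnt / n_hap
    return WindowTable(frame, calls.labels)


def merge_identical_windows(calls: "WindowCalls") -> "WindowCalls":
    """Concatenate adjacent windows whose full call vectors are identical.

    Mirrors RFMix's behaviour of merging contiguous windows where every
    haplotype of every individual has the same ancestry assignment: the
    merged window spans the union and sums the SNP counts.  Windows with
    equal proportions but permuted calls are *not* merged.
    """
    w = calls.windows
    same_chrom = w["chrom"].to_numpy()[1:] == w["chrom"].to_numpy()[:-1]
    same_calls = (calls.calls[1:] == calls.calls[:-1]).all(axis=1)
    new_group = np.concatenate(([True], ~(same_chrom & same_calls)))
    gid = np.cumsum(new_group) - 1
    first = np.nonzero(new_group)[0]
    merged = pd.DataFrame(
        {
            "chrom": w["chrom"].to_numpy()[first],
            "start": np.minimum.reduceat(w["start"].to_numpy(), first),
            "end": np.maximum.reduceat(w["end"].to_numpy(), first),
            "n_snps": np.add.reduceat(w["n_snps"].to_numpy(), first),
        }
    )
    return WindowCalls(merged, calls.calls[first], list(calls.samples), calls.labels)


def _runs_from_calls(codes: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Maximal-run boundaries for one haplotype on one chromosome block."""
    change = np.concatenate(([True], codes[1:] != codes[:-1]))
    run_first = np.nonzero(change)[0]
    run_last = np.concatenate((run_first[1:] - 1, [len(codes) - 1]))
    return codes[run_first], starts[run_first], ends[run_last]


def haplotype_metrics(source: "WindowCalls | Iterable[DiploidGenome]") -> pd.DataFrame:
    """Per-sample generation-proxy metrics.

    Returns a DataFrame indexed by sample id with ``total_haplotypes``
    (maximal same-ancestry tracts summed over both homologs and all
    chromosomes), and per ancestry the tract count, mean tract length
    (bp; NaN if the ancestry is absent), and length-weighted genome
    fraction.  Accepts window calls (runs recomputed from the calls,
    window spans counted in bp) or tract-level genomes.
    """
    if isinstance(source, WindowCalls):
        return _metrics_from_calls(source)
    return _metrics_from_genomes(list(source))


def _metrics_rows(labels, ids, counts, lengths):
    n = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    total_bp = l.sum(axis=1, keepdims=True)
    data = {"total_haplotypes": n.sum(axis=1).astype(int)}
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = np.where(n > 0, l / np.where(n > 0, n, 1), np.nan)
        frac = l / total_bp
    for a, label in enumerate(labels):
        data[f"n_tracts_{label}"] = n[:, a].astype(int)
        data[f"mean_length_bp_{label}"] = mean_len[:, a]
        data[f"fraction_{label}"] = frac[:, a]
    return pd.DataFrame(data, index=pd.Index(ids, name="sample"))


def _metrics_from_genomes(genomes: list[DiploidGenome]) -> pd.DataFrame:
    labels = genomes[0].labels
    n_anc = len(labels)
    counts = np.zeros((len(genomes), n_anc), dtype=np.int64)
    lengths = np.zeros((len(genomes), n_anc), dtype=np.int64)
    for i, g in enumerate(genomes):
        for hap in (g.hap1, g.hap2):
            lengths[i] += hap.bp_per_ancestry()
            for chrom in hap.codes:
                counts[i] += np.bincount(hap.codes[chrom], minlength=n_anc)
    return _metrics_rows(labels, [g.id for g in genomes], counts, lengths)


def _metrics_from_calls(calls: "WindowCalls") -> pd.DataFrame:
    labels = calls.labels
    n_anc = len(labels)
    n_hap = 2 * calls.n_samples
    counts = np.zeros((n_hap, n_anc), dtype=np.int64)
    lengths = np.zeros((n_hap, n_anc), dtype=np.int64)
    w = calls.windows
    chroms = w["chrom"].to_numpy()
    block_first = np.concatenate(([0], np.nonzero(chroms[1:] != chroms[:-1])[0] + 1))
    block_last = np.concatenate((block_first[1:], [len(chroms)]))
    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    for b0, b1 in zip(block_first, block_last):
        s, e = starts[b0:b1], ends[b0:b1]
        for h in range(n_hap):
            codes, rs, re = _runs_from_calls(calls.calls[b0:b1, h], s, e)
            np.add.at(counts[h], codes, 1)
            np.add.at(lengths[h], codes, re - rs)
    counts2 = counts[0::2] + counts[1::2]
    lengths2 = lengths[0::2] + lengths[1::2]
    return _metrics_rows(labels, calls.samples, counts2, lengths2)


def global_ancestry(sample: DiploidGenome) -> dict[str, float]:
    """Length-weighted genome fraction per ancestry over both homologs."""
    bp = sample.hap1.bp_per_ancestry() + sample.hap2.bp_per_ancestry()
    total = bp.sum()
    return {label: float(bp[i] / total) for i, label in enumerate(sample.labels)}


def count_correlation(metrics: pd.DataFrame, ancestry_a: str, ancestry_b: str) -> float:
    """Pearson correlation of per-sample tract counts for two ancestries."""
    if len(metrics) < 3:
        raise ValueError("need at least 3 samples")
    x = metrics[f"n_tracts_{ancestry_a}"].to_numpy(dtype=float)
    y = metrics[f"n_tracts_{ancestry_b}"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("tract counts have zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def tail_groups(
    metrics: pd.DataFrame, fraction: float = 0.10
) -> tuple[list[str], list[str]]:
    """Early-/advanced-generation proxies: tails of the tract-count ranking.

    The lower tail contains every sample whose total tract count is at
    or below the smallest threshold capturing at least ``fraction`` of
    samples (ties always wholly included); the upper tail is symmetric.
    Few tracts = early generation, many = advanced.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    n = len(metrics)
    if n < 20:
        raise ValueError("need at least 20 samples for tail selection")
    counts = metrics["total_haplotypes"].to_numpy()
    if counts.min() == counts.max():
        raise ValueError("all tract counts equal; tail groups degenerate")
    k = int(np.ceil(fraction * n))
    order = np.sort(counts)
    t_low = order[k - 1]
    t_high = order[n - k]
    early = metrics.index[counts <= t_low].tolist()
    advanced = metrics.index[counts >= t_high].tolist()
    return early, advanced


def locus_frequencies(
    genomes: Iterable[DiploidGenome], grid: MarkerGrid, ancestry: str
) -> dict[str, np.ndarray]:
    """Frequency of ``ancestry`` among all haplotypes at each grid locus.

    Exact per-marker haplotype counting via tract-interval accumulation;
    cost scales with tract count, not marker density.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("no genomes")
    code = genomes[0].labels.index(ancestry)
    n_hap = 2 * len(genomes)
    out: dict[str, np.ndarray] = {}
    for chrom, pos in grid:
        diff = np.zeros(len(pos) + 1, dtype=np.int32)
        for g in genomes:
            for hap in (g.hap1, g.hap2):
                ends = hap.ends[chrom]
                codes = hap.codes[chrom]
                sel = codes == code
                if not sel.any():
                    continue
                starts = np.concatenate(([0], ends[:-1]))
                i0 = np.searchsorted(pos, starts[sel], side="left")
                i1 = np.searchsorted(pos, ends[sel], side="left")
                np.add.at(diff, i0, 1)
                np.add.at(diff, i1, -1)
        out[chrom] = np.cumsum(diff[:-1]) / n_hap
    return out
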