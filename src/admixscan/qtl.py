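"""QTL-window enrichment arithmetic and region queries.

Given a CattleQTLdb-like table of trait-associated intervals, asks how
surprising the QTL content of a set of 1 Mb windows is under a uniform
placement model: database entries fall as a Poisson process with density
lambda = entries per Mb, so a window holds >=1 entry with probability
1 - exp(-lambda), and counts of non-empty windows among n sampled
windows are Binomial.  All tail probabilities are computed exactly (the
window counts here are 12-15; no normal approximation), in the log
domain where the magnitudes require it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .genome import GenomeMap, default_bovine_map

__all__ = [
    "ExcludedChrom",
    "EnrichmentConfig",
    "mean_entries_per_window",
    "presence_probability",
    "binomial_tail_at_least",
    "exactly_k_empty_probability",
    "region_query",
    "dedup_colocalized",
]

#: Autosomal genome length (Mb) of the bundled ARS-UCD1.2 map.
DEFAULT_GENOME_MB = 2489.39


@dataclass(frozen=True)
class ExcludedChrom:
    """A chromosome dropped from the density because its entries cluster.

    ``length_mb`` may be omitted; it is then resolved from the active
    genome map when the density is computed.
    """

    chrom: str
    entries: int
    length_mb: float | None = None


@dataclass(frozen=True)
class EnrichmentConfig:
    """Inputs for the uniform-placement QTL density."""

    total_entries: int
    genome_length_mb: float = DEFAULT_GENOME_MB
    window_mb: float = 1.0
    excluded: tuple[ExcludedChrom, ...] = ()

    def __post_init__(self) -> None:
        if self.total_entries < 0:
            raise ValueError("total_entries must be >= 0")
        if self.genome_length_mb <= 0 or self.window_mb <= 0:
            raise ValueError("lengths must be positive")


def mean_entries_per_window(
    config: EnrichmentConfig, gmap: GenomeMap | None = None
) -> float:
    """lambda = (entries - excluded) / (genome Mb - excluded Mb) * window Mb."""
    entries = config.total_entries
    length = config.genome_length_mb
    for exc in config.excluded:
        entries -= exc.entries
        if exc.length_mb is not None:
            length -= exc.length_mb
        else:
            gmap = gmap or default_bovine_map()
            length -= gmap.length(exc.chrom) / 1e6
    if length <= 0:
        raise ValueError("no genome length left after exclusions")
    if entries < 0:
        raise ValueError("excluded entries exceed the total")
    return entries / length * config.window_mb


def presence_probability(lam: float) -> float:
    """P(>=1 entry in a window) = 1 - exp(-lambda)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return float(-np.expm1(-lam))


def binomial_tail_at_least(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), exact summation."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def exactly_k_empty_probability(n_regions: int, k_empty: int, lam: float) -> float:
    """P(exactly k of n windows are empty) under the Poisson density.

    A window is empty with probability exp(-lambda); the count of empty
    windows is Binomial(n, exp(-lambda)).  Computed in the log domain:
    for lambda ~ 65 the per-window emptiness probability is ~1e-29 and
    the result underflows long before the naive product does not.
    """
    if not 0 <= k_empty <= n_regions:
        raise ValueError("k_empty must lie in [0, n_regions]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    log_choose = (
        gammaln(n_regions + 1) - gammaln(k_empty + 1) - gammaln(n_regions - k_empty + 1)
    )
    log_p_empty = -lam
    # log(1 - exp(-lam)) without losing precision at either extreme
    with np.errstate(divide="ignore"):
        log_p_full = np.log(-np.expm1(-lam)) if lam > 0 else -np.inf
    if k_empty < n_regions and lam == 0:
        return 0.0
    log_prob = log_choose + k_empty * log_p_empty
    if n_regions - k_empty > 0:
        log_prob += (n_regions - k_empty) * log_p_full
    return float(np.exp(log_prob))


# ---------------------------------------------------------------------------
# region queries against a QTL table


def region_query(
    table: pd.DataFrame,
    centers: Sequence[tuple[str, int]],
    width_bp: int = 1_000_000,
    gmap: GenomeMap | None = None,
) -> pd.DataFrame:
    """Count QTL records overlapping windows centred on given positions.

    Each region is ``[center - width/2, center + width/2)``, clipped to
    the chromosome when a map is supplied.  Overlap is any-bp overlap.
    Returns one row per region: chrom, center, start, end, n_entries,
    n_traits, traits (sorted unique trait names).  Duplicate table rows
    count twice; collapse them first with :func:`dedup_colocalized` if
    that is not wanted.
    """
    rows = []
    for chrom, center in centers:
        lo = center - width_bp // 2
        hi = center + width_bp // 2
        if gmap is not None:
            length = gmap.length(chrom)  # raises CoordinateError if unknown
            lo = max(0, lo)
            hi = min(length, hi)
        sub = table[
            (table["chrom"] == chrom) & (table["start"] < hi) & (table["end"] > lo)
        ]
        traits = sorted(sub["trait"].unique())
        rows.append((chrom, center, lo, hi, len(sub), len(traits), traits))
    return pd.DataFrame(
        rows, columns=["chrom", "center", "start", "end", "n_entries", "n_traits", "traits"]
    )


def dedup_colocalized(table: pd.DataFrame, max_gap_bp: int = 1_000_000) -> pd.DataFrame:
    """Collapse co-localized same-source, same-trait entries.

    Databases report one underlying QTL many times when studies map it
    with different marker sets, so entries sharing (source_id, trait)
    whose intervals overlap or fall within ``max_gap_bp`` of each other
    are merged into a single spanning record.  The 1 Mb default matches
    the window scale of the enrichment analysis; set ``max_gap_bp=0`` to
    merge only strictly overlapping intervals.  Entries from different
    sources or for different traits are never merged.  Output is sorted
    by chrom, start, trait, source_id.
    """
    out = []
    for (source, trait), grp in table.groupby(["source_id", "trait"], sort=False):
        for chrom, sub in grp.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            cur = None
            for row in sub.itertuples(index=False):
                if cur is None:
                    cur = dict(row._asdict())
                elif row.start <= cur["end"] + max_gap_bp:
                    cur["end"] = max(cur["end"], row.end)
                else:
                    out.append(cur)
                    cur = dict(row._asdict())
            if cur is not None:
                out.append(cur)
    result = pd.DataFrame(out, columns=list(table.columns))
    return result.sort_values(["chrom", "start", "trait", "source_id"]).reset_index(
        drop=True
    )
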