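"""Early- vs advanced-generation window contrasts (pooled two-proportion Z).

Animals are split into early- and advanced-generation groups by their
total ancestry-tract count (the generation proxy); each window's Brahman
proportion is then compared between groups with the pooled two-sample
Z-test

    Z_i = (p_ei - p_ai) / sqrt( p(1-p) (1/n_e + 1/n_a) ),

where p is the haplotype-count-weighted pooled proportion and n_e, n_a
are haplotype counts (twice the sample sizes).  The same statistic
applied to the groups' global Brahman fractions gives the genome-wide
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import DiploidGenome
from .scan import bh_adjust, neg_log10_p_two_sided
from .windows import WindowCalls, window_proportions

__all__ = [
    "TwoProportionZ",
    "ContrastResult",
    "z_two_proportion",
    "contrast_table",
    "contrast_scan",
    "genomewide_contrast",
]


class TwoProportionZ(NamedTuple):
    pooled_p: float
    z: float  # NaN when the pooled proportion is 0 or 1 (degenerate)


def z_two_proportion(p_e: float, n_e: int, p_a: float, n_a: int) -> TwoProportionZ:
    """Pooled two-proportion Z; sign follows ``p_e - p_a``.

    When the pooled proportion is exactly 0 or 1 both groups are fixed
    for the same ancestry: the test is degenerate, Z is NaN and the
    caller should treat the p-value as 1.
    """
    if n_e <= 0 or n_a <= 0:
        raise ValueError("haplotype counts must be positive")
    pooled = (n_e * p_e + n_a * p_a) / (n_e + n_a)
    if pooled <= 0.0 or pooled >= 1.0:
        return TwoProportionZ(float(pooled), float("nan"))
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_e + 1.0 / n_a))
    return TwoProportionZ(float(pooled), float((p_e - p_a) / se))


@dataclass
class ContrastResult:
    """Per-window early-vs-advanced test plus the scan summary.

    ``frame`` columns: chrom, start, end, p_e, p_a, pooled_p, z,
    neg_log10_p, bh_p, significant, direction ("advanced" where the
    advanced group carries more of the target ancestry).
    """

    frame: pd.DataFrame
    n_e: int
    n_a: int
    fdr_q: float
    target_ancestry: str
    nominal_threshold: float

    @property
    def fraction_significant(self) -> float:
        return float(self.frame["significant"].mean())

    @property
    def fraction_advanced_higher(self) -> float:
        """Among significant windows, the share with p_a > p_e."""
        sig = self.frame[self.frame["significant"]]
        if len(sig) == 0:
            return float("nan")
        return float((sig["p_a"] > sig["p_e"]).mean())

    def top(self, k: int = 5) -> pd.DataFrame:
        return (
            self.frame.sort_values(
                ["neg_log10_p", "chrom", "start"], ascending=[False, True, True]
            )
            .head(k)
            .reset_index(drop=True)
        )

    def summary(self) -> str:
        n_sig = int(self.frame["significant"].sum())
        lines = [
            f"Generation contrast: n_e={self.n_e} vs n_a={self.n_a} haplotypes "
            f"(FDR q={self.fdr_q})",
            f"  windows: {len(self.frame)}  significant: {n_sig} "
            f"({100 * self.fraction_significant:.1f}%)",
            f"  nominal -log10 p threshold: {self.nominal_threshold:.4f}",
        ]
        if n_sig:
            lines.append(
                f"  advanced group higher in {100 * self.fraction_advanced_higher:.1f}% "
                "of significant windows"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def contrast_table(
    windows: pd.DataFrame,
    p_e: np.ndarray,
    n_e: int,
    p_a: np.ndarray,
    n_a: int,
    q: float = 0.001,
    target_ancestry: str = "Brahman",
) -> ContrastResult:
    """Vectorised pooled-Z contrast over precomputed window proportions."""
    p_e = np.asarray(p_e, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    pooled = (n_e * p_e + n_a * p_a) / (n_e + n_a)
    ok = (pooled > 0.0) & (pooled < 1.0)
    z = np.full(len(pooled), np.nan)
    se = np.sqrt(pooled[ok] * (1.0 - pooled[ok]) * (1.0 / n_e + 1.0 / n_a))
    z[ok] = (p_e[ok] - p_a[ok]) / se
    nlp = np.zeros(len(pooled))
    nlp[ok] = neg_log10_p_two_sided(z[ok])
    raw_p = np.power(10.0, -nlp)  # 1.0 at degenerate windows
    bh = bh_adjust(raw_p, q)
    frame = windows[["chrom", "start", "end"]].copy()
    frame["p_e"] = p_e
    frame["p_a"] = p_a
    frame["pooled_p"] = pooled
    frame["z"] = z
    frame["neg_log10_p"] = nlp
    frame["bh_p"] = bh.adjusted_p
    frame["significant"] = bh.reject
    frame["direction"] = np.where(p_a > p_e, "advanced", np.where(p_a < p_e, "early", "none"))
    return ContrastResult(
        frame=frame,
        n_e=n_e,
        n_a=n_a,
        fdr_q=q,
        target_ancestry=target_ancestry,
        nominal_threshold=bh.nominal_threshold,
    )


def contrast_scan(
    calls: WindowCalls,
    early_ids: Sequence[str],
    advanced_ids: Sequence[str],
    q: float = 0.001,
    target_ancestry: str = "Brahman",
) -> ContrastResult:
    """Window-wise early-vs-advanced contrast from cohort window calls."""
    overlap = set(early_ids) & set(advanced_ids)
    if overlap:
        raise ValueError(f"groups are not disjoint: {sorted(overlap)[:3]}...")
    if len(early_ids) < 2 or len(advanced_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    early = window_proportions(calls.subset(early_ids))
    advanced = window_proportions(calls.subset(advanced_ids))
    return contrast_table(
        calls.windows,
        early.p(target_ancestry),
        2 * len(early_ids),
        advanced.p(target_ancestry),
        2 * len(advanced_ids),
        q=q,
        target_ancestry=target_ancestry,
    )


def genomewide_contrast(
    early: Iterable[DiploidGenome],
    advanced: Iterable[DiploidGenome],
    target_ancestry: str = "Brahman",
) -> dict:
    """Pooled-Z test of the groups' global (genome-wide) ancestry fractions.

    Group proportions are the means of the individuals' length-weighted
    global fractions; haplotype counts are twice the sample sizes.
    Returns a record dict; ``degenerate`` is True when a group has fewer
    than two samples or both groups are fixed for one ancestry.
    """
    early = list(early)
    advanced = list(advanced)
    p_e = float(np.mean([g.global_fraction(target_ancestry) for g in early]))
    p_a = float(np.mean([g.global_fraction(target_ancestry) for g in advanced]))
    n_e, n_a = 2 * len(early), 2 * len(advanced)
    degenerate = len(early) < 2 or len(advanced) < 2
    pooled, z = z_two_proportion(p_e, n_e, p_a, n_a)
    if np.isnan(z):
        degenerate = True
    nlp = float(neg_log10_p_two_sided(z)) if not np.isnan(z) else 0.0
    return {
        "p_e": p_e,
        "p_a": p_a,
        "n_e": n_e,
        "n_a": n_a,
        "pooled_p": pooled,
        "z": z,
        "neg_log10_p": nlp,
        "p_value": float(10.0 ** -nlp),
        "direction": "advanced" if p_a > p_e else ("early" if p_a < p_e else "none"),
        "degenerate": degenerate,
        "target_ancestry": target_ancestry,
    }
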