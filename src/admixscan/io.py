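"""Readers/writers for RFMix-style msp window calls, tract BED, QTL tables.

The msp dialect is pinned to RFMix v2 most-likely-assignment output:

    #Subpopulation order/codes: Angus=0<TAB>Brahman=1
    #chm<TAB>spos<TAB>epos<TAB>sgpos<TAB>egpos<TAB>n snps<TAB>S1.0<TAB>S1.1 ...
    1<TAB>1<TAB>75000<TAB>...<TAB>25<TAB>0<TAB>1 ...

File coordinates are 1-based inclusive and are converted to the 0-based
half-open convention used internally on read; genetic positions
(sgpos/egpos) are carried opaquely.  All readers and writers are
gzip-transparent (paths ending in ``.gz``).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import DiploidGenome, HaploidGenome
from .windows import WindowCalls

__all__ = [
    "MspFile",
    "MspParseError",
    "read_msp",
    "write_msp",
    "read_qtl_table",
    "write_tracts_bed",
    "read_tracts_bed",
    "CompositionRule",
    "filter_samples",
    "brangus_rule",
    "santa_gertrudis_rule",
    "beefmaster_rule",
]


class MspParseError(ValueError):
    """Malformed msp input; the message names the offending line."""


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class MspFile:
    """Parsed msp content: legend, window records, per-haplotype codes.

    ``frame`` columns: chrom (str), spos, epos (0-based half-open int),
    sgpos, egpos (opaque strings), n_snps (int).  ``calls[w, 2*i + h]``
    is the code of haplotype ``h`` of sample ``i`` in window ``w``.
    """

    labels: tuple[str, ...]
    samples: list[str]
    frame: pd.DataFrame
    calls: np.ndarray

    def to_window_calls(self) -> WindowCalls:
        windows = self.frame[["chrom", "spos", "epos", "n_snps"]].rename(
            columns={"spos": "start", "epos": "end"}
        )
        return WindowCalls(windows.copy(), self.calls.copy(), list(self.samples), self.labels)

    @classmethod
    def from_window_calls(cls, calls: WindowCalls) -> "MspFile":
        frame = calls.windows.rename(columns={"start": "spos", "end": "epos"}).copy()
        # synthetic genetic positions: physical Mb
        frame["sgpos"] = [f"{s / 1e6:.5f}" for s in frame["spos"]]
        frame["egpos"] = [f"{e / 1e6:.5f}" for e in frame["epos"]]
        frame = frame[["chrom", "spos", "epos", "sgpos", "egpos", "n_snps"]]
        return cls(calls.labels, list(calls.samples), frame, calls.calls.copy())


def read_msp(path) -> MspFile:
    """Parse an msp file, validating legend, sorting, and row shape."""
    with _open_text(path) as fh:
        return _parse_msp(fh)


def _parse_msp(fh) -> MspFile:
    header1 = fh.readline().rstrip("\n")
    prefix = "#Subpopulation order/codes:"
    if not header1.startswith(prefix):
        raise MspParseError("line 1: missing '#Subpopulation order/codes:' header")
    legend: dict[int, str] = {}
    for item in header1[len(prefix):].strip().split("\t"):
        if not item:
            continue
        try:
            label, code = item.rsplit("=", 1)
            legend[int(code)] = label.strip()
        except ValueError:
            raise MspParseError(f"line 1: malformed legend entry {item!r}") from None
    if sorted(legend) != list(range(len(legend))) or not legend:
        raise MspParseError("line 1: legend codes must be 0..k-1")
    labels = tuple(legend[i] for i in range(len(legend)))

    header2 = fh.readline().rstrip("\n")
    cols = header2.lstrip("#").split("\t")
    fixed = ["chm", "spos", "epos", "sgpos", "egpos", "n snps"]
    if cols[: len(fixed)] != fixed:
        raise MspParseError(f"line 2: expected columns {fixed}, got {cols[:6]}")
    hap_cols = cols[len(fixed):]
    if len(hap_cols) % 2:
        raise MspParseError("line 2: odd number of haplotype columns")
    samples = []
    for i in range(0, len(hap_cols), 2):
        s0, s1 = hap_cols[i], hap_cols[i + 1]
        if not (s0.endswith(".0") and s1.endswith(".1") and s0[:-2] == s1[:-2]):
            raise MspParseError(
                f"line 2: haplotype columns {s0!r}, {s1!r} are not a <sample>.0/.1 pair"
            )
        samples.append(s0[:-2])
    n_hap = len(hap_cols)

    records = []
    call_rows = []
    for lineno, line in enumerate(fh, start=3):
        line = line.rstrip("\n").rstrip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 6 + n_hap:
            raise MspParseError(
                f"line {lineno}: expected {6 + n_hap} columns, found {len(fields)}"
            )
        chrom = fields[0]
        try:
            spos1, epos1 = int(fields[1]), int(fields[2])
            n_snps = int(fields[5])
        except ValueError:
            raise MspParseError(f"line {lineno}: malformed coordinates") from None
        spos, epos = spos1 - 1, epos1  # 1-based inclusive -> 0-based half-open
        if spos >= epos:
            raise MspParseError(f"line {lineno}: spos >= epos")
        try:
            codes = np.array(fields[6:], dtype=np.int8)
        except ValueError:
            raise MspParseError(f"line {lineno}: non-integer ancestry code") from None
        if codes.min() < 0 or codes.max() >= len(labels):
            raise MspParseError(
                f"line {lineno}: ancestry code outside legend 0..{len(labels) - 1}"
            )
        records.append((chrom, spos, epos, fields[3], fields[4], n_snps))
        call_rows.append(codes)

    frame = pd.DataFrame(
        records, columns=["chrom", "spos", "epos", "sgpos", "egpos", "n_snps"]
    )
    # sortedness: records grouped by chromosome (first-appearance order),
    # strictly increasing start within each chromosome
    seen: dict[str, int] = {}
    last_chrom = None
    last_spos = -1
    for i, (chrom, spos) in enumerate(zip(frame["chrom"], frame["spos"])):
        if chrom != last_chrom:
            if chrom in seen:
                raise MspParseError(
                    f"line {i + 3}: records for chromosome {chrom!r} are not contiguous"
                )
            seen[chrom] = i
            last_chrom, last_spos = chrom, -1
        if spos <= last_spos:
            raise MspParseError(f"line {i + 3}: records not sorted by position")
        last_spos = spos
    calls = np.vstack(call_rows) if call_rows else np.empty((0, n_hap), dtype=np.int8)
    return MspFile(labels, samples, frame, calls)


def write_msp(msp: MspFile, path) -> None:
    """Write the pinned msp dialect (1-based inclusive coordinates)."""
    with _open_text(path, "wt") as fh:
        legend = "\t".join(f"{label}={i}" for i, label in enumerate(msp.labels))
        fh.write(f"#Subpopulation order/codes: {legend}\n")
        hap_cols = "\t".join(f"{s}.{h}" for s in msp.samples for h in (0, 1))
        fh.write(f"#chm\tspos\tepos\tsgpos\tegpos\tn snps\t{hap_cols}\n")
        f = msp.frame
        for i in range(len(f)):
            row = f.iloc[i]
            codes = "\t".join(str(int(c)) for c in msp.calls[i])
            fh.write(
                f"{row.chrom}\t{row.spos + 1}\t{row.epos}\t{row.sgpos}\t{row.egpos}\t"
                f"{row.n_snps}\t{codes}\n"
            )


# ---------------------------------------------------------------------------
# QTL tables


def read_qtl_table(path) -> pd.DataFrame:
    """Read a QTL TSV: chrom, start, end, trait, trait_class, source_id.

    Coordinates are 0-based half-open.  Raises on malformed or inverted
    intervals, naming the line.  Duplicates are retained (collapse with
    :func:`admixscan.qtl.dedup_colocalized`).
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chrom", "chr", "chromosome"):
                continue
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: expected >=5 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: malformed coordinates") from None
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            trait = fields[3]
            trait_class = fields[4]
            source = fields[5] if len(fields) > 5 else ""
            rows.append((fields[0], start, end, trait, trait_class, source))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "trait", "trait_class", "source_id"]
    )


# ---------------------------------------------------------------------------
# tract BED


def write_tracts_bed(genomes: Sequence[DiploidGenome], path) -> None:
    """Pooled BED4 + haplotype id: chrom, start, end, ancestry, <sample>.<h>."""
    with _open_text(path, "wt") as fh:
        for g in genomes:
            for h, hap in enumerate((g.hap1, g.hap2)):
                for t in hap.tracts():
                    fh.write(f"{t.chrom}\t{t.start_bp}\t{t.end_bp}\t{t.ancestry}\t{g.id}.{h}\n")


def read_tracts_bed(path, labels: Sequence[str]) -> list[DiploidGenome]:
    """Rebuild diploid mosaics from a pooled tract BED written by this package."""
    from .genome import AncestryTract

    labels = tuple(labels)
    per_hap: dict[tuple[str, int], list[AncestryTract]] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"line {lineno}: expected 5 columns")
            chrom, start, end, ancestry, hap_id = fields
            sample, h = hap_id.rsplit(".", 1)
            key = (sample, int(h))
            if sample not in order:
                order.append(sample)
            per_hap.setdefault(key, []).append(
                AncestryTract(chrom, int(start), int(end), ancestry)
            )
    genomes = []
    for sample in order:
        hap1 = HaploidGenome.from_tracts(labels, per_hap[(sample, 0)])
        hap2 = HaploidGenome.from_tracts(labels, per_hap[(sample, 1)])
        genomes.append(DiploidGenome(sample, hap1, hap2))
    return genomes


# ---------------------------------------------------------------------------
# sample-composition filters


@dataclass(frozen=True)
class CompositionRule:
    """Per-ancestry keep-bounds on global ancestry proportions.

    ``bounds[label] = (min_excl, max_excl)``: a sample is kept only if
    ``min_excl < p < max_excl`` for every bounded ancestry (either bound
    may be None).  Violations at the boundary remove the sample, so a
    "remove >= 50% Brahman" rule is ``max_excl = 0.50``.
    """

    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.bounds.items():
            if lo is not None and not 0 <= lo <= 1:
                raise ValueError(f"{label}: min bound outside [0, 1]")
            if hi is not None and not 0 <= hi <= 1:
                raise ValueError(f"{label}: max bound outside [0, 1]")
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{label}: min bound exceeds max bound")

    def violation(self, props: dict[str, float]) -> str | None:
        for label, (lo, hi) in self.bounds.items():
            p = props.get(label, 0.0)
            if lo is not None and p <= lo:
                return f"{label} <= {lo}"
            if hi is not None and p >= hi:
                return f"{label} >= {hi}"
        return None


def brangus_rule() -> CompositionRule:
    """Remove likely founders: >= 50% Brahman or >= 90% Angus."""
    return CompositionRule({"Brahman": (None, 0.50), "Angus": (None, 0.90)})


def santa_gertrudis_rule() -> CompositionRule:
    """Remove likely founders: >= 50% Brahman or >= 90% Shorthorn."""
    return CompositionRule({"Brahman": (None, 0.50), "Shorthorn": (None, 0.90)})


def beefmaster_rule() -> CompositionRule:
    """Remove likely purebreds (>= 90% any founder breed) and likely F1s
    (<= 5% assignment to any one founder breed)."""
    return CompositionRule(
        {b: (0.05, 0.90) for b in ("Shorthorn", "Hereford", "Brahman")}
    )


def filter_samples(
    global_props: pd.DataFrame, rule: CompositionRule
) -> tuple[list[str], list[tuple[str, str]]]:
    """Partition samples into kept and removed (with the violated bound).

    ``global_props`` is indexed by sample id with one column per
    ancestry; each row must sum to 1 within 1e-6.
    """
    sums = global_props.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(
            f"ancestry proportions do not sum to 1 for {bad.index[0]!r} ({bad.iloc[0]:.6f})"
        )
    kept: list[str] = []
    removed: list[tuple[str, str]] = []
    for sample, row in global_props.iterrows():
        why = rule.violation(row.to_dict())
        if why is None:
            kept.append(sample)
        else:
            removed.append((sample, why))
    return kept, removed
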