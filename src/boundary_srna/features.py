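"""Sequence characteristics of boundary-associated small RNAs.

Reads placed in peak-bearing regions are grouped into four categories —
PASR_plus / PASR_RC (TSS regions, sense / antisense) and TASR_plus /
TASR_RC (terminus regions) — and summarised by length distribution
(19–28 nt plus an "other" bin) and 5' terminal nucleotide composition.
The counting unit is the distinct collapsed read sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import SENSE, TSS
from .libraries import MappedRead
from .peaks import PeakCall, ScanConfig

CATEGORIES = ("PASR_plus", "PASR_RC", "TASR_plus", "TASR_RC")
LENGTH_BINS = tuple(range(19, 29))
RNA_BASES = ("A", "C", "G", "U")


def category_of(anchor: str, region_strand: str) -> str:
    stem = "PASR" if anchor == TSS else "TASR"
    return f"{stem}_plus" if region_strand == SENSE else f"{stem}_RC"


@dataclass(frozen=True)
class FeatureSummary:
    """Per-category length histogram and 5' nucleotide fractions."""

    category: str
    n_reads: int
    length_counts: dict[int | str, int]
    length_fractions: dict[int | str, float] | None
    five_prime_counts: dict[str, int]
    five_prime_fractions: dict[str, float] | None


def collect_boundary_srnas(
    placements: Iterable[MappedRead],
    peaks: Sequence[PeakCall],
    config: ScanConfig,
) -> dict[str, set[str]]:
    """Distinct read sequences per category, from peak-bearing regions.

    A read qualifies if at least one of its placements overlaps — fully
    or partially — the scrolling scan interval of a region that carries
    at least one screened peak.
    """
    bounds: dict[tuple[str, str, str], tuple[int, int]] = {}
    for peak in peaks:
        if not peak.screened:
            continue
        r = peak.region
        key = (r.gene_id, r.anchor, r.region_strand)
        bounds[key] = config.bounds(r.L)
    categories: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for p in placements:
        key = (p.gene_id, p.anchor, p.region_strand)
        if key not in bounds:
            continue
        lo, hi = bounds[key]
        if p.start_offset < hi and p.end_offset > lo:
            categories[category_of(p.anchor, p.region_strand)].add(p.sequence)
    return categories


def length_distribution(read_seqs: Iterable[str]) -> tuple[dict, dict | None]:
    """Counts and fractions per length bin 19–28 plus "other"."""
    counts: Counter = Counter()
    n = 0
    for seq in read_seqs:
        n += 1
        counts[len(seq) if len(seq) in LENGTH_BINS else "other"] += 1
    hist = {b: counts.get(b, 0) for b in (*LENGTH_BINS, "other")}
    if n == 0:
        return hist, None
    return hist, {b: c / n for b, c in hist.items()}


def five_prime_composition(read_seqs: Iterable[str]) -> tuple[dict[str, int], dict[str, float] | None]:
    """First-nucleotide counts and fractions in the RNA alphabet.

    T is reported as U; reads starting with any other symbol (e.g. N)
    are tallied separately and excluded from the fractions.
    """
    counts = {b: 0 for b in RNA_BASES}
    other = 0
    for seq in read_seqs:
        first = seq[0].upper().replace("T", "U")
        if first in counts:
            counts[first] += 1
        else:
            other += 1
    counts_out: dict[str, int] = {**counts, "other": other}
    n = sum(counts.values())
    if n == 0:
        return counts_out, None
    return counts_out, {b: counts[b] / n for b in RNA_BASES}


def summarize_category(category: str, read_seqs: set[str]) -> FeatureSummary:
    lc, lf = length_distribution(read_seqs)
    fc, ff = five_prime_composition(read_seqs)
    return FeatureSummary(
        category=category,
        n_reads=len(read_seqs),
        length_counts=lc,
        length_fractions=lf,
        five_prime_counts=fc,
        five_prime_fractions=ff,
    )


def feature_table(categories: Mapping[str, set[str]]) -> pd.DataFrame:
    """One row per category with histogram and composition columns."""
    rows = []
    for cat in CATEGORIES:
        s = summarize_category(cat, categories.get(cat, set()))
        row: dict = {"category": cat, "n_reads": s.n_reads}
        for b in (*LENGTH_BINS, "other"):
            row[f"len_{b}"] = s.length_counts[b]
            row[f"len_{b}_frac"] = s.length_fractions[b] if s.length_fractions else float("nan")
        for b in RNA_BASES:
            row[f"five_prime_{b}"] = s.five_prime_counts[b]
            row[f"five_prime_{b}_frac"] = (
                s.five_prime_fractions[b] if s.five_prime_fractions else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(categories: Mapping[str, set[str]], path: str | Path) -> None:
    feature_table(categories).to_csv(path, sep="\t", index=False)
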