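"""Positional overlap between peaks and site-specific DNA methylation.

The published correspondence was judged by eye on a genome browser;
here it is a reproducible rule: a peak overlaps methylation when at
least ``min_sites`` methylated cytosines with level >= ``level_min``
fall within the peak interval extended by ``slop`` nt on each side.
Tracks are read from bedGraph (per-position levels in [0, 1]) or BED
(intervals treated as fully methylated, level 1.0, merged).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)


class MethylationLoadError(ValueError):
    """Malformed methylation track input."""


@dataclass
class MethylationTrack:
    """Sorted per-chromosome methylated positions with levels in [0, 1]."""

    sites: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[tuple[str, int, float]]) -> "MethylationTrack":
        by_chrom: dict[str, dict[int, float]] = {}
        for chrom, pos, level in records:
            # duplicate positions keep the maximal level
            d = by_chrom.setdefault(chrom, {})
            d[pos] = max(d.get(pos, 0.0), level)
        sites = {}
        for chrom, d in by_chrom.items():
            pos = np.array(sorted(d), dtype=np.int64)
            sites[chrom] = (pos, np.array([d[p] for p in pos]))
        return cls(sites=sites)

    def n_sites(self) -> int:
        return sum(len(p) for p, _ in self.sites.values())

    def qualifying_sites(
        self, chromosome: str, start: int, end: int, level_min: float
    ) -> int:
        """Count sites with level >= level_min in [start, end) (0-based)."""
        if chromosome not in self.sites:
            log.info("methylation track has no chromosome %s", chromosome)
            return 0
        pos, lev = self.sites[chromosome]
        lo, hi = bisect_left(pos, start), bisect_right(pos, end - 1)
        return int(np.count_nonzero(lev[lo:hi] >= level_min))


def load_methylation_track(path: str | Path, dialect: str | None = None) -> MethylationTrack:
    """Load a bedGraph (chrom, start, end, level) or BED interval track.

    bedGraph intervals are expanded to per-position sites; BED records
    (3 columns, or 4+ with a non-numeric name) become level-1.0 sites
    over the merged intervals.
    """
    path = Path(path)
    if dialect is None:
        dialect = "bed" if path.suffix.lower() == ".bed" else "bedgraph"
    records: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MethylationLoadError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MethylationLoadError(f"{path}:{lineno}: bad coordinates") from exc
            if end <= start or start < 0:
                raise MethylationLoadError(f"{path}:{lineno}: invalid interval")
            if dialect == "bedgraph":
                if len(fields) < 4:
                    raise MethylationLoadError(f"{path}:{lineno}: bedGraph needs a level column")
                try:
                    level = float(fields[3])
                except ValueError as exc:
                    raise MethylationLoadError(f"{path}:{lineno}: bad level") from exc
                if not 0.0 <= level <= 1.0:
                    raise MethylationLoadError(
                        f"{path}:{lineno}: level {level} outside [0, 1]"
                    )
            else:
                level = 1.0
            for p in range(start, end):
                records.append((chrom, p, level))
    return MethylationTrack.from_records(records)


def peak_methylation_overlap(
    chromosome: str,
    peak_interval: tuple[int, int],
    track: MethylationTrack,
    level_min: float = 0.1,
    slop: int = 50,
    min_sites: int = 3,
) -> tuple[bool, int]:
    """Flag a peak as methylation-overlapping; returns (flag, site count).

    The extended interval is inclusive of the slop boundary on both
    sides: positions in [start - slop, end + slop) qualify.
    """
    start, end = peak_interval
    n = track.qualifying_sites(
        chromosome, max(0, start - slop), end + slop, level_min
    )
    return n >= min_sites, n
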