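"""Double-stranded-precursor evidence from dsRNA-seq coverage runs.

dsRNA-seq reads (nuclease-protected duplexes) are placed into boundary
regions by perfect matching; maximal runs of consecutive positions with
coverage depth >= ``min_depth`` are extracted, and a peak counts as
dsRNA-covered when it resides entirely within a run of at least 100 nt.
Duplex evidence is strand-agnostic by default: placements from the
sense and antisense region over the same genomic interval are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .peaks import as_placements


@dataclass(frozen=True)
class CoverageRun:
    """A maximal interval with depth >= min_depth at every position."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def coverage_runs(
    placements: Iterable,
    length: int,
    min_depth: int = 1,
) -> list[CoverageRun]:
    """Maximal covered runs over a span of ``length`` positions.

    Depth counts overlapping placements (read counts, not RPM — the
    criterion is physical coverage, not abundance).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = np.zeros(length + 1, dtype=np.int64)
    for p in as_placements(placements):
        depth[max(p.start, 0)] += 1
        depth[min(p.end, length)] -= 1
    covered = np.cumsum(depth[:-1]) >= min_depth
    runs: list[CoverageRun] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        runs.append(CoverageRun(int(s), int(e)))
    return runs


def peak_in_run(
    peak_interval: tuple[int, int],
    runs: Sequence[CoverageRun],
    min_run: int = 100,
    mode: str = "contain",
    min_overlap_fraction: float = 0.5,
) -> bool:
    """Whether a peak resides within a covered run of >= ``min_run`` nt.

    ``contain`` (default) requires the full peak interval inside one
    qualifying run; ``overlap`` accepts a fractional overlap of at
    least ``min_overlap_fraction`` of the peak length.
    """
    s, e = peak_interval
    for run in runs:
        if run.length < min_run:
            continue
        if mode == "contain":
            if run.start <= s and e <= run.end:
                return True
        elif mode == "overlap":
            ov = min(e, run.end) - max(s, run.start)
            if e > s and ov / (e - s) >= min_overlap_fraction:
                return True
        else:
            raise ValueError(f"unknown containment mode {mode!r}")
    return False


def strand_pooled_placements(
    placements_by_strand: dict[str, list],
    L: int,
    target_strand: str,
) -> list[tuple[int, int, float]]:
    """Pool placements from both region strands into one strand's coordinates.

    A placement [s, e) on the opposite strand of the same genomic
    interval maps to [L - e, L - s) on the target strand.
    """
    pooled: list[tuple[int, int, float]] = []
    for strand, rows in placements_by_strand.items():
        for p in as_placements(rows):
            if strand == target_strand:
                pooled.append((p.start, p.end, p.rpm))
            else:
                pooled.append((L - p.end, L - p.start, p.rpm))
    return pooled


def write_runs_bed(
    runs_by_region: dict, path, regions_by_key: dict
) -> None:
    """Coverage runs in genomic BED coordinates (name = region id)."""
    with open(path, "w") as fh:
        for key, runs in sorted(runs_by_region.items()):
            region = regions_by_key[key]
            for run in runs:
                gs, ge = region.to_genomic(run.start, run.end)
                fh.write(
                    f"{region.chromosome}\t{gs}\t{ge}\t{region.name}\t{run.length}\t"
                    f"{'+' if region.seq_is_forward else '-'}\n"
                )
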