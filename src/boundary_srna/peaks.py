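"""Scrolling-window peak detection on boundary-region abundance profiles.

For each region of length L the summed RPM of all placed reads is S1
and the regional mean density A1 = S1/L.  A 50-nt window is scrolled in
1-nt steps; at each step S2 is the summed RPM of reads overlapping the
window and A2 = S2/50.  A window passes when A2 is at least
``ratio_threshold`` times A1 (default 10) *and* at least
``abs_threshold`` RPM/nt (default 1).  Maximal groups of mutually
overlapping passing windows are merged into candidate peaks, which are
then screened against the surrounding signal: the mean in-peak density
must exceed the out-of-peak density by ``noise_ratio_min`` so that a
peak is not submerged in the regional sRNA noise (an automated stand-in
for by-eye screening).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import BoundaryRegion

#: read-to-window assignment policies for S2
ASSIGNMENT_POLICIES = ("overlap", "five_prime", "coverage")


@dataclass(frozen=True)
class Placement:
    """Minimal view of a placed read inside one region."""

    start: int
    end: int
    rpm: float


def as_placements(rows: Iterable) -> list[Placement]:
    """Coerce MappedRead objects or (start, end, rpm) tuples."""
    out = []
    for r in rows:
        if isinstance(r, Placement):
            out.append(r)
        elif hasattr(r, "start_offset"):
            out.append(Placement(r.start_offset, r.end_offset, r.rpm))
        else:
            s, e, rpm = r
            out.append(Placement(int(s), int(e), float(rpm)))
    return out


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the scrolling-window screen.

    ``scan_interval`` restricts scrolling to a sub-interval of the
    region; ``None`` scans the whole region.  ``noise_ratio_min`` is
    the automated surrogate for manual noise screening;
    ``min_peak_rpm_fraction`` optionally requires a peak to hold at
    least that fraction of the regional S1 (0 disables it).
    """

    window: int = 50
    step: int = 1
    ratio_threshold: float = 10.0
    abs_threshold: float = 1.0
    scan_interval: tuple[int, int] | None = None
    noise_ratio_min: float = 3.0
    min_peak_rpm_fraction: float = 0.0
    assignment: str = "overlap"
    min_pair_overlap: int = 1

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be positive")
        if min(self.ratio_threshold, self.abs_threshold, self.noise_ratio_min) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.assignment not in ASSIGNMENT_POLICIES:
            raise ValueError(f"unknown assignment policy {self.assignment!r}")

    def bounds(self, L: int) -> tuple[int, int]:
        lo, hi = self.scan_interval if self.scan_interval is not None else (0, L)
        lo, hi = max(0, lo), min(L, hi)
        if hi - lo < self.window:
            raise ValueError(
                f"scan interval [{lo}, {hi}) shorter than the {self.window}-nt window"
            )
        return lo, hi


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-region RPM signal pooled over one or more libraries."""

    region: BoundaryRegion
    library_pool: tuple[str, ...]
    placements: tuple[Placement, ...]
    per_position_rpm: np.ndarray
    S1: float

    @property
    def L(self) -> int:
        return self.region.L

    @property
    def A1(self) -> float:
        return self.S1 / self.L


@dataclass(frozen=True)
class WindowStat:
    start_offset: int
    width: int
    S2: float
    passes: bool

    @property
    def A2(self) -> float:
        return self.S2 / self.width


@dataclass(frozen=True)
class PeakCall:
    """A merged run of passing windows, screened against background."""

    region: BoundaryRegion
    peak_start: int
    peak_end: int
    a2_max: float
    mean_density_in: float
    mean_density_out: float
    screened: bool

    @property
    def noise_ratio(self) -> float:
        if self.mean_density_out == 0.0:
            return math.inf
        return self.mean_density_in / self.mean_density_out

    @property
    def genomic_interval(self) -> tuple[int, int]:
        return self.region.to_genomic(self.peak_start, self.peak_end)

    @property
    def length(self) -> int:
        return self.peak_end - self.peak_start


def build_profile(
    placements: Iterable,
    region: BoundaryRegion,
    library_pool: Sequence[str] = (),
) -> AbundanceProfile:
    """Sum placements into S1 and a per-position coverage vector.

    ``per_position_rpm[p]`` is the summed RPM of placements whose
    interval contains position p; S1 is the summed RPM of all
    placements regardless of position.
    """
    L = region.L
    if L <= 0:
        raise ValueError(f"{region.name}: empty region")
    placed = as_placements(placements)
    cov = np.zeros(L + 1)
    s1 = 0.0
    for p in placed:
        if not 0 <= p.start < p.end <= L:
            raise ValueError(f"placement [{p.start}, {p.end}) outside region of length {L}")
        cov[p.start] += p.rpm
        cov[p.end] -= p.rpm
        s1 += p.rpm
    return AbundanceProfile(
        region=region,
        library_pool=tuple(library_pool),
        placements=tuple(placed),
        per_position_rpm=np.cumsum(cov[:-1]),
        S1=s1,
    )


def _window_sums(profile: AbundanceProfile, config: ScanConfig) -> tuple[np.ndarray, int]:
    """S2 for every window start in the scan interval (incremental form)."""
    lo, hi = config.bounds(profile.L)
    w = config.window
    n = hi - lo - w + 1
    starts = np.arange(lo, hi - w + 1)
    if config.assignment == "coverage":
        csum = np.concatenate(([0.0], np.cumsum(profile.per_position_rpm)))
        return csum[starts + w] - csum[starts], lo
    # difference array over window starts: placement [s, e) overlaps
    # window [x, x+w) iff x in [s - w + 1, e - 1]
    diff = np.zeros(n + 1)
    for p in profile.placements:
        if config.assignment == "five_prime":
            a, b = p.start - w + 1, p.start
        else:
            a, b = p.start - w + 1, p.end - 1
        a = max(a, lo) - lo
        b = min(b, hi - w) - lo
        if a <= b:
            diff[a] += p.rpm
            diff[b + 1] -= p.rpm
    return np.cumsum(diff[:-1]), lo


def scroll_windows(profile: AbundanceProfile, config: ScanConfig) -> list[WindowStat]:
    """Scroll the window across the region and apply the dual criterion."""
    s2, lo = _window_sums(profile, config)
    a1 = profile.A1
    stats = []
    for i in range(0, len(s2), config.step):
        a2 = s2[i] / config.window
        passes = a2 >= config.ratio_threshold * a1 and a2 >= config.abs_threshold
        stats.append(WindowStat(lo + i, config.window, float(s2[i]), bool(passes)))
    return stats


def call_peaks(
    window_stats: Sequence[WindowStat],
    profile: AbundanceProfile,
    config: ScanConfig,
) -> list[PeakCall]:
    """Merge passing windows into peaks and screen them against noise.

    Passing windows are merged while their 50-nt intervals share at
    least one position; abutting-but-disjoint runs stay separate.  The
    noise ratio compares the mean per-position density inside the peak
    with the mean over the scan interval outside all candidate peaks;
    zero outside density screens as passing.
    """
    w = config.window
    lo, hi = config.bounds(profile.L)
    passing = [s.start_offset for s in window_stats if s.passes]
    if not passing:
        return []
    groups: list[list[int]] = [[passing[0]]]
    for start in passing[1:]:
        if start < groups[-1][-1] + w:  # window intervals overlap
            groups[-1].append(start)
        else:
            groups.append([start])

    a2_by_start = {s.start_offset: s.A2 for s in window_stats}
    intervals = [(g[0], g[-1] + w) for g in groups]
    outside = np.ones(hi - lo, dtype=bool)
    for s, e in intervals:
        outside[s - lo : e - lo] = False
    cov = profile.per_position_rpm
    out_density = float(cov[lo:hi][outside].mean()) if outside.any() else 0.0

    calls = []
    for g, (s, e) in zip(groups, intervals):
        in_density = float(cov[s:e].mean())
        noise_ok = out_density == 0.0 or in_density / out_density >= config.noise_ratio_min
        frac_ok = True
        if config.min_peak_rpm_fraction > 0 and profile.S1 > 0:
            in_rpm = sum(p.rpm for p in profile.placements if p.start < e and p.end > s)
            frac_ok = in_rpm / profile.S1 >= config.min_peak_rpm_fraction
        calls.append(
            PeakCall(
                region=profile.region,
                peak_start=s,
                peak_end=e,
                a2_max=max(a2_by_start[x] for x in g),
                mean_density_in=in_density,
                mean_density_out=out_density,
                screened=bool(noise_ok and frac_ok),
            )
        )
    return calls


def scan_region(
    placements: Iterable,
    region: BoundaryRegion,
    config: ScanConfig,
    library_pool: Sequence[str] = (),
) -> list[PeakCall]:
    """Convenience: profile, scroll and call in one step."""
    profile = build_profile(placements, region, library_pool)
    return call_peaks(scroll_windows(profile, config), profile, config)


def pair_peaks(
    sense_peaks: Sequence[PeakCall],
    antisense_peaks: Sequence[PeakCall],
    min_pair_overlap: int = 1,
) -> list[tuple[PeakCall, PeakCall]]:
    """Symmetric sense/antisense peaks at the same anchor of one gene.

    A pair is reported when two *screened* peaks overlap by at least
    ``min_pair_overlap`` nt in genomic coordinates.
    """
    pairs = []
    for sp in sense_peaks:
        if not sp.screened:
            continue
        ss, se = sp.genomic_interval
        for ap in antisense_peaks:
            if not ap.screened:
                continue
            if (sp.region.gene_id, sp.region.anchor) != (ap.region.gene_id, ap.region.anchor):
                continue
            as_, ae = ap.genomic_interval
            if min(se, ae) - max(ss, as_) >= min_pair_overlap:
                pairs.append((sp, ap))
    return pairs
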