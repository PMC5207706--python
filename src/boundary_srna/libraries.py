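"""Small-RNA library loading, RPM normalisation and perfect-match placement.

A library is either a collapsed FASTA (unique sequences with the raw
count encoded in the header, e.g. ``>r1_15``) or a plain FASTQ where
every record counts once.  Identical sequences are collapsed with
summed counts; the library total is taken *before* any filtering so RPM
values are comparable across libraries.  Reads are placed into boundary
regions by exact substring matching only — no mismatches, no indels —
independently on the sense and antisense region sequences.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import BoundaryRegion

log = logging.getLogger(__name__)

MAX_READ_LENGTH = 40  # exclusive bound; HTS sRNA reads are all shorter than 40 nt

LIBRARY_ROLES = ("wt", "ago1", "ago4", "mutant", "dsrna")


class LibraryLoadError(ValueError):
    """Unreadable or malformed library file."""


@dataclass(frozen=True)
class Library:
    """Metadata for one sequencing library."""

    library_id: str
    role: str
    organ_or_genotype: str
    total_raw_count: int
    platform_note: str = ""

    def __post_init__(self) -> None:
        if self.role not in LIBRARY_ROLES:
            raise ValueError(f"{self.library_id}: unknown role {self.role!r}")
        if self.total_raw_count <= 0:
            raise ValueError(f"{self.library_id}: empty library")


@dataclass(frozen=True)
class SmallRNARead:
    """One collapsed read: a unique sequence with its summed raw count."""

    sequence: str
    raw_count: int
    rpm: float
    library_id: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MappedRead:
    """A perfect placement of a read inside a boundary region."""

    sequence: str
    gene_id: str
    anchor: str
    region_strand: str
    start_offset: int
    end_offset: int
    raw_count: int
    rpm: float
    library_id: str


def normalize_rpm(raw_count: int, total_raw_count: int) -> float:
    """Reads-per-million: raw count over library total, times 1e6."""
    if total_raw_count <= 0:
        raise ValueError("total_raw_count must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    return raw_count / total_raw_count * 1e6


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _parse_collapsed_header(header: str, separator: str) -> int:
    name = header.split()[0]
    _, sep, count = name.rpartition(separator)
    if not sep or not count.isdigit():
        raise LibraryLoadError(
            f"collapsed-FASTA header {header!r} lacks a trailing "
            f"{separator!r}-separated count"
        )
    return int(count)


def load_library(
    path: str | Path,
    library_id: str,
    role: str,
    organ_or_genotype: str,
    fmt: str | None = None,
    count_separator: str = "_",
    platform_note: str = "",
) -> tuple[Library, list[SmallRNARead]]:
    """Load and collapse one library.

    Returns the library metadata (with total raw count computed before
    any filtering) and its collapsed reads.  Reads containing N or of
    length >= 40 nt contribute to the total but are excluded from the
    returned (mappable) read set.
    """
    from Bio import SeqIO

    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    counts: dict[str, int] = defaultdict(int)
    total = 0
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            count = 1 if fmt == "fastq" else _parse_collapsed_header(
                rec.description or rec.id, count_separator
            )
            if count <= 0:
                raise LibraryLoadError(f"{path} record {i + 1}: non-positive count")
            counts[_normalize_seq(str(rec.seq))] += count
            total += count
    except LibraryLoadError:
        raise
    except Exception as exc:  # Bio.SeqIO errors carry no line numbers
        raise LibraryLoadError(f"cannot parse {path}: {exc}") from exc
    if total == 0:
        raise LibraryLoadError(f"{path}: no reads")

    library = Library(
        library_id=library_id,
        role=role,
        organ_or_genotype=organ_or_genotype,
        total_raw_count=total,
        platform_note=platform_note,
    )
    reads: list[SmallRNARead] = []
    n_dropped = 0
    for seq in sorted(counts):
        if len(seq) >= MAX_READ_LENGTH or "N" in seq:
            n_dropped += 1
            continue
        reads.append(
            SmallRNARead(
                sequence=seq,
                raw_count=counts[seq],
                rpm=normalize_rpm(counts[seq], total),
                library_id=library_id,
            )
        )
    if n_dropped:
        log.warning(
            "%s: %d collapsed reads excluded from mapping (N bases or length >= %d)",
            library_id, n_dropped, MAX_READ_LENGTH,
        )
    return library, reads


class RegionIndex:
    """Exact-match index over region sequences.

    Seeds every region k-mer into a dictionary; a read is placed by
    looking up its first k bases and verifying the full sequence.
    Reads shorter than k fall back to a linear scan.
    """

    def __init__(self, regions: Sequence[BoundaryRegion], k: int = 12) -> None:
        self.regions = list(regions)
        self.k = k
        self._seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for idx, region in enumerate(self.regions):
            seq = _normalize_seq(region.sequence)
            for off in range(len(seq) - k + 1):
                self._seeds[seq[off : off + k]].append((idx, off))

    def find(self, read_seq: str) -> list[tuple[BoundaryRegion, int]]:
        """All (region, offset) placements where the read matches exactly."""
        seq = _normalize_seq(read_seq)
        hits: list[tuple[BoundaryRegion, int]] = []
        if len(seq) < self.k:
            for region in self.regions:
                rseq = _normalize_seq(region.sequence)
                off = rseq.find(seq)
                while off != -1:
                    hits.append((region, off))
                    off = rseq.find(seq, off + 1)
            return hits
        for idx, off in self._seeds.get(seq[: self.k], ()):
            region = self.regions[idx]
            if _normalize_seq(region.sequence).startswith(seq, off):
                hits.append((region, off))
        return hits


def map_perfect(
    reads: Iterable[SmallRNARead],
    regions: Sequence[BoundaryRegion],
    index: RegionIndex | None = None,
) -> list[MappedRead]:
    """Place reads into regions at every exact occurrence.

    U and T are equivalent; a read may hit several regions and several
    offsets.  Reads without any perfect match simply yield nothing.
    """
    if index is None:
        index = RegionIndex(regions)
    placements: list[MappedRead] = []
    for read in reads:
        for region, off in index.find(read.sequence):
            placements.append(
                MappedRead(
                    sequence=read.sequence,
                    gene_id=region.gene_id,
                    anchor=region.anchor,
                    region_strand=region.region_strand,
                    start_offset=off,
                    end_offset=off + read.length,
                    raw_count=read.raw_count,
                    rpm=read.rpm,
                    library_id=read.library_id,
                )
            )
    return placements


PLACEMENT_COLUMNS = [
    "gene_id",
    "anchor",
    "region_strand",
    "start",
    "end",
    "sequence",
    "raw_count",
    "rpm",
    "library_id",
]


def placements_to_frame(placements: Iterable[MappedRead]) -> pd.DataFrame:
    """Tabulate placements (one row per read-region-offset)."""
    rows = [
        (p.gene_id, p.anchor, p.region_strand, p.start_offset, p.end_offset,
         p.sequence, p.raw_count, p.rpm, p.library_id)
        for p in placements
    ]
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)


def write_placements(placements: Iterable[MappedRead], path: str | Path) -> None:
    placements_to_frame(placements).to_csv(path, sep="\t", index=False)


def read_placements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "library_id": str})
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise LibraryLoadError(f"{path}: placement table missing columns {sorted(missing)}")
    return df
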