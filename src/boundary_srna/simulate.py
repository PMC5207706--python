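"""Self-contained synthetic dataset with planted ground truth.

The generator emits everything the pipeline consumes — a random
genome, a TAIR-style GFF3, collapsed-FASTA sRNA libraries for four
wild-type organs, four AGO1-IP and four AGO4-IP libraries, an
eight-genotype biogenesis-mutant panel, one dsRNA-seq library, a
methylation bedGraph and a truth table — so every stage can be tested
against known answers without downloads.

The stated world: reads are 19–28 nt with a 23–24-nt mode and a 5'-A
bias (~36% A, ~29% U); a configurable fraction of genes carries a
planted boundary peak whose pooled read budget is ``enrichment`` times
the region's background; organ-specific peaks send ~90% of their reads
to one organ; AGO4-preferring peaks load the AGO4-IP libraries
ten-fold over AGO1-IP; suppressed genotypes keep only
``suppression_factor`` of the peak budget; dsRNA-covered peaks get a
continuous tile of duplex reads; methylated peaks get co-located
cytosine sites.  Background reads are scattered uniformly per region
and are verified post hoc not to form accidental threshold-passing
windows (offending regions are re-drawn with a derived seed).

Determinism: one seed; per-library sub-streams are derived from stable
library names, so adding a library never perturbs another.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    ANTISENSE,
    SENSE,
    TERMINUS,
    TSS,
    BoundaryRegion,
    GeneModel,
    extract_boundary_regions,
)
from .peaks import ScanConfig, build_profile, scroll_windows

log = logging.getLogger(__name__)

ORGANS = ("flower", "leaf", "root", "seedling")
MUTANTS = ("dcl2", "dcl3", "dcl4", "dcl234", "rdr2", "rdr6", "nrpd1a", "nrpd1b")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world (defaults are the stated world)."""

    seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (400, 3000)
    intergenic_gap: int = 700
    flank: int = 500
    frac_tss_peaks: float = 0.2
    frac_terminus_peaks: float = 0.2
    frac_paired: float = 0.3
    peak_span_range: tuple[int, int] = (60, 120)
    peak_margin: int = 60
    enrichment: float = 20.0
    bg_reads_per_region: int = 8
    ago_bg_reads_per_region: int = 4
    library_size: int = 100_000
    length_probs: dict[int, float] = field(
        default_factory=lambda: {
            19: 0.03, 20: 0.05, 21: 0.12, 22: 0.11, 23: 0.20,
            24: 0.32, 25: 0.07, 26: 0.05, 27: 0.03, 28: 0.02,
        }
    )
    five_prime_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.36, "T": 0.29, "C": 0.175, "G": 0.175}
    )
    frac_organ_specific: float = 0.3
    organ_dominance: float = 0.91
    ago4_frac: float = 0.5
    ago1_frac: float = 0.25
    ago_contrast: float = 10.0
    suppression_factor: float = 0.05
    frac_rddm: float = 0.5  # suppressed in dcl234, rdr2, nrpd1a
    frac_rdr6: float = 0.3  # suppressed in dcl234, rdr6
    dsrna_frac: float = 0.6
    dsrna_tile_length: int = 36
    dsrna_tile_step: int = 12
    dsrna_flank: int = 60
    dsrna_tile_depth: int = 2
    methylated_frac: float = 0.5
    meth_sites_per_peak: int = 6
    meth_level_range: tuple[float, float] = (0.6, 0.95)
    max_bg_redraws: int = 5

    def __post_init__(self) -> None:
        for name, p in (
            ("frac_tss_peaks", self.frac_tss_peaks),
            ("frac_terminus_peaks", self.frac_terminus_peaks),
            ("frac_paired", self.frac_paired),
            ("frac_organ_specific", self.frac_organ_specific),
            ("ago4_frac", self.ago4_frac),
            ("dsrna_frac", self.dsrna_frac),
            ("methylated_frac", self.methylated_frac),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        span_max = self.peak_span_range[1] + 2 * self.peak_margin
        min_region = self.flank + min(self.flank, self.gene_length_range[0])
        if span_max > min_region:
            raise ValueError("peak span plus margins exceeds the smallest region")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-purpose sub-stream keyed by a stable name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


@dataclass
class SimulatedDataset:
    """Paths to the emitted files plus the in-memory truth table."""

    root: Path
    genome_fasta: Path
    gff3: Path
    metadata_yaml: Path
    methylation_bedgraph: Path
    truth_tsv: Path
    library_paths: dict[str, Path]
    truth: pd.DataFrame


class _ReadSampler:
    """Samples read sequences from a region with length and 5'-base bias."""

    def __init__(self, config: SimConfig) -> None:
        self.lengths = np.array(sorted(config.length_probs))
        self.length_p = np.array([config.length_probs[k] for k in self.lengths])
        self.length_p = self.length_p / self.length_p.sum()
        self.bases = list(config.five_prime_probs)
        self.base_p = np.array([config.five_prime_probs[b] for b in self.bases])
        self.base_p = self.base_p / self.base_p.sum()
        self.max_len = int(self.lengths.max())

    def sample(
        self,
        rng: np.random.Generator,
        seq: str,
        arr: np.ndarray,
        lo: int,
        hi: int,
        n: int,
    ) -> list[str]:
        """Draw n reads starting in [lo, hi - max_len] of the region sequence."""
        hi_start = hi - self.max_len
        if hi_start < lo:
            lo, hi_start = max(0, hi_start), max(lo, self.max_len)
        window = arr[lo : hi_start + 1]
        n_per_base = rng.multinomial(n, self.base_p)
        starts = np.empty(n, dtype=np.int64)
        k = 0
        for base, nb in zip(self.bases, n_per_base):
            if nb == 0:
                continue
            candidates = np.flatnonzero(window == ord(base))
            if len(candidates) == 0:
                starts[k : k + nb] = lo + rng.integers(0, len(window), size=nb)
            else:
                starts[k : k + nb] = lo + rng.choice(candidates, size=nb)
            k += nb
        lens = rng.choice(self.lengths, size=n, p=self.length_p)
        return [seq[s : s + l] for s, l in zip(starts, lens)]


def _plan_genome(config: SimConfig, rng: np.random.Generator):
    """Lay out genes on chromosomes and synthesise the sequences."""
    glo, ghi = config.gene_length_range
    margin = config.flank + config.intergenic_gap
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    genomes: dict[str, str] = {}
    models: list[GeneModel] = []
    gid = 0
    for ci, n_here in enumerate(per_chrom, start=1):
        chrom = f"Chr{ci}"
        cursor = margin
        spans = []
        for _ in range(n_here):
            gid += 1
            body = int(rng.integers(glo, ghi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = cursor, cursor + body - 1  # 0-based inclusive
            spans.append((f"SYN{ci}G{gid:05d}", strand, start, end, body))
            cursor = end + 1 + margin
        chrom_len = cursor + margin
        genomes[chrom] = _random_seq(rng, chrom_len)
        for gene_id, strand, s0, e0, body in spans:
            tss, term = (s0 + 1, e0 + 1) if strand == "+" else (e0 + 1, s0 + 1)
            models.append(
                GeneModel(
                    gene_id=gene_id, chromosome=chrom, strand=strand,
                    tss=tss, terminus=term, body_length=body,
                )
            )
    return genomes, models


def _plant_truth(config: SimConfig, rng: np.random.Generator,
                 models: Sequence[GeneModel],
                 regions_by_key: dict) -> pd.DataFrame:
    """Decide which genes carry peaks and assign every planted label."""
    rows = []
    span_lo, span_hi = config.peak_span_range
    for model in models:
        for anchor, frac in ((TSS, config.frac_tss_peaks), (TERMINUS, config.frac_terminus_peaks)):
            if rng.random() >= frac:
                continue
            region = regions_by_key[(model.gene_id, anchor, SENSE)]
            span = int(rng.integers(span_lo, span_hi + 1))
            lo = max(config.peak_margin, region.anchor_offset - 250)
            hi = min(region.L - config.peak_margin - span, region.anchor_offset + 150)
            if hi < lo:
                lo, hi = config.peak_margin, region.L - config.peak_margin - span
            pstart = int(rng.integers(lo, hi + 1))
            paired = rng.random() < config.frac_paired
            organ = (
                ORGANS[int(rng.integers(len(ORGANS)))]
                if rng.random() < config.frac_organ_specific
                else "none"
            )
            u = rng.random()
            ago = "AGO4" if u < config.ago4_frac else (
                "AGO1" if u < config.ago4_frac + config.ago1_frac else "none"
            )
            v = rng.random()
            if v < config.frac_rddm:
                suppressed = ("dcl234", "rdr2", "nrpd1a")
            elif v < config.frac_rddm + config.frac_rdr6:
                suppressed = ("dcl234", "rdr6")
            else:
                suppressed = ()
            dsrna = rng.random() < config.dsrna_frac
            meth = rng.random() < config.methylated_frac
            gstart, gend = region.to_genomic(pstart, pstart + span)
            strands = (SENSE, ANTISENSE) if paired else (SENSE,)
            for strand in strands:
                rows.append(
                    {
                        "gene_id": model.gene_id,
                        "anchor": anchor,
                        "region_strand": strand,
                        "chromosome": model.chromosome,
                        "start": gstart,
                        "end": gend,
                        "organ": organ,
                        "ago": ago,
                        "suppressed": ",".join(suppressed),
                        "dsrna_covered": dsrna,
                        "methylated": meth,
                        "paired": paired,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "anchor", "region_strand", "chromosome", "start", "end",
            "organ", "ago", "suppressed", "dsrna_covered", "methylated", "paired",
        ],
    )


def _local_interval(region: BoundaryRegion, gstart: int, gend: int) -> tuple[int, int]:
    if region.seq_is_forward:
        return gstart - region.start, gend - region.start
    return region.end - gend, region.end - gstart


def _write_collapsed_fasta(path: Path, counts: dict[str, int],
                           target_total: int, filler: str) -> None:
    emitted = sum(counts.values())
    if emitted > target_total:
        raise ValueError(
            f"{path.name}: emitted {emitted} reads exceed the configured "
            f"library size {target_total}"
        )
    with open(path, "w") as fh:
        for i, seq in enumerate(sorted(counts), start=1):
            fh.write(f">s{i}_{counts[seq]}\n{seq}\n")
        if emitted < target_total:
            fh.write(f">filler_{target_total - emitted}\n{filler}\n")


def _background_passes(counts_placements, region, config: SimConfig,
                       scan: ScanConfig) -> bool:
    """True when background alone would trip the A2 window criteria."""
    rpm = 1e6 / config.library_size
    placements = [(s, e, rpm) for s, e in counts_placements]
    profile = build_profile(placements, region)
    return any(w.passes for w in scroll_windows(profile, scan))


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimulatedDataset:
    """Generate the full dataset under ``outdir`` and return its manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = _rng(config.seed, "design")
    genomes, models = _plan_genome(config, design)

    regions: list[BoundaryRegion] = []
    for model in models:
        regions.extend(extract_boundary_regions(model, genomes, flank=config.flank))
    regions_by_key = {(r.gene_id, r.anchor, r.region_strand): r for r in regions}
    region_arrays = {
        k: np.frombuffer(r.sequence.encode(), dtype=np.uint8)
        for k, r in regions_by_key.items()
    }

    truth = _plant_truth(config, design, models, regions_by_key)
    sampler = _ReadSampler(config)
    scan = ScanConfig()

    wt_ids = [f"wt_{o}" for o in ORGANS]
    ago_ids = [f"{g}_{o}" for g in ("ago1", "ago4") for o in ORGANS]
    mutant_ids = list(MUTANTS)
    all_ids = wt_ids + ago_ids + mutant_ids + ["dsrna"]
    lib_counts: dict[str, dict[str, int]] = {lid: {} for lid in all_ids}
    lib_rngs = {lid: _rng(config.seed, f"library:{lid}") for lid in all_ids}

    def emit(lib_id: str, key, lo: int, hi: int, n: int) -> None:
        if n <= 0:
            return
        region = regions_by_key[key]
        reads = sampler.sample(
            lib_rngs[lib_id], region.sequence, region_arrays[key], lo, hi, n
        )
        counts = lib_counts[lib_id]
        for seq in reads:
            counts[seq] = counts.get(seq, 0) + 1

    # --- background, with the post-hoc accidental-window check -------------
    bg_lib_sets = {
        "wt": (wt_ids, config.bg_reads_per_region),
        "ago": (ago_ids, config.ago_bg_reads_per_region),
        "mutant": (mutant_ids, config.bg_reads_per_region),
    }
    for key, region in regions_by_key.items():
        for attempt in range(config.max_bg_redraws):
            drawn: dict[str, list[str]] = {}
            placements: list[tuple[int, int]] = []
            for group, (lib_ids, n_bg) in bg_lib_sets.items():
                for lib_id in lib_ids:
                    rng = _rng(
                        config.seed, f"bg:{lib_id}:{region.name}:attempt{attempt}"
                    )
                    reads = sampler.sample(
                        rng, region.sequence, region_arrays[key], 0, region.L, n_bg
                    )
                    drawn[lib_id] = reads
                    if group == "wt":
                        off = 0
                        # placements only needed for the WT pooled check
                        for seq in reads:
                            off = region.sequence.find(seq, 0)
                            placements.append((off, off + len(seq)))
            if not _background_passes(placements, region, config, scan):
                break
            log.info(
                "background redraw for %s (attempt %d): accidental window", region.name, attempt
            )
        for lib_id, reads in drawn.items():
            counts = lib_counts[lib_id]
            for seq in reads:
                counts[seq] = counts.get(seq, 0) + 1

    # --- planted peak reads -------------------------------------------------
    pooled_bg_rpm = config.bg_reads_per_region * len(wt_ids)
    n_peak_pooled = int(round(config.enrichment * pooled_bg_rpm))
    meth_records: list[tuple[str, int, float]] = []
    design_meth = _rng(config.seed, "methylation")

    for _, t in truth.iterrows():
        key = (t.gene_id, t.anchor, t.region_strand)
        region = regions_by_key[key]
        ps, pe = _local_interval(region, t.start, t.end)
        organ_w = np.full(len(ORGANS), 1.0 / len(ORGANS))
        if t.organ != "none":
            oi = ORGANS.index(t.organ)
            organ_w = np.full(len(ORGANS), (1.0 - config.organ_dominance) / (len(ORGANS) - 1))
            organ_w[oi] = config.organ_dominance

        # wild-type organ libraries
        wt_split = _rng(config.seed, f"split:wt:{region.name}").multinomial(
            n_peak_pooled, organ_w
        )
        for organ, n in zip(ORGANS, wt_split):
            emit(f"wt_{organ}", key, ps, pe, int(n))

        # AGO-IP libraries
        if t.ago == "AGO4":
            n4, n1 = n_peak_pooled, int(round(n_peak_pooled / config.ago_contrast))
        elif t.ago == "AGO1":
            n4, n1 = int(round(n_peak_pooled / config.ago_contrast)), n_peak_pooled
        else:
            n4 = n1 = n_peak_pooled // 2
        for prefix, total in (("ago1", n1), ("ago4", n4)):
            split = _rng(config.seed, f"split:{prefix}:{region.name}").multinomial(
                total, organ_w
            )
            for organ, n in zip(ORGANS, split):
                emit(f"{prefix}_{organ}", key, ps, pe, int(n))

        # mutant panel
        suppressed = set(t.suppressed.split(",")) if t.suppressed else set()
        for genotype in MUTANTS:
            factor = config.suppression_factor if genotype in suppressed else 1.0
            emit(genotype, key, ps, pe, int(round(n_peak_pooled * factor)))

        # dsRNA-seq tiles (sense region coordinates; evidence is strand-agnostic,
        # so paired truth rows share one tile set emitted for the sense row)
        if t.dsrna_covered and t.region_strand == SENSE:
            lo = max(0, ps - config.dsrna_flank)
            hi = min(region.L, pe + config.dsrna_flank)
            counts = lib_counts["dsrna"]
            for start in range(lo, hi - config.dsrna_tile_length + 1, config.dsrna_tile_step):
                seq = region.sequence[start : start + config.dsrna_tile_length]
                counts[seq] = counts.get(seq, 0) + config.dsrna_tile_depth
            last = ((hi - config.dsrna_tile_length - lo) // config.dsrna_tile_step
                    ) * config.dsrna_tile_step + lo
            if last + config.dsrna_tile_length < hi:  # close the right edge
                seq = region.sequence[hi - config.dsrna_tile_length : hi]
                counts[seq] = counts.get(seq, 0) + config.dsrna_tile_depth

        # methylation sites inside the planted interval (genomic coords)
        if t.methylated and t.region_strand == SENSE:
            span = t.end - t.start
            n_sites = min(config.meth_sites_per_peak, span)
            offs = design_meth.choice(span, size=n_sites, replace=False)
            lo_l, hi_l = config.meth_level_range
            for off in sorted(offs):
                level = float(design_meth.uniform(lo_l, hi_l))
                meth_records.append((t.chromosome, int(t.start + off), round(level, 3)))

    # --- write everything ---------------------------------------------------
    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        for chrom in sorted(genomes):
            fh.write(f">{chrom}\n")
            seq = genomes[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    gff3 = outdir / "annotation.gff3"
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = sorted((m.tss, m.terminus))
            fh.write(
                f"{m.chromosome}\tsim\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
                f"{m.chromosome}\tsim\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.1;Parent={m.gene_id}\n"
            )

    library_paths: dict[str, Path] = {}
    meta_libs = []
    for lib_id in all_ids:
        path = outdir / f"{lib_id}.fa"
        filler = _random_seq(_rng(config.seed, f"filler:{lib_id}"), 30)
        _write_collapsed_fasta(path, lib_counts[lib_id], config.library_size, filler)
        library_paths[lib_id] = path
        if lib_id.startswith("wt_"):
            role, label = "wt", lib_id.split("_", 1)[1]
        elif lib_id.startswith(("ago1_", "ago4_")):
            role, label = lib_id.split("_", 1)[0], lib_id.split("_", 1)[1]
        elif lib_id == "dsrna":
            role, label = "dsrna", "dsrna"
        else:
            role, label = "mutant", lib_id
        meta_libs.append(
            {"library_id": lib_id, "path": path.name, "role": role,
             "organ_or_genotype": label}
        )

    meth_path = outdir / "methylation.bedgraph"
    with open(meth_path, "w") as fh:
        for chrom, pos, level in sorted(meth_records):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{level}\n")

    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    metadata = {
        "genome_fasta": genome_fasta.name,
        "annotation_gff3": gff3.name,
        "methylation_bedgraph": meth_path.name,
        "truth_tsv": truth_path.name,
        "libraries": meta_libs,
    }
    metadata_yaml = outdir / "metadata.yaml"
    with open(metadata_yaml, "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)

    return SimulatedDataset(
        root=outdir,
        genome_fasta=genome_fasta,
        gff3=gff3,
        metadata_yaml=metadata_yaml,
        methylation_bedgraph=meth_path,
        truth_tsv=truth_path,
        library_paths=library_paths,
        truth=truth,
    )


# --------------------------------------------------------------------------
# truth comparison


def _match_calls(catalog: pd.DataFrame, truth: pd.DataFrame,
                 min_overlap_fraction: float = 0.5):
    """Match screened calls to planted peaks (>= 50% of the planted span).

    Matching is by gene, strand and genomic locus but deliberately not
    by anchor: for genes shorter than twice the flank the TSS and
    terminus regions overlap, so a peak planted at one anchor is
    legitimately re-discovered inside the other anchor's region.
    """
    matched_truth = np.zeros(len(truth), dtype=bool)
    call_matches: list[int | None] = []
    for _, call in catalog.iterrows():
        hit = None
        for ti, t in truth.iterrows():
            if (call.gene_id, call.region_strand) != (t.gene_id, t.region_strand):
                continue
            ov = min(call.end, t.end) - max(call.start, t.start)
            if ov >= min_overlap_fraction * (t.end - t.start):
                hit = ti
                matched_truth[truth.index.get_loc(ti)] = True
                break
        call_matches.append(hit)
    return matched_truth, call_matches


def truth_evaluation(
    catalog: pd.DataFrame,
    truth: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
    mutant_panel: Sequence[str] = MUTANTS,
) -> dict[str, float | None]:
    """Sensitivity/precision of peak calls and per-label agreement.

    ``catalog`` is the pipeline's screened-peak table; ``truth`` the
    simulator's planted table.  Undefined metrics (empty denominators)
    are reported as ``None``.
    """
    required = {"gene_id", "anchor", "region_strand", "start", "end"}
    for name, df in (("catalog", catalog), ("truth", truth)):
        if not required <= set(df.columns):
            raise ValueError(f"{name} table lacks columns {sorted(required - set(df.columns))}")
    if "suppressed" in truth.columns:
        # round-tripping through TSV turns empty strings into NaN
        truth = truth.assign(suppressed=truth.suppressed.fillna("").astype(str))
    matched_truth, call_matches = _match_calls(catalog, truth, min_overlap_fraction)

    metrics: dict[str, float | None] = {
        "n_truth": float(len(truth)),
        "n_calls": float(len(catalog)),
        "sensitivity": float(matched_truth.mean()) if len(truth) else None,
        "precision": (
            sum(m is not None for m in call_matches) / len(call_matches)
            if call_matches
            else None
        ),
    }

    def agreement(pairs: list[bool]) -> float | None:
        return sum(pairs) / len(pairs) if pairs else None

    ago_pairs, organ_pairs, mut_pairs, meth_pairs, dsrna_pairs = [], [], [], [], []
    for (_, call), ti in zip(catalog.iterrows(), call_matches):
        if ti is None:
            continue
        t = truth.loc[ti]
        if call.anchor != t.anchor:
            # echo call inside the other anchor's overlapping region of a
            # short gene: counts for detection, but its evidence (dsRNA
            # tiles, flanking signal) is clipped at the region boundary,
            # so labels are compared at the planted anchor only
            continue
        if "ago" in truth.columns and "ago_overall" in catalog.columns:
            ago_pairs.append(str(call.ago_overall) == t.ago)
        if "organ" in truth.columns and "organ_specific" in catalog.columns:
            organ_pairs.append(str(call.organ_specific) == str(t.organ))
        if "suppressed" in truth.columns and "mutant_dependence" in catalog.columns:
            pred_map = dict(
                kv.split(":") for kv in str(call.mutant_dependence).split(";") if ":" in kv
            )
            suppressed = set(t.suppressed.split(",")) if t.suppressed else set()
            for genotype in mutant_panel:
                expected = "repressed" if genotype in suppressed else "not_repressed"
                mut_pairs.append(pred_map.get(genotype) == expected)
        if "methylated" in truth.columns and "methylation_overlap" in catalog.columns:
            meth_pairs.append(bool(call.methylation_overlap) == bool(t.methylated))
        if "dsrna_covered" in truth.columns and "dsrna_covered" in catalog.columns:
            dsrna_pairs.append(bool(call.dsrna_covered) == bool(t.dsrna_covered))

    metrics["ago_agreement"] = agreement(ago_pairs)
    metrics["organ_agreement"] = agreement(organ_pairs)
    metrics["mutant_agreement"] = agreement(mut_pairs)
    metrics["methylation_agreement"] = agreement(meth_pairs)
    metrics["dsrna_agreement"] = agreement(dsrna_pairs)
    return metrics
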