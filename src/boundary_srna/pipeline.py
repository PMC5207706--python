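"""End-to-end orchestration: from raw inputs to the annotated peak catalog.

Stages: gene models -> boundary regions -> library loading and perfect
mapping -> pooled-WT scrolling-window peak calling and screening ->
sense/antisense pairing -> sequence features -> AGO preference, organ
specificity and mutant dependence -> dsRNA coverage -> methylation
overlap -> catalog and summary tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import comparative, dsrna, features
from .annotation import (
    ANTISENSE,
    SENSE,
    BoundaryRegion,
    extract_boundary_regions,
    load_gene_models,
)
from .comparative import MUTANT_PANEL, PeakAnnotation
from .libraries import Library, MappedRead, RegionIndex, load_library, map_perfect
from .methylation import MethylationTrack, load_methylation_track
from .peaks import PeakCall, ScanConfig, build_profile, call_peaks, pair_peaks, scroll_windows

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline, in one place."""

    flank: int = 500
    scan: ScanConfig = field(default_factory=ScanConfig)
    ago_fold: float = 2.0
    ago_floor: float = 1.0
    organ_dominance: float = 0.8
    repression_fold: float = 5.0
    wt_floor: float = 1.0
    mutant_panel: tuple[str, ...] = MUTANT_PANEL
    dsrna_min_depth: int = 1
    dsrna_min_run: int = 100
    dsrna_mode: str = "contain"
    dsrna_strand_agnostic: bool = True
    meth_level_min: float = 0.1
    meth_slop: int = 50
    meth_min_sites: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scan = ScanConfig(**raw.pop("scan", {}))
        if "mutant_panel" in raw:
            raw["mutant_panel"] = tuple(raw["mutant_panel"])
        return cls(scan=scan, **raw)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, ready for reporting."""

    regions: list[BoundaryRegion]
    libraries: dict[str, Library]
    placements: dict[tuple[str, str, str], list[MappedRead]]
    peaks: list[PeakCall]
    annotations: list[PeakAnnotation]
    catalog: pd.DataFrame
    feature_table: pd.DataFrame
    summary: pd.DataFrame


CATALOG_COLUMNS = [
    "gene_id", "anchor", "region_strand", "chromosome", "start", "end",
    "a2_max", "noise_ratio", "paired", "ago_preference", "ago_overall",
    "organ_specific",
    "mutant_dependence", "dsrna_covered", "methylation_overlap",
    "methylation_sites",
]


def percentage(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Half-up rounded percentage string, e.g. percentage(145, 233) == '62.23%'."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be between 0 and denominator")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return f"{value}%"


def _load_genome(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def load_dataset_libraries(
    metadata_yaml: str | Path,
) -> tuple[dict[str, Library], dict[str, list]]:
    """Read the library-metadata config and load every listed library."""
    metadata_yaml = Path(metadata_yaml)
    with open(metadata_yaml) as fh:
        meta = yaml.safe_load(fh)
    libraries: dict[str, Library] = {}
    reads_by_lib: dict[str, list] = {}
    for entry in meta["libraries"]:
        path = metadata_yaml.parent / entry["path"]
        lib, reads = load_library(
            path,
            library_id=entry["library_id"],
            role=entry["role"],
            organ_or_genotype=entry["organ_or_genotype"],
        )
        libraries[lib.library_id] = lib
        reads_by_lib[lib.library_id] = reads
    return libraries, reads_by_lib


def _density(
    placements: Sequence[MappedRead],
    peak: PeakCall,
    lib_ids: set[str],
) -> float:
    return comparative.peak_density(
        [p for p in placements if p.library_id in lib_ids], peak
    )


def run_pipeline(
    dataset_dir: str | Path,
    config: PipelineConfig | None = None,
    metadata_name: str = "metadata.yaml",
) -> PipelineResult:
    """Run every stage on a dataset directory written by the simulator
    (or any directory with the same metadata layout)."""
    config = config or PipelineConfig()
    dataset_dir = Path(dataset_dir)
    with open(dataset_dir / metadata_name) as fh:
        meta = yaml.safe_load(fh)

    t0 = time.perf_counter()
    genome = _load_genome(dataset_dir / meta["genome_fasta"])
    models = load_gene_models(dataset_dir / meta["annotation_gff3"])
    regions: list[BoundaryRegion] = []
    for model in models:
        regions.extend(extract_boundary_regions(model, genome, flank=config.flank))
    regions_by_key = {(r.gene_id, r.anchor, r.region_strand): r for r in regions}
    log.info("regions: %d from %d genes (%.1fs)", len(regions), len(models),
             time.perf_counter() - t0)

    libraries, reads_by_lib = load_dataset_libraries(dataset_dir / metadata_name)
    index = RegionIndex(regions)
    placements_by_region: dict[tuple[str, str, str], list[MappedRead]] = {
        k: [] for k in regions_by_key
    }
    for lib_id, reads in reads_by_lib.items():
        for p in map_perfect(reads, regions, index=index):
            placements_by_region[(p.gene_id, p.anchor, p.region_strand)].append(p)
    log.info("mapping done (%.1fs)", time.perf_counter() - t0)

    wt_ids = {lid for lid, lib in libraries.items() if lib.role == "wt"}
    ago1_by_organ = {
        lib.organ_or_genotype: lid for lid, lib in libraries.items() if lib.role == "ago1"
    }
    ago4_by_organ = {
        lib.organ_or_genotype: lid for lid, lib in libraries.items() if lib.role == "ago4"
    }
    mutant_ids = {
        lib.organ_or_genotype: lid for lid, lib in libraries.items() if lib.role == "mutant"
    }
    dsrna_ids = {lid for lid, lib in libraries.items() if lib.role == "dsrna"}

    # pooled-WT peak calling
    all_peaks: list[PeakCall] = []
    for key, region in regions_by_key.items():
        wt_placements = [p for p in placements_by_region[key] if p.library_id in wt_ids]
        profile = build_profile(wt_placements, region, sorted(wt_ids))
        all_peaks.extend(call_peaks(scroll_windows(profile, config.scan), profile, config.scan))
    screened = [p for p in all_peaks if p.screened]
    log.info("peaks: %d candidate, %d screened (%.1fs)", len(all_peaks), len(screened),
             time.perf_counter() - t0)

    # sense/antisense pairing per gene+anchor
    paired_ids: set[int] = set()
    by_anchor: dict[tuple[str, str], dict[str, list[PeakCall]]] = {}
    for p in screened:
        by_anchor.setdefault((p.region.gene_id, p.region.anchor), {}).setdefault(
            p.region.region_strand, []
        ).append(p)
    for strands in by_anchor.values():
        for sp, ap in pair_peaks(
            strands.get(SENSE, []), strands.get(ANTISENSE, []),
            config.scan.min_pair_overlap,
        ):
            paired_ids.update((id(sp), id(ap)))

    # sequence features over peak-bearing regions
    wt_placements_flat = [
        p for plist in placements_by_region.values() for p in plist
        if p.library_id in wt_ids
    ]
    categories = features.collect_boundary_srnas(wt_placements_flat, screened, config.scan)
    feat_table = features.feature_table(categories)

    # methylation track is optional
    track: MethylationTrack | None = None
    meth_file = meta.get("methylation_bedgraph")
    if meth_file and (dataset_dir / meth_file).exists():
        track = load_methylation_track(dataset_dir / meth_file)

    # per-peak annotation
    annotations: list[PeakAnnotation] = []
    rows = []
    for peak in screened:
        key = (peak.region.gene_id, peak.region.anchor, peak.region.region_strand)
        plist = placements_by_region[key]
        ann = PeakAnnotation(paired=id(peak) in paired_ids)

        organs = sorted(set(ago1_by_organ) & set(ago4_by_organ))
        ago1_d = {o: _density(plist, peak, {ago1_by_organ[o]}) for o in organs}
        ago4_d = {o: _density(plist, peak, {ago4_by_organ[o]}) for o in organs}
        ann.ago_preference = comparative.ago_preference(
            ago1_d, ago4_d, fold=config.ago_fold, floor=config.ago_floor
        )
        if organs:
            # overall preference from the group-pooled accumulation levels
            ann.ago_overall = comparative.ago_preference(
                {"pooled": sum(ago1_d.values())},
                {"pooled": sum(ago4_d.values())},
                fold=config.ago_fold,
                floor=config.ago_floor,
            )["pooled"]

        wt_by_organ = {
            libraries[lid].organ_or_genotype: _density(plist, peak, {lid})
            for lid in sorted(wt_ids)
        }
        if len(wt_by_organ) >= 2:
            ann.organ_specific = comparative.organ_specificity(
                wt_by_organ, dominance=config.organ_dominance
            )

        wt_density = _density(plist, peak, wt_ids)
        ann.mutant_dependence = comparative.annotate_mutant_panel(
            wt_density,
            {g: _density(plist, peak, {lid}) for g, lid in sorted(mutant_ids.items())},
            panel=config.mutant_panel,
            repression_fold=config.repression_fold,
            wt_floor=config.wt_floor,
        )

        if dsrna_ids:
            region = peak.region
            if config.dsrna_strand_agnostic:
                sibling = regions_by_key.get(
                    (region.gene_id, region.anchor,
                     ANTISENSE if region.region_strand == SENSE else SENSE)
                )
                by_strand = {
                    region.region_strand: [
                        p for p in plist if p.library_id in dsrna_ids
                    ]
                }
                if sibling is not None:
                    sib_key = (sibling.gene_id, sibling.anchor, sibling.region_strand)
                    by_strand[sibling.region_strand] = [
                        p for p in placements_by_region[sib_key]
                        if p.library_id in dsrna_ids
                    ]
                pooled = dsrna.strand_pooled_placements(
                    by_strand, region.L, region.region_strand
                )
            else:
                pooled = [p for p in plist if p.library_id in dsrna_ids]
            runs = dsrna.coverage_runs(pooled, region.L, config.dsrna_min_depth)
            ann.dsrna_covered = dsrna.peak_in_run(
                (peak.peak_start, peak.peak_end), runs,
                min_run=config.dsrna_min_run, mode=config.dsrna_mode,
            )

        if track is not None:
            from .methylation import peak_methylation_overlap

            flag, n_sites = peak_methylation_overlap(
                peak.region.chromosome, peak.genomic_interval, track,
                level_min=config.meth_level_min, slop=config.meth_slop,
                min_sites=config.meth_min_sites,
            )
            ann.methylation_overlap, ann.methylation_sites = flag, n_sites

        annotations.append(ann)
        gs, ge = peak.genomic_interval
        rows.append(
            {
                "gene_id": peak.region.gene_id,
                "anchor": peak.region.anchor,
                "region_strand": peak.region.region_strand,
                "chromosome": peak.region.chromosome,
                "start": gs,
                "end": ge,
                "a2_max": peak.a2_max,
                "noise_ratio": peak.noise_ratio,
                "paired": ann.paired,
                "ago_preference": ";".join(
                    f"{o}:{l}" for o, l in sorted(ann.ago_preference.items())
                ),
                "ago_overall": ann.ago_overall,
                "organ_specific": ann.organ_specific,
                "mutant_dependence": ";".join(
                    f"{g}:{s}" for g, s in sorted(ann.mutant_dependence.items())
                ),
                "dsrna_covered": ann.dsrna_covered,
                "methylation_overlap": ann.methylation_overlap,
                "methylation_sites": ann.methylation_sites,
            }
        )
    catalog = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    catalog = catalog.sort_values(
        ["chromosome", "start", "gene_id", "anchor", "region_strand"]
    ).reset_index(drop=True)
    summary = summarize_catalog(catalog)
    log.info("pipeline finished (%.1fs)", time.perf_counter() - t0)
    return PipelineResult(
        regions=regions,
        libraries=libraries,
        placements=placements_by_region,
        peaks=screened,
        annotations=annotations,
        catalog=catalog,
        feature_table=feat_table,
        summary=summary,
    )


def summarize_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-category gene counts and stage-retention percentages.

    Categories are anchor x strand plus paired sets; retention counts
    genes whose peaks carry an AGO label, reside in dsRNA coverage, or
    overlap methylation.
    """
    if catalog.empty:
        catalog = pd.DataFrame(columns=CATALOG_COLUMNS)
    rows = []
    for anchor, stem in (("TSS", "PASR"), ("terminus", "TASR")):
        sub = catalog[catalog.anchor == anchor]
        for label, strand in (
            (f"{stem}_plus", SENSE),
            (f"{stem}_RC", ANTISENSE),
            (f"{stem}_paired", None),
        ):
            part = sub[sub.paired.astype(bool)] if strand is None else sub[
                sub.region_strand == strand
            ]
            genes = part.gene_id.nunique()
            n_ago = part[part.ago_preference.str.contains("AGO", na=False)].gene_id.nunique()
            n_ds = part[part.dsrna_covered.astype(bool)].gene_id.nunique()
            n_me = part[part.methylation_overlap.astype(bool)].gene_id.nunique()
            rows.append(
                {
                    "category": label,
                    "n_genes": genes,
                    "n_ago": n_ago,
                    "pct_ago": percentage(n_ago, genes) if genes else "NA",
                    "n_dsrna": n_ds,
                    "pct_dsrna": percentage(n_ds, genes) if genes else "NA",
                    "n_methylated": n_me,
                    "pct_methylated": percentage(n_me, genes) if genes else "NA",
                }
            )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write catalog, peak BED, features and summary tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": outdir / "catalog.tsv",
        "peaks_bed": outdir / "peaks.bed",
        "features": outdir / "features.tsv",
        "summary": outdir / "summary.tsv",
    }
    result.catalog.to_csv(paths["catalog"], sep="\t", index=False)
    result.feature_table.to_csv(paths["features"], sep="\t", index=False)
    result.summary.to_csv(paths["summary"], sep="\t", index=False)
    with open(paths["peaks_bed"], "w") as fh:
        for peak in result.peaks:
            gs, ge = peak.genomic_interval
            strand = "+" if peak.region.seq_is_forward else "-"
            nr = peak.noise_ratio
            fh.write(
                f"{peak.region.chromosome}\t{gs}\t{ge}\t{peak.region.name}\t"
                f"{peak.a2_max:.3f}\t{strand}\t"
                f"{'inf' if nr == float('inf') else f'{nr:.3f}'}\t"
                f"{int(peak.screened)}\n"
            )
    return paths
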