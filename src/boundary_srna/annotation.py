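"""Gene models and boundary-region extraction.

For each protein-coding gene, the longest transcript model defines the
transcription start site (TSS) and the transcription terminus.  Around
each anchor, a flanking region is extracted: ``flank`` nt outside the
gene body plus up to ``flank`` nt of gene body (the whole body if the
gene is shorter), i.e. L = flank + min(flank, body_length) — 1,000 nt
with the default flank of 500 for genes of at least 500 nt.  Each
genomic interval yields a *sense* region (gene-strand sequence) and an
*antisense* region (its reverse complement), so four regions per gene.

Coordinate conventions: GFF3 input is 1-based inclusive; every internal
interval is 0-based half-open; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

TSS = "TSS"
TERMINUS = "terminus"
SENSE = "sense"
ANTISENSE = "antisense"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DEFAULT_COMPARTMENT_PATTERNS = {
    "chloroplast": ("chrc", "pt", "chloroplast", "plastid"),
    "mitochondrial": ("chrm", "mt", "mitochondria", "mitochondrion"),
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Inconsistent or out-of-bounds annotation records."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's longest transcript model, anchored by TSS and terminus.

    ``tss`` and ``terminus`` are 1-based genomic positions; for a
    minus-strand gene the TSS is the genomically rightmost transcribed
    base.  ``body_length`` is the inclusive TSS-to-terminus distance.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    terminus: int
    body_length: int
    compartment: str = "nuclear"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.body_length != abs(self.tss - self.terminus) + 1:
            raise AnnotationError(
                f"{self.gene_id}: body_length {self.body_length} does not match "
                f"|tss - terminus| + 1"
            )
        if self.strand == "+" and self.tss > self.terminus:
            raise AnnotationError(f"{self.gene_id}: plus-strand TSS after terminus")
        if self.strand == "-" and self.tss < self.terminus:
            raise AnnotationError(f"{self.gene_id}: minus-strand TSS before terminus")


@dataclass(frozen=True)
class BoundaryRegion:
    """One extracted flanking region with its oriented sequence.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    ``seq_is_forward`` records whether ``sequence`` reads along the
    forward genomic strand; offsets within ``sequence`` are converted to
    genomic coordinates accordingly.  ``anchor_offset`` is the 0-based
    position of the anchor base inside ``sequence``.
    """

    gene_id: str
    anchor: str
    region_strand: str
    chromosome: str
    start: int
    end: int
    anchor_offset: int
    sequence: str
    seq_is_forward: bool
    truncated: bool = False

    @property
    def L(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.anchor}|{self.region_strand}"

    def to_genomic(self, offset_start: int, offset_end: int) -> tuple[int, int]:
        """Map a half-open local interval to genomic coordinates."""
        if not 0 <= offset_start <= offset_end <= self.L:
            raise ValueError("offsets outside region")
        if self.seq_is_forward:
            return self.start + offset_start, self.start + offset_end
        return self.end - offset_end, self.end - offset_start

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise AnnotationError(f"{self.name}: sequence length != interval length")
        if not 0 <= self.anchor_offset < self.L:
            raise AnnotationError(f"{self.name}: anchor offset outside region")


def infer_compartment(
    chromosome: str,
    patterns: Mapping[str, Sequence[str]] = DEFAULT_COMPARTMENT_PATTERNS,
) -> str:
    low = chromosome.lower()
    for compartment, names in patterns.items():
        if low in names:
            return compartment
    return "nuclear"


def select_longest_model(
    gene_id: str,
    records: Iterable[tuple[str, str, int, int]],
) -> GeneModel:
    """Pick the transcript with the maximal genomic span for one gene.

    ``records`` are ``(chromosome, strand, start, end)`` tuples in
    1-based inclusive coordinates, one per transcript model.  All
    records must agree on chromosome and strand.
    """
    recs = list(records)
    if not recs:
        raise AnnotationError(f"{gene_id}: no transcript records")
    chroms = {r[0] for r in recs}
    strands = {r[1] for r in recs}
    if len(chroms) > 1 or len(strands) > 1:
        raise AnnotationError(
            f"{gene_id}: transcript records disagree on chromosome/strand "
            f"({sorted(chroms)}, {sorted(strands)})"
        )
    chrom, strand = recs[0][0], recs[0][1]
    best = max(recs, key=lambda r: r[3] - r[2])
    start, end = best[2], best[3]
    if end < start:
        raise AnnotationError(f"{gene_id}: transcript end before start")
    body = end - start + 1
    tss, terminus = (start, end) if strand == "+" else (end, start)
    return GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        tss=tss,
        terminus=terminus,
        body_length=body,
        compartment=infer_compartment(chrom),
    )


def load_gene_models(
    gff3_path: str | Path,
    gene_type: str = "gene",
    transcript_type: str = "mRNA",
) -> list[GeneModel]:
    """Parse a TAIR-style GFF3 and return one longest model per gene.

    Falls back to the gene record itself for genes without annotated
    transcript children.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type(gene_type, order_by=("seqid", "start")):
        recs = [
            (t.seqid, t.strand, t.start, t.end)
            for t in db.children(gene, featuretype=transcript_type)
        ]
        if not recs:
            recs = [(gene.seqid, gene.strand, gene.start, gene.end)]
        models.append(select_longest_model(gene.id, recs))
    return models


def _clip(
    start: int, end: int, chrom_len: int
) -> tuple[int, int, bool]:
    s, e = max(start, 0), min(end, chrom_len)
    return s, e, (s != start or e != end)


def extract_boundary_regions(
    model: GeneModel,
    genome: Mapping[str, str],
    flank: int = 500,
) -> list[BoundaryRegion]:
    """Extract the four boundary regions of one gene.

    The TSS region covers ``flank`` nt upstream of the TSS plus
    ``min(flank, body_length)`` nt of gene body beginning at the TSS;
    the terminus region covers ``min(flank, body_length)`` nt of body
    ending at the terminus plus ``flank`` nt downstream.  Regions
    running past a chromosome end are truncated and flagged.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if model.body_length < 1:
        raise AnnotationError(f"{model.gene_id}: zero-length gene body")
    chrom_seq = str(genome[model.chromosome])
    chrom_len = len(chrom_seq)
    t0, q0 = model.tss - 1, model.terminus - 1
    if not (0 <= t0 < chrom_len and 0 <= q0 < chrom_len):
        raise AnnotationError(
            f"{model.gene_id}: anchors outside chromosome {model.chromosome} "
            f"(length {chrom_len})"
        )
    g = min(flank, model.body_length)
    if model.strand == "+":
        intervals = {TSS: (t0 - flank, t0 + g), TERMINUS: (q0 - g + 1, q0 + flank + 1)}
        sense_forward = True
    else:
        intervals = {TSS: (t0 - g + 1, t0 + flank + 1), TERMINUS: (q0 - flank, q0 + g)}
        sense_forward = False

    regions: list[BoundaryRegion] = []
    for anchor, (raw_s, raw_e) in intervals.items():
        s, e, truncated = _clip(raw_s, raw_e, chrom_len)
        if truncated:
            log.warning(
                "%s %s region truncated at chromosome end (%d..%d -> %d..%d)",
                model.gene_id, anchor, raw_s, raw_e, s, e,
            )
        fwd_seq = chrom_seq[s:e].upper()
        anchor_pos = t0 if anchor == TSS else q0
        for region_strand in (SENSE, ANTISENSE):
            forward = sense_forward if region_strand == SENSE else not sense_forward
            seq = fwd_seq if forward else reverse_complement(fwd_seq)
            offset = anchor_pos - s if forward else e - 1 - anchor_pos
            regions.append(
                BoundaryRegion(
                    gene_id=model.gene_id,
                    anchor=anchor,
                    region_strand=region_strand,
                    chromosome=model.chromosome,
                    start=s,
                    end=e,
                    anchor_offset=offset,
                    sequence=seq,
                    seq_is_forward=forward,
                    truncated=truncated,
                )
            )
    return regions


def write_region_bed(regions: Iterable[BoundaryRegion], path: str | Path) -> None:
    """Write the region catalog as BED6 (score = L, strand = genomic read strand)."""
    with open(path, "w") as fh:
        for r in regions:
            strand = "+" if r.seq_is_forward else "-"
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.name}\t{r.L}\t{strand}\n")


def write_region_fasta(regions: Iterable[BoundaryRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.name}\n{r.sequence}\n")
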