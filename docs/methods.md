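# Methods

## Region model

A gene contributes four boundary regions, anchored at the TSS and the
transcription terminus of its **longest transcript model** (maximal genomic
span, not summed exon length — the anchors of the primary transcript are
what matters).  Each region covers `flank` nt outside the gene body plus
`min(flank, body_length)` nt inside it, i.e. `L = flank + min(flank,
body_length)`; for the default `flank = 500` this is the canonical 1,000-nt
region (500 upstream + the anchor base + 499 downstream), or `500 + body`
for sub-500-nt genes.  Each genomic interval is read on both strands: the
*sense* region carries the gene-strand sequence, the *antisense* region its
reverse complement.

Coordinates: GFF3 in, 1-based inclusive; everything internal, 0-based
half-open; BED out, 0-based half-open.  Regions running past a chromosome
end are truncated and flagged rather than discarded, and the reduced L is
the one used in A1 — this keeps organellar genes near sequence ends.
Overlap with neighbouring genes is ignored; for genes shorter than
2 × flank the TSS and terminus regions of the *same* gene overlap, which is
intrinsic to the region definition (see "Truth evaluation" below for the
consequence).

## Read placement and normalisation

Libraries are collapsed FASTA (`>name_count`) or FASTQ (each record counts
once).  The RPM denominator is the library total **before** any filtering;
reads with N or length ≥ 40 nt stay in the denominator but are excluded
from mapping.  Placement is exact substring matching (U≡T) against the
extracted region sequences — not the whole genome — matching a workflow
that screens only boundary regions; genome-wide uniqueness is deliberately
not assessed.  Multi-mapping reads contribute their full RPM to every
placement (`full` policy; a `fractional` policy would divide by the number
of placements, but full counting is the plainest reading of a
perfect-match screen and is the default).  Internally an exact 12-mer seed
index over the region sequences makes placement O(1) per read; a naive
scan is kept in the tests as the independent oracle.

## Window statistic and screening

`S1`, `A1 = S1/L` per region; a 50-nt window scrolled at 1-nt steps with
`S2` the summed RPM of reads **overlapping** the window and `A2 = S2/50`.
A read is assigned to a window if its interval overlaps it (`overlap`
policy, matching "located within or partially resided within"); the
`five_prime` and `coverage` alternatives are selectable.  The dual pass
criterion uses inclusive comparisons: `A2 ≥ ratio_threshold × A1` (default
10) and `A2 ≥ abs_threshold` (default 1 RPM/nt).  S2 is computed with a
difference array over window starts — exactly equivalent to the naive
recount, and bit-identical for integer-valued RPM.

Merging: passing windows merge while their 50-nt intervals share at least
one position; abutting-but-disjoint runs stay separate.  The peak interval
is the union of its windows.

The published screen ends with a manual step — peaks must not be
"submerged" in surrounding signal.  The reproducible surrogate is a noise
ratio: mean per-position density inside the peak over the mean across the
scan interval outside *all* candidate peaks of that region (excluding all
candidates avoids one peak inflating another's background), with
`noise_ratio_min = 3.0` and zero outside density passing.  The scan
interval defaults to the whole region; the original figure-defined
scrolling extent is not enumerated in text, so it is exposed as
configuration rather than hard-coded.

Peak detection pools the four WT organ libraries (RPM summed per
placement); per-library profiles are retained for the organ classifier.

## Classifier rules and their defaults

The published comparisons are qualitative ("preferentially loaded",
"greatly repressed").  The quantitative stand-ins, all configurable:

| rule | default | rationale |
|---|---|---|
| AGO preference | winner ≥ 2× loser and ≥ 1 RPM/nt, per organ | separates the order-of-magnitude contrasts seen in IP data from noise |
| overall AGO label | same rule on group-pooled densities | robust to near-empty minor organs of organ-specific peaks |
| organ specificity | one organ ≥ 80% of summed WT density | dominance, not mere maximum |
| mutant dependence | WT ≥ 1 RPM/nt and WT/mutant ≥ 5 (mutant 0 ⇒ repressed); WT below floor ⇒ insufficient_signal | mutant densities are compared over the exact WT-defined peak interval, no re-calling |
| dsRNA coverage | peak fully inside a ≥ 100-nt run of depth ≥ 1; strand-agnostic (duplex evidence covers both strands) | "resides within" implies containment; `overlap` mode selectable |
| methylation overlap | ≥ 3 sites, level ≥ 0.1, within peak ± 50 nt (slop boundary inclusive) | reproducible version of a by-eye browser correspondence |

Coverage-run depth counts reads, not RPM: the criterion is physical
coverage.  Methylation tracks are bedGraph per-cytosine levels in [0, 1] or
BED intervals (level 1.0, merged); sequence context (CG/CHG/CHH) is ignored
by default.

## Synthetic world

Defaults are the stated experimental ensemble: 200 genes (400–3,000 nt,
uniform) on two chromosomes; 20% of genes carry a planted TSS peak and 20%
a terminus peak (30% of planted peaks also on the antisense strand, i.e.
paired); peak spans 60–120 nt placed near the anchor; read lengths 19–28 nt
with a 23–24-nt mode (52% of mass) and 5′-base bias A 0.36 / U 0.29;
library size 100,000 reads each, 17 libraries.  Background is 8 reads per
region per WT library scattered uniformly; the planted peak budget is
**20×** the pooled regional background, giving an expected contrast
`A2/A1 ≈ 20E/(1+E) ≈ 19` at `E = 20` — above the 10× threshold but of the
same order, so both sides of the criterion are genuinely exercised.
Organ-specific peaks send 91% of their WT and AGO reads to one organ;
AGO-preferring peaks load the preferred IP group 10-fold over the other;
suppressed genotypes (half the peaks follow the heterochromatic-siRNA
pattern *dcl234*+*rdr2*+*nrpd1a*, 30% the *dcl234*+*rdr6* pattern, the rest
none) keep 5% of the peak budget.  dsRNA-covered peaks receive a
continuous tile of 36-nt duplex reads spanning the peak ± 60 nt;
methylated peaks receive 6 cytosine sites (levels 0.6–0.95) inside the
planted interval.  Library totals are padded to exactly the configured
size with a single unmappable filler sequence, so RPM denominators are
exact by construction.

Randomness is one seed; every library draws from a sub-stream keyed by its
stable name (CRC32), so adding a library never perturbs another, and the
same seed + config is byte-identical.  After drawing background the
generator re-scans each region with the real window criteria and redraws
(up to 5 times, logged) any region whose background alone would pass — at
the default rates this is essentially never triggered, but it makes the
false-positive contract explicit.

What the simulator does **not** emulate: real sequence composition,
transposons, rRNA/tRNA fragments, adapter artefacts, sequencing error,
overdispersion between biological replicates, or a genome-wide sRNA
landscape outside boundary regions.  A green recovery test therefore
establishes the correctness of the screening arithmetic and the
classification rules under the stated signal model — not performance on
real libraries.

## Truth evaluation

A screened call matches a planted peak when gene, strand and genomic locus
agree and the overlap is ≥ 50% of the planted span.  Matching is
deliberately **anchor-agnostic**: for genes shorter than 2 × flank the two
anchors' regions overlap, so a peak planted at one anchor is legitimately
re-discovered inside the other anchor's region ("echo" calls).  Echo calls
count for detection, but label agreement is assessed only at the planted
anchor, because their dsRNA tiles and flanking signal are structurally
clipped at the region boundary.  AGO agreement uses the group-pooled
overall label; per-organ labels remain in the catalog.

## Numerical choices

- Inclusive thresholds everywhere ("ten times or more", "1 RPM/nt or
  higher"); `mutant_density = 0` classifies as repressed; zero
  out-of-peak density passes noise screening.
- Percentages are rounded half-up (`decimal`), matching two-decimal
  printed style; integer-printed ratios use 0 decimals.
- Window sums via difference arrays: exact for integer-valued RPM,
  ≤ 1e-9 relative otherwise (asserted against naive recounts).
- Ties in organ dominance break lexicographically (deterministic output).

## CLI

The command-line layer is deliberately thin: `simulate`,
`extract-regions`, `run` (mapping → scanning → all classifiers →
catalog/summary in one pass, `--evaluate` to score against a truth table)
and `validate`.  Finer stage-by-stage subcommands were folded into `run`:
the intermediate placement tables for a 17-library ensemble are bulky, and
every stage is directly importable as a library function, which is the
interface a pipeline author would script against.

## Known limitations

- No statistical null model: thresholds, not p-values, define peaks
  (by design — the screen is a reproduction of a rule-based catalog).
- Perfect matching only; one mismatch discards a read.
- Regions are screened independently; reads mapping outside boundary
  regions are invisible, and genome-wide multi-mapping is not assessed.
- Organ/AGO/mutant classifiers assume libraries are comparable after RPM
  normalisation; no batch or size-factor correction.
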