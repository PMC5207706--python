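import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boundary_srna.annotation import ANTISENSE, SENSE, reverse_complement
from boundary_srna.libraries import (
    LibraryLoadError,
    SmallRNARead,
    load_library,
    map_perfect,
    normalize_rpm,
    placements_to_frame,
)

from conftest import make_region, random_sequence


def _write_fasta(path, records):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in records))


class TestLoadLibrary:
    def test_collapsed_counts_sum(self, tmp_path):
        fa = tmp_path / "lib.fa"
        _write_fasta(fa, [("r1_5", "ACGTACGTACGTACGTACGTA"), ("r2_3", "TTTTGGGGCCCCAAAATTTTG")])
        lib, reads = load_library(fa, "L", "wt", "leaf")
        assert lib.total_raw_count == 8
        assert sorted(r.raw_count for r in reads) == [3, 5]

    def test_identical_sequences_collapse(self, tmp_path):
        fa = tmp_path / "lib.fa"
        seq = "ACGTACGTACGTACGTACGTA"
        _write_fasta(fa, [("r1_5", seq), ("r2_3", seq)])
        lib, reads = load_library(fa, "L", "wt", "leaf")
        assert len(reads) == 1
        assert reads[0].raw_count == 8 == lib.total_raw_count

    def test_fastq_counts_each_record_once(self, tmp_path, rng):
        unique = [random_sequence(rng, 21) for _ in range(800)]
        chosen = [unique[i] for i in rng.integers(0, 800, size=1_000)]
        chosen.extend(u for u in unique if u not in set(chosen))  # ensure all appear
        fq = tmp_path / "lib.fastq"
        fq.write_text("".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(chosen)))
        lib, reads = load_library(fq, "L", "wt", "leaf")
        assert lib.total_raw_count == len(chosen)
        assert len(reads) == len(set(chosen))
        assert sum(r.raw_count for r in reads) == len(chosen)

    def test_filtered_reads_still_count_in_total(self, tmp_path):
        fa = tmp_path / "lib.fa"
        _write_fasta(
            fa,
            [
                ("keep_4", "ACGTACGTACGTACGTACGTA"),
                ("with_n_2", "ACGTNCGTACGTACGTACGTA"),
                ("long_3", "A" * 45),
            ],
        )
        lib, reads = load_library(fa, "L", "wt", "leaf")
        assert lib.total_raw_count == 9  # denominator includes the filtered reads
        assert [r.sequence for r in reads] == ["ACGTACGTACGTACGTACGTA"]
        assert reads[0].rpm == pytest.approx(4 / 9 * 1e6)

    def test_malformed_count_field(self, tmp_path):
        fa = tmp_path / "lib.fa"
        _write_fasta(fa, [("nocount", "ACGT")])
        with pytest.raises(LibraryLoadError):
            load_library(fa, "L", "wt", "leaf")


class TestNormalizeRpm:
    def test_printed_formula(self):
        assert normalize_rpm(5, 2_000_000) == 2.5
        assert normalize_rpm(0, 10**6) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_rpm(1, 0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=10**6), min_size=1, max_size=200))
    def test_rpm_conservation(self, counts):
        total = sum(counts)
        assert sum(normalize_rpm(c, total) for c in counts) == pytest.approx(
            1e6, rel=1e-6
        )


def _read(seq, count=1, total=1_000_000, lib="L"):
    return SmallRNARead(seq, count, normalize_rpm(count, total), lib)


class TestMapPerfect:
    def test_single_exact_occurrence(self, rng):
        seq = random_sequence(rng, 100)
        region = make_region(seq)
        read = _read(seq[17:25])
        hits = map_perfect([read], [region])
        assert [(h.start_offset, h.end_offset) for h in hits] == [(17, 25)]
        assert region.sequence[17:25] == read.sequence

    def test_one_mismatch_yields_nothing(self, rng):
        seq = random_sequence(rng, 100)
        region = make_region(seq)
        sub = list(seq[10:30])
        sub[10] = {"A": "C"}.get(sub[10], "A")
        assert map_perfect([_read("".join(sub))], [region]) == []

    def test_multiple_occurrences_match_naive_scan(self, rng):
        motif = random_sequence(rng, 19)
        filler = random_sequence(rng, 300)
        seq = filler[:50] + motif + filler[50:150] + motif + filler[150:]
        region = make_region(seq)
        hits = map_perfect([_read(motif)], [region])
        naive = [i for i in range(len(seq) - len(motif) + 1)
                 if seq[i:i + len(motif)] == motif]
        assert sorted(h.start_offset for h in hits) == naive
        assert len(naive) >= 2

    def test_t_u_equivalence(self, rng):
        seq = random_sequence(rng, 80)
        region = make_region(seq)
        read_t, read_u = seq[5:27], seq[5:27].replace("T", "U")
        hits_t = map_perfect([_read(read_t)], [region])
        hits_u = map_perfect([_read(read_u)], [region])
        assert [(h.start_offset, h.end_offset) for h in hits_t] == [
            (h.start_offset, h.end_offset) for h in hits_u
        ]

    def test_antisense_symmetry(self, rng):
        seq = random_sequence(rng, 200)
        sense = make_region(seq, region_strand=SENSE)
        anti = make_region(reverse_complement(seq), region_strand=ANTISENSE)
        read = _read(seq[40:64])
        (hit,) = map_perfect([read], [sense])
        (rc_hit,) = map_perfect([_read(reverse_complement(read.sequence))], [anti])
        L, n = len(seq), len(read.sequence)
        assert rc_hit.start_offset == L - hit.start_offset - n

    def test_placement_frame_columns(self, rng):
        seq = random_sequence(rng, 60)
        df = placements_to_frame(map_perfect([_read(seq[10:31])], [make_region(seq)]))
        assert list(df.loc[0, ["start", "end"]]) == [10, 31]
        assert df.loc[0, "rpm"] == pytest.approx(1.0)
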