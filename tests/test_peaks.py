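"""Unit and property tests of the scrolling-window peak caller."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boundary_srna.peaks import (
    ScanConfig,
    build_profile,
    call_peaks,
    pair_peaks,
    scan_region,
    scroll_windows,
)

from conftest import make_region, random_sequence


def _region(rng, L=1_000, **kw):
    return make_region(random_sequence(rng, L), **kw)


def _random_placements(rng, L, n, rpm_pool=None):
    out = []
    for _ in range(n):
        length = int(rng.integers(19, 29))
        start = int(rng.integers(0, L - length))
        rpm = float(rng.integers(1, 50)) if rpm_pool is None else rpm_pool
        out.append((start, start + length, rpm))
    return out


def naive_window_sum(placements, start, width):
    """Independent recount: rpm of placements overlapping [start, start+width)."""
    return sum(r for s, e, r in placements if s < start + width and e > start)


class TestBuildProfile:
    def test_single_placement(self, rng):
        profile = build_profile([(100, 124, 100.0)], _region(rng))
        assert profile.S1 == 100.0
        assert profile.A1 == pytest.approx(0.1)
        assert profile.per_position_rpm[100] == 100.0
        assert profile.per_position_rpm[99] == 0.0

    def test_empty_profile(self, rng):
        profile = build_profile([], _region(rng))
        assert profile.S1 == 0.0 and profile.A1 == 0.0
        assert not profile.per_position_rpm.any()

    def test_per_position_recount_oracle(self, rng):
        L = 1_000
        placements = _random_placements(rng, L, 50)
        profile = build_profile(placements, _region(rng, L))
        expected = np.zeros(L)
        for p in range(L):
            expected[p] = sum(r for s, e, r in placements if s <= p < e)
        np.testing.assert_allclose(profile.per_position_rpm, expected)

    def test_out_of_bounds_placement_rejected(self, rng):
        with pytest.raises(ValueError):
            build_profile([(990, 1_020, 1.0)], _region(rng, 1_000))


class TestScrollWindows:
    def test_worked_example(self, rng):
        profile = build_profile([(100, 124, 100.0)], _region(rng))
        stats = {s.start_offset: s for s in scroll_windows(profile, ScanConfig())}
        w = stats[100]
        assert w.S2 == 100.0 and w.A2 == pytest.approx(2.0)
        assert w.passes  # 2.0 >= 1.0 and 2.0 >= 10 * 0.1

    def test_flat_signal_never_passes(self, rng):
        # every position covered equally: A2 == A1 < 10 * A1
        L = 1_000
        placements = [(s, s + 20, 5.0) for s in range(0, L - 19, 20)]
        profile = build_profile(placements, _region(rng, L))
        assert profile.A1 > 0
        stats = scroll_windows(profile, ScanConfig(scan_interval=(20, L - 40)))
        assert not any(s.passes for s in stats)

    def test_empty_profile_fails_absolute_floor(self, rng):
        profile = build_profile([], _region(rng))
        assert not any(s.passes for s in scroll_windows(profile, ScanConfig()))

    def test_scan_interval_shorter_than_window(self, rng):
        profile = build_profile([], _region(rng))
        with pytest.raises(ValueError):
            scroll_windows(profile, ScanConfig(scan_interval=(10, 40)))

    def test_incremental_equals_naive_recount_integer_exact(self, rng):
        # integer rpm values sum exactly in floating point
        L = 600
        placements = _random_placements(rng, L, 80)
        profile = build_profile(placements, _region(rng, L))
        for w in scroll_windows(profile, ScanConfig()):
            assert w.S2 == naive_window_sum(placements, w.start_offset, w.width)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_incremental_matches_naive_for_float_rpm(self, seed):
        rng = np.random.default_rng(seed)
        L = 300
        placements = [
            (s, e, float(rng.uniform(0.1, 100.0)))
            for s, e, _ in _random_placements(rng, L, 30)
        ]
        profile = build_profile(placements, make_region(random_sequence(rng, L)))
        for w in scroll_windows(profile, ScanConfig(abs_threshold=0.0)):
            naive = naive_window_sum(placements, w.start_offset, w.width)
            assert w.S2 == pytest.approx(naive, rel=1e-9, abs=1e-9)

    def test_five_prime_assignment_counts_start_only(self, rng):
        profile = build_profile([(100, 124, 10.0)], _region(rng))
        stats = {
            s.start_offset: s
            for s in scroll_windows(profile, ScanConfig(assignment="five_prime"))
        }
        assert stats[100].S2 == 10.0  # window covers the 5' end
        assert stats[101].S2 == 0.0  # 5' end now upstream of the window


class TestCallPeaks:
    def test_merged_run_is_union_of_windows(self, rng):
        region = _region(rng)
        # one dense read stack => passing windows form one contiguous run
        placements = [(100, 124, 400.0)]
        peaks = scan_region(placements, region, ScanConfig())
        assert len(peaks) == 1
        (peak,) = peaks
        # passing windows are exactly those overlapping the read stack
        assert peak.peak_start < 100 < peak.peak_end
        assert peak.screened

    def test_two_separated_runs_stay_separate(self, rng):
        region = _region(rng)
        placements = [(100, 124, 500.0), (500, 524, 500.0)]
        peaks = scan_region(placements, region, ScanConfig())
        assert len(peaks) == 2
        intervals = sorted((p.peak_start, p.peak_end) for p in peaks)
        assert intervals[0][1] <= intervals[1][0]
        # interval-merge oracle: enumerate passing offsets and group by overlap
        profile = build_profile(placements, region)
        passing = [w.start_offset for w in scroll_windows(profile, ScanConfig()) if w.passes]
        groups = [[passing[0]]]
        for x in passing[1:]:
            (groups[-1].append(x) if x < groups[-1][-1] + 50 else groups.append([x]))
        assert intervals == [(g[0], g[-1] + 50) for g in groups]

    def test_noise_screening_rejects_submerged_peak(self, rng):
        region = _region(rng)
        # modest stack over a dense floor: its windows pass a relaxed A2
        # criterion but the in/out density contrast stays below 3
        floor = [(s, s + 24, 40.0) for s in range(0, 970, 10)]
        stack = [(500, 524, 450.0)]
        config = ScanConfig(ratio_threshold=2.0, noise_ratio_min=3.0)
        peaks = scan_region(floor + stack, region, config)
        assert peaks and not any(p.screened for p in peaks)
        # same data, lenient noise threshold: the peak survives screening
        lenient = ScanConfig(ratio_threshold=2.0, noise_ratio_min=1.5)
        assert any(p.screened for p in scan_region(floor + stack, region, lenient))

    def test_zero_outside_density_screens_as_passing(self, rng):
        peaks = scan_region([(100, 124, 400.0)], _region(rng), ScanConfig())
        assert peaks[0].mean_density_out == 0.0
        assert peaks[0].noise_ratio == np.inf
        assert peaks[0].screened


class TestInvariants:
    @pytest.mark.parametrize(
        "param", ["ratio_threshold", "abs_threshold", "noise_ratio_min"]
    )
    def test_threshold_monotonicity(self, rng, param):
        region = _region(rng)
        placements = _random_placements(rng, region.L, 60) + [(300, 330, 800.0)]
        base = ScanConfig()
        n_screened = []
        for factor in (1.0, 2.0, 5.0, 20.0):
            config = ScanConfig(**{**base.__dict__, param: getattr(base, param) * factor})
            n_screened.append(
                sum(p.screened for p in scan_region(placements, region, config))
            )
        assert n_screened == sorted(n_screened, reverse=True)

    def test_scale_equivariance(self, rng):
        region = _region(rng)
        placements = _random_placements(rng, region.L, 30) + [(200, 230, 900.0)]
        c = 7.0
        scaled = [(s, e, r * c) for s, e, r in placements]
        p1 = build_profile(placements, region)
        p2 = build_profile(scaled, region)
        assert p2.S1 == pytest.approx(c * p1.S1)
        assert p2.A1 == pytest.approx(c * p1.A1)
        w1 = scroll_windows(p1, ScanConfig())
        w2 = scroll_windows(p2, ScanConfig())
        for a, b in zip(w1, w2):
            assert b.S2 == pytest.approx(c * a.S2, rel=1e-9)
        # c > 1 keeps every passing window above the absolute floor
        assert [a.passes for a in w1] == [
            a.passes or not a.passes and b.passes for a, b in zip(w1, w2)
        ]
        peaks1 = call_peaks(w1, p1, ScanConfig())
        peaks2 = call_peaks(w2, p2, ScanConfig())
        assert [(p.peak_start, p.peak_end, p.screened) for p in peaks1] == [
            (p.peak_start, p.peak_end, p.screened) for p in peaks2
        ]

    def test_ratio_criterion_scale_invariant(self, rng):
        region = _region(rng)
        placements = _random_placements(rng, region.L, 40)
        config = ScanConfig(abs_threshold=0.0)
        for c in (0.01, 1.0, 250.0):
            scaled = [(s, e, r * c) for s, e, r in placements]
            profile = build_profile(scaled, region)
            flags = [w.passes for w in scroll_windows(profile, config)]
            if c == 0.01:
                reference = flags
            assert flags == reference


class TestPairPeaks:
    def _peak_pair(self, rng, sense_iv, anti_iv):
        L = 1_000
        seq = random_sequence(rng, L)
        sense = make_region(seq, region_strand="sense")
        anti = make_region(seq, region_strand="antisense", seq_is_forward=False)
        sp = scan_region([(sense_iv[0], sense_iv[1], 500.0)], sense, ScanConfig())
        ap = scan_region(
            [(L - anti_iv[1], L - anti_iv[0], 500.0)], anti, ScanConfig()
        )
        return sp, ap

    def test_overlapping_peaks_pair(self, rng):
        sp, ap = self._peak_pair(rng, (500, 560), (520, 580))
        assert len(pair_peaks(sp, ap)) == 1

    def test_disjoint_peaks_do_not_pair(self, rng):
        sp, ap = self._peak_pair(rng, (100, 160), (700, 760))
        assert pair_peaks(sp, ap) == []
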