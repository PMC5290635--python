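"""Chromothripsis gating, multi-chromosome joining and DM candidate graphs."""

import numpy as np
import pytest

from longevol.chromothripsis import (
    ChromothripsisParams,
    call_chromothripsis,
    chromosome_features,
    dm_candidates,
)
from longevol.io_formats import Breakpoint, CNSegment
from longevol.synthetic_data import simulate_chromothripsis_chrom


def _segments(states, chrom="chr7", sample="S1", seg_len=100_000, lafs=None):
    segs = []
    for i, cn in enumerate(states):
        laf = None if lafs is None else lafs[i]
        segs.append(
            CNSegment(sample, chrom, i * seg_len + 1, (i + 1) * seg_len, float(cn), laf=laf)
        )
    return segs


def _intra_bps(n, chrom="chr7", support=150, sample="S1", span=500_000):
    rng = np.random.default_rng(0)
    out = []
    for _ in range(n):
        a, b = sorted(rng.integers(1, span, size=2).tolist())
        out.append(Breakpoint(sample, chrom, a + 1, chrom, b + 2, support))
    return out


class TestFeatures:
    def test_single_flat_segment(self):
        f = chromosome_features(_segments([2]), [], "chr7")
        assert (f.n_segments, f.n_switches, f.n_intra_supported) == (1, 0, 0)
        assert f.max_cn == 2 and f.frac_deleted == 0.0

    def test_oscillating_states_counted(self):
        f = chromosome_features(_segments([2, 20, 2, 20, 2]), _intra_bps(15), "chr7")
        assert f.n_switches == 4 and f.n_states == 2
        assert f.max_cn == 20 and f.n_intra_supported == 15

    def test_support_threshold_gates_break_count(self):
        f = chromosome_features(
            _segments([2, 20, 2]), _intra_bps(15, support=50), "chr7", support_min=100
        )
        assert f.n_intra_supported == 0

    def test_fractional_states_rounded(self):
        f = chromosome_features(_segments([1.9, 2.2, 2.4]), [], "chr7")
        assert f.n_switches == 0 and f.n_states == 1  # all round to 2

    def test_deleted_fraction_and_laf_shift(self):
        f = chromosome_features(
            _segments([2, 0, 2, 1], lafs=[0.5, 0.0, 0.5, 0.1]), [], "chr7"
        )
        assert f.frac_deleted == pytest.approx(0.5)
        assert f.laf_shift == pytest.approx((0.0 + 0.5 + 0.0 + 0.4) / 4)

    def test_empty_chromosome(self):
        f = chromosome_features([], [], "chrX")
        assert f.n_segments == 0 and f.max_cn == 0.0


class TestCalls:
    def test_flat_diploid_genome_negative(self):
        segs = _segments([2], "chr1") + _segments([2], "chr2")
        assert call_chromothripsis(segs, []) == []

    def test_amplifying_call(self):
        states = [2, 25, 2, 25, 2, 25, 2, 25, 2, 25, 2]  # 10 switches
        calls = call_chromothripsis(_segments(states), _intra_bps(12))
        assert len(calls) == 1 and calls[0].event_type == "amplifying"
        assert calls[0].chroms == {"chr7"}

    def test_two_linked_amplified_chromosomes_merge(self):
        states = [2, 25, 2, 25, 2, 25, 2, 25, 2, 25, 2]
        segs = _segments(states, "chr7") + _segments(states, "chr12")
        bps = _intra_bps(12, "chr7") + _intra_bps(12, "chr12")
        bps.append(Breakpoint("S1", "chr7", 150_000, "chr12", 150_000, 200))
        calls = call_chromothripsis(segs, bps)
        assert len(calls) == 1
        assert calls[0].chroms == {"chr7", "chr12"}
        assert calls[0].event_type == "amplifying" and calls[0].n_inter_links == 1

    def test_unlinked_positives_stay_separate(self):
        states = [2, 25, 2, 25, 2, 25, 2, 25, 2, 25, 2]
        segs = _segments(states, "chr7") + _segments(states, "chr12")
        bps = _intra_bps(12, "chr7") + _intra_bps(12, "chr12")
        calls = call_chromothripsis(segs, bps)
        assert {c.chroms for c in calls} == {frozenset({"chr12"}), frozenset({"chr7"})}

    def test_deleting_call(self):
        # 12 switches, ~45% of length deleted, 11 supported intra breaks
        states = [2, 0, 2, 1, 2, 0, 2, 1, 2, 0, 2, 1, 2]
        calls = call_chromothripsis(_segments(states), _intra_bps(11))
        assert len(calls) == 1 and calls[0].event_type == "deleting"

    def test_laf_shift_never_gates(self):
        states = [2, 25, 2, 25, 2, 25, 2, 25, 2, 25, 2]
        lafs = [0.5] * len(states)
        calls = call_chromothripsis(_segments(states, lafs=lafs), _intra_bps(12))
        assert len(calls) == 1  # balanced LAF does not veto the call

    def test_input_order_invariance(self):
        states = [2, 25, 2, 25, 2, 25, 2, 25, 2, 25, 2]
        segs = _segments(states)
        bps = _intra_bps(12)
        a = call_chromothripsis(segs, bps)
        b = call_chromothripsis(segs[::-1], bps[::-1])
        assert [c.to_jsonable() for c in a] == [c.to_jsonable() for c in b]

    def test_raising_support_min_is_monotone(self):
        segs, bps, _ = simulate_chromothripsis_chrom("amplifying", seed=5)
        counts = []
        n_calls = []
        for smin in (50, 110, 200, 400):
            p = ChromothripsisParams(support_min=smin)
            f = chromosome_features(segs, bps, "chr7", support_min=smin)
            counts.append(f.n_intra_supported)
            n_calls.append(len(call_chromothripsis(segs, bps, p)))
        assert counts == sorted(counts, reverse=True)
        assert n_calls == sorted(n_calls, reverse=True)

    def test_empty_input(self):
        assert call_chromothripsis([], []) == []


class TestDmCandidates:
    def test_two_chromosome_component(self):
        segs = [
            CNSegment("S1", "chr7", 1_000_000, 1_200_000, 25.0),
            CNSegment("S1", "chr1", 2_000_000, 2_100_000, 22.0),
        ]
        bps = [Breakpoint("S1", "chr7", 1_100_000, "chr1", 2_050_000, 150)]
        (dm,) = dm_candidates(segs, bps)
        assert dm.chroms == {"chr1", "chr7"}
        assert len(dm.linking_breakpoints) == 1

    def test_isolated_high_copy_segment_is_not_a_candidate(self):
        segs = [CNSegment("S1", "chr7", 1, 100_000, 30.0)]
        assert dm_candidates(segs, []) == []

    def test_low_copy_segments_never_qualify(self):
        segs = [
            CNSegment("S1", "chr7", 1, 100_000, 5.0),
            CNSegment("S1", "chr1", 1, 100_000, 8.0),
        ]
        bps = [Breakpoint("S1", "chr7", 50_000, "chr1", 50_000, 150)]
        assert dm_candidates(segs, bps) == []

    def test_merge_tolerance_matches_nearby_ends(self):
        segs = [
            CNSegment("S1", "chr7", 100_000, 200_000, 25.0),
            CNSegment("S1", "chr7", 500_000, 600_000, 25.0),
        ]
        # ends fall 5 kb outside the segments: within the 10 kb tolerance
        bps = [Breakpoint("S1", "chr7", 95_000, "chr7", 605_000, 150)]
        assert len(dm_candidates(segs, bps)) == 1
        assert dm_candidates(segs, bps, merge_tol=1_000) == []

    def test_components_partition_qualifying_segments(self):
        segs = [
            CNSegment("S1", "chr7", i * 200_000 + 1, i * 200_000 + 100_000, 25.0)
            for i in range(6)
        ]
        bps = [
            Breakpoint("S1", "chr7", 50_000, "chr7", 250_000, 150),
            Breakpoint("S1", "chr7", 850_000, "chr7", 1_050_000, 150),
        ]
        dms = dm_candidates(segs, bps)
        seen = [
            (s.chrom, s.start) for dm in dms for s in dm.segments
        ]
        assert len(seen) == len(set(seen))  # no segment in two components
        assert len(dms) == 2


def test_detector_on_simulated_chromosomes():
    """Planted chromothriptic chromosomes are detected; quiet ones are not."""
    hits = 0
    false_hits = 0
    for i in range(10):
        mode = "amplifying" if i % 2 else "deleting"
        segs, bps, _ = simulate_chromothripsis_chrom(mode, seed=300 + i)
        hits += bool(call_chromothripsis(segs, bps))
        segs, bps, _ = simulate_chromothripsis_chrom("quiet", seed=400 + i)
        false_hits += bool(call_chromothripsis(segs, bps))
    assert hits == 10 and false_hits == 0
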