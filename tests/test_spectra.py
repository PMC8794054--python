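"""Hilbert layer tests: triplets, cycles, phase alignment, HHT."""

import numpy as np
import pytest

from itemd.sifting import IMFSet, Signal
from itemd.spectra import (
    detect_cycles,
    filter_cycles,
    hht,
    hilbert_triplet,
    interior_slice,
    phase_align,
)

FS = 512.0
T10 = np.arange(int(10 * FS)) / FS


class TestHilbertTriplet:
    def test_sine_frequency_and_amplitude(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        sl = interior_slice(T10.size)
        assert np.mean(trip.if_hz[sl]) == pytest.approx(8.0, abs=0.05)
        assert np.all(np.abs(trip.ia[sl] - 1.0) < 0.01)

    def test_amplitude_scaling_leaves_frequency(self):
        x = np.sin(2 * np.pi * 8 * T10)
        a = hilbert_triplet(x, FS)
        b = hilbert_triplet(0.5 * x, FS)
        sl = interior_slice(T10.size)
        assert np.allclose(b.ia[sl], 0.5 * a.ia[sl], atol=0.01)
        assert np.allclose(b.if_hz[sl], a.if_hz[sl], atol=0.05)

    def test_iterated_sine_frequency_distortion(self):
        from itemd.simulate import iterated_sine

        sig = iterated_sine(4.0, 8, 10.0, FS)
        trip = hilbert_triplet(sig.samples, FS)
        f = trip.if_hz[interior_slice(sig.n_samples)]
        fd = (f.max() - f.min()) / 4.0
        assert fd == pytest.approx(0.68, abs=0.04)

    def test_rejects_non_finite(self):
        x = np.ones(64)
        x[5] = np.inf
        with pytest.raises(ValueError):
            hilbert_triplet(x, FS)

    def test_invariants(self):
        rng = np.random.default_rng(0)
        trip = hilbert_triplet(rng.normal(size=1024), FS)
        assert np.all(trip.ia >= 0)
        assert np.all((trip.ip >= 0) & (trip.ip < 2 * np.pi))
        assert trip.ia.size == trip.ip.size == trip.if_hz.size == 1024


class TestDetectCycles:
    def test_sine_cycle_count(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        cycles = detect_cycles(trip)
        assert abs(len(cycles) - 79) <= 1

    def test_dc_gives_empty_table(self):
        trip = hilbert_triplet(np.zeros(512), FS)
        assert len(detect_cycles(trip)) == 0

    def test_iterated_sine_cycles(self):
        from itemd.simulate import iterated_sine

        sig = iterated_sine(4.0, 4, 10.0, FS)
        trip = hilbert_triplet(sig.samples, FS)
        cycles = detect_cycles(trip)
        assert abs(len(cycles) - 39) <= 1
        lengths = (cycles["end"] - cycles["start"]).to_numpy()
        assert np.median(lengths) == pytest.approx(128, abs=4)

    def test_cycles_ordered_and_disjoint(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        cycles = detect_cycles(trip)
        assert np.all(cycles["end"].to_numpy()[:-1] == cycles["start"].to_numpy()[1:])

    def test_deterministic(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        a, b = detect_cycles(trip), detect_cycles(trip)
        assert a.equals(b)


class TestFilterCycles:
    def test_identical_cycle_amplitudes_all_tie_through_percentile(self):
        import pandas as pd

        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        table = pd.DataFrame({
            "start": [0, 64, 128, 192], "end": [64, 128, 192, 256],
            "good": True, "mean_if": 8.0, "mean_ia": 1.0, "max_ia": 1.0,
        })
        out = filter_cycles(table, trip, amp_percentile=50.0,
                            require_monotonic_phase=False)
        # every amplitude equals the 50th percentile; ties are kept
        assert out["good"].all()

    def test_distinct_amplitudes_keep_at_most_half_plus_ties(self):
        t = T10
        x = (1 + 0.5 * np.sin(2 * np.pi * 0.1 * t)) * np.sin(2 * np.pi * 8 * t)
        trip = hilbert_triplet(x, FS)
        cycles = detect_cycles(trip)
        out = filter_cycles(cycles, trip, amp_percentile=50.0,
                            freq_lo=7.0, freq_hi=14.0)
        n_kept = int(out["good"].sum())
        assert n_kept <= np.ceil(len(out) / 2) + 1
        assert n_kept >= 1

    def test_frequency_band(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        cycles = detect_cycles(trip)
        out = filter_cycles(cycles, trip, amp_percentile=None,
                            freq_lo=10.0, freq_hi=16.0)
        assert not out["good"].any()

    def test_phase_reversal_rejected(self):
        x = np.sin(2 * np.pi * 8 * T10).copy()
        # reverse one cycle in the middle: phase runs backwards there
        s, e = 2560, 2624
        x[s:e] = x[s:e][::-1]
        trip = hilbert_triplet(x, FS)
        cycles = detect_cycles(trip)
        out = filter_cycles(cycles, trip, amp_percentile=None,
                            require_monotonic_phase=True)
        assert not out["good"].all()
        assert out["good"].sum() > len(out) / 2

    def test_bad_thresholds_rejected(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        cycles = detect_cycles(trip)
        with pytest.raises(ValueError):
            filter_cycles(cycles, trip, amp_percentile=150.0)
        with pytest.raises(ValueError):
            filter_cycles(cycles, trip, freq_lo=10.0, freq_hi=5.0)


class TestPhaseAlign:
    def test_sine_profile_flat(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        prof = phase_align(trip, detect_cycles(trip), 48)
        assert prof.phase.size == 48
        assert np.abs(prof.mean_if - 8.0).max() < 0.02 * 8.0

    def test_se_shrinks_with_more_cycles(self):
        x = np.sin(2 * np.pi * 8 * T10)
        trip = hilbert_triplet(x, FS)
        cycles = detect_cycles(trip)
        few = cycles.iloc[:5].copy()
        prof_few = phase_align(trip, few, 48)
        prof_all = phase_align(trip, cycles, 48)
        assert np.nanmean(prof_all.se_if) <= np.nanmean(prof_few.se_if) + 1e-12

    def test_iterated_sine_profile_range_matches_distortion(self):
        from itemd.simulate import iterated_sine

        sig = iterated_sine(4.0, 8, 10.0, FS)
        trip = hilbert_triplet(sig.samples, FS)
        prof = phase_align(trip, detect_cycles(trip), 48)
        assert prof.range() / 4.0 == pytest.approx(0.68, abs=0.04)

    def test_fast_rise_asymmetry(self):
        # phase-warped sine: instantaneous frequency peaks at the
        # ascending zero crossing, so the ascending half must be faster
        theta = 2 * np.pi * 4 * T10
        x = np.sin(theta + 0.3 * np.sin(theta))
        trip = hilbert_triplet(x, FS)
        prof = phase_align(trip, detect_cycles(trip), 48)
        rising = (prof.phase < np.pi / 2) | (prof.phase >= 3 * np.pi / 2)
        assert prof.mean_if[rising].mean() > prof.mean_if[~rising].mean()

    def test_no_good_cycles_gives_empty_profile(self):
        trip = hilbert_triplet(np.sin(2 * np.pi * 8 * T10), FS)
        cycles = detect_cycles(trip)
        cycles["good"] = False
        prof = phase_align(trip, cycles, 48)
        assert prof.is_empty


class TestHHT:
    def test_sine_power_concentrated(self):
        x = np.sin(2 * np.pi * 8 * T10)
        imfset = IMFSet(x[:, None], np.zeros_like(x), FS)
        edges = np.arange(1.0, 64.0, 0.5)
        power, dropped = hht(imfset, edges)
        total = power.sum()
        near = (edges[:-1] >= 7.0) & (edges[:-1] < 9.0)
        assert power[:, near].sum() > 0.95 * total

    def test_energy_bookkeeping_exact(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2048)
        imfset = IMFSet(x[:, None], np.zeros_like(x), FS)
        edges = np.linspace(1.0, 255.0, 120)
        power, dropped = hht(imfset, edges)
        trip = hilbert_triplet(x, FS)
        in_range = (trip.if_hz >= edges[0]) & (trip.if_hz < edges[-1])
        # every accumulated sample contributes ia^2 exactly once
        assert power.sum() == pytest.approx(np.sum(trip.ia[in_range] ** 2), rel=1e-9)
        assert dropped == int(np.sum(~in_range))

    def test_zero_signal_zero_matrix(self):
        z = np.zeros(512)
        imfset = IMFSet(z[:, None], z, FS)
        power, _ = hht(imfset, np.linspace(1, 100, 20))
        assert not power.any()

    def test_bad_edges_rejected(self):
        z = np.zeros(512)
        imfset = IMFSet(z[:, None], z, FS)
        with pytest.raises(ValueError):
            hht(imfset, np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            hht(imfset, np.array([0.0, 10.0]))
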