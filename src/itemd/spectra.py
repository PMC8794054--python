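"""Hilbert spectral layer.

Instantaneous amplitude/phase/frequency from the amplitude-normalized
Hilbert transform, cycle detection from phase jumps, cycle quality
filtering, phase-aligned instantaneous frequency (the waveform-shape
summary), and the Hilbert-Huang transform (HHT).

The amplitude-normalized Hilbert transform divides an IMF pointwise by
a spline envelope through the peaks of its absolute value (iterated a
few times) before taking the analytic-signal angle.  This removes
amplitude modulation from the phase estimate, which would otherwise
leak into instantaneous frequency as spurious within-cycle structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

__all__ = [
    "HilbertTriplet",
    "ShapeProfile",
    "hilbert_triplet",
    "detect_cycles",
    "filter_cycles",
    "phase_align",
    "hht",
    "interior_slice",
]

_AMP_FLOOR = 1e-12
#: phase offset so that cycle phase 0 sits at the ascending zero
#: crossing of the normalized IMF (analytic angle of a sine lags the
#: sine argument by pi/2)
_PHASE_OFFSET = np.pi / 2

EDGE_FRACTION = 0.05


def interior_slice(n: int, edge_fraction: float = EDGE_FRACTION) -> slice:
    """Slice excluding the leading/trailing ``edge_fraction`` of samples.

    Hilbert-transform estimates are unreliable near signal boundaries;
    any min/max/mean of instantaneous frequency should be taken over
    this interior window.
    """
    k = int(round(edge_fraction * n))
    return slice(k, n - k if k else n)


@dataclass
class HilbertTriplet:
    """Instantaneous amplitude, phase and frequency of one IMF.

    ``ip`` is wrapped to [0, 2pi) with phase 0 at the ascending zero
    crossing; ``ip_unwrapped`` keeps the monotone (smoothed) phase used
    to derive frequency.
    """

    ia: np.ndarray
    ip: np.ndarray
    if_hz: np.ndarray
    fs: float
    ip_unwrapped: np.ndarray


def _normalize_amplitude(x: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Iteratively divide by the spline envelope of |x| peaks."""
    y = np.asarray(x, dtype=float).copy()
    n = y.size
    t = np.arange(n)
    for _ in range(n_iter):
        a = np.abs(y)
        idx = np.nonzero((a[1:-1] >= a[:-2]) & (a[1:-1] >= a[2:]) & (a[1:-1] > 0))[0] + 1
        if idx.size < 2:
            break
        locs = np.r_[0, idx, n - 1]
        vals = np.r_[a[idx[0]], a[idx], a[idx[-1]]]
        keep = np.r_[True, np.diff(locs) > 0]
        locs, vals = locs[keep], vals[keep]
        if locs.size < 4:
            env = np.interp(t, locs, vals)
        else:
            env = CubicSpline(locs, vals)(t)
        env = np.maximum(env, _AMP_FLOOR)
        y = y / env
    return np.clip(y, -1.0, 1.0)


def hilbert_triplet(
    imf: np.ndarray, fs: float, phase_smooth_window: int = 5
) -> HilbertTriplet:
    """Amplitude, phase and frequency from the analytic signal.

    Amplitude is the magnitude of the analytic signal of the raw IMF.
    Phase comes from the amplitude-normalized IMF: unwrapped, smoothed
    by a centered ``phase_smooth_window``-sample moving average, then
    wrapped back.  Instantaneous frequency is the forward difference of
    the smoothed unwrapped phase scaled by ``fs / 2pi``.
    """
    imf = np.asarray(imf, dtype=float)
    if not np.all(np.isfinite(imf)):
        raise ValueError("IMF contains non-finite samples")
    ia = np.abs(hilbert(imf))
    norm = _normalize_amplitude(imf)
    phase = np.unwrap(np.angle(hilbert(norm))) + _PHASE_OFFSET
    if phase_smooth_window and phase_smooth_window > 1:
        phase = uniform_filter1d(phase, phase_smooth_window, mode="nearest")
    df = np.diff(phase)
    if_hz = np.r_[df, df[-1]] * fs / (2 * np.pi)
    ip = np.mod(phase, 2 * np.pi)
    return HilbertTriplet(ia=ia, ip=ip, if_hz=if_hz, fs=fs, ip_unwrapped=phase)


def detect_cycles(triplet: HilbertTriplet) -> pd.DataFrame:
    """Find complete cycles from downward jumps of the wrapped phase.

    Returns a table with one row per complete cycle: half-open 0-based
    sample interval, a ``good`` flag (all complete cycles start good),
    and per-cycle mean frequency and mean/max amplitude.
    """
    ip = triplet.ip
    jumps = np.nonzero(np.diff(ip) < -np.pi)[0] + 1  # first sample of a new cycle
    cols = ["start", "end", "good", "mean_if", "mean_ia", "max_ia"]
    if jumps.size < 2:
        return pd.DataFrame(columns=cols).astype(
            {"start": int, "end": int, "good": bool}
        )
    rows = []
    for s, e in zip(jumps[:-1], jumps[1:]):
        seg_if = triplet.if_hz[s:e]
        seg_ia = triplet.ia[s:e]
        rows.append(
            (int(s), int(e), True, float(seg_if.mean()), float(seg_ia.mean()),
             float(seg_ia.max()))
        )
    return pd.DataFrame(rows, columns=cols)


def filter_cycles(
    cycles: pd.DataFrame,
    triplet: HilbertTriplet,
    amp_percentile: float | None = 50.0,
    freq_lo: float | None = None,
    freq_hi: float | None = None,
    require_monotonic_phase: bool = True,
) -> pd.DataFrame:
    """Set the ``good`` flag from amplitude, frequency and phase tests.

    A cycle survives when (all enabled): its mean amplitude is at or
    above the ``amp_percentile`` percentile of cycle mean amplitudes,
    its mean frequency lies in ``[freq_lo, freq_hi]``, and its smoothed
    unwrapped phase is non-decreasing throughout.
    """
    if amp_percentile is not None and not (0 <= amp_percentile <= 100):
        raise ValueError("amp_percentile must be in [0, 100]")
    if freq_lo is not None and freq_hi is not None and freq_lo >= freq_hi:
        raise ValueError("freq_lo must be below freq_hi")
    out = cycles.copy()
    if out.empty:
        return out
    good = np.ones(len(out), dtype=bool)
    if amp_percentile is not None:
        thresh = np.percentile(out["mean_ia"].to_numpy(), amp_percentile)
        good &= out["mean_ia"].to_numpy() >= thresh
    if freq_lo is not None:
        good &= out["mean_if"].to_numpy() >= freq_lo
    if freq_hi is not None:
        good &= out["mean_if"].to_numpy() <= freq_hi
    if require_monotonic_phase:
        phase = triplet.ip_unwrapped
        mono = np.array(
            [np.all(np.diff(phase[s:e]) >= 0) for s, e in zip(out["start"], out["end"])]
        )
        good &= mono
    out["good"] = good
    return out


@dataclass
class ShapeProfile:
    """Phase-aligned instantaneous-frequency waveform summary.

    ``mean_if``/``se_if`` are the pointwise mean and standard error of
    within-cycle instantaneous frequency across good cycles, resampled
    onto ``phase`` (an ``n_points`` uniform grid over [0, 2pi)).
    """

    phase: np.ndarray
    mean_if: np.ndarray
    se_if: np.ndarray
    n_cycles: int

    @property
    def is_empty(self) -> bool:
        return self.n_cycles == 0

    def range(self) -> float:
        """Max minus min of the mean profile, Hz."""
        return float(self.mean_if.max() - self.mean_if.min())


def phase_align(
    triplet: HilbertTriplet, cycles: pd.DataFrame, n_points: int = 48
) -> ShapeProfile:
    """Resample each good cycle's IF onto a common uniform phase grid.

    Within each cycle the unwrapped phase (shifted to start at 0) is the
    sample coordinate; IF is linearly interpolated onto ``n_points``
    phases spanning [0, 2pi).  The profile is the pointwise mean with
    its standard error (n-1 denominator) across cycles.
    """
    grid = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    good = cycles[cycles["good"]] if not cycles.empty else cycles
    if len(good) == 0:
        return ShapeProfile(grid, np.full(n_points, np.nan), np.full(n_points, np.nan), 0)
    aligned = np.empty((len(good), n_points))
    for row_i, (s, e) in enumerate(zip(good["start"], good["end"])):
        ph = triplet.ip_unwrapped[s:e]
        ph = ph - ph[0]
        # guard tiny non-monotonic wiggles left by smoothing
        ph = np.maximum.accumulate(ph)
        aligned[row_i] = np.interp(grid, ph, triplet.if_hz[s:e])
    mean = aligned.mean(axis=0)
    if len(good) > 1:
        se = aligned.std(axis=0, ddof=1) / np.sqrt(len(good))
    else:
        se = np.zeros(n_points)
    return ShapeProfile(grid, mean, se, int(len(good)))


def hht(imfset, freq_edges: np.ndarray):
    """Hilbert-Huang transform: instantaneous power binned by frequency.

    For every IMF and sample, the instantaneous power ``ia**2`` is
    accumulated into the frequency bin (defined by the strictly
    increasing ``freq_edges``) containing the sample's instantaneous
    frequency.  Samples whose frequency falls outside the grid are
    dropped and counted.

    Returns
    -------
    power : ndarray, shape (n_samples, len(freq_edges) - 1)
    n_dropped : int
    """
    edges = np.asarray(freq_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("freq_edges must be strictly increasing with >= 2 values")
    if edges[0] <= 0 or edges[-1] >= imfset.source_fs / 2:
        raise ValueError("freq_edges must lie inside (0, fs/2)")
    n = imfset.n_samples
    power = np.zeros((n, edges.size - 1))
    t_idx = np.arange(n)
    n_dropped = 0
    for i in range(imfset.n_imfs):
        trip = hilbert_triplet(imfset.imf(i), imfset.source_fs)
        bins = np.searchsorted(edges, trip.if_hz, side="right") - 1
        ok = (bins >= 0) & (bins < edges.size - 1)
        n_dropped += int(np.sum(~ok))
        np.add.at(power, (t_idx[ok], bins[ok]), trip.ia[ok] ** 2)
    return power, n_dropped
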