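"""Evaluation metrics and statistical comparison.

Pseudo-mode splitting index (PMSI) for mode mixing, frequency
distortion (FD) for nonsinusoidality, Pearson shape correlation against
ground truth, signal-IMF selection, Welch PSD peak finding, and the
one-sided Welch t-test comparison with Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .sifting import IMFSet, Signal
from .spectra import ShapeProfile, hilbert_triplet, interior_slice

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationRecord",
    "pmsi_pair",
    "pmsi_of_interest",
    "frequency_distortion",
    "shape_correlation",
    "select_imf",
    "spectral_peak",
    "compare_methods",
]


@dataclass
class EvaluationRecord:
    """One method x condition x realization evaluation result."""

    method: str
    condition: float
    r: float
    pmsi: float
    seed: int


def pmsi_pair(c_i: np.ndarray, c_j: np.ndarray) -> float:
    """Pseudo-mode splitting index of two adjacent IMFs.

    ``max(<c_i, c_j> / (|c_i|^2 + |c_j|^2), 0)``: 0 for orthogonal,
    well-separated modes, 0.5 for a mode split identically into both.
    """
    c_i = np.asarray(c_i, dtype=float)
    c_j = np.asarray(c_j, dtype=float)
    if c_i.shape != c_j.shape:
        raise ValueError("PMSI inputs must have equal length")
    denom = float(np.dot(c_i, c_i) + np.dot(c_j, c_j))
    if denom == 0.0:
        logger.warning("PMSI of two zero-norm inputs; returning 0")
        return 0.0
    return max(float(np.dot(c_i, c_j)) / denom, 0.0)


def pmsi_of_interest(imfs: IMFSet, index: int) -> float:
    """Summed PMSI of an IMF with its faster and slower neighbors."""
    if imfs.n_imfs < 2:
        raise ValueError("summed PMSI needs at least two IMFs")
    if not 0 <= index < imfs.n_imfs:
        raise IndexError(f"IMF index {index} out of range")
    total = 0.0
    if index > 0:
        total += pmsi_pair(imfs.imf(index - 1), imfs.imf(index))
    if index < imfs.n_imfs - 1:
        total += pmsi_pair(imfs.imf(index), imfs.imf(index + 1))
    return total


def frequency_distortion(if_interior: np.ndarray, f0: float) -> float:
    """Frequency distortion in percent: ``(max IF - min IF) / f0 * 100``.

    0% for a pure sinusoid; 100% means the within-cycle IF range equals
    the base frequency itself.  ``if_interior`` must already be
    edge-trimmed (or come from a cycle-averaged profile).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    arr = np.asarray(if_interior, dtype=float)
    if arr.size == 0:
        raise ValueError("empty instantaneous-frequency input")
    return float((arr.max() - arr.min()) / f0 * 100.0)


def shape_correlation(profile: ShapeProfile, truth: ShapeProfile) -> float:
    """Pearson correlation of two phase-aligned mean-IF profiles.

    Returns NaN when either profile has zero variance (undefined
    correlation, excluded from aggregates).
    """
    a = np.asarray(profile.mean_if, dtype=float)
    b = np.asarray(truth.mean_if, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the same phase grid length")
    if np.ptp(a) == 0 or np.ptp(b) == 0 or np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def mean_interior_if(imf: np.ndarray, fs: float) -> float:
    """Mean instantaneous frequency over interior samples, Hz."""
    trip = hilbert_triplet(imf, fs)
    return float(np.mean(trip.if_hz[interior_slice(imf.size)]))


def select_imf(imfs: IMFSet, target_freq: float) -> int:
    """Index of the IMF whose mean interior IF is closest to target.

    Ties resolve to the faster (lower-index) IMF.
    """
    dists = [
        abs(mean_interior_if(imfs.imf(i), imfs.source_fs) - target_freq)
        for i in range(imfs.n_imfs)
    ]
    return int(np.argmin(dists))


def spectral_peak(
    signal: Signal, band_lo: float, band_hi: float, floor_factor: float = 6.0
) -> float:
    """Largest local Welch-PSD maximum inside a band, Hz (NaN if none).

    Welch PSD with 8 s segments (full length if shorter).  A peak must
    be a local maximum of the full PSD and stand at least
    ``floor_factor`` times above the median PSD level - a peak that
    does not clear the background is treated as absent (the
    no-oscillation-present / subject-exclusion case).
    """
    if not (0 < band_lo < band_hi < signal.fs / 2):
        raise ValueError("band must satisfy 0 < lo < hi < fs/2")
    nperseg = min(int(8 * signal.fs), signal.n_samples)
    freqs, psd = sps.welch(signal.samples, fs=signal.fs, nperseg=nperseg)
    peaks, _ = sps.find_peaks(psd)
    in_band = peaks[(freqs[peaks] >= band_lo) & (freqs[peaks] <= band_hi)]
    if in_band.size == 0:
        return float("nan")
    best = in_band[np.argmax(psd[in_band])]
    if psd[best] < floor_factor * np.median(psd):
        return float("nan")
    return float(freqs[best])


def compare_methods(
    records: pd.DataFrame,
    value: str = "r",
    reference: str = "itemd",
    alternative: str = "greater",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-condition one-sided Welch t-test of a reference method.

    For every condition, tests the reference method against its best
    competitor (the competitor with the most favorable mean given the
    alternative) with a one-sided Welch t-test, Bonferroni-corrected by
    the number of conditions.  ``alternative='greater'`` claims the
    reference has larger values (e.g. shape correlation); ``'less'``
    claims smaller (e.g. PMSI).

    Returns a frame with condition, competitor, p_raw, p_corrected and
    significant (corrected p < ``alpha``).
    """
    required = {"method", "condition", value}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    methods = records["method"].unique()
    if reference not in methods or len(methods) < 2:
        raise ValueError("need the reference method plus at least one competitor")
    conditions = np.sort(records["condition"].unique())
    n_cond = len(conditions)
    rows = []
    for cond in conditions:
        sub = records[records["condition"] == cond]
        ref_vals = sub.loc[sub["method"] == reference, value].dropna().to_numpy()
        best_name, best_vals, best_mean = None, None, None
        for m in methods:
            if m == reference:
                continue
            v = sub.loc[sub["method"] == m, value].dropna().to_numpy()
            if v.size == 0:
                continue
            mu = v.mean()
            better = (best_mean is None
                      or (alternative == "greater" and mu > best_mean)
                      or (alternative == "less" and mu < best_mean))
            if better:
                best_name, best_vals, best_mean = m, v, mu
        if best_vals is None or ref_vals.size < 3 or best_vals.size < 3:
            p = 1.0
        elif np.var(ref_vals) == 0 and np.var(best_vals) == 0:
            p = 1.0
        else:
            res = stats.ttest_ind(
                ref_vals, best_vals, equal_var=False, alternative=alternative
            )
            p = float(res.pvalue)
            if not np.isfinite(p):
                p = 1.0
        p_corr = min(p * n_cond, 1.0)
        rows.append((cond, best_name, p, p_corr, p_corr < alpha))
    return pd.DataFrame(
        rows, columns=["condition", "competitor", "p_raw", "p_corrected", "significant"]
    )
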