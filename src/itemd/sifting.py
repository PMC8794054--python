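"""Extrema-based sifting engines.

Implements the classic empirical mode decomposition (EMD) sift, the
masked sift with uniformly spread mask phases, the noise-assisted
ensemble sift, and the zero-crossing dyadic mask initialization.

All engines share one inner loop: an intrinsic mode function (IMF) is
peeled off a working signal by repeatedly subtracting the mean of cubic
spline envelopes through its maxima and minima until a Cauchy-type
stopping criterion is met.  Envelope edges are stabilized by mirroring
the two extrema nearest each boundary about the signal ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from ._kernels import _sift_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "Signal",
    "IMFSet",
    "MaskSpec",
    "SiftConfig",
    "find_extrema",
    "sift",
    "mask_sift",
    "ensemble_sift",
    "zero_crossing_mask_init",
]

_MAX_INNER_SIFTS = 100


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like
        The sample values, arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if x.size < 8:
            raise ValueError("signal must contain at least 8 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("signal contains non-finite samples")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError("sampling rate must be positive and finite")
        object.__setattr__(self, "samples", x)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residual for one signal.

    ``imfs`` has shape ``(n_samples, n_imfs)`` with columns ordered fast
    to slow.  The decomposition is strictly additive: the columns plus
    ``residual`` reconstruct the source signal.
    """

    imfs: np.ndarray
    residual: np.ndarray
    source_fs: float

    def __post_init__(self):
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        if self.imfs.shape[0] == 1 and self.imfs.shape[1] > 1 and \
                self.residual.size == self.imfs.shape[1]:
            self.imfs = self.imfs.T
        self.residual = np.asarray(self.residual, dtype=float)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.imfs.shape[0]

    def imf(self, i: int) -> np.ndarray:
        return self.imfs[:, i]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=1) + self.residual


@dataclass
class MaskSpec:
    """Mask frequencies (Hz, one per IMF level) and phase count.

    ``amplitude_mode`` selects the mask sinusoid amplitude rule:

    ``"ratio_prev"`` (default)
        Amplitude equals the standard deviation of the previously
        extracted IMF (for the first level, of the first IMF of a plain
        sift of the working signal).  The mask then tracks the amplitude
        scale of the content being peeled off, a convention common to
        masked-EMD implementations.
    ``"2rms"``
        Twice the RMS of the current working signal, a deliberately
        dominant mask.
    """

    frequencies: np.ndarray
    amplitude_mode: str = "ratio_prev"
    n_phases: int = 4
    phase_offset: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("mask frequencies must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("mask frequencies must be finite and positive")
        if self.amplitude_mode not in ("ratio_prev", "2rms"):
            raise ValueError(f"unknown amplitude_mode {self.amplitude_mode!r}")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        self.frequencies = f


@dataclass
class SiftConfig:
    """Shared sift options.

    ``sd_thresh`` is the Cauchy stopping tolerance of the inner loop:
    the energy of the subtracted envelope mean relative to the energy
    of the current iterate.  The default 0.1 keeps the inner loop
    shallow (a handful of envelope subtractions), which leaves the
    shape-encoding harmonics of a strong oscillation attached to it -
    deep inner sifting progressively peels them into faster IMFs.

    ``sift_threshold`` stops IMF extraction once the residual energy
    falls below this fraction of the input energy (the decomposition is
    considered complete); extraction also stops at ``max_imfs`` or when
    the residual has too few extrema.
    """

    max_imfs: int = 6
    sift_threshold: float = 1e-8
    n_phases: int = 4
    seed: int | None = None
    sd_thresh: float = 0.1
    max_inner_sifts: int = _MAX_INNER_SIFTS

    def __post_init__(self):
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.sift_threshold <= 0:
            raise ValueError("sift_threshold must be positive")
        if self.sd_thresh <= 0:
            raise ValueError("sd_thresh must be positive")
        if self.max_inner_sifts < 1:
            raise ValueError("max_inner_sifts must be >= 1")


# ---------------------------------------------------------------------------
# extrema and envelopes
# ---------------------------------------------------------------------------

def find_extrema(x: np.ndarray):
    """Locate interior maxima and minima of ``x``.

    Plateaus (runs of equal samples) count as a single extremum at the
    plateau midpoint.  Endpoints are never reported.

    Returns
    -------
    (max_locs, max_vals, min_locs, min_vals)
        Integer sample indices (strictly increasing) and values.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    empty = np.array([], dtype=int), np.array([])
    if n < 3:
        return (*empty, *empty)

    # run-length compress so plateaus become single points
    change = np.r_[True, x[1:] != x[:-1]]
    starts = np.nonzero(change)[0]
    if starts.size < 3:
        return (*empty, *empty)
    vals = x[starts]
    ends = np.r_[starts[1:], n]  # exclusive run ends

    d = np.sign(np.diff(vals))
    is_max = (d[:-1] > 0) & (d[1:] < 0)
    is_min = (d[:-1] < 0) & (d[1:] > 0)
    max_runs = np.nonzero(is_max)[0] + 1
    min_runs = np.nonzero(is_min)[0] + 1

    max_locs = (starts[max_runs] + ends[max_runs] - 1) // 2
    min_locs = (starts[min_runs] + ends[min_runs] - 1) // 2
    return max_locs, vals[max_runs], min_locs, vals[min_runs]


def _envelope(locs: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline envelope through extrema, mirrored edges."""
    n_mirror = min(2, locs.size)
    left_l = -locs[:n_mirror][::-1]
    left_v = vals[:n_mirror][::-1]
    right_l = 2 * (n - 1) - locs[-n_mirror:][::-1]
    right_v = vals[-n_mirror:][::-1]
    xs = np.r_[left_l, locs, right_l]
    ys = np.r_[left_v, vals, right_v]
    # mirrored points can coincide with edge extrema at the boundary
    keep = np.r_[True, np.diff(xs) > 0]
    xs, ys = xs[keep], ys[keep]
    t = np.arange(n)
    if xs.size < 3:
        return np.interp(t, xs, ys)
    return CubicSpline(xs, ys, bc_type="natural")(t)


def _extract_imf(
    x: np.ndarray, threshold: float, max_inner: int = _MAX_INNER_SIFTS
) -> np.ndarray | None:
    """One full inner sift: peel the fastest IMF off ``x``.

    Returns ``None`` when ``x`` has fewer than 2 maxima or 2 minima
    (monotone/trend remainder).
    """
    h, done = _sift_kernel(np.ascontiguousarray(x, dtype=float), threshold, max_inner)
    if done == 0:
        return None
    return h


# ---------------------------------------------------------------------------
# sift variants
# ---------------------------------------------------------------------------

def sift(signal: Signal, config: SiftConfig | None = None) -> IMFSet:
    """Standard EMD: extract IMFs until the residual is a trend.

    The decomposition is additive by construction: each IMF is
    subtracted from the working signal, and whatever remains after the
    last extraction is the residual.
    """
    config = config or SiftConfig()
    x = signal.samples
    energy_floor = config.sift_threshold * float(np.sum(x * x))
    work = x.copy()
    imfs = []
    for _ in range(config.max_imfs):
        c = _extract_imf(work, config.sd_thresh, config.max_inner_sifts)
        if c is None:
            break
        imfs.append(c)
        work = work - c
        if float(np.sum(work * work)) <= energy_floor:
            break
        mx_l, _, mn_l, _ = find_extrema(work)
        if mx_l.size + mn_l.size < 2:
            break
    if not imfs:
        imfs = [np.zeros_like(x)]
    return IMFSet(np.column_stack(imfs), work, signal.fs)


def _pad_mask_frequencies(freqs: np.ndarray, n_levels: int, fs: float) -> np.ndarray:
    """Extend a mask-frequency vector by successive halving."""
    f = list(freqs)
    while len(f) < n_levels:
        f.append(f[-1] / 2.0)
    f = np.minimum(np.asarray(f[:n_levels], dtype=float), 0.499 * fs)
    return f


def mask_sift(signal: Signal, mask: MaskSpec, config: SiftConfig | None = None) -> IMFSet:
    """Masked EMD with uniformly spread mask phases.

    At each level a sinusoid at the level's mask frequency is added at
    ``n_phases`` uniformly spaced phase offsets; the first IMF of each
    masked signal is extracted and the level's IMF is the phase average,
    which cancels the mask itself.  Content much slower than the mask
    frequency is ignored by the sift at that level, suppressing mode
    mixing from intermittency.
    """
    config = config or SiftConfig()
    fs = signal.fs
    if np.any(mask.frequencies >= fs / 2):
        raise ValueError(
            f"mask frequency {mask.frequencies.max():g} Hz is at or above "
            f"the Nyquist frequency {fs / 2:g} Hz"
        )
    n_phases = mask.n_phases
    freqs = _pad_mask_frequencies(mask.frequencies, config.max_imfs, fs)
    t = signal.times
    x = signal.samples
    energy_floor = config.sift_threshold * float(np.sum(x * x))
    work = x.copy()
    imfs = []
    prev_imf = None
    for m_freq in freqs:
        if len(imfs) and float(np.sum(work * work)) <= energy_floor:
            break
        mx_l, _, mn_l, _ = find_extrema(work)
        if len(imfs) and mx_l.size < 2 and mn_l.size < 2:
            break
        if mask.amplitude_mode == "2rms":
            amp = 2.0 * float(np.sqrt(np.mean(work**2)))
        elif prev_imf is not None:
            amp = float(np.std(prev_imf))
        else:
            c0 = _extract_imf(work, config.sd_thresh, config.max_inner_sifts)
            amp = float(np.std(c0 if c0 is not None else work))
        if amp == 0.0:
            break
        acc = np.zeros_like(work)
        got = 0
        for k in range(n_phases):
            phi = mask.phase_offset + 2 * np.pi * k / n_phases
            masked = work + amp * np.sin(2 * np.pi * m_freq * t + phi)
            c = _extract_imf(masked, config.sd_thresh, config.max_inner_sifts)
            if c is None:
                continue
            acc += c
            got += 1
        if got == 0:
            break
        c_level = acc / n_phases
        imfs.append(c_level)
        prev_imf = c_level
        work = work - c_level
        if len(imfs) >= config.max_imfs:
            break
    if not imfs:
        imfs = [np.zeros_like(work)]
    return IMFSet(np.column_stack(imfs), work, fs)


def ensemble_sift(
    signal: Signal,
    n_ensembles: int = 4,
    noise_sd: float = 0.2,
    config: SiftConfig | None = None,
) -> IMFSet:
    """Ensemble EMD: average IMFs over noise-perturbed sift runs.

    Each ensemble member sifts the signal plus an independent white
    noise realization of standard deviation ``noise_sd``; per-level IMFs
    are averaged across members.  The residual is recomputed as input
    minus the summed average IMFs so the additive invariant holds
    exactly.  With ``n_ensembles=1`` and ``noise_sd=0`` this reduces to
    the plain sift.
    """
    if n_ensembles < 1:
        raise ValueError("n_ensembles must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    config = config or SiftConfig()
    if n_ensembles == 1 and noise_sd == 0:
        return sift(signal, config)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_ensembles)
    members = []
    for k in range(n_ensembles):
        rng = np.random.default_rng(children[k])
        noisy = signal.samples + rng.normal(0.0, noise_sd, signal.n_samples)
        members.append(sift(Signal(noisy, signal.fs), config))

    n_levels = max(m.n_imfs for m in members)
    stack = np.zeros((signal.n_samples, n_levels))
    for m in members:
        stack[:, : m.n_imfs] += m.imfs
    stack /= n_ensembles
    residual = signal.samples - stack.sum(axis=1)
    return IMFSet(stack, residual, signal.fs)


def _zero_crossing_count(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def zero_crossing_mask_init(signal: Signal, config: SiftConfig | None = None) -> MaskSpec:
    """Dyadic mask initialization from first-IMF zero crossings.

    The first mask frequency is the zero-crossing rate of the first IMF
    of a standard sift, ``n_zc / (2 * duration)``; later frequencies are
    divided by powers of two.  Falls back to ``fs / 4`` when the first
    IMF has fewer than 2 zero crossings.
    """
    config = config or SiftConfig()
    first_cfg = SiftConfig(
        max_imfs=1,
        sift_threshold=config.sift_threshold,
        sd_thresh=config.sd_thresh,
        max_inner_sifts=config.max_inner_sifts,
    )
    first = sift(signal, first_cfg).imf(0)
    n_zc = _zero_crossing_count(first)
    if n_zc < 2:
        logger.warning(
            "first IMF has %d zero crossings; falling back to fs/4 mask", n_zc
        )
        f0 = signal.fs / 4.0
    else:
        f0 = n_zc / (2.0 * signal.duration)
    freqs = f0 / (2.0 ** np.arange(config.max_imfs))
    freqs = np.minimum(freqs, 0.499 * signal.fs)
    return MaskSpec(freqs, n_phases=config.n_phases)
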