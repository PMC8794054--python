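"""Iterated masking sift (itEMD).

The mask frequencies of a masked sift are refined from the data itself:
after each masked decomposition, every mask is reset to the
amplitude-weighted mean instantaneous frequency (AW-IFM) of the IMF it
produced, and the sift repeats until the masks stop moving.  At the
fixed point each IMF's mask sits at the frequency where that IMF
carries its power, which concentrates an oscillation - including its
shape-encoding harmonics - into a single mode even under heavy noise,
sparsity or nonsinusoidality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sifting import IMFSet, MaskSpec, Signal, SiftConfig, mask_sift, zero_crossing_mask_init
from .spectra import hilbert_triplet, interior_slice

logger = logging.getLogger(__name__)

__all__ = ["ItemdConfig", "MaskTrajectory", "aw_ifm", "itemd_sift", "mask_stability"]

_EMPTY_IMF_REL_RMS = 1e-12


class UndefinedFrequencyError(ValueError):
    """Raised when an IMF carries no amplitude to weight a frequency by."""


@dataclass
class ItemdConfig:
    """Iteration options for the iterated masking sift.

    stop_tol : float
        Convergence threshold on the maximum (over IMFs) relative mask
        change between iterations (dimensionless; default 0.1).
    max_iter : int
        Iteration cap; a warning is logged when it is reached without
        convergence.
    weight_power : float
        Exponent applied to instantaneous amplitude when weighting
        instantaneous frequency; 2 weights by instantaneous power.
    init_mode : str
        "dyadic" (zero-crossing dyadic mask of a standard first sift),
        "random" (uniform draws in [random_lo, random_hi] Hz), or
        "explicit" (caller supplies ``initial_mask``).
    """

    stop_tol: float = 0.1
    max_iter: int = 15
    weight_power: float = 2.0
    init_mode: str = "dyadic"
    random_lo: float = 1.0
    random_hi: float = 128.0
    initial_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.stop_tol <= 0:
            raise ValueError("stop_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.weight_power <= 0:
            raise ValueError("weight_power must be positive")
        if self.init_mode not in ("dyadic", "random", "explicit"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class MaskTrajectory:
    """Per-iteration history of the mask-frequency vector.

    ``masks[j]`` is the mask vector fed into iteration ``j`` (so the
    list has ``n_iter + 1`` entries, the last being the converged /
    final update).  ``rel_changes[j]`` is the per-IMF relative change
    produced by iteration ``j``.
    """

    masks: list = field(default_factory=list)
    rel_changes: list = field(default_factory=list)
    converged: bool = False
    refine_start: int | None = None

    @property
    def n_iter(self) -> int:
        return len(self.masks) - 1

    @property
    def final_mask(self) -> np.ndarray:
        return self.masks[-1]


def aw_ifm(imf: np.ndarray, fs: float, weight_power: float = 2.0) -> float:
    """Amplitude-weighted mean instantaneous frequency of one IMF, Hz.

    Computes ``sum(IA**p * IF) / sum(IA**p)`` over interior samples
    (boundary transients of the Hilbert transform excluded), with IF
    clipped to the physical band (0, fs/2) before averaging.

    Raises
    ------
    UndefinedFrequencyError
        If the IMF carries (numerically) zero amplitude.
    """
    imf = np.asarray(imf, dtype=float)
    trip = hilbert_triplet(imf, fs)
    sl = interior_slice(imf.size)
    ia = trip.ia[sl]
    f = np.clip(trip.if_hz[sl], 0.0, fs / 2)
    w = ia**weight_power
    total = float(w.sum())
    if total <= 0 or not np.isfinite(total):
        raise UndefinedFrequencyError("IMF has no amplitude to weight by")
    val = float(np.sum(w * f) / total)
    if not (0 < val < fs / 2):
        raise UndefinedFrequencyError(f"weighted mean frequency {val:g} Hz out of band")
    return val


def _initial_mask(signal: Signal, config: SiftConfig, it_config: ItemdConfig) -> np.ndarray:
    if it_config.init_mode == "explicit":
        if it_config.initial_mask is None:
            raise ValueError("init_mode='explicit' requires initial_mask")
        return np.asarray(it_config.initial_mask, dtype=float)
    if it_config.init_mode == "random":
        rng = np.random.default_rng(config.seed)
        hi = min(it_config.random_hi, 0.499 * signal.fs)
        m = rng.uniform(it_config.random_lo, hi, size=config.max_imfs)
        return np.sort(m)[::-1]
    return zero_crossing_mask_init(signal, config).frequencies


def itemd_sift(
    signal: Signal,
    config: SiftConfig | None = None,
    it_config: ItemdConfig | None = None,
) -> tuple[IMFSet, MaskTrajectory]:
    """Run the iterated masking sift to mask equilibrium.

    Each iteration performs a masked sift with the current mask vector,
    then replaces every mask frequency with the AW-IFM of the IMF it
    produced.  Iteration stops when the maximum relative mask change
    over all (non-empty) IMFs drops below ``stop_tol``, or at
    ``max_iter`` with a logged warning.  Mask vectors are kept sorted
    fast-to-slow, and masks closer together than ``stop_tol`` (which
    the convergence criterion cannot resolve) are merged, the slower
    one dropped - this is how masks that collapse onto one oscillation
    stop splitting it across levels.

    Once the exploration phase has equilibrated, the same fixed-point
    iteration continues with dominant ("2rms") mask amplitudes until it
    re-converges: each level then cleanly claims the band its mask has
    settled on, dissolving spurious weak-mask equilibria that pin a
    mask between an oscillation and its harmonics.  The returned
    decomposition is the last sift of the refinement phase; the
    trajectory spans both phases (``refine_start`` marks the boundary).
    """
    config = config or SiftConfig()
    it_config = it_config or ItemdConfig()
    mask = _initial_mask(signal, config, it_config)
    traj = MaskTrajectory(masks=[mask.copy()])

    # phase 1 - exploration: IMF-tracking ("ratio_prev") mask
    # amplitudes are essential here: masks sitting on a harmonic band
    # of a stronger, slower oscillation do not dominate it, so their
    # IMFs leak fundamental content, their updated frequencies drift
    # onto the oscillation and merge - the bandwidth-adaptation
    # mechanism that lets one IMF keep a nonsinusoidal waveform
    # together with its harmonics
    imfset, mask, converged = _iterate_masks(
        signal, mask, config, it_config, "ratio_prev", traj
    )
    if not converged:
        logger.warning(
            "itemd reached max_iter=%d without convergence", it_config.max_iter
        )
    traj.refine_start = traj.n_iter

    # phase 2 - refinement: rerun the same update with dominant masks
    imfset, mask, refined = _iterate_masks(
        signal, mask, config, it_config, "2rms", traj
    )
    traj.converged = converged and refined
    return imfset, traj


def _iterate_masks(signal, mask, config, it_config, amplitude_mode, traj):
    """Fixed-point AW-IFM iteration under one mask-amplitude rule."""
    input_rms = float(np.sqrt(np.mean(signal.samples**2)))
    imfset = None
    converged = False
    for iteration in range(it_config.max_iter):
        spec = MaskSpec(mask, amplitude_mode=amplitude_mode, n_phases=config.n_phases)
        imfset = mask_sift(signal, spec, config)
        n = min(imfset.n_imfs, mask.size)
        new_mask = mask[:n].copy()
        active = np.zeros(n, dtype=bool)
        for i in range(n):
            imf_i = imfset.imf(i)
            if float(np.sqrt(np.mean(imf_i**2))) <= _EMPTY_IMF_REL_RMS * input_rms:
                continue  # empty IMF: freeze its mask, exclude from convergence
            try:
                new_mask[i] = aw_ifm(imf_i, signal.fs, it_config.weight_power)
                active[i] = True
            except UndefinedFrequencyError:
                pass  # keep previous mask frequency
        rel = np.abs(new_mask - mask[:n]) / mask[:n]
        traj.rel_changes.append(rel.copy())

        # sort fast -> slow, then merge masks closer than the stopping
        # tolerance: two masks within stop_tol of each other cannot be
        # resolved by the convergence criterion and would only split one
        # mode across two levels
        order = np.argsort(new_mask)[::-1]
        new_mask = new_mask[order]
        keep = [0]
        for i in range(1, new_mask.size):
            if (new_mask[keep[-1]] > 0
                    and (new_mask[keep[-1]] - new_mask[i]) / new_mask[keep[-1]]
                    < it_config.stop_tol):
                continue
            keep.append(i)
        new_mask = new_mask[keep]
        traj.masks.append(new_mask.copy())
        max_change = float(rel[active].max()) if active.any() else 0.0
        logger.info(
            "itemd %s iteration %d: mask=%s max_rel_change=%.4g",
            amplitude_mode, iteration + 1,
            np.array2string(new_mask, precision=3), max_change,
        )
        mask = new_mask
        if max_change < it_config.stop_tol:
            converged = True
            break
    return imfset, mask, converged


def mask_stability(trajectory: MaskTrajectory, imf_index: int):
    """Between-iteration relative mask change of one IMF.

    A diagnostic for oscillation presence: masks tracking a genuine
    oscillation settle quickly (median change below a few percent)
    while masks chasing noise keep wandering.

    Returns
    -------
    changes : ndarray
        Per-iteration ``|dm| / m`` for the chosen IMF.
    median : float
    """
    if trajectory.n_iter < 2:
        raise ValueError("mask_stability requires a trajectory with >= 2 iterations")
    changes = []
    for rel in trajectory.rel_changes:
        if imf_index < rel.size:
            changes.append(float(rel[imf_index]))
    if not changes:
        raise ValueError(f"IMF index {imf_index} never present in trajectory")
    arr = np.asarray(changes)
    return arr, float(np.median(arr))
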