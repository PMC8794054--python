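# itemd — iterated-masking empirical mode decomposition

Neural recordings mix oscillations that are noisy, intermittent, and
strongly nonsinusoidal — flat-topped hippocampal theta, sawtooth-like
cortical rhythms, short alpha bursts.  Empirical mode decomposition
(EMD) can represent such activity without a fixed Fourier basis, but
its standard remedies for mode mixing (ensemble sifting, hand-picked
masked sifting) either sinusoidalize the waveform or demand manual
mask tuning.  `itemd` implements the **iterated masking sift**: the
mask frequencies are learned from the data itself by repeatedly
resetting each mask to the amplitude-weighted mean instantaneous
frequency (AW-IFM) of the intrinsic mode function (IMF) it produced,

```
m_i  ←  Σ_t IA_i(t)² · IF_i(t)  /  Σ_t IA_i(t)² ,
```

until the relative mask change falls below a tolerance Σ (default
0.1).  At the equilibrium each mask sits where its mode carries its
power, so a nonsinusoidal oscillation is concentrated — together with
its shape-encoding harmonics — into a single IMF even under heavy
noise or sparsity.

The package is aimed at electrophysiologists analyzing single-channel
LFP/EEG/MEG time series, and provides the full surrounding stack:

- `itemd.sifting` — standard EMD, masked sifting with uniformly
  spread mask phases, ensemble EMD, zero-crossing dyadic mask
  initialization;
- `itemd.iterate` — the iterated masking sift and its mask-stability
  diagnostic;
- `itemd.spectra` — amplitude-normalized Hilbert transform
  (instantaneous amplitude/phase/frequency), cycle detection and
  quality filtering, phase-aligned instantaneous frequency (waveform
  shape), Hilbert–Huang transform;
- `itemd.metrics` — pseudo-mode splitting index (PMSI), frequency
  distortion (FD), shape correlation, Welch-PSD peak finding, and
  one-sided Welch *t* tests with Bonferroni correction;
- `itemd.simulate` — generators for the benchmark signal families
  (iterated sines, white/brown noise, bursts) and the three
  noise/distortion/sparsity benchmark sweeps;
- a CLI (`itemd decompose|simulate|evaluate|shape`).

Two scalar metrics recur throughout.  PMSI quantifies mode mixing
between adjacent IMFs,

```
PMSI(c_i, c_j) = max( ⟨c_i, c_j⟩ / (|c_i|² + |c_j|²), 0 ),
```

0 for orthogonal modes and 0.5 for a mode split identically in two.
FD quantifies nonsinusoidality as the within-cycle instantaneous-
frequency range relative to the base frequency,
`FD = (max IF − min IF) / f₀ × 100 %` (0 % for a sinusoid).

## Worked example

Decompose 10 s of a flat-topped 4 Hz oscillation (8th-order iterated
sine, FD = 68 %) buried in white noise of equal RMS:

```python
import numpy as np
from itemd import SimulationSpec, make_signal, itemd_sift, SiftConfig
from itemd.metrics import select_imf, pmsi_of_interest, shape_correlation
from itemd.iterate import aw_ifm
from itemd.simulate import ground_truth_profile, _profile_of_imf

sig, parts = make_signal(SimulationSpec(f0=4.0, n_sin=8, sigma_noise=1.0, seed=42))
imfs, traj = itemd_sift(sig, SiftConfig(seed=42))
print("converged:", traj.converged, "after", traj.n_iter, "iterations")
print("equilibrium masks (Hz):", np.round(traj.final_mask, 2))

idx = select_imf(imfs, 4.0)
print("signal IMF: %d   mean frequency: %.2f Hz" % (idx + 1, aw_ifm(imfs.imf(idx), sig.fs)))
print("summed PMSI: %.4f" % pmsi_of_interest(imfs, idx))

truth = ground_truth_profile(4.0, 8)
prof = _profile_of_imf(imfs.imf(idx), sig.fs, None)
print("waveform-shape correlation with ground truth: r = %.2f"
      % shape_correlation(prof, truth))
```

Output:

```
converged: True after 11 iterations
equilibrium masks (Hz): [120.74  45.42  16.92   4.08   1.9 ]
signal IMF: 4   mean frequency: 4.08 Hz
summed PMSI: 0.0067
waveform-shape correlation with ground truth: r = 0.77
```

The masks settle on three broadband noise levels, the 4 Hz
oscillation, and a slow remainder.  The signal IMF is nearly
orthogonal to its neighbors (PMSI ≈ 0.007; a fully split mode would
score 1.0 for the summed index), and its phase-aligned instantaneous
frequency — the waveform-shape summary — correlates at r = 0.77 with
the noiseless ground-truth shape even at unit noise RMS, where a
fixed dyadic mask splits the mode and ensemble sifting returns a
near-sinusoid.

The same decomposition from the shell:

```sh
itemd simulate --nsin 8 --sigma 1.0 --seed 42 --out signal.csv
itemd decompose signal.csv --fs 512 --method itemd --seed 42 --out-dir out/
```

which writes the IMFs as CSV plus a JSON report with the full mask
trajectory and configuration echo.

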