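# cortnet

Source-space EEG functional connectivity for infant N2-sleep recordings.

Epilepsy in the first year of life carries a high risk of neurodevelopmental
delay, and the clinical course is hard to predict from conventional EEG
reading. One promising family of markers treats the sleeping brain as a
network: band-limited cortical activity is reconstructed from high-density
scalp EEG, and the coupling between cortical regions is quantified per
frequency band and compared between clinical groups. `cortnet` implements
that analysis as a tested Python pipeline for researchers working with
infant sleep EEG — together with a synthetic-data generator with exact
ground truth, so every stage can be validated without clinical recordings.

## The analysis

Given 64-channel N2-sleep EEG (EDF or arrays), the pipeline:

1. **Conditions** the data: resampling to 250 Hz, spherical-spline
   interpolation of bad channels, common-average reference.
2. **Filters** into 25 narrow bands on a geometric ladder,
   `fc[k] = 0.5 · 1.2^k` Hz (0.5 → 39.7 Hz), with linear-phase Kaiser FIR
   band-passes (passband `[0.85, 1.15]·fc`, stopband `[0.5, 1.5]·fc`,
   ≥ 40 dB attenuation), applied zero-phase per continuous segment.
3. **Detects sleep spindles** (11–15 Hz envelope detector with a
   cross-channel summed-power gate) and can excise them to test whether a
   network effect is spindle-bound.
4. **Inverse-models** each band to cortical sources with a minimum-norm /
   dSPM operator (`K = Gᵀ(GGᵀ + λC)⁻¹`, identity noise covariance) and
   collapses dipoles to 58 parcel signals by the parcel mean. A desk-scale
   spherical head model is built in; real head models enter as a gain
   matrix + parcel map file.
5. **Estimates connectivity** per parcel pair (1653 pairs), band and mode:
   - **AAC** via the orthogonalized correlation coefficient (oCC):
     envelopes are correlated after removing each signal's instantaneous
     zero-lag component with respect to the other
     (`y⊥ = Im[y·conj(x)/|x|]`), killing volume-conduction artifacts;
   - **PPC** via the debiased squared weighted phase lag index (dwPLI),
     built from windowed imaginary cross-spectra, insensitive to zero-lag
     coupling and to sample-size bias.
6. **Prunes unresolvable edges**: per parcel pair, synchronized activity is
   simulated, forward-projected, reconstructed, and compared with the
   leakage-induced coupling of non-synchronized pairs (500 iterations,
   surrogate 99th percentile).
7. **Compares groups**: global mean connectivity per band (Kruskal–Wallis),
   one-tailed edge-wise rank-sum tests in both directions with
   Benjamini–Hochberg FDR (α = 0.05) summarized as network density
   *K* = significant/unmasked edges, rank-biserial effect sizes, region and
   edge-length summaries, spindle-removal contrasts, and neurocognitive
   trajectory (1 y → 2 y) comparisons.

## Worked example

Generate a synthetic cohort with one envelope-coupled parcel pair
(target envelope correlation 0.6 at 13 Hz) and recover the coupling:

```python
import numpy as np
from scipy.signal import hilbert
from cortnet import CouplingSpec, simulate_parcel_sources, occ, dwpli
from cortnet.spindles import spindle_band_filter

fs = 250.0
spec = [CouplingSpec(pair=(0, 1), mode="envelope", band_hz=13.0, strength=0.6)]
sources = simulate_parcel_sources(spec, n_parcels=4, fs=fs, duration_s=600, seed=42)
banded = spindle_band_filter(sources, fs, (11, 15))
z = hilbert(banded, axis=1)
print(f"oCC(coupled pair 0-1)   = {occ(z[0], z[1], fs):.3f}")
print(f"oCC(uncoupled pair 2-3) = {occ(z[2], z[3], fs):.3f}")
print(f"dwPLI(coupled pair 0-1) = {dwpli(z[0], z[1], fs):.3f}")
```

prints

```
oCC(coupled pair 0-1)   = 0.624
oCC(uncoupled pair 2-3) = -0.033
dwPLI(coupled pair 0-1) = 1.000
```

The implanted envelope correlation (0.6) is recovered by the oCC on the
coupled pair, an uncoupled pair sits at the noise floor, and the coupled
pair's fixed carrier lag saturates the dwPLI.

The full pipeline runs from the shell:

```bash
cortnet run --seed 1 --out results/smoke          # synthetic smoke cohort
cortnet fidelity --iters 500 --pct 99 --seed 7 --out mask.tsv
cortnet --help                                    # all subcommands
```

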