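# Methods

This note documents the models, defaults and numerical choices behind
`cortnet`, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal flow

Sensor EEG (channels × samples, µV, 250 Hz target rate) is carried in a
`Recording` that also stores a list of half-open sample ranges — the
*segments*. Segments encode the discontinuity of N2-sleep epochs and of
spindle-excised data; every filter, Hilbert transform and analysis window
is confined to a single segment, so no estimate ever spans a cut. Spindle
removal excises data and re-segments rather than zeroing, so windowed
metrics only ever see genuine signal.

## Filter bank

The 25 analysis bands form a geometric ladder `fc[k] = 0.5 · 1.2^k` Hz
(top band 39.7 Hz). Each band-pass is a linear-phase Kaiser-window FIR
with passband `[0.85, 1.15]·fc`, stopband `[0.5, 1.5]·fc` and a 40 dB
stopband contract. The Kaiser order/β rule is driven by the narrower
transition band with a small design margin (+5 dB, 0.9× width) so the
*measured* response meets −40 dB at the stopband edges; the passband
ripple of a 45 dB Kaiser design is ≈ 0.05 dB, far inside the 1 dB
tolerance at `fc`. Filters are applied by FFT convolution with the
symmetric taps centred (zero phase — phase metrics downstream must not be
biased), one filter length is trimmed from each segment end, and segments
shorter than three filter lengths are skipped for that band and logged.
At `fc = 0.5` Hz the filter is ≈ 13 s long, so the lowest bands need
segments of ≈ 40 s or more; this is an inherent cost of the 40 dB/relative-
transition contract, not a tunable.

Broadband conditioning (0.15–48 Hz) uses the same design with transition
widths of 0.1 Hz (low edge) and 4 Hz (high edge) and half-length trimming;
synthetic data are generated band-limited at 250 Hz and skip it.

## Spindle detection and removal

Per channel: band-pass to 11–15 Hz, Hilbert envelope, 0.1 s moving-average
smoothing; events are flagged where the envelope exceeds `k_upper = 3`
times the channel-mean envelope, extended to the span above
`k_lower = 1.5` times the mean, and kept when that span lasts 0.5–3 s. The
channel-mean baseline needs ≥ 30 s of data. The smoothing window is kept
short (0.1 s) so the duration gate is decided by the burst, not by the
smoother.

Cross-channel gate: candidate segments (union of per-channel detections)
are retained only if the summed squared envelope over all channels peaks,
within the segment, above `θ = 0.5` times the mean of per-candidate peak
amplitudes of that summed envelope. The mean is taken per recording (not
per candidate subset); `θ = 0` disables the gate. Spindle groups merge
gated events with gaps ≤ 1 s; spindles-per-group counts channel-level
detections overlapping the group span, which is the reading under which a
≈ 1.4 s group can contain ≈ 15 "spindles".

All thresholds are exposed in `SpindleDetectorParams`; they are declared
defaults of this detector family, not fitted values.

## Forward and inverse model

The built-in head model is deliberately desk-scale: sensors on the unit
sphere, radially oriented dipoles on an inner shell (fractional radius
0.70–0.87, seeded jitter), and the homogeneous-sphere analytic surface
potential for a radial dipole,

    V(γ) = q/(4πσR²) Σ_{n≥1} (2n+1) f^{n−1} P_n(cos γ),

truncated at 60 Legendre terms (converges quickly for f ≤ 0.87). Parcels
are contiguous angular patches from k-means on source directions, labelled
frontal/central/temporal/occipital × hemisphere by centroid octant.
Three-compartment conductivities (1.79, 0.1, 0.43 S/m) are carried as
metadata for user-supplied realistic gain matrices; the toy model itself
is single-shell. Fixed radial orientations mean parcel means need no
sign-flip alignment — the plain-mean collapse presumes consistent
orientation.

The inverse is minimum-norm with identity noise covariance and no depth
prior: `K = Gᵀ(GGᵀ + λI)⁻¹`, dSPM normalization `√(diag(KKᵀ))` per source.
λ defaults to the SNR rule `trace(GGᵀ)/(n_sensors · SNR²)` with SNR = 3,
exposed in config. The whole sensor→parcel chain is one linear map;
precomputing it equals stagewise application to 1e−10 (tested), and on the
identity bundle the chain is the identity — the pipeline's
null-transformation test.

## Connectivity estimators

Both estimators consume per-segment Hilbert analytic signals; segments
shorter than two cycles of `fc` are skipped.

**oCC (AAC).** In non-overlapping 1 s windows, `y⊥ = Im[y·conj(x)/|x|]`
removes the component of `y` sharing `x`'s instantaneous phase; the
Pearson correlation between the concatenated window-wise envelopes of
`y⊥` and `|x|` is averaged with the roles swapped. `y = x` gives exactly 0
(self-orthogonalization), which is the volume-conduction suppression
property; sub-float-precision residues (≈ 1e−17 from complex arithmetic)
are snapped to zero so this holds bit-exactly. Linear envelopes are the
default; log envelopes are a config option. At least 30 windows are
required, otherwise the pair is masked.

**dwPLI (PPC).** Each window contributes one imaginary cross-spectral
sample `I_j = Im⟨x·conj(y)⟩`; the debiased squared estimator is
`[(ΣI)² − ΣI²] / [(Σ|I|)² − ΣI²]`, zero by convention when every `I_j`
vanishes. Windows are `max(1 s, 4/fc)` — at least four carrier cycles per
cross-spectral sample, matching the oCC non-overlap convention (the
windowing of this estimator is a package choice). Raw values may be
slightly negative; the adjacency matrix stores a [0, 1]-clipped copy and
keeps the raw value. The non-debiased PLI² is provided for contrast; its
null mean is ≈ 1/n_windows while the debiased null mean is ≈ 0 (tested at
100 windows over 200 seeds).

Adjacency matrices mask the diagonal and any pair with too few windows as
NaN — never silently zero.

## Fidelity edge pruning

Whether an edge is measurable at all is decided by simulation, per parcel
pair: the pair shares a narrow-band 10 Hz oscillation at a fixed π/4 lag
(sign-consistent imaginary cross-spectrum *and* Pearson-constructive
leakage; a quarter-cycle lag would make the members Pearson-orthogonal),
all other parcels carry independent white noise, and the activity is
pushed through forward → inverse → collapse. The per-iteration statistic
is the reconstructed interaction `|corr(recon_i, recon_j)|`; surrogates
are the same interaction for randomly sampled non-synchronized pairs (two
per iteration), pooled over all pairs and iterations — the global leakage
floor. An edge is retained when its median statistic reaches the
surrogate 99th percentile (with a 1e−9 epsilon guarding exact-tie float
round-off on the identity model, where every statistic is exactly 1).

An earlier candidate rule — comparing each member's reconstruction
fidelity `corr(recon_m, orig_m)` against the pooled 99th percentile of the
same quantity on non-synchronized parcels — is degenerate: the minimum of
two draws from approximately the surrogate distribution almost never
exceeds that distribution's 99th percentile, so every edge of any
non-identity model is excluded. The interaction-vs-leakage rule is the
decision-theoretically meaningful one and is what this package implements.

Defaults: 500 iterations, 99th percentile, 2 s of simulated signal per
iteration (20 probe-carrier cycles), sensor-noise-free (the mask probes
the deterministic distortion of the chain; `snr_db` is exposed for
sensitivity analysis). Internals run in float32; the correlation
statistics are insensitive at the 1e−4 level while decision margins are
orders of magnitude larger. The mask depends only on (bundle, inverse,
parameters, seed), never on subject data. On the built-in toy model the
retained set is small (the single-shell spherical geometry with mean-
collapsed patches is very leaky); the excluded *fraction* is stable across
seeds to well under a percentage point at 50 iterations, which is the
property the mask is validated on — the excluded count of any real
MRI-based head model is a property of that model.

## Group statistics

Global level: per-subject mean over unmasked edges, Kruskal–Wallis across
groups per band (degenerate all-identical input returns H = 0, p = 1).
Edge level: one-tailed Wilcoxon rank-sum per unmasked edge and direction,
BH-FDR at α = 0.05 per (band × mode × direction) family, network density
K = significant/unmasked. Rank-sum p-values are exact (scipy) when
min(n) ≤ 10 and the edge has no ties, else a tie-corrected normal
approximation with continuity correction, vectorized over edges and
cross-checked against scipy. The effect size is the rank-biserial
correlation `(#A>B − #A<B)/(n_A·n_B)`; it is *a* standard rank effect
size, chosen because the rank-sum test is the underlying statistic, and
reported magnitudes are not claimed to be comparable to any other ES
definition. BH goes through `statsmodels`; the test suite checks it
against a hand-coded textbook step-up.

Region summaries report, per region and region pair, the fraction of
possible (unmasked) edges that are significant, inter-/intra-hemispheric
fractions, and centroid-distance edge lengths (to be viewed on a log
scale); region pairs with no possible edge are omitted. Trajectory
analysis labels subjects by their 1 y → 2 y neurocognitive pair, drops
groups below two subjects and the Typical→Severe trajectory, and compares
groups sharing the 1 y label on global connectivity per band (two-sided
rank-sum, BH over bands).

Band summary panels pick, per third of the spectrum (< 3, 3–13, > 13 Hz),
the band with the greatest K.

## Synthetic data: what it emulates, what it does not

The generator produces 1/f^1.1 background with a 10–14 Hz bump (infant N2
flavour), envelope-coupled pairs whose jointly log-normal slow
(0.1–0.5 Hz) envelopes hit the target Pearson correlation *analytically*
(the mixing weight is inverted from the log-normal correlation formula,
not tuned), phase-coupled pairs sharing a constant-modulus carrier with a
fixed lag plus slow von-Mises jitter, raised-cosine spindle bursts with
exact sample-level truth intervals, and sensor projection with white noise
at a requested SNR. Envelope-coupled members ride a shared carrier offset
by π/2 by default so the coupling survives orthogonalization (a zero-lag
shared carrier would be — correctly — removed as volume conduction);
independent carriers are available as an option.

Cohorts add group structure as an additive offset on coupling strength;
a matrix-level cohort simulator (baseline + Gaussian edge noise + implanted
edge offsets) supports the statistical-power and FDR experiments at sizes
where signal-level simulation would be pointless overhead.

Not emulated: ocular/muscle artifacts, line noise (the analysis band ends
below 48 Hz), realistic cortical geometry and conductivity, sleep-stage
transitions, and any biophysical neural-mass dynamics. Passing tests
therefore establish the *estimators and inference machinery* — recovery of
known couplings, null behaviour, FDR control, mask logic — not the
clinical sensitivity of the markers on real infant EEG.

## Numerical and degenerate-input conventions

- Zero-variance signals correlate as 0; `y = x` returns oCC 0 and dwPLI 0
  exactly (float residues below 1e−12 of signal scale are snapped).
- Excision sample indices round half-up, so excised durations are exact.
- Masked cells are NaN end-to-end; global means and test families are
  computed over surviving cells only.
- Every stochastic operation takes an explicit seed; cohorts derive
  per-subject seeds from a `SeedSequence` spawn, and identical
  (config, seed) reruns of the pipeline are cache hits (no recomputation).

## Problem sizes used in the validation suite

Unit and acceptance tests run at deliberately small scale: 2–58 parcels,
60–600 s records, 10–50 mask iterations, 15 subjects per group for the
FDR experiment (50 replicates), 1000 replicates for the Kruskal–Wallis
type-I check. These sizes were chosen so each property is measured with
comfortable statistical margin; the library itself has no scale
assumptions beyond memory.

## Known limitations

- The toy head model is a crude single-shell sphere; its fidelity mask
  retains few edges and its point-spread is broad. It validates mechanics,
  not anatomy.
- EDF export writes plain EDF (one continuous record); segment structure
  survives only in the HDF5 representation.
- The exact parameterization of the cited spindle-detector family and of
  the dSPM regularization are not published quantities; both are declared
  configuration here.
- The dwPLI windowing convention (4 cycles minimum) and the fidelity
  simulation band/lag are package choices, documented above.
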