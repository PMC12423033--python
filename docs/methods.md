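# Methods

## Signal model and solver

A participant's parcellated fMRI record is a real C × T matrix x (one row
per ROI, sampling interval `dt` = TR seconds). It is modelled as a sum of K
multivariate intrinsic modes, x_c(t) = Σ_k u_k,c(t) + r_c(t): each mode is
an AM–FM oscillation whose analytic spectrum is concentrated around a
central frequency ω_k *shared by all channels*, and r is whatever the
solver leaves unassigned. The modes minimise the summed bandwidth of their
analytic representations subject to per-channel reconstruction, and the
constrained problem is solved by ADMM entirely in the frequency domain on
the nonnegative half-spectrum (normalised frequency f ∈ [0, 0.5]
cycles/sample):

- **mode update** (Wiener-like filter, Gauss–Seidel over modes):
  û_k,c ← (x̂_c − Σ_{j≠k} û_j,c + λ̂_c/2) / (1 + 2α (f − f_k)²)
- **frequency update** (power centroid pooled over *all* channels — this
  pooling is what makes ω_k shared):
  f_k ← Σ_c ∫ f |û_k,c(f)|² df / Σ_c ∫ |û_k,c(f)|² df
- **dual ascent**: λ̂ ← λ̂ + τ (x̂ − Σ_k û_k)

Convergence is declared when Σ_k ‖û_k^{n+1} − û_k^n‖² / ‖û_k^n‖² (summed
over channels and frequencies) falls below `tol`. After the loop the modes
are recovered by inverse FFT (Hermitian completion), sorted by ascending
ω_k, and the residual is defined as input minus mode sum, so
`modes + residual` equals the input to machine precision by construction.
Central frequencies are reported in Hz (f_k / dt).

### Parameters

| name | default | meaning |
|------|---------|---------|
| K | 10 | number of modes; 6 suffices for the synthetic cohort below |
| alpha | 1000 | bandwidth penalty; larger → narrower modes |
| tau | 0 | dual step; 0 tolerates broadband noise, ≥ 0.5 enforces near-exact reconstruction of clean signals |
| tol | 1e-7 | summed relative spectral change declaring convergence |
| max_iter | 500 | iteration cap |
| init | "log" | center-frequency initialisation (below) |
| boundary | "mirror" | mirror-extend by T/2 per side before the FFT, crop after; reduces edge ringing |
| pin_first_mode_dc | False | optionally hold ω_1 = 0 |

**Initialisation.** The default places K centers geometrically between
5/T and Nyquist/2 (normalised), with the first replaced by DC. Physiological
spectra are 1/f-like and the central frequencies that emerge from fMRI
decompositions are roughly geometrically spaced, so a log grid seeds the
crowded low end densely enough that slow oscillations just above the drift
band (e.g. 25 mHz at TR = 0.72 s) get their own mode instead of being
absorbed by the DC-seeded drift mode. A uniform grid over [0, Nyquist/2]
("uniform"), random draws ("random", the only path consuming the seed) and
all-zero ("zero") are available; with the uniform grid the 25 mHz tone of
the reference cohort is systematically merged into the drift mode, which is
why it is not the default.

**Degenerate inputs.** Constant channels contribute only to the near-DC
mode. An all-constant signal with K ≥ 2 warns and yields duplicated
near-DC modes; modes that captured no energy report ω = 0 by convention.
Center collisions within one frequency bin are kept (with a warning), never
merged.

**τ and reconstruction.** With τ = 0 the Wiener filters shrink spectral
leakage near record edges, leaving ~2% residual on tone fixtures (interior
error ~0.1%); with τ ≥ 0.5 the dual ascent enforces the constraint and the
full-record error falls below 1%. Noiseless reconstruction checks therefore
run with τ = 1; noisy data keep τ = 0 so the residual can absorb noise.

## Band profiling and selection

Per mode: central frequency ω_k; relative energy E_k/E_tot with
E_k = Σ_{c,t} u_k,c(t)² and E_tot the energy of the decomposed input; and
an RMS bandwidth, 2·sqrt of the power-weighted second central moment of the
channel-summed power spectrum about its centroid (the factor 2 makes it a
full width; the second-moment convention is stated because the quantity is
convention-dependent and tail-sensitive for line spectra). Bands (half-open,
lower-inclusive, tiling [0, Nyquist]):

trend [0, 10) mHz · neurophysiological [10, 200) mHz · respiratory
[200, 350) mHz · vascular_cardiac [350, 800) mHz · other_high [800, Nyq].

Selection uses the mode's global ω_k, not per-channel instantaneous
frequency, because the shared center is what defines the mode's timescale.

## Connectivity statistics

Per mode and participant: Pearson correlation between ROI waveforms,
Fisher-Z transformed (|r| clipped to 1 − 1e-7), diagonal set to 0. The null
"randomly mixes the temporal samples" of the mode: each permutation draws an
**independent** random permutation of time indices per channel — a shared
permutation would preserve cross-ROI alignment and produce a degenerate
null, so independence is essential. Group inference contrasts, per
off-diagonal edge, the N observed z values with the pooled null z values by
a two-sided Welch t statistic; its p-value is the tail fraction over
label-shuffled statistics with continuity correction p = (b+1)/(n+1), and
Benjamini–Hochberg at level q (default 0.001) over the C(C−1)/2 upper-
triangle edges gives a symmetric mask. Identically-constant edges (from
constant channels) are excluded and reported non-significant. The label
permutations are shared across edges, which preserves their joint null
distribution and keeps the test vectorisable.

**Permutation resolution.** BH at level q over E edges can only reject a
lone true edge if the p-value floor 1/(n_stat_perm + 1) is below q/E. At
q = 0.001 and C = 10 (45 edges) that requires n_stat_perm > 45,000; the
power validation therefore uses 60,000 label permutations, while null
calibration (where no rejection is expected) uses 2,000.

Display convention: the composite matrix carries all group-mean z values in
the lower triangle and only significant ones in the upper triangle.

## Reproducibility

FC matrices are compared across participants by Pearson correlation of
their vectorized upper triangles (row-major, `triu_indices(C, 1)` order),
over all N(N−1)/2 unordered pairs; modes are matched across participants by
index after the ascending-frequency sort. Similarity is computed on
Fisher-Z matrices, consistent with the rest of the statistics. Participants
with constant FC vectors yield NaN pairs, excluded from summaries with a
warning.

## Synthetic cohorts

The generator emulates the structure of parcellated resting fMRI:
per participant, Σ_components loading × waveform + white Gaussian noise,
channels mean-centred, everything drawn from one seeded generator
(bit-reproducible). Waveforms are standardised to unit RMS so a component's
`amplitude` is its per-unit-loading signal RMS:

- **trend**: integrated white noise low-passed below 8 mHz, redrawn per
  participant (drifts are individual-specific);
- **neural_oscillation / respiratory / cardiac**: AM tone (15% depth,
  5 mHz modulation) with per-participant frequency jitter (±10%) and
  amplitude jitter (±20%), random phase;
- **task_block**: boxcar convolved with the canonical double-gamma HRF
  (response gamma shape 6, undershoot shape 16, ratio 1/6, peak ≈ 5 s,
  undershoot ≈ 15 s, peak-normalised, value 0 at t = 0);
- loadings: fixed per-ROI templates shared across participants (planting
  reproducible connectivity), or redrawn per participant
  (individual-specific components); components above Nyquist are refused
  unless aliasing is explicitly enabled, in which case they fold to the
  aliased frequency with a warning.

**Reference cohort** (`default_cohort_spec`): N = 10 participants, C = 20
ROIs in 4 modules, T = 1200 samples at dt = 0.72 s; individual drift
(amplitude 1.5), neural tones at 25/60/110 mHz with module-structured
shared loadings (weights ±0.7–1.0 spanning pairs of modules, giving a
block-structured ground-truth FC with both positive and negative edges),
an individual-loading respiratory tone at 250 mHz (amplitude 0.8), and
noise_sd = 1.4 — per-ROI signal variance ≈ 2, i.e. broadband SNR ≈ 0 dB.
Ground truth exposes the waveforms, loadings, jittered frequencies, and
per-band FC (group-mean correlation of the noiseless band component sums).

What the cohort does *not* emulate: 1/f-continuous background spectra,
spatially correlated (non-white) noise, hemodynamic lag differences between
ROIs, motion spikes, and session-length nonstationarity. Passing tests
demonstrate correct recovery of discrete planted structure at realistic
SNR, not performance on real scanner data.

## Validation study conditions

Problem sizes used by the test suite and `scripts/acceptance.py` (chosen to
exercise each property at the smallest informative scale):

- tone recovery: 8 channels, tones 20/100/250 mHz, T = 1200, K = 3;
- univariate equivalence: 5 random two-tone fixtures, C = 1, agreement to
  1e-8 with an independently coded univariate solver;
- reconstruction: noiseless two-tone fixture, τ = 1;
- band selection: 20 single-participant cohorts (one seed each);
- null calibration: 50 replicates (tests) / 20 (script) of N = 20, C = 10
  signal-free datasets, n_perm = 200, n_stat_perm = 2000, q = 0.001;
- power: 20 (tests) / 10 (script) replicates with one planted r = 0.6 edge,
  n_stat_perm = 60,000;
- FC recovery and reproducibility: the reference cohort, K = 6
  (reproducibility over 10 seeds in tests, 3 in the script).

## Known limitations

- The ADMM landscape is non-convex; initialisation matters, and the log
  grid, while robust on 1/f-like physiological mixtures, is not a global
  optimiser. Badly separated components at high α can still share a mode.
- The RMS bandwidth is dominated by spectral tails for near-line spectra;
  comparisons across bandwidth conventions require the stated factor.
- K and α are user choices; the package deliberately does not auto-select
  them.
- The permutation null destroys *all* temporal structure, including
  autocorrelation, so it is a null of no cross-ROI dependence, not a
  surrogate preserving spectra; this matches the mode-shuffling design it
  implements.
- Group inference assumes participants are exchangeable with the pooled
  null under H0; no hierarchical variance model is fitted.
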