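# modeconn

Multiscale functional connectivity for parcellated fMRI time series via
**multivariate variational mode decomposition (MVMD)**.

Resting-state BOLD signals superimpose processes living at very different
timescales: near-DC scanner/physiology drifts, neurophysiological
fluctuations in the 10–200 mHz band, respiratory oscillations around
250 mHz, and vascular/cardiac components at 400–800 mHz (partly aliased at
typical repetition times). Conventional static functional connectivity (FC)
mixes all of them into one correlation matrix. `modeconn` instead

1. decomposes each participant's ROI × time matrix into K narrow-band
   multivariate *intrinsic modes* that share central frequencies across
   ROIs (frequency-domain ADMM: Wiener-like mode updates, channel-pooled
   power-centroid frequency updates),
2. classifies each mode by its central frequency into physiological bands
   and selects the neurophysiological ones,
3. computes per-mode Pearson FC, Fisher-Z transformed, with significance
   assessed against a null built by independently permuting the temporal
   samples of each ROI's mode waveform (permutation Welch t-test,
   Benjamini–Hochberg FDR at q = 0.001), and
4. quantifies cross-participant reproducibility of each mode's FC as the
   Pearson similarity of vectorized FC matrices over all participant pairs.

## The model

A C-channel signal is written as x_c(t) = Σ_k u_k,c(t), where each
multivariate mode u_k = [u_k,1 … u_k,C] is an AM–FM oscillation
concentrated around a shared central frequency ω_k. The modes solve

min_{u,ω}  Σ_k Σ_c ‖ ∂_t [ (δ(t) + j/(πt)) * u_k,c(t) ] e^{−jω_k t} ‖²
s.t.  Σ_k u_k,c = x_c  for every channel c,

i.e. joint bandwidth minimisation of the analytic mode spectra with a
per-channel reconstruction constraint, relaxed by a quadratic penalty α
(larger α → narrower modes) and solved by ADMM in the frequency domain.
Defaults follow common fMRI practice: K = 10, α = 1000, TR = 0.72 s.

## Worked example

```bash
python examples/01_decompose_tones.py
```

```
planted frequencies (Hz): [0.02, 0.1, 0.25]
recovered omega (Hz):     [0.02   0.0999 0.25  ]
relative error (%):       [0.23 0.07 0.01]
reconstruction rel. L2:   0.0330
converged: True after 7 iterations
```

An 8-channel mixture of tones at 20/100/250 mHz is pulled apart into three
modes whose central frequencies match the planted ones to ≤ 0.25%; the sum
of modes reproduces the input to ~3% (the small residual is spectral
leakage retained by design when the dual step τ = 0).

Profiling one synthetic participant (`examples/02_band_profile.py`):

```
mode   f (mHz)  BW (mHz)  E_k/E_tot  band
   0       1.4      15.8      0.173  trend
   1      23.8      32.4      0.112  neurophysiological
   2      55.3      20.6      0.100  neurophysiological
   3     112.0      20.7      0.130  neurophysiological
   4     243.2      35.0      0.096  respiratory
   5     484.1      56.3      0.032  vascular_cardiac
selected neurophysiological modes: [1, 2, 3]
```

The drift mode sits at ~0 Hz with the largest energy share, the three
planted neural tones (25/60/110 mHz, jittered per participant) are
recovered and selected, and the respiratory tone is excluded.

Other examples: `03_connectivity.py` (per-mode FC + significance),
`04_reproducibility.py` (per-mode similarity across participants),
`05_task_regressor.py` (canonical double-gamma HRF and block regressors).

## Command line

```bash
modeconn run --simulate --seed 1 --out myrun     # all four stages
modeconn print-config                            # every default
modeconn decompose --seed 1 --out out ts1.tsv    # one stage at a time
```

Inputs are delimited text, one column per ROI with a header of ROI labels,
one row per time point; each channel is mean-centred on ingest. Runs are
bit-reproducible for a fixed config and seed.

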