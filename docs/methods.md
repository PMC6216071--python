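# Methods

## The estimation chain

`ggcbench` estimates frequency-resolved directed influence — Granger–Geweke
causality (GGC) — between channels of multichannel, trial-based time series,
without fitting an autoregressive model to the data. The chain is

1. **Multitaper cross-spectral density.** Each trial is demeaned per channel,
   multiplied by each of the `2·NW − 1` discrete prolate spheroidal (DPSS)
   tapers, and Fourier transformed; the cross-spectral matrix S(f) is the
   average of the channel outer products over tapers and trials. The default
   time-bandwidth product is NW = 4 (7 tapers), and spectra are computed on
   the unpadded grid from 0 to Nyquist with step Fs/N.
2. **Wilson spectral factorization.** S(f) is decomposed into a causal
   minimum-phase factor ψ with S = ψψ*, giving the transfer function
   H = ψ·A0⁻¹ and innovation covariance Σ = A0·A0ᵀ (A0 the zero-lag
   coefficient of ψ) — the same quantities a parametric MVAR fit would
   provide, obtained nonparametrically.
3. **Geweke's spectral measure.** The influence of sender j on receiver i is
   f_{j→i}(f) = ln[ S_ii / (S_ii − (Σ_jj − Σ_ij²/Σ_ii)·|H_ij|²) ] for the
   bivariate (pairwise) case. The conditional measure factorizes both the
   full M-channel spectrum and the reduced spectrum without the sender,
   forms Q(f) = G̃(f)⁻¹H(f) (G̃ embeds the reduced factor with an identity
   row/column at the sender), and splits the reduced innovation power of the
   receiver into the sender's partialled contribution and an intrinsic rest:
   F_{j→i|rest}(f) = ln[ Σ_R(i,i) / (Σ_R(i,i) − |Q_ij|²·σ̃_jj) ], where
   σ̃_jj is the sender's innovation variance with all other innovations
   partialled out. At M = 2 the conditional measure reduces exactly to the
   pairwise one; the naive ratio Σ_R(i,i)/(QΣQ*)_ii is identically zero
   because the reduced innovations are white, which is why the partialled
   decomposition is required.
4. **Time-reversal testing.** net-GGC_ij = GGC_ij − GGC_ji; tr-GGC is the
   difference between net-GGC on the original and on the time-reversed
   data, kept only where positive. Time reversal preserves every channel's
   power spectrum but flips the direction of lagged dependence, so
   artifacts that are symmetric under reversal (shared reference signals,
   SNR imbalance, instantaneously mixed additive noise) cancel in the
   difference while genuine lagged influences survive. Only this
   "difference-based" variant is implemented; the variant token in the API
   leaves room for others.

A useful identity used by the scenario drivers (and tested against the
direct data route): the multitaper CSD of time-reversed trials is exactly
the per-frequency transpose of the CSD of the original trials, so tr-GGC
costs two factorization passes, not two data passes.

## Wilson iteration: numerical choices

- Iteration: ψ_{k+1} = ψ_k·[ψ_k⁻¹ S ψ_k⁻* + I]₊ on the full (two-sided)
  circular frequency grid, initialized from the Cholesky factor of the
  frequency-averaged spectrum. The causal-part operator []₊ keeps lags
  0..N/2 of the lag expansion, with half weight and an upper-triangular
  projection at lag 0 (this pins the normalization: A0 upper triangular
  with positive diagonal). For an even-length grid the shared ±N/2 lag bin
  also takes half weight; keeping it whole makes the iteration cycle at an
  error equal to that bin's magnitude instead of converging.
- Stopping: maximum over frequency of the relative Frobenius change of ψ
  below `tol` (default 1e-9, max 100 iterations), plus the requirement that
  the reconstruction residual max_f ‖S − ψψ*‖/‖S‖ is itself below `tol`.
  The iteration is a Newton scheme and converges quadratically; typical
  converged residuals are 1e-10..1e-12. Non-convergence sets a flag and
  emits a warning, never silently.
- Regularization: if any frequency's spectrum has a non-positive eigenvalue
  (possible for finite-sample estimates at DC after demeaning), add
  `1e-10 · mean(diag) · I` once.
- Grid truncation: factorizing a spectrum sampled on an N-point grid
  implicitly factorizes the circularly wrapped autocovariance; the wrapping
  error scales like r^(N/2) for pole radius r. For the bundled models at
  the default N = 400 this is ≤ 1e-9; comparison tests with sharper poles
  use finer grids accordingly.

## Conventions

- Model form x(t) = Σ_k A_k x(t−k) + w(t); stability requires the companion
  spectral radius < 1 and is enforced at construction and simulation.
- PSD: one-sided density (units²/Hz) on [0, Nyquist], interior bins doubled,
  DC/Nyquist single-weight, so the integral equals the process variance.
  The analytic spectrum H Σ H*/Fs uses the identical convention, making the
  parametric oracle and the multitaper estimate directly comparable.
- GGC indexing is receiver-first: `values[i, j, f]` is the influence from
  channel j to channel i.
- Innovations are Gaussian. GGC depends on second-order structure only, so
  this choice is a convenience, not a restriction of the measures.
- Seeding: one master integer seed; every trial, reference series, and
  noise source draws from a counter-keyed substream
  (`SeedSequence(seed, spawn_key=…)`), so trial k's data never change when
  the trial count changes and corruption streams are independent of the
  network innovations by construction.

## Simulation scenarios

All drivers share the defaults of the benchmark design: 100 trials of 400
samples at Fs = 200 Hz, NW = 4, corruption weight α swept over 0.1..0.9 in
steps of 0.1, and report the median and 5th/95th percentile GGC and tr-GGC
curves across `n_repeats` independent seed replicates (default 10; the
replicate dimension is an extension over a single-run design and is echoed
in the output config).

- **Common reference**: two AR(2) oscillators (pole radius 0.8, resonance
  40 Hz) with a unidirectional 1→2 influence (lag coefficients −0.35, 0.7);
  observed signals x′ = (1−α)x − αR with one shared reference R per trial —
  white with the innovations' variance, or an AR(2) oscillation at 40, 20,
  or 70 Hz.
- **SNR imbalance / additive noise**: network of identical AR(2) nodes
  (self coefficients 0.5, −0.8; couplings 0.2, −0.1), noise added as
  x′ = (1−α)x + αe on a chosen channel subset. Noise e is K·η with S = M
  independent sources: K = I ("IND") or a random full-rank matrix with
  unit-norm standard-normal rows ("MIX"). Sources are white or, for the
  mixed-color option, alternately white (odd positions) and 1/f
  ("white+pink"); the split is a documented convention. Pink noise is made
  by scaling the spectrum of white noise by f^(−1/2) (DC zeroed) and
  rescaling to unit variance, which hits the −1 log-log slope exactly in
  expectation.
- **Three-node MVAR(3) benchmark**: the classic conditional-causality
  demonstration system of Stokes & Purdon (2017) — a 1→2→3 chain of
  resonators at 40, 10 and 50 Hz, Fs = 120 Hz, 1000 realizations of 500
  samples by default. Coefficients ship as a JSON config transcribed from
  the original work (never hard-coded from memory); the loader rejects
  configs that are unstable or whose analytic PSD peaks do not round to the
  documented resonances. The driver reports per-realization medians and
  percentiles, a pooled estimate using all realizations at once, the true
  curves computed from the model's analytic spectrum, and per-node PSDs.
  Note the 10 Hz node's resonance is broad (pole radius 0.7): its true PSD
  argmax sits at 7.7 Hz, so peak checks compare against the analytic
  spectrum rather than the nominal label.

## Synthetic SEP fixture

`generate_synthetic_sep` emulates the layout of the companion epicranial
SEP recordings (15 channels, Fs = 2000 Hz, epochs −100..+200 ms, RAT
MAT-file structure with fields data/dimord/times/Fs) so that I/O and
windowed estimation are testable without the recordings. Every channel
carries independent unit-variance 1/f background; from 5 ms post-onset the
driver channel (12, "cS1") carries a stochastic narrowband 60 Hz AR(2)
kernel under an exponentially decaying envelope (τ = 15 ms), and channels
10 and 14 receive an attenuated copy delayed by 2 ms. It is synthetic: a
stationary kernel under a deterministic envelope, with none of the evoked
transients, volume conduction, inter-animal variability, or artifacts of
real EEG — passing fixture tests demonstrates the pipeline's mechanics and
directional sensitivity, not performance on real recordings.

## Test scales and what passing shows

The test suite runs scaled-down scenario sweeps (5 replicates per α;
100 realizations for the three-node benchmark; an oracle-equivalence check
at 1000-sample trials, where the 0.8 Hz taper bandwidth no longer smooths
the sharp GGC resonance peak — at 400 samples the 2 Hz bandwidth biases the
peak low by ~17% purely through resolution). Null thresholds derive from
the finite-sample bias scale of averaged spectra, 1/(n_trials·n_tapers) =
1/700 for the defaults: plain-GGC null values concentrate below ~10/700 and
"null" band means in the qualitative assertions use 0.02 (≈5× the empirical
95th percentile under independence).

## Known limitations

- Stationary models only; no time-varying coupling or adaptive estimation.
- Only the difference-based time-reversal variant; no surrogate or
  permutation significance machinery beyond rectification at zero.
- Pairwise/conditional GGC assume an invertible (full-rank) spectrum;
  heavily rank-deficient inputs (e.g., α = 1 common reference on two
  channels) are regularized but not meaningfully interpretable.
- The conditional measure inherits the usual sensitivity of reduced-model
  factorizations to short data; single-realization estimates are noisy and
  are reported with percentile bands for that reason.
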