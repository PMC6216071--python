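# ggcbench

Nonparametric **Granger–Geweke causality** (GGC) with **time-reversal
testing**, plus the MVAR simulation scenarios used to benchmark its
robustness against the observation artifacts that plague directed
connectivity analysis of electrophysiological recordings: shared (non-silent)
reference signals, SNR imbalance between channels, and independent or mixed
additive noise.

It is written for researchers who analyze multichannel trial-based time
series (EEG/LFP-style data, epochs × channels × trials) and want
frequency-resolved directed-influence estimates that do not require fitting
an autoregressive model to the data — together with simulation drivers to
probe when those estimates can and cannot be trusted.

## The method

For a stationary multichannel process with cross-spectral matrix S(f), the
chain is: estimate S(f) by the multitaper method (DPSS tapers, default
NW = 4, averaged over tapers and trials); factorize it with Wilson's
algorithm into a minimum-phase factor, S = ψψ*, yielding the transfer
function H(f) = ψA₀⁻¹ and innovation covariance Σ = A₀A₀ᵀ; then apply
Geweke's spectral measure of the influence of channel *j* on channel *i*,

    f_{j→i}(f) = ln  S_ii(f) / ( S_ii(f) − (Σ_jj − Σ_ij²/Σ_ii) |H_ij(f)|² )

pairwise (per channel pair) or conditionally on all remaining channels (via
full and reduced factorizations). On top of either sits the time-reversal
test: net-GGC_ij = GGC_ij − GGC_ji, and

    tr-GGC_ij = [ net-GGC_ij(original) − net-GGC_ij(time-reversed) ]₊

inferred only where positive. Reversing time preserves every channel's power
spectrum but flips lagged dependence, so reversal-symmetric artifacts cancel
while genuine time-lagged influences survive. See `docs/methods.md` for the
exact conditional formula, numerical choices and conventions.

## Worked example

Two coupled 40 Hz oscillators with a true 1 → 2 influence, observed against
a strong common white-noise reference (α = 0.6) — the classic setting where
plain GGC reports a spurious 2 → 1 influence:

```python
import ggcbench as gb

model = gb.build_two_node_oscillator_model()       # 40 Hz oscillators, 1 -> 2
x = gb.simulate_mvar(model, n_samples=400, n_trials=100, seed=1)

ref = gb.make_reference("white", 400, 100, fs=200.0, seed=2)
x_obs = gb.apply_common_reference(x, ref, alpha_CR=0.6)

ggc = gb.pairwise_ggc(x_obs, NW=4)
tr = gb.tr_ggc(x_obs, NW=4)

band = (ggc.freqs >= 38) & (ggc.freqs <= 42)
print(f"GGC  1->2 (38-42 Hz): {ggc.values[1, 0][band].mean():.3f}")
print(f"GGC  2->1 (38-42 Hz): {ggc.values[0, 1][band].mean():.3f}")
print(f"trGGC 1->2 (38-42 Hz): {tr.values[1, 0][band].mean():.3f}")
print(f"trGGC 2->1 (38-42 Hz): {tr.values[0, 1][band].mean():.3f}")
```

```
GGC  1->2 (38-42 Hz): 1.513
GGC  2->1 (38-42 Hz): 0.137
trGGC 1->2 (38-42 Hz): 2.860
trGGC 2->1 (38-42 Hz): 0.000
```

Plain GGC shows a non-trivial spurious 2 → 1 value (0.137) induced purely by
the shared reference; the time-reversal-tested estimate keeps the true
direction and drives the spurious one to exactly zero in the resonance band.
(`values[i, j]` is receiver-first: the influence *from j to i*.)

## Scenario drivers and CLI

The sweeps behind the benchmark figures are one call each —
`run_common_reference`, `run_additive_noise` (independent or mixed noise,
pairwise or conditional estimation, any coupling pattern and noisy-channel
subset), and `run_stokes_purdon` (the three-node MVAR(3)
conditional-causality demonstration, coefficients shipped as a validated
JSON config) — or one shell command each:

```bash
ggcbench common-reference --ref-type osc20 --repeats 10 --seed 0 --out cr.csv
ggcbench additive-noise --mode MIX --conditional --noise-color white+pink --out mix.csv
ggcbench stokes-purdon --realizations 1000 --out sp.csv
ggcbench sep-synth --trials 65 --seed 0 --out rat_synth.mat
ggcbench estimate --input rat_synth.mat --window 5 50 --time-reversed --out ggc.csv
```

Every command writes a CSV of median and 5th/95th-percentile curves per
edge plus a JSON manifest (full config, seeds, version). `bench_io` reads
and writes the companion dataset's `RAT` MAT-file layout (15-channel
epicranial SEPs, 2000 Hz, −100..+200 ms epochs) and generates a synthetic
SEP-like fixture with a gamma-band driver at channel 12 so the whole chain
is testable without the recordings.

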