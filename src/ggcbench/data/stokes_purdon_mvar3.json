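{
  "description": "Three-node MVAR(3) demonstration network with a 1 -> 2 -> 3 chain, transcribed from the example system of Stokes & Purdon, PNAS 114(34):E7063-E7072 (2017). Node i is an AR(2) resonator with pole radius r and resonance frequency f (lag-1 coefficient 2 r cos(2 pi f / Fs), lag-2 coefficient -r^2); each coupling lists the lag-1..3 cross coefficients from source to target.",
  "sampling_rate": 120.0,
  "n_channels": 3,
  "order": 3,
  "oscillators": [
    {"r": 0.9, "f": 40.0},
    {"r": 0.7, "f": 10.0},
    {"r": 0.8, "f": 50.0}
  ],
  "couplings": [
    {"source": 1, "target": 2, "lags": [-0.356, 0.7136, -0.356]},
    {"source": 2, "target": 3, "lags": [-0.3098, 0.5, -0.3098]}
  ],
  "noise_cov": "identity"
}
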