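"""Observation models that corrupt clean simulated signals.

Three corruption mechanisms commonly encountered in electrophysiology are
implemented, each as an explicit, invertible linear mix so that their
effect on causality estimates can be studied in isolation:

* common reference: every channel of a trial shares one reference series
  R(t), mixed in as ``x' = (1 - a) x - a R``;
* per-channel additive noise / SNR imbalance: selected channels receive
  ``x' = (1 - a) x + a e`` while the others pass through unchanged;
* independent or mixed additive noise: the per-channel noise E is a linear
  mixture ``E = K eta`` of independent white or pink sources, with K the
  identity (independent case) or a random full-rank matrix (mixed case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import TrialsArray

__all__ = [
    "ReferenceSignal",
    "NoiseEnsemble",
    "make_reference",
    "apply_common_reference",
    "make_noise_ensemble",
    "apply_additive_noise",
]


@dataclass
class ReferenceSignal:
    """One shared reference series per trial, shape (time, trial)."""

    data: np.ndarray
    kind: str
    sampling_rate: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("reference data must be (time, trial)")
        if not np.isfinite(self.data).all():
            raise ValueError("reference contains non-finite values")


@dataclass
class NoiseEnsemble:
    """Independent sources eta mixed into per-channel noise E = K eta.

    ``sources`` has shape (time, S, trial); ``mixed`` has shape
    (time, M, trial).
    """

    sources: np.ndarray
    mixing: np.ndarray
    mixed: np.ndarray
    color: str
    meta: dict = field(default_factory=dict)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def make_reference(
    kind: str,
    n_samples: int,
    n_trials: int,
    fs: float,
    r_R: float = 0.8,
    f_R: float = 40.0,
    variance: float = 1.0,
    seed: int = 0,
    burn_in: int = 1000,
) -> ReferenceSignal:
    """Generate a reference series: white noise or an AR(2) oscillation.

    The AR(2) kind uses coefficients ``[2 r_R cos(2 pi f_R / fs), -r_R^2]``
    with unit-variance innovations, giving a resonance near ``f_R``.
    """
    if kind == "white":
        data = np.empty((n_samples, n_trials))
        for t in range(n_trials):
            data[:, t] = _rng(seed, t).standard_normal(n_samples) * np.sqrt(variance)
        params = {"variance": variance}
    elif kind == "ar2":
        if not 0 < r_R < 1:
            raise ValueError("r_R must lie in (0, 1)")
        if not 0 < f_R < fs / 2:
            raise ValueError("f_R must lie in (0, fs/2)")
        a1 = 2 * r_R * np.cos(2 * np.pi * f_R / fs)
        a2 = -(r_R**2)
        total = n_samples + burn_in
        data = np.empty((n_samples, n_trials))
        for t in range(n_trials):
            w = _rng(seed, t).standard_normal(total) * np.sqrt(variance)
            x = np.zeros(total)
            for i in range(total):
                x[i] = w[i]
                if i >= 1:
                    x[i] += a1 * x[i - 1]
                if i >= 2:
                    x[i] += a2 * x[i - 2]
            data[:, t] = x[burn_in:]
        params = {"r_R": r_R, "f_R": f_R, "variance": variance}
    else:
        raise ValueError(f"unknown reference kind {kind!r}; use 'white' or 'ar2'")
    return ReferenceSignal(data=data, kind=kind, sampling_rate=fs, params=params)


def apply_common_reference(
    X: TrialsArray, R: ReferenceSignal, alpha_CR: float
) -> TrialsArray:
    """Mix a shared reference into every channel: x' = (1 - a) x - a R.

    The same reference series is subtracted from all channels of a trial,
    so the ratio a / (1 - a) controls how much of the observed signal is
    reference rather than unipolar activity.
    """
    if not 0 <= alpha_CR <= 1:
        raise ValueError("alpha_CR must lie in [0, 1]")
    if R.data.shape != (X.n_samples, X.n_trials):
        raise ValueError("reference and data disagree in time length or trial count")
    if R.sampling_rate != X.sampling_rate:
        raise ValueError("reference and data disagree in sampling rate")
    out = (1 - alpha_CR) * X.data - alpha_CR * R.data[:, None, :]
    return TrialsArray(
        data=out,
        sampling_rate=X.sampling_rate,
        times=None if X.times is None else X.times.copy(),
        time_unit=X.time_unit,
        meta={**X.meta, "alpha_CR": alpha_CR, "reference": R.kind},
    )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping of white noise.

    The discrete spectrum of a white draw is scaled by f^(-1/2) (DC set to
    zero), giving an exact 1/f power-law target before the inverse
    transform.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def make_noise_ensemble(
    n_channels: int,
    S_count: int,
    color: str = "white",
    K_mode: str = "identity",
    K: np.ndarray | None = None,
    n_samples: int = 400,
    n_trials: int = 100,
    seed: int = 0,
) -> NoiseEnsemble:
    """Build S independent noise sources and mix them into M channels.

    ``color`` selects the source spectra: "white", "pink", or "white+pink"
    (odd-indexed sources white, even-indexed pink, counting from 1).
    ``K_mode`` selects the mixing matrix: "identity" (independent noise;
    requires S = M), "random_full_rank" (standard-normal entries redrawn
    until full rank, rows scaled to unit norm), or "given".
    """
    if K_mode == "identity":
        if S_count != n_channels:
            raise ValueError("identity mixing requires S_count == n_channels")
        k = np.eye(n_channels)
    elif K_mode == "random_full_rank":
        rng_k = _rng(seed, 2**16)
        for _ in range(100):
            k = rng_k.standard_normal((n_channels, S_count))
            sv = np.linalg.svd(k, compute_uv=False)
            if sv[-1] > 1e-10 * sv[0]:
                break
        else:  # pragma: no cover - essentially impossible
            raise RuntimeError("could not draw a full-rank mixing matrix")
        k = k / np.linalg.norm(k, axis=1, keepdims=True)
    elif K_mode == "given":
        if K is None:
            raise ValueError("K_mode='given' requires K")
        k = np.asarray(K, dtype=float)
        if k.shape != (n_channels, S_count):
            raise ValueError("K must have shape (n_channels, S_count)")
        sv = np.linalg.svd(k, compute_uv=False)
        if min(k.shape) == k.shape[0] and sv[-1] <= 1e-10 * sv[0]:
            raise ValueError("given K is rank deficient")
    else:
        raise ValueError(f"unknown K_mode {K_mode!r}")

    if color not in ("white", "pink", "white+pink"):
        raise ValueError(f"unknown noise color {color!r}")
    sources = np.empty((n_samples, S_count, n_trials))
    for t in range(n_trials):
        for s in range(S_count):
            rng = _rng(seed, t, s)
            if color == "white" or (color == "white+pink" and s % 2 == 0):
                sources[:, s, t] = rng.standard_normal(n_samples)
            else:
                sources[:, s, t] = _pink_noise(rng, n_samples)
    mixed = np.einsum("ms,tsr->tmr", k, sources)
    return NoiseEnsemble(
        sources=sources,
        mixing=k,
        mixed=mixed,
        color=color,
        meta={
            "K_mode": K_mode,
            "seed": seed,
            "channel_variance": mixed.var(axis=(0, 2)).tolist(),
        },
    )


def apply_additive_noise(
    X: TrialsArray,
    E: NoiseEnsemble,
    alpha_N: float,
    channels: list[int] | None = None,
) -> TrialsArray:
    """Add observation noise to selected channels: x' = (1 - a) x + a e.

    ``channels`` are 1-based indices; unselected channels are copied
    unchanged, which is how an SNR imbalance between channels is created.
    """
    if not 0 <= alpha_N <= 1:
        raise ValueError("alpha_N must lie in [0, 1]")
    m = X.n_channels
    if channels is None:
        channels = list(range(1, m + 1))
    if len(channels) == 0:
        raise ValueError("channels must be a non-empty subset")
    if any(not 1 <= c <= m for c in channels):
        raise ValueError(f"channels must lie in 1..{m}")
    if E.mixed.shape[0] != X.n_samples or E.mixed.shape[2] != X.n_trials:
        raise ValueError("noise ensemble and data disagree in shape")
    if E.mixed.shape[1] != m:
        raise ValueError("noise ensemble has the wrong channel count")
    out = X.data.copy()
    idx = np.asarray(sorted(set(channels))) - 1
    out[:, idx, :] = (1 - alpha_N) * X.data[:, idx, :] + alpha_N * E.mixed[:, idx, :]
    return TrialsArray(
        data=out,
        sampling_rate=X.sampling_rate,
        times=None if X.times is None else X.times.copy(),
        time_unit=X.time_unit,
        meta={**X.meta, "alpha_N": alpha_N, "noisy_channels": sorted(set(channels))},
    )
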