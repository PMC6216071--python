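"""Stable MVAR models: construction, simulation, and analytic spectra.

The package simulates directed brain-network activity with multivariate
autoregressive (MVAR) processes

    x(t) = sum_k A_k x(t - k) + w(t),    k = 1..p,

where ``w`` is a zero-mean white innovation process with covariance
``Sigma_w``.  Two builders cover the canonical benchmark networks used by
the simulation scenarios: a two-node coupled-oscillator network and an
arbitrary-size network with fixed self- and cross-coefficients used in the
SNR-imbalance and additive-noise experiments.  ``analytic_spectral_matrix``
provides the exact cross-spectral density of any stable model and serves as
the parametric oracle for the nonparametric estimation chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MVARModel",
    "TrialsArray",
    "build_two_node_oscillator_model",
    "build_snr_network_model",
    "simulate_mvar",
    "analytic_spectral_matrix",
]


class StabilityError(ValueError):
    """Raised when an MVAR parameterization is not stable."""


def _companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of the lag-coefficient stack (p, M, M)."""
    p, m, _ = coeffs.shape
    comp = np.zeros((p * m, p * m))
    comp[:m, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[m:, :-m] = np.eye((p - 1) * m)
    return comp


@dataclass(frozen=True)
class MVARModel:
    """A stable MVAR(p) process with Gaussian innovations.

    Parameters
    ----------
    coeffs
        Lag-coefficient stack of shape ``(p, M, M)``; ``coeffs[k-1]`` is
        ``A_k`` in ``x(t) = sum_k A_k x(t-k) + w(t)``.
    noise_cov
        Innovation covariance ``Sigma_w`` (M x M, symmetric positive
        definite).
    sampling_rate
        Sampling rate in Hz.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, M, M)")
        ncov = np.asarray(self.noise_cov, dtype=float)
        m = coeffs.shape[1]
        if ncov.shape != (m, m):
            raise ValueError("noise_cov must be M x M")
        if not np.isfinite(coeffs).all() or not np.isfinite(ncov).all():
            raise ValueError("model parameters must be finite")
        if not np.allclose(ncov, ncov.T):
            raise ValueError("noise_cov must be symmetric")
        try:
            np.linalg.cholesky(ncov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("noise_cov must be positive definite") from exc
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        rho = self.companion_spectral_radius()
        if coeffs.shape[0] > 0 and rho >= 1.0:
            raise StabilityError(
                f"unstable MVAR model: companion spectral radius {rho:.6f} >= 1"
            )
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_cov", ncov)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def companion_spectral_radius(self) -> float:
        if self.order == 0:
            return 0.0
        comp = _companion_matrix(np.asarray(self.coeffs, dtype=float))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "order": self.order,
            "coeffs": np.asarray(self.coeffs).ravel().tolist(),
            "noise_cov": np.asarray(self.noise_cov).ravel().tolist(),
            "sampling_rate": float(self.sampling_rate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MVARModel":
        m = int(d["n_channels"])
        p = int(d["order"])
        coeffs = np.asarray(d["coeffs"], dtype=float).reshape(p, m, m)
        ncov = np.asarray(d["noise_cov"], dtype=float).reshape(m, m)
        return cls(coeffs=coeffs, noise_cov=ncov, sampling_rate=float(d["sampling_rate"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MVARModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TrialsArray:
    """Trial-based multichannel signals, shape (time, channel, trial)."""

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray | None = None
    time_unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (time, channel, trial)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.data.shape[0],):
                raise ValueError("times length must match the time dimension")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def build_two_node_oscillator_model(
    r1: float = 0.8,
    r2: float = 0.8,
    f1: float = 40.0,
    f2: float = 40.0,
    fs: float = 200.0,
    coupling: tuple[float, float] = (-0.35, 0.7),
    noise_cov: np.ndarray | None = None,
) -> MVARModel:
    """Two coupled AR(2) oscillators with a unidirectional 1 -> 2 influence.

    Each node is an AR(2) resonator with pole radius ``r_i`` and resonance
    frequency ``f_i`` (diagonal coefficients ``2 r_i cos(2 pi f_i / fs)`` at
    lag 1 and ``-r_i**2`` at lag 2).  Node 2 additionally receives node 1
    through the two ``coupling`` lag coefficients.  This is the generative
    network for the common-reference experiments.
    """
    for r, f in ((r1, f1), (r2, f2)):
        if not 0 < r < 1:
            raise ValueError("pole radius must lie in (0, 1)")
        if not 0 < f < fs / 2:
            raise ValueError("resonance frequency must lie in (0, fs/2)")
    th1 = 2 * np.pi * f1 / fs
    th2 = 2 * np.pi * f2 / fs
    a1 = np.array([[2 * r1 * np.cos(th1), 0.0], [coupling[0], 2 * r2 * np.cos(th2)]])
    a2 = np.array([[-r1**2, 0.0], [coupling[1], -r2**2]])
    ncov = np.eye(2) if noise_cov is None else np.asarray(noise_cov, dtype=float)
    return MVARModel(coeffs=np.stack([a1, a2]), noise_cov=ncov, sampling_rate=fs)


def build_snr_network_model(
    n_channels: int,
    interactions: list[tuple[int, int]],
    fs: float = 200.0,
) -> MVARModel:
    """Network of identical AR(2) nodes with optional directed couplings.

    Every node carries self coefficients ``[0.5, -0.8]``; each
    ``(source, target)`` pair in ``interactions`` (1-based channel indices)
    adds cross coefficients ``[0.2, -0.1]`` from source to target at lags 1
    and 2.  Each target may receive at most one source.  This is the
    generative network for the SNR-imbalance and additive-noise experiments.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    a1 = np.eye(n_channels) * 0.5
    a2 = np.eye(n_channels) * -0.8
    seen_targets: set[int] = set()
    for src, tgt in interactions:
        if not (1 <= src <= n_channels and 1 <= tgt <= n_channels):
            raise IndexError(f"interaction ({src}, {tgt}) outside 1..{n_channels}")
        if src == tgt:
            raise ValueError("self-interactions are not allowed")
        if tgt in seen_targets:
            raise ValueError(f"target {tgt} receives more than one source")
        seen_targets.add(tgt)
        a1[tgt - 1, src - 1] = 0.2
        a2[tgt - 1, src - 1] = -0.1
    return MVARModel(
        coeffs=np.stack([a1, a2]), noise_cov=np.eye(n_channels), sampling_rate=fs
    )


def _trial_rng(seed: int, trial: int) -> np.random.Generator:
    # Counter-based substream: trial k's stream does not depend on n_trials.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(trial,)))


def simulate_mvar(
    model: MVARModel,
    n_samples: int,
    n_trials: int,
    seed: int,
    burn_in: int = 1000,
) -> TrialsArray:
    """Simulate independent trials of a stable MVAR model.

    Innovations are Gaussian with covariance ``Sigma_w``; each trial starts
    from zero initial conditions and the first ``burn_in`` samples are
    discarded to erase the transient.  Trials use independent counter-based
    substreams of ``seed`` so that results for trial ``k`` do not change
    when ``n_trials`` changes.
    """
    if n_samples < max(model.order, 1):
        raise ValueError("n_samples must be at least the model order")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    rho = model.companion_spectral_radius()
    if model.order > 0 and rho >= 1.0:
        raise StabilityError("refusing to simulate an unstable model")
    m, p = model.n_channels, model.order
    total = n_samples + burn_in
    chol = np.linalg.cholesky(model.noise_cov)
    # Draw innovations per trial (independent substreams), then run the
    # recursion vectorized across trials.
    w = np.empty((total, m, n_trials))
    for t in range(n_trials):
        z = _trial_rng(seed, t).standard_normal((total, m))
        w[:, :, t] = z @ chol.T
    x = np.zeros((total, m, n_trials))
    coeffs = np.asarray(model.coeffs)
    for t in range(total):
        acc = w[t]
        for k in range(1, min(p, t) + 1):
            acc = acc + coeffs[k - 1] @ x[t - k]
        x[t] = acc
    return TrialsArray(
        data=x[burn_in:],
        sampling_rate=model.sampling_rate,
        meta={"seed": seed, "burn_in": burn_in},
    )


def analytic_spectral_matrix(model: MVARModel, freqs: np.ndarray):
    """Exact one-sided cross-spectral density of a stable MVAR model.

    Evaluates ``H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1}`` and
    ``S(f) = H Sigma_w H* / fs`` on the requested grid, doubled at interior
    frequencies so the one-sided density integrates to the process variance
    over [0, fs/2].  Shares its PSD convention with ``multitaper_csd`` so
    the two are directly comparable.
    """
    from .spectral import SpectralMatrix  # local import to avoid a cycle

    freqs = np.asarray(freqs, dtype=float)
    fs = model.sampling_rate
    if freqs.min() < 0 or freqs.max() > fs / 2 + 1e-9:
        raise ValueError("freqs must lie in [0, fs/2]")
    m, p = model.n_channels, model.order
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)  # (F, p)
    a = np.broadcast_to(np.eye(m), (len(freqs), m, m)).astype(complex).copy()
    for k in range(p):
        a -= z[:, k, None, None] * model.coeffs[k]
    cond = np.linalg.cond(a)
    if np.any(~np.isfinite(cond)) or np.any(cond > 1e12):
        raise np.linalg.LinAlgError(
            "spectral matrix singular at some frequency (model not stable?)"
        )
    h = np.linalg.inv(a)
    s = h @ model.noise_cov @ h.conj().transpose(0, 2, 1) / fs
    scale = np.where((freqs > 0) & (freqs < fs / 2), 2.0, 1.0)
    s = s * scale[:, None, None]
    return SpectralMatrix(
        freqs=freqs,
        S=s,
        sampling_rate=fs,
        meta={"source": "analytic", "order": p},
    )
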