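"""Multitaper cross-spectral density estimation over trials.

The nonparametric causality chain starts from a direct estimate of the
cross-spectral density matrix S(f).  Spectra are estimated with the
multitaper method: each trial is demeaned per channel, multiplied by the
discrete prolate spheroidal (DPSS) tapers for a chosen time-bandwidth
product NW, Fourier transformed, and the outer products are averaged over
tapers and trials.

PSD convention (used identically by ``analytic_spectral_matrix``):
one-sided density in units^2/Hz on the grid 0..Nyquist with step
``fs / n_samples`` (no zero padding); interior bins carry twice the
two-sided density while DC and Nyquist carry it once, so the integral over
[0, fs/2] equals the process variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .mvar import TrialsArray

__all__ = ["SpectralMatrix", "multitaper_csd"]


@dataclass
class SpectralMatrix:
    """Frequency-indexed Hermitian cross-spectral density matrices.

    ``S`` has shape ``(n_freqs, M, M)`` with the one-sided PSD convention
    described in the module docstring.
    """

    freqs: np.ndarray
    S: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.S = np.asarray(self.S, dtype=complex)
        if self.S.ndim != 3 or self.S.shape[1] != self.S.shape[2]:
            raise ValueError("S must have shape (n_freqs, M, M)")
        if self.S.shape[0] != self.freqs.shape[0]:
            raise ValueError("freqs length must match S")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]

    def validate(self, eps_scale: float = 1e-10) -> None:
        """Check Hermitian symmetry and numerical positive semidefiniteness."""
        herm_err = np.max(np.abs(self.S - self.S.conj().transpose(0, 2, 1)))
        scale = np.max(np.abs(self.S))
        if herm_err > 1e-8 * max(scale, 1e-300):
            raise ValueError("spectral matrix is not Hermitian")
        diag = np.diagonal(self.S, axis1=1, axis2=2)
        if np.any(diag.real < -eps_scale * max(scale, 1e-300)) or np.any(
            np.abs(diag.imag) > 1e-8 * max(scale, 1e-300)
        ):
            raise ValueError("diagonal PSDs must be real and non-negative")
        eig = np.linalg.eigvalsh(self.S)
        tr = np.trace(self.S, axis1=1, axis2=2).real
        if np.any(eig < -eps_scale * tr[:, None]):
            raise ValueError("spectral matrix has significantly negative eigenvalues")

    def subset(self, channels) -> "SpectralMatrix":
        """Cross-spectrum restricted to a subset of channel indices (0-based)."""
        idx = np.asarray(channels, dtype=int)
        return SpectralMatrix(
            freqs=self.freqs,
            S=self.S[:, idx][:, :, idx],
            sampling_rate=self.sampling_rate,
            meta=dict(self.meta),
        )

    def two_sided(self) -> tuple[np.ndarray, np.ndarray]:
        """Full circular-grid spectrum in DTFT scale, for factorization.

        Returns ``(n, P)`` where ``P[k]`` is the two-sided spectrum times
        ``fs`` at frequency ``k * fs / n`` for ``k = 0..n-1``; with this
        scale ``mean_k P[k]`` equals the process covariance, which is the
        normalization Wilson's iteration expects.
        """
        df = self.freqs[1] - self.freqs[0]
        if not np.allclose(np.diff(self.freqs), df, rtol=1e-6):
            raise ValueError("factorization requires a uniform frequency grid")
        if abs(self.freqs[0]) > 1e-9 * df:
            raise ValueError("frequency grid must start at 0")
        n = int(round(self.sampling_rate / df))
        nyq = self.sampling_rate / 2
        has_nyquist = n % 2 == 0
        expected = n // 2 + 1 if has_nyquist else (n + 1) // 2
        if len(self.freqs) != expected:
            raise ValueError("frequency grid does not span 0..Nyquist for its step")
        # back to two-sided density, then to DTFT scale
        interior = (self.freqs > 0) & (self.freqs < nyq)
        s2 = self.S.copy()
        s2[interior] *= 0.5
        p_half = s2 * self.sampling_rate
        m = self.n_channels
        full = np.empty((n, m, m), dtype=complex)
        full[: len(self.freqs)] = p_half
        # negative frequencies: S(-f) = conj(S(f)) = S(f)^T for a real process
        tail = np.arange(len(self.freqs), n)
        full[tail] = p_half[n - tail].conj()
        return n, full

    def to_csv(self, path) -> None:
        """Long-format export: frequency, i, j, re, im."""
        m = self.n_channels
        ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        rows = {
            "frequency": np.repeat(self.freqs, m * m),
            "i": np.tile(ii.ravel(), len(self.freqs)),
            "j": np.tile(jj.ravel(), len(self.freqs)),
            "re": self.S.real.reshape(-1),
            "im": self.S.imag.reshape(-1),
        }
        pd.DataFrame(rows).to_csv(path, index=False)


def multitaper_csd(
    X: TrialsArray,
    NW: float = 4.0,
    n_tapers: int | None = None,
) -> SpectralMatrix:
    """Trial- and taper-averaged multitaper cross-spectral density.

    Parameters
    ----------
    X
        Trial-based signals, shape (time, channel, trial).
    NW
        Time-bandwidth product of the DPSS taper family.
    n_tapers
        Number of tapers; defaults to ``2 * NW - 1``.
    """
    data = X.data
    if np.isnan(data).any():
        raise ValueError("input contains NaN")
    n, m, n_trials = data.shape
    if n_trials < 1:
        raise ValueError("at least one trial is required")
    if NW < 1:
        raise ValueError("NW must be >= 1")
    if n_tapers is None:
        n_tapers = int(2 * NW - 1)
    if n <= 2 * NW or n_tapers >= n:
        raise ValueError("too few samples for the requested taper family")
    tapers = dpss(n, NW, Kmax=n_tapers)  # (K, n), unit energy each
    demeaned = data - data.mean(axis=0, keepdims=True)
    n_freqs = n // 2 + 1
    fs = X.sampling_rate
    acc = np.zeros((n_freqs, m, m), dtype=complex)
    for k in range(n_tapers):
        spec = np.fft.rfft(tapers[k][:, None, None] * demeaned, axis=0)
        # average over trials of the channel outer products, per frequency
        acc += np.einsum("fit,fjt->fij", spec, spec.conj()) / n_trials
    acc /= n_tapers
    s2 = acc / fs  # two-sided density
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.where((freqs > 0) & (freqs < fs / 2), 2.0, 1.0)
    s1 = s2 * scale[:, None, None]
    # enforce exact Hermitian symmetry against rounding
    s1 = 0.5 * (s1 + s1.conj().transpose(0, 2, 1))
    return SpectralMatrix(
        freqs=freqs,
        S=s1,
        sampling_rate=fs,
        meta={
            "NW": NW,
            "n_tapers": n_tapers,
            "n_trials": n_trials,
            "n_samples": n,
            "Fs": fs,
        },
    )
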