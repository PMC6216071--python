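"""Wilson's iterative spectral matrix factorization.

Decomposes a Hermitian positive-definite spectral density matrix S(f) into
a minimum-phase causal factor psi with S = psi psi*, from which the
transfer function H(f) = psi A0^{-1} and the innovation covariance
Sigma = A0 A0^T follow (A0 is the zero-lag coefficient of psi).  These are
exactly the quantities a parametric MVAR fit would supply, obtained here
without fitting a model — the key step that makes Granger-Geweke causality
nonparametric.

The iteration is Wilson's Newton scheme on the full (two-sided) frequency
grid:

    psi_{k+1} = psi_k [psi_k^{-1} S psi_k^{-*} + I]_+

where []_+ keeps the causal part of the lag expansion (half weight and
upper-triangular normalization at lag zero, negative lags zeroed).
Convergence is quadratic; the stopping rule is the maximum over frequency
of the relative Frobenius change of psi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import SpectralMatrix

__all__ = ["SpectralFactorization", "wilson_factorize", "FactorizationWarning"]


class FactorizationWarning(UserWarning):
    pass


@dataclass
class SpectralFactorization:
    """Minimum-phase factorization of a cross-spectral density.

    Attributes
    ----------
    psi
        Causal minimum-phase factor, shape (n_freqs, M, M), on the
        one-sided grid of the input, in DTFT scale (``psi psi* = fs *``
        two-sided density).
    H
        Transfer function ``psi A0^{-1}``, same shape.
    Sigma
        Innovation covariance ``A0 A0^T`` (M x M, real).
    residual
        Max over frequency of the relative Frobenius error
        ``||S - psi psi*|| / ||S||``.
    """

    freqs: np.ndarray
    psi: np.ndarray
    H: np.ndarray
    Sigma: np.ndarray
    residual: float
    iterations: int
    converged: bool
    meta: dict = field(default_factory=dict)


def _causal_part(g: np.ndarray, n_keep: int) -> np.ndarray:
    """[]_+ operator: retain non-negative lags of the circular lag expansion.

    Lag 0 takes half weight and its upper-triangular part, which pins the
    normalization of the factor (A0 upper triangular with positive
    diagonal); lags beyond ``n_keep`` (the acausal half) are zeroed.  For
    an even-length grid the shared bin at lag n/2 aliases the +n/2 and
    -n/2 contributions together, so only half of it belongs to the causal
    part — keeping it whole makes the iteration cycle instead of converge.
    """
    n = g.shape[0]
    lags = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * lags[0]
    lags[0] = np.triu(beta0)
    if n % 2 == 0 and n_keep == n // 2:
        lags[n_keep] *= 0.5
    lags[n_keep + 1 :] = 0.0
    return np.fft.fft(lags, axis=0)


def wilson_factorize(
    S: SpectralMatrix,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> SpectralFactorization:
    """Factorize a spectral matrix into its minimum-phase factor.

    Nearly singular inputs (finite-sample spectra can have a zero
    eigenvalue at DC after demeaning) are regularized by adding
    ``1e-10 * mean(diag) * I`` when the smallest eigenvalue at any
    frequency is non-positive.
    """
    n, full = S.two_sided()
    m = S.n_channels
    n_half = len(S.freqs)

    eig = np.linalg.eigvalsh(full)
    if eig.min() <= 0:
        delta = 1e-10 * float(np.mean(np.diagonal(full, axis1=1, axis2=2).real))
        if delta <= 0:
            raise ValueError("spectral matrix is not positive definite")
        full = full + delta * np.eye(m)
        eig = np.linalg.eigvalsh(full)
        if eig.min() <= 0:
            raise ValueError(
                "spectral matrix not positive definite after regularization"
            )

    # init: constant Cholesky factor of the integrated spectrum (lag-0 cov)
    gamma0 = np.fft.ifft(full, axis=0)[0].real
    gamma0 = 0.5 * (gamma0 + gamma0.T)
    try:
        chol = np.linalg.cholesky(gamma0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("integrated spectrum is not positive definite") from exc
    psi = np.broadcast_to(chol.T.astype(complex), full.shape).copy()  # upper-tri A0

    def _residual(p: np.ndarray) -> float:
        num = np.linalg.norm(full - p @ p.conj().transpose(0, 2, 1), axis=(1, 2))
        den = np.linalg.norm(full, axis=(1, 2))
        return float(np.max(num / np.maximum(den, 1e-300)))

    eye = np.eye(m)
    converged = False
    it = 0
    residual = _residual(psi)
    for it in range(1, max_iter + 1):
        # g = psi^-1 S psi^-* + I, per frequency
        psi_inv_s = np.linalg.solve(psi, full)
        g = np.linalg.solve(psi, psi_inv_s.conj().transpose(0, 2, 1)).conj().transpose(
            0, 2, 1
        )
        g = g + eye
        gp = _causal_part(g, n // 2)
        psi_new = psi @ gp
        num = np.linalg.norm(psi_new - psi, axis=(1, 2))
        den = np.linalg.norm(psi, axis=(1, 2))
        change = float(np.max(num / np.maximum(den, 1e-300)))
        psi = psi_new
        if change < tol:
            # the change criterion alone can leave the reconstruction error
            # marginally above tol; require both before declaring success
            residual = _residual(psi)
            if residual < tol:
                converged = True
                break

    if not converged:
        residual = _residual(psi)
        warnings.warn(
            f"Wilson factorization did not converge in {it} iterations "
            f"(residual {residual:.3e})",
            FactorizationWarning,
            stacklevel=2,
        )

    a0 = np.fft.ifft(psi, axis=0)[0].real
    sigma = a0 @ a0.T
    sigma = 0.5 * (sigma + sigma.T)
    h = psi[:n_half] @ np.linalg.inv(a0)
    return SpectralFactorization(
        freqs=S.freqs,
        psi=psi[:n_half],
        H=h,
        Sigma=sigma,
        residual=residual,
        iterations=it,
        converged=converged,
        meta={"tol": tol, "max_iter": max_iter, "n_fft": n},
    )
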