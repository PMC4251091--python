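"""Centering, whitening, and the augmented matrices of the constrained model.

Whitening maps the centred data X - mean onto k decorrelated unit-variance
coordinates X_tilde = Dw (X - mean 1^T). Working in whitened coordinates, a
unit vector b yields a calculated curve b^T X_tilde whose relation to the
raw-domain signal b^T Dw X differs only by an offset (the centring shift);
appending a constant row to X_tilde lets that offset ride along as one extra
weight d instead of a separate variable: with b_bar = [b; d],

    b_bar^T [X_tilde; 1] = b^T X_tilde + d,
    b_bar^T [X_tilde; 0] = b^T X_tilde        (the zeros row kills d),

so the non-Gaussianity contrast sees only b while the reference-distance
term sees the offset-corrected curve.

Covariance is normalised by 1/t (population form): expectations over the
time axis are taken as plain sample means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Chromatogram3D

__all__ = ["WhitenedData", "AugmentedWeight", "center_whiten", "raw_output"]


@dataclass
class WhitenedData:
    """Whitened chromatogram and the pieces needed to map back to raw units."""

    X_tilde: np.ndarray        # k x t, rows zero-mean, covariance I_k
    Dw: np.ndarray             # k x m whitening matrix
    mean_vec: np.ndarray       # per-wavelength mean, length m
    X_tilde_prime: np.ndarray  # (k+1) x t, X_tilde with an all-zeros row appended
    X_tilde_dprime: np.ndarray # (k+1) x t, X_tilde with an all-ones row appended
    k: int

    @property
    def t(self) -> int:
        return self.X_tilde.shape[1]


@dataclass
class AugmentedWeight:
    """An augmented unmixing weight b_bar = [b; d] with unit-norm b.

    ``scale`` calibrates the curve amplitude to the raw/reference domain;
    it defaults to 1 so that plain b^T X_tilde + d is recovered.
    """

    b: np.ndarray
    d: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        nrm = np.linalg.norm(self.b)
        if abs(nrm - 1.0) > 1e-8:
            raise ValueError(f"b must be unit-norm, got ||b|| = {nrm}")


def center_whiten(X: Chromatogram3D | np.ndarray, variance_tol: float = 1e-10) -> WhitenedData:
    """Centre and whiten X, retaining components by relative eigenvalue.

    Eigen-decomposes the 1/t-normalised sample covariance of X and keeps the
    k components whose eigenvalue exceeds ``variance_tol`` times the largest
    one — all numerically nonzero directions, so no small compound is
    discarded by an eigenvalue cutoff. Raises ``ValueError`` on constant
    input (zero variance).
    """
    A = X.absorbance if isinstance(X, Chromatogram3D) else np.asarray(X, dtype=float)
    m, t = A.shape
    if m < 2 or t < 2:
        raise ValueError("need at least 2 wavelengths and 2 time points")
    mean_vec = A.mean(axis=1)
    Xc = A - mean_vec[:, None]
    cov = (Xc @ Xc.T) / t
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise ValueError("constant input: covariance has no positive eigenvalue")
    keep = evals > variance_tol * evals[-1]
    evals, evecs = evals[keep][::-1], evecs[:, keep][:, ::-1]  # descending
    Dw = evecs.T / np.sqrt(evals)[:, None]
    X_tilde = Dw @ Xc
    k = X_tilde.shape[0]
    ones = np.ones((1, t))
    return WhitenedData(
        X_tilde=X_tilde,
        Dw=Dw,
        mean_vec=mean_vec,
        X_tilde_prime=np.vstack([X_tilde, np.zeros((1, t))]),
        X_tilde_dprime=np.vstack([X_tilde, ones]),
        k=k,
    )


def raw_output(W: WhitenedData, w: AugmentedWeight) -> np.ndarray:
    """The raw-domain calculated curve y = scale * (b^T X_tilde) + d * 1."""
    if w.b.shape != (W.k,):
        raise ValueError(f"b has shape {w.b.shape}, expected ({W.k},)")
    return w.scale * (w.b @ W.X_tilde) + w.d
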