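"""Synthetic HPLC-DAD data with known bilinear ground truth.

The generator builds X = A S (+ optional i.i.d. Gaussian detector noise):
rows of S are unit-maximum Gaussian elution peaks with integer (mu, sigma),
columns of A are smooth positive spectra composed of 2-3 seeded Gaussian
bands over the wavelength axis, scaled to unit maximum. Any full-column-rank
positive spectra suffice for separability as long as there are more
wavelength channels than compounds; the generator additionally rejects
seeds giving pairwise column correlations >= 0.95 or ill-conditioned A so
the synthetic mixtures are unambiguous.

``five_compound_fixture`` is the standard benchmark mixture used throughout
the tests: five overlapping peaks at (50,21), (75,12), (90,10), (155,17),
(175,9) on a 241-point time axis with 101 wavelength channels, noiseless by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Chromatogram3D
from .reference import ReferenceParams, gaussian_reference

__all__ = [
    "SimulationSpec",
    "FIVE_COMPOUND_THETAS",
    "five_compound_fixture",
    "make_peaks",
    "make_spectra",
    "make_dataset",
]

FIVE_COMPOUND_THETAS = (
    ReferenceParams(50, 21),
    ReferenceParams(75, 12),
    ReferenceParams(90, 10),
    ReferenceParams(155, 17),
    ReferenceParams(175, 9),
)


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic chromatogram."""

    t: int = 241
    m: int = 101
    thetas: tuple[ReferenceParams, ...] = FIVE_COMPOUND_THETAS
    noise_sd: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        self.thetas = tuple(
            th if isinstance(th, ReferenceParams) else ReferenceParams(*th)
            for th in self.thetas
        )
        if len(set(self.thetas)) != len(self.thetas):
            raise ValueError("thetas must be pairwise distinct")
        for th in self.thetas:
            th.validate(self.t)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.m < len(self.thetas) + 1:
            raise ValueError("need more wavelength channels than compounds")

    @property
    def n(self) -> int:
        return len(self.thetas)


def five_compound_fixture(noise_sd: float = 0.0, seed: int = 7) -> SimulationSpec:
    """The five-compound benchmark mixture (noiseless by default)."""
    return SimulationSpec(noise_sd=noise_sd, seed=seed)


def make_peaks(spec: SimulationSpec) -> np.ndarray:
    """Elution-peak matrix S (n x t): one unit-maximum Gaussian per row."""
    return np.vstack(
        [gaussian_reference(th, spec.t).values for th in spec.thetas]
    )


def make_spectra(spec: SimulationSpec, max_retries: int = 100) -> np.ndarray:
    """Spectra matrix A (m x n): smooth positive unit-max columns, full rank.

    Each column is a sum of 2-3 Gaussian absorbance bands with seeded
    centres/widths/heights plus a small baseline. Seeds whose columns are
    nearly collinear (pairwise correlation >= 0.95) or rank-deficient are
    re-drawn, up to ``max_retries`` times.
    """
    wl = np.arange(spec.m, dtype=float)
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_retries):
        A = np.empty((spec.m, spec.n))
        for j in range(spec.n):
            n_bands = rng.integers(2, 4)
            centers = rng.uniform(0.05 * spec.m, 0.95 * spec.m, size=n_bands)
            widths = rng.uniform(0.04 * spec.m, 0.15 * spec.m, size=n_bands)
            heights = rng.uniform(0.3, 1.0, size=n_bands)
            col = sum(
                h * np.exp(-((wl - c) ** 2) / (2 * w**2))
                for c, w, h in zip(centers, widths, heights)
            ) + 0.02
            A[:, j] = col / col.max()
        if np.linalg.matrix_rank(A) < spec.n:
            continue
        corr = np.corrcoef(A.T)
        off = corr[~np.eye(spec.n, dtype=bool)] if spec.n > 1 else np.array([0.0])
        if np.abs(off).max() < 0.95:
            return A
    raise RuntimeError(
        f"could not generate well-separated spectra in {max_retries} tries "
        f"(seed={spec.seed})"
    )


def make_dataset(spec: SimulationSpec) -> tuple[Chromatogram3D, np.ndarray, np.ndarray]:
    """Generate (X, A, S) with X = A S + noise_sd * N(0,1), seeded.

    At ``noise_sd=0`` the product is exact: X == A S to the last bit.
    """
    S = make_peaks(spec)
    A = make_spectra(spec)
    X = A @ S
    if spec.noise_sd > 0:
        # Independent stream so the spectra draw is unaffected by noise_sd.
        noise_rng = np.random.default_rng((spec.seed, 1))
        X = X + spec.noise_sd * noise_rng.standard_normal(X.shape)
    return Chromatogram3D(absorbance=X), A, S
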