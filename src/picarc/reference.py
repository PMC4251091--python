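"""Gaussian reference-curve family and the admissible (mu, sigma) domain.

A chromatogram peak is modelled as a unit-maximum Gaussian on the integer
elution-time axis 1..t,

    r(x; mu, sigma) = exp(-(x - mu)^2 / (2 sigma^2)),

with the usual 1/(sqrt(2 pi) sigma) factor dropped so the peak maximum is
exactly 1 — amplitude is carried by the spectra, not the elution profile.
The peak centre mu ranges over the whole time axis, and sigma is bounded by
requiring that the central 99.73% of the Gaussian mass (mu +/- 3 sigma) fit
inside the time window: sigma < t / 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log2

import numpy as np

__all__ = [
    "ReferenceParams",
    "ReferenceCurve",
    "sigma_upper_bound",
    "sigma_max",
    "gaussian_reference",
    "parameter_grid",
]


@dataclass(frozen=True, order=True)
class ReferenceParams:
    """A candidate peak parameterisation theta = (mu, sigma), both integers.

    ``mu`` is the peak centre on the 1-based time axis; ``sigma`` the peak
    width. Ordering is lexicographic (mu, then sigma), which is the tie-break
    order used throughout the genetic search.
    """

    mu: int
    sigma: int

    def validate(self, t: int) -> None:
        """Raise ``ValueError`` unless (mu, sigma) lies in the admissible domain for t."""
        smax = sigma_max(t)
        if not (1 <= self.mu <= t):
            raise ValueError(f"mu={self.mu} outside 1..{t}")
        if not (1 <= self.sigma <= smax):
            raise ValueError(
                f"sigma={self.sigma} outside admissible range 1..{smax} for t={t}"
            )

    def is_valid(self, t: int) -> bool:
        try:
            self.validate(t)
        except ValueError:
            return False
        return True

    def on_boundary(self, t: int) -> bool:
        """True when theta sits on the edge of the (mu, sigma) search domain."""
        return (
            self.mu in (1, t)
            or self.sigma == 1
            or self.sigma == sigma_max(t)
        )


@dataclass(frozen=True)
class ReferenceCurve:
    """A unit-maximum Gaussian evaluated on the time axis 1..t."""

    values: np.ndarray = field(compare=False)
    params: ReferenceParams

    def __len__(self) -> int:
        return len(self.values)


def sigma_upper_bound(t: int) -> float:
    """Strict upper bound on sigma so that mu +/- 3 sigma fits in a window of t points.

    The bound is t/6: a Gaussian holds 99.73% of its mass within three
    standard deviations of its centre, so widths at or above t/6 cannot fit
    even when centred. Raises ``ValueError`` for t < 7, where no integer
    sigma >= 1 satisfies the bound.
    """
    if t < 7:
        raise ValueError(f"t={t} < 7 admits no integer sigma (bound t/6 = {t / 6:g})")
    return t / 6.0


def sigma_max(t: int) -> int:
    """Largest admissible integer sigma for a window of t points: ceil(t/6) - 1."""
    sigma_upper_bound(t)  # domain check
    return ceil(t / 6) - 1


def gaussian_reference(params: ReferenceParams, t: int) -> ReferenceCurve:
    """Evaluate the unit-maximum Gaussian r(x; theta) for x = 1..t.

    The curve is evaluated pointwise on the truncated window with no
    renormalisation: the sigma bound guarantees at least 99.73% of the mass
    fits, so truncation error is negligible by construction.
    """
    params.validate(t)
    x = np.arange(1, t + 1, dtype=float)
    values = np.exp(-((x - params.mu) ** 2) / (2.0 * params.sigma**2))
    return ReferenceCurve(values=values, params=params)


def parameter_grid(t: int) -> list[ReferenceParams]:
    """All integer (mu, sigma) with 1 <= mu <= t and 1 <= sigma <= ceil(t/6)-1."""
    smax = sigma_max(t)
    return [
        ReferenceParams(mu, sigma)
        for mu in range(1, t + 1)
        for sigma in range(1, smax + 1)
    ]


def bit_widths(t: int) -> tuple[int, int]:
    """Bit widths needed to encode mu-1 (0..t-1) and sigma-1 (0..sigma_max-1)."""
    smax = sigma_max(t)
    wmu = max(1, ceil(log2(t)))
    wsig = max(1, ceil(log2(smax))) if smax > 1 else 1
    return wmu, wsig
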