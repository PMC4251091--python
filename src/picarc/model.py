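"""The reference-constrained ICA objective and its fitness surface.

A single unit fits a unit-norm weight b (plus an amplitude/offset
calibration) so that the calculated curve y = scale * (b^T X_tilde) + d
both is maximally non-Gaussian — the fastICA negentropy proxy E{G(b^T x)}
with G(u) = u^4/4 — and stays close to a Gaussian reference curve r(theta).
The measurement operator

    epsilon(theta) = sum_j (y_j - r_j(theta))^2

is the fitness that the genetic search minimises over the integer (mu,
sigma) grid: its local minima mark the compounds actually present, so the
number of compounds never has to be known in advance.

The penalised fixed-point update here augments the classic fastICA step

    b+ = E{x g(b^T x)} - E{g'(b^T x)} b

with the gradient and (scalar) curvature of the reference-distance penalty,
followed by renormalisation to ||b|| = 1. The curve amplitude ``scale`` and
offset ``d`` are re-solved in closed form (a 1-D least squares against r)
at every iteration: the offset absorbs the centring shift between whitened
and raw domains, the scale absorbs the unit-variance normalisation. A pure
least-squares mode (``fitness_mode='ls'``) skips the negentropy term and
takes b proportional to X_tilde @ (r - mean r) in closed form; it is exact
on noiseless data and serves as an independent cross-check of the default
mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import AugmentedWeight, WhitenedData
from .reference import ReferenceCurve, ReferenceParams, gaussian_reference

__all__ = [
    "FitOptions",
    "CalculatedCurve",
    "SingleUnitFit",
    "FitnessCache",
    "contrast",
    "measure_distance",
    "fit_single_unit",
    "fitness",
    "parallel_refine",
]


@dataclass
class FitOptions:
    """Tunables of the single-unit fit.

    gamma        weight of the reference-distance penalty relative to the
                 negentropy term; the penalty enters as the raw squared
                 distance summed over all t time points, so the objective is
                 E{G(u)} - gamma * ||y - r||^2. The default gamma = 10 makes
                 the reference constraint dominate at the one-grid-step
                 scale — its local minima then sit at the compounds actually
                 present — while the negentropy term still supplies the ICA
                 character away from them. At gamma near 1 the quartic
                 contrast (which grows with source kurtosis, not O(1)) can
                 drag minima several grid steps off the true peaks.
    tol          convergence tolerance on |1 - |b+ . b||.
    max_iter     fixed-point iteration cap.
    fitness_mode 'picarc' (penalised fastICA update) or 'ls' (closed-form
                 least squares, no negentropy term).
    """

    gamma: float = 10.0
    tol: float = 1e-6
    max_iter: int = 200
    fitness_mode: str = "picarc"

    def __post_init__(self) -> None:
        if self.fitness_mode not in ("picarc", "ls"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.gamma < 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("gamma >= 0, tol > 0, max_iter >= 1 required")


@dataclass
class CalculatedCurve:
    """A raw-domain output curve y fitted against a particular reference."""

    values: np.ndarray
    source_theta: ReferenceParams | None = None


@dataclass
class SingleUnitFit:
    weight: AugmentedWeight
    curve: CalculatedCurve
    epsilon: float
    iterations: int
    converged: bool


class FitnessCache(dict):
    """Memoised epsilon(theta) values; the (mu, sigma) grid is finite."""

    def __init__(self) -> None:
        super().__init__()
        self.hits = 0
        self.evals = 0


def contrast(u):
    """The quartic contrast G(u) = u^4/4 with derivatives g = u^3, g' = 3u^2."""
    u = np.asarray(u, dtype=float)
    return u**4 / 4.0, u**3, 3.0 * u**2


def measure_distance(y, r) -> float:
    """Squared Euclidean distance sum_j (y_j - r_j)^2 between two curves."""
    yv = y.values if hasattr(y, "values") else np.asarray(y, dtype=float)
    rv = r.values if hasattr(r, "values") else np.asarray(r, dtype=float)
    if yv.shape != rv.shape:
        raise ValueError(f"length mismatch: {yv.shape} vs {rv.shape}")
    diff = yv - rv
    return float(diff @ diff)


def _init_b(Xt: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Deterministic init: project the centred reference onto the whitened rows."""
    b0 = Xt @ rc
    nrm = np.linalg.norm(b0)
    if nrm < 1e-300:
        b0 = np.zeros(Xt.shape[0])
        b0[0] = 1.0
        return b0
    return b0 / nrm


def _calibrate(u: np.ndarray, rv: np.ndarray, rc: np.ndarray) -> tuple[float, float]:
    """Closed-form (scale, offset) minimising ||scale*u + offset - r||^2.

    u has zero mean (rows of X_tilde are centred), so the optimum decouples:
    scale = <u, r - mean r> / <u, u>, offset = mean r.
    """
    uu = u @ u
    alpha = (u @ rc) / uu if uu > 0 else 0.0
    return alpha, float(rv.mean())


def _penalized_step(
    b: np.ndarray, Xt: np.ndarray, rv: np.ndarray, rc: np.ndarray, gamma: float
) -> tuple[np.ndarray, float, float]:
    """One fixed-point update of b; returns (new b, scale, offset) pre-update."""
    t = Xt.shape[1]
    u = b @ Xt
    # Resolve the sign indeterminacy toward positive correlation with r.
    if u @ rc < 0:
        b, u = -b, -u
    alpha, beta = _calibrate(u, rv, rc)
    _, g, gp = contrast(u)
    resid = alpha * u + beta - rv
    # Newton-style step on E{G(u)} - gamma * ||y - r||^2 with the distance
    # kept as the raw sum over time points: the quartic contrast contributes
    # +E{g'(u)} to the curvature, the penalty -2*gamma*alpha^2*t.
    grad = Xt @ g / t - gamma * 2.0 * alpha * (Xt @ resid)
    b_new = grad - (gp.mean() - gamma * 2.0 * alpha**2 * t) * b
    nrm = np.linalg.norm(b_new)
    if nrm < 1e-300:
        b_new = b
    else:
        b_new = b_new / nrm
    return b_new, alpha, beta


def _finalize(b, Xt, rv, rc, theta, iterations, converged) -> SingleUnitFit:
    u = b @ Xt
    if u @ rc < 0:
        b, u = -b, -u
    alpha, beta = _calibrate(u, rv, rc)
    y = alpha * u + beta
    eps = measure_distance(y, rv)
    weight = AugmentedWeight(b=b, d=beta, scale=alpha)
    return SingleUnitFit(
        weight=weight,
        curve=CalculatedCurve(values=y, source_theta=theta),
        epsilon=eps,
        iterations=iterations,
        converged=converged,
    )


def fit_single_unit(
    W: WhitenedData, r: ReferenceCurve, opts: FitOptions | None = None
) -> SingleUnitFit:
    """Fit one unit against reference r; deterministic given (W, r, opts).

    Non-convergence within ``opts.max_iter`` is reported via the
    ``converged`` flag, never raised — the search treats such points like
    any other fitness evaluation.
    """
    opts = opts or FitOptions()
    Xt = W.X_tilde
    if len(r.values) != Xt.shape[1]:
        raise ValueError("reference length does not match data time axis")
    rv = r.values
    rc = rv - rv.mean()
    b = _init_b(Xt, rc)

    if opts.fitness_mode == "ls":
        return _finalize(b, Xt, rv, rc, r.params, iterations=0, converged=True)

    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        b_new, _, _ = _penalized_step(b, Xt, rv, rc, opts.gamma)
        if abs(1.0 - abs(b_new @ b)) < opts.tol:
            b = b_new
            converged = True
            break
        b = b_new
    return _finalize(b, Xt, rv, rc, r.params, iterations=it, converged=converged)


def fitness(
    theta: ReferenceParams,
    W: WhitenedData,
    opts: FitOptions | None = None,
    cache: FitnessCache | None = None,
) -> float:
    """epsilon(theta): the reference-distance of the best single-unit fit at theta."""
    if cache is not None and theta in cache:
        cache.hits += 1
        return cache[theta]
    r = gaussian_reference(theta, W.t)
    eps = fit_single_unit(W, r, opts).epsilon
    if cache is not None:
        cache[theta] = eps
        cache.evals += 1
    return eps


def parallel_refine(
    thetas: list[ReferenceParams],
    W: WhitenedData,
    opts: FitOptions | None = None,
    decorrelate: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly refine all units for the solution set theta*.

    Returns (Y_star, B): Y_star is n x t, one raw-domain curve per theta
    ordered by ascending mu, each calibrated so its peak is positive; B
    holds the unit vectors as columns (k x n).

    By default the units are iterated in parallel without symmetric
    decorrelation: each reference already pins its unit to one compound, and
    overlapping elution peaks are genuinely correlated, so forcing
    orthogonal outputs would bias the recovered curves. Pass
    ``decorrelate=True`` for the classical fastICA symmetric step
    B <- B (B^T B)^{-1/2} after every update.
    """
    if not thetas:
        raise ValueError("need at least one theta")
    if len(set(thetas)) != len(thetas):
        raise ValueError("thetas must be pairwise distinct")
    opts = opts or FitOptions()
    order = sorted(range(len(thetas)), key=lambda i: (thetas[i].mu, thetas[i].sigma))
    thetas = [thetas[i] for i in order]
    Xt = W.X_tilde
    refs = [gaussian_reference(th, W.t) for th in thetas]
    rvs = [r.values for r in refs]
    rcs = [rv - rv.mean() for rv in rvs]
    n = len(thetas)

    B = np.column_stack([_init_b(Xt, rc) for rc in rcs])
    if decorrelate:
        B = _sym_decorrelate(B)
    for _ in range(opts.max_iter):
        B_new = np.empty_like(B)
        for i in range(n):
            if opts.fitness_mode == "ls":
                B_new[:, i] = B[:, i]
            else:
                B_new[:, i], _, _ = _penalized_step(
                    B[:, i], Xt, rvs[i], rcs[i], opts.gamma
                )
        if decorrelate:
            B_new = _sym_decorrelate(B_new)
        delta = max(
            abs(1.0 - abs(B_new[:, i] @ B[:, i])) for i in range(n)
        )
        B = B_new
        if delta < opts.tol or opts.fitness_mode == "ls":
            break

    Y = np.empty((n, W.t))
    for i in range(n):
        fit = _finalize(B[:, i], Xt, rvs[i], rcs[i], thetas[i], 0, True)
        B[:, i] = fit.weight.b
        Y[i] = fit.curve.values
    return Y, B


def _sym_decorrelate(B: np.ndarray) -> np.ndarray:
    """Symmetric decorrelation: B (B^T B)^{-1/2}, columns made orthonormal."""
    G = B.T @ B
    evals, evecs = np.linalg.eigh(G)
    if evals[0] < 1e-12 * max(evals[-1], 1.0):
        raise np.linalg.LinAlgError("degenerate unit set: B^T B is singular")
    G_isqrt = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    return B @ G_isqrt
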