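"""End-to-end separation: search, refine, estimate.

Ties the pieces together: the genetic search locates the compound
parameters theta*, the parallel refinement turns them into raw-domain
elution curves Y*, and the pseudo-inverse estimator recovers the spectra
A = X pinv(Y*).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import replace

import numpy as np

from .estimator import estimate_spectra
from .io_formats import Chromatogram3D, SeparationResult
from .mga import MGAConfig, MGAResult, run
from .model import FitOptions, parallel_refine
from .preprocess import center_whiten
from .reference import ReferenceParams

logger = logging.getLogger(__name__)

__all__ = ["separate", "consensus_solutions"]


def consensus_solutions(
    runs: list[MGAResult], min_support: int | None = None
) -> list[ReferenceParams]:
    """Solutions appearing in at least half the runs (or ``min_support`` of them).

    Repeated runs with different seeds are the standard remedy for the
    occasional stochastic failure of a single search; the consensus keeps
    every theta recovered by a majority.
    """
    if not runs:
        return []
    need = min_support if min_support is not None else (len(runs) + 1) // 2
    counts: Counter[ReferenceParams] = Counter()
    for res in runs:
        counts.update(set(res.solutions))
    return sorted(
        (th for th, c in counts.items() if c >= need),
        key=lambda th: (th.mu, th.sigma),
    )


def separate(
    X: Chromatogram3D,
    cfg: MGAConfig | None = None,
    fit_opts: FitOptions | None = None,
    repeat: int = 1,
) -> tuple[SeparationResult, list[MGAResult]]:
    """Separate a chromatogram into per-compound peaks and spectra.

    With ``repeat > 1`` the genetic search runs that many times with
    consecutive seeds and the consensus solution set (thetas found in at
    least half the runs) is refined. Returns the separation plus the raw
    per-run search results.
    """
    cfg = cfg or MGAConfig()
    fit_opts = fit_opts or FitOptions()
    results = [
        run(X, replace(cfg, seed=cfg.seed + i), fit_opts) for i in range(repeat)
    ]
    thetas = (
        consensus_solutions(results) if repeat > 1 else list(results[0].solutions)
    )
    run_log = [h for res in results for h in res.history]
    if not thetas:
        logger.warning("no solutions found; returning empty separation")
        t = X.n_times
        return (
            SeparationResult(
                thetas=[],
                peaks=np.empty((0, t)),
                spectra=np.empty((X.n_wavelengths, 0)),
                fitness=[],
                run_log=run_log,
            ),
            results,
        )
    W = center_whiten(X)
    Y, _ = parallel_refine(thetas, W, fit_opts)
    thetas = sorted(thetas, key=lambda th: (th.mu, th.sigma))
    A = estimate_spectra(X, Y)
    cache = results[0].cache
    fitness_vals = [float(cache[th]) if cache and th in cache else float("nan") for th in thetas]
    result = SeparationResult(
        thetas=thetas, peaks=Y, spectra=A, fitness=fitness_vals, run_log=run_log
    )
    return result, results
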