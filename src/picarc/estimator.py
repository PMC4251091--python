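"""Spectra estimation from recovered peaks, and scoring against known truth.

With the bilinear model X = A S and the recovered elution-peak matrix
Y* ~ S, the least-squares spectra are A = X pinv(S); noise is ignored, so on
noiseless full-rank data this inverts the mixture exactly. Negative spectral
values are physically meaningless but can arise from imperfect peak
recovery; they are flagged in the log, never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import Chromatogram3D
from .reference import ReferenceParams

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "estimate_spectra", "evaluate"]


@dataclass
class EvaluationReport:
    """Per-compound recovery errors against a known simulation truth.

    ``matching`` maps recovered-compound index -> true-compound index
    (greedy nearest-theta pairing); errors are mean squared differences of
    unit-maximum-scaled curves/spectra, so they are invariant to amplitude.
    """

    matching: dict[int, int]
    curve_error: dict[int, float]
    spectrum_error: dict[int, float]
    unmatched_true: list[int]
    unmatched_recovered: list[int]

    @property
    def max_curve_error(self) -> float:
        return max(self.curve_error.values(), default=float("nan"))

    @property
    def max_spectrum_error(self) -> float:
        return max(self.spectrum_error.values(), default=float("nan"))


def estimate_spectra(X: Chromatogram3D | np.ndarray, S: np.ndarray) -> np.ndarray:
    """Least-squares spectra A = X pinv(S); requires S of full row rank."""
    Xm = X.absorbance if isinstance(X, Chromatogram3D) else np.asarray(X, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise np.linalg.LinAlgError("collinear peaks: S is rank-deficient")
    A = Xm @ np.linalg.pinv(S)
    n_neg = int((A < 0).sum())
    if n_neg:
        logger.warning(
            "estimated spectra contain %d negative entries (min %.3g); "
            "likely imperfect peak recovery or noise", n_neg, A.min(),
        )
    return A


def _unit_max(v: np.ndarray) -> np.ndarray:
    peak = np.abs(v).max()
    return v / peak if peak > 0 else v


def evaluate(
    recovered_thetas: list[ReferenceParams],
    recovered_peaks: np.ndarray,
    recovered_spectra: np.ndarray,
    true_thetas: list[ReferenceParams],
    true_peaks: np.ndarray,
    true_spectra: np.ndarray,
) -> EvaluationReport:
    """Match recovered compounds to truth and score both profile families.

    Pairing is greedy on Euclidean theta distance, smallest distance first;
    each true compound is used at most once. Curves (rows) and spectra
    (columns) are scaled to unit maximum before the MSE, making the report
    invariant to compound order and positive rescaling.
    """
    recovered_peaks = np.atleast_2d(recovered_peaks)
    true_peaks = np.atleast_2d(true_peaks)
    pairs = sorted(
        (
            (np.hypot(rt.mu - tt.mu, rt.sigma - tt.sigma), i, j)
            for i, rt in enumerate(recovered_thetas)
            for j, tt in enumerate(true_thetas)
        ),
    )
    matching: dict[int, int] = {}
    used_true: set[int] = set()
    for _, i, j in pairs:
        if i in matching or j in used_true:
            continue
        matching[i] = j
        used_true.add(j)
    curve_error, spectrum_error = {}, {}
    for i, j in matching.items():
        yc = _unit_max(recovered_peaks[i])
        tc = _unit_max(true_peaks[j])
        curve_error[i] = float(((yc - tc) ** 2).mean())
        ys = _unit_max(recovered_spectra[:, i])
        ts = _unit_max(true_spectra[:, j])
        spectrum_error[i] = float(((ys - ts) ** 2).mean())
    return EvaluationReport(
        matching=matching,
        curve_error=curve_error,
        spectrum_error=spectrum_error,
        unmatched_true=sorted(set(range(len(true_thetas))) - used_true),
        unmatched_recovered=sorted(set(range(len(recovered_thetas))) - set(matching)),
    )
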