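"""Reading and writing chromatogram matrices and separation results.

An HPLC-DAD acquisition is a matrix of absorbance over (wavelength channel,
elution time). On disk it may be stored either way round; in memory it is
always wavelength x time, and every load logs the orientation applied so a
silent transpose can never happen.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io

from .reference import ReferenceParams

logger = logging.getLogger(__name__)

__all__ = [
    "Chromatogram3D",
    "SeparationResult",
    "read_matrix_csv",
    "read_mat_dataset",
    "write_result",
    "load_matrix_csv",
]


@dataclass
class Chromatogram3D:
    """The observed absorbance matrix X (m wavelength channels x t time points).

    ``time_axis`` is 1-based integer indices 1..t, the axis on which peak
    centres mu are reported.
    """

    absorbance: np.ndarray
    time_axis: np.ndarray = None  # type: ignore[assignment]
    wavelength_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        m, t = self.absorbance.shape
        if m < 2:
            raise ValueError(f"need at least 2 wavelength channels, got {m}")
        if t < 7:
            raise ValueError(f"need at least 7 time points, got {t}")
        if not np.isfinite(self.absorbance).all():
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValueError(
                f"non-finite absorbance at wavelength row {bad[0] + 1}, time column {bad[1] + 1}"
            )
        if self.time_axis is None:
            self.time_axis = np.arange(1, t + 1)
        self.time_axis = np.asarray(self.time_axis)
        if len(self.time_axis) != t:
            raise ValueError("time_axis length does not match absorbance columns")
        if self.wavelength_axis is not None and len(self.wavelength_axis) != m:
            raise ValueError("wavelength_axis length does not match absorbance rows")

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_times(self) -> int:
        return self.absorbance.shape[1]


@dataclass
class SeparationResult:
    """The separated compounds: parameters theta*, elution peaks Y* and spectra A.

    ``peaks`` holds one recovered elution profile per row (n x t), ordered by
    ascending peak centre mu; ``spectra`` the matching spectra as columns
    (m x n). ``fitness`` carries the measurement-operator distance for each
    theta*, and ``run_log`` a per-generation summary of the genetic search.
    """

    thetas: list[ReferenceParams]
    peaks: np.ndarray
    spectra: np.ndarray
    fitness: list[float] = field(default_factory=list)
    run_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        n = len(self.thetas)
        if self.peaks.shape[0] != n:
            raise ValueError("peaks must have one row per theta")
        if self.spectra.ndim == 2 and self.spectra.shape[1] != n:
            raise ValueError("spectra must have one column per theta")
        mus = [th.mu for th in self.thetas]
        if mus != sorted(mus):
            raise ValueError("thetas (and peak rows) must be ordered by ascending mu")


def _parse_numeric_table(path: Path) -> np.ndarray:
    """Parse a rectangular numeric CSV, auto-detecting a single header row."""
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise ValueError(f"{path}: empty file")

    def row_floats(row: list[str], irow: int) -> list[float]:
        out = []
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {irow + 1}, column {j + 1}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite value {cell!r} at row {irow + 1}, column {j + 1}"
                )
            out.append(v)
        return out

    start = 0
    try:
        row_floats(rows[0], 0)
    except ValueError:
        # Non-numeric first row: treat as header and require the rest numeric.
        start = 1
        if len(rows) == 1:
            raise ValueError(f"{path}: no numeric rows after header")
    width = len(rows[start])
    data = []
    for i in range(start, len(rows)):
        if len(rows[i]) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1} (expected {width} columns, got {len(rows[i])})"
            )
        data.append(row_floats(rows[i], i))
    return np.array(data, dtype=float)


def read_matrix_csv(path: str | Path, orientation: str = "wavelength-rows") -> Chromatogram3D:
    """Read a chromatogram matrix from CSV.

    ``orientation`` says what the on-disk rows are: ``wavelength-rows``
    (rows = wavelength channels) or ``time-rows`` (rows = time points). The
    returned matrix is always wavelength x time.
    """
    if orientation not in ("wavelength-rows", "time-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    data = _parse_numeric_table(Path(path))
    if orientation == "time-rows":
        data = data.T
    logger.info(
        "read %s as %s -> %d wavelengths x %d times", path, orientation, *data.shape
    )
    return Chromatogram3D(absorbance=data)


def load_matrix_csv(path: str | Path) -> np.ndarray:
    """Load a plain numeric CSV matrix (no orientation semantics)."""
    return _parse_numeric_table(Path(path))


def read_mat_dataset(
    path: str | Path,
    variable_name: str | None = None,
    orientation: str = "auto",
) -> Chromatogram3D:
    """Load a 2-D numeric variable from a MATLAB v5 .mat file.

    When ``variable_name`` is None and the file holds exactly one 2-D numeric
    variable, that one is used. ``orientation='auto'`` assumes the longer axis
    is time (DAD runs typically have more time points than channels kept);
    pass ``wavelength-rows`` or ``time-rows`` to override. The orientation
    actually applied is always logged.
    """
    contents = scipy.io.loadmat(str(path))
    variables = {
        k: v
        for k, v in contents.items()
        if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2
    }
    if variable_name is None:
        if len(variables) != 1:
            raise ValueError(
                f"{path}: specify variable_name; available 2-D variables: "
                f"{sorted(variables)}"
            )
        variable_name = next(iter(variables))
    if variable_name not in variables:
        raise KeyError(
            f"{path}: variable {variable_name!r} not found; available: {sorted(variables)}"
        )
    data = np.asarray(variables[variable_name], dtype=float)
    if orientation == "auto":
        # Heuristic: the longer axis is elution time.
        applied = "wavelength-rows" if data.shape[1] >= data.shape[0] else "time-rows"
    elif orientation in ("wavelength-rows", "time-rows"):
        applied = orientation
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if applied == "time-rows":
        data = data.T
    logger.info(
        "read %s[%s] as %s (%s) -> %d wavelengths x %d times",
        path, variable_name, applied,
        "heuristic" if orientation == "auto" else "explicit",
        *data.shape,
    )
    return Chromatogram3D(absorbance=data)


def _save_matrix(path: Path, mat: np.ndarray) -> None:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.size == 0:
        path.write_text("")
        return
    np.savetxt(path, mat, delimiter=",", fmt="%.17g")


def write_result(result: SeparationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write a SeparationResult as peaks.csv, spectra.csv, thetas.csv + summary.json.

    Matrices are written at full double precision so write/read round-trips
    are lossless to ~1e-16 relative.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "peaks": out / "peaks.csv",
        "spectra": out / "spectra.csv",
        "thetas": out / "thetas.csv",
        "summary": out / "summary.json",
    }
    _save_matrix(files["peaks"], result.peaks)
    _save_matrix(files["spectra"], result.spectra)
    fits = list(result.fitness) or [float("nan")] * len(result.thetas)
    with open(files["thetas"], "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["mu", "sigma", "fitness"])
        for th, f in zip(result.thetas, fits):
            wr.writerow([th.mu, th.sigma, repr(float(f))])
    summary = {
        "n_compounds": len(result.thetas),
        "thetas": [[th.mu, th.sigma] for th in result.thetas],
        "fitness": [float(f) for f in fits],
        "run_log": result.run_log,
    }
    files["summary"].write_text(json.dumps(summary, indent=2))
    return files
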