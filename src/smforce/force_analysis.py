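"""High-force fraction estimation and force-PDF reconstruction.

The proportion of sensors under load is estimated by thresholding: from
cell-free data (no force possible) the empirical ``f``-quantile ``q_f`` of
the FRET efficiency is taken as a threshold with nominal false-positive rate
``f``; on cell-derived data the corrected high-force fraction is then
``n_low / n_total - f``.  Uncertainty comes from a bootstrap that resamples
whole tracks.

Force magnitudes are recovered by density subtraction: average shifted
histograms (ASH) of the cell-free and cell-impacted efficiency data are
built on a common grid, the cell-free PDF is scaled in width (about an
anchor efficiency, i.e. ``x -> anchor + s_width*(x - anchor)``) and height
to match the cell PDF in the low-force window (efficiency > 0.75), then
subtracted.  The non-negative residual is the efficiency PDF of the
force-bearing fraction; the calibration map converts it to a force PDF via
an analytic change-of-variables Jacobian, from which quartiles are read off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .calibration import SensorCalibration, force_from_efficiency, dE_dF
from .resampling import BootstrapSummary, bootstrap_tracks, summarize_bootstrap

__all__ = [
    "ThresholdResult",
    "HighForceResult",
    "ForcePDF",
    "compute_threshold",
    "high_force_fraction",
    "bootstrap_fraction",
    "ash_pdf",
    "sturges_bins",
    "estimate_force_pdf",
]

logger = logging.getLogger(__name__)

MIN_THRESHOLD_POINTS = 20


@dataclass(frozen=True)
class ThresholdResult:
    """Efficiency threshold ``q_f`` at nominal false-positive rate ``f``."""

    q_f: float
    f: float
    n: int


@dataclass(frozen=True)
class HighForceResult:
    """Corrected high-force fraction ``n_low/n_total - f`` with bootstrap."""

    fraction_point: float
    n_low: int
    n_total: int
    f: float
    bootstrap: BootstrapSummary | None = None

    def to_dict(self) -> dict:
        d = {
            "fraction_point": self.fraction_point,
            "n_low": self.n_low,
            "n_total": self.n_total,
            "f": self.f,
        }
        if self.bootstrap is not None:
            d["bootstrap"] = self.bootstrap.to_dict()
        return d


@dataclass(frozen=True)
class ForcePDF:
    """Force probability density of the high-force fraction.

    ``no_force_detected`` is set when the residual efficiency PDF carries
    essentially no mass (below ``mass_floor``), in which case the quartiles
    are None.
    """

    force_grid: np.ndarray
    density: np.ndarray
    q1: float | None
    median: float | None
    q3: float | None
    s_width: float
    s_height: float
    residual_mass: float
    no_force_detected: bool
    efficiency_grid: np.ndarray | None = None
    residual_density: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "force_grid": np.asarray(self.force_grid).tolist(),
            "density": np.asarray(self.density).tolist(),
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "s_width": self.s_width,
            "s_height": self.s_height,
            "residual_mass": self.residual_mass,
            "no_force_detected": self.no_force_detected,
        }


def compute_threshold(
    no_cell_efficiencies, f: float = 0.05, min_points: int = MIN_THRESHOLD_POINTS
) -> ThresholdResult:
    """Empirical ``f``-quantile of cell-free efficiencies.

    Uses linear interpolation between order statistics (numpy's default
    quantile rule).
    """
    values = np.asarray(no_cell_efficiencies, dtype=float)
    values = values[~np.isnan(values)]
    if not 0 < f < 1:
        raise ValueError(f"false-positive rate f must lie in (0, 1), got {f}")
    if values.size < min_points:
        raise ValueError(
            f"need at least {min_points} cell-free datapoints to set a "
            f"threshold, got {values.size}"
        )
    return ThresholdResult(q_f=float(np.quantile(values, f)), f=f, n=values.size)


def _fraction(values: np.ndarray, threshold: ThresholdResult) -> tuple[float, int, int]:
    n_total = values.size
    n_low = int(np.count_nonzero(values < threshold.q_f))
    return n_low / n_total - threshold.f, n_low, n_total


def high_force_fraction(cell_efficiencies, threshold: ThresholdResult) -> HighForceResult:
    """Corrected high-force fraction ``n_low/n_total - f`` (point estimate).

    Accepts a flat array or a sequence of per-track arrays.  May be negative
    under sampling noise; not clamped.
    """
    values = _pool(cell_efficiencies)
    if values.size == 0:
        raise ValueError("cell_efficiencies is empty")
    frac, n_low, n_total = _fraction(values, threshold)
    return HighForceResult(frac, n_low, n_total, threshold.f)


def bootstrap_fraction(
    cell_tracks: Sequence[np.ndarray],
    threshold: ThresholdResult,
    n_boot: int = 1000,
    seed: int | None = None,
) -> HighForceResult:
    """High-force fraction with a track-preserving bootstrap distribution.

    ``cell_tracks`` is a sequence of per-track efficiency arrays; resampling
    draws tracks (not observations) with replacement to the original track
    count, ``n_boot`` times.
    """
    tracks = [np.asarray(t, dtype=float) for t in cell_tracks]
    tracks = [t[~np.isnan(t)] for t in tracks if t.size]
    point = high_force_fraction(tracks, threshold)

    def stat(sample: list[np.ndarray]) -> float:
        return _fraction(np.concatenate(sample), threshold)[0]

    boot = bootstrap_tracks(tracks, stat, n_boot=n_boot, seed=seed)
    return HighForceResult(
        point.fraction_point,
        point.n_low,
        point.n_total,
        threshold.f,
        bootstrap=summarize_bootstrap(boot),
    )


def _pool(values) -> np.ndarray:
    if isinstance(values, np.ndarray) and values.ndim == 1:
        arr = values.astype(float)
    else:
        try:
            arr = np.asarray(values, dtype=float).ravel()
        except (ValueError, TypeError):
            arr = np.concatenate([np.asarray(v, dtype=float) for v in values])
    return arr[~np.isnan(arr)]


def sturges_bins(n: int) -> int:
    """Sturges's rule: ``1 + ceil(log2(n))`` bins."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return 1
    return 1 + math.ceil(math.log2(n))


def ash_pdf(
    values,
    range_lo: float = -0.5,
    range_hi: float = 1.5,
    n_shifts: int = 40,
    n_points_for_bins: int | None = None,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average shifted histogram density estimate on a fixed range.

    The number of coarse bins follows Sturges's rule on
    ``n_points_for_bins`` (defaulting to the sample size); ``n_shifts``
    offset histograms are averaged, which is equivalent to a triangular
    kernel on the fine grid of width ``bin_width / n_shifts``.  Values
    outside the range are excluded (logged); the returned density integrates
    to 1 over the range.

    Returns ``(grid_centers, density)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("ash_pdf requires a non-empty sample")
    if not range_hi > range_lo:
        raise ValueError("range_hi must exceed range_lo")
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")

    inside = values[(values >= range_lo) & (values <= range_hi)]
    n_excluded = values.size - inside.size
    if n_excluded:
        logger.info("ash_pdf: excluded %d values outside [%g, %g]",
                    n_excluded, range_lo, range_hi)
    if inside.size == 0:
        raise ValueError("all values fall outside the histogram range")

    if n_bins is None:
        n_bins = sturges_bins(
            n_points_for_bins if n_points_for_bins is not None else inside.size
        )
    m = n_shifts
    h = (range_hi - range_lo) / n_bins
    delta = h / m
    n_fine = n_bins * m
    # fine counts with m-1 guard bins on each side for the kernel overhang
    edges = range_lo + delta * np.arange(-(m - 1), n_fine + m)
    counts, _ = np.histogram(inside, bins=edges)
    weights = 1.0 - np.abs(np.arange(-(m - 1), m)) / m
    density = np.convolve(counts, weights, mode="valid") / (inside.size * h)
    centers = range_lo + delta * (np.arange(n_fine) + 0.5)
    # renormalize: mass smeared past the range ends is truncated
    density = density / (density.sum() * delta)
    return centers, density


def estimate_force_pdf(
    cell_efficiencies,
    no_cell_efficiencies,
    calib: SensorCalibration = SensorCalibration(),
    anchor_E: float = 0.87,
    fit_window_lo: float = 0.75,
    range_lo: float = -0.5,
    range_hi: float = 1.5,
    n_shifts: int = 40,
    mass_floor: float = 1e-3,
) -> ForcePDF:
    """Reconstruct the force PDF of the high-force fraction.

    Both efficiency PDFs are built by :func:`ash_pdf` on a shared grid
    (Sturges bins from the cell-impacted sample size).  The cell-free PDF is
    scaled in width about ``anchor_E`` and in height by nonlinear least
    squares against the cell PDF on grid points with efficiency above
    ``fit_window_lo``, subtracted, and the residual clipped at zero.  The
    surviving low-efficiency density is mapped to force with the analytic
    Jacobian ``|dE/dF|`` of the calibration; grid points at negative force
    (efficiency above the zero-force efficiency) or with efficiencies
    outside (0, 1) are dropped before renormalization.  Quartiles are
    computed by inverse-CDF interpolation.

    If the residual mass is below ``mass_floor`` the result flags
    ``no_force_detected`` and carries no quartiles.
    """
    cell = _pool(cell_efficiencies)
    nocell = _pool(no_cell_efficiencies)
    if cell.size == 0 or nocell.size == 0:
        raise ValueError("both efficiency samples must be non-empty")

    n_bins = sturges_bins(cell.size)
    grid, pdf_cell = ash_pdf(cell, range_lo, range_hi, n_shifts, n_bins=n_bins)
    _, pdf_nocell = ash_pdf(nocell, range_lo, range_hi, n_shifts, n_bins=n_bins)

    window = grid > fit_window_lo

    def scaled_nocell(params: np.ndarray) -> np.ndarray:
        s_width, s_height = params
        # graph points (x, y) -> (anchor + s_width*(x - anchor), s_height*y);
        # evaluate on the fixed grid by pulling back through the x map
        x_back = anchor_E + (grid - anchor_E) / s_width
        return s_height * np.interp(x_back, grid, pdf_nocell, left=0.0, right=0.0)

    def residuals(params: np.ndarray) -> np.ndarray:
        return scaled_nocell(params)[window] - pdf_cell[window]

    fit = least_squares(
        residuals, x0=[1.0, 1.0], bounds=([1e-6, 1e-6], [5.0, 5.0])
    )
    s_width, s_height = (float(v) for v in fit.x)

    residual = pdf_cell - scaled_nocell(fit.x)
    residual = np.clip(residual, 0.0, None)
    delta = grid[1] - grid[0]
    mass = float(residual.sum() * delta)

    if mass < mass_floor:
        return ForcePDF(
            force_grid=np.array([]),
            density=np.array([]),
            q1=None,
            median=None,
            q3=None,
            s_width=s_width,
            s_height=s_height,
            residual_mass=mass,
            no_force_detected=True,
            efficiency_grid=grid,
            residual_density=residual,
        )

    # change of variables E -> F on grid points with a defined, non-negative force
    valid = (grid > 0.0) & (grid < 1.0)
    E_valid = grid[valid]
    forces = force_from_efficiency(E_valid, calib)
    keep = forces >= 0.0
    forces = forces[keep]
    dens_E = residual[valid][keep]
    jac = np.abs(dE_dF(forces, calib))
    dens_F = dens_E * jac

    order = np.argsort(forces)
    forces = forces[order]
    dens_F = dens_F[order]
    total = np.trapezoid(dens_F, forces)
    if total <= 0:
        return ForcePDF(
            force_grid=forces,
            density=dens_F,
            q1=None,
            median=None,
            q3=None,
            s_width=s_width,
            s_height=s_height,
            residual_mass=mass,
            no_force_detected=True,
            efficiency_grid=grid,
            residual_density=residual,
        )
    dens_F = dens_F / total

    cdf = np.concatenate(
        [[0.0], np.cumsum(np.diff(forces) * 0.5 * (dens_F[1:] + dens_F[:-1]))]
    )
    cdf /= cdf[-1]
    q1, med, q3 = np.interp([0.25, 0.5, 0.75], cdf, forces)

    return ForcePDF(
        force_grid=forces,
        density=dens_F,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        s_width=s_width,
        s_height=s_height,
        residual_mass=mass,
        no_force_detected=False,
        efficiency_grid=grid,
        residual_density=residual,
    )
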