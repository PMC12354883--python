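"""Mobile vs. immobilized track classification via the smallest enclosing circle.

On a fluid bilayer a free sensor diffuses, so the smallest circle enclosing
its track grows like sqrt(time); an immobilized (receptor-bound) sensor
stays put.  The *reduced radius* — circle radius divided by the square root
of the track duration — is therefore a diffusion-scale-free immobilization
criterion: tracks below 0.35 um/s^0.5 are classified immobilized.  Tracks
with fewer than five observations are labeled ``too_short`` and excluded
from fraction denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import TrajectoryDataset
from .resampling import BootstrapSummary, summarize_bootstrap

__all__ = [
    "smallest_enclosing_circle",
    "classify_mobility",
    "bound_fraction",
    "ImmobileFractionResult",
]

logger = logging.getLogger(__name__)

REDUCED_RADIUS_THRESHOLD = 0.35  # um / s^0.5
MIN_OBSERVATIONS = 5

_EPS = 1e-10


def _contains(center: np.ndarray, r: float, p: np.ndarray) -> bool:
    return np.hypot(*(p - center)) <= r + _EPS * (1.0 + r)


def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    center = 0.5 * (p + q)
    return center, float(np.hypot(*(p - center)))


def _circumcircle(a, b, c) -> tuple[np.ndarray, float] | None:
    # circle through three points; None when (nearly) collinear
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-14:
        return None
    a2, b2, c2 = (a * a).sum(), (b * b).sum(), (c * c).sum()
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _circle_with_two_boundary(pts, p, q) -> tuple[np.ndarray, float]:
    # smallest circle containing pts with p and q on the boundary
    circ = _circle_two(p, q)
    pq = q - p
    best_left = best_right = None
    cross_left = cross_right = 0.0
    for r in pts:
        if _contains(*circ, r):
            continue
        cross = pq[0] * (r[1] - p[1]) - pq[1] * (r[0] - p[0])
        cc = _circumcircle(p, q, r)
        if cc is None:
            continue
        c_cross = pq[0] * (cc[0][1] - p[1]) - pq[1] * (cc[0][0] - p[0])
        if cross > 0 and (best_left is None or c_cross > cross_left):
            best_left, cross_left = cc, c_cross
        elif cross < 0 and (best_right is None or c_cross < cross_right):
            best_right, cross_right = cc, c_cross
    if best_left is None and best_right is None:
        return circ
    if best_left is None:
        return best_right
    if best_right is None:
        return best_left
    return best_left if best_left[1] <= best_right[1] else best_right


def _circle_with_one_boundary(pts, p) -> tuple[np.ndarray, float]:
    # smallest circle containing pts with p on the boundary
    center, r = p.copy(), 0.0
    for j, q in enumerate(pts):
        if not _contains(center, r, q):
            if r == 0.0:
                center, r = _circle_two(p, q)
            else:
                center, r = _circle_with_two_boundary(pts[:j], p, q)
    return center, r


def smallest_enclosing_circle(points) -> tuple[np.ndarray, float]:
    """Smallest circle enclosing a 2-D point set.

    Deterministic incremental construction (points processed in input
    order, no shuffling) so repeated runs give identical output.  Expected
    linear time for tracks of typical length.

    Returns ``(center, radius)``; a single point yields radius 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("smallest_enclosing_circle requires at least one point")
    if pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")

    center, r = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        if not _contains(center, r, pts[i]):
            center, r = _circle_with_one_boundary(pts[:i], pts[i])
    return center, r


@dataclass(frozen=True)
class ImmobileFractionResult:
    """Fraction of (non-too_short) tracks classified immobilized."""

    fraction: float
    n_immobilized: int
    n_classified: int
    bootstrap: BootstrapSummary | None = None

    def to_dict(self) -> dict:
        d = {
            "fraction": self.fraction,
            "n_immobilized": self.n_immobilized,
            "n_classified": self.n_classified,
        }
        if self.bootstrap is not None:
            d["bootstrap"] = self.bootstrap.to_dict()
        return d


def classify_mobility(
    ds: TrajectoryDataset,
    reduced_radius_threshold: float = REDUCED_RADIUS_THRESHOLD,
    min_observations: int = MIN_OBSERVATIONS,
) -> pd.DataFrame:
    """Per-track mobility labels.

    Duration is measured from timestamps (last minus first ``time_s``), not
    frame counts, to match the um/s^0.5 unit of the threshold.  Tracks with
    fewer than ``min_observations`` observations are labeled ``too_short``;
    zero-duration tracks with enough observations are immobilized by
    convention (logged).

    Returns a frame with columns ``track_id``, ``center_x_um``,
    ``center_y_um``, ``radius_um``, ``duration_s``, ``reduced_radius``,
    ``label``.
    """
    rows = []
    for tid, g in ds.tracks():
        n = len(g)
        pts = g[["x_um", "y_um"]].to_numpy(dtype=float)
        center, radius = smallest_enclosing_circle(pts)
        duration = float(g["time_s"].iloc[-1] - g["time_s"].iloc[0])
        if n < min_observations:
            label, reduced = "too_short", np.nan
        elif duration <= 0:
            logger.info("track %s has zero duration; immobilized by convention", tid)
            label, reduced = "immobilized", 0.0
        else:
            reduced = radius / np.sqrt(duration)
            label = "immobilized" if reduced < reduced_radius_threshold else "mobile"
        rows.append(
            {
                "track_id": tid,
                "center_x_um": center[0],
                "center_y_um": center[1],
                "radius_um": radius,
                "duration_s": duration,
                "reduced_radius": reduced,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def bound_fraction(
    labels: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> ImmobileFractionResult:
    """Fraction of classifiable tracks that are immobilized (bound proxy).

    ``too_short`` tracks are excluded from the denominator.  A
    track-preserving bootstrap (each track contributes one label) supplies
    the distribution summary; pass ``n_boot=0`` to skip it.
    """
    classified = labels[labels["label"] != "too_short"]
    if classified.empty:
        raise ValueError("no classifiable tracks (all too_short)")
    flags = (classified["label"] == "immobilized").to_numpy()
    frac = float(flags.mean())
    boot = None
    if n_boot and len(flags) >= 2:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(flags), size=(n_boot, len(flags)))
        boot = summarize_bootstrap(flags[idx].mean(axis=1))
    return ImmobileFractionResult(frac, int(flags.sum()), int(flags.size), boot)
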