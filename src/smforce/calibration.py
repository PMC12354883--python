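"""Force-sensor calibration: dye separation <-> FRET efficiency <-> force.

The molecular force sensor (MFS) is a peptide-based entropic spring flanked
by a FRET dye pair.  Pulling on the sensor extends the spring, increases the
inter-dye separation ``r`` and thereby lowers the FRET efficiency ``E``.  Two
relations tie the three quantities together:

* a linear entropic-spring law between force and dye separation,
  ``F(r) = (r - b*n - c) / (a*n)``, where ``a`` is the per-residue compliance,
  ``b`` the per-residue contour offset, ``c`` a spring-specific constant and
  ``n`` the number of amino acids in the spring element;
* the Foerster relation ``E(r) = 1 / (1 + (r / R0)**6)``.

Composing the closed-form inverse of the Foerster relation with the linear
law yields the calibration map ``F(E)`` used throughout the package.

Units are fixed package-wide: lengths in nm, forces in pN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "SensorCalibration",
    "force_from_separation",
    "separation_from_force",
    "efficiency_from_separation",
    "separation_from_efficiency",
    "force_from_efficiency",
    "efficiency_from_force",
    "uncertainty_profile",
    "propagate_uncertainty",
]


@dataclass(frozen=True)
class SensorCalibration:
    """Entropic-spring and Foerster parameters of one sensor construct.

    Parameters
    ----------
    a:
        Spring compliance slope, nm/pN. Must be positive.
    b:
        Per-residue contour offset, nm.
    c:
        Spring-specific constant (zero-force offset of the construct), nm.
    n:
        Number of amino acids in the spring element.
    R0:
        Foerster radius of the dye pair, nm.

    The defaults describe the flagelliform spider-silk peptide sensor with
    29 residues and an R0 of 5.1 nm.
    """

    a: float = 0.0122
    b: float = 0.044
    c: float = 2.4
    n: int = 29
    R0: float = 5.1

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"spring compliance a must be > 0, got {self.a}")
        if self.b < 0 or self.c < 0:
            raise ValueError("offsets b and c must be >= 0")
        if self.n < 1:
            raise ValueError(f"residue count n must be >= 1, got {self.n}")
        if not self.R0 > 0:
            raise ValueError(f"Foerster radius R0 must be > 0, got {self.R0}")
        if not self.r0 > 0:
            raise ValueError("zero-force separation b*n + c must be > 0")

    @property
    def r0(self) -> float:
        """Zero-force dye separation ``b*n + c`` in nm."""
        return self.b * self.n + self.c

    @property
    def e0(self) -> float:
        """FRET efficiency of the collapsed (zero-force) sensor."""
        return float(efficiency_from_separation(self.r0, self.R0))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "SensorCalibration":
        """Build a calibration from config keys ``a, b, c, n, R0``."""
        kwargs = {k: mapping[k] for k in ("a", "b", "c", "n", "R0") if k in mapping}
        if "n" in kwargs:
            kwargs["n"] = int(kwargs["n"])
        return cls(**kwargs)


def _require_positive(x: np.ndarray, name: str) -> None:
    if np.any(np.asarray(x) <= 0):
        raise ValueError(f"{name} must be strictly positive")


def force_from_separation(r, calib: SensorCalibration = SensorCalibration()):
    """Force (pN) exerted on the sensor at dye separation ``r`` (nm).

    Linear entropic-spring law ``F = (r - b*n - c) / (a*n)``.  Separations
    below the zero-force separation yield negative forces; clamping is left
    to the caller (the force-PDF stage clips densities, not values).
    """
    r = np.asarray(r, dtype=float)
    _require_positive(r, "dye separation r")
    out = (r - calib.b * calib.n - calib.c) / (calib.a * calib.n)
    return out if out.ndim else float(out)


def separation_from_force(force, calib: SensorCalibration = SensorCalibration()):
    """Dye separation (nm) at force ``force`` (pN); inverse of the spring law."""
    force = np.asarray(force, dtype=float)
    out = calib.a * calib.n * force + calib.b * calib.n + calib.c
    return out if out.ndim else float(out)


def efficiency_from_separation(r, R0: float = SensorCalibration.R0):
    """FRET efficiency at dye separation ``r``: ``1 / (1 + (r/R0)**6)``."""
    r = np.asarray(r, dtype=float)
    _require_positive(r, "dye separation r")
    _require_positive(R0, "Foerster radius R0")
    out = 1.0 / (1.0 + (r / R0) ** 6)
    return out if out.ndim else float(out)


def separation_from_efficiency(E, R0: float = SensorCalibration.R0):
    """Dye separation (nm) at efficiency ``E``: ``R0 * (1/E - 1)**(1/6)``.

    Closed-form inverse of the Foerster relation, valid for ``0 < E < 1``.
    """
    E = np.asarray(E, dtype=float)
    if np.any((E <= 0) | (E >= 1)):
        raise ValueError("FRET efficiency must lie strictly in (0, 1)")
    _require_positive(R0, "Foerster radius R0")
    out = R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
    return out if out.ndim else float(out)


def force_from_efficiency(E, calib: SensorCalibration = SensorCalibration()):
    """Force (pN) from FRET efficiency via the closed-form inverse map.

    Strictly decreasing in ``E``; negative for efficiencies above the
    zero-force efficiency ``calib.e0``.
    """
    r = separation_from_efficiency(E, calib.R0)
    return force_from_separation(r, calib)


def efficiency_from_force(force, calib: SensorCalibration = SensorCalibration()):
    """FRET efficiency of a sensor under ``force`` pN (forward map)."""
    return efficiency_from_separation(separation_from_force(force, calib), calib.R0)


def dE_dF(force, calib: SensorCalibration = SensorCalibration()):
    """Analytic derivative dE/dF at the given force(s), in 1/pN (negative)."""
    force = np.asarray(force, dtype=float)
    r = separation_from_force(force, calib)
    E = efficiency_from_separation(r, calib.R0)
    # dE/dr = -6 r^5 / R0^6 * E^2 ; dr/dF = a*n
    out = -6.0 * r**5 / calib.R0**6 * E**2 * (calib.a * calib.n)
    return out if out.ndim else float(out)


def uncertainty_profile(
    calib: SensorCalibration = SensorCalibration(),
    delta_E: float = 0.005,
    F_max: float = 9.0,
    n_grid: int = 100,
):
    """Force-uncertainty profile over an evenly spaced force grid.

    Maps ``n_grid`` forces on [0, F_max] to efficiencies ``E_i`` and computes
    ``dF_i = F(E_i - delta_E) - F_i``, i.e. the force error caused by an
    efficiency measurement biased low by ``delta_E``.

    Returns
    -------
    forces, delta_F : ndarray
        The force grid and the per-grid-point uncertainty, both in pN.
    """
    if delta_E < 0:
        raise ValueError("delta_E must be >= 0")
    if not F_max > 0:
        raise ValueError("F_max must be > 0")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    forces = np.linspace(0.0, F_max, n_grid)
    E = efficiency_from_force(forces, calib)
    shifted = E - delta_E
    if np.any(shifted <= 0):
        raise ValueError(
            "delta_E pushes grid efficiencies to <= 0; reduce delta_E or F_max"
        )
    delta_F = force_from_efficiency(shifted, calib) - forces
    return forces, delta_F


def propagate_uncertainty(
    calib: SensorCalibration = SensorCalibration(),
    delta_E: float = 0.005,
    F_max: float = 9.0,
    n_grid: int = 100,
) -> float:
    """Maximum force uncertainty (pN) over the [0, F_max] grid.

    Headline accuracy figure of the sensor: with the default calibration and
    an efficiency uncertainty of 0.005 the result stays below 0.15 pN for
    tensions up to 9 pN.
    """
    _, delta_F = uncertainty_profile(calib, delta_E, F_max, n_grid)
    return float(np.max(delta_F))
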