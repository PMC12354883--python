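"""Declarative run configuration for the analysis pipeline.

A single YAML file holds every tunable parameter with the package defaults
pre-filled (false-positive rate f = 0.05, ASH range -0.5..1.5 with 40
shifts, fit window > 0.75, width-scaling anchor 0.87, reduced-radius
threshold 0.35 um/s^0.5, minimum track length 5, 1000 bootstrap and 9999
permutation resamples).  A run's config is embedded verbatim in its result
bundle, so every output is reproducible from the bundle alone.

Note the anchor efficiency (0.87) is deliberately a constant independent of
the calibration's zero-force efficiency (~0.877): it anchors the width
scaling of the measured no-force peak, whose mode need not coincide exactly
with the nominal calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .calibration import SensorCalibration
from .synthetic import EmissionModel, MotionModel, SyntheticScenario

__all__ = ["FilterParams", "AnalysisParams", "QCGates", "RunConfig"]


@dataclass(frozen=True)
class FilterParams:
    """Preprocessing filter settings (see :mod:`smforce.preprocessing`)."""

    min_track_length: int = 5
    efficiency_range: tuple = (-0.5, 1.5)
    stoichiometry_range: tuple = (0.3, 0.7)
    neighbor_radius_um: float = 0.8
    single_emitter_z_threshold: float = 4.0


@dataclass(frozen=True)
class AnalysisParams:
    """Force/mobility/statistics analysis settings."""

    false_positive_rate: float = 0.05
    ash_range: tuple = (-0.5, 1.5)
    ash_shifts: int = 40
    fit_window_lo: float = 0.75
    anchor_efficiency: float = 0.87
    pdf_mass_floor: float = 1e-3
    n_bootstrap: int = 1000
    n_permutations: int = 9999
    reduced_radius_threshold: float = 0.35
    min_observations: int = 5


@dataclass(frozen=True)
class QCGates:
    """Numeric QC gate thresholds (see :func:`smforce.pipeline.qc_evaluate`)."""

    no_cell_force_absence: float = 0.02
    positive_control_min_fraction: float = 0.04
    mobile_fraction_min: float = 0.5
    no_cell_immobile_max: float = 0.1


@dataclass
class RunConfig:
    """Full configuration of one simulate -> preprocess -> analyze run."""

    calibration: SensorCalibration = field(default_factory=SensorCalibration)
    emission: EmissionModel = field(default_factory=EmissionModel)
    motion: MotionModel = field(default_factory=MotionModel)
    cell_scenario: SyntheticScenario = field(
        default_factory=lambda: SyntheticScenario(
            n_tracks=300,
            phi_force=0.1,
            force_pN=5.0,
            phi_immobile=0.3,
            cell_present=True,
        )
    )
    no_cell_scenario: SyntheticScenario = field(
        default_factory=lambda: SyntheticScenario(
            n_tracks=300, phi_force=0.0, phi_immobile=0.0, cell_present=False
        )
    )
    filters: FilterParams = field(default_factory=FilterParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    qc_gates: QCGates = field(default_factory=QCGates)
    seed: int = 0
    positive_control: bool = False

    def __post_init__(self) -> None:
        # the scenario seeds derive from the run seed so a single integer
        # pins every random stream
        self.cell_scenario = SyntheticScenario(
            **{**asdict(self.cell_scenario), "seed": self.seed * 2 + 1}
        )
        self.no_cell_scenario = SyntheticScenario(
            **{**asdict(self.no_cell_scenario), "seed": self.seed * 2 + 2}
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, key, **extra):
            sub = dict(d.get(key) or {})
            sub.update(extra)
            for tkey in ("efficiency_range", "stoichiometry_range", "ash_range"):
                if tkey in sub and sub[tkey] is not None:
                    sub[tkey] = tuple(sub[tkey])
            return klass(**sub)

        return cls(
            calibration=build(SensorCalibration, "calibration"),
            emission=build(EmissionModel, "emission"),
            motion=build(MotionModel, "motion"),
            cell_scenario=build(SyntheticScenario, "cell_scenario"),
            no_cell_scenario=build(SyntheticScenario, "no_cell_scenario"),
            filters=build(FilterParams, "filters"),
            analysis=build(AnalysisParams, "analysis"),
            qc_gates=build(QCGates, "qc_gates"),
            seed=int(d.get("seed", 0)),
            positive_control=bool(d.get("positive_control", False)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
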