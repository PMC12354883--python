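"""Synthetic single-molecule trajectory and binding-event generators.

The generators emulate the statistical structure of sensor data on supported
lipid bilayers so that every downstream stage (thresholding, force-PDF
subtraction, mobility classification, permutation tests, lifetime fits) can
be exercised and validated against known ground truth:

* zero-force FRET efficiency noise is Gaussian (``mu0 = 0.865``,
  ``sigma0 = 0.164``, the no-cell distribution of the sensor platform);
* a force-bearing minority has its efficiency mean shifted by the
  calibration map ``E(F)``; force-bearing sensors are always immobilized
  (a freely diffusing anchor cannot sustain a pulling force);
* mobile sensors diffuse freely (default ``D = 0.7 um^2/s``); immobilized
  ones are static up to localization jitter;
* track lengths are geometric (photobleaching-limited observation);
* binding-event durations are the minimum of an exponential bond lifetime
  and a geometric per-frame photobleaching lifetime, discretized to frames.

All randomness flows from a single scenario seed through
``numpy.random.SeedSequence`` spawning, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .calibration import SensorCalibration, efficiency_from_force
from .dataset import TrajectoryDataset, TRAJECTORY_COLUMNS

__all__ = [
    "EmissionModel",
    "MotionModel",
    "SyntheticScenario",
    "LifetimeScenario",
    "generate_force_dataset",
    "generate_lifetime_dataset",
]


@dataclass(frozen=True)
class EmissionModel:
    """Photophysics of one observation.

    mu0, sigma0:
        Mean and SD of the zero-force FRET efficiency distribution.
    total_intensity:
        Mean summed donor+acceptor photon count per observation.
    intensity_noise:
        Log-normal sigma of the total intensity (relative noise).
    """

    mu0: float = 0.865
    sigma0: float = 0.164
    total_intensity: float = 1000.0
    intensity_noise: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.mu0 < 1:
            raise ValueError(f"mu0 must be in (0, 1), got {self.mu0}")
        if not self.sigma0 > 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if not self.total_intensity > 0:
            raise ValueError("total_intensity must be > 0")


@dataclass(frozen=True)
class MotionModel:
    """Lateral motion of sensors on the bilayer.

    D_mobile:
        Diffusion coefficient of freely diffusing sensors, um^2/s.
    immobile_jitter:
        Localization noise SD of immobilized sensors, um.
    frame_interval:
        Time between frames, s.
    """

    D_mobile: float = 0.7
    immobile_jitter: float = 0.02
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if not self.D_mobile > 0:
            raise ValueError("D_mobile must be > 0")
        if self.immobile_jitter < 0:
            raise ValueError("immobile_jitter must be >= 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")


@dataclass(frozen=True)
class SyntheticScenario:
    """One simulated force-measurement condition.

    phi_force tracks bear a constant force ``force_pN``; they are a subset of
    the phi_immobile immobilized tracks.  Track lengths are geometric with
    mean ``mean_track_length`` (conditioned on >= 1 observation; filtering by
    a minimum length is a downstream concern).
    """

    n_tracks: int = 300
    mean_track_length: float = 10.0
    phi_force: float = 0.0
    force_pN: float = 0.0
    phi_immobile: float = 0.0
    cell_present: bool = False
    field_size_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if not 0 <= self.phi_force <= 1 or not 0 <= self.phi_immobile <= 1:
            raise ValueError("phi_force and phi_immobile must lie in [0, 1]")
        if self.phi_force > self.phi_immobile:
            raise ValueError(
                "phi_force must not exceed phi_immobile: "
                "mobile sensors cannot bear force"
            )
        if self.mean_track_length < 1:
            raise ValueError("mean_track_length must be >= 1")


@dataclass(frozen=True)
class LifetimeScenario:
    """Binding-event durations recorded at several frame intervals."""

    tau_bond: float = 10.0
    p_bleach_per_frame: float = 0.2
    recording_intervals: tuple = (0.5, 1.0, 2.0, 4.0, 8.0)
    n_events_per_interval: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_bond > 0:
            raise ValueError("tau_bond must be > 0")
        if not 0 <= self.p_bleach_per_frame < 1:
            raise ValueError("p_bleach_per_frame must lie in [0, 1)")
        iv = np.asarray(self.recording_intervals, dtype=float)
        if np.any(iv <= 0) or len(set(iv.tolist())) != len(iv):
            raise ValueError("recording intervals must be positive and distinct")
        if self.n_events_per_interval < 1:
            raise ValueError("n_events_per_interval must be >= 1")


def generate_force_dataset(
    scenario: SyntheticScenario,
    emission: EmissionModel = EmissionModel(),
    motion: MotionModel = MotionModel(),
    calib: SensorCalibration = SensorCalibration(),
) -> TrajectoryDataset:
    """Simulate a trajectory dataset for one condition.

    Per-track ground truth (applied force, mobility) is recorded in the
    ``truth_force_pN`` and ``truth_mobile`` columns so downstream estimators
    can be tested for recovery.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_layout, rng_motion, rng_emission = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    n = scenario.n_tracks
    n_immobile = int(round(scenario.phi_immobile * n))
    n_force = int(round(scenario.phi_force * n))
    n_force = min(n_force, n_immobile)
    # immobilized tracks first, the force-bearing ones among them; shuffle ids
    order = rng_layout.permutation(n)
    immobile = np.zeros(n, dtype=bool)
    immobile[order[:n_immobile]] = True
    under_force = np.zeros(n, dtype=bool)
    under_force[order[:n_force]] = True

    p_geom = 1.0 / scenario.mean_track_length
    lengths = rng_layout.geometric(p_geom, size=n)
    starts = rng_layout.uniform(0, scenario.field_size_um, size=(n, 2))

    dt = motion.frame_interval
    step_sd = np.sqrt(2.0 * motion.D_mobile * dt)

    rows = []
    for tid in range(n):
        L = int(lengths[tid])
        frames = np.arange(L)
        if immobile[tid]:
            xy = starts[tid] + rng_motion.normal(
                0.0, motion.immobile_jitter, size=(L, 2)
            )
        else:
            steps = rng_motion.normal(0.0, step_sd, size=(L, 2))
            steps[0] = 0.0
            xy = starts[tid] + np.cumsum(steps, axis=0)

        if under_force[tid]:
            mu = float(efficiency_from_force(scenario.force_pN, calib))
            truth_force = scenario.force_pN
        else:
            mu = emission.mu0
            truth_force = 0.0
        eff = rng_emission.normal(mu, emission.sigma0, size=L)

        total = rng_emission.lognormal(
            np.log(emission.total_intensity), emission.intensity_noise, size=L
        )
        counts = np.maximum(np.rint(total).astype(int), 1)
        p_acc = np.clip(eff, 1e-3, 1.0 - 1e-3)
        i_acceptor = rng_emission.binomial(counts, p_acc).astype(float)
        i_donor = counts - i_acceptor

        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": frames,
                    "time_s": frames * dt,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                    "i_donor": i_donor,
                    "i_acceptor": i_acceptor,
                    "efficiency": eff,
                    "cell_contact": scenario.cell_present,
                    "truth_force_pN": truth_force,
                    "truth_mobile": not immobile[tid],
                }
            )
        )

    data = pd.concat(rows, ignore_index=True)[TRAJECTORY_COLUMNS]
    meta = {
        "scenario": asdict(scenario),
        "emission": asdict(emission),
        "motion": asdict(motion),
        "calibration": asdict(calib),
        "seed": scenario.seed,
    }
    ds = TrajectoryDataset(data, meta, [f"generated {n} synthetic tracks"])
    ds.validate()
    return ds


def generate_lifetime_dataset(scenario: LifetimeScenario) -> pd.DataFrame:
    """Simulate binding-event durations under bleaching + unbinding.

    Each event lasts ``min(ceil(T_bond / dt), K_bleach)`` frames, where
    ``T_bond`` is exponential with mean ``tau_bond`` and ``K_bleach`` is
    geometric with per-frame failure probability ``p_bleach_per_frame``
    (infinite when bleaching is off).  Both processes are competing per-frame
    survival probabilities, so observed frame counts are geometric with
    survival ``exp(-dt/tau_bond) * (1 - p_bleach)``.

    Returns a frame with columns ``interval_s``, ``duration_frames``,
    ``duration_s`` and ``truth_cause`` ("unbind" or "bleach").
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    frames_out, intervals_out, cause_out = [], [], []
    for dt in scenario.recording_intervals:
        n = scenario.n_events_per_interval
        t_bond = rng.exponential(scenario.tau_bond, size=n)
        k_bond = np.maximum(np.ceil(t_bond / dt).astype(int), 1)
        if scenario.p_bleach_per_frame > 0:
            k_bleach = rng.geometric(scenario.p_bleach_per_frame, size=n)
        else:
            k_bleach = np.full(n, np.iinfo(np.int64).max)
        k = np.minimum(k_bond, k_bleach)
        frames_out.append(k)
        intervals_out.append(np.full(n, dt))
        cause_out.append(np.where(k_bond <= k_bleach, "unbind", "bleach"))
    df = pd.DataFrame(
        {
            "interval_s": np.concatenate(intervals_out),
            "duration_frames": np.concatenate(frames_out),
            "truth_cause": np.concatenate(cause_out),
        }
    )
    df["duration_s"] = df["interval_s"] * df["duration_frames"]
    return df
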