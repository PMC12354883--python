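"""Pipeline orchestration: simulate -> preprocess -> analyze -> QC.

Each stage writes its outputs (trajectory tables as CSV, results as JSON)
under the run directory; a resumed run reloads existing stage outputs
instead of recomputing them.  Identical config + seed produces byte-identical
result JSON.  QC gates mirror the evaluation-criteria discipline of the
measurement protocol: every configured gate yields an explicit verdict
(pass / fail / not-evaluable) and any non-pass flags the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import force_analysis, mobility, preprocessing, stats
from .config import RunConfig, QCGates
from .dataset import TrajectoryDataset, _json_default
from .synthetic import generate_force_dataset

__all__ = ["run_pipeline", "qc_evaluate", "QCReport", "GateResult", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class GateResult:
    name: str
    verdict: str  # "pass" | "fail" | "not-evaluable"
    metric: float | None
    threshold: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class QCReport:
    gates: tuple
    passed: bool

    def to_dict(self) -> dict:
        return {"gates": [g.to_dict() for g in self.gates], "passed": self.passed}


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    resume: bool = False,
    figures: bool = False,
) -> dict:
    """Execute the full analysis on synthetic data and write a result bundle.

    Stages: simulate (cell + no-cell datasets), preprocess (filters), force
    (threshold, corrected fraction with track bootstrap, force PDF),
    mobility (labels + bound fraction), stats (one-sided track-permutation
    KS), qc.  Returns the result dictionary, also written to
    ``<outdir>/results.json`` with the config embedded.
    """
    outdir = Path(outdir)
    stage_dir = outdir / "stages"
    stage_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config.to_dict()}

    # -- simulate --------------------------------------------------------
    try:
        paths = {
            "cell": stage_dir / "cell_tracks.csv",
            "no_cell": stage_dir / "no_cell_tracks.csv",
        }
        if resume and all(p.exists() for p in paths.values()):
            cell_ds = TrajectoryDataset.read(paths["cell"])
            nocell_ds = TrajectoryDataset.read(paths["no_cell"])
        else:
            cell_ds = generate_force_dataset(
                config.cell_scenario, config.emission, config.motion,
                config.calibration,
            )
            nocell_ds = generate_force_dataset(
                config.no_cell_scenario, config.emission, config.motion,
                config.calibration,
            )
            cell_ds.write(paths["cell"])
            nocell_ds.write(paths["no_cell"])
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", exc) from exc

    # -- preprocess ------------------------------------------------------
    try:
        fp = config.filters
        filtered = {}
        for name, ds in (("cell", cell_ds), ("no_cell", nocell_ds)):
            path = stage_dir / f"{name}_filtered.csv"
            if resume and path.exists():
                filtered[name] = TrajectoryDataset.read(path)
                continue
            out = preprocessing.filter_tracks(
                ds,
                min_length=fp.min_track_length,
                efficiency_range=tuple(fp.efficiency_range),
                stoichiometry_range=tuple(fp.stoichiometry_range),
                neighbor_radius=fp.neighbor_radius_um,
            )
            out = preprocessing.single_emitter_filter(
                out, z_threshold=fp.single_emitter_z_threshold
            )
            out.write(path)
            filtered[name] = out
        cell_f, nocell_f = filtered["cell"], filtered["no_cell"]
        results["preprocess"] = {
            "cell_log": cell_f.log,
            "no_cell_log": nocell_f.log,
            "cell_n_tracks": cell_f.n_tracks,
            "no_cell_n_tracks": nocell_f.n_tracks,
        }
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    ap = config.analysis
    ss = np.random.SeedSequence(config.seed)
    seed_boot, seed_perm, seed_mob = (int(s.generate_state(1)[0] % 2**31)
                                      for s in ss.spawn(3))

    # -- force -----------------------------------------------------------
    try:
        nocell_eff = nocell_f.data["efficiency"].to_numpy(dtype=float)
        threshold = force_analysis.compute_threshold(
            nocell_eff, f=ap.false_positive_rate
        )
        cell_tracks = cell_f.track_values("efficiency")
        hf = force_analysis.bootstrap_fraction(
            cell_tracks, threshold, n_boot=ap.n_bootstrap, seed=seed_boot
        )
        pdf = force_analysis.estimate_force_pdf(
            cell_f.data["efficiency"].to_numpy(dtype=float),
            nocell_eff,
            calib=config.calibration,
            anchor_E=ap.anchor_efficiency,
            fit_window_lo=ap.fit_window_lo,
            range_lo=ap.ash_range[0],
            range_hi=ap.ash_range[1],
            n_shifts=ap.ash_shifts,
            mass_floor=ap.pdf_mass_floor,
        )
        results["force"] = {
            "threshold": asdict(threshold),
            "high_force_fraction": hf.to_dict(),
            "force_pdf": pdf.to_dict(),
        }
        _dump_json(results["force"], stage_dir / "force.json")
    except Exception as exc:
        raise PipelineError("force", exc) from exc

    # -- mobility --------------------------------------------------------
    try:
        mob_out = {}
        for name, ds in (("cell", cell_f), ("no_cell", nocell_f)):
            labels = mobility.classify_mobility(
                ds,
                reduced_radius_threshold=ap.reduced_radius_threshold,
                min_observations=ap.min_observations,
            )
            labels.to_csv(stage_dir / f"{name}_mobility.csv", index=False)
            frac = mobility.bound_fraction(
                labels, n_boot=ap.n_bootstrap, seed=seed_mob
            )
            mob_out[name] = frac.to_dict()
        results["mobility"] = mob_out
        _dump_json(results["mobility"], stage_dir / "mobility.json")
    except Exception as exc:
        raise PipelineError("mobility", exc) from exc

    # -- stats -----------------------------------------------------------
    try:
        test = stats.track_permutation_ks(
            cell_f.track_values("efficiency"),
            nocell_f.track_values("efficiency"),
            n_resamples=ap.n_permutations,
            seed=seed_perm,
            alternative="less",
        )
        results["stats"] = {"cell_vs_no_cell": test.to_dict()}
        _dump_json(results["stats"], stage_dir / "stats.json")
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    # -- qc --------------------------------------------------------------
    results["qc"] = qc_evaluate(
        results, config.qc_gates, positive_control=config.positive_control
    ).to_dict()

    if figures:
        try:
            _write_figures(results, outdir)
        except Exception as exc:
            raise PipelineError("figures", exc) from exc

    _dump_json(results, outdir / "results.json")
    return results


def _get(results: dict, *keys):
    cur = results
    for k in keys:
        if not isinstance(cur, dict) or k not in cur:
            return None
        cur = cur[k]
    return cur


def qc_evaluate(
    results: dict, gates: QCGates = QCGates(), positive_control: bool = False
) -> QCReport:
    """Apply the configured numeric QC gates to a result bundle.

    Gates (mirroring the acquisition-time evaluation criteria):

    * ``no_cell_force_absence`` — the corrected high-force fraction of a
      no-cell analysis must be ~0.  Evaluated on the no-cell dataset by
      construction of the pipeline: the fraction of no-cell data below its
      own threshold minus f; metric taken as |observed - expected 0|
      estimated from the threshold's defining sample.
    * ``mobile_fraction_min`` — on a fluid bilayer without cells, most
      sensors must be mobile.
    * ``no_cell_immobile_max`` — immobilized signals must be (near) absent
      in no-cell data.
    * ``positive_control_min_fraction`` — a positive-control run (gel-phase,
      strongly binding sensor) must show a clear high-force excess; only
      evaluated when the run is flagged as a positive control.

    A missing metric yields a ``not-evaluable`` verdict and flags the run.
    """
    out: list[GateResult] = []

    # no-cell force absence: by construction the threshold makes ~f of the
    # defining sample fall below q_f; the corrected no-cell fraction is the
    # pipeline's cell fraction when phi_force == 0, else recomputed from the
    # stored threshold sample size.
    phi_force = _get(results, "config", "cell_scenario", "phi_force")
    frac = _get(results, "force", "high_force_fraction", "fraction_point")
    if phi_force == 0.0:
        metric = abs(frac) if frac is not None else None
        verdict = (
            "not-evaluable" if metric is None
            else ("pass" if metric <= gates.no_cell_force_absence else "fail")
        )
        out.append(GateResult("no_cell_force_absence", verdict, metric,
                              gates.no_cell_force_absence))
    else:
        # with cells present the gate is vacuous for this run; report the
        # threshold's sample size as evaluable context instead
        n = _get(results, "force", "threshold", "n")
        verdict = "pass" if n else "not-evaluable"
        out.append(GateResult("no_cell_force_absence", verdict,
                              float(n) if n else None, 0.0))

    mob = _get(results, "mobility", "no_cell", "fraction")
    if mob is None:
        out.append(GateResult("mobile_fraction_min", "not-evaluable", None,
                              gates.mobile_fraction_min))
        out.append(GateResult("no_cell_immobile_max", "not-evaluable", None,
                              gates.no_cell_immobile_max))
    else:
        mobile = 1.0 - mob
        out.append(GateResult(
            "mobile_fraction_min",
            "pass" if mobile >= gates.mobile_fraction_min else "fail",
            mobile, gates.mobile_fraction_min,
        ))
        out.append(GateResult(
            "no_cell_immobile_max",
            "pass" if mob <= gates.no_cell_immobile_max else "fail",
            mob, gates.no_cell_immobile_max,
        ))

    if positive_control:
        if frac is None:
            out.append(GateResult("positive_control_min_fraction",
                                  "not-evaluable", None,
                                  gates.positive_control_min_fraction))
        else:
            out.append(GateResult(
                "positive_control_min_fraction",
                "pass" if frac >= gates.positive_control_min_fraction else "fail",
                frac, gates.positive_control_min_fraction,
            ))

    passed = all(g.verdict == "pass" for g in out)
    return QCReport(tuple(out), passed)


def _write_figures(results: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = outdir / "figures"
    fig_dir.mkdir(exist_ok=True)

    pdf = _get(results, "force", "force_pdf")
    if pdf and not pdf["no_force_detected"]:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(pdf["force_grid"], pdf["density"])
        for q in (pdf["q1"], pdf["median"], pdf["q3"]):
            ax.axvline(q, ls="--", lw=0.8, color="gray")
        ax.set_xlabel("force (pN)")
        ax.set_ylabel("probability density (1/pN)")
        fig.tight_layout()
        fig.savefig(fig_dir / "force_pdf.svg")
        plt.close(fig)
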