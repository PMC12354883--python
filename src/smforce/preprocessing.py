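"""Single-molecule filtering and FRET efficiency / stoichiometry computation.

Implements the standard cleanup contracts applied to single-molecule FRET
trajectory tables before any force analysis:

* corrected FRET efficiency and stoichiometry from donor/acceptor
  intensities, with the usual ALEX-style correction factors (donor
  bleed-through, direct acceptor excitation, detection- and
  excitation-efficiency factors);
* discarding observations with an overlapping same-frame neighbor
  (nearest-neighbor proximity filter);
* discarding tracks shorter than a minimum length (default 5 observations);
* windowing on efficiency and stoichiometry;
* removing multi-emitter signals whose summed intensity shows more than one
  downward bleaching step (binary-segmentation changepoint count).

Every rule logs the number of observations/tracks it removed to the
dataset's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dataset import TrajectoryDataset

__all__ = [
    "FretCorrections",
    "compute_fret",
    "filter_tracks",
    "single_emitter_filter",
    "count_bleaching_steps",
]


@dataclass(frozen=True)
class FretCorrections:
    """ALEX/FRET correction factors.

    bleedthrough:
        Donor emission leaking into the acceptor channel, as a fraction of
        the donor intensity.
    direct_excitation:
        Direct acceptor excitation by the donor laser, as a fraction of the
        acceptor intensity under acceptor excitation.
    detection:
        Detection/quantum-yield factor (gamma) multiplying the donor
        intensity.
    excitation:
        Excitation efficiency factor (beta) normalizing the
        acceptor-excitation intensity in the stoichiometry.

    Identity defaults reduce the efficiency to the proximity ratio
    ``acceptor / (acceptor + donor)``.
    """

    bleedthrough: float = 0.0
    direct_excitation: float = 0.0
    detection: float = 1.0
    excitation: float = 1.0


def compute_fret(
    ds: TrajectoryDataset, corrections: FretCorrections = FretCorrections()
) -> TrajectoryDataset:
    """Fill ``efficiency`` (and ``stoichiometry`` when possible) columns.

    Corrected sensitized emission::

        F_corr = i_acceptor - bleedthrough * i_donor
                 - direct_excitation * i_acceptor_aex

    efficiency ``= F_corr / (detection * i_donor + F_corr)``; stoichiometry
    ``= (detection * i_donor + F_corr) / (detection * i_donor + F_corr +
    i_acceptor_aex / excitation)`` (requires the acceptor-excitation
    intensity column ``i_acceptor_aex``; left NaN otherwise).

    Negative corrected intensities are permitted (noise) but counted in the
    log; observations with a zero denominator are dropped with a log entry.
    """
    out = ds.copy()
    df = out.data
    for col in ("i_donor", "i_acceptor"):
        if col not in df.columns:
            raise ValueError(f"compute_fret requires intensity column {col}")
    aex = (
        df["i_acceptor_aex"].to_numpy(dtype=float)
        if "i_acceptor_aex" in df.columns
        else np.zeros(len(df))
    )
    donor = df["i_donor"].to_numpy(dtype=float)
    acceptor = df["i_acceptor"].to_numpy(dtype=float)

    f_corr = (
        acceptor
        - corrections.bleedthrough * donor
        - corrections.direct_excitation * aex
    )
    n_negative = int(np.count_nonzero(f_corr < 0))
    if n_negative:
        out.append_log(
            f"compute_fret: {n_negative} observations with negative corrected "
            "acceptor intensity (kept, noise)"
        )
    denom = corrections.detection * donor + f_corr
    bad = denom == 0
    eff = np.full(len(df), np.nan)
    eff[~bad] = f_corr[~bad] / denom[~bad]
    df = df.assign(efficiency=eff)
    if "i_acceptor_aex" in df.columns:
        s_denom = denom + aex / corrections.excitation
        stoich = np.full(len(df), np.nan)
        ok = s_denom != 0
        stoich[ok] = denom[ok] / s_denom[ok]
        df = df.assign(stoichiometry=stoich)
    if bad.any():
        df = df.loc[~bad]
        out.append_log(
            f"compute_fret: dropped {int(bad.sum())} observations with zero "
            "total intensity"
        )
    out.data = df.reset_index(drop=True)
    return out


def filter_tracks(
    ds: TrajectoryDataset,
    min_length: int = 5,
    efficiency_range: tuple[float, float] | None = (-0.5, 1.5),
    stoichiometry_range: tuple[float, float] | None = (0.3, 0.7),
    neighbor_radius: float = 0.8,
) -> TrajectoryDataset:
    """Apply the proximity, window and minimum-track-length filters.

    Order: same-frame neighbor removal (both partners of any pair closer
    than ``neighbor_radius`` um are dropped), efficiency/stoichiometry
    windows (each only if the column is present and not all-NaN), then
    removal of tracks with fewer than ``min_length`` observations.  Each
    rule's removal count is appended to the provenance log.
    """
    out = ds.copy()
    df = out.data

    if neighbor_radius > 0 and len(df):
        drop = np.zeros(len(df), dtype=bool)
        positions = df[["x_um", "y_um"]].to_numpy(dtype=float)
        for _, idx in df.groupby("frame").indices.items():
            if len(idx) < 2:
                continue
            tree = cKDTree(positions[idx])
            pairs = tree.query_pairs(neighbor_radius, output_type="ndarray")
            if len(pairs):
                drop[idx[np.unique(pairs.ravel())]] = True
        if drop.any():
            df = df.loc[~drop]
        out.append_log(
            f"filter_tracks/proximity: removed {int(drop.sum())} observations "
            f"with a same-frame neighbor within {neighbor_radius} um"
        )
    else:
        out.append_log("filter_tracks/proximity: skipped (radius 0 or empty)")

    for name, col, window in (
        ("efficiency", "efficiency", efficiency_range),
        ("stoichiometry", "stoichiometry", stoichiometry_range),
    ):
        if window is None or col not in df.columns or df[col].isna().all():
            out.append_log(f"filter_tracks/{name}-window: skipped")
            continue
        vals = df[col].to_numpy(dtype=float)
        keep = np.isnan(vals) | ((vals >= window[0]) & (vals <= window[1]))
        out.append_log(
            f"filter_tracks/{name}-window: removed {int((~keep).sum())} "
            f"observations outside [{window[0]}, {window[1]}]"
        )
        df = df.loc[keep]

    if min_length > 1 and len(df):
        sizes = df.groupby("track_id")["frame"].transform("size")
        keep = sizes >= min_length
        n_tracks_removed = df.loc[~keep, "track_id"].nunique()
        df = df.loc[keep]
        out.append_log(
            f"filter_tracks/min-length: removed {n_tracks_removed} tracks "
            f"shorter than {min_length} observations"
        )

    out.data = df.reset_index(drop=True)
    return out


def count_bleaching_steps(
    intensity, z_threshold: float = 4.0, min_segment: int = 2
) -> int:
    """Number of significant *downward* mean shifts in an intensity trace.

    Binary segmentation: recursively split at the point maximizing the
    two-sample z statistic of the mean difference, accept the split when it
    exceeds ``z_threshold`` noise standard deviations (noise estimated
    robustly from successive differences), and count accepted splits whose
    right-side mean is below the left-side mean.
    """
    y = np.asarray(intensity, dtype=float).ravel()
    n = y.size
    if n < 2 * min_segment:
        return 0
    diffs = np.diff(y)
    noise = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2)
    if noise == 0:
        noise = max(np.std(diffs) / np.sqrt(2), 1e-12)

    steps: list[float] = []

    def split(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 2 * min_segment:
            return
        seg = y[lo:hi]
        best_stat, best_k = 0.0, -1
        for k in range(min_segment, m - min_segment + 1):
            left, right = seg[:k], seg[k:]
            stat = abs(right.mean() - left.mean()) * np.sqrt(
                k * (m - k) / m
            ) / noise
            if stat > best_stat:
                best_stat, best_k = stat, k
        if best_k < 0 or best_stat <= z_threshold:
            return
        steps.append(y[lo + best_k : hi].mean() - y[lo : lo + best_k].mean())
        split(lo, lo + best_k)
        split(lo + best_k, hi)

    split(0, n)
    return sum(1 for s in steps if s < 0)


def single_emitter_filter(
    ds: TrajectoryDataset, z_threshold: float = 4.0, min_track_length: int = 4
) -> TrajectoryDataset:
    """Remove tracks whose summed intensity bleaches in more than one step.

    A single emitter disappears in at most one downward intensity step;
    two or more steps indicate overlapping emitters.  Tracks too short for
    changepoint analysis pass unfiltered (logged).
    """
    out = ds.copy()
    df = out.data
    if "i_donor" not in df.columns or "i_acceptor" not in df.columns:
        raise ValueError("single_emitter_filter requires intensity columns")
    total = df["i_donor"].to_numpy(dtype=float) + df["i_acceptor"].to_numpy(
        dtype=float
    )
    df = df.assign(_total=total)
    removed, too_short = [], 0
    for tid, g in df.groupby("track_id"):
        if len(g) < min_track_length:
            too_short += 1
            continue
        if count_bleaching_steps(g["_total"].to_numpy(), z_threshold) > 1:
            removed.append(tid)
    if too_short:
        out.append_log(
            f"single_emitter_filter: {too_short} tracks too short for "
            "changepoint analysis, passed unfiltered"
        )
    out.append_log(
        f"single_emitter_filter: removed {len(removed)} multi-emitter tracks"
    )
    df = df.loc[~df["track_id"].isin(removed)].drop(columns="_total")
    out.data = df.reset_index(drop=True)
    return out
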