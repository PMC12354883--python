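"""Track-preserving bootstrap helpers.

Observations within a single-molecule track are correlated, so resampling
always moves whole tracks, never individual observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["BootstrapSummary", "summarize_bootstrap", "bootstrap_tracks"]


@dataclass(frozen=True)
class BootstrapSummary:
    """Box-and-whisker style summary of a bootstrap distribution.

    Whiskers follow the 1.5*IQR convention: they extend to the most extreme
    resampled values within 1.5 interquartile ranges of the quartiles.
    ``se`` is the bootstrap standard deviation, reported as standard error.
    """

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    mean: float
    se: float
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_lo": self.whisker_lo,
            "whisker_hi": self.whisker_hi,
            "mean": self.mean,
            "se": self.se,
            "n_boot": self.n_boot,
        }


def summarize_bootstrap(samples: np.ndarray) -> BootstrapSummary:
    samples = np.asarray(samples, dtype=float)
    q1, med, q3 = np.quantile(samples, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    inside = samples[(samples >= q1 - 1.5 * iqr) & (samples <= q3 + 1.5 * iqr)]
    return BootstrapSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        mean=float(samples.mean()),
        se=float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
        n_boot=int(samples.size),
    )


def bootstrap_tracks(
    tracks: Sequence[np.ndarray],
    statistic: Callable[[list[np.ndarray]], float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Resample whole tracks with replacement and recompute ``statistic``.

    Each resample draws ``len(tracks)`` tracks, keeping every track intact.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks to bootstrap")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(tracks)
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        out[b] = statistic([tracks[i] for i in idx])
    return out
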