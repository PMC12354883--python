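"""Track-preserving permutation hypothesis tests for efficiency distributions.

Observations within a single-molecule track are correlated, which rules out
the ordinary two-sample KS test.  Instead, the one-sided KS statistic
(maximum signed difference of empirical CDFs, evaluated at the pooled
sorted unique values) is combined with a permutation scheme that reassigns
*whole tracks* between the two groups, preserving the group track counts.

The default alternative, ``"less"``, states that sample A (e.g. sensors
under T-cells) is stochastically smaller than sample B (cell-free sensors):
TCR-engaged sensors experience force and hence reduced efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "PermutationTestResult",
    "track_permutation_ks",
    "cdf_difference_curve",
    "significance_stars",
]

EXACT_ENUMERATION_LIMIT = 20000


@dataclass(frozen=True)
class PermutationTestResult:
    """Result of a track-preserving one-sided permutation KS test.

    ``p_value`` uses the add-one estimator ``(1 + #{perm >= obs}) /
    (1 + n_resamples)`` for Monte-Carlo resampling, so it is never 0; when
    the number of distinct track assignments is small the null distribution
    is enumerated exactly instead (``method == "exact"``).
    """

    statistic: float
    p_value: float
    n_resamples: int
    seed: int | None
    alternative: str
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "alternative": self.alternative,
            "method": self.method,
            "stars": significance_stars(self.p_value),
        }


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_tracks(sample) -> list[np.ndarray]:
    tracks = [np.asarray(t, dtype=float).ravel() for t in sample]
    tracks = [t[~np.isnan(t)] for t in tracks]
    return [t for t in tracks if t.size]


def _track_cdf_matrix(tracks: list[np.ndarray], grid: np.ndarray) -> np.ndarray:
    # M[t, k] = number of observations in track t that are <= grid[k]
    M = np.empty((len(tracks), grid.size))
    for i, t in enumerate(tracks):
        M[i] = np.searchsorted(np.sort(t), grid, side="right")
    return M


def _stat_from_sums(sa, na, s_tot, n_tot, sign: float) -> np.ndarray:
    # signed max difference of CDFs; sign=+1 -> D+ = max(CDF_A - CDF_B)
    cdf_a = sa / na
    cdf_b = (s_tot - sa) / (n_tot - na)
    diff = sign * (cdf_a - cdf_b)
    return diff.max(axis=-1)


def track_permutation_ks(
    sample_a_tracks,
    sample_b_tracks,
    n_resamples: int = 9999,
    seed: int | None = None,
    alternative: str = "less",
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> PermutationTestResult:
    """One-sided KS permutation test with intact tracks.

    Parameters
    ----------
    sample_a_tracks, sample_b_tracks:
        Sequences of per-track 1-D value arrays.
    alternative:
        ``"less"``: A stochastically smaller than B (statistic
        ``D+ = max_x CDF_A(x) - CDF_B(x)``); ``"greater"``: the reverse.
    exact_limit:
        When the number of distinct track assignments ``C(T, T_A)`` is at
        most this, the null distribution is enumerated exactly.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if n_resamples < 99:
        raise ValueError("n_resamples must be >= 99")
    tracks_a = _as_tracks(sample_a_tracks)
    tracks_b = _as_tracks(sample_b_tracks)
    if len(tracks_a) < 2 or len(tracks_b) < 2:
        raise ValueError("each sample needs at least 2 non-empty tracks")

    sign = 1.0 if alternative == "less" else -1.0
    tracks = tracks_a + tracks_b
    ta, t_tot = len(tracks_a), len(tracks)
    n_assignments = comb(t_tot, ta)
    if n_assignments < 2:
        raise ValueError("not enough tracks for at least 2 distinct permutations")

    grid = np.unique(np.concatenate(tracks))
    M = _track_cdf_matrix(tracks, grid)
    sizes = np.array([t.size for t in tracks])
    s_tot = M.sum(axis=0)
    n_tot = sizes.sum()

    idx_a = np.arange(ta)
    observed = float(
        _stat_from_sums(M[idx_a].sum(axis=0), sizes[idx_a].sum(), s_tot, n_tot, sign)
    )
    tol = 1e-12

    if n_assignments <= exact_limit:
        stats = np.empty(n_assignments)
        for i, idx in enumerate(combinations(range(t_tot), ta)):
            idx = list(idx)
            stats[i] = _stat_from_sums(
                M[idx].sum(axis=0), sizes[idx].sum(), s_tot, n_tot, sign
            )
        p = float(np.count_nonzero(stats >= observed - tol) / n_assignments)
        return PermutationTestResult(
            observed, p, n_assignments, seed, alternative, "exact"
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        idx = rng.permutation(t_tot)[:ta]
        stat = _stat_from_sums(
            M[idx].sum(axis=0), sizes[idx].sum(), s_tot, n_tot, sign
        )
        if stat >= observed - tol:
            count += 1
    p = (1 + count) / (1 + n_resamples)
    return PermutationTestResult(
        observed, float(p), n_resamples, seed, alternative, "monte_carlo"
    )


def cdf_difference_curve(sample_a, sample_b, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """``CDF_A - CDF_B`` evaluated on a shared grid.

    ``sample_a``/``sample_b`` are flat value arrays (pool tracks first);
    with ``grid=None`` the pooled sorted unique values are used, so the
    curve's maximum equals the ``D+`` statistic of
    :func:`track_permutation_ks` on the same data.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if grid is None:
        grid = np.unique(np.concatenate([a, b]))
    else:
        grid = np.asarray(grid, dtype=float)
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return grid, cdf_a - cdf_b
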