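"""Positional bias of spacer categories along oriented CRISPR arrays.

Positions are normalized midpoints: spacer i of n (0-based from the leader
end) sits at (i + 0.5)/n; reverse-oriented arrays are flipped first.
Sliding-window densities use a window of 12% of the array length stepped by
1.5%; region enrichment splits the array into leading/middle/distal thirds
with exact (Clopper-Pearson) binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from crispr_memory.datasets import ArrayRecord
from crispr_memory.errors import ValidationError

__all__ = [
    "PositionalProfile",
    "normalized_positions",
    "sliding_window_density",
    "region_assignment",
    "region_enrichment",
    "eligibility_filter",
    "clopper_pearson",
]

REGIONS = ("leading", "middle", "distal")


@dataclass
class PositionalProfile:
    flag: str
    centers: np.ndarray           # window centers as fractions of array length
    density: np.ndarray           # NaN where the window holds no spacer
    n_in_window: np.ndarray
    n_arrays: int


def normalized_positions(array: ArrayRecord) -> np.ndarray:
    """Normalized spacer midpoints, leader end at 0."""
    if array.orientation == "unknown":
        raise ValidationError(
            f"array {array.array_id} has unknown orientation; ineligible")
    n = array.n_spacers
    pos = (np.arange(n) + 0.5) / n
    if array.orientation == "reverse":
        pos = 1.0 - pos[::-1]
    return pos


def window_centers(width_frac: float, step_frac: float) -> np.ndarray:
    """Window-center grid from w/2 to 1 - w/2, symmetric about 0.5.

    The step is rounded so the windows tile [0, 1] exactly (the grid would
    otherwise stop short of the trailing end and break mirror symmetry).
    """
    if width_frac <= 0:
        raise ValidationError("window width must be > 0")
    if not (0 < step_frac <= width_frac <= 1):
        raise ValidationError("need 0 < step <= width <= 1")
    half = width_frac / 2.0
    n_steps = max(1, round((1.0 - width_frac) / step_frac))
    return np.linspace(half, 1.0 - half, n_steps + 1)


def sliding_window_density(positions: Sequence[float], flags: Sequence[bool],
                           width_frac: float = 0.12, step_frac: float = 0.015,
                           n_arrays: int = 0, flag_name: str = "flag",
                           ) -> PositionalProfile:
    """Fraction of flagged spacers per sliding window, pooled over arrays.

    Windows are [c - w/2, c + w/2), half-open, clipped at the array ends;
    empty windows report NaN density.
    """
    positions = np.asarray(positions, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if positions.shape != flags.shape:
        raise ValidationError("positions and flags must have equal length")
    centers = window_centers(width_frac, step_frac)
    half = width_frac / 2.0
    density = np.full(centers.size, np.nan)
    n_in_window = np.zeros(centers.size, dtype=int)
    for idx, c in enumerate(centers):
        lo = max(0.0, c - half)
        hi = min(1.0 + 1e-12, c + half)
        in_win = (positions >= lo) & (positions < hi)
        n = int(in_win.sum())
        n_in_window[idx] = n
        if n:
            density[idx] = float(flags[in_win].sum()) / n
    return PositionalProfile(flag=flag_name, centers=centers, density=density,
                             n_in_window=n_in_window, n_arrays=n_arrays)


def region_assignment(array: ArrayRecord) -> list[str]:
    """Leading/middle/distal third per spacer by normalized midpoint."""
    out = []
    for p in normalized_positions(array):
        if p < 1.0 / 3.0:
            out.append("leading")
        elif p < 2.0 / 3.0:
            out.append("middle")
        else:
            out.append("distal")
    return out


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if not (0 <= k <= n):
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def region_enrichment(regions: Sequence[str], focal: Sequence[bool],
                      denominator: Sequence[bool] | None = None,
                      level: float = 0.95) -> pd.DataFrame:
    """Per-region focal fraction with exact CIs.

    ``denominator`` restricts the population counted in each region (e.g.
    phage-targeting spacers when the focal predicate is lysogenic-targeting);
    by default every spacer counts. Regions with an empty denominator report
    missing fractions.
    """
    regions = list(regions)
    focal = list(focal)
    if denominator is None:
        denominator = [True] * len(regions)
    rows = []
    for region in REGIONS:
        n = sum(1 for r, d in zip(regions, denominator) if r == region and d)
        k = sum(1 for r, d, f in zip(regions, denominator, focal)
                if r == region and d and f)
        if n == 0:
            rows.append({"region": region, "k": 0, "n": 0, "fraction": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        lo, hi = clopper_pearson(k, n, level)
        rows.append({"region": region, "k": k, "n": n, "fraction": k / n,
                     "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows, columns=["region", "k", "n", "fraction", "ci_lo", "ci_hi"])


def eligibility_filter(arrays: Iterable[ArrayRecord], min_spacers: int = 6,
                       min_arrays_per_subtype: int = 25) -> list[ArrayRecord]:
    """Oriented arrays with >= min_spacers spacers, from subtypes providing
    >= min_arrays_per_subtype such arrays. Unsubtyped arrays are excluded."""
    oriented = [
        rec for rec in arrays
        if rec.orientation != "unknown" and rec.n_spacers >= min_spacers
        and rec.subtype is not None
    ]
    by_subtype: dict[str, int] = {}
    for rec in oriented:
        by_subtype[rec.subtype] = by_subtype.get(rec.subtype, 0) + 1
    return [rec for rec in oriented if by_subtype[rec.subtype] >= min_arrays_per_subtype]
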