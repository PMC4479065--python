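"""Ancestral effective population size from the decay of LD.

Under drift-recombination equilibrium without mutation (Sved 1971), the
expected squared correlation between loci c Morgans apart is

    E(r²) = 1 / (1 + 4 Ne c),

so an observed mean r² at genetic distance c inverts to
Ne = (1/r² - 1) / (4c).  LD at distance c predominantly reflects the
effective size about t = 1/(2c) generations ago, which turns a set of
distance windows into a trajectory of ancestral Ne over time: small
distances probe the distant past, large distances the recent past.

Physical map distances (Mb) are converted to Morgans with a uniform
``cm_per_mb`` factor (default 1 cM/Mb); this conversion is the largest
single assumption of the method and is recorded in every output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ld import correct_r2

__all__ = ["c_for_generation", "ne_from_r2", "default_time_grid", "ne_trajectory"]


def c_for_generation(t: float) -> float:
    """Genetic distance (Morgans) probing Ne ``t`` generations ago: c = 1/(2t)."""
    if t <= 0:
        raise ValueError("t must be positive")
    return 1.0 / (2.0 * t)


def ne_from_r2(mean_r2: float, c: float) -> float:
    """Invert E(r²) = 1/(1 + 4 Ne c) to Ne = (1/r² - 1)/(4c).

    r² >= 1 gives Ne = 0 (complete LD); r² <= 0 is undefined and raises.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    if mean_r2 <= 0:
        raise ValueError("mean r² must be positive to invert the Sved expectation")
    if mean_r2 >= 1:
        return 0.0
    return (1.0 / mean_r2 - 1.0) / (4.0 * c)


def default_time_grid(n_points: int = 21, t_min: float = 5.0,
                      t_max: float = 1500.0) -> np.ndarray:
    """Log-spaced grid of generations ago, 21 points from 5 to 1500."""
    return np.geomspace(t_min, t_max, n_points)


def ne_trajectory(pairs: pd.DataFrame, time_points=None,
                  window_frac: float = 0.10, cm_per_mb: float = 1.0,
                  n_individuals: int | None = None,
                  use_corrected: bool = False) -> pd.DataFrame:
    """Ancestral Ne at each requested time point from an LD pair table.

    For each t: the target genetic distance is c = 1/(2t); pairs whose
    genetic distance (dist_mb * cm_per_mb / 100) lies within
    ``+-window_frac`` of c are averaged and the mean r² inverted.
    Columns: ``t, c_morgan, window_mb_lo, window_mb_hi, n_pairs,
    mean_r2, ne``.  Windows with no pairs, or with mean r² outside
    (0, 1], are emitted with NaN Ne (flagged rather than dropped).

    ``use_corrected`` applies the haplotype-count sampling correction to
    the mean r² before inversion (requires ``n_individuals``).
    """
    if time_points is None:
        time_points = default_time_grid()
    if use_corrected and n_individuals is None:
        raise ValueError("use_corrected requires n_individuals")
    c_pairs = pairs["dist_mb"].to_numpy() * cm_per_mb / 100.0
    r2 = pairs["r2"].to_numpy()
    rows = []
    for t in np.asarray(time_points, dtype=float):
        c = c_for_generation(t)
        lo, hi = c * (1 - window_frac), c * (1 + window_frac)
        sel = (c_pairs >= lo) & (c_pairs <= hi)
        n = int(sel.sum())
        mean_r2 = float(r2[sel].mean()) if n else np.nan
        if n and use_corrected:
            mean_r2 = correct_r2(mean_r2, n_individuals)
        ne = np.nan
        if n and np.isfinite(mean_r2) and mean_r2 > 0:
            ne = ne_from_r2(mean_r2, c)
        rows.append({"t": t, "c_morgan": c,
                     "window_mb_lo": lo * 100.0 / cm_per_mb,
                     "window_mb_hi": hi * 100.0 / cm_per_mb,
                     "n_pairs": n, "mean_r2": mean_r2, "ne": ne})
    return pd.DataFrame(rows).sort_values("t", ignore_index=True)
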