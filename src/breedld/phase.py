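"""Consistency of gametic phase between populations.

For genomic prediction across populations the question is whether a
marker-QTL phase learned in one population transfers to another.  The
proxy computed here is the Pearson correlation, within a distance bin,
of signed r values (sign from composite D, magnitude sqrt(r²)) over the
marker pairs shared by two populations' LD tables.

Signed r is orientation-dependent: flipping which allele a dose column
counts negates it.  Both LD tables must therefore derive from the same
per-marker allele orientation; :func:`shared_pairs` takes the two
orientation registries and refuses to proceed on any mismatch rather
than silently corrupting signs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ld import BinScheme

__all__ = ["shared_pairs", "phase_consistency", "consistency_matrix",
           "OrientationMismatchError"]


class OrientationMismatchError(ValueError):
    """The two populations count different alleles at a shared marker."""


def shared_pairs(ld_a: pd.DataFrame, ld_b: pd.DataFrame,
                 orientation_a: dict[str, str] | None = None,
                 orientation_b: dict[str, str] | None = None) -> pd.DataFrame:
    """Align two LD pair tables on their shared (marker_i, marker_j) pairs.

    Returns columns ``name_i, name_j, dist_mb, r_a, r_b``.  When both
    orientation registries (marker name -> counted allele) are supplied,
    every marker involved in a shared pair must agree, otherwise an
    :class:`OrientationMismatchError` is raised.  A disjoint
    intersection yields an empty frame, not an error.
    """
    merged = ld_a.merge(ld_b, on=["name_i", "name_j"], suffixes=("_a", "_b"))
    if orientation_a is not None and orientation_b is not None and len(merged):
        involved = set(merged["name_i"]) | set(merged["name_j"])
        bad = [m for m in involved
               if orientation_a.get(m) != orientation_b.get(m)]
        if bad:
            raise OrientationMismatchError(
                f"{len(bad)} shared markers counted on different alleles, "
                f"e.g. {sorted(bad)[:5]}")
    if not len(merged):
        return pd.DataFrame(columns=["name_i", "name_j", "dist_mb", "r_a", "r_b"])
    out = merged[["name_i", "name_j", "dist_mb_a", "r_a", "r_b"]].copy()
    return out.rename(columns={"dist_mb_a": "dist_mb"})


def phase_consistency(aligned: pd.DataFrame,
                      bins: BinScheme | None = None,
                      min_pairs: int = 3) -> pd.DataFrame:
    """Per-distance-bin Pearson correlation of signed r between populations.

    Bins with fewer than ``min_pairs`` shared pairs, or with zero
    variance of signed r in either population, are reported with NaN
    correlation (flagged, not dropped).
    """
    bins = bins or BinScheme.default()
    idx = bins.assign(aligned["dist_mb"].to_numpy()) if len(aligned) \
        else np.array([], dtype=int)
    rows = []
    for b, label in enumerate(bins.labels):
        sel = aligned.loc[idx == b]
        corr = np.nan
        if len(sel) >= min_pairs:
            ra = sel["r_a"].to_numpy()
            rb = sel["r_b"].to_numpy()
            if ra.std() > 0 and rb.std() > 0:
                corr = float(np.corrcoef(ra, rb)[0, 1])
        rows.append({"bin": label, "lo_mb": bins.edges[b], "hi_mb": bins.edges[b + 1],
                     "n_pairs": int(len(sel)), "correlation": corr})
    return pd.DataFrame(rows)


def pooled_consistency(aligned: pd.DataFrame, lo_mb: float, hi_mb: float,
                       min_pairs: int = 3) -> float:
    """Correlation of signed r pooling all shared pairs with lo < d <= hi."""
    sel = aligned[(aligned["dist_mb"] > lo_mb) & (aligned["dist_mb"] <= hi_mb)]
    if len(sel) < min_pairs:
        return np.nan
    ra, rb = sel["r_a"].to_numpy(), sel["r_b"].to_numpy()
    if ra.std() == 0 or rb.std() == 0:
        return np.nan
    return float(np.corrcoef(ra, rb)[0, 1])


def consistency_matrix(ld_tables: dict[str, pd.DataFrame],
                       orientations: dict[str, dict[str, str]] | None = None,
                       window_a: tuple[float, float] = (0.0, 0.20),
                       window_b: tuple[float, float] = (0.02, 0.03)) -> pd.DataFrame:
    """Square population-by-population phase-consistency matrix.

    Above the diagonal: pooled correlation over ``window_a`` (default
    distances below 0.20 Mb); below the diagonal: ``window_b`` (default
    0.02-0.03 Mb); 1.0 on the diagonal.
    """
    labels = list(ld_tables)
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            kw = {}
            if orientations is not None:
                kw = {"orientation_a": orientations[a], "orientation_b": orientations[b]}
            aligned = shared_pairs(ld_tables[a], ld_tables[b], **kw)
            mat.loc[a, b] = pooled_consistency(aligned, *window_a)
            mat.loc[b, a] = pooled_consistency(aligned, *window_b)
    return mat
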