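"""Pairwise linkage disequilibrium from unphased genotypes.

With unphased SNP-array data the gametic disequilibrium D cannot be
counted directly from haplotypes.  The composite (Burrows-type) estimator
used here needs only the two-locus genotype classes:

    D = N/(N-1) * [ (4 N_AABB + 2 (N_AABb + N_AaBB) + N_AaBb) / (2N)
                    - 2 f(A) f(B) ]

where N is the number of individuals complete at both loci and N_AABB
etc. are the counts of the double-genotype classes.  Because the
bracketed numerator equals the sum over individuals of the dose product
x*y (doses of A and B), the estimator reduces to half the sample
covariance of the two dose columns — which is how the vectorised table
builders compute it.  From D,

    r² = D² / (f(A) f(a) f(B) f(b)),   signed r = sign(D) * sqrt(r²).

Under random mating (HWE) the composite estimator tracks the true
haplotype r²; the simulator's phased output provides the oracle for
that agreement.  The N/(N-1) factor and non-HWE genotype configurations
can push the ratio above 1, so r² is capped at 1 (the definition's range
is 0-1) and the cap is flagged per pair.

Missing genotypes are handled pairwise-complete: each pair uses only
the individuals called at both markers, and N in the formula is that
complete-observation count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MarkerMap

__all__ = ["BinScheme", "composite_D", "pair_r2", "ld_pairs", "adjacent_ld",
           "ld_decay", "correct_r2", "LDUndefinedError"]


class LDUndefinedError(ValueError):
    """LD undefined: monomorphic locus or fewer than 2 complete individuals."""


# ---------------------------------------------------------------------------
# distance bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Contiguous, non-overlapping distance bins in Mb.

    ``edges`` has one more entry than there are bins; assignment is
    half-open [lo, hi) with ties going to the upper bin, the first bin
    excludes zero distance and the last edge may be ``inf``.
    """

    edges: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing, >= 2 of them")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            out.append(f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}")
        return out

    def assign(self, dist_mb: np.ndarray) -> np.ndarray:
        """Bin index per distance; -1 for distances outside every bin."""
        d = np.asarray(dist_mb, dtype=float)
        idx = np.searchsorted(self.edges, d, side="right") - 1
        idx[(d <= self.edges[0]) | (d >= self.edges[-1])] = -1
        idx[idx == self.n_bins] = -1
        return idx

    @classmethod
    def default(cls) -> "BinScheme":
        """The 20-bin SNP-chip decay scheme.

        One bin below 0.02 Mb, 0.01-Mb bins from 0.02 to 0.1, 0.1-Mb
        bins from 0.1 to 1, one bin from 1 to 1.2, and one open bin
        above 1.2 Mb.
        """
        edges = ([0.0, 0.02] + [round(0.02 + 0.01 * k, 2) for k in range(1, 9)]
                 + [round(0.1 * k, 1) for k in range(2, 11)] + [1.2, np.inf])
        return cls(tuple(edges))


# ---------------------------------------------------------------------------
# scalar estimators
# ---------------------------------------------------------------------------

def composite_D(counts: np.ndarray, n_individuals: int | None = None) -> float:
    """Composite D from a 3x3 two-locus genotype-count table.

    ``counts[i, j]`` is the number of individuals with dose i of allele A
    and dose j of allele B (i, j in 0..2), so ``counts[2, 2]`` = N_AABB,
    ``counts[2, 1]`` = N_AABb, ``counts[1, 2]`` = N_AaBB and
    ``counts[1, 1]`` = N_AaBb.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3, 3):
        raise ValueError("counts must be a 3x3 dose-class table")
    n = c.sum()
    if n_individuals is not None and n_individuals != n:
        raise ValueError(f"N={n_individuals} but counts sum to {n:g}")
    if n < 2:
        raise LDUndefinedError("composite D needs at least 2 individuals")
    doses = np.arange(3, dtype=float)
    sum_x = (c.sum(axis=1) * doses).sum()
    sum_y = (c.sum(axis=0) * doses).sum()
    f_a = sum_x / (2 * n)
    f_b = sum_y / (2 * n)
    if f_a in (0.0, 1.0) or f_b in (0.0, 1.0):
        raise LDUndefinedError("monomorphic locus: D undefined")
    sum_xy = (c * np.outer(doses, doses)).sum()
    return n / (n - 1) * (sum_xy / (2 * n) - 2 * f_a * f_b)


def pair_r2(doses_i: np.ndarray, doses_j: np.ndarray) -> tuple[float, float, float]:
    """(D, signed r, r²) for one marker pair, pairwise-complete.

    r² is capped at 1; signed r = sign(D) * sqrt(capped r²).  Raises
    :class:`LDUndefinedError` when fewer than 2 individuals are complete
    at both markers or either marker is monomorphic in that subset.
    """
    x = np.asarray(doses_i, dtype=float)
    y = np.asarray(doses_j, dtype=float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise LDUndefinedError("fewer than 2 pairwise-complete individuals")
    f_a = x.sum() / (2 * n)
    f_b = y.sum() / (2 * n)
    if f_a in (0.0, 1.0) or f_b in (0.0, 1.0):
        raise LDUndefinedError("monomorphic in the pairwise-complete subset")
    d = n / (n - 1) * ((x * y).sum() / (2 * n) - 2 * f_a * f_b)
    r2 = d * d / (f_a * (1 - f_a) * f_b * (1 - f_b))
    r2 = min(r2, 1.0)
    r = np.sign(d) * np.sqrt(r2)
    return float(d), float(r), float(r2)


def correct_r2(r2, n_individuals: int):
    """Small-sample correction (r² - 1/N)/(1 - 1/N), N = 2 * individuals.

    N counts haplotypes (chromosomes).  The result is floored at 0.
    Accepts scalars or arrays.
    """
    n_hap = 2 * n_individuals
    if n_hap < 2:
        raise ValueError("need at least one individual (N = 2n >= 2)")
    out = (np.asarray(r2, dtype=float) - 1.0 / n_hap) / (1.0 - 1.0 / n_hap)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(r2) else out


# ---------------------------------------------------------------------------
# vectorised pair tables
# ---------------------------------------------------------------------------

def ld_pairs(genotypes: GenotypeMatrix, markers: MarkerMap,
             max_dist_mb: float = 15.0, min_n: int = 2) -> pd.DataFrame:
    """All same-chromosome marker pairs within ``max_dist_mb``.

    Returns a long-format table (the LD pair table consumed by the
    decay, phase and Ne analyses) with columns ``chrom, name_i, name_j,
    dist_mb, n, D, r, r2, capped``.  Pairs that are monomorphic in their
    pairwise-complete subset or have fewer than ``min_n`` complete
    individuals are skipped.
    """
    doses = genotypes.doses
    valid = (doses >= 0)
    z = np.where(valid, doses, 0).astype(np.float64)
    v = valid.astype(np.float64)
    z2 = z * z

    frames = []
    for chrom in markers.chromosomes():
        idx = markers.indices_of(chrom)
        pos = markers.pos[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        m = len(idx)
        if m < 2:
            continue
        zc, vc, z2c = z[:, idx], v[:, idx], z2[:, idx]
        names = markers.name[idx]
        max_bp = max_dist_mb * 1e6
        cols: dict[str, list] = {k: [] for k in
                                 ("name_i", "name_j", "dist_mb", "n", "D", "r", "r2", "capped")}
        for a in range(m - 1):
            hi = int(np.searchsorted(pos, pos[a] + max_bp, side="right"))
            if hi <= a + 1:
                continue
            js = slice(a + 1, hi)
            n_ab = vc[:, a] @ vc[:, js]
            sx = zc[:, a] @ vc[:, js]
            sy = vc[:, a] @ zc[:, js]
            sxy = zc[:, a] @ zc[:, js]
            with np.errstate(divide="ignore", invalid="ignore"):
                f_a = sx / (2 * n_ab)
                f_b = sy / (2 * n_ab)
                d = n_ab / (n_ab - 1) * (sxy / (2 * n_ab) - 2 * f_a * f_b)
                denom = f_a * (1 - f_a) * f_b * (1 - f_b)
                r2 = d * d / denom
            keep = ((n_ab >= max(min_n, 2)) & (f_a > 0) & (f_a < 1)
                    & (f_b > 0) & (f_b < 1))
            if not keep.any():
                continue
            capped = r2 > 1.0
            r2 = np.minimum(r2, 1.0)
            r = np.sign(d) * np.sqrt(r2)
            w = np.flatnonzero(keep)
            cols["name_i"].append(np.repeat(names[a], len(w)))
            cols["name_j"].append(names[a + 1:hi][w])
            cols["dist_mb"].append((pos[a + 1:hi][w] - pos[a]) / 1e6)
            cols["n"].append(n_ab[w].astype(np.int64))
            cols["D"].append(d[w])
            cols["r"].append(r[w])
            cols["r2"].append(r2[w])
            cols["capped"].append(capped[w])
        if cols["name_i"]:
            df = pd.DataFrame({k: np.concatenate(vs) for k, vs in cols.items()})
            df.insert(0, "chrom", chrom)
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "name_i", "name_j", "dist_mb",
                                     "n", "D", "r", "r2", "capped"])
    return pd.concat(frames, ignore_index=True)


def adjacent_ld(genotypes: GenotypeMatrix, markers: MarkerMap) -> pd.DataFrame:
    """Mean r² and mean distance between consecutive markers.

    One row per chromosome plus an "overall" row; pairs skipped by the
    estimator (monomorphic subset, too few complete individuals) are
    excluded from both the r² mean and the distance mean.  Chromosomes
    with fewer than 2 markers are omitted.
    """
    rows = []
    all_r2, all_d = [], []
    for chrom in markers.chromosomes():
        idx = markers.indices_of(chrom)
        pos = markers.pos[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        if len(idx) < 2:
            continue
        r2s, dists = [], []
        for a in range(len(idx) - 1):
            try:
                _, _, r2 = pair_r2(genotypes.doses[:, idx[a]],
                                   genotypes.doses[:, idx[a + 1]])
            except LDUndefinedError:
                continue
            r2s.append(r2)
            dists.append((pos[a + 1] - pos[a]) / 1e6)
        if r2s:
            rows.append({"chrom": chrom, "n_pairs": len(r2s),
                         "mean_r2": float(np.mean(r2s)),
                         "mean_dist_mb": float(np.mean(dists))})
            all_r2 += r2s
            all_d += dists
    rows.append({"chrom": "overall", "n_pairs": len(all_r2),
                 "mean_r2": float(np.mean(all_r2)) if all_r2 else np.nan,
                 "mean_dist_mb": float(np.mean(all_d)) if all_d else np.nan})
    return pd.DataFrame(rows)


def ld_decay(genotypes: GenotypeMatrix, markers: MarkerMap,
             bins: BinScheme | None = None,
             max_dist_mb: float = 15.0,
             pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Distance-binned LD decay table: per bin mean r², SD and pair count.

    Every same-chromosome pair within ``max_dist_mb`` lands in exactly
    one bin.  Empty bins are reported with count 0 and NaN mean.  A
    precomputed pair table can be passed to avoid recomputation.
    """
    bins = bins or BinScheme.default()
    if pairs is None:
        pairs = ld_pairs(genotypes, markers, max_dist_mb=max_dist_mb)
    idx = bins.assign(pairs["dist_mb"].to_numpy()) if len(pairs) else np.array([], int)
    rows = []
    for b, label in enumerate(bins.labels):
        sel = pairs.loc[idx == b, "r2"]
        rows.append({"bin": label,
                     "lo_mb": bins.edges[b], "hi_mb": bins.edges[b + 1],
                     "n_pairs": int(len(sel)),
                     "mean_r2": float(sel.mean()) if len(sel) else np.nan,
                     "sd_r2": float(sel.std(ddof=1)) if len(sel) > 1 else np.nan})
    return pd.DataFrame(rows)
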