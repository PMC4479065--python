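"""Genomic relationship matrix and principal components.

The VanRaden genomic relationship matrix over n individuals and m
markers is

    G = (M - 2P)(M - 2P)' / (2 * sum_i p_i (1 - p_i)),

where M is the n x m allele-dose matrix, p_i the frequency of the
counted allele at marker i in the pooled sample, and P the n x m matrix
repeating the p_i row-wise.  Principal components of G give a
structure/breed-composition view of the joint sample.

Two frequency conventions coexist deliberately: centering and scaling
use the pooled (all-populations) frequency, while missing doses are
imputed with 2x the *within-population* frequency — the population the
individual belongs to.  Markers monomorphic in the pooled sample are
dropped (their denominator contribution is zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = ["GMatrix", "PCAResult", "build_G", "pca"]


@dataclass
class GMatrix:
    """Symmetric relationship matrix with the frequencies that built it."""

    values: np.ndarray           # (n, n)
    ids: np.ndarray              # individual ids
    populations: np.ndarray      # population label per individual
    p: np.ndarray                # pooled counted-allele frequency per marker used
    marker_names: np.ndarray     # markers actually used
    imputation: str              # policy record

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PCAResult:
    """Scores (eigenvectors scaled by sqrt(eigenvalue)) and spectrum."""

    scores: np.ndarray            # (n, k)
    eigenvalues: np.ndarray       # (k,), non-increasing
    variance_ratio: np.ndarray    # (k,), fraction of total (non-negative) variance
    ids: np.ndarray
    populations: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{k + 1}" for k in range(self.scores.shape[1])])
        df.insert(0, "population", self.populations)
        df.insert(0, "iid", self.ids)
        return df


def build_G(genotypes: GenotypeMatrix, marker_names: np.ndarray | None = None) -> GMatrix:
    """VanRaden G from a (possibly multi-population) dose matrix.

    Missing doses are imputed as 2x the counted-allele frequency within
    the individual's own population (falling back to the pooled
    frequency if that population has no call at the marker); centering
    and the denominator use pooled frequencies.  Markers monomorphic in
    the pooled sample are dropped with a denominator contribution of 0.
    """
    z = genotypes.doses_float()
    pops = genotypes.samples.population
    names = marker_names if marker_names is not None else np.arange(z.shape[1]).astype(str)

    with np.errstate(invalid="ignore"):
        pooled = np.nanmean(z, axis=0) / 2.0
    poly = np.isfinite(pooled) & (pooled > 0) & (pooled < 1)
    z = z[:, poly]
    pooled = pooled[poly]
    names = np.asarray(names)[poly]
    if z.shape[1] == 0:
        raise ValueError("no polymorphic markers left to build G")

    # within-population imputation of missing entries
    for pop in np.unique(pops):
        rows = pops == pop
        block = z[rows]
        if np.isnan(block).any():
            with np.errstate(invalid="ignore"):
                pop_freq = np.nanmean(block, axis=0) / 2.0
            pop_freq = np.where(np.isfinite(pop_freq), pop_freq, pooled)
            fill = np.broadcast_to(2.0 * pop_freq, block.shape)
            z[rows] = np.where(np.isnan(block), fill, block)

    w = z - 2.0 * pooled
    denom = 2.0 * float((pooled * (1.0 - pooled)).sum())
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry
    return GMatrix(g, genotypes.samples.iid.copy(), pops.copy(), pooled, names,
                   imputation="2*within-population frequency; pooled centering")


def pca(gmat: GMatrix, k: int = 2) -> PCAResult:
    """Top-k eigendecomposition of G with a fixed sign convention.

    Scores are eigenvectors scaled by sqrt(max(eigenvalue, 0)); each
    component's sign is chosen so its largest-magnitude loading is
    positive, making output reproducible bit-for-bit.
    """
    if k > gmat.n:
        raise ValueError(f"k={k} exceeds matrix size {gmat.n}")
    if not np.all(np.isfinite(gmat.values)):
        raise ValueError("non-finite entries in G")
    eigval, eigvec = np.linalg.eigh(gmat.values)
    order = np.argsort(eigval)[::-1][:k]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = eigvec * np.sqrt(np.maximum(eigval, 0.0))
    total = float(np.maximum(np.linalg.eigvalsh(gmat.values), 0.0).sum())
    ratio = np.maximum(eigval, 0.0) / total if total > 0 else np.zeros(k)
    return PCAResult(scores, eigval, ratio, gmat.ids, gmat.populations)
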