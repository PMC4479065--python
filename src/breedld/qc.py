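"""Per-population SNP-array quality control.

Filters follow standard SNP-chip practice for LD studies: minor allele
frequency (with a higher threshold for small samples), SNP call rate, a
1-df chi-square Hardy-Weinberg test, heterozygosity excess (Ho - He),
individual call rate, and restriction to mapped autosomes.  QC is meant
to run within population ("within breed"): call :func:`apply_qc` once
per population so that frequencies and HWE are not confounded by
structure.

Order of application: (1) individuals below the call-rate threshold are
removed; (2) non-autosomal/unmapped markers are removed; (3) per-SNP
statistics are computed on the remaining individuals and SNPs failing
any criterion are removed.  The report counts failures per criterion on
the post-step-2 marker set; a SNP may fail several criteria, so the
unique total is at most the sum of the per-criterion counts.

Missing genotypes are never imputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap

__all__ = ["QCConfig", "QCReport", "AlleleStats", "allele_stats",
           "hwe_chi2", "het_excess", "apply_qc"]


@dataclass
class QCConfig:
    """Thresholds for the per-population filter set.

    ``maf_min`` is typically 0.05 for large samples and 0.15 for small
    ones; ``hwe_p_min`` of 1e-6 removes SNPs with genotyping artifacts;
    ``het_excess_max`` flags SNPs whose observed heterozygosity exceeds
    the Hardy-Weinberg expectation by more than the threshold (a
    paralogous-locus signature).
    """

    maf_min: float = 0.05
    snp_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    het_excess_max: float = 0.15
    ind_call_rate_min: float = 0.90
    autosomes_only: bool = True
    max_autosome: int = 29

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_rate_min", "hwe_p_min",
                     "het_excess_max", "ind_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


class AlleleStats(NamedTuple):
    f_ref: float          # frequency of the counted (reference) allele
    maf: float
    call_rate: float
    n_hom_ref: int        # dose 2
    n_het: int            # dose 1
    n_hom_alt: int        # dose 0
    het_obs: float        # observed heterozygosity among called genotypes


def allele_stats(doses: np.ndarray) -> AlleleStats:
    """Single-column allele/genotype statistics over non-missing entries.

    An all-missing column gets call rate 0 and NaN frequencies (flagged).
    """
    doses = np.asarray(doses)
    called = doses != MISSING
    n = int(called.sum())
    call_rate = n / len(doses) if len(doses) else 0.0
    if n == 0:
        return AlleleStats(np.nan, np.nan, 0.0, 0, 0, 0, np.nan)
    d = doses[called]
    n2 = int((d == 2).sum())
    n1 = int((d == 1).sum())
    n0 = int((d == 0).sum())
    f = (2 * n2 + n1) / (2 * n)
    return AlleleStats(f, min(f, 1 - f), call_rate, n2, n1, n0, n1 / n)


def hwe_chi2(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test from genotype counts.

    Expected counts are n*p², 2npq, n*q² from the observed allele
    frequency; no continuity correction.  A monomorphic locus returns
    (0, 1) so it can never be the reason for HWE exclusion.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("empty genotype table")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def het_excess(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Observed minus expected heterozygosity, Ho - He (He = 2pq)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("empty genotype table")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    return n_het / n - 2 * p * (1 - p)


@dataclass
class QCReport:
    """Accounting of one population's QC pass.

    ``failed_by_criterion`` maps criterion name -> set of marker names
    failing it (computed on the autosomal, post-individual-QC set); the
    bookkeeping identity is
    ``n_remaining = n_input - n_non_autosomal - n_failed_any``.
    """

    population: str
    n_input_snps: int
    n_input_individuals: int
    n_non_autosomal: int
    failed_by_criterion: dict[str, set] = field(default_factory=dict)
    removed_individuals: list = field(default_factory=list)
    n_remaining: int = 0

    @property
    def n_failed_any(self) -> int:
        u: set = set()
        for s in self.failed_by_criterion.values():
            u |= s
        return len(u)

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.failed_by_criterion.items()}

    def to_frame(self) -> pd.DataFrame:
        row = {"population": self.population,
               "n_individuals": self.n_input_individuals,
               "individuals_removed": len(self.removed_individuals),
               "input_snps": self.n_input_snps,
               "non_autosomal": self.n_non_autosomal}
        row.update({f"fail_{k}": v for k, v in self.counts.items()})
        row["fail_any"] = self.n_failed_any
        row["remaining"] = self.n_remaining
        return pd.DataFrame([row])


_CRITERIA = ("maf", "call_rate", "hwe", "het_excess")


def apply_qc(genotypes: GenotypeMatrix, markers: MarkerMap,
             config: QCConfig) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Filter one population's genotypes; returns the survivors and a report.

    The input should be population-homogeneous (QC is within breed).
    An input that filters down to nothing is returned as an explicit
    empty result, not an error.
    """
    pops = set(genotypes.samples.population.tolist())
    pop_label = pops.pop() if len(pops) == 1 else "+".join(sorted(pops))
    report = QCReport(population=pop_label,
                      n_input_snps=genotypes.n_markers,
                      n_input_individuals=genotypes.n_individuals,
                      n_non_autosomal=0)

    # (1) individual call rate
    called = genotypes.doses != MISSING
    ind_cr = called.mean(axis=1) if genotypes.n_markers else np.ones(genotypes.n_individuals)
    keep_ind = ind_cr >= config.ind_call_rate_min
    report.removed_individuals = genotypes.samples.iid[~keep_ind].tolist()
    geno = genotypes.subset_individuals(np.flatnonzero(keep_ind))

    # (2) non-autosomal / unmapped markers
    if config.autosomes_only:
        auto = markers.is_autosomal(config.max_autosome)
    else:
        auto = np.ones(len(markers), dtype=bool)
    report.n_non_autosomal = int((~auto).sum())
    keep_idx = np.flatnonzero(auto)
    geno = geno.subset_markers(keep_idx)
    mk = markers.subset(keep_idx)

    # (3) per-SNP statistics on the remaining individuals
    failed: dict[str, set] = {k: set() for k in _CRITERIA}
    ok = np.ones(geno.n_markers, dtype=bool)
    for j in range(geno.n_markers):
        st = allele_stats(geno.doses[:, j])
        name = mk.name[j]
        if st.call_rate < config.snp_call_rate_min:
            failed["call_rate"].add(name)
        if np.isfinite(st.maf):
            if st.maf < config.maf_min:
                failed["maf"].add(name)
        elif config.maf_min > 0:  # all-missing column: MAF undefined
            failed["maf"].add(name)
        if np.isfinite(st.f_ref) and 0.0 < st.f_ref < 1.0:
            _, p = hwe_chi2(st.n_hom_ref, st.n_het, st.n_hom_alt)
            if p < config.hwe_p_min:
                failed["hwe"].add(name)
            if het_excess(st.n_hom_ref, st.n_het, st.n_hom_alt) > config.het_excess_max:
                failed["het_excess"].add(name)
        if name in failed["call_rate"] or name in failed["maf"] \
                or name in failed["hwe"] or name in failed["het_excess"]:
            ok[j] = False
    report.failed_by_criterion = failed
    keep = np.flatnonzero(ok)
    report.n_remaining = len(keep)
    return geno.subset_markers(keep), mk.subset(keep), report
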