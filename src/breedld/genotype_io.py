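"""Genotype containers and PLINK-format input/output.

The canonical in-memory representation used throughout the package is a
triplet of :class:`GenotypeMatrix` (individuals x markers allele-dose
matrix), :class:`MarkerMap` (chromosome, base-pair position and name per
marker) and :class:`SampleTable` (individual ids and population labels).

Doses count copies of a *reference allele* recorded per marker: 0, 1 or 2,
with missing genotypes encoded by the sentinel ``MISSING`` (-1).  The
reference allele is the allele listed first in a .bim file (A1) or the
first allele encountered in a .ped file.  Squared LD (r²) is invariant to
this orientation but signed r is not, so the orientation is stored
explicitly and must be shared across populations before signed statistics
are compared (see :mod:`breedld.phase`).

Both PLINK dialects are supported: text .ped/.map and binary
.bed/.bim/.fam (SNP-major, standard magic bytes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: PLINK .bed magic bytes followed by the SNP-major flag.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> dose of allele A1 (reference).
# 00 = hom A1 (dose 2), 01 = missing, 10 = het, 11 = hom A2 (dose 0)
_BED_CODE_TO_DOSE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSE_TO_BED_CODE = {2: 0b00, 1: 0b10, 0: 0b11, int(MISSING): 0b01}


class PlinkParseError(ValueError):
    """Raised for malformed PLINK input; the message names marker/line."""


@dataclass
class MarkerMap:
    """Per-marker chromosome code, 1-based bp position and unique name.

    Chromosome codes are stored as strings so that autosome numbers and
    sex/unmapped codes ("X", "0", ...) coexist; autosomes are the codes
    "1".."max_autosome" (29 for goat).
    """

    chrom: np.ndarray  # str
    pos: np.ndarray  # int64, base pairs, 1-based
    name: np.ndarray  # str

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.name = np.asarray(self.name, dtype=str)
        if not (len(self.chrom) == len(self.pos) == len(self.name)):
            raise ValueError("MarkerMap field lengths differ")
        if len(np.unique(self.name)) != len(self.name):
            raise ValueError("duplicate marker names in MarkerMap")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        """Chromosome codes in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return [self.chrom[i] for i in np.sort(idx)]

    def indices_of(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == str(chrom))

    def is_autosomal(self, max_autosome: int = 29) -> np.ndarray:
        """Boolean mask of markers on autosomes 1..max_autosome with pos > 0."""
        auto = {str(c) for c in range(1, max_autosome + 1)}
        mask = np.fromiter((c in auto for c in self.chrom), dtype=bool, count=len(self))
        return mask & (self.pos > 0)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[idx], self.pos[idx], self.name[idx])

    def validate_sorted(self) -> None:
        """Check positions strictly increase within each chromosome."""
        for c in self.chromosomes():
            p = self.pos[self.indices_of(c)]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")


@dataclass
class SampleTable:
    """Individual identifiers with population labels."""

    iid: np.ndarray  # str
    population: np.ndarray  # str

    def __post_init__(self) -> None:
        self.iid = np.asarray(self.iid, dtype=str)
        self.population = np.asarray(self.population, dtype=str)
        if len(self.iid) != len(self.population):
            raise ValueError("SampleTable field lengths differ")
        if len(np.unique(self.iid)) != len(self.iid):
            raise ValueError("duplicate individual ids")

    def __len__(self) -> int:
        return len(self.iid)

    def subset(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(self.iid[idx], self.population[idx])


@dataclass
class GenotypeMatrix:
    """Allele-dose matrix (individuals x markers), entries in {0,1,2,-1}.

    ``ref_allele[j]``/``alt_allele[j]`` record which allele dose column j
    counts, pinning the orientation of signed LD statistics.
    """

    doses: np.ndarray  # int8 (n_individuals, n_markers)
    samples: SampleTable
    ref_allele: np.ndarray  # str per marker
    alt_allele: np.ndarray  # str per marker

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.int8)
        if self.doses.ndim != 2:
            raise ValueError("doses must be 2-D (individuals x markers)")
        if self.doses.shape[0] != len(self.samples):
            raise ValueError("doses rows != number of samples")
        self.ref_allele = np.asarray(self.ref_allele, dtype=str)
        self.alt_allele = np.asarray(self.alt_allele, dtype=str)
        if len(self.ref_allele) != self.doses.shape[1]:
            raise ValueError("ref_allele length != number of markers")
        valid = (self.doses >= MISSING) & (self.doses <= 2)
        if not valid.all():
            raise ValueError("doses must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.doses.shape[0]

    @property
    def n_markers(self) -> int:
        return self.doses.shape[1]

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.doses[idx], self.samples.subset(idx),
                              self.ref_allele, self.alt_allele)

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.doses[:, idx], self.samples,
                              self.ref_allele[idx], self.alt_allele[idx])

    def orientation(self) -> dict[str, str]:
        """Marker-name -> counted (reference) allele, keyed externally by name."""
        raise NotImplementedError("use orientation_map(genotypes, markers)")

    def doses_float(self) -> np.ndarray:
        """float64 copy with missing as NaN."""
        z = self.doses.astype(np.float64)
        z[self.doses == MISSING] = np.nan
        return z


def orientation_map(genotypes: GenotypeMatrix, markers: MarkerMap) -> dict[str, str]:
    """Marker name -> reference (counted) allele, the orientation registry."""
    return dict(zip(markers.name.tolist(), genotypes.ref_allele.tolist()))


# ---------------------------------------------------------------------------
# PLINK text dialect (.ped/.map)
# ---------------------------------------------------------------------------

def _read_map(path: str) -> MarkerMap:
    chroms, names, poss = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            chroms.append(parts[0])
            names.append(parts[1])
            try:
                poss.append(int(parts[3]))
            except ValueError as exc:
                raise PlinkParseError(f"{path}:{lineno}: bad position {parts[3]!r}") from exc
    return MarkerMap(np.array(chroms), np.array(poss), np.array(names))


def _read_ref_sidecar(path: str, markers: MarkerMap):
    """Optional ``<prefix>.ref`` file pinning per-marker allele orientation.

    The text .ped/.map dialect carries no allele order, so without this
    sidecar the reference allele is whichever is encountered first and a
    write/read cycle may flip dose orientation at some markers.  The
    writer emits the sidecar (marker, ref, alt per line); standard tools
    simply ignore it.
    """
    ref = np.full(len(markers), "", dtype=object)
    alt = np.full(len(markers), "", dtype=object)
    if not os.path.exists(path):
        return ref, alt
    idx = {n: j for j, n in enumerate(markers.name)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3 or parts[0] not in idx:
                raise PlinkParseError(f"{path}:{lineno}: bad orientation line")
            j = idx[parts[0]]
            ref[j], alt[j] = parts[1], parts[2]
    return ref, alt


def _read_ped(path: str, markers: MarkerMap, ref=None, alt=None):
    n_mark = len(markers)
    iids, fids, rows = [], [], []
    # allele registry per marker: first-seen allele is the reference
    # unless a .ref sidecar pinned the orientation
    if ref is None:
        ref = np.full(n_mark, "", dtype=object)
        alt = np.full(n_mark, "", dtype=object)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mark:
                raise PlinkParseError(
                    f"{path}:{lineno}: expected {6 + 2 * n_mark} fields, got {len(parts)}")
            fids.append(parts[0])
            iids.append(parts[1])
            alleles = parts[6:]
            doses = np.full(n_mark, MISSING, dtype=np.int8)
            for j in range(n_mark):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    continue
                for a in (a1, a2):
                    if a == ref[j] or a == alt[j]:
                        continue
                    if ref[j] == "":
                        ref[j] = a
                    elif alt[j] == "":
                        alt[j] = a
                    else:
                        raise PlinkParseError(
                            f"{path}:{lineno}: marker {markers.name[j]}: "
                            f"third allele {a!r} (have {ref[j]!r}/{alt[j]!r})")
                doses[j] = (a1 == ref[j]) + (a2 == ref[j])
            rows.append(doses)
    # monomorphic markers may have no alt allele observed
    alt[alt == ""] = "0"
    ref[ref == ""] = "0"
    samples = SampleTable(np.array(iids), np.array(fids))
    geno = GenotypeMatrix(np.array(rows, dtype=np.int8), samples,
                          ref.astype(str), alt.astype(str))
    return geno, samples


# ---------------------------------------------------------------------------
# PLINK binary dialect (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

def _read_bim(path: str):
    chroms, names, poss, a1s, a2s = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise PlinkParseError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            chroms.append(parts[0])
            names.append(parts[1])
            poss.append(int(parts[3]))
            a1s.append(parts[4])
            a2s.append(parts[5])
    markers = MarkerMap(np.array(chroms), np.array(poss), np.array(names))
    return markers, np.array(a1s, dtype=str), np.array(a2s, dtype=str)


def _read_fam(path: str) -> SampleTable:
    fids, iids = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise PlinkParseError(f"{path}:{lineno}: expected >=2 fields")
            fids.append(parts[0])
            iids.append(parts[1])
    return SampleTable(np.array(iids), np.array(fids))


def _read_bed(path: str, n_ind: int, n_mark: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PlinkParseError(f"{path}: bad magic bytes (not SNP-major PLINK .bed)")
    body = raw[3:]
    bytes_per_snp = (n_ind + 3) // 4
    if len(body) != bytes_per_snp * n_mark:
        raise PlinkParseError(
            f"{path}: size mismatch ({len(body)} body bytes, "
            f"expected {bytes_per_snp * n_mark})")
    body = body.reshape(n_mark, bytes_per_snp)
    # expand each byte into four 2-bit codes, little-end first
    codes = np.empty((n_mark, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n_ind]
    return _BED_CODE_TO_DOSE[codes].T.copy()  # (n_ind, n_mark)


def read_plink(prefix: str):
    """Read a PLINK fileset (either dialect) into the canonical triplet.

    Returns ``(GenotypeMatrix, MarkerMap, SampleTable)``.  Doses count the
    A1 allele of the .bim (binary dialect) or the first allele encountered
    in the .ped (text dialect).
    """
    if os.path.exists(prefix + ".bed"):
        markers, a1, a2 = _read_bim(prefix + ".bim")
        samples = _read_fam(prefix + ".fam")
        doses = _read_bed(prefix + ".bed", len(samples), len(markers))
        geno = GenotypeMatrix(doses, samples, a1, a2)
        return geno, markers, samples
    if os.path.exists(prefix + ".ped"):
        markers = _read_map(prefix + ".map")
        ref, alt = _read_ref_sidecar(prefix + ".ref", markers)
        geno, samples = _read_ped(prefix + ".ped", markers,
                                  ref if ref.any() else None,
                                  alt if ref.any() else None)
        return geno, markers, samples
    raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped")


def write_plink(genotypes: GenotypeMatrix, markers: MarkerMap,
                samples: SampleTable, prefix: str, dialect: str = "bed") -> None:
    """Write a PLINK fileset readable by :func:`read_plink` and standard tools.

    ``dialect`` is "bed" (binary) or "ped" (text).  Refuses to write an
    empty marker set.
    """
    if markers.n_markers == 0:
        raise ValueError("refusing to write PLINK files with no markers")
    if genotypes.doses.shape != (len(samples), len(markers)):
        raise ValueError("genotypes/markers/samples dimensions disagree")
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    if dialect == "bed":
        _write_bim(markers, genotypes, prefix + ".bim")
        _write_fam(samples, prefix + ".fam")
        _write_bed(genotypes.doses, prefix + ".bed")
    elif dialect == "ped":
        _write_map(markers, prefix + ".map")
        _write_ped(genotypes, markers, samples, prefix + ".ped")
        with open(prefix + ".ref", "w") as fh:
            for j in range(len(markers)):
                fh.write(f"{markers.name[j]} {genotypes.ref_allele[j]} "
                         f"{genotypes.alt_allele[j]}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_map(markers: MarkerMap, path: str) -> None:
    with open(path, "w") as fh:
        for c, n, p in zip(markers.chrom, markers.name, markers.pos):
            fh.write(f"{c}\t{n}\t0\t{p}\n")


def _write_ped(genotypes: GenotypeMatrix, markers: MarkerMap,
               samples: SampleTable, path: str) -> None:
    ref, alt = genotypes.ref_allele, genotypes.alt_allele
    with open(path, "w") as fh:
        for i in range(len(samples)):
            fields = [samples.population[i], samples.iid[i], "0", "0", "0", "-9"]
            for j in range(len(markers)):
                d = int(genotypes.doses[i, j])
                if d == int(MISSING):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [ref[j], ref[j]]
                elif d == 1:
                    fields += [ref[j], alt[j]]
                else:
                    fields += [alt[j], alt[j]]
            fh.write(" ".join(fields) + "\n")


def _write_bim(markers: MarkerMap, genotypes: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        for j in range(len(markers)):
            fh.write(f"{markers.chrom[j]}\t{markers.name[j]}\t0\t{markers.pos[j]}\t"
                     f"{genotypes.ref_allele[j]}\t{genotypes.alt_allele[j]}\n")


def _write_fam(samples: SampleTable, path: str) -> None:
    with open(path, "w") as fh:
        for i in range(len(samples)):
            fh.write(f"{samples.population[i]} {samples.iid[i]} 0 0 0 -9\n")


def _write_bed(doses: np.ndarray, path: str) -> None:
    n_ind, n_mark = doses.shape
    bytes_per_snp = (n_ind + 3) // 4
    # index doses+1 in {0,1,2,3} -> codes for doses {-1,0,1,2}
    lut = np.array([_DOSE_TO_BED_CODE[-1], _DOSE_TO_BED_CODE[0],
                    _DOSE_TO_BED_CODE[1], _DOSE_TO_BED_CODE[2]], dtype=np.uint8)
    codes = lut[doses.T.astype(np.int16) + 1]  # (n_mark, n_ind)
    padded = np.zeros((n_mark, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_ind] = codes
    out = np.zeros((n_mark, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    with open(path, "wb") as fh:
        fh.write(_BED_MAGIC)
        out.tofile(fh)


# ---------------------------------------------------------------------------
# Map summaries
# ---------------------------------------------------------------------------

def summarize_map(markers: MarkerMap) -> pd.DataFrame:
    """Per-chromosome marker-map summary plus an "overall" row.

    Columns: chrom, length_mb (max - min position), n_snps, mean_gap_mb,
    sd_gap_mb, longest_gap_mb.  Distances are (pos_j - pos_i)/1e6.
    Single-marker chromosomes get length 0 and NaN gaps (flagged by NaN).
    """
    rows = []
    all_gaps = []
    total_len = 0.0
    total_n = 0
    for c in markers.chromosomes():
        idx = markers.indices_of(c)
        pos = np.sort(markers.pos[idx])
        n = len(pos)
        if n >= 2:
            gaps = np.diff(pos) / 1e6
            length = (pos[-1] - pos[0]) / 1e6
            rows.append({"chrom": c, "length_mb": length, "n_snps": n,
                         "mean_gap_mb": gaps.mean(),
                         "sd_gap_mb": gaps.std(ddof=1) if len(gaps) > 1 else 0.0,
                         "longest_gap_mb": gaps.max()})
            all_gaps.append(gaps)
            total_len += length
        else:
            rows.append({"chrom": c, "length_mb": 0.0, "n_snps": n,
                         "mean_gap_mb": np.nan, "sd_gap_mb": np.nan,
                         "longest_gap_mb": np.nan})
        total_n += n
    gaps = np.concatenate(all_gaps) if all_gaps else np.array([])
    rows.append({"chrom": "overall", "length_mb": total_len, "n_snps": total_n,
                 "mean_gap_mb": gaps.mean() if gaps.size else np.nan,
                 "sd_gap_mb": gaps.std(ddof=1) if gaps.size > 1 else np.nan,
                 "longest_gap_mb": gaps.max() if gaps.size else np.nan})
    return pd.DataFrame(rows)
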