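"""End-to-end orchestration: QC -> LD -> phase -> Ne -> PCA.

Populations are quality-controlled independently (within breed);
cross-population stages (phase consistency, joint PCA) operate on the
intersection of the per-population QC survivor marker sets.  Every stage
writes a CSV-first report table and a run manifest records every
threshold, seed and version so each stage output can be reproduced by
calling the module operations directly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (GenotypeMatrix, MarkerMap, SampleTable,
                          orientation_map, read_plink, summarize_map)
from .ld import BinScheme, adjacent_ld, ld_decay, ld_pairs
from .ne import default_time_grid, ne_trajectory
from .phase import consistency_matrix, phase_consistency, shared_pairs
from .qc import QCConfig, apply_qc
from .structure import build_G, pca

__all__ = ["RunConfig", "PipelineError", "run_all", "merge_populations"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and knobs for a full multi-population run.

    ``populations`` maps population label -> PLINK path prefix (either
    dialect); in-memory data can instead be passed directly to
    :func:`run_all`.  ``qc`` is either one :class:`QCConfig` for all
    populations or a per-population mapping (e.g. MAF 0.05 for the large
    samples, 0.15 for the small ones).
    """

    out_dir: str
    populations: dict[str, str] = field(default_factory=dict)
    qc: QCConfig | dict[str, QCConfig] = field(default_factory=QCConfig)
    bins: BinScheme = field(default_factory=BinScheme.default)
    ne_time_points: tuple = ()
    cm_per_mb: float = 1.0
    max_dist_mb: float = 15.0
    pca_components: int = 2
    seed: int = 0

    def qc_for(self, pop: str) -> QCConfig:
        if isinstance(self.qc, dict):
            return self.qc[pop]
        return self.qc


def merge_populations(data: dict[str, tuple[GenotypeMatrix, MarkerMap]]
                      ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Stack populations on the markers passing QC in every one of them.

    Markers are matched by name; allele orientations must agree (the
    doses count the same allele everywhere) or a ValueError is raised.
    """
    labels = list(data)
    shared: set | None = None
    for geno, markers in data.values():
        names = set(markers.name.tolist())
        shared = names if shared is None else shared & names
    if not shared:
        raise ValueError("no marker passes QC in every population")
    first_geno, first_markers = data[labels[0]]
    first_names = first_markers.name.tolist()
    order = [n for n in first_names if n in shared]
    first_idx = {n: i for i, n in enumerate(first_names)}

    doses_blocks, iids, pops = [], [], []
    ref = None
    for label in labels:
        geno, markers = data[label]
        idx_of = {n: j for j, n in enumerate(markers.name.tolist())}
        cols = np.array([idx_of[n] for n in order])
        block = geno.doses[:, cols]
        this_ref = geno.ref_allele[cols]
        if ref is None:
            ref = this_ref
            alt = geno.alt_allele[cols]
        elif not np.array_equal(ref, this_ref):
            raise ValueError(f"allele orientation differs for population {label!r}")
        doses_blocks.append(block)
        iids.append(geno.samples.iid)
        pops.append(geno.samples.population)
    merged_markers = first_markers.subset(np.array([first_idx[n] for n in order]))
    samples = SampleTable(np.concatenate(iids), np.concatenate(pops))
    geno = GenotypeMatrix(np.vstack(doses_blocks), samples, ref, alt)
    return geno, merged_markers


def run_all(config: RunConfig,
            data: dict[str, tuple[GenotypeMatrix, MarkerMap]] | None = None
            ) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the report tables in memory as well.  Files written:
    ``qc_report.csv, map_summary.csv, adjacent_ld.csv, ld_decay.csv,
    phase_matrix.csv, phase_bins.csv, ne_trajectories.csv,
    pca_scores.csv, manifest.json``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    reports: dict[str, pd.DataFrame] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # ---- load + QC -------------------------------------------------------
    filtered: dict[str, tuple[GenotypeMatrix, MarkerMap]] = {}
    qc_rows, map_rows, adj_rows, decay_rows, ne_rows = [], [], [], [], []
    pair_tables: dict[str, pd.DataFrame] = {}
    orientations: dict[str, dict[str, str]] = {}
    n_used: dict[str, int] = {}

    for pop in (data or config.populations):
        if data is not None:
            geno, markers = data[pop]
        else:
            geno, markers, _ = stage("read")(read_plink, config.populations[pop])
        geno_f, markers_f, report = stage("qc")(apply_qc, geno, markers,
                                                config.qc_for(pop))
        filtered[pop] = (geno_f, markers_f)
        orientations[pop] = orientation_map(geno_f, markers_f)
        n_used[pop] = geno_f.n_individuals
        qc_rows.append(report.to_frame())

        ms = stage("map_summary")(summarize_map, markers_f)
        ms.insert(0, "population", pop)
        map_rows.append(ms)

        adj = stage("adjacent_ld")(adjacent_ld, geno_f, markers_f)
        adj.insert(0, "population", pop)
        adj_rows.append(adj)

        pairs = stage("ld_pairs")(ld_pairs, geno_f, markers_f,
                                  config.max_dist_mb)
        pair_tables[pop] = pairs
        dec = stage("ld_decay")(ld_decay, geno_f, markers_f, config.bins,
                                config.max_dist_mb, pairs=pairs)
        dec.insert(0, "population", pop)
        decay_rows.append(dec)

        tp = config.ne_time_points or default_time_grid()
        tr = stage("ne")(ne_trajectory, pairs, tp,
                         cm_per_mb=config.cm_per_mb,
                         n_individuals=geno_f.n_individuals)
        tr.insert(0, "population", pop)
        ne_rows.append(tr)

    reports["qc_report"] = pd.concat(qc_rows, ignore_index=True)
    reports["map_summary"] = pd.concat(map_rows, ignore_index=True)
    reports["adjacent_ld"] = pd.concat(adj_rows, ignore_index=True)
    reports["ld_decay"] = pd.concat(decay_rows, ignore_index=True)
    reports["ne_trajectories"] = pd.concat(ne_rows, ignore_index=True)

    # ---- phase consistency ----------------------------------------------
    reports["phase_matrix"] = stage("phase")(
        consistency_matrix, pair_tables, orientations)
    bin_rows = []
    labels = list(pair_tables)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            aligned = stage("phase")(shared_pairs, pair_tables[a], pair_tables[b],
                                     orientations[a], orientations[b])
            pc = stage("phase")(phase_consistency, aligned, config.bins)
            pc.insert(0, "pop_b", b)
            pc.insert(0, "pop_a", a)
            bin_rows.append(pc)
    reports["phase_bins"] = (pd.concat(bin_rows, ignore_index=True)
                             if bin_rows else pd.DataFrame())

    # ---- joint PCA -------------------------------------------------------
    joint_geno, joint_markers = stage("merge")(merge_populations, filtered)
    gmat = stage("G")(build_G, joint_geno, joint_markers.name)
    res = stage("pca")(pca, gmat, config.pca_components)
    scores = res.to_frame()
    reports["pca_scores"] = scores

    # ---- write bundle ----------------------------------------------------
    for name, df in reports.items():
        path = os.path.join(config.out_dir, f"{name}.csv")
        df.to_csv(path, index=(name == "phase_matrix"))
    manifest = {
        "package": "breedld",
        "version": __version__,
        "seed": config.seed,
        "cm_per_mb": config.cm_per_mb,
        "max_dist_mb": config.max_dist_mb,
        "bins_mb": list(config.bins.edges[:-1]) + [None if np.isinf(config.bins.edges[-1])
                                                   else config.bins.edges[-1]],
        "ne_time_points": list(map(float, config.ne_time_points
                                   or default_time_grid())),
        "pca_components": config.pca_components,
        "pca_eigenvalues": res.eigenvalues.tolist(),
        "populations": {p: {"n_individuals_used": n_used[p],
                            "qc": vars(config.qc_for(p))} for p in filtered},
        "joint_markers": int(len(joint_markers)),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return reports
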