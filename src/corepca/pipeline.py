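"""End-to-end orchestration: ingest -> map -> representatives -> core ->
fit -> PCA -> annotation analysis, with TSV outputs and a JSON report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment_frame import (
    EnsembleMatrix,
    build_ensemble,
    complete_columns,
    map_to_alignment,
    read_master_alignment,
    write_column_maps_tsv,
)
from .annotation_analysis import (
    point_biserial,
    separation_index,
    write_separation_tsv,
)
from .core_superpose import (
    find_invariant_core,
    fit_on_core,
    write_core_columns_tsv,
    write_core_trace_tsv,
)
from .ensemble_pca import pca, variance_explained, write_pca_tables
from .representatives import select_representatives, write_cluster_report_tsv
from .structure_io import annotate, read_manifest, read_structure

log = logging.getLogger("corepca")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline thresholds and paths; defaults follow the method's choices."""

    manifest: str
    alignment: str
    outdir: str
    cluster_threshold: float = 1.0  # Å, redundancy clustering
    core_volume_cutoff: float = 0.5  # Å³, total ellipsoid-volume stop
    occupancy: float = 1.0  # column-occupancy for the common frame
    identity_gate: float = 0.95  # sequence/row reconciliation gate
    n_components: int = 10
    trajectory_amplitude: float = 2.0  # SD units
    trajectory_frames: int = 15
    n_permutations: int = 9999
    seed: int = 0
    representative_overrides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("cluster_threshold", "core_volume_cutoff", "occupancy",
                     "identity_gate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _subset(ens: EnsembleMatrix, keep: list[str]) -> EnsembleMatrix:
    idx = [ens.index_of(e) for e in keep]
    return EnsembleMatrix(
        entry_ids=list(keep),
        coords=ens.coords[idx].copy(),
        mask=ens.mask[idx].copy(),
    )


def run_pipeline(config: RunConfig, *, until: str = "analyze") -> dict:
    """Run the stages up to and including ``until``; return the report.

    Stage order: ingest, map, representatives, core, pca, analyze. All
    stage outputs (TSV/JSON) land under ``config.outdir``. Any stage
    error aborts with the stage name and the offending entry ids.
    """
    order = ["ingest", "map", "representatives", "core", "pca", "analyze"]
    if until not in order:
        raise ValueError(f"unknown stage {until!r}; choose from {order}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        return t0

    def finish() -> dict:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    # --- ingest -----------------------------------------------------------
    t0 = stage("ingest")
    entries = read_manifest(config.manifest)
    aln = read_master_alignment(config.alignment)
    models, annotations = [], {}
    for entry in entries:
        try:
            model = read_structure(entry.path, entry.entry_id, entry.chain)
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"stage ingest failed for {entry.entry_id}: {exc}")
        models.append(model)
        annotations[entry.entry_id] = annotate(entry, model)
    report["stages"]["ingest"] = {
        "n_entries": len(models),
        "seconds": round(time.perf_counter() - t0, 3),
    }
    if until == "ingest":
        return finish()

    # --- map to alignment columns ----------------------------------------
    t0 = stage("map")
    maps = []
    for model in models:
        row = aln.rows.get(model.entry_id)
        if row is None:
            raise RuntimeError(f"stage map: no alignment row for {model.entry_id}")
        try:
            maps.append(map_to_alignment(model, row, min_identity=config.identity_gate))
        except ValueError as exc:
            raise RuntimeError(f"stage map failed for {model.entry_id}: {exc}")
    ens = build_ensemble(models, maps, aln)
    write_column_maps_tsv(maps, outdir / "column_maps.tsv")
    report["stages"]["map"] = {
        "n_columns": aln.n_columns,
        "seconds": round(time.perf_counter() - t0, 3),
    }
    if until == "map":
        return finish()

    # --- representatives --------------------------------------------------
    t0 = stage("representatives")
    row_seq = {eid: aln.rows[eid].replace("-", "") for eid in ens.entry_ids}
    group_of = {
        eid: (
            row_seq[eid],
            annotations[eid].nucleotide_state,
            annotations[eid].assembly_state,
        )
        for eid in ens.entry_ids
    }
    resolutions = {eid: annotations[eid].resolution for eid in ens.entry_ids}
    reports = select_representatives(
        ens,
        group_of,
        resolutions,
        threshold=config.cluster_threshold,
        overrides=set(config.representative_overrides),
    )
    write_cluster_report_tsv(reports, outdir / "clusters.tsv")
    rep_ids = sorted(eid for r in reports for eid in r.representative_ids)
    reps = _subset(ens, rep_ids)
    report["stages"]["representatives"] = {
        "n_groups": len(reports),
        "n_representatives": len(rep_ids),
        "seconds": round(time.perf_counter() - t0, 3),
    }
    if until == "representatives":
        return finish()

    # --- invariant core ---------------------------------------------------
    t0 = stage("core")
    frame_columns = complete_columns(reps, min_occupancy=config.occupancy)
    trace = find_invariant_core(
        reps, frame_columns, volume_cutoff=config.core_volume_cutoff
    )
    write_core_trace_tsv(trace, outdir / "core_trace.tsv")
    write_core_columns_tsv(trace, outdir / "core_columns.tsv")
    report["stages"]["core"] = {
        "n_frame_columns": len(frame_columns),
        "core_size": len(trace.core),
        "initial_volume": round(trace.initial_volume, 4),
        "cutoff": trace.cutoff,
        "seconds": round(time.perf_counter() - t0, 3),
    }
    if until == "core":
        return finish()

    # --- fit + PCA --------------------------------------------------------
    t0 = stage("pca")
    fitted, _ = fit_on_core(reps, trace.core)
    res = pca(fitted, frame_columns)
    res_core = pca(fitted, trace.core)
    write_pca_tables(res, outdir, n_components=config.n_components)
    k = min(config.n_components, res.n_components)
    report["stages"]["pca"] = {
        "columns": "complete",
        "n_columns": len(frame_columns),
        "eigenvalues": [round(float(v), 6) for v in res.eigenvalues[:k]],
        "proportions": [round(float(v), 6) for v in res.proportions[:k]],
        "cumulative_pc1_2": round(variance_explained(res, min(2, res.n_components)), 6),
        "cumulative_pc1_3": round(variance_explained(res, min(3, res.n_components)), 6),
        "core_column_proportions": [
            round(float(v), 6) for v in res_core.proportions[:k]
        ],
        "seconds": round(time.perf_counter() - t0, 3),
    }
    if until == "pca":
        return finish()

    # --- annotation analysis ---------------------------------------------
    t0 = stage("analyze")
    kk = min(3, res.n_components)
    scores = pd.DataFrame(
        res.scores[:, :kk], columns=[f"PC{i}" for i in range(1, kk + 1)]
    )
    scores.insert(0, "entry_id", res.entry_ids)
    scatter = scores.copy()
    scatter["subfamily"] = [annotations[e].subfamily for e in res.entry_ids]
    scatter["nucleotide_state"] = [
        annotations[e].nucleotide_state for e in res.entry_ids
    ]
    scatter["assembly_state"] = [annotations[e].assembly_state for e in res.entry_ids]
    scatter.to_csv(outdir / "pc_scores_annotated.tsv", sep="\t", index=False)

    separation = {}
    score_cols = scores.drop(columns="entry_id")
    for annot in ("assembly_state", "nucleotide_state", "subfamily"):
        labels = [getattr(annotations[e], annot) for e in res.entry_ids]
        try:
            rep = separation_index(
                score_cols,
                labels,
                annotation=annot,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
        except ValueError as exc:
            separation[annot] = {"error": str(exc)}
            continue
        write_separation_tsv(rep, outdir / f"separation_{annot}.tsv")
        separation[annot] = {
            row["pc"]: {
                "eta_sq": round(row["eta_sq"], 6),
                "p_value": row["p_value"],
                "null_q95": round(row["null_q95"], 6),
            }
            for _, row in rep.table.iterrows()
        }

    binary = [
        e for e in res.entry_ids
        if annotations[e].assembly_state in ("polymerized", "unpolymerized")
    ]
    r_pb = None
    states = [annotations[e].assembly_state for e in binary]
    if len(set(states)) == 2:
        pc1 = scores.set_index("entry_id").loc[binary, "PC1"].to_numpy()
        r_pb = point_biserial(pc1, np.asarray(states, dtype=object))
    report["stages"]["analyze"] = {
        "separation": separation,
        "pc1_assembly_point_biserial_r": round(r_pb, 6) if r_pb is not None else None,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    return finish()
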