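"""Redundancy reduction: RMSD clustering of identically annotated entries.

Entries sharing the same construct sequence, nucleotide state, and
assembly state are complete-linkage clustered on pairwise post-fit Cα
RMSD; each cluster contributes its highest-resolution member (ties:
most built residues, then lexicographic id), unless a manual override
names a different member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment_frame import EnsembleMatrix
from .core_superpose import kabsch

__all__ = ["ClusterReport", "pairwise_rmsd", "cluster_and_pick", "select_representatives"]


def pairwise_rmsd(
    ens: EnsembleMatrix,
    i: int,
    j: int,
    columns: list[int] | None = None,
) -> float:
    """Post-superposition Cα RMSD between two in-frame entries.

    With ``columns`` given, both entries must occupy them all; otherwise
    the shared occupied columns of the pair are used. Fewer than 3
    shared columns is an error.
    """
    if columns is not None:
        idx = np.asarray(columns, dtype=int) - 1
        if not (ens.mask[i, idx].all() and ens.mask[j, idx].all()):
            raise ValueError("both entries must occupy all given columns")
    else:
        idx = np.where(ens.mask[i] & ens.mask[j])[0]
    if len(idx) < 3:
        raise ValueError(f"only {len(idx)} shared columns (need >= 3)")
    return kabsch(ens.coords[i, idx], ens.coords[j, idx]).rmsd


@dataclass
class ClusterReport:
    """Clustering outcome for one identically-annotated group."""

    group_key: tuple
    members: list[str]
    rmsd: np.ndarray  # symmetric (m, m) Å
    clusters: list[list[str]]
    representatives: list[tuple[str, str]]  # (entry_id, reason)
    threshold: float

    @property
    def representative_ids(self) -> list[str]:
        return [eid for eid, _ in self.representatives]


def cluster_and_pick(
    members: list[str],
    rmsd: np.ndarray,
    resolutions: Mapping[str, float | None],
    completeness: Mapping[str, int],
    *,
    group_key: tuple = (),
    threshold: float = 1.0,
    overrides: set[str] | None = None,
) -> ClusterReport:
    """Complete-linkage clustering at ``threshold`` plus representative choice.

    Complete linkage guarantees every cluster's diameter (max pairwise
    RMSD) stays strictly below the threshold. The representative is the
    highest-resolution member (unknown resolution sorts last); ties fall
    to the most built residues, then the lexicographically first id. An
    override id present in a cluster is chosen instead, flagged as such.
    """
    if not members:
        raise ValueError("empty group")
    overrides = overrides or set()
    m = len(members)
    if m == 1:
        clusters = [[members[0]]]
    else:
        condensed = squareform(rmsd, checks=False)
        Z = linkage(condensed, method="complete")
        # cut strictly below threshold so diameters are < threshold
        assignment = fcluster(Z, t=threshold * (1 - 1e-12), criterion="distance")
        clusters = [
            [members[i] for i in range(m) if assignment[i] == c]
            for c in sorted(set(assignment))
        ]

    reps: list[tuple[str, str]] = []
    for cluster in clusters:
        forced = sorted(set(cluster) & overrides)
        if forced:
            reps.append((forced[0], "override"))
            continue

        def quality(eid: str) -> tuple:
            res = resolutions.get(eid)
            return (
                res if res is not None else float("inf"),
                -completeness.get(eid, 0),
                eid,
            )

        ranked = sorted(cluster, key=quality)
        best = ranked[0]
        reason = "resolution"
        if len(ranked) > 1:
            r0, r1 = resolutions.get(ranked[0]), resolutions.get(ranked[1])
            if r0 == r1:
                reason = "completeness"
        reps.append((best, reason))
    return ClusterReport(
        group_key=group_key,
        members=list(members),
        rmsd=rmsd,
        clusters=clusters,
        representatives=reps,
        threshold=threshold,
    )


def select_representatives(
    ens: EnsembleMatrix,
    group_of: Mapping[str, tuple],
    resolutions: Mapping[str, float | None],
    *,
    threshold: float = 1.0,
    overrides: set[str] | None = None,
) -> list[ClusterReport]:
    """Cluster every identically-annotated group of an ensemble.

    ``group_of`` maps entry_id to its (sequence class, nucleotide state,
    assembly state) key. Completeness is the number of occupied columns.
    """
    completeness = {
        eid: int(ens.mask[e].sum()) for e, eid in enumerate(ens.entry_ids)
    }
    groups: dict[tuple, list[str]] = {}
    for eid in ens.entry_ids:
        groups.setdefault(group_of[eid], []).append(eid)

    reports = []
    for key in sorted(groups, key=str):
        members = groups[key]
        m = len(members)
        mat = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                r = pairwise_rmsd(
                    ens, ens.index_of(members[a]), ens.index_of(members[b])
                )
                mat[a, b] = mat[b, a] = r
        reports.append(
            cluster_and_pick(
                members,
                mat,
                resolutions,
                completeness,
                group_key=key,
                threshold=threshold,
                overrides=overrides,
            )
        )
    return reports


def write_cluster_report_tsv(reports: list[ClusterReport], path: str | Path) -> None:
    lines = ["group\tmember\tcluster\tis_representative\treason"]
    for rep in reports:
        rep_map = dict(rep.representatives)
        for ci, cluster in enumerate(rep.clusters, start=1):
            for eid in cluster:
                is_rep = eid in rep_map
                reason = rep_map.get(eid, "")
                lines.append(
                    f"{'|'.join(map(str, rep.group_key))}\t{eid}\t{ci}"
                    f"\t{int(is_rep)}\t{reason}"
                )
    Path(path).write_text("\n".join(lines) + "\n")
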