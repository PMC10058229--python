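"""Annotation-correlation statistics and domain-aligned RMSD comparisons.

Quantifies how position in PC subspace tracks categorical annotations
(subfamily, nucleotide hydrolysis state, polymerization state) via
eta-squared with a permutation null, and computes fit-on-one-domain /
report-on-another RMSD panels for pairs of in-frame structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_superpose import apply_transform, kabsch

__all__ = [
    "SeparationReport",
    "DomainRmsdReport",
    "eta_squared",
    "separation_index",
    "domain_aligned_rmsd",
    "rmsd_matrix",
    "point_biserial",
]

EXCLUDED_LABELS = {"special", "ambiguous", "special/ambiguous"}


def eta_squared(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-group / total variance of a score (0: none, 1: fully determined)."""
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for lab in np.unique(labels):
        grp = values[labels == lab]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
    return float(ss_between / ss_total)


def point_biserial(values: np.ndarray, labels: np.ndarray) -> float:
    """Pearson correlation between a score and a binary label (0/1-coded)."""
    labs = np.unique(labels)
    if len(labs) != 2:
        raise ValueError("point-biserial requires exactly 2 labels")
    x = (np.asarray(labels) == labs[1]).astype(float)
    v = np.asarray(values, dtype=float)
    if v.std() == 0 or x.std() == 0:
        return 0.0
    return float(np.corrcoef(v, x)[0, 1])


@dataclass
class SeparationReport:
    """Per-(PC, annotation) eta-squared with its permutation null."""

    annotation: str
    table: pd.DataFrame  # columns: pc, eta_sq, p_value, null_q95
    group_sizes: dict[Hashable, int]
    n_excluded: int
    n_permutations: int
    seed: int


def separation_index(
    scores: pd.DataFrame,
    labels: Sequence[Hashable],
    *,
    annotation: str = "label",
    n_permutations: int = 9999,
    seed: int = 0,
) -> SeparationReport:
    """How strongly each PC's scores separate the annotation groups.

    ``scores`` has one row per entry and one column per PC. Entries whose
    label is special/ambiguous are excluded from the statistic but
    counted in the report. The permutation null shuffles labels with a
    seeded generator; p-values use the add-one estimator.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(scores):
        raise ValueError("one label per score row required")
    keep = ~np.isin(labels, list(EXCLUDED_LABELS))
    n_excluded = int((~keep).sum())
    sub = scores.loc[keep]
    labs = labels[keep]

    uniq, counts = np.unique(labs, return_counts=True)
    # singleton groups carry no within-group variance information for the
    # permutation test; drop and count them
    small = {u for u, c in zip(uniq, counts) if c < 2}
    if small:
        keep2 = ~np.isin(labs, list(small))
        n_excluded += int((~keep2).sum())
        sub = sub.loc[keep2]
        labs = labs[keep2]
        uniq, counts = np.unique(labs, return_counts=True)
    if len(uniq) < 2:
        raise ValueError(f"need >= 2 annotation groups, got {list(uniq)}")

    rng = np.random.default_rng(seed)
    group_idx = [np.where(labs == u)[0] for u in uniq]
    rows = []
    for pc_name in sub.columns:
        v = sub[pc_name].to_numpy(dtype=float)
        obs = eta_squared(v, labs)
        # permuting labels == permuting values; vectorized over permutations
        V = rng.permuted(np.tile(v, (n_permutations, 1)), axis=1)
        grand = v.mean()
        ss_total = ((v - grand) ** 2).sum()
        if ss_total == 0:
            null = np.zeros(n_permutations)
        else:
            ss_between = sum(
                V[:, idx].sum(axis=1) ** 2 / len(idx) for idx in group_idx
            ) - len(v) * grand**2
            null = ss_between / ss_total
        p = (1 + (null >= obs - 1e-12).sum()) / (n_permutations + 1)
        rows.append(
            {
                "pc": pc_name,
                "eta_sq": obs,
                "p_value": float(p),
                "null_q95": float(np.quantile(null, 0.95)),
                "null_mean": float(null.mean()),
            }
        )
    return SeparationReport(
        annotation=annotation,
        table=pd.DataFrame(rows),
        group_sizes={u: int(c) for u, c in zip(uniq, counts)},
        n_excluded=n_excluded,
        n_permutations=n_permutations,
        seed=seed,
    )


def domain_aligned_rmsd(
    a: Mapping[Hashable, np.ndarray],
    b: Mapping[Hashable, np.ndarray],
    fit_keys: Sequence[Hashable],
    report_keys: Sequence[Hashable],
) -> float:
    """RMSD over one position set after superposing on another.

    ``a`` and ``b`` map position keys (alignment columns; or
    (chain, column) pairs for a concatenated heterodimer; or
    (column, atom-name) for all-shared-atom scope) to 3-vectors. The
    structures are superposed using ``fit_keys`` only; the RMSD is then
    computed over ``report_keys``, which may be a different set — the
    fit-on-one-domain, measure-on-the-other comparison.
    """
    fit_shared = [k for k in fit_keys if k in a and k in b]
    rep_shared = [k for k in report_keys if k in a and k in b]
    if len(fit_shared) < 3:
        raise ValueError(f"only {len(fit_shared)} shared fit positions (need >= 3)")
    if not rep_shared:
        raise ValueError("no shared report positions")
    A_fit = np.array([a[k] for k in fit_shared], dtype=float)
    B_fit = np.array([b[k] for k in fit_shared], dtype=float)
    sup = kabsch(A_fit, B_fit)
    A_rep = np.array([a[k] for k in rep_shared], dtype=float)
    B_rep = apply_transform(np.array([b[k] for k in rep_shared], dtype=float), sup)
    return float(np.sqrt(((A_rep - B_rep) ** 2).sum(axis=1).mean()))


@dataclass
class DomainRmsdReport:
    """All-pairs domain-aligned RMSDs: symmetric, zero diagonal."""

    entry_ids: list[str]
    fit_keys: list
    report_keys: list
    matrix: np.ndarray  # (n, n) Å

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.entry_ids, columns=self.entry_ids)


def rmsd_matrix(
    coords: Mapping[str, Mapping[Hashable, np.ndarray]],
    fit_keys: Sequence[Hashable],
    report_keys: Sequence[Hashable],
) -> DomainRmsdReport:
    """Domain-aligned RMSD between every pair of entries."""
    ids = list(coords)
    if len(ids) < 2:
        raise ValueError("need at least 2 entries")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = domain_aligned_rmsd(coords[ids[i]], coords[ids[j]], fit_keys, report_keys)
            mat[i, j] = mat[j, i] = r
    return DomainRmsdReport(
        entry_ids=ids,
        fit_keys=list(fit_keys),
        report_keys=list(report_keys),
        matrix=mat,
    )


def ensemble_coord_maps(ens, columns=None) -> dict[str, dict[int, np.ndarray]]:
    """Column -> Cα maps for every ensemble entry (occupied columns only)."""
    out: dict[str, dict[int, np.ndarray]] = {}
    cols = columns if columns is not None else range(1, ens.n_columns + 1)
    for e, eid in enumerate(ens.entry_ids):
        out[eid] = {
            c: ens.coords[e, c - 1] for c in cols if ens.mask[e, c - 1]
        }
    return out


def write_separation_tsv(rep: SeparationReport, path: str | Path) -> None:
    df = rep.table.copy()
    df.insert(0, "annotation", rep.annotation)
    df["n_excluded"] = rep.n_excluded
    df["n_permutations"] = rep.n_permutations
    df.to_csv(path, sep="\t", index=False)
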