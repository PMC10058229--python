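"""Rigid superposition and invariant-core detection.

The superposition kernel is the closed-form least-squares (Kabsch)
solution with reflection correction. Ensembles are brought into a common
frame by iterated fitting to the evolving column-wise mean. The
structurally invariant core is found by iteratively discarding the
alignment column whose positional scatter — measured as the volume of
its 3x3 covariance ellipsoid — is largest, until the total remaining
volume drops below a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_frame import EnsembleMatrix

__all__ = [
    "SuperpositionResult",
    "CoreTrace",
    "kabsch",
    "apply_transform",
    "rmsd_after_fit",
    "iterative_mean_fit",
    "find_invariant_core",
    "fit_on_core",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid motion mapping a mobile point set onto a reference."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å


def kabsch(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``Y`` onto ``X``.

    Returns rotation R and translation t minimizing
    ``sum_i w_i * || R @ Y_i + t - X_i ||^2``, with a proper rotation
    enforced by flipping the sign of the smallest singular value when
    the optimum would otherwise be a reflection.

    Parameters
    ----------
    X, Y : (n, 3) arrays, n >= 3, not all collinear.
    weights : optional non-negative weights, length n.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both be (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    xc = (w[:, None] * X).sum(axis=0)
    yc = (w[:, None] * Y).sum(axis=0)
    X0 = X - xc
    Y0 = Y - yc

    H = (w[:, None] * Y0).T @ X0  # 3x3 cross-covariance
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear/coincident) point sets leave the rotation
    # about the degenerate axis undetermined
    if S[1] <= 1e-12 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = xc - R @ yc
    residual = (Y0 @ R.T) - X0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", residual, residual)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_transform(coords: np.ndarray, sup: SuperpositionResult) -> np.ndarray:
    """Apply a superposition's rigid motion to an (..., 3) array."""
    return coords @ sup.rotation.T + sup.translation


def rmsd_after_fit(X: np.ndarray, Y: np.ndarray) -> float:
    """Cα RMSD of two point sets after optimal rigid superposition."""
    return kabsch(X, Y).rmsd


def iterative_mean_fit(
    ens: EnsembleMatrix,
    columns: list[int],
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[EnsembleMatrix, np.ndarray]:
    """Superpose all entries onto their evolving mean over ``columns``.

    All entries are first fitted to entry 1, the column-wise mean is
    computed, everything is refitted to the mean, and the cycle repeats
    until the mean moves less than ``tol`` (Å, RMS) or ``max_iter``
    rounds have run. Whole-chain coordinates are transformed, not only
    the fit columns.

    Returns the fitted ensemble and the final (k, 3) mean coordinates.
    """
    idx = np.asarray(columns, dtype=int) - 1
    if idx.size < 3:
        raise ValueError("at least 3 fit columns required")
    if not ens.mask[:, idx].all():
        missing = [ens.entry_ids[e] for e in np.where(~ens.mask[:, idx].all(axis=1))[0]]
        raise ValueError(f"entries missing fit columns: {missing}")

    out = ens.copy()
    ref = out.coords[0, idx, :]
    for e in range(out.n_entries):
        sup = kabsch(ref, out.coords[e, idx, :])
        out.coords[e] = apply_transform(out.coords[e], sup)

    mean = out.coords[:, idx, :].mean(axis=0)
    for _ in range(max_iter):
        for e in range(out.n_entries):
            sup = kabsch(mean, out.coords[e, idx, :])
            out.coords[e] = apply_transform(out.coords[e], sup)
        new_mean = out.coords[:, idx, :].mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < tol:
            break
    return out, mean


@dataclass
class CoreTrace:
    """Record of the iterative high-variance column removal.

    ``removal_order`` rows are ``(column, column_volume, remaining_volume)``
    in Å³, where ``remaining_volume`` is the total ellipsoid volume of
    the surviving columns at the moment of that removal. ``core`` is the
    surviving (selected) column set, ascending.
    """

    removal_order: list[tuple[int, float, float]]
    core: list[int]
    cutoff: float
    initial_volume: float


def _column_volumes(coords: np.ndarray) -> np.ndarray:
    """Per-column ellipsoid volume of positional scatter across entries.

    ``coords`` is (E, k, 3) fitted coordinates. The volume of column c is
    (4/3)*pi*sqrt(l1*l2*l3) with l the eigenvalues of the 3x3 covariance
    (divisor n-1), negative eigenvalues clamped to zero.
    """
    E = coords.shape[0]
    centered = coords - coords.mean(axis=0, keepdims=True)
    # (k, 3, 3) covariance per column
    cov = np.einsum("eki,ekj->kij", centered, centered) / (E - 1)
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    return (4.0 / 3.0) * np.pi * np.sqrt(lam.prod(axis=1))


def find_invariant_core(
    ens: EnsembleMatrix,
    start_columns: list[int],
    *,
    volume_cutoff: float = 0.5,
) -> CoreTrace:
    """Iteratively discard the highest-scatter column until a tight core remains.

    Each round: refit the ensemble on the current column set (iterated
    mean fitting), compute every current column's covariance-ellipsoid
    volume, and remove the single largest-volume column (ties break to
    the lowest column index). Stops when the total remaining volume is
    at most ``volume_cutoff`` (Å³) or only 3 columns remain.
    """
    if ens.n_entries < 2:
        raise ValueError("core finding requires at least 2 entries")
    if len(start_columns) < 3:
        raise ValueError("at least 3 start columns required")

    current = sorted(start_columns)
    removal: list[tuple[int, float, float]] = []
    initial_volume: float | None = None
    while True:
        fitted, _ = iterative_mean_fit(ens, current)
        vols = _column_volumes(fitted.take(current))
        total = float(vols.sum())
        if initial_volume is None:
            initial_volume = total
        if total <= volume_cutoff or len(current) <= 3:
            break
        # largest volume; ties -> lowest column index (current is sorted,
        # argmax returns the first maximum)
        imax = int(np.argmax(vols))
        col, vol = current[imax], float(vols[imax])
        removal.append((col, vol, total - vol))
        current.pop(imax)
    return CoreTrace(
        removal_order=removal,
        core=current,
        cutoff=volume_cutoff,
        initial_volume=initial_volume,
    )


def fit_on_core(
    ens: EnsembleMatrix, core_columns: list[int]
) -> tuple[EnsembleMatrix, np.ndarray]:
    """Superpose the whole ensemble using only the invariant-core columns."""
    return iterative_mean_fit(ens, core_columns)


def write_core_trace_tsv(trace: CoreTrace, path: str | Path) -> None:
    lines = ["step\tcolumn\tcolumn_volume\tremaining_volume"]
    for i, (col, vol, rem) in enumerate(trace.removal_order, start=1):
        lines.append(f"{i}\t{col}\t{vol:.6f}\t{rem:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_core_columns_tsv(trace: CoreTrace, path: str | Path) -> None:
    Path(path).write_text("column\n" + "\n".join(str(c) for c in trace.core) + "\n")
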