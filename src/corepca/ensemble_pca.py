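"""Principal component analysis of core-fitted Cα coordinates.

Each fitted entry is flattened to a 3L vector over the analysis columns;
the eigendecomposition of the (n-1)-divisor covariance yields collective
motions (loadings), per-structure scores, and variance proportions.
Components are sign-fixed so the largest-magnitude loading element is
positive, making score plots reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_frame import EnsembleMatrix
from .core_superpose import apply_transform, kabsch
from .structure_io import ChainModel, write_chain_pdb

__all__ = [
    "PCAResult",
    "pca",
    "variance_explained",
    "loading_vectors",
    "pc_trajectory",
    "project",
]


@dataclass
class PCAResult:
    """Eigenstructure of the fitted-coordinate covariance.

    ``loadings`` rows are unit 3L vectors (component-major); ``scores``
    is entries x components; ``eigenvalues`` are descending, in Å².
    """

    columns: list[int]  # 1-based analysis columns, ascending order used
    entry_ids: list[str]
    mean: np.ndarray  # (3L,)
    eigenvalues: np.ndarray  # (k,), descending
    proportions: np.ndarray  # (k,), sums to 1 (all-zero if no variance)
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (k, 3L), orthonormal rows
    sign_convention: str = "largest-abs-loading-positive"

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca(fitted: EnsembleMatrix, columns: list[int]) -> PCAResult:
    """PCA of the fitted ensemble over the given (fully occupied) columns."""
    n = fitted.n_entries
    if n < 3:
        raise ValueError("PCA requires at least 3 entries")
    idx = np.asarray(columns, dtype=int) - 1
    if not fitted.mask[:, idx].all():
        raise ValueError("PCA columns must be fully occupied")

    X = fitted.coords[:, idx, :].reshape(n, -1)  # (n, 3L)
    mean = X.mean(axis=0)
    Xc = X - mean

    # economy SVD: eigenvalues of cov = s^2/(n-1); exact variance budget
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = Vt
    scores = U * s

    # sign convention: flip so each component's largest-|element| is positive
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]

    total = eigenvalues.sum()
    proportions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAResult(
        columns=list(columns),
        entry_ids=list(fitted.entry_ids),
        mean=mean,
        eigenvalues=eigenvalues,
        proportions=proportions,
        scores=scores,
        loadings=loadings,
    )


def variance_explained(res: PCAResult, k: int) -> float:
    """Cumulative proportion of variance in the first ``k`` components."""
    if not 1 <= k <= res.n_components:
        raise ValueError(f"k must be in [1, {res.n_components}]")
    return float(res.proportions[:k].sum())


def loading_vectors(res: PCAResult, pc: int) -> pd.DataFrame:
    """Per-column (dx, dy, dz) loading triplets and magnitudes for one PC.

    ``pc`` is 1-based. Squared magnitudes sum to 1 (unit loading). The
    table is what a porcupine-style rendering on a representative needs.
    """
    if not 1 <= pc <= res.n_components:
        raise ValueError(f"pc must be in [1, {res.n_components}]")
    v = res.loadings[pc - 1].reshape(-1, 3)
    mag = np.linalg.norm(v, axis=1)
    return pd.DataFrame(
        {
            "column": res.columns,
            "dx": v[:, 0],
            "dy": v[:, 1],
            "dz": v[:, 2],
            "magnitude": mag,
        }
    )


def pc_trajectory(
    res: PCAResult,
    pc: int,
    *,
    amplitude: float = 2.0,
    n_frames: int = 15,
) -> np.ndarray:
    """Linear morph along one PC: frames of shape (n_frames, L, 3).

    Frame j is ``mean + s_j * sqrt(eigenvalue_pc) * loading_pc`` with
    ``s_j`` linearly spaced over [-amplitude, +amplitude] (SD units).
    With an odd frame count the middle frame is exactly the mean.
    """
    if not 1 <= pc <= res.n_components:
        raise ValueError(f"pc must be in [1, {res.n_components}]")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    sd = np.sqrt(res.eigenvalues[pc - 1])
    s = np.linspace(-amplitude, amplitude, n_frames)
    frames = res.mean[None, :] + s[:, None] * sd * res.loadings[pc - 1][None, :]
    return frames.reshape(n_frames, -1, 3)


def write_trajectory_pdb(
    res: PCAResult,
    pc: int,
    representative: ChainModel,
    column_of_key: dict[tuple[int, str], int],
    path: str | Path,
    *,
    amplitude: float = 2.0,
    n_frames: int = 15,
) -> None:
    """Write a PC morph as a multi-model PDB on a representative's numbering.

    Only representative residues mapped to the PCA columns are written;
    their order follows the PCA column order.
    """
    frames = pc_trajectory(res, pc, amplitude=amplitude, n_frames=n_frames)
    col_pos = {c: i for i, c in enumerate(res.columns)}
    keep: list[tuple[int, int]] = []  # (residue index, column position)
    for i, r in enumerate(representative.residues):
        col = column_of_key.get(r.key)
        if col in col_pos:
            keep.append((i, col_pos[col]))
    if len(keep) < 3:
        raise ValueError("representative covers fewer than 3 PCA columns")
    sub = ChainModel(
        entry_id=representative.entry_id,
        chain_id=representative.chain_id,
        residues=[representative.residues[i] for i, _ in keep],
        resolution=representative.resolution,
        method=representative.method,
    )
    order = [p for _, p in keep]
    write_chain_pdb(sub, path, models=[f[order] for f in frames])


def project(coords: np.ndarray, res: PCAResult) -> np.ndarray:
    """Score vector of an in-frame model over the PCA columns.

    ``coords`` is (L, 3) at the PCA columns, in order. The model is
    superposed onto the PCA mean, mean-subtracted, and dotted with the
    loadings.
    """
    coords = np.asarray(coords, dtype=float)
    L = len(res.columns)
    if coords.shape != (L, 3):
        raise ValueError(f"expected ({L}, 3) coordinates at the PCA columns")
    mean_pts = res.mean.reshape(-1, 3)
    sup = kabsch(mean_pts, coords)
    fitted = apply_transform(coords, sup)
    return (fitted.reshape(-1) - res.mean) @ res.loadings.T


def write_pca_tables(res: PCAResult, outdir: str | Path, *, n_components: int = 10) -> None:
    """Eigenvalue/proportion, score, and loading tables as TSV."""
    outdir = Path(outdir)
    k = min(n_components, res.n_components)
    pd.DataFrame(
        {
            "component": np.arange(1, res.n_components + 1),
            "eigenvalue": res.eigenvalues,
            "proportion": res.proportions,
            "cumulative": np.cumsum(res.proportions),
        }
    ).to_csv(outdir / "pca_eigenvalues.tsv", sep="\t", index=False)
    score_df = pd.DataFrame(
        res.scores[:, :k],
        columns=[f"PC{i}" for i in range(1, k + 1)],
    )
    score_df.insert(0, "entry_id", res.entry_ids)
    score_df.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
    loads = []
    for pc in range(1, k + 1):
        df = loading_vectors(res, pc)
        df.insert(0, "pc", pc)
        loads.append(df)
    pd.concat(loads).to_csv(outdir / "pca_loadings.tsv", sep="\t", index=False)
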