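"""Master-alignment column frame.

Every structure's observed residues are reconciled against that entry's
own row of the master (gapped) alignment, yielding a residue -> column
map; the per-entry maps are assembled into the ensemble coordinate
tensor on which superposition and PCA operate. Columns are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .structure_io import ChainModel, extract_sequence

__all__ = [
    "MasterAlignment",
    "ColumnMap",
    "EnsembleMatrix",
    "read_master_alignment",
    "map_to_alignment",
    "build_ensemble",
    "complete_columns",
]

GAP = "-"


@dataclass
class MasterAlignment:
    """Gapped FASTA alignment: one row per entry, equal row lengths."""

    rows: dict[str, str]
    n_columns: int

    def __post_init__(self) -> None:
        for eid, row in self.rows.items():
            if len(row) != self.n_columns:
                raise ValueError(
                    f"row {eid!r} has length {len(row)}, expected {self.n_columns}"
                )


def read_master_alignment(path: str | Path) -> MasterAlignment:
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate alignment row {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"unequal alignment row lengths: {sorted(lengths)}")
    return MasterAlignment(rows=rows, n_columns=lengths.pop())


@dataclass
class ColumnMap:
    """Residue-key -> alignment-column (1-based) map for one entry.

    Mapped columns are strictly increasing over the residue order and
    each column is claimed at most once.
    """

    entry_id: str
    mapping: dict[tuple[int, str], int]
    identity: float  # fractional identity over the aligned region

    def __post_init__(self) -> None:
        cols = list(self.mapping.values())
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError(f"{self.entry_id}: column map not strictly increasing")

    @property
    def columns(self) -> list[int]:
        return list(self.mapping.values())


def map_to_alignment(
    model: ChainModel,
    row: str,
    *,
    min_identity: float = 0.95,
) -> ColumnMap:
    """Map each observed residue to its master-alignment column.

    The observed one-letter sequence is globally aligned (match +2,
    mismatch -1, gap open -5, gap extend -1) against the entry's own
    ungapped row sequence; the residue -> row-position map is composed
    with the row-position -> column map given by the gap structure.
    Unresolved residues and construct differences show up as gaps.

    Raises
    ------
    ValueError
        If identity over the aligned region falls below ``min_identity``
        (a manifest/row mismatch), reporting the percent identity.
    """
    observed = extract_sequence(model)
    ungapped: list[str] = []
    col_of_pos: list[int] = []  # ungapped position -> 1-based column
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            ungapped.append(ch)
            col_of_pos.append(col)
    row_seq = "".join(ungapped)
    if not row_seq:
        raise ValueError(f"{model.entry_id}: alignment row is all gaps")

    aligner = PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-1,
    )
    aln = aligner.align(observed, row_seq)[0]

    matches = 0
    aligned_pairs = 0
    mapping: dict[tuple[int, str], int] = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for i, j in zip(range(t0, t1), range(q0, q1)):
            aligned_pairs += 1
            if observed[i] == row_seq[j]:
                matches += 1
            mapping[model.residues[i].key] = col_of_pos[j]

    identity = matches / aligned_pairs if aligned_pairs else 0.0
    if identity < min_identity:
        raise ValueError(
            f"{model.entry_id}: sequence/row identity {identity * 100:.1f}% "
            f"below {min_identity * 100:.0f}% — manifest row mismatch?"
        )
    return ColumnMap(entry_id=model.entry_id, mapping=mapping, identity=identity)


@dataclass
class EnsembleMatrix:
    """Representatives x alignment-columns x 3 coordinate tensor.

    ``coords[e, c-1]`` is the Cα of the residue entry ``e`` maps to
    column ``c``; ``mask[e, c-1]`` is True exactly where such a residue
    exists. Unoccupied coordinates are NaN.
    """

    entry_ids: list[str]
    coords: np.ndarray  # (E, C, 3), NaN where mask is False
    mask: np.ndarray  # (E, C) bool

    def __post_init__(self) -> None:
        e, c, d = self.coords.shape
        if d != 3 or self.mask.shape != (e, c):
            raise ValueError("coords/mask shape mismatch")
        if not np.all(np.isfinite(self.coords[self.mask])):
            raise ValueError("non-finite coordinates under mask")

    @property
    def n_entries(self) -> int:
        return len(self.entry_ids)

    @property
    def n_columns(self) -> int:
        return self.coords.shape[1]

    def index_of(self, entry_id: str) -> int:
        return self.entry_ids.index(entry_id)

    def take(self, columns: list[int]) -> np.ndarray:
        """Coordinates at the given 1-based columns, shape (E, k, 3)."""
        idx = np.asarray(columns, dtype=int) - 1
        return self.coords[:, idx, :]

    def copy(self) -> "EnsembleMatrix":
        return EnsembleMatrix(
            entry_ids=list(self.entry_ids),
            coords=self.coords.copy(),
            mask=self.mask.copy(),
        )


def build_ensemble(
    models: list[ChainModel],
    maps: list[ColumnMap],
    aln: MasterAlignment,
) -> EnsembleMatrix:
    """Assemble the coordinate tensor from per-entry column maps."""
    if not models:
        raise ValueError("empty model list")
    if len(models) != len(maps):
        raise ValueError("one ColumnMap required per model")
    E, C = len(models), aln.n_columns
    coords = np.full((E, C, 3), np.nan)
    mask = np.zeros((E, C), dtype=bool)
    for e, (model, cmap) in enumerate(zip(models, maps)):
        if model.entry_id != cmap.entry_id:
            raise ValueError(
                f"model/map entry mismatch: {model.entry_id} vs {cmap.entry_id}"
            )
        by_key = {r.key: r for r in model.residues}
        for key, col in cmap.mapping.items():
            if not 1 <= col <= C:
                raise ValueError(f"{model.entry_id}: column {col} outside alignment")
            if mask[e, col - 1]:
                raise ValueError(f"{model.entry_id}: column {col} claimed twice")
            res = by_key.get(key)
            if res is None:
                continue
            coords[e, col - 1] = res.ca
            mask[e, col - 1] = True
    return EnsembleMatrix(entry_ids=[m.entry_id for m in models], coords=coords, mask=mask)


def complete_columns(
    ens: EnsembleMatrix, *, min_occupancy: float = 1.0
) -> list[int]:
    """Columns occupied by (a fraction >= ``min_occupancy`` of) all entries.

    The default 1.0 is the strict intersection — the ungapped common
    frame. Returns ascending 1-based columns; raises if none qualify.
    """
    if ens.n_entries == 0:
        raise ValueError("empty ensemble")
    occ = ens.mask.mean(axis=0)
    cols = [c + 1 for c in range(ens.n_columns) if occ[c] >= min_occupancy - 1e-12]
    if not cols:
        raise ValueError("no common frame: no column meets the occupancy threshold")
    return cols


def write_column_maps_tsv(maps: list[ColumnMap], path: str | Path) -> None:
    lines = ["entry_id\tresnum\ticode\tcolumn"]
    for cmap in maps:
        for (num, icode), col in cmap.mapping.items():
            lines.append(f"{cmap.entry_id}\t{num}\t{icode}\t{col}")
    Path(path).write_text("\n".join(lines) + "\n")
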