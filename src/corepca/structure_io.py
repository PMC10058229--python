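"""Coordinate-file ingestion and annotation handling.

Parses PDB/mmCIF files into per-chain Cα models, reads the annotation
manifest, and applies the semiautomatic nucleotide- and assembly-state
classification rules used throughout the pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "ChainModel",
    "AnnotationRecord",
    "ManifestEntry",
    "read_structure",
    "extract_sequence",
    "classify_nucleotide",
    "classify_assembly",
    "read_manifest",
    "write_chain_pdb",
    "DEFAULT_NUCLEOTIDE_TABLE",
    "NUCLEOTIDE_STATES",
    "ASSEMBLY_STATES",
]

NUCLEOTIDE_STATES = ("NTP", "NTPa", "NDP", "apo", "other")
ASSEMBLY_STATES = ("polymerized", "unpolymerized", "special")

#: Default ligand-code -> hydrolysis-state table. ATP/GTP are true
#: triphosphates; ANP (AMP-PNP), AGS (ATP-gamma-S), GNP (GMP-PNP),
#: GCP (GMPCPP), GSP (GTP-gamma-S) and ACP (AMP-PCP) are slowly- or
#: non-hydrolyzable analogues; ADP/GDP are diphosphates.
DEFAULT_NUCLEOTIDE_TABLE: dict[str, str] = {
    "ATP": "NTP",
    "GTP": "NTP",
    "ANP": "NTPa",
    "AGS": "NTPa",
    "GNP": "NTPa",
    "GCP": "NTPa",
    "GSP": "NTPa",
    "ACP": "NTPa",
    "ADP": "NDP",
    "GDP": "NDP",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Residue:
    """One residue keyed by author numbering, carrying its Cα position."""

    number: int
    icode: str  # insertion code, "" if none
    aa: str  # one-letter code, "X" for nonstandard
    ca: np.ndarray  # shape (3,), Å
    resname: str = ""  # three-letter deposition name (for nonstandard mapping)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class ChainModel:
    """Ordered Cα trace of one subunit chain.

    Residues appear in file order; keys (author number, insertion code)
    are unique; every residue has exactly one finite Cα coordinate.
    """

    entry_id: str
    chain_id: str
    residues: list[Residue]
    resolution: float | None = None
    method: str = "other"  # one of {x-ray, cryo-EM, NMR, other}

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.entry_id}: duplicate residue keys")
        for r in self.residues:
            if not np.all(np.isfinite(r.ca)):
                raise ValueError(f"{self.entry_id}: non-finite Cα at {r.key}")

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """Cα coordinates as an (n, 3) array in file order."""
        return np.array([r.ca for r in self.residues], dtype=float)


@dataclass
class AnnotationRecord:
    """Per-entry annotations driving the correlation analysis."""

    entry_id: str
    subfamily: str
    ligand_codes: set[str]
    nucleotide_state: str
    assembly_state: str
    organism: str = ""
    resolution: float | None = None
    assembly_provenance: str = "declared"  # declared | heuristic

    def __post_init__(self) -> None:
        if self.nucleotide_state not in NUCLEOTIDE_STATES:
            raise ValueError(
                f"nucleotide_state {self.nucleotide_state!r} not in "
                f"{NUCLEOTIDE_STATES}"
            )
        if self.assembly_state not in ASSEMBLY_STATES:
            raise ValueError(
                f"assembly_state {self.assembly_state!r} not in {ASSEMBLY_STATES}"
            )


@dataclass
class ManifestEntry:
    """One manifest row: where to find the chain plus its annotations."""

    entry_id: str
    path: str
    chain: str
    subfamily: str
    ligands: set[str]
    nucleotide_state: str | None
    assembly_state: str | None
    organism: str
    resolution: float | None
    method: str | None = None


def _method_class(text: str) -> str:
    t = text.upper()
    if "X-RAY" in t or "XRAY" in t:
        return "x-ray"
    if "ELECTRON MICROSCOPY" in t or "CRYO" in t or "EM" == t.strip():
        return "cryo-EM"
    if "NMR" in t:
        return "NMR"
    return "other"


def _pdb_expdta(path: Path) -> str:
    """EXPDTA record of a PDB file, or "" (gemmi does not surface it)."""
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("EXPDTA"):
                    return line[6:].strip()
                if line.startswith("ATOM") or line.startswith("HETATM"):
                    break
    except (OSError, UnicodeDecodeError):
        pass
    return ""


def read_structure(path: str | Path, entry_id: str, chain_id: str) -> ChainModel:
    """Parse one chain of a PDB or mmCIF file into a :class:`ChainModel`.

    Only the first model of multi-model files is used. For alternate
    locations the highest-occupancy Cα is kept (ties broken by
    alphabetically first altloc id). Residues without a Cα are skipped.

    Raises
    ------
    ValueError
        If the chain is absent (the message lists available chains) or
        contains no Cα atoms.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    chain = model.find_chain(chain_id)
    if chain is None:
        available = sorted({ch.name for ch in model})
        raise ValueError(
            f"{entry_id}: chain {chain_id!r} not found in {path}; "
            f"available chains: {available}"
        )

    residues: list[Residue] = []
    for res in chain:
        cas = [a for a in res if a.name == "CA" and a.element != gemmi.Element("Ca")]
        if not cas:
            continue
        # highest occupancy wins; equal occupancies -> first altloc id
        best = min(cas, key=lambda a: (-a.occ, a.altloc or ""))
        aa = _THREE_TO_ONE.get(res.name, "X")
        icode = res.seqid.icode.strip()
        residues.append(
            Residue(
                number=res.seqid.num,
                icode=icode,
                aa=aa,
                ca=np.array([best.pos.x, best.pos.y, best.pos.z]),
                resname=res.name,
            )
        )
    if not residues:
        raise ValueError(f"{entry_id}: chain {chain_id!r} has no Cα atoms")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    method_text = ""
    if st.meta.experiments:
        method_text = st.meta.experiments[0].method or ""
    if not method_text and path.suffix.lower() in {".pdb", ".ent"}:
        method_text = _pdb_expdta(path)

    return ChainModel(
        entry_id=entry_id,
        chain_id=chain_id,
        residues=residues,
        resolution=resolution,
        method=_method_class(method_text) if method_text else "other",
    )


def extract_sequence(
    model: ChainModel, nonstandard: Mapping[str, str] | None = None
) -> str:
    """One-letter sequence of the model, same length as its residue list.

    Nonstandard residues map to "X" by default; ``nonstandard`` supplies
    a three-letter -> one-letter override table (e.g. ``{"MSE": "M"}``).
    """
    if len(model) == 0:
        raise ValueError("empty model")
    table = dict(nonstandard or {})
    out = []
    for r in model.residues:
        aa = r.aa
        if aa == "X" and r.resname in table:
            aa = table[r.resname]
        out.append(aa)
    return "".join(out)


def classify_nucleotide(
    ligand_codes: Iterable[str], table: Mapping[str, str] | None = None
) -> str:
    """Assign the nucleotide hydrolysis state from bound-ligand codes.

    Pure function of the code *set*: order never matters. Codes from
    several classes resolve with precedence NTP > NTPa > NDP; an empty
    set is apo; codes absent from the table fall through to "other".
    """
    table = dict(table) if table is not None else DEFAULT_NUCLEOTIDE_TABLE
    codes = {c.strip().upper() for c in ligand_codes if c.strip()}
    if not codes:
        return "apo"
    classes = {table[c] for c in codes if c in table}
    for state in ("NTP", "NTPa", "NDP"):
        if state in classes:
            return state
    return "other"


def classify_assembly(
    method: str | None, declared: str | None
) -> tuple[str, str]:
    """Assign polymerization state; returns ``(state, provenance)``.

    A declared manifest state always wins (provenance "declared").
    Otherwise a heuristic mirrors semiautomatic assignment from the
    experimental technique: filament/helical reconstructions are
    polymerized, everything else unpolymerized (provenance "heuristic").
    """
    if declared is not None and declared != "":
        if declared not in ASSEMBLY_STATES:
            raise ValueError(
                f"declared assembly state {declared!r} not in {ASSEMBLY_STATES}"
            )
        return declared, "declared"
    text = (method or "").lower()
    if "filament" in text or "helical" in text:
        return "polymerized", "heuristic"
    return "unpolymerized", "heuristic"


_MANIFEST_COLUMNS = [
    "entry_id", "path", "chain", "subfamily", "ligands",
    "nucleotide_state", "assembly_state", "organism", "resolution",
]


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read the TSV manifest (header per the documented schema).

    ``ligands`` is a comma-separated list of 3-letter codes;
    ``nucleotide_state`` and ``assembly_state`` may be empty, meaning
    "classify automatically". An optional ``method`` column supplies a
    free-text technique descriptor for the assembly heuristic.
    """
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        for row in reader:
            eid = row["entry_id"].strip()
            if not eid:
                continue
            if eid in seen:
                raise ValueError(f"duplicate entry_id {eid!r} in manifest")
            seen.add(eid)
            ligands = {
                c.strip().upper() for c in row["ligands"].split(",") if c.strip()
            }
            res = row["resolution"].strip()
            entries.append(
                ManifestEntry(
                    entry_id=eid,
                    path=row["path"].strip(),
                    chain=row["chain"].strip(),
                    subfamily=row["subfamily"].strip(),
                    ligands=ligands,
                    nucleotide_state=row["nucleotide_state"].strip() or None,
                    assembly_state=row["assembly_state"].strip() or None,
                    organism=row["organism"].strip(),
                    resolution=float(res) if res else None,
                    method=(row.get("method") or "").strip() or None,
                )
            )
    if not entries:
        raise ValueError(f"{path}: empty manifest")
    return entries


def annotate(entry: ManifestEntry, model: ChainModel | None = None) -> AnnotationRecord:
    """Build the :class:`AnnotationRecord` for one manifest row.

    Declared states win; otherwise nucleotide state comes from the ligand
    table and assembly state from the technique heuristic.
    """
    nuc = entry.nucleotide_state or classify_nucleotide(entry.ligands)
    if nuc not in NUCLEOTIDE_STATES:
        raise ValueError(f"{entry.entry_id}: bad nucleotide_state {nuc!r}")
    method = entry.method or (model.method if model is not None else None)
    assembly, prov = classify_assembly(method, entry.assembly_state)
    return AnnotationRecord(
        entry_id=entry.entry_id,
        subfamily=entry.subfamily,
        ligand_codes=set(entry.ligands),
        nucleotide_state=nuc,
        assembly_state=assembly,
        organism=entry.organism,
        resolution=entry.resolution,
        assembly_provenance=prov,
    )


_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def write_chain_pdb(
    model: ChainModel, path: str | Path, *, models: Sequence[np.ndarray] | None = None
) -> None:
    """Write a ChainModel (or several coordinate frames of it) as PDB.

    ``models`` optionally supplies alternative (n, 3) coordinate arrays,
    one per MODEL record — used for morph trajectories. Coordinates are
    written at standard fixed-width %8.3f precision.
    """
    frames = models if models is not None else [model.coords()]
    lines: list[str] = []
    for mi, frame in enumerate(frames, start=1):
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (len(model), 3):
            raise ValueError("frame shape does not match model length")
        if len(frames) > 1:
            lines.append(f"MODEL     {mi:4d}")
        for i, (res, xyz) in enumerate(zip(model.residues, frame), start=1):
            resname = _ONE_TO_THREE.get(res.aa, "UNK")
            icode = res.icode or " "
            lines.append(
                f"ATOM  {i:5d}  CA  {resname:>3s} {model.chain_id[:1]}"
                f"{res.number:4d}{icode}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}           C"
            )
        if len(frames) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
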