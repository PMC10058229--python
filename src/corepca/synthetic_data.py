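"""Synthetic structure ensembles with a planted polymerization switch.

Generates toy Cα "folds" shared across several subfamilies: a smooth
helical base chain, a two-state hinge deformation tied to the assembly
state (the planted switch), one family-specific deformation mode
orthogonal to the hinge, isotropic Gaussian coordinate noise, occasional
unresolved residues, family-specific alignment indels, and random rigid
poses. Nucleotide labels are drawn independently of geometry, so any
apparent nucleotide/conformation correlation downstream is a false
positive by construction.

Output is a directory of single-chain PDB files, a gapped master-
alignment FASTA, and the manifest TSV — exactly what the ingestion
stage consumes, so the full pipeline runs on synthetic data unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .structure_io import ChainModel, Residue, write_chain_pdb

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_base_chain",
    "apply_hinge",
    "generate_ensemble",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CA_SPACING = 3.8  # Å, consecutive Cα distance

#: ligand-code choices drawn per entry, independent of conformation
_LIGAND_CHOICES = ("GTP", "GCP", "GDP", "")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults: 3 subfamilies, 8 entries per (family, state), two assembly
    states separated by a 15° hinge, 0.3 Å isotropic noise, 1% missing
    residues, 1 Å family-mode amplitude on an 80-residue chain split at
    residue 40.
    """

    n_families: int = 3
    n_per_state: int = 8
    length: int = 80
    hinge_split: int = 40
    theta_unpolymerized: float = 0.0  # degrees
    theta_polymerized: float = 15.0  # degrees
    family_amplitude: float = 1.0  # Å
    noise_sd: float = 0.3  # Å
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 < self.hinge_split < self.length:
            raise ValueError("hinge split must lie strictly inside the chain")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing rate must be in [0, 1]")
        if self.length < 8:
            raise ValueError("chain length must be >= 8")


@dataclass
class SyntheticDataset:
    """Paths and ground truth of one generated dataset."""

    manifest: Path
    alignment: Path
    pdb_dir: Path
    entry_states: dict[str, str]  # entry_id -> assembly state
    entry_families: dict[str, str]
    hinge_split: int
    mobile_base_positions: list[int]  # 1-based base-chain positions that move


def generate_base_chain(length: int, seed: int) -> np.ndarray:
    """Smooth non-self-intersecting Cα curve with 3.8 Å spacing.

    A wide helical parametrization perturbed by a small smooth random
    field (seeded), then re-stepped so every consecutive Cα distance is
    exactly 3.8 Å. Deterministic for a given (length, seed).
    """
    if length < 8:
        raise ValueError("length must be >= 8")
    rng = np.random.default_rng(seed)
    i = np.arange(length + 1, dtype=float)
    r, dt, rise = 10.0, 0.25, 2.867
    pts = np.stack([r * np.cos(dt * i), r * np.sin(dt * i), rise * i], axis=1)
    pts += gaussian_filter1d(rng.normal(0, 0.6, size=pts.shape), sigma=4, axis=0)
    # re-step: unit-direction walk with exact spacing
    steps = np.diff(pts, axis=0)
    steps *= _CA_SPACING / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([pts[0], pts[0] + np.cumsum(steps, axis=0)])[:length]


def _hinge_axis(chain: np.ndarray, split: int) -> tuple[np.ndarray, np.ndarray]:
    """Pivot point and unit axis perpendicular to the local chain direction."""
    pivot = chain[split - 1]
    u = chain[split - 1] - chain[max(split - 3, 0)]
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    axis = np.cross(u, ref)
    return pivot, axis / np.linalg.norm(axis)


def apply_hinge(chain: np.ndarray, split: int, angle_deg: float) -> np.ndarray:
    """Rotate residues after ``split`` (1-based) about a hinge at the split.

    The axis passes through the split residue, perpendicular to the
    local chain direction; residues up to and including the split are
    unmoved. angle 0 is the identity; +θ then −θ round-trips exactly.
    """
    if not 1 < split < len(chain):
        raise ValueError("split must be interior")
    pivot, axis = _hinge_axis(chain, split)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    out = chain.copy()
    out[split:] = rot.apply(out[split:] - pivot) + pivot
    return out


def _family_mode(
    length: int, hinge_diff: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random 3L-mode, unit norm, orthogonal to the hinge mode."""
    m = gaussian_filter1d(rng.normal(size=(length, 3)), sigma=5, axis=0).reshape(-1)
    h = hinge_diff.reshape(-1)
    hnorm = np.linalg.norm(h)
    if hnorm > 0:  # degenerate specs may plant no hinge at all
        hn = h / hnorm
        m = m - (m @ hn) * hn
    return (m / np.linalg.norm(m)).reshape(length, 3)


def generate_ensemble(
    spec: SyntheticSpec, outdir: str | Path
) -> SyntheticDataset:
    """Write the synthetic dataset (PDBs, master FASTA, manifest TSV).

    Byte-identical output for a fixed spec (including seed). See the
    module docstring for what is planted; ground truth is returned for
    tests.
    """
    outdir = Path(outdir)
    pdb_dir = outdir / "structures"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    L = spec.length

    base = generate_base_chain(L, spec.seed)
    hinged = {
        "unpolymerized": apply_hinge(base, spec.hinge_split, spec.theta_unpolymerized),
        "polymerized": apply_hinge(base, spec.hinge_split, spec.theta_polymerized),
    }
    hinge_diff = hinged["polymerized"] - hinged["unpolymerized"]
    mobile = [p for p in range(1, L + 1) if np.linalg.norm(hinge_diff[p - 1]) > 1e-9]

    # base construct sequence; each family mutates ~5% of positions and
    # carries its own short insertion (the alignment indel)
    base_seq = rng.choice(list(_AA), size=L)
    families = [f"fam{chr(ord('A') + f)}" for f in range(spec.n_families)]
    fam_seqs: dict[str, np.ndarray] = {}
    fam_modes: dict[str, np.ndarray] = {}
    fam_insert: dict[str, tuple[int, str]] = {}  # anchor base position, letters
    for fi, fam in enumerate(families):
        seq = base_seq.copy()
        n_mut = max(1, L // 20)
        pos = rng.choice(L, size=n_mut, replace=False)
        for p in pos:
            seq[p] = rng.choice([a for a in _AA if a != seq[p]])
        fam_seqs[fam] = seq
        fam_modes[fam] = _family_mode(L, hinge_diff, rng)
        n_ins = fi % 3  # 0, 1, 2 extra residues
        anchor = 15 + 10 * fi
        fam_insert[fam] = (anchor, "".join(rng.choice(list(_AA), size=n_ins)))

    # master column layout: base positions with per-family insert blocks
    # tokens: ("core", base_pos) or ("ins", family, j)
    tokens: list[tuple] = []
    for p in range(1, L + 1):
        tokens.append(("core", p))
        for fam in families:
            anchor, ins = fam_insert[fam]
            if p == anchor:
                for j in range(len(ins)):
                    tokens.append(("ins", fam, j))
    n_columns = len(tokens)

    def family_row(fam: str) -> str:
        row = []
        for tok in tokens:
            if tok[0] == "core":
                row.append(fam_seqs[fam][tok[1] - 1])
            else:
                row.append(fam_insert[fam][1][tok[2]] if tok[1] == fam else "-")
        return "".join(row)

    def family_tokens(fam: str) -> list[tuple]:
        return [t for t in tokens if t[0] == "core" or t[1] == fam]

    fasta_lines: list[str] = []
    manifest_lines = [
        "entry_id\tpath\tchain\tsubfamily\tligands\tnucleotide_state"
        "\tassembly_state\torganism\tresolution"
    ]
    entry_states: dict[str, str] = {}
    entry_families: dict[str, str] = {}

    for fam in families:
        toks = family_tokens(fam)
        anchor, ins = fam_insert[fam]
        for state in ("unpolymerized", "polymerized"):
            conf = hinged[state] + spec.family_amplitude * fam_modes[fam]
            # insert-residue geometry: small bulge off the anchor residue
            coords_by_token: dict[tuple, np.ndarray] = {}
            for t in toks:
                if t[0] == "core":
                    coords_by_token[t] = conf[t[1] - 1]
            if ins:
                a = conf[anchor - 1]
                nxt = conf[anchor] if anchor < L else conf[anchor - 2]
                out_dir = np.cross(nxt - a, [0.0, 0.0, 1.0])
                nrm = np.linalg.norm(out_dir)
                out_dir = out_dir / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                for j in range(len(ins)):
                    frac = (j + 1) / (len(ins) + 1)
                    coords_by_token[("ins", fam, j)] = (
                        a + frac * (nxt - a) + 2.0 * out_dir
                    )
            for k in range(spec.n_per_state):
                eid = f"{fam}_{state[:5]}_{k:02d}"
                entry_states[eid] = state
                entry_families[eid] = fam
                coords = np.array([coords_by_token[t] for t in toks])
                coords = coords + rng.normal(0, spec.noise_sd, size=coords.shape)
                # random rigid pose
                pose = Rotation.random(random_state=np.random.RandomState(
                    rng.integers(0, 2**31)))
                coords = pose.apply(coords) + rng.uniform(-50, 50, size=3)
                # occasional unresolved residues
                present = rng.random(len(toks)) >= spec.missing_rate
                if present.sum() < 8:
                    present[:] = True
                residues = []
                for num, (t, keep) in enumerate(zip(toks, present), start=1):
                    if not keep:
                        continue
                    aa = (
                        fam_seqs[fam][t[1] - 1]
                        if t[0] == "core"
                        else fam_insert[fam][1][t[2]]
                    )
                    residues.append(
                        Residue(number=num, icode="", aa=aa, ca=coords[num - 1])
                    )
                model = ChainModel(
                    entry_id=eid, chain_id="A", residues=residues
                )
                pdb_path = pdb_dir / f"{eid}.pdb"
                write_chain_pdb(model, pdb_path)

                ligand = rng.choice(_LIGAND_CHOICES)
                resolution = round(float(rng.uniform(1.5, 3.5)), 2)
                fasta_lines += [f">{eid}", family_row(fam)]
                manifest_lines.append(
                    f"{eid}\t{pdb_path}\tA\t{fam}\t{ligand}\t\t{state}"
                    f"\tsynthetic\t{resolution:.2f}"
                )

    aln_path = outdir / "master_alignment.fasta"
    aln_path.write_text("\n".join(fasta_lines) + "\n")
    manifest_path = outdir / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_lines) + "\n")
    return SyntheticDataset(
        manifest=manifest_path,
        alignment=aln_path,
        pdb_dir=pdb_dir,
        entry_states=entry_states,
        entry_families=entry_families,
        hinge_split=spec.hinge_split,
        mobile_base_positions=mobile,
    )
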