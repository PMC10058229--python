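import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py importable

from corepca import RunConfig, SyntheticSpec, generate_ensemble, run_pipeline
from corepca.alignment_frame import EnsembleMatrix
from corepca.structure_io import ChainModel, Residue


def make_chain(coords, entry_id="e", chain_id="A", seq=None, start=1):
    """ChainModel from an (n, 3) array with sequential numbering."""
    coords = np.asarray(coords, dtype=float)
    seq = seq or "A" * len(coords)
    residues = [
        Residue(number=start + i, icode="", aa=seq[i], ca=coords[i])
        for i in range(len(coords))
    ]
    return ChainModel(entry_id=entry_id, chain_id=chain_id, residues=residues)


def make_ensemble(coord_list, entry_ids=None) -> EnsembleMatrix:
    """Fully occupied EnsembleMatrix from a list of (L, 3) arrays."""
    coords = np.asarray(coord_list, dtype=float)
    e, c, _ = coords.shape
    ids = entry_ids or [f"e{i}" for i in range(e)]
    return EnsembleMatrix(
        entry_ids=list(ids), coords=coords, mask=np.ones((e, c), dtype=bool)
    )


def random_rigid(rng):
    """Random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-30, 30, size=3)
    return R.as_matrix(), t


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One default-conditions synthetic dataset, generated once."""
    d = tmp_path_factory.mktemp("synth")
    return generate_ensemble(SyntheticSpec(seed=1), d)


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline report + output dir for the default dataset."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        manifest=str(default_dataset.manifest),
        alignment=str(default_dataset.alignment),
        outdir=str(out),
        seed=1,
    )
    report = run_pipeline(cfg)
    return report, out, default_dataset
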