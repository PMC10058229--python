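"""Ensemble PCA: variance accounting, loadings, trajectories, projection."""

import numpy as np
import pytest

from corepca.core_superpose import iterative_mean_fit
from corepca.ensemble_pca import (
    loading_vectors,
    pc_trajectory,
    pca,
    project,
    variance_explained,
)
from conftest import make_ensemble
from oracles import power_iteration_eigs


def _two_mode_ensemble(var_ratio=(4.0, 1.0), n=8, L=12, seed=0):
    """Noise-free ensemble varying along two orthonormal 3L modes with
    exactly the requested score variances (closed-form construction)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(L, 3)) * 10
    m1 = rng.normal(size=3 * L)
    m2 = rng.normal(size=3 * L)
    m1 /= np.linalg.norm(m1)
    m2 -= (m2 @ m1) * m1
    m2 /= np.linalg.norm(m2)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a -= a.mean()
    b -= b.mean()
    b -= (b @ a) / (a @ a) * a  # sample-orthogonal scores
    a *= np.sqrt(var_ratio[0] / (a @ a / (n - 1)))
    b *= np.sqrt(var_ratio[1] / (b @ b / (n - 1)))
    flat = base.reshape(-1)[None, :] + np.outer(a, m1) + np.outer(b, m2)
    return make_ensemble(flat.reshape(n, L, 3)), (m1, m2), (a, b)


def test_identical_structures_have_zero_eigenvalues():
    ens = make_ensemble(np.tile(np.random.default_rng(0).normal(size=(1, 10, 3)) * 9,
                                (4, 1, 1)))
    res = pca(ens, list(range(1, 11)))
    assert res.eigenvalues.max() <= 1e-12


def test_rank_one_variation_loads_entirely_on_pc1():
    ens, _, _ = _two_mode_ensemble(var_ratio=(4.0, 0.0))
    res = pca(ens, list(range(1, 13)))
    assert res.proportions[0] == pytest.approx(1.0, abs=1e-9)
    assert variance_explained(res, 1) == pytest.approx(1.0, abs=1e-9)


def test_planted_4_to_1_modes_give_exact_proportions():
    ens, _, _ = _two_mode_ensemble(var_ratio=(4.0, 1.0))
    res = pca(ens, list(range(1, 13)))
    assert res.proportions[0] == pytest.approx(0.8, abs=1e-6)
    assert res.proportions[1] == pytest.approx(0.2, abs=1e-6)
    assert variance_explained(res, 1) == pytest.approx(0.8, abs=1e-6)


def test_pca_requires_three_entries():
    ens = make_ensemble(np.random.default_rng(0).normal(size=(2, 5, 3)))
    with pytest.raises(ValueError, match="3 entries"):
        pca(ens, [1, 2, 3, 4, 5])


def test_variance_explained_bounds():
    ens, _, _ = _two_mode_ensemble()
    res = pca(ens, list(range(1, 13)))
    assert variance_explained(res, res.n_components) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        variance_explained(res, 0)
    with pytest.raises(ValueError):
        variance_explained(res, res.n_components + 1)


def test_loadings_orthonormal_and_variance_budget_exact():
    rng = np.random.default_rng(3)
    ens = make_ensemble(rng.normal(size=(7, 9, 3)) * 5)
    res = pca(ens, list(range(1, 10)))
    G = res.loadings @ res.loadings.T
    np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-9)
    X = ens.coords.reshape(7, -1)
    total = ((X - X.mean(0)) ** 2).sum() / 6
    assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)
    # score covariance is diagonal with the eigenvalues on the diagonal
    S = res.scores.T @ res.scores / 6
    np.testing.assert_allclose(S, np.diag(res.eigenvalues), atol=1e-9 * total)


def test_eigenvalues_match_power_iteration_oracle():
    rng = np.random.default_rng(4)
    ens = make_ensemble(rng.normal(size=(8, 6, 3)) * 4)
    res = pca(ens, list(range(1, 7)))
    X = ens.coords.reshape(8, -1)
    C = np.cov(X, rowvar=False)
    ref = power_iteration_eigs(C, 5)
    np.testing.assert_allclose(res.eigenvalues[:5], ref, atol=1e-6)


def test_sign_convention_makes_largest_loading_positive():
    ens, _, _ = _two_mode_ensemble()
    res = pca(ens, list(range(1, 13)))
    for k in range(res.n_components):
        j = np.argmax(np.abs(res.loadings[k]))
        assert res.loadings[k, j] >= 0


def test_loading_vectors_unit_norm_and_1_based():
    ens, _, _ = _two_mode_ensemble()
    res = pca(ens, list(range(1, 13)))
    df = loading_vectors(res, 1)
    assert (df["magnitude"] ** 2).sum() == pytest.approx(1.0, abs=1e-9)
    assert list(df["column"]) == list(range(1, 13))
    with pytest.raises(ValueError):
        loading_vectors(res, 0)


def test_hinge_loading_concentrates_on_mobile_columns():
    # mode displacing only columns 9..12: top loadings live there
    rng = np.random.default_rng(5)
    L, n = 12, 8
    base = rng.normal(size=(L, 3)) * 10
    mode = np.zeros((L, 3))
    mode[8:] = rng.normal(size=(4, 3))
    mode /= np.linalg.norm(mode)
    amps = rng.normal(size=n) * 3
    ens = make_ensemble(base[None] + amps[:, None, None] * mode[None])
    res = pca(ens, list(range(1, 13)))
    df = loading_vectors(res, 1)
    top = set(df.nlargest(4, "magnitude")["column"])
    assert top <= {9, 10, 11, 12}


def test_trajectory_amplitude_zero_and_middle_frame_are_the_mean():
    ens, _, _ = _two_mode_ensemble()
    res = pca(ens, list(range(1, 13)))
    frames0 = pc_trajectory(res, 1, amplitude=0.0, n_frames=5)
    mean = res.mean.reshape(-1, 3)
    for f in frames0:
        np.testing.assert_allclose(f, mean, atol=1e-12)
    frames = pc_trajectory(res, 1, amplitude=2.0, n_frames=15)
    np.testing.assert_allclose(frames[7], mean, atol=1e-12)


def test_trajectory_frames_project_onto_their_own_scores():
    ens, _, _ = _two_mode_ensemble()
    # mean-fit first so loadings are orthogonal to rigid motions
    fitted, _ = iterative_mean_fit(ens, list(range(1, 13)), tol=1e-13)
    res = pca(fitted, list(range(1, 13)))
    s = np.linspace(-1.0, 1.0, 7)
    frames = pc_trajectory(res, 2, amplitude=1.0, n_frames=7)
    sd = np.sqrt(res.eigenvalues[1])
    for j, frame in enumerate(frames):
        scores = project(frame, res)
        assert scores[1] == pytest.approx(s[j] * sd, abs=1e-6)
        np.testing.assert_allclose(
            np.delete(scores[:5], 1), 0, atol=1e-6
        )


def test_projection_round_trip_and_mean():
    ens, _, _ = _two_mode_ensemble()
    fitted, _ = iterative_mean_fit(ens, list(range(1, 13)), tol=1e-13)
    res = pca(fitted, list(range(1, 13)))
    for e in range(fitted.n_entries):
        got = project(fitted.coords[e], res)
        np.testing.assert_allclose(got, res.scores[e], atol=1e-8)
    np.testing.assert_allclose(
        project(res.mean.reshape(-1, 3), res), 0, atol=1e-9
    )


def test_pca_invariant_to_prior_rigid_motions():
    from conftest import random_rigid

    rng = np.random.default_rng(6)
    ens, _, _ = _two_mode_ensemble()
    moved = ens.copy()
    for e in range(moved.n_entries):
        R, t = random_rigid(rng)
        moved.coords[e] = moved.coords[e] @ R.T + t
    cols = list(range(1, 13))
    f1, _ = iterative_mean_fit(ens, cols, tol=1e-13)
    f2, _ = iterative_mean_fit(moved, cols, tol=1e-13)
    r1 = pca(f1, cols)
    r2 = pca(f2, cols)
    np.testing.assert_allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-8)
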