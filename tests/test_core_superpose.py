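"""Superposition kernel, iterated mean fitting, and invariant-core finding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from corepca.core_superpose import (
    apply_transform,
    find_invariant_core,
    fit_on_core,
    iterative_mean_fit,
    kabsch,
)
from conftest import make_ensemble, random_rigid
from oracles import quaternion_grid_rmsd


def test_self_superposition_is_the_identity():
    X = np.random.default_rng(0).normal(size=(10, 3)) * 8
    sup = kabsch(X, X)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(sup.translation, 0, atol=1e-9)
    assert sup.rmsd < 1e-9


def test_exact_rigid_motion_is_recovered():
    X = np.random.default_rng(1).normal(size=(12, 3)) * 10
    Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    Y = X @ Rz.T + np.array([1.0, 2.0, 3.0])
    sup = kabsch(X, Y)
    assert sup.rmsd < 1e-9
    np.testing.assert_allclose(sup.rotation @ Rz, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(sup.rotation.T @ sup.rotation, np.eye(3), atol=1e-9)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_collinear_points_are_degenerate():
    X = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="degenerate"):
        kabsch(X, X)


def test_fewer_than_three_points_rejected():
    X = np.random.default_rng(0).normal(size=(2, 3))
    with pytest.raises(ValueError, match="3 points"):
        kabsch(X, X)


def test_rmsd_symmetric_and_rigid_invariant():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(15, 3)) * 10
    Y = X + rng.normal(size=(15, 3))
    r_xy = kabsch(X, Y).rmsd
    assert kabsch(Y, X).rmsd == pytest.approx(r_xy, abs=1e-9)
    for _ in range(5):
        R, t = random_rigid(rng)
        assert kabsch(X @ R.T + t, Y).rmsd == pytest.approx(r_xy, abs=1e-9)
        assert kabsch(X, Y @ R.T + t).rmsd == pytest.approx(r_xy, abs=1e-9)


def test_kabsch_matches_quaternion_grid_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        X = rng.normal(size=(10, 3)) * 10
        Y = X + rng.normal(size=(10, 3)) * 2
        R, t = random_rigid(rng)
        Y = Y @ R.T + t
        assert kabsch(X, Y).rmsd == pytest.approx(
            quaternion_grid_rmsd(X, Y), abs=1e-3
        )


def test_weighted_fit_prioritizes_heavy_points():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 3)) * 10
    Y = X.copy()
    Y[0] += 5.0  # one outlier
    w = np.ones(10)
    w[0] = 1e-9
    sup = kabsch(X, Y, weights=w)
    # with the outlier down-weighted, the remaining points fit perfectly
    res = apply_transform(Y[1:], sup) - X[1:]
    assert np.abs(res).max() < 1e-6


def test_mean_fit_collapses_identical_structures_in_scattered_poses():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(20, 3)) * 10
    frames = []
    for _ in range(4):
        R, t = random_rigid(rng)
        frames.append(base @ R.T + t)
    ens = make_ensemble(frames)
    fitted, mean = iterative_mean_fit(ens, list(range(1, 21)))
    for e in range(4):
        np.testing.assert_allclose(fitted.coords[e], fitted.coords[0], atol=1e-6)
    np.testing.assert_allclose(mean, fitted.coords[0], atol=1e-6)


def test_two_structure_mean_is_the_midpoint():
    rng = np.random.default_rng(6)
    a = rng.normal(size=(12, 3)) * 10
    b = a + rng.normal(size=(12, 3)) * 0.5
    ens = make_ensemble([a, b])
    fitted, mean = iterative_mean_fit(ens, list(range(1, 13)))
    np.testing.assert_allclose(
        mean, (fitted.coords[0] + fitted.coords[1]) / 2, atol=1e-9
    )
    # symmetric residuals about the mean
    np.testing.assert_allclose(
        fitted.coords[0] - mean, -(fitted.coords[1] - mean), atol=1e-9
    )


def test_mean_fit_transforms_non_fit_columns_too():
    rng = np.random.default_rng(7)
    base = rng.normal(size=(10, 3)) * 10
    R, t = random_rigid(rng)
    moved = base @ R.T + t
    ens = make_ensemble([base, moved])
    fitted, _ = iterative_mean_fit(ens, [1, 2, 3, 4, 5])
    # identical rigid copies: all columns coincide after fitting on 5
    np.testing.assert_allclose(fitted.coords[0], fitted.coords[1], atol=1e-6)


def test_zero_noise_ensemble_has_empty_removal_order():
    rng = np.random.default_rng(8)
    base = rng.normal(size=(15, 3)) * 10
    frames = []
    for _ in range(3):
        R, t = random_rigid(rng)
        frames.append(base @ R.T + t)
    ens = make_ensemble(frames)
    trace = find_invariant_core(ens, list(range(1, 16)))
    assert trace.removal_order == []
    assert trace.core == list(range(1, 16))
    assert trace.initial_volume == pytest.approx(0.0, abs=1e-12)


def _noisy_ensemble(rng, n_entries=6, L=20, sd=0.1, hot=None, hot_sd=None):
    base = rng.normal(size=(L, 3)) * 12
    frames = []
    for _ in range(n_entries):
        noise = rng.normal(0, sd, size=(L, 3))
        if hot is not None:
            noise[hot] = rng.normal(0, hot_sd, size=3)
        R, t = random_rigid(rng)
        frames.append((base + noise) @ R.T + t)
    return make_ensemble(frames)


def test_planted_high_variance_column_is_removed_first():
    rng = np.random.default_rng(9)
    ens = _noisy_ensemble(rng, sd=0.1, hot=7, hot_sd=1.0)
    trace = find_invariant_core(ens, list(range(1, 21)), volume_cutoff=1e-6)
    assert trace.removal_order[0][0] == 8  # 1-based column of index 7


def test_remaining_volume_strictly_decreases():
    rng = np.random.default_rng(10)
    ens = _noisy_ensemble(rng, sd=0.3)
    trace = find_invariant_core(ens, list(range(1, 21)), volume_cutoff=1e-4)
    rems = [rem for _, _, rem in trace.removal_order]
    assert len(rems) > 5
    assert all(b < a for a, b in zip(rems, rems[1:]))


def test_core_finding_is_pose_invariant():
    rng = np.random.default_rng(11)
    ens = _noisy_ensemble(rng, sd=0.2)
    trace1 = find_invariant_core(ens, list(range(1, 21)), volume_cutoff=1e-4)
    repose = ens.copy()
    for e in range(ens.n_entries):
        R, t = random_rigid(rng)
        repose.coords[e] = repose.coords[e] @ R.T + t
    trace2 = find_invariant_core(repose, list(range(1, 21)), volume_cutoff=1e-4)
    assert [c for c, _, _ in trace1.removal_order] == [
        c for c, _, _ in trace2.removal_order
    ]


def test_planted_core_recovered_with_high_jaccard():
    # mobile columns with 20-fold the core's positional SD (400x variance)
    rng = np.random.default_rng(12)
    L, n = 30, 8
    base = rng.normal(size=(L, 3)) * 12
    core_cols = set(range(1, 21))
    frames = []
    for _ in range(n):
        noise = rng.normal(0, 0.05, size=(L, 3))
        noise[20:] = rng.normal(0, 1.0, size=(10, 3))
        R, t = random_rigid(rng)
        frames.append((base + noise) @ R.T + t)
    ens = make_ensemble(frames)
    trace = find_invariant_core(ens, list(range(1, L + 1)), volume_cutoff=0.5)
    got = set(trace.core)
    jaccard = len(got & core_cols) / len(got | core_cols)
    assert jaccard >= 0.9


def test_fit_on_core_whole_chain_and_scatter_ordering():
    rng = np.random.default_rng(13)
    L, n = 30, 8
    base = rng.normal(size=(L, 3)) * 12
    frames = []
    for _ in range(n):
        noise = rng.normal(0, 0.05, size=(L, 3))
        noise[20:] = rng.normal(0, 1.0, size=(10, 3))
        R, t = random_rigid(rng)
        frames.append((base + noise) @ R.T + t)
    ens = make_ensemble(frames)
    fitted, _ = fit_on_core(ens, list(range(1, 21)))
    scatter = fitted.coords.std(axis=0).mean(axis=1)
    assert scatter[:20].max() < scatter[20:].min()


def test_fit_on_all_columns_equals_iterative_mean_fit():
    rng = np.random.default_rng(14)
    ens = _noisy_ensemble(rng, n_entries=4, sd=0.2)
    cols = list(range(1, 21))
    f1, m1 = fit_on_core(ens, cols)
    f2, m2 = iterative_mean_fit(ens, cols)
    np.testing.assert_allclose(f1.coords, f2.coords, atol=1e-12)
    np.testing.assert_allclose(m1, m2, atol=1e-12)


def test_single_entry_fit_is_a_rigid_motion():
    rng = np.random.default_rng(15)
    base = rng.normal(size=(10, 3)) * 10
    ens = make_ensemble([base])
    fitted, _ = iterative_mean_fit(ens, list(range(1, 11)))
    # internal geometry unchanged
    d0 = np.linalg.norm(base[:, None] - base[None, :], axis=2)
    d1 = np.linalg.norm(
        fitted.coords[0][:, None] - fitted.coords[0][None, :], axis=2
    )
    np.testing.assert_allclose(d0, d1, atol=1e-9)


def test_mean_shift_sequence_is_eventually_monotone():
    rng = np.random.default_rng(16)
    base = rng.normal(size=(15, 3)) * 10
    frames = [
        (base + rng.normal(0, 0.5, size=(15, 3))) @ random_rigid(rng)[0].T
        + rng.uniform(-20, 20, 3)
        for _ in range(5)
    ]
    ens = make_ensemble(frames)
    # instrument: track mean shifts across refit rounds
    from corepca.core_superpose import apply_transform, kabsch

    out = ens.copy()
    idx = np.arange(15)
    ref = out.coords[0]
    for e in range(5):
        sup = kabsch(ref, out.coords[e])
        out.coords[e] = apply_transform(out.coords[e], sup)
    mean = out.coords.mean(axis=0)
    shifts = []
    for _ in range(20):
        for e in range(5):
            sup = kabsch(mean, out.coords[e])
            out.coords[e] = apply_transform(out.coords[e], sup)
        new_mean = out.coords.mean(axis=0)
        shifts.append(float(np.sqrt(((new_mean - mean) ** 2).sum(1).mean())))
        mean = new_mean
    # monotone non-increasing after the first refit, down to the
    # floating-point floor where the sequence flatlines
    assert all(
        b <= a * (1 + 1e-9) or a < 1e-12
        for a, b in zip(shifts[1:], shifts[2:])
    )
    assert shifts[5] < 1e-10  # converged well below the default tolerance
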