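"""Attractor classification on constructed and simulated trajectories."""

import numpy as np
import pytest

import metaecosim as me
from metaecosim.classify import _monotone_decay

from conftest import constant_trajectory


def _params():
    return me.ModelParams.with_dispersal(0.0, 0.0)


def test_constant_identical_patches_is_homogeneous_equilibrium(nested):
    traj = constant_trajectory(nested, [1.0] * 4 + [2.0] * 4 + [0.1] * 4, _params())
    rep = me.classify_trajectory(traj)
    assert rep.state_code == "HOM_EQ"
    assert rep.amplitude < 1e-12
    assert rep.heterogeneity < 1e-12


def test_offset_oscillation_in_one_patch_is_heterogeneous(nested):
    """A cycle riding on a shifted mean in one patch flips both labels."""
    t = np.linspace(0.0, 5000.0, 4001)
    X = np.tile([1.0] * 4 + [2.0] * 4 + [0.1] * 4, (len(t), 1))
    X[:, 8] += 0.3 * (1.0 + np.sin(2 * np.pi * t / 250.0))  # patch A1 consumer
    rep = me.classify_trajectory(me.Trajectory(t, X, _params(), nested))
    assert rep.kind == "oscillation"
    assert rep.spatial == "heterogeneous"
    assert rep.period == pytest.approx(250.0, rel=1e-3)


def test_phase_shifted_identical_cycles_are_homogeneous(nested):
    """Same orbit, different phase: not spatial heterogeneity."""
    t = np.linspace(0.0, 5000.0, 4001)
    X = np.tile([1.0] * 4 + [2.0] * 4 + [0.1] * 4, (len(t), 1))
    for i, phase in enumerate([0.0, 0.3, 1.1, 2.7]):
        X[:, 8 + i] += 0.3 * (1.0 + np.sin(2 * np.pi * t / 311.0 + phase))
    rep = me.classify_trajectory(me.Trajectory(t, X, _params(), nested))
    assert rep.kind == "oscillation"
    assert rep.spatial == "homogeneous"


def test_window_shorter_than_two_periods_is_inconclusive(nested):
    t = np.linspace(0.0, 400.0, 801)
    X = np.tile([1.0] * 12, (len(t), 1))
    X[:, 8] += 0.5 * (1 + np.sin(2 * np.pi * t / 300.0))
    rep = me.classify_trajectory(me.Trajectory(t, X, _params(), nested))
    assert rep.inconclusive
    assert rep.state_code == "FAILED"


def test_loosening_amplitude_tolerance_only_moves_toward_equilibrium(nested):
    t = np.linspace(0.0, 5000.0, 4001)
    X = np.tile([1.0] * 12, (len(t), 1))
    X[:, 8] += 1e-4 * np.sin(2 * np.pi * t / 200.0)
    traj = me.Trajectory(t, X, _params(), nested)
    tight = me.classify_trajectory(traj, tol_eq=1e-6)
    loose = me.classify_trajectory(traj, tol_eq=1e-2)
    assert tight.kind == "oscillation"
    assert loose.kind == "equilibrium"


def test_report_invariants(nested):
    t = np.linspace(0.0, 5000.0, 4001)
    X = np.tile([1.0] * 12, (len(t), 1))
    X[:, 4:8] += 0.5 * (1 + np.sin(2 * np.pi * t[:, None] / 400.0))
    rep = me.classify_trajectory(me.Trajectory(t, X, _params(), nested))
    assert np.all(rep.mins <= rep.means + 1e-12)
    assert np.all(rep.means <= rep.maxs + 1e-12)
    assert rep.meta_c_min <= rep.meta_c_max


def test_labels_invariant_under_location_swap(nested):
    """Swapping locations permutes patches but not the verdict."""
    t = np.linspace(0.0, 5000.0, 2001)
    base = np.array([0.6, 0.6, 0.58, 0.58, 6.7, 1.9, 1.9, 6.7,
                     0.08, 0.09, 0.09, 0.08])
    X = np.tile(base, (len(t), 1))
    traj = me.Trajectory(t, X, _params(), nested)
    perm = nested.location_swap_permutation()
    full_perm = np.concatenate([perm, perm + 4, perm + 8])
    traj_swapped = me.Trajectory(t, X[:, full_perm], _params(), nested)
    a = me.classify_trajectory(traj)
    b = me.classify_trajectory(traj_swapped)
    assert a.state_code == b.state_code == "HET_EQ"
    assert a.heterogeneity == pytest.approx(b.heterogeneity)


def _fake_report(means, kind="equilibrium", spatial="heterogeneous"):
    means = np.asarray(means, dtype=float)
    return me.AttractorReport(
        kind=kind,
        spatial=spatial,
        means=means,
        mins=means,
        maxs=means,
        meta_c_min=float(means[2].sum()),
        meta_c_max=float(means[2].sum()),
        amplitude=0.0,
        heterogeneity=float(means[1].max() - means[1].min()),
    )


def _mirror(means, nested):
    perm = nested.location_swap_permutation()
    return np.asarray(means)[:, perm]


def test_ensemble_single_attractor_consensus(nested):
    m = [[0.6] * 4, [4.0] * 4, [0.09] * 4]
    v = me.classify_ensemble(
        [_fake_report(m, spatial="homogeneous") for _ in range(5)], nested
    )
    assert v.state_code == "HOM_EQ"
    assert v.n_attractors == 1
    assert not v.bistable


def test_ensemble_detects_mirror_pair_as_bistable(nested):
    m = np.array([[0.6, 0.61, 0.58, 0.59], [6.7, 1.9, 1.9, 6.7],
                  [0.08, 0.09, 0.09, 0.08]])
    reports = [_fake_report(m) for _ in range(3)] + [
        _fake_report(_mirror(m, nested)) for _ in range(2)
    ]
    v = me.classify_ensemble(reports, nested)
    assert v.state_code == "HET_EQ"
    assert v.n_attractors == 2
    assert v.bistable


def test_ensemble_disagreement_is_mixed(nested):
    m = [[0.6] * 4, [4.0] * 4, [0.09] * 4]
    reports = [
        _fake_report(m, spatial="homogeneous"),
        _fake_report(m, kind="oscillation", spatial="homogeneous"),
    ]
    v = me.classify_ensemble(reports, nested)
    assert v.state_code == "MIXED"


def test_ensemble_counts_inconclusive_members(nested):
    m = [[0.6] * 4, [4.0] * 4, [0.09] * 4]
    bad = _fake_report(m, spatial="homogeneous")
    bad.inconclusive = True
    v = me.classify_ensemble(
        [_fake_report(m, spatial="homogeneous"), bad, bad], nested
    )
    assert v.n_inconclusive == 2
    assert v.state_code == "HOM_EQ"
    with pytest.raises(ValueError):
        me.classify_ensemble([bad])


def test_monotone_decay_discriminates_trends():
    assert _monotone_decay([4.0, 2.0, 1.0, 0.5], rel=0.01)
    assert not _monotone_decay([4.0, 2.0, 2.5, 0.5], rel=0.01)  # fluctuating
    assert not _monotone_decay([1.0, 0.9999, 0.9998, 0.9997], rel=0.01)  # flat


def test_settling_agrees_with_fixed_point_oracle(nested, closed_eq):
    """Uncoupled patches settle exactly on the analytic equilibrium."""
    p = me.ModelParams.with_dispersal(0.0, 0.0)
    ens = me.sample_initial_conditions(9, 2, me.default_ic_ranges(p))
    for x0 in ens.draws:
        rep = me.settle_and_classify(p, nested, x0)
        assert rep.state_code == "HOM_EQ"
        expected = np.tile(np.array(closed_eq)[:, None], (1, 4))
        np.testing.assert_allclose(rep.means, expected, atol=1e-5)
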