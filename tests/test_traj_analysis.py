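"""Superposition, RMSF, distance series, RDF, DCCM, H-bonds, mixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from poremode.enm import dccm_from_modes, mode_fluctuations
from poremode.structure_io import AtomRecord, StructureModel, Trajectory
from poremode.synthetic_data import (
    EnsembleSpec,
    MixtureSpec,
    SolventSpec,
    make_solvent_box,
    sample_harmonic_ensemble,
    sample_mixture_series,
)
from poremode.traj_analysis import (
    dccm_from_traj,
    distance_series,
    fit_mixture_1d,
    hbond_series,
    kabsch_superpose,
    nearest_ion_series,
    rdf,
    rmsf,
)

from conftest import random_ca_structure


def quaternion_rmsd(mobile, reference):
    """Independent minimal-RMSD via the quaternion eigenvalue method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    R = x.T @ y
    K = np.array(
        [
            [R[0, 0] + R[1, 1] + R[2, 2], R[1, 2] - R[2, 1], R[2, 0] - R[0, 2], R[0, 1] - R[1, 0]],
            [R[1, 2] - R[2, 1], R[0, 0] - R[1, 1] - R[2, 2], R[0, 1] + R[1, 0], R[0, 2] + R[2, 0]],
            [R[2, 0] - R[0, 2], R[0, 1] + R[1, 0], -R[0, 0] + R[1, 1] - R[2, 2], R[1, 2] + R[2, 1]],
            [R[0, 1] - R[1, 0], R[0, 2] + R[2, 0], R[1, 2] + R[2, 1], -R[0, 0] - R[1, 1] + R[2, 2]],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = mobile.shape[0]
    msd = max((x**2).sum() + (y**2).sum() - 2 * lam_max, 0.0) / n
    return float(np.sqrt(msd))


def make_traj(frames, topology=None, box=None):
    if topology is None:
        topology = random_ca_structure(frames.shape[1], seed=0)
    return Trajectory(frames=np.asarray(frames, float), topology=topology, box=box)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def test_self_superposition_rmsd_zero():
    c = random_ca_structure(10, seed=1).coords
    rotated, r = kabsch_superpose(c, c)
    assert r == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(rotated, c, atol=1e-12)


def test_rigid_copy_recovered():
    c = random_ca_structure(12, seed=2).coords
    rot = Rotation.from_euler("xyz", [0.3, 1.4, -2.0])
    moved = rot.apply(c) + np.array([1.0, -5.0, 3.0])
    rotated, r = kabsch_superpose(moved, c)
    assert r < 1e-10
    np.testing.assert_allclose(rotated, c, atol=1e-9)


def test_rmsd_matches_quaternion_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        _, r = kabsch_superpose(a, b)
        assert r == pytest.approx(quaternion_rmsd(a, b), abs=1e-10)


def test_collinear_fit_set_rejected():
    line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line + 1.0)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def test_static_trajectory_rmsf_zero():
    c = random_ca_structure(8, seed=4).coords
    traj = make_traj(np.tile(c, (5, 1, 1)))
    np.testing.assert_allclose(rmsf(traj).values, 0.0, atol=1e-12)


def test_rigid_body_motion_removed_by_fit():
    c = random_ca_structure(15, seed=5).coords
    rng = np.random.default_rng(6)
    frames = []
    for _ in range(10):
        rot = Rotation.from_rotvec(rng.normal(scale=0.5, size=3))
        frames.append(rot.apply(c) + rng.normal(scale=5.0, size=3))
    prof = rmsf(make_traj(np.stack(frames)))
    np.testing.assert_allclose(prof.values, 0.0, atol=1e-6)


def test_harmonic_ensemble_rmsf_matches_closed_form(small_system):
    s, _, modes = small_system
    k_set = list(range(1, modes.n_modes + 1))
    kT = 0.25
    spec = EnsembleSpec(modes=modes, k_set=k_set, kT=kT, n_frames=20000, seed=7)
    traj = sample_harmonic_ensemble(spec, s.coords)
    target = np.sqrt(kT * mode_fluctuations(modes, k_set))
    got = rmsf(traj).values
    assert np.max(np.abs(got - target) / target) < 0.05


def test_rmsf_needs_two_frames():
    c = random_ca_structure(5, seed=8).coords
    with pytest.raises(ValueError, match="2 frames"):
        rmsf(make_traj(c[None]))


# ---------------------------------------------------------------------------
# Distance series
# ---------------------------------------------------------------------------

def test_constant_pair_distance():
    c = np.zeros((2, 3))
    c[1, 0] = 7.0
    traj = make_traj(np.tile(c, (6, 1, 1)))
    s = distance_series(traj, ([0], [1]))
    np.testing.assert_allclose(s.values, 7.0)
    np.testing.assert_allclose(s.in_nm(), 0.7)


def test_min_metric_matches_brute_force():
    rng = np.random.default_rng(9)
    frames = rng.uniform(0, 20, (8, 12, 3))
    traj = make_traj(frames)
    A, B = [0, 1, 2], [5, 8, 11]
    s = distance_series(traj, (A, B), metric="min")
    for f in range(8):
        expect = min(
            np.linalg.norm(frames[f, i] - frames[f, j]) for i in A for j in B
        )
        assert s.values[f] == pytest.approx(expect, abs=1e-12)
    # symmetric under set swap
    np.testing.assert_array_equal(
        distance_series(traj, (B, A), metric="min").values, s.values
    )


def test_empty_set_rejected():
    traj = make_traj(np.zeros((2, 3, 3)))
    with pytest.raises(ValueError, match="non-empty"):
        distance_series(traj, ([], [0]))


# ---------------------------------------------------------------------------
# Nearest-ion series
# ---------------------------------------------------------------------------

def test_single_ion_constant_distance():
    frames = np.zeros((4, 2, 3))
    frames[:, 1, 0] = 5.0
    s = nearest_ion_series(make_traj(frames), [0], [1])
    np.testing.assert_allclose(s.values, 5.0)


def test_switches_to_closer_ion_at_crossing():
    n_frames = 11
    frames = np.zeros((n_frames, 3, 3))
    frames[:, 1, 0] = 10.0  # static ion at 10 Å
    frames[:, 2, 0] = np.linspace(20.0, 2.0, n_frames)  # approaching ion
    s = nearest_ion_series(make_traj(frames), [0], [1, 2])
    expect = np.minimum(10.0, np.linspace(20.0, 2.0, n_frames))
    np.testing.assert_allclose(s.values, expect)


def test_minimum_image_shortens_distances():
    frames = np.zeros((1, 2, 3))
    frames[0, 1, 0] = 18.0  # beyond half of a 20 Å box
    topo = random_ca_structure(2, seed=10)
    no_pbc = nearest_ion_series(make_traj(frames, topo), [0], [1]).values[0]
    with_pbc = nearest_ion_series(
        Trajectory(frames=frames, topology=topo, box=np.array([20.0, 20.0, 20.0])),
        [0],
        [1],
    ).values[0]
    assert with_pbc == pytest.approx(2.0)
    assert with_pbc <= no_pbc


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def test_ideal_gas_g_is_one():
    # all-pairs g(r): every particle is a reference, self-pairs excluded
    traj = make_solvent_box(SolventSpec(n_particles=500, n_frames=100, seed=11))
    solvent = np.arange(1, 501)
    prof = rdf(traj, solvent, solvent, r_max=12.0, bin_width=0.5)
    window = (prof.r_centers >= 2.0) & (prof.r_centers <= 10.0)
    np.testing.assert_allclose(prof.g[window], 1.0, atol=0.05)


def test_hard_exclusion_zero_inside():
    traj = make_solvent_box(
        SolventSpec(box=(24.0, 24.0, 24.0), n_particles=300, n_frames=100,
                    exclusion_radius=3.0, seed=12)
    )
    prof = rdf(traj, [0], np.arange(1, 301), r_max=10.0, bin_width=0.25)
    assert np.all(prof.g[prof.r_centers < 3.0 - 0.125] == 0.0)
    far = prof.r_centers > 5.0
    np.testing.assert_allclose(prof.g[far], 1.0, atol=0.25)


def test_mass_balance():
    traj = make_solvent_box(SolventSpec(n_particles=400, n_frames=50, seed=13))
    prof = rdf(traj, [0], np.arange(1, 401), r_max=15.0, bin_width=0.3)
    assert prof.mass_balance() == pytest.approx(prof.mean_pair_count, rel=0.01)


def test_tiny_configuration_matches_hand_enumeration():
    rng = np.random.default_rng(14)
    box = np.array([30.0, 30.0, 30.0])
    pts = rng.uniform(0, 30, (20, 3))
    frames = pts[None]
    topo = random_ca_structure(20, seed=14)
    traj = Trajectory(frames=frames, topology=topo, box=box)
    r_max, bw = 12.0, 2.0
    prof = rdf(traj, [0], np.arange(1, 20), r_max=r_max, bin_width=bw)
    # exhaustive pair enumeration with minimum image
    counts = np.zeros(6)
    for j in range(1, 20):
        d = pts[0] - pts[j]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d)
        if r < r_max:
            counts[int(r // bw)] += 1
    rho = 19 / box.prod()
    centers = bw * (np.arange(6) + 0.5)
    expect = counts / (rho * 4 * np.pi * centers**2 * bw)
    np.testing.assert_allclose(prof.g, expect, atol=1e-10)


def test_r_max_beyond_half_box_rejected():
    traj = make_solvent_box(SolventSpec(box=(20.0, 20.0, 20.0), n_frames=2, seed=15))
    with pytest.raises(ValueError, match="half"):
        rdf(traj, [0], [1, 2], r_max=11.0)


def test_self_pairs_excluded_when_sets_overlap():
    # 2 points at fixed separation; ref set == target set
    frames = np.zeros((1, 2, 3))
    frames[0, 1, 0] = 5.0
    traj = Trajectory(frames=frames, topology=random_ca_structure(2, seed=16),
                      box=np.array([40.0, 40.0, 40.0]))
    prof = rdf(traj, [0, 1], [0, 1], r_max=10.0, bin_width=1.0)
    assert prof.mean_pair_count == pytest.approx(1.0)  # only the cross pair


# ---------------------------------------------------------------------------
# DCCM from trajectory
# ---------------------------------------------------------------------------

def test_rank_one_motion_equals_mode_correlation(small_system):
    s, _, modes = small_system
    from poremode.enm import mode_correlation

    V = modes.mode_vector(2)
    t = np.linspace(0, 4 * np.pi, 40)
    amp = 1e-4 * np.sin(t)  # tiny: superposition corrections are 2nd order
    frames = s.coords[None] + amp[:, None, None] * V[None]
    cmap = dccm_from_traj(make_traj(frames))
    expect = mode_correlation(modes, 2).values
    np.testing.assert_allclose(cmap.values, expect, atol=1e-6)


def test_harmonic_ensemble_dccm_converges_to_mode_dccm(small_system):
    s, _, modes = small_system
    k_set = list(range(1, 11))
    spec = EnsembleSpec(modes=modes, k_set=k_set, kT=0.25, n_frames=5000, seed=17)
    traj = sample_harmonic_ensemble(spec, s.coords)
    got = dccm_from_traj(traj).values
    expect = dccm_from_modes(modes, k_set).values
    assert np.max(np.abs(got - expect)) <= 0.1


def test_reversed_frame_order_gives_identical_map(small_system):
    s, _, modes = small_system
    spec = EnsembleSpec(modes=modes, kT=0.2, n_frames=200, seed=18)
    traj = sample_harmonic_ensemble(spec, s.coords)
    a = dccm_from_traj(traj).values
    b = dccm_from_traj(make_traj(traj.frames[::-1], traj.topology)).values
    # moments are permutation-invariant; the only order dependence is the
    # first-pass fit reference (frame 0), refined away by the second pass
    np.testing.assert_allclose(a, b, atol=1e-5)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _linear_frames(da_dist, n=1):
    """Donor at origin, acceptor along x; optional H on the D-A axis."""
    frames = np.zeros((n, 3, 3))
    frames[:, 1, 0] = 1.0  # hydrogen 1 Å from donor toward acceptor
    frames[:, 2, 0] = da_dist
    return frames


def test_heavy_atom_distance_criterion():
    traj = make_traj(_linear_frames(2.8))
    counts, occ = hbond_series(traj, [0], None, [2], d_max=3.5)
    assert counts[0] == 1 and occ[(0, 2)] == 1.0
    counts, _ = hbond_series(make_traj(_linear_frames(4.0)), [0], None, [2], d_max=3.5)
    assert counts[0] == 0


def test_angle_criterion_with_hydrogens():
    frames = _linear_frames(2.8)
    traj = make_traj(frames)
    counts, _ = hbond_series(traj, [0], [1], [2], d_max=3.5, angle_min=150.0)
    assert counts[0] == 1  # perfectly linear D-H...A = 180 deg
    bent = frames.copy()
    bent[0, 1] = [0.5, 0.87, 0.0]  # H off-axis: angle ~ 120 deg
    counts, _ = hbond_series(make_traj(bent), [0], [1], [2], d_max=3.5, angle_min=150.0)
    assert counts[0] == 0


def test_occupancy_matches_hand_count():
    dists = [2.8, 2.9, 4.2, 3.1, 5.0]  # bonded in frames 0,1,3 -> 3/5
    frames = np.concatenate([_linear_frames(d) for d in dists])
    counts, occ = hbond_series(make_traj(frames), [0], None, [2], d_max=3.5)
    np.testing.assert_array_equal(counts, [1, 1, 0, 1, 0])
    assert occ[(0, 2)] == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture
# ---------------------------------------------------------------------------

def test_single_gaussian_recovery():
    rng = np.random.default_rng(19)
    x = rng.normal(0.8, 0.05, 5000)
    fit = fit_mixture_1d(x, k_max=3, seed=1)
    assert fit.k == 1
    assert fit.means[0] == pytest.approx(0.8, abs=0.01)
    assert fit.weights[0] == pytest.approx(1.0)


def test_bimodal_recovery_against_generating_truth():
    spec = MixtureSpec(
        components=[(0.80, 0.05, 0.6), (1.10, 0.05, 0.4)], n_samples=10000, seed=20
    )
    samples, _ = sample_mixture_series(spec)
    fit = fit_mixture_1d(samples, k_max=3, seed=2)
    assert fit.k == 2
    np.testing.assert_allclose(fit.means, [0.80, 1.10], atol=0.01)
    np.testing.assert_allclose(fit.weights, [0.6, 0.4], atol=0.05)
    np.testing.assert_allclose(fit.sds, [0.05, 0.05], atol=0.01)


def test_matches_sklearn_reference():
    sklearn_mix = pytest.importorskip("sklearn.mixture")
    spec = MixtureSpec(
        components=[(8.0, 0.5, 0.5), (11.0, 0.5, 0.5)], n_samples=5000, seed=21
    )
    samples, _ = sample_mixture_series(spec)
    fit = fit_mixture_1d(samples, k_max=2, seed=3)
    gm = sklearn_mix.GaussianMixture(n_components=2, n_init=5, random_state=0)
    gm.fit(samples[:, None])
    ref_means = np.sort(gm.means_.ravel())
    np.testing.assert_allclose(fit.means, ref_means, atol=0.02)


def test_loglik_trace_is_monotone():
    spec = MixtureSpec(n_samples=2000, seed=22)
    samples, _ = sample_mixture_series(spec)
    fit = fit_mixture_1d(samples, k_max=3, seed=4)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-7 * np.abs(fit.loglik_trace[:-1]))
    assert abs(sum(fit.weights) - 1.0) < 1e-9


@settings(deadline=None, max_examples=10, derandomize=True)
@given(seed=st.integers(0, 10_000), sep=st.floats(2.0, 6.0))
def test_em_likelihood_never_decreases(seed, sep):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 1, 300), rng.normal(sep, 1, 300)])
    fit = fit_mixture_1d(x, k_max=2, n_starts=2, seed=seed)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-7 * np.abs(fit.loglik_trace[:-1]))


def test_degenerate_samples_rejected():
    with pytest.raises(ValueError, match="degenerate|zero variance"):
        fit_mixture_1d(np.full(1000, 3.14), k_max=2, seed=5)


def test_deterministic_given_seed():
    spec = MixtureSpec(n_samples=3000, seed=23)
    samples, _ = sample_mixture_series(spec)
    a = fit_mixture_1d(samples, seed=6)
    b = fit_mixture_1d(samples, seed=6)
    assert a.components == b.components and a.bic == b.bic
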