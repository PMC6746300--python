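"""Synthetic generators: toy dimer geometry, Markov switching, maps, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from chearray import maps, switch, synth
from chearray.errors import ValidationError
from chearray.switch import SelectionSpec
from chearray.synth import (
    SwitchingParams,
    generate_fit_ensemble,
    generate_half_maps,
    generate_state_ensemble,
    generate_switching_trajectory,
    make_toy_dimer,
    toy_contact_pairs,
)


# --------------------------------------------------------------- toy dimer


def test_toy_dimer_selection_counts(toy_model):
    p4_a = SelectionSpec(chain="A", domain="P4", atom_name="CA")
    assert len(p4_a.resolve(toy_model.atoms)) == 191  # residues 352..542
    p5_a = SelectionSpec(chain="A", domain="P5")
    assert len(p5_a.resolve(toy_model.atoms)) == 129  # residues 543..671
    p3_a = SelectionSpec(chain="A", domain="P3")
    assert len(p3_a.resolve(toy_model.atoms)) == 62  # residues 290..351
    # receptor anchors carry receptor residue labels 379 and 390
    rcpt = SelectionSpec(domain="RCPT")
    resids = set(toy_model.atoms["resid"].to_numpy()[rcpt.resolve(toy_model.atoms)])
    assert {379, 390} <= resids


def test_toy_dimer_deterministic():
    a, b = make_toy_dimer(), make_toy_dimer()
    assert np.array_equal(a.coords, b.coords)
    assert a.atoms.equals(b.atoms)


def test_toy_p4_is_mirror_asymmetric(p4_template):
    """No improper rotation maps the P4 bead cloud onto itself within 1 A."""
    from chearray.switch import superpose

    X = p4_template.coords - p4_template.coords.mean(axis=0)
    best = np.inf
    for mirror_axis in range(3):
        M = X.copy()
        M[:, mirror_axis] *= -1.0
        # optimal proper rotation after the reflection: exhaustive symmetry
        # search over the superposition of the mirrored cloud onto the original
        _, _, rmsd = superpose(M, X)
        best = min(best, rmsd)
    assert best > 1.0


def test_dip_moves_p4_not_p5(toy_model):
    dipped = toy_model.dipped_coords(25.0)
    p4 = SelectionSpec(chain="A", domain="P4").resolve(toy_model.atoms)
    p5 = np.concatenate([
        SelectionSpec(chain="A", domain="P5").resolve(toy_model.atoms),
        SelectionSpec(chain="B", domain="P5").resolve(toy_model.atoms),
    ])
    assert np.linalg.norm(dipped[p4] - toy_model.coords[p4], axis=1).min() > 1.0
    assert np.array_equal(dipped[p5], toy_model.coords[p5])


def _min_dist(model, coords, name):
    pair = toy_contact_pairs()[name]
    ia = pair.a.resolve(model.atoms)
    ib = pair.b.resolve(model.atoms)
    return np.linalg.norm(coords[ia][:, None] - coords[ib][None], axis=-1).min()


@pytest.mark.parametrize("name,undipped_bound,dipped_bound", [
    ("R297/E397", False, True),
    ("E390/R379", False, True),
    ("D333/K390", True, False),
    ("D345/R379", True, False),
])
def test_contact_proxies_are_state_linked(toy_model, name, undipped_bound,
                                          dipped_bound):
    cutoff = 4.5
    dipped = toy_model.dipped_coords(25.0)
    assert (_min_dist(toy_model, toy_model.coords, name) <= cutoff) == undipped_bound
    assert (_min_dist(toy_model, dipped, name) <= cutoff) == dipped_bound


def test_mutant_blocks_stabilizing_contact():
    mut = make_toy_dimer(mutant=True)
    dipped = mut.dipped_coords(25.0)
    assert _min_dist(mut, dipped, "R297/E397") > 4.5
    # the receptor-tip bridge is untouched by the mutation
    assert _min_dist(mut, dipped, "E390/R379") <= 4.5


# ---------------------------------------------------------------- switching


def test_switching_zero_rate_stays_undipped(toy_model):
    params = SwitchingParams(k_dip=0.0, n_frames=500, seed=1)
    _, truth = generate_switching_trajectory(toy_model, params)
    assert not truth.states.any()
    assert truth.events == []


def test_switching_frozen_dipped_geometry(toy_model):
    params = SwitchingParams(k_dip=0.0, k_undip=0.0, noise_sigma=0.0,
                             n_frames=3, seed=1, start_dipped=True)
    traj, truth = generate_switching_trajectory(toy_model, params)
    assert truth.states.all()
    assert np.array_equal(traj.coordinates[0], traj.coordinates[2])
    dipped = toy_model.dipped_coords(params.dip_angle)
    assert np.array_equal(traj.coordinates[0], dipped)


def test_switching_stationary_occupancy(toy_model):
    """Long-run dipped fraction matches the Markov stationary distribution.

    The tolerance is 3 standard errors of the mean of a two-state Markov
    chain, i.e. the binomial SE inflated by the autocorrelation factor
    sqrt((1+rho)/(1-rho)) with rho = exp(-(k_dip+k_undip) dt).
    """
    k_dip, k_undip, dt, n = 0.5, 1.0, 0.02, 50_000
    params = SwitchingParams(k_dip=k_dip, k_undip=k_undip, frame_interval=dt,
                             n_frames=n, noise_sigma=0.0, seed=17)
    _, truth = generate_switching_trajectory(toy_model, params)
    p = truth.stationary_dipped
    assert p == pytest.approx(k_dip / (k_dip + k_undip))
    rho = np.exp(-(k_dip + k_undip) * dt)
    se = np.sqrt(p * (1 - p) / n) * np.sqrt((1 + rho) / (1 - rho))
    assert abs(truth.states.mean() - p) <= 3 * se


def test_switching_truth_consistent_with_data(toy_model):
    params = SwitchingParams(seed=23, n_frames=1500)
    traj, truth = generate_switching_trajectory(toy_model, params)
    # events exactly tile the dipped frames
    from_events = np.zeros(params.n_frames, dtype=bool)
    for ev in truth.events:
        a = int(round(ev.start / params.frame_interval))
        b = int(round(ev.end / params.frame_interval))
        from_events[a:b] = True
    assert np.array_equal(from_events, truth.states)
    # contact intervals coincide with events for the wild type
    assert truth.contact_intervals == [(e.start, e.end) for e in truth.events]


def test_switching_mutant_contact_intervals_empty(toy_model):
    params = SwitchingParams(seed=23, n_frames=1500, mutant=True)
    _, truth = generate_switching_trajectory(make_toy_dimer(mutant=True), params)
    assert truth.contact_intervals == []


def test_switching_seed_reproducibility(toy_model):
    params = SwitchingParams(seed=5, n_frames=200)
    t1, _ = generate_switching_trajectory(toy_model, params)
    t2, _ = generate_switching_trajectory(toy_model, params)
    assert np.array_equal(t1.coordinates, t2.coordinates)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=10, deadline=None)
def test_switching_params_validation_property(seed):
    with pytest.raises(ValidationError):
        SwitchingParams(k_dip=-0.1, seed=seed)
    with pytest.raises(ValidationError):
        SwitchingParams(n_frames=0, seed=seed)


# ----------------------------------------------------------------- ensemble


def test_state_ensemble_populations_and_labels(toy_model):
    traj, truth = generate_state_ensemble(toy_model, n_frames=500, seed=2)
    assert traj.n_frames == 500
    counts = np.bincount(truth.labels, minlength=4) / 500
    assert np.abs(counts - truth.populations).max() < 0.06
    with pytest.raises(ValidationError):
        generate_state_ensemble(toy_model, populations=(0.5, 0.4))


# -------------------------------------------------------------------- maps


def test_half_maps_infinite_snr_identical(spherical_cloud):
    h1, h2, truth = generate_half_maps(spherical_cloud, snr=np.inf, seed=1)
    assert np.array_equal(h1.values, h2.values)
    curve = maps.fsc(h1, h2)
    assert np.all(np.abs(curve.correlation - 1.0) < 1e-9)


def test_half_maps_independent_noise(spherical_cloud):
    h1, h2, truth = generate_half_maps(spherical_cloud, snr=1.0, seed=1)
    assert not np.array_equal(h1.values, h2.values)
    # the two noise realizations decorrelate shell-wise (few-mode low-k
    # shells are excluded: their empirical correlation has a large SE)
    n1 = maps.DensityMap(h1.values - truth.reference.values, h1.voxel_size)
    n2 = maps.DensityMap(h2.values - truth.reference.values, h2.voxel_size)
    curve = maps.fsc(n1, n2)
    rich = curve.counts > 200
    assert np.abs(curve.correlation[rich]).mean() < 0.1


def test_half_maps_z_attenuation_direction(spherical_cloud):
    h1, h2, _ = generate_half_maps(
        spherical_cloud, resolution=8, snr=0.5, noise_mode="white",
        anisotropy=(np.array([0.0, 0.0, 1.0]), 0.3), seed=2,
    )
    cset = maps.conical_fsc(h1, h2, axes=np.eye(3))
    rx, ry, rz = (r.resolution for r in cset.resolutions())
    assert rz > rx and rz > ry  # Z cone strictly coarser (in Angstrom)


def test_half_maps_validation(spherical_cloud):
    with pytest.raises(ValidationError):
        generate_half_maps(spherical_cloud, snr=0.0)
    with pytest.raises(ValidationError):
        generate_half_maps(spherical_cloud, noise_mode="pink")


# -------------------------------------------------------------------- fits


def test_fit_ensemble_single_pose_zero_jitter():
    from chearray.docking import DockingConfig, cluster_fits

    pose = (Rotation.identity().as_quat(), np.zeros(3))
    fits, truth = generate_fit_ensemble([pose], [1.0], n=50,
                                        angle_jitter=0.0, shift_jitter=0.0, seed=3)
    classes = cluster_fits(fits, DockingConfig())
    assert len(classes) == 1
    assert classes[0].occupancy == 1.0


def test_fit_ensemble_deterministic():
    pose = (Rotation.identity().as_quat(), np.zeros(3))
    f1, _ = generate_fit_ensemble([pose], [1.0], n=20, seed=9)
    f2, _ = generate_fit_ensemble([pose], [1.0], n=20, seed=9)
    for a, b in zip(f1, f2):
        assert np.array_equal(a.rotation, b.rotation)
        assert a.score == b.score


def test_fit_ensemble_weights_must_sum_to_one():
    pose = (Rotation.identity().as_quat(), np.zeros(3))
    with pytest.raises(ValidationError):
        generate_fit_ensemble([pose, pose], [0.5, 0.6], n=10)


@given(st.integers(min_value=1, max_value=3), st.integers(min_value=1, max_value=3))
@settings(max_examples=6, deadline=None)
def test_lattice_counts_scale_with_cells_property(n1, n2):
    """Per-unit-cell conservation holds for every supercell size."""
    from chearray import lattice as lat

    model = lat.build_lattice(lat.LatticeSpec(n_cells=(n1, n2)))
    st_counts = lat.stoichiometry_report(model)
    k = n1 * n2
    assert st_counts["TOD"] == 6 * k
    assert st_counts["CheA_dimer"] == 3 * k
    assert st_counts["CheW"] == 12 * k
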