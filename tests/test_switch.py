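"""Trajectory analysis: superposition, PCA, dips, clustering, contacts."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from chearray import switch, synth
from chearray.errors import ConfigurationError, NumericError, ValidationError
from chearray.switch import (
    ContactPair,
    ProjectionSeries,
    SelectionSpec,
    Trajectory,
    align_trajectory,
    annotate_events,
    cluster_conformations,
    contact_occupancy,
    detect_dips,
    fit_pca,
    project,
    rmsd_matrix,
    superpose,
)


# --------------------------------------------------------------- superpose


def test_superpose_identity():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 3))
    R, t, rmsd = superpose(X, X)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(R.as_matrix(), np.eye(3), atol=1e-9)
    assert np.allclose(t, 0.0, atol=1e-9)


def test_superpose_recovers_rotation():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 3)) * [5, 3, 2]
    R_true = Rotation.from_euler("z", 37, degrees=True)
    moved = R_true.apply(X) + [4.0, -2.0, 1.0]
    R, t, rmsd = superpose(moved, X)
    assert rmsd == pytest.approx(0.0, abs=1e-6)
    assert np.allclose((R * R_true).magnitude(), 0.0, atol=1e-6)


def test_superpose_noise_rmsd_expectation():
    """RMSD to a noiseless reference approximates sigma*sqrt(3)."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(1000, 3)) * 10
    sigma = 0.7
    noisy = X + rng.normal(0, sigma, X.shape)
    _, _, rmsd = superpose(noisy, X)
    assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.05)


def test_superpose_degenerate_selection():
    line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.raises(NumericError):
        superpose(line, line + 1.0)


def test_superpose_shape_mismatch():
    with pytest.raises(ValidationError):
        superpose(np.zeros((4, 3)), np.zeros((5, 3)))


# ------------------------------------------------------------------- align


def test_align_removes_planted_drift_exactly(toy_model):
    params = synth.SwitchingParams(seed=3, n_frames=120, noise_sigma=0.0,
                                   drift_sigma=0.8)
    traj, truth = synth.generate_switching_trajectory(toy_model, params)
    aligned = align_trajectory(traj, toy_model.coords, switch.P5_ALIGN)
    undipped = ~truth.states
    assert np.abs(aligned.coordinates[undipped] - toy_model.coords).max() < 1e-9


def test_align_never_worse_than_unaligned(toy_model):
    params = synth.SwitchingParams(seed=5, n_frames=40, drift_sigma=0.4)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    idx = switch.P5_ALIGN.resolve(traj.atoms)
    aligned = align_trajectory(traj, toy_model.coords, switch.P5_ALIGN)
    ref = toy_model.coords[idx]
    for f in range(traj.n_frames):
        pre = np.sqrt(np.mean(np.sum((traj.coordinates[f][idx] - ref) ** 2, -1)))
        post = np.sqrt(np.mean(np.sum((aligned.coordinates[f][idx] - ref) ** 2, -1)))
        assert post <= pre + 1e-9


# --------------------------------------------------------------------- PCA


def _rigid_shift_trajectory(toy_model, direction, n_frames=60):
    """Only motion: chain A's P4 displaced along a fixed vector."""
    idx = switch.P4_CA.resolve(toy_model.atoms)
    chain_a = idx[toy_model.atoms["chain"].to_numpy()[idx] == "A"]
    coords = np.repeat(toy_model.coords[None], n_frames, axis=0)
    amp = np.linspace(0, 5, n_frames)
    for f in range(n_frames):
        coords[f, chain_a] += amp[f] * direction
    return Trajectory(coords, toy_model.atoms.copy(), 0.02)


def test_pca_single_mode_limit(toy_model):
    direction = np.array([0.0, 0.6, -0.8])
    traj = _rigid_shift_trajectory(toy_model, direction)
    model = fit_pca(traj, switch.P4_CA)
    assert model.fractional_variances[0] >= 0.99
    # PC1 is parallel to the planted displacement of the moving beads
    idx = model.selection_index
    chains = toy_model.atoms["chain"].to_numpy()[idx]
    disp = np.zeros((len(idx), 3))
    disp[chains == "A"] = direction
    disp = disp.ravel() / np.linalg.norm(disp)
    assert abs(float(disp @ model.components[0])) >= 0.99


def test_pca_fractional_variances_sum_to_one(toy_model):
    params = synth.SwitchingParams(seed=1, n_frames=100)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    model = fit_pca(traj, switch.P4_CA)
    assert model.fractional_variances.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(model.fractional_variances) <= 1e-12)


def test_pca_requires_two_frames(toy_model):
    traj = Trajectory(toy_model.coords[None], toy_model.atoms, 0.02)
    with pytest.raises(ValidationError):
        fit_pca(traj, switch.P4_CA)


def test_project_model_mean_is_zero(toy_model):
    params = synth.SwitchingParams(seed=2, n_frames=50)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    model = fit_pca(traj, switch.P4_CA)
    mean_coords = traj.coordinates.mean(axis=0)
    mean_traj = Trajectory(mean_coords[None], traj.atoms, 0.02)
    series = project(mean_traj, model)
    assert series.value[0] == pytest.approx(0.0, abs=1e-9)


def test_project_two_state_offsets(toy_model):
    """State means of the PC1 series match the planted dip displacement."""
    params = synth.SwitchingParams(seed=12, n_frames=4000, k_dip=0.1, k_undip=0.1)
    traj, truth = synth.generate_switching_trajectory(toy_model, params)
    aligned = align_trajectory(traj, toy_model.coords, switch.P5_ALIGN)
    model = fit_pca(aligned, switch.P4_CA)
    series = project(aligned, model)
    gap = series.value[truth.states].mean() - series.value[~truth.states].mean()
    idx = model.selection_index
    planted = (toy_model.dipped_coords(params.dip_angle) - toy_model.coords)[idx]
    assert abs(gap) == pytest.approx(np.linalg.norm(planted), rel=0.1)


def test_project_orthogonal_motion_is_flat(toy_model):
    direction = np.array([1.0, 0.0, 0.0])
    traj = _rigid_shift_trajectory(toy_model, direction)
    model = fit_pca(traj, switch.P4_CA)
    # motion along PC2 (orthogonal complement) projects to ~0 on PC1:
    # build a trajectory moving orthogonally to PC1
    pc1 = model.components[0].reshape(-1, 3)
    ortho = np.array([0.0, 0.0, 1.0]) - pc1[0] * pc1[0][2]
    ortho /= np.linalg.norm(ortho)
    # displacement orthogonal to PC1 in full selection space
    disp = np.cross(pc1, np.tile([0.37, 0.62, 0.41], (len(pc1), 1)))
    flat = disp.ravel()
    flat -= (flat @ model.components[0]) * model.components[0]
    idx = model.selection_index
    coords = np.repeat(traj.coordinates.mean(axis=0)[None], 30, axis=0)
    for f in range(30):
        coords[f, idx] += 0.1 * f * flat.reshape(-1, 3)
    t2 = Trajectory(coords, traj.atoms.copy(), 0.02)
    series = project(t2, model)
    assert np.abs(series.value - series.value[0]).max() < 1e-6


# --------------------------------------------------------------------- dips


def test_detect_dips_constant_series_no_events():
    series = ProjectionSeries(np.arange(100) * 0.02, np.full(100, -2.0))
    assert detect_dips(series, threshold=0.0, hysteresis=0.5) == []


def test_detect_dips_recovers_planted_runs():
    t = np.arange(3000) * 0.02
    v = np.full(3000, -3.0)
    plant = [(200, 900), (1500, 1980), (2500, 2560)]  # frames
    for a, b in plant:
        v[a:b] = 3.0
    rng = np.random.default_rng(0)
    v = v + rng.normal(0, 0.3, v.shape)
    events = detect_dips(ProjectionSeries(t, v), threshold=0.0, min_duration=10.0,
                         hysteresis=1.0)
    assert len(events) == 3
    for ev, (a, b) in zip(events, plant):
        assert abs(ev.start - a * 0.02) <= 0.02 + 1e-9  # +-1 frame
        assert abs(ev.end - b * 0.02) <= 0.02 + 1e-9
        assert ev.extended == ((b - a) * 0.02 > 10.0)


def test_detect_dips_default_threshold_bimodal(toy_model):
    params = synth.SwitchingParams(seed=21, n_frames=6000, k_dip=0.08, k_undip=0.04)
    traj, truth = synth.generate_switching_trajectory(toy_model, params)
    aligned = align_trajectory(traj, toy_model.coords, switch.P5_ALIGN)
    model = fit_pca(aligned, switch.P4_CA)
    series = project(aligned, model)
    events = detect_dips(series)
    # every sufficiently long planted event is found
    long_planted = [e for e in truth.events if e.duration > 1.0]
    assert len(events) >= len(long_planted)


def test_detect_dips_pure_noise_no_events():
    rng = np.random.default_rng(9)
    series = ProjectionSeries(np.arange(10000) * 0.02, rng.normal(0, 1.0, 10000))
    assert detect_dips(series) == []


def test_detect_dips_validation():
    with pytest.raises(ValidationError):
        detect_dips(ProjectionSeries(np.array([]), np.array([])))
    t = np.array([0.0, 0.2, 0.1])
    with pytest.raises(ValidationError):
        detect_dips(ProjectionSeries(t, np.zeros(3)), threshold=0.0)


# --------------------------------------------------------------------- RMSD


def test_rmsd_matrix_matches_bruteforce(toy_model):
    params = synth.SwitchingParams(seed=4, n_frames=5)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    mat = rmsd_matrix(traj, switch.P4_CA)
    idx = switch.P4_CA.resolve(traj.atoms)
    for i in range(5):
        for j in range(5):
            d = traj.coordinates[i, idx] - traj.coordinates[j, idx]
            expected = np.sqrt(np.mean(np.sum(d**2, axis=1)))
            assert mat.matrix[i, j] == pytest.approx(expected, abs=1e-9)
    assert np.all(np.diag(mat.matrix) == 0.0)


def test_rmsd_matrix_homogeneity(toy_model):
    params = synth.SwitchingParams(seed=4, n_frames=6)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    m1 = rmsd_matrix(traj, switch.P4_CA).matrix
    t2 = Trajectory(traj.coordinates * 2.0, traj.atoms, traj.frame_interval)
    m2 = rmsd_matrix(t2, switch.P4_CA).matrix
    assert np.allclose(m2, 2.0 * m1, atol=1e-9)


def test_rmsd_matrix_triangle_inequality(toy_model):
    params = synth.SwitchingParams(seed=6, n_frames=30)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    m = rmsd_matrix(traj, switch.P4_CA).matrix
    n = len(m)
    for i in range(n):
        for j in range(n):
            assert np.all(m[i, j] <= m[i] + m[:, j] + 0.1)


def test_rmsd_matrix_subsample(toy_model):
    params = synth.SwitchingParams(seed=4, n_frames=20)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    mat = rmsd_matrix(traj, switch.P4_CA, subsample=5)
    assert mat.matrix.shape == (4, 4)
    assert list(mat.frame_index) == [0, 5, 10, 15]


# ---------------------------------------------------------------- clusters


def test_cluster_identical_frames_single_cluster():
    mat = switch.RMSDMatrix(np.zeros((20, 20)), np.arange(20))
    res = cluster_conformations(mat, n_clusters=1)
    assert res.populations[0] == 1.0
    assert set(res.labels) == {0}


def test_cluster_argument_validation():
    mat = switch.RMSDMatrix(np.zeros((5, 5)), np.arange(5))
    with pytest.raises(ValidationError):
        cluster_conformations(mat)
    with pytest.raises(ValidationError):
        cluster_conformations(mat, n_clusters=2, cut_height=1.0)
    with pytest.raises(ValidationError):
        cluster_conformations(mat, n_clusters=10)


def test_cluster_two_state_merge_heights(toy_model):
    """The final merge joining two well-separated states towers over the rest."""
    traj, truth = synth.generate_state_ensemble(
        toy_model, populations=(0.5, 0.5), state_angles=(0.0, 25.0),
        n_frames=100, noise_sigma=0.2, seed=3,
    )
    mat = rmsd_matrix(traj, switch.P4_CA)
    res = cluster_conformations(mat, n_clusters=2)
    heights = res.linkage_matrix[:, 2]
    assert heights[-1] > 5 * np.max(heights[:-1])
    # labels agree with planted states up to permutation
    agree = (res.labels == truth.labels).mean()
    assert max(agree, 1 - agree) == 1.0


def test_cluster_newick_export(toy_model):
    traj, _ = synth.generate_state_ensemble(
        toy_model, populations=(0.6, 0.4), state_angles=(0.0, 25.0),
        n_frames=12, noise_sigma=0.2, seed=3,
    )
    mat = rmsd_matrix(traj, switch.P4_CA)
    res = cluster_conformations(mat, n_clusters=2)
    import dendropy

    tree = dendropy.Tree.get(data=res.dendrogram_newick(), schema="newick")
    assert len(tree.leaf_nodes()) == 12


# ---------------------------------------------------------------- contacts


def test_contact_occupancy_bounds(toy_model):
    n = 10
    coords = np.repeat(toy_model.coords[None], n, axis=0)
    traj = Trajectory(coords, toy_model.atoms.copy(), 0.02)
    pairs = synth.toy_contact_pairs()
    series = contact_occupancy(traj, [pairs["D333/K390"], pairs["R297/E397"]])
    assert series[0].occupancy == 1.0  # undipped contact held at contact_gap
    assert series[1].occupancy == 0.0  # dipped contact cannot form undipped


def test_contact_occupancy_tracks_dipped_frames(toy_model):
    params = synth.SwitchingParams(seed=8, n_frames=2000)
    traj, truth = synth.generate_switching_trajectory(toy_model, params)
    pairs = synth.toy_contact_pairs()
    series = contact_occupancy(traj, [pairs["R297/E397"]])[0]
    planted = truth.states.mean()
    assert series.occupancy == pytest.approx(planted, abs=1.5 / 2000 + 0.01)
    assert (series.bound == truth.states).mean() > 0.99


def test_contact_unresolvable_pair_raises(toy_model):
    traj = Trajectory(toy_model.coords[None], toy_model.atoms, 0.02)
    bad = ContactPair(
        SelectionSpec(chain="Z", resid_range=(1, 1)),
        SelectionSpec(chain="A", resid_range=(297, 297)),
        name="bogus",
    )
    with pytest.raises(ConfigurationError, match="bogus"):
        contact_occupancy(traj, [bad])


def test_annotate_events_flags(toy_model):
    time = np.arange(100) * 0.02
    bound = np.zeros(100, dtype=bool)
    bound[10:30] = True
    contact = switch.ContactSeries(
        pair=synth.toy_contact_pairs()["R297/E397"],
        time=time, min_distance=np.where(bound, 1.0, 10.0),
        bound=bound, occupancy=bound.mean(),
    )
    ev_in = switch.DipEvent(start=0.2, end=0.6, duration=0.4,
                            peak_amplitude=1.0, extended=False)
    ev_out = switch.DipEvent(start=1.0, end=1.4, duration=0.4,
                             peak_amplitude=1.0, extended=False)
    out = annotate_events([ev_in, ev_out], contact)
    assert out[0].stabilizing_contact_formed is True
    assert out[1].stabilizing_contact_formed is False
    disjoint = switch.DipEvent(start=50.0, end=60.0, duration=10.0,
                               peak_amplitude=1.0, extended=True)
    with pytest.raises(ValidationError):
        annotate_events([disjoint], contact)


# -------------------------------------------------------------- pipeline IO


def test_pipeline_outputs_deterministic(tmp_path, toy_model):
    """Identical inputs and seeds give byte-identical CSV outputs."""
    outputs = []
    for run in range(2):
        params = synth.SwitchingParams(seed=13, n_frames=300)
        traj, _ = synth.generate_switching_trajectory(toy_model, params)
        aligned = align_trajectory(traj, toy_model.coords, switch.P5_ALIGN)
        model = fit_pca(aligned, switch.P4_CA)
        series = project(aligned, model)
        path = tmp_path / f"proj_{run}.csv"
        series.to_frame().to_csv(path, index=False)
        outputs.append(path.read_bytes())
    assert outputs[0] == outputs[1]


def test_trajectory_dcd_roundtrip(tmp_path, toy_model):
    import warnings

    params = synth.SwitchingParams(seed=1, n_frames=4)
    traj, _ = synth.generate_switching_trajectory(toy_model, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj.write(tmp_path / "top.pdb", tmp_path / "t.dcd")
        back = Trajectory.read(tmp_path / "top.pdb", tmp_path / "t.dcd",
                               frame_interval=params.frame_interval)
    assert back.n_frames == traj.n_frames
    assert np.abs(back.coordinates - traj.coordinates).max() < 1e-4
    # selections resolve identically after the round-trip
    for sel in (switch.P5_ALIGN, switch.P4_CA):
        assert np.array_equal(sel.resolve(back.atoms), sel.resolve(traj.atoms))
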