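"""Geometric descriptors: analytic cases, invariances, and mdtraj oracles."""

import mdtraj as md
import numpy as np
import pandas as pd
import pytest
from mdtraj.geometry.sasa import _ATOMIC_RADII
from scipy.spatial.transform import Rotation

from conftest import carbon_cloud, make_mdtraj
from vardyn.synthdata import make_synthetic_trajectory
from vardyn.trajfeatures import (
    FEATURE_NAMES,
    AtomRecord,
    Trajectory,
    assign_secondary_structure,
    count_contacts,
    count_hbonds,
    inertia_scalar,
    inertia_tensor,
    radius_of_gyration,
    sasa_shrake_rupley,
    select_stable_window,
    stability_surrogate,
    summarize_features,
    superpose_rmsd,
    zscore_apply,
    zscore_invert,
    zscore_scale,
)

MDTRAJ_C_RADIUS = _ATOMIC_RADII["C"] * 10.0  # nm -> A


def _atoms(n, residue_indices=None, element="C", role="CA"):
    res = residue_indices or list(range(1, n + 1))
    return [
        AtomRecord(i + 1, "CA", element, res[i], "GLY", backbone_role=role)
        for i in range(n)
    ]


# ---------------------------------------------------------------- Rg / inertia


def test_rg_analytic_cases():
    assert radius_of_gyration(np.array([[3.0, -2, 7]]), np.array([1.0])) == 0.0
    two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert radius_of_gyration(two, np.ones(2)) == pytest.approx(1.0, abs=1e-9)
    square = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    assert radius_of_gyration(square, np.ones(4)) == pytest.approx(
        np.sqrt(2) / 2, abs=1e-9
    )
    with pytest.raises(ValueError):
        radius_of_gyration(two, np.zeros(2))


def test_inertia_analytic_and_eigen_identity():
    assert inertia_scalar(np.array([[0.0, 0, 0]]), np.array([5.0])) == 0.0
    two = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    assert inertia_scalar(two, np.ones(2)) == pytest.approx(4.0, abs=1e-9)
    rng = np.random.default_rng(1)
    cloud = rng.normal(size=(10, 3))
    masses = rng.uniform(1, 20, size=10)
    tensor = inertia_tensor(cloud, masses)
    assert inertia_scalar(cloud, masses) == pytest.approx(
        np.linalg.eigvalsh(tensor).sum(), abs=1e-9
    )


# ---------------------------------------------------------------------- RMSD


def test_rmsd_identity_and_rigid_motion():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(15, 3))
    assert superpose_rmsd(x, x) == pytest.approx(0.0, abs=1e-9)
    moved = Rotation.from_euler("z", 37, degrees=True).apply(x) + [5.0, -3.0, 2.0]
    assert superpose_rmsd(moved, x) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_against_mdtraj_oracle():
    rng = np.random.default_rng(3)
    for n in (20, 35, 50):
        topo, ref = carbon_cloud(n, seed=n)
        frame = ref + rng.normal(scale=0.8, size=ref.shape)
        mine = superpose_rmsd(frame, ref)
        t = make_mdtraj(topo, np.stack([ref, frame]))
        oracle = float(md.rmsd(t, t, frame=0)[1]) * 10.0
        assert mine == pytest.approx(oracle, rel=1e-3)


def test_rmsd_three_atom_case_matches_oracle():
    ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    frame = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0]])
    topo = _atoms(3)
    t = make_mdtraj(topo, np.stack([ref, frame]))
    oracle = float(md.rmsd(t, t, frame=0)[1]) * 10.0
    assert superpose_rmsd(frame, ref) == pytest.approx(oracle, abs=1e-5)


def test_rmsd_rejects_degenerate_input():
    line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    with pytest.raises(ValueError):
        superpose_rmsd(line, line * 2)
    with pytest.raises(ValueError):
        superpose_rmsd(np.zeros((4, 3)), np.zeros((3, 3)))


# ---------------------------------------------------------------------- SASA


def test_sasa_isolated_and_distant_spheres():
    one = np.array([[0.0, 0, 0]])
    total, per_atom = sasa_shrake_rupley(one, np.array([1.7]))
    assert total == pytest.approx(4 * np.pi * 3.1**2, rel=1e-12)
    two_far = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    total, _ = sasa_shrake_rupley(two_far, np.array([1.7, 1.7]))
    assert total == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-12)


def test_sasa_two_sphere_cap_formula():
    """Two intersecting equal spheres against the analytic cap area."""
    r_exp, sep = 3.1, 3.1
    frame = np.array([[0.0, 0, 0], [sep, 0, 0]])
    total, _ = sasa_shrake_rupley(frame, np.array([1.7, 1.7]), n_points=960)
    analytic = 2 * (4 * np.pi * r_exp**2 - 2 * np.pi * r_exp * (r_exp - sep / 2))
    assert total == pytest.approx(analytic, rel=2e-3)  # point-sampling tolerance


def test_sasa_against_mdtraj_oracle():
    for n, seed in ((20, 4), (35, 5), (50, 6)):
        topo, coords = carbon_cloud(n, seed=seed, spread=4.0)
        mine, _ = sasa_shrake_rupley(
            coords, np.full(n, MDTRAJ_C_RADIUS), probe=1.4, n_points=960
        )
        t = make_mdtraj(topo, coords)
        oracle = float(
            md.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960).sum()
        ) * 100.0
        assert mine == pytest.approx(oracle, rel=2e-2)


def test_sasa_input_validation():
    one = np.array([[0.0, 0, 0]])
    with pytest.raises(ValueError):
        sasa_shrake_rupley(one, np.array([-1.0]))
    with pytest.raises(ValueError):
        sasa_shrake_rupley(one, np.array([1.0]), n_points=4)


# ------------------------------------------------------------------- contacts


def test_contacts_boundary_and_brute_force():
    topo3 = _atoms(3)
    frame3 = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
    assert count_contacts(frame3, topo3, cutoff=5.0, min_seq_separation=3) == 0

    topo5 = _atoms(5)
    frame5 = np.array([[i * 4.0, 0, 0] for i in range(5)])

    def brute(cutoff, sep):
        hits = 0
        for i in range(5):
            for j in range(i + 1, 5):
                if j - i >= sep and np.linalg.norm(frame5[i] - frame5[j]) <= cutoff:
                    hits += 1
        return hits

    for cutoff in (5.0, 9.0, 13.0):
        assert count_contacts(frame5, topo5, cutoff, 3) == brute(cutoff, 3)
    # infinite cutoff: all eligible pairs
    assert count_contacts(frame5, topo5, 1e6, 3) == brute(1e6, 3) == 3


# -------------------------------------------------------------------- H-bonds


def _nh_oc_system(h_o_dist, angle_deg=180.0):
    """N-H donor (residue 1) and O=C acceptor (residue 2) on the x axis."""
    n = np.array([0.0, 0, 0])
    h = np.array([1.01, 0, 0])
    ang = np.deg2rad(180.0 - angle_deg)
    o = h + h_o_dist * np.array([np.cos(ang), np.sin(ang), 0.0])
    c = o + np.array([1.23, 0.0, 0.0])
    topo = [
        AtomRecord(1, "N", "N", 1, "ALA", backbone_role="N"),
        AtomRecord(2, "H", "H", 1, "ALA", backbone_role="H"),
        AtomRecord(3, "O", "O", 2, "ALA", backbone_role="O"),
        AtomRecord(4, "C", "C", 2, "ALA", backbone_role="C"),
    ]
    return topo, np.array([n, h, o, c])


def test_hbond_collinear_geometry_counts():
    topo, frame = _nh_oc_system(2.0, angle_deg=180.0)
    assert count_hbonds(frame, topo) == 1


def test_hbond_distance_and_angle_rejection():
    topo, frame = _nh_oc_system(5.0, angle_deg=180.0)  # N..O = 6.01 A
    assert count_hbonds(frame, topo) == 0
    topo, frame = _nh_oc_system(2.0, angle_deg=90.0)
    assert count_hbonds(frame, topo, angle_cutoff=120.0) == 0


# --------------------------------------------------------- secondary structure


def test_helix_assignment_matches_mdtraj(helix20):
    topo, coords = helix20
    labels, (h, e, c) = assign_secondary_structure(coords, topo)
    assert h >= 0.7 and e == 0.0
    t = make_mdtraj(topo, coords)
    oracle = md.compute_dssp(t, simplified=True)[0]
    mine = ["C" if l == "C" else l for l in labels]
    agreement = np.mean([a == b for a, b in zip(mine, oracle)])
    assert agreement >= 0.9


def test_extended_chain_is_all_coil():
    n = 12
    topo, coords = [], []
    serial = 0
    for i in range(n):  # residues far apart: no H-bond partners
        base = np.array([i * 12.0, 0.0, 0.0])
        for name, element, role, offset in (
            ("N", "N", "N", [0.0, 0, 0]),
            ("CA", "C", "CA", [1.46, 0, 0]),
            ("C", "C", "C", [2.0, 1.3, 0]),
            ("O", "O", "O", [2.0, 2.53, 0]),
        ):
            serial += 1
            topo.append(AtomRecord(serial, name, element, i + 1, "GLY", backbone_role=role))
            coords.append(base + offset)
    labels, (h, e, c) = assign_secondary_structure(np.array(coords), topo)
    assert (h, e, c) == (0.0, 0.0, 1.0)


def test_fractions_partition(helix20):
    topo, coords = helix20
    rng = np.random.default_rng(8)
    noisy = coords + rng.normal(scale=0.5, size=coords.shape)
    _, fracs = assign_secondary_structure(noisy, topo)
    assert sum(fracs) == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------- stability proxy


def test_stability_single_atom_is_surface_term_only():
    topo = _atoms(1)
    frame = np.array([[0.0, 0, 0]])
    sasa, _ = sasa_shrake_rupley(frame, np.array([topo[0].vdw_radius]))
    assert stability_surrogate(frame, topo) == pytest.approx(0.00542 * sasa, rel=1e-9)


def test_stability_lj_minimum_and_repulsion():
    from vardyn._elements import LJ_PARAMS
    from vardyn.trajfeatures import StabilityParams

    eps, sigma = LJ_PARAMS["C"]
    params = StabilityParams(role_charge={}, element_charge={"C": 0.0})
    topo = _atoms(2, residue_indices=[1, 3])  # separation >= 2 residues
    r_min = sigma * 2 ** (1 / 6)
    frame = np.array([[0.0, 0, 0], [r_min, 0, 0]])
    sasa, _ = sasa_shrake_rupley(frame, np.array([1.7, 1.7]))
    e_min = stability_surrogate(frame, topo, params, sasa_total=sasa)
    assert e_min == pytest.approx(-eps + 0.00542 * sasa, rel=1e-6)
    squeezed = np.array([[0.0, 0, 0], [0.8 * sigma, 0, 0]])
    e_squeezed = stability_surrogate(squeezed, topo, params, sasa_total=sasa)
    assert e_squeezed > e_min


def test_stability_missing_element_errors():
    from vardyn.trajfeatures import StabilityParams

    topo = [AtomRecord(1, "FE", "F", 1, "HEM")]
    with pytest.raises(ValueError):
        stability_surrogate(np.zeros((1, 3)), topo, StabilityParams(lj={"C": (0.1, 3.4)}))


# --------------------------------------------------------------- stable window


def test_stable_window_constant_series():
    m = np.ones((100, 3))
    start, end = select_stable_window(m)
    assert (start, end) == (75, 99)  # latest full-length window


def test_stable_window_ramp_then_plateau():
    t = np.arange(1001, dtype=float)
    ramp = np.where(t <= 500, t, 500.0)
    m = np.column_stack([ramp, ramp * 2, ramp + 1])
    start, end = select_stable_window(m)
    assert start >= 501 and end <= 1000


def test_stable_window_noise_fallback_and_short_series():
    rng = np.random.default_rng(9)
    m = rng.normal(size=(200, 4))
    start, end = select_stable_window(m, alpha=0.2)
    assert (start, end) == (100, 199)  # last half fallback
    with pytest.warns(UserWarning):
        start, end = select_stable_window(np.ones((5, 2)))
    assert (start, end) == (0, 4)


# ------------------------------------------------------------------- summary


def test_single_frame_summary_equals_raw_descriptors():
    traj = make_synthetic_trajectory(n_residues=8, n_frames=1, seed=10)
    series, vector = summarize_features(traj, traj.frames[0])
    assert (vector.window_start, vector.window_end) == (0, 0)
    frame = traj.frames[0]
    assert vector.values["rg"] == pytest.approx(
        radius_of_gyration(frame, traj.masses), abs=1e-12
    )
    assert vector.values["rmsd"] == pytest.approx(0.0, abs=1e-9)
    assert list(series.data.columns) == list(FEATURE_NAMES)


def test_rmsd_series_increases_with_drift():
    means = []
    for drift in (0.0, 1.0, 3.0):
        traj = make_synthetic_trajectory(n_residues=10, n_frames=12, drift=drift, seed=11)
        ref = traj.frames[0]
        rmsds = [superpose_rmsd(f, ref) for f in traj.frames]
        means.append(np.mean(rmsds))
    assert means[0] == pytest.approx(0.0, abs=1e-9)
    assert means[0] < means[1] < means[2]


def test_summarize_deterministic():
    traj = make_synthetic_trajectory(n_residues=8, n_frames=12, drift=0.5, seed=12)
    _, v1 = summarize_features(traj, traj.frames[0])
    _, v2 = summarize_features(traj, traj.frames[0])
    assert v1.values == v2.values


# ------------------------------------------------------- rigid-motion property


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rigid_motion_invariance(helix20, seed):
    """Rg, SASA, inertia, contacts, hbonds and SS fractions are invariant
    under a global rotation + translation."""
    topo, coords = helix20
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    moved = rot.apply(coords) + rng.normal(scale=20.0, size=3)
    masses = np.array([a.mass for a in topo])
    radii = np.array([a.vdw_radius for a in topo])
    assert radius_of_gyration(moved, masses) == pytest.approx(
        radius_of_gyration(coords, masses), rel=1e-9
    )
    assert inertia_scalar(moved, masses) == pytest.approx(
        inertia_scalar(coords, masses), rel=1e-9
    )
    s1, _ = sasa_shrake_rupley(coords, radii, n_points=240)
    s2, _ = sasa_shrake_rupley(moved, radii, n_points=240)
    assert s2 == pytest.approx(s1, rel=1e-6)
    assert count_contacts(moved, topo) == count_contacts(coords, topo)
    assert count_hbonds(moved, topo) == count_hbonds(coords, topo)
    _, f1 = assign_secondary_structure(coords, topo)
    _, f2 = assign_secondary_structure(moved, topo)
    assert np.allclose(f1, f2)


# -------------------------------------------------------------------- scaling


def test_zscore_round_trip_and_guards():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning):
        scaled, (means, stds) = zscore_scale(df)
    assert scaled["a"].mean() == pytest.approx(0.0, abs=1e-12)
    assert scaled["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
    assert (scaled["b"] == 0.0).all()
    recovered = zscore_invert(scaled, means, stds)
    assert np.allclose(recovered["a"], df["a"], atol=1e-12)
    applied = zscore_apply(df, means, stds)
    assert np.allclose(applied["a"], scaled["a"], atol=1e-12)
    with pytest.raises(ValueError):
        zscore_scale(pd.DataFrame({"a": []}))
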