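"""Frame geometry: alignment, helix angles, radial thickness, carbonyl flips."""

import numpy as np
import pandas as pd
import pytest

from bilayergate.errors import InsufficientDataError, SelectionError
from bilayergate.geometry import (
    HELIX_PRESETS,
    FlipTrace,
    Frame,
    HelixSpec,
    align_to_pore_axis,
    bulk_thickness,
    carbonyl_flip_state,
    classify_flip_trace,
    first_alkyl_carbons,
    flip_dwells,
    helix_kink,
    helix_tilt,
    hydrophobic_length,
    radial_thickness_profile,
)
from bilayergate.synthetic import gen_ideal_helix, gen_membrane_frames


def _helix_frame(xyz, chain="A", start_res=1):
    n = xyz.shape[0]
    return Frame(
        names=np.array(["CA"] * n, dtype=object),
        resnames=np.array(["ALA"] * n, dtype=object),
        resids=np.arange(start_res, start_res + n),
        chains=np.array([chain] * n, dtype=object),
        xyz=xyz,
    )


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


# --------------------------------------------------------------- alignment


def test_alignment_is_idempotent(aligned_tetramer):
    again = align_to_pore_axis(aligned_tetramer)
    np.testing.assert_allclose(again.xyz, aligned_tetramer.xyz, atol=1e-6)


def test_alignment_centres_filter_on_axis(aligned_tetramer):
    f = aligned_tetramer
    mask = f.mask(resid=(75, 76, 77, 78, 79), name="CA")
    centroid = f.xyz[mask].mean(axis=0)
    assert abs(centroid[0]) < 1e-9 and abs(centroid[1]) < 1e-9


def test_alignment_undoes_random_rotation(tetramer, rng):
    aligned = align_to_pore_axis(tetramer)
    R = _random_rotation(rng)
    rotated = Frame(
        names=tetramer.names,
        resnames=tetramer.resnames,
        resids=tetramer.resids,
        chains=tetramer.chains,
        xyz=tetramer.xyz @ R.T + np.array([5.0, -3.0, 12.0]),
    )
    realigned = align_to_pore_axis(rotated)
    # pore axis and filter centre are restored; chains may have rotated
    # about z, so compare z coordinates and axial distances, not raw xyz
    np.testing.assert_allclose(
        np.sort(realigned.xyz[:, 2]), np.sort(aligned.xyz[:, 2]), atol=1e-3
    )
    r_new = np.sort(np.hypot(realigned.xyz[:, 0], realigned.xyz[:, 1]))
    r_old = np.sort(np.hypot(aligned.xyz[:, 0], aligned.xyz[:, 1]))
    np.testing.assert_allclose(r_new, r_old, atol=1e-3)


def test_alignment_requires_pore_residues():
    xyz = gen_ideal_helix(30)
    frame = _helix_frame(xyz, start_res=1)  # residues 1..30: no 75-79
    with pytest.raises(SelectionError):
        align_to_pore_axis(frame)


# ---------------------------------------------------------- tilt and kink


def test_tilt_of_vertical_and_45deg_vectors():
    spec = HelixSpec(span=(1, 2), upper=(1, 2), lower=(1, 2))
    up = _helix_frame(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 30.0]]))
    assert helix_tilt(up, spec)["A"] == pytest.approx(0.0, abs=1e-9)
    diag = _helix_frame(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 1.0]]))
    assert helix_tilt(diag, spec)["A"] == pytest.approx(45.0, abs=1e-9)


def test_tilt_recovers_generated_helix():
    # 37 residues at 100 deg/turn: endpoints share helical phase, so the
    # Calpha chord parallels the helix axis and tilt is exact
    spec = HelixSpec(span=(1, 37), upper=(19, 37), lower=(1, 19))
    for tilt in (0.0, 30.0):
        frame = _helix_frame(gen_ideal_helix(37, tilt_deg=tilt))
        assert helix_tilt(frame, spec)["A"] == pytest.approx(tilt, abs=0.5)


def test_kink_collinear_perpendicular_and_generated():
    spec = HelixSpec(span=(1, 3), upper=(2, 3), lower=(1, 2))
    straight = _helix_frame(np.array([[0, 0, 0.0], [0, 0, 10.0], [0, 0, 20.0]]))
    assert helix_kink(straight, spec)["A"] == pytest.approx(180.0, abs=1e-9)
    bent = _helix_frame(np.array([[0, 0, 0.0], [0, 0, 10.0], [10.0, 0, 10.0]]))
    assert helix_kink(bent, spec)["A"] == pytest.approx(90.0, abs=1e-9)

    # generator: 40 deg bend -> 140 deg kink (phase-aligned sub-spans)
    xyz = gen_ideal_helix(37, kink_after=19, kink_deg=40.0)
    frame = _helix_frame(xyz)
    spec37 = HelixSpec(span=(1, 37), upper=(19, 37), lower=(1, 19))
    assert helix_kink(frame, spec37)["A"] == pytest.approx(140.0, abs=1.0)


def test_tilt_kink_invariant_under_z_rotation_and_translation(aligned_tetramer):
    from bilayergate.synthetic import _rot_z

    spec = HELIX_PRESETS["kcsa-m1"]
    t0 = helix_tilt(aligned_tetramer, spec)
    k0 = helix_kink(aligned_tetramer, spec)
    moved = Frame(
        names=aligned_tetramer.names,
        resnames=aligned_tetramer.resnames,
        resids=aligned_tetramer.resids,
        chains=aligned_tetramer.chains,
        xyz=aligned_tetramer.xyz @ _rot_z(1.234).T + np.array([0.0, 0.0, 7.0]),
    )
    t1 = helix_tilt(moved, spec)
    k1 = helix_kink(moved, spec)
    np.testing.assert_allclose(t1.values, t0.values, atol=1e-9)
    np.testing.assert_allclose(k1.values, k0.values, atol=1e-9)


def test_closed_state_tetramer_angles(aligned_tetramer):
    """Closed-state pore geometry: M1 20/140, M2 33/169 (tilt/kink)."""
    m1, m2 = HELIX_PRESETS["kcsa-m1"], HELIX_PRESETS["kcsa-m2"]
    assert helix_tilt(aligned_tetramer, m1).mean() == pytest.approx(20.0, abs=4.0)
    assert helix_tilt(aligned_tetramer, m2).mean() == pytest.approx(33.0, abs=4.0)
    assert helix_kink(aligned_tetramer, m1).mean() == pytest.approx(140.0, abs=5.0)
    assert helix_kink(aligned_tetramer, m2).mean() == pytest.approx(169.0, abs=5.0)


# ------------------------------------------------------ hydrophobic length


def test_hydrophobic_length_pure_projections():
    spec = HelixSpec(span=(1, 2), upper=(1, 2), lower=(1, 2))
    vertical = _helix_frame(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 30.0]]))
    assert hydrophobic_length(vertical, spec)["A"] == pytest.approx(30.0)
    flat = _helix_frame(np.array([[0.0, 0.0, 5.0], [10.0, 7.0, 5.0]]))
    assert hydrophobic_length(flat, spec)["A"] == pytest.approx(0.0)


def test_hydrophobic_length_tilted_helix_closed_form():
    # 28 residues, rise 1.5 A, tilt 30 deg -> 27 * 1.5 * cos(30 deg);
    # turn of 320/3 deg makes the endpoints phase-aligned (27 * 320/3 = 2880)
    xyz = gen_ideal_helix(28, turn_deg=320.0 / 3.0, tilt_deg=30.0)
    frame = _helix_frame(xyz)
    spec = HelixSpec(span=(1, 28), upper=(14, 28), lower=(1, 14))
    expected = 27 * 1.5 * np.cos(np.radians(30.0))
    assert hydrophobic_length(frame, spec)["A"] == pytest.approx(expected, abs=0.2)


def test_length_never_exceeds_euclidean_distance(aligned_tetramer):
    spec = HELIX_PRESETS["kcsa-m2"]
    span = spec.length_span
    for c in "ABCD":
        v = aligned_tetramer.coord(c, span[1], "CA") - aligned_tetramer.coord(
            c, span[0], "CA"
        )
        assert hydrophobic_length(aligned_tetramer, spec)[c] <= np.linalg.norm(v) + 1e-12


# ------------------------------------------------- radial thickness profile


def test_first_alkyl_carbon_selection_counts():
    frames, _ = gen_membrane_frames(1, 200, box=120.0, seed=0)
    idx = first_alkyl_carbons(frames[0])
    assert idx.size == 2 * 2 * 200  # two atoms per lipid, both leaflets

    protein_only = _helix_frame(gen_ideal_helix(10))
    with pytest.raises(SelectionError):
        first_alkyl_carbons(protein_only)


def test_flat_membrane_thickness_exact():
    frames, _ = gen_membrane_frames(3, 200, box=120.0, leaflet_z=15.0,
                                    atom_noise_sd=0.0, seed=1)
    prof = radial_thickness_profile(frames, bin_width=5.0, r_max=60.0)
    populated = np.isfinite(prof.thickness)
    np.testing.assert_allclose(prof.thickness[populated], 30.0, atol=1e-9)
    value, _ = bulk_thickness(prof, r_min=45.0)
    assert value == pytest.approx(30.0, abs=1e-9)


def test_dimple_deformation_recovery():
    """Gaussian dimple near the protein edge recovered within 0.3 A."""
    def deform(r):
        return 5.0 * np.exp(-((r - 20.0) ** 2) / 50.0)

    frames, _ = gen_membrane_frames(
        150, 300, box=140.0, leaflet_z=15.0, deformation=deform,
        atom_noise_sd=0.5, seed=9,
    )
    prof = radial_thickness_profile(frames, bin_width=2.0, r_max=70.0)
    expected = 30.0 - 2.0 * deform(prof.r_centers)
    ok = (prof.counts.min(axis=0) >= 20) & np.isfinite(prof.thickness)
    assert ok.sum() > 10
    np.testing.assert_allclose(prof.thickness[ok], expected[ok], atol=0.3)
    value, err = bulk_thickness(prof, r_min=45.0)
    assert value == pytest.approx(30.0, abs=0.2)


def test_bulk_thickness_needs_populated_bins():
    frames, _ = gen_membrane_frames(2, 100, box=100.0, seed=2)
    prof = radial_thickness_profile(frames, bin_width=5.0, r_max=40.0)
    with pytest.raises(InsufficientDataError):
        bulk_thickness(prof, r_min=45.0)


def test_empty_bins_are_nan_not_zero():
    frames, _ = gen_membrane_frames(2, 50, box=80.0, seed=3)
    prof = radial_thickness_profile(frames, bin_width=2.0, r_max=70.0)
    # far bins beyond the box diagonal are unpopulated
    assert np.isnan(prof.thickness[-1])


# ------------------------------------------------------------ carbonyl flip


def _carbonyl_frame(c_xyz, o_xyz):
    return Frame(
        names=np.array(["C", "O", "CA"], dtype=object),
        resnames=np.array(["VAL"] * 3, dtype=object),
        resids=np.array([76, 76, 76]),
        chains=np.array(["A"] * 3, dtype=object),
        xyz=np.array([c_xyz, o_xyz, [5.0, 0.0, 2.0]]),
    )


def test_flip_state_inward_and_flipped():
    inward = _carbonyl_frame([5.0, 0.0, 0.0], [4.0, 0.0, 0.0])
    assert carbonyl_flip_state(inward, "A", 76) == "inward"
    flipped = _carbonyl_frame([5.0, 0.0, 0.0], [6.0, 0.0, 0.0])
    assert carbonyl_flip_state(flipped, "A", 76) == "flipped"


def test_flip_trace_classification_and_dwells():
    frames = [
        _carbonyl_frame([5.0, 0.0, 0.0], [4.0, 0.0, 0.0]) for _ in range(100)
    ] + [_carbonyl_frame([5.0, 0.0, 0.0], [6.0, 0.0, 0.0]) for _ in range(100)]
    trace = classify_flip_trace(frames, "A", 76, frame_dt=0.1)
    dwells, _ = flip_dwells(trace, long_threshold=75.0)
    assert list(dwells["state"]) == ["inward", "flipped"]
    np.testing.assert_allclose(dwells["duration_ns"], [10.0, 10.0])
    assert dwells["censored"].all()


def test_flip_hysteresis_suppresses_boundary_chatter():
    # projections oscillating within the +/-0.17 band must not switch state
    frames = []
    for k in range(50):
        x = 0.1 if k % 2 == 0 else -0.1
        # C=O mostly axial: radial projection of the unit vector ~ +/-0.0995
        frames.append(_carbonyl_frame([5.0, 0.0, 0.0], [5.0 + x, 0.0, 1.0]))
    trace = classify_flip_trace(frames, "A", 76, frame_dt=0.1)
    assert len(set(trace.states)) == 1


def test_flip_dwell_trivial_cases():
    all_in = FlipTrace("V76", "A", np.array(["inward"] * 50, dtype=object), 0.1)
    dwells, frac = flip_dwells(all_in, long_threshold=1.0)
    assert len(dwells) == 1 and dwells["duration_ns"].iloc[0] == pytest.approx(5.0)
    assert frac == 1.0

    alternating = FlipTrace(
        "V76", "A", np.array(["inward", "flipped"] * 25, dtype=object), 0.1
    )
    dwells, frac = flip_dwells(alternating, long_threshold=0.2)
    np.testing.assert_allclose(dwells["duration_ns"], 0.1)
    assert frac == 0.0


def test_flip_series_mean_dwell_matches_geometric():
    from bilayergate.synthetic import gen_flip_series

    trace, truth = gen_flip_series(0.05, 0.05, 20000, frame_dt=0.1, seed=21)
    dwells, _ = flip_dwells(trace)
    interior = dwells[~dwells["censored"]]
    mean_dwell = interior["duration_ns"].mean()
    assert mean_dwell == pytest.approx(0.1 / 0.05, rel=0.15)
    frac_flipped = (trace.states == "flipped").mean()
    assert frac_flipped == pytest.approx(0.5, abs=0.05)
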