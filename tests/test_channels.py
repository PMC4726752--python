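"""Tunnel detection, choke-point diameters and blocking classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chokepoint.channels import (
    BottleneckSeries,
    bottleneck_diameter,
    classify_channel,
    detect_tunnels,
    diameter_series,
    salt_bridge_present,
    salt_bridge_series,
)
from chokepoint.structio import Ensemble, StructureFrame, vdw_radius
from chokepoint.synthetic import (
    GATE_ACIDIC,
    GATE_BASIC,
    TunnelSpec,
    make_tunnel_ensemble,
    suggested_start,
)
from conftest import make_atom

R_C = vdw_radius("C")


def _two_carbon_frame(distance):
    return StructureFrame(0, [
        make_atom(1, "CA", "C", "GLY", "A", 1, [0, 0, 0]),
        make_atom(2, "CA", "C", "GLY", "A", 2, [distance, 0, 0]),
    ])


# ------------------------------------------------------------ choke diameters

def test_single_carbon_pair_diameter():
    frame = _two_carbon_frame(10.0)
    d = bottleneck_diameter(frame, (("A", 1), ("A", 2)))
    assert d == pytest.approx(10.0 - 2 * R_C)


def test_diameter_invariant_under_rotation():
    frame = _two_carbon_frame(7.5)
    d0 = bottleneck_diameter(frame, (("A", 1), ("A", 2)))
    R = Rotation.from_euler("xyz", [0.5, 1.0, -2.0]).as_matrix()
    moved = frame.with_coords(frame.coords @ R.T + [3, -4, 5])
    assert bottleneck_diameter(moved, (("A", 1), ("A", 2))) == pytest.approx(d0, abs=1e-9)


def test_diameter_matches_brute_force_over_atom_pairs():
    """50 seeded random multi-atom residue pairs against exhaustive search."""
    rng = np.random.default_rng(9)
    for _ in range(50):
        n1, n2 = rng.integers(2, 6, 2)
        elements = ["C", "N", "O", "S"]
        atoms = []
        for i in range(n1):
            el = elements[rng.integers(4)]
            atoms.append(make_atom(i + 1, f"X{i}", el, "UNK", "A", 1, rng.normal(0, 4, 3)))
        for i in range(n2):
            el = elements[rng.integers(4)]
            atoms.append(make_atom(n1 + i + 1, f"Y{i}", el, "UNK", "A", 2,
                                   rng.normal(10, 4, 3)))
        frame = StructureFrame(0, atoms)
        expected = min(
            np.linalg.norm(a.position - b.position)
            - vdw_radius(a.element) - vdw_radius(b.element)
            for a in atoms[:n1] for b in atoms[n1:]
        )
        got = bottleneck_diameter(frame, (("A", 1), ("A", 2)))
        assert got == pytest.approx(expected, abs=1e-9)


def test_missing_residue_is_an_error():
    with pytest.raises(KeyError):
        bottleneck_diameter(_two_carbon_frame(5.0), (("A", 1), ("B", 9)))


def test_series_constant_and_decreasing():
    const = Ensemble([_two_carbon_frame(8.0).with_coords(
        _two_carbon_frame(8.0).coords, i) for i in range(4)])
    s = diameter_series(const, (("A", 1), ("A", 2)))
    assert len(set(s.diameters)) == 1

    frames = []
    for i in range(10):
        f = _two_carbon_frame(10.0 - 0.5 * i)
        frames.append(f.with_coords(f.coords, i))
    dec = diameter_series(Ensemble(frames), (("A", 1), ("A", 2)))
    assert all(a > b for a, b in zip(dec.diameters, dec.diameters[1:]))


def test_gate_diameter_follows_ring_radius_schedule():
    """Linearly closing constriction: series == 2 r(t) − 2 r_vdW exactly."""
    radii = np.linspace(4.0, 2.5, 6)
    spec = TunnelSpec(radius_fn=lambda t: radii[t], noise_sd=0.0, seed=0)
    ens = make_tunnel_ensemble(spec, 6)
    s = diameter_series(ens, (GATE_BASIC, GATE_ACIDIC))
    assert list(s.diameters) == pytest.approx(list(2 * radii - 2 * R_C), abs=1e-9)
    assert all(a > b for a, b in zip(s.diameters, s.diameters[1:]))


# ---------------------------------------------------------------- classification

def test_classify_counts_open_frames():
    s = BottleneckSeries(("a", "b"), (5.0, 3.0, 5.0, 3.0))
    rep = classify_channel(s, 4.0)
    assert rep.open_fraction == 0.5
    assert not rep.blocked_persistently


def test_classify_extremes():
    s = BottleneckSeries(("a", "b"), (5.0, 3.0, 1.0))
    assert classify_channel(s, -np.inf).open_fraction == 1.0
    assert classify_channel(s, np.inf).blocked_persistently


def test_classify_all_closed():
    s = BottleneckSeries(("a", "b"), (1.0, 2.0))
    rep = classify_channel(s, 4.0)
    assert rep.open_fraction == 0.0 and rep.blocked_persistently


# ---------------------------------------------------------------- salt bridges

def _arg_glu_frame(no_distance):
    return StructureFrame(0, [
        make_atom(1, "CA", "C", "ARG", "A", 1, [0, 0, 0]),
        make_atom(2, "NH1", "N", "ARG", "A", 1, [1, 0, 0]),
        make_atom(3, "CA", "C", "GLU", "A", 2, [1 + no_distance + 2, 0, 0]),
        make_atom(4, "OE1", "O", "GLU", "A", 2, [1 + no_distance, 0, 0]),
    ])


def test_salt_bridge_within_cutoff():
    present, d = salt_bridge_present(_arg_glu_frame(3.5), ("A", 1), ("A", 2))
    assert present and d == pytest.approx(3.5)


def test_salt_bridge_beyond_cutoff():
    present, d = salt_bridge_present(_arg_glu_frame(5.0), ("A", 1), ("A", 2))
    assert not present and d == pytest.approx(5.0)


def test_non_ionic_residue_is_an_error(glycine_frame):
    frame = _arg_glu_frame(3.0)
    merged = StructureFrame(0, list(frame.atoms) + [
        make_atom(9, "CA", "C", "GLY", "A", 3, [20, 0, 0])])
    with pytest.raises(ValueError, match="basic"):
        salt_bridge_present(merged, ("A", 3), ("A", 2))
    with pytest.raises(ValueError, match="acidic"):
        salt_bridge_present(merged, ("A", 1), ("A", 3))


def test_salt_bridge_series_persistence():
    frames = [
        _arg_glu_frame(3.0).with_coords(_arg_glu_frame(3.0).coords, 0),
        _arg_glu_frame(6.0).with_coords(_arg_glu_frame(6.0).coords, 1),
    ]
    # different topologies would be rejected; distances differ only by coords
    flags, persistence = salt_bridge_series(Ensemble(frames), ("A", 1), ("A", 2))
    assert flags == [True, False] and persistence == 0.5


# ------------------------------------------------------------- tunnel search

def _tube_ensemble(free_radius, n_frames=1, base=7.2, seed=0):
    return make_tunnel_ensemble(
        TunnelSpec(base_radius=base, radius_fn=lambda t: free_radius + R_C, seed=seed),
        n_frames,
    )


def test_tube_bottleneck_recovered_within_grid_spacing():
    for free_r in (1.5, 2.5, 3.5):
        ens = _tube_ensemble(free_r)
        tunnels = detect_tunnels(
            ens[0], [0, 0, 6.0], probe_radius=1.0, grid_spacing=0.5
        )
        assert tunnels, f"no tunnel found at clearance {free_r}"
        assert tunnels[0].bottleneck_radius == pytest.approx(free_r, abs=0.5)


def test_shrinking_constriction_never_widens_bottleneck():
    got = []
    for free_r in (3.5, 2.5, 1.5):
        ens = _tube_ensemble(free_r)
        tunnels = detect_tunnels(ens[0], [0, 0, 6.0], probe_radius=1.0, grid_spacing=0.5)
        got.append(tunnels[0].bottleneck_radius)
    assert got[0] >= got[1] >= got[2]


def test_bottleneck_converges_with_grid_refinement():
    """Error against the analytic clearance is bounded by the grid spacing."""
    ens = _tube_ensemble(2.5)
    for spacing in (1.0, 0.5, 0.25):
        tunnels = detect_tunnels(ens[0], [0, 0, 6.0], probe_radius=1.0,
                                 grid_spacing=spacing)
        assert abs(tunnels[0].bottleneck_radius - 2.5) <= spacing + 1e-9


def test_fully_enclosed_start_yields_no_tunnel():
    # capsule: dense carbon sphere shell around the start point
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(800, 3))
    pts = 6.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
    atoms = [make_atom(i + 1, "CA", "C", "GLY", "T", i + 1, p) for i, p in enumerate(pts)]
    frame = StructureFrame(0, atoms)
    tunnels = detect_tunnels(frame, [0, 0, 0], probe_radius=1.4, grid_spacing=0.5)
    assert tunnels == []


def test_buried_start_is_an_error():
    frame = StructureFrame(0, [make_atom(1, "CA", "C", "GLY", "A", 1, [0, 0, 0])])
    with pytest.raises(ValueError, match="clearance"):
        detect_tunnels(frame, [0.2, 0, 0], probe_radius=1.4)


def test_tunnel_profile_invariants():
    ens = _tube_ensemble(2.5)
    t = detect_tunnels(ens[0], [0, 0, 6.0], probe_radius=1.0, grid_spacing=0.5)[0]
    assert t.bottleneck_radius == pytest.approx(t.radius_at.min())
    assert np.all(t.radius_at >= t.probe_radius)
    assert len(t.centerline) == len(t.radius_at)
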