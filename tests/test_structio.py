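"""Structure I/O, selections, distances and superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from chokepoint.structio import (
    Atom,
    AtomSpec,
    Ensemble,
    Selection,
    StructureFrame,
    TopologyError,
    measure_distance,
    parse_selection,
    read_structure,
    rmsd_series,
    select_atoms,
    superpose,
    vdw_radius,
    write_structure,
)
from conftest import make_atom


# ---------------------------------------------------------------------- I/O

def test_round_trip_preserves_identifiers_and_coordinates(tmp_path, simple_frame):
    shifted = simple_frame.with_coords(simple_frame.coords + [0.123, -4.567, 8.901], 1)
    ens = Ensemble([simple_frame, shifted])
    path = tmp_path / "two_model.pdb"
    write_structure(ens, path)
    back = read_structure(path)
    assert len(back) == 2
    assert back.topology_key == ens.topology_key
    for orig, rd in zip(ens, back):
        assert np.abs(rd.coords - orig.coords).max() <= 1e-3


def test_b_factor_column_survives_round_trip(tmp_path, simple_frame):
    scored = simple_frame.with_b_factors(np.array([0.25, 0.5, 0.99]))
    path = tmp_path / "scores.pdb"
    write_structure(Ensemble([scored]), path)
    back = read_structure(path)[0]
    assert [a.b_factor for a in back.atoms] == pytest.approx([0.25, 0.5, 0.99], abs=1e-2)


def test_inconsistent_model_topology_is_an_error(tmp_path):
    text = (
        "MODEL        1\n"
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\nEND\n"
    )
    path = tmp_path / "bad.pdb"
    path.write_text(text)
    with pytest.raises(Exception):
        read_structure(path)


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    text = (
        "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.30  0.00           C\n"
        "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.70  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "alt.pdb"
    path.write_text(text)
    frame = read_structure(path)[0]
    assert len(frame) == 1
    assert frame.atoms[0].position[0] == pytest.approx(9.0)


def test_hetatm_records_are_retained(mini_holo_complex):
    frame = read_structure(mini_holo_complex)[0]
    res_names = {a.res_name for a in frame.atoms}
    assert {"FAD", "PHB"} <= res_names


def test_empty_ensemble_rejected():
    with pytest.raises(ValueError):
        Ensemble([])


def test_duplicate_atom_identity_rejected():
    a = make_atom(1, "CA", "C", "GLY", "A", 1, [0, 0, 0])
    b = make_atom(2, "CA", "C", "GLY", "A", 1, [1, 0, 0])
    with pytest.raises(TopologyError):
        StructureFrame(0, [a, b])


# ---------------------------------------------------------------- selections

def test_alpha_carbon_selection_on_ca_chain(ca_chain):
    assert len(select_atoms(ca_chain, Selection(klass="ca"))) == 10


def test_glycine_heavy_selection_is_main_chain(glycine_frame):
    atoms = select_atoms(
        glycine_frame, parse_selection("chain:A resid:248 class:heavy")
    )
    assert [a.name for a in atoms] == ["N", "CA", "C", "O"]


def test_empty_selection_is_valid_and_logged(ca_chain, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="chokepoint.structio"):
        assert select_atoms(ca_chain, "chain:Z") == []
    assert any("matched no atoms" in r.message for r in caplog.records)


# ----------------------------------------------------------------- distances

def test_three_four_five_distance(simple_frame):
    d = measure_distance(simple_frame, AtomSpec("A", 1, "CA"), AtomSpec("A", 2, "CA"))
    assert d == pytest.approx(5.0)


def test_distance_is_symmetric_and_zero_on_self(simple_frame):
    a, b = AtomSpec("A", 1, "CA"), AtomSpec("A", 3, "OG")
    assert measure_distance(simple_frame, a, b) == measure_distance(simple_frame, b, a)
    assert measure_distance(simple_frame, a, a) == 0.0


def test_unresolvable_spec_names_the_spec(simple_frame):
    with pytest.raises(KeyError, match="B:9:CA"):
        measure_distance(simple_frame, AtomSpec("A", 1, "CA"), AtomSpec("B", 9, "CA"))


# --------------------------------------------------------------- vdW radii

def test_bondi_radii_and_unknown_element():
    assert vdw_radius("C") == 1.70
    assert vdw_radius("N") == 1.55
    with pytest.raises(KeyError):
        vdw_radius("Xx")


# -------------------------------------------------------------- superposition

def test_superpose_self_gives_zero(ca_chain):
    _, rmsd = superpose(ca_chain, ca_chain, Selection(klass="ca"))
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_superpose_recovers_rigid_motion(ca_chain):
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = ca_chain.with_coords(ca_chain.coords @ R.T + [10.0, -2.0, 3.0])
    _, rmsd = superpose(moved, ca_chain, Selection(klass="ca"))
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_matches_independent_oracle(ca_chain):
    """Kabsch RMSD must agree with scipy's align_vectors solution to 1e-9."""
    rng = np.random.default_rng(5)
    noisy = ca_chain.coords + rng.normal(0, 1.0, ca_chain.coords.shape)
    R = Rotation.from_euler("xyz", [0.4, -1.0, 2.2]).as_matrix()
    mobile = ca_chain.with_coords(noisy @ R.T + [4, 5, 6])
    _, rmsd = superpose(mobile, ca_chain, Selection(klass="ca"))
    X = mobile.coords - mobile.coords.mean(0)
    Y = ca_chain.coords - ca_chain.coords.mean(0)
    _, rssd = Rotation.align_vectors(Y, X)
    assert rmsd == pytest.approx(rssd / np.sqrt(len(X)), abs=1e-9)


def test_superpose_with_residue_pairing(ca_chain):
    """Cross-numbering superposition through an explicit residue map."""
    renumbered = StructureFrame(0, [
        make_atom(i + 1, "CA", "C", "ALA", "A", 100 + i, p)
        for i, p in enumerate(ca_chain.coords)
    ])
    pairing = {100 + i: i + 1 for i in range(10)}
    _, rmsd = superpose(renumbered, ca_chain, Selection(klass="ca"), pairing)
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_superpose_underdetermined(simple_frame):
    with pytest.raises(ValueError, match="underdetermined"):
        superpose(simple_frame, simple_frame, Selection(names=frozenset({"OG"}), klass="all"))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    angles=st.tuples(*[st.floats(-3.1, 3.1) for _ in range(3)]),
    shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
)
def test_rmsd_invariant_under_rigid_pretransform(angles, shift):
    rng = np.random.default_rng(2)
    base = rng.normal(0, 5, (12, 3))
    frame = StructureFrame(0, [
        make_atom(i + 1, "CA", "C", "ALA", "A", i + 1, p) for i, p in enumerate(base)
    ])
    mobile = frame.with_coords(base + rng.normal(0, 0.8, base.shape))
    _, rmsd0 = superpose(mobile, frame, Selection(klass="ca"))
    R = Rotation.from_euler("xyz", angles).as_matrix()
    pre = mobile.with_coords(mobile.coords @ R.T + np.asarray(shift))
    _, rmsd1 = superpose(pre, frame, Selection(klass="ca"))
    assert abs(rmsd0 - rmsd1) < 1e-6


def test_rmsd_series_hand_computed(ca_chain):
    """Per-frame RMS of known displacements, after superposition is a no-op
    (zero-mean, rotation-free perturbation constructed along atom index)."""
    f0 = ca_chain
    # identical frames -> zeros
    ens = Ensemble([f0, f0.with_coords(f0.coords, 1)])
    assert rmsd_series(ens, f0, Selection(klass="ca")) == pytest.approx([0.0, 0.0], abs=1e-9)
    # pure translation -> zero after superposition
    ens2 = Ensemble([f0, f0.with_coords(f0.coords + [1.0, 0, 0], 1)])
    assert rmsd_series(ens2, f0, Selection(klass="ca"))[1] == pytest.approx(0.0, abs=1e-9)


def test_measure_distance_invariant_under_atom_reordering(simple_frame):
    reordered = StructureFrame(0, list(reversed(simple_frame.atoms)))
    a, b = AtomSpec("A", 1, "CA"), AtomSpec("A", 3, "OG")
    assert measure_distance(simple_frame, a, b) == measure_distance(reordered, a, b)
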