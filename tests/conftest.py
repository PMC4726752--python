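"""Shared fixtures: tiny hand-built frames and synthetic stand-ins.

All structure fixtures are generated programmatically; nothing binary is
stored.  The "mini holo complex" fixture is a *synthetic stand-in* for a
flavin–substrate co-crystal: a pseudo-FAD C4X atom and a six-carbon substrate
ring laid out so the C4X → target-carbon distance is exactly 4.32 Å, the
diagnostic geometry of a catalytically competent flavin monooxygenase active
site.
"""

import numpy as np
import pytest

from chokepoint.structio import Atom, AtomSpec, Ensemble, StructureFrame


def make_atom(serial, name, element, res_name, chain, res_seq, pos, **kw):
    return Atom(serial, name, element, res_name, chain, res_seq, "", np.asarray(pos, float), **kw)


@pytest.fixture
def simple_frame():
    """Three heavy atoms at easy coordinates (3-4-5 triangle + one off-axis)."""
    return StructureFrame(0, [
        make_atom(1, "CA", "C", "GLY", "A", 1, [0, 0, 0]),
        make_atom(2, "CA", "C", "GLY", "A", 2, [3, 4, 0]),
        make_atom(3, "OG", "O", "SER", "A", 3, [1, 1, 1]),
    ])


@pytest.fixture
def glycine_frame():
    """One glycine with main-chain atoms plus a hydrogen."""
    return StructureFrame(0, [
        make_atom(1, "N", "N", "GLY", "A", 248, [0, 0, 0]),
        make_atom(2, "CA", "C", "GLY", "A", 248, [1.5, 0, 0]),
        make_atom(3, "C", "C", "GLY", "A", 248, [2.2, 1.3, 0]),
        make_atom(4, "O", "O", "GLY", "A", 248, [3.4, 1.4, 0.2]),
        make_atom(5, "HA", "H", "GLY", "A", 248, [1.6, -1.0, 0.3]),
    ])


@pytest.fixture
def ca_chain():
    """A 10-residue synthetic alpha-carbon chain."""
    rng = np.random.default_rng(11)
    atoms = [
        make_atom(i + 1, "CA", "C", "ALA", "A", i + 1,
                  [3.8 * i, 0, 0] + rng.normal(0, 0.3, 3))
        for i in range(10)
    ]
    return StructureFrame(0, atoms)


@pytest.fixture
def mini_holo_complex(tmp_path):
    """Synthetic stand-in for a flavin–substrate co-crystal (PDB file on disk).

    HETATM content: a pseudo-FAD with atom C4X and a pseudo-substrate "PHB"
    benzene ring whose hydroxylation-target carbon C3 lies exactly 4.32 Å
    from C4X; plus three protein H-bonding residues (Ser OG and two backbone
    carbonyl O) at fixed positions.
    """
    from chokepoint.structio import write_structure

    c4x = np.array([0.0, 0.0, 0.0])
    # benzene ring in the y-z plane centred so C3 sits at (4.32, 0, 0)
    ring_center = np.array([4.32, 1.39, 0.0])
    ring = []
    for i in range(6):
        ang = -np.pi / 2 + i * np.pi / 3
        ring.append(ring_center + 1.39 * np.array([0.0, np.sin(ang), np.cos(ang)]))
    ring[0] = np.array([4.32, 0.0, 0.0])  # C3, the target carbon

    atoms = [
        make_atom(1, "OG", "O", "SER", "A", 212, [2.0, 3.5, 1.0]),
        make_atom(2, "O", "O", "PRO", "A", 293, [5.5, 3.8, -1.2]),
        make_atom(3, "O", "O", "THR", "A", 294, [6.1, 0.5, 2.4]),
        make_atom(4, "C4X", "C", "FAD", "A", 400, c4x),
    ]
    names = ["C3", "C4", "C5", "C6", "C1", "C2"]
    for i, (nm, p) in enumerate(zip(names, ring)):
        atoms.append(make_atom(5 + i, nm, "C", "PHB", "A", 401, p))
    frame = StructureFrame(0, atoms)
    path = tmp_path / "synthetic_holo_site.pdb"
    write_structure(Ensemble([frame]), path)
    return path
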