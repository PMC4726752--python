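"""Structure I/O and geometry primitives.

Multi-model PDB files stand in for molecular-dynamics trajectory frames: each
MODEL is one :class:`StructureFrame`, and an ordered sequence of frames sharing
a single topology is an :class:`Ensemble`.  On top of that sit the geometric
primitives every downstream analysis needs — atom selection, interatomic
distances, least-squares (Kabsch) superposition and per-frame RMSD series —
plus a versioned Bondi van-der-Waals radius table used to convert
center-to-center distances into free clearance.

File parsing and writing are delegated to :mod:`biotite`; this module owns the
frame/ensemble data model and the geometry.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "AtomSpec",
    "Ensemble",
    "LookupError_",
    "ParseError",
    "RigidTransform",
    "Selection",
    "StructureFrame",
    "TopologyError",
    "measure_distance",
    "parse_selection",
    "read_structure",
    "rmsd_series",
    "select_atoms",
    "superpose",
    "vdw_radius",
    "vdw_radii_version",
    "write_structure",
]


class ParseError(ValueError):
    """A structure file could not be parsed."""


class TopologyError(ValueError):
    """Frames of one ensemble do not share the same atoms in the same order."""


class LookupError_(KeyError):
    """An AtomSpec did not resolve to exactly one atom."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class UnknownElementError(KeyError):
    """Element symbol absent from the shipped vdW radius table."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


# ---------------------------------------------------------------------------
# vdW radii


def _load_radius_table() -> tuple[int, dict[str, float]]:
    text = resources.files("chokepoint.data").joinpath("bondi_radii.json").read_text()
    doc = json.loads(text)
    return int(doc["version"]), {k.upper(): float(v) for k, v in doc["radii"].items()}


_RADII_VERSION, _RADII = _load_radius_table()


def vdw_radii_version() -> int:
    """Version number of the shipped Bondi radius table."""
    return _RADII_VERSION


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius of *element* in Å.

    Unknown elements raise :class:`UnknownElementError` rather than silently
    defaulting, so that clearance-based results never hide a bad element
    assignment.
    """
    try:
        return _RADII[element.strip().upper()]
    except KeyError:
        raise UnknownElementError(
            f"element {element!r} has no entry in the Bondi radius table "
            f"(version {_RADII_VERSION}); known: {sorted(_RADII)}"
        ) from None


# ---------------------------------------------------------------------------
# Data model


@dataclass(frozen=True)
class Atom:
    """One atom of one frame.

    ``position`` is a length-3 float array in Å.  Identity within a frame is
    the tuple ``(chain, res_seq, insertion, name)``.
    """

    serial: int
    name: str
    element: str
    res_name: str
    chain: str
    res_seq: int
    insertion: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def identity(self) -> tuple[str, int, str, str]:
        return (self.chain, self.res_seq, self.insertion, self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() == "H"


@dataclass(frozen=True)
class AtomSpec:
    """Address of exactly one atom: chain, residue number, optional insertion
    code, atom name."""

    chain: str
    res_seq: int
    name: str
    insertion: str = ""

    def __str__(self) -> str:
        ins = self.insertion or ""
        return f"{self.chain}:{self.res_seq}{ins}:{self.name}"


class StructureFrame:
    """A single conformation: an ordered collection of atoms.

    Atom identity (chain, res_seq, insertion, name) must be unique within a
    frame; duplicate identities raise :class:`TopologyError` at construction.
    """

    def __init__(self, frame_index: int, atoms: Sequence[Atom]):
        if frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        self.frame_index = int(frame_index)
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self._index: dict[tuple[str, int, str, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.identity in self._index:
                raise TopologyError(
                    f"duplicate atom identity {a.identity} in frame {frame_index}"
                )
            self._index[a.identity] = i
        self._coords = (
            np.stack([a.position for a in self.atoms])
            if self.atoms
            else np.empty((0, 3))
        )

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order (read-only view)."""
        v = self._coords.view()
        v.flags.writeable = False
        return v

    @property
    def topology_key(self) -> tuple[tuple[str, int, str, str], ...]:
        return tuple(a.identity for a in self.atoms)

    def resolve(self, spec: AtomSpec) -> Atom:
        """Return the unique atom addressed by *spec* or raise."""
        key = (spec.chain, spec.res_seq, spec.insertion or "", spec.name)
        try:
            return self.atoms[self._index[key]]
        except KeyError:
            raise LookupError_(
                f"atom spec {spec} does not resolve in frame {self.frame_index}"
            ) from None

    def residue_atoms(
        self, chain: str, res_seq: int, insertion: str = "", heavy_only: bool = True
    ) -> list[Atom]:
        out = [
            a
            for a in self.atoms
            if a.chain == chain
            and a.res_seq == res_seq
            and a.insertion == (insertion or "")
            and not (heavy_only and a.is_hydrogen)
        ]
        return out

    def with_coords(self, coords: np.ndarray, frame_index: int | None = None) -> "StructureFrame":
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return StructureFrame(
            self.frame_index if frame_index is None else frame_index, atoms
        )

    def with_b_factors(self, values: np.ndarray) -> "StructureFrame":
        values = np.asarray(values, float)
        if values.shape != (len(self.atoms),):
            raise ValueError("b-factor array shape mismatch")
        atoms = [replace(a, b_factor=float(v)) for a, v in zip(self.atoms, values)]
        return StructureFrame(self.frame_index, atoms)


class Ensemble:
    """Ordered frames sharing one topology — the in-memory stand-in for an MD
    trajectory."""

    def __init__(self, frames: Sequence[StructureFrame]):
        frames = list(frames)
        if not frames:
            raise ValueError("an Ensemble needs at least one frame")
        key = frames[0].topology_key
        for f in frames[1:]:
            if f.topology_key != key:
                raise TopologyError(
                    f"frame {f.frame_index} topology differs from frame "
                    f"{frames[0].frame_index} "
                    f"({len(f)} vs {len(frames[0])} atoms or reordered identities)"
                )
        self.frames: tuple[StructureFrame, ...] = tuple(frames)
        self.topology_key = key

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> StructureFrame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# Selections


_MAIN_CHAIN = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class Selection:
    """Predicate over atoms: chain / residue range / residue names / atom-name
    class.  ``klass`` is one of ``all``, ``heavy``, ``mainchain``, ``ca``,
    ``sidechain``."""

    chain: str | None = None
    res_range: tuple[int, int] | None = None
    res_names: frozenset[str] | None = None
    names: frozenset[str] | None = None
    klass: str = "heavy"

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.res_range is not None and not (
            self.res_range[0] <= atom.res_seq <= self.res_range[1]
        ):
            return False
        if self.res_names is not None and atom.res_name not in self.res_names:
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        if self.klass == "all":
            return True
        if self.klass == "heavy":
            return not atom.is_hydrogen
        if self.klass == "ca":
            return atom.name == "CA" and not atom.is_hydrogen
        if self.klass == "mainchain":
            return atom.name in _MAIN_CHAIN and not atom.is_hydrogen
        if self.klass == "sidechain":
            return atom.name not in _MAIN_CHAIN and not atom.is_hydrogen
        raise ValueError(f"unknown atom class {self.klass!r}")


def parse_selection(text: str) -> Selection:
    """Parse a selection string like ``"chain:A resid:240-260 name:CA class:heavy"``.

    Tokens: ``chain:<id>``, ``resid:<n>`` or ``resid:<a>-<b>``,
    ``resname:<X>[,<Y>...]``, ``name:<X>[,<Y>...]``,
    ``class:{all,heavy,mainchain,ca,sidechain}``.
    """
    kw: dict = {}
    for token in text.split():
        if ":" not in token:
            raise ValueError(f"bad selection token {token!r}")
        key, val = token.split(":", 1)
        if key == "chain":
            kw["chain"] = val
        elif key == "resid":
            lo, _, hi = val.partition("-")
            kw["res_range"] = (int(lo), int(hi) if hi else int(lo))
        elif key == "resname":
            kw["res_names"] = frozenset(v.upper() for v in val.split(","))
        elif key == "name":
            kw["names"] = frozenset(v.upper() for v in val.split(","))
        elif key == "class":
            kw["klass"] = val
        else:
            raise ValueError(f"unknown selection key {key!r}")
    return Selection(**kw)


def select_atoms(frame: StructureFrame, expr: Selection | str) -> list[Atom]:
    """Atoms of *frame* matching *expr*, in file order.

    An empty result is valid but logged, since a typo'd chain or residue range
    usually shows up as an unexpectedly empty selection.
    """
    if isinstance(expr, str):
        expr = parse_selection(expr)
    out = [a for a in frame.atoms if expr.matches(a)]
    if not out:
        logger.warning("selection %r matched no atoms in frame %d", expr, frame.frame_index)
    return out


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)


def _stack_to_ensemble(stack) -> Ensemble:
    import biotite.structure as struc

    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    n_models = stack.stack_depth()
    ins = (
        stack.ins_code
        if "ins_code" in stack.get_annotation_categories()
        else np.full(stack.array_length(), "")
    )
    occ = (
        stack.occupancy
        if "occupancy" in stack.get_annotation_categories()
        else np.ones(stack.array_length())
    )
    bfac = (
        stack.b_factor
        if "b_factor" in stack.get_annotation_categories()
        else np.zeros(stack.array_length())
    )
    frames = []
    for m in range(n_models):
        atoms = [
            Atom(
                serial=i + 1,
                name=str(stack.atom_name[i]),
                element=str(stack.element[i]),
                res_name=str(stack.res_name[i]),
                chain=str(stack.chain_id[i]),
                res_seq=int(stack.res_id[i]),
                insertion=str(ins[i]).strip(),
                position=stack.coord[m, i],
                occupancy=float(occ[i]),
                b_factor=float(bfac[i]),
            )
            for i in range(stack.array_length())
        ]
        frames.append(StructureFrame(m, atoms))
    return Ensemble(frames)


def read_structure(path, dialect: str = "pdb") -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    HETATM records (cofactors, ligands) are retained; hydrogens are retained
    in the data model but excluded from heavy-atom selections; alternate
    locations are resolved to the highest-occupancy conformer (first wins on
    tie).  A single-model file yields a one-frame ensemble.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(
            model=None,
            altloc="occupancy",
            extra_fields=["b_factor", "occupancy"],
        )
    except FileNotFoundError:
        raise
    except TopologyError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError / ValueError
        msg = str(exc)
        if "model" in msg.lower() and ("atom" in msg.lower() or "differ" in msg.lower()):
            raise TopologyError(f"{path}: inconsistent topology across models: {msg}") from exc
        raise ParseError(f"{path}: {msg}") from exc
    try:
        return _stack_to_ensemble(stack)
    except TopologyError as exc:
        raise TopologyError(f"{path}: {exc}") from exc


def write_structure(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB file.

    Round trip: ``read_structure(write_structure(e))`` reproduces identifiers
    exactly and coordinates to the PDB fixed-column precision of 1e-3 Å.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = len(ensemble.frames[0])
    if n_atoms == 0:
        raise ValueError("refusing to write an ensemble with no atoms")
    arrays = []
    for frame in ensemble.frames:
        arr = struc.AtomArray(n_atoms)
        arr.coord = np.asarray(frame.coords, dtype=np.float32)
        arr.chain_id = np.array([a.chain for a in frame.atoms])
        arr.res_id = np.array([a.res_seq for a in frame.atoms])
        arr.ins_code = np.array([a.insertion for a in frame.atoms])
        arr.res_name = np.array([a.res_name for a in frame.atoms])
        arr.atom_name = np.array([a.name for a in frame.atoms])
        arr.element = np.array([a.element.upper() for a in frame.atoms])
        arr.set_annotation("b_factor", np.array([a.b_factor for a in frame.atoms]))
        arr.set_annotation("occupancy", np.array([a.occupancy for a in frame.atoms]))
        arr.hetero = np.array(
            [a.res_name not in _STANDARD_RESIDUES for a in frame.atoms]
        )
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


# ---------------------------------------------------------------------------
# Geometry


def measure_distance(frame: StructureFrame, a: AtomSpec, b: AtomSpec) -> float:
    """Euclidean distance in Å between the atoms addressed by *a* and *b*."""
    pa = frame.resolve(a).position
    pb = frame.resolve(b).position
    return float(np.linalg.norm(pa - pb))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R @ x + t`` (det R = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    # Closed-form least-squares superposition via SVD of the covariance;
    # reflection corrected so the rotation is always proper.
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _paired_coords(
    mobile: StructureFrame,
    reference: StructureFrame,
    expr: Selection | str,
    pairing: Mapping[int, int] | None,
) -> tuple[np.ndarray, np.ndarray]:
    sel = parse_selection(expr) if isinstance(expr, str) else expr
    mob_atoms = [a for a in mobile.atoms if sel.matches(a)]
    xs, ys = [], []
    for a in mob_atoms:
        if pairing is None:
            key = a.identity
        else:
            if a.res_seq not in pairing:
                continue
            key = (a.chain, pairing[a.res_seq], a.insertion, a.name)
        idx = reference._index.get(key)
        if idx is None and pairing is not None:
            # cross-protein pairing: allow any chain in the reference
            for (ch, rs, ic, nm), j in reference._index.items():
                if rs == key[1] and nm == key[3] and ic == key[2]:
                    idx = j
                    break
        if idx is not None:
            xs.append(a.position)
            ys.append(reference.atoms[idx].position)
    return np.array(xs, float).reshape(-1, 3), np.array(ys, float).reshape(-1, 3)


def superpose(
    mobile: StructureFrame,
    reference: StructureFrame,
    expr: Selection | str = Selection(klass="heavy"),
    pairing: Mapping[int, int] | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid-body superposition of *mobile* onto *reference*.

    Atoms are paired by identity (chain, res_seq, insertion, name), or — for
    cross-homolog comparisons — through *pairing*, a mobile→reference residue
    number map (e.g. from a sequence alignment); within paired residues atoms
    match by name.  Returns the proper rigid transform and the RMSD of the
    paired atoms after applying it.
    """
    X, Y = _paired_coords(mobile, reference, expr, pairing)
    if len(X) < 3:
        raise ValueError(
            f"superposition underdetermined: only {len(X)} paired atoms (need >= 3)"
        )
    return _kabsch(X, Y)


def rmsd_series(
    ensemble: Ensemble,
    reference: StructureFrame,
    expr: Selection | str = Selection(klass="heavy"),
    pairing: Mapping[int, int] | None = None,
) -> list[float]:
    """Per-frame RMSD to *reference* after optimal superposition of each frame."""
    return [superpose(f, reference, expr, pairing)[1] for f in ensemble]
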