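"""Synthetic fixtures with analytically known answers.

Every generator here is a pure function of its spec and seed, and each one is
built so the downstream analysis has a closed-form expected result:

* :func:`make_tunnel_ensemble` — a capped pseudo-atom tube with a constriction
  ring whose radius follows a per-frame schedule; the choke-point diameter
  between the two gate pseudo-residues is exactly ``2·r(t) − 2·r_vdW(C)`` and
  the tunnel's free bottleneck radius is ``r(t) − r_vdW(C)`` on the axis.
  This emulates a channel breathing between open and closed states in an MD
  trajectory.
* :func:`make_blocked_variant` — the same tube with Arg/Glu-like side-chain
  tips reaching across the lumen (minimal N–O distance 3.0 Å in every frame),
  emulating a channel-blocking salt bridge in a double mutant.
* :func:`make_reference_site` — atoms realizing an exact target distance
  matrix (classical multidimensional scaling embedding), standing in for a
  crystallographic active site.
* :func:`make_msa` — an alignment whose per-column normalized-entropy
  conservation matches a target profile in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .conservation import MSA, _AA
from .structio import Atom, AtomSpec, Ensemble, StructureFrame, vdw_radius

__all__ = [
    "SiteSpec",
    "TunnelSpec",
    "GATE_BASIC",
    "GATE_ACIDIC",
    "make_blocked_variant",
    "make_msa",
    "make_reference_site",
    "make_tunnel_ensemble",
    "suggested_start",
]

# gate pseudo-residue identifiers (chain, res_seq): an Arg-like basic gate and
# a Glu-like acidic gate facing each other across the constriction
GATE_BASIC = ("A", 248)
GATE_ACIDIC = ("A", 382)

_R_C = 1.70  # Bondi carbon radius; the tube is all-carbon


@dataclass(frozen=True)
class TunnelSpec:
    """Geometry of the synthetic tube.

    All radii are *atom-center* radii in Å: a ring of atoms at center radius r
    leaves a free (surface) radius of ``r − 1.70`` on the axis.  ``radius_fn``
    maps frame index to the constriction center radius; Gaussian noise of sd
    ``noise_sd`` is added to the ring radius (not per atom), seeded, so the
    analytic bottleneck stays known per frame.
    """

    length: float = 20.0
    base_radius: float = 6.0
    constriction_frac: float = 0.5
    radius_fn: Callable[[int], float] = lambda t: 4.0
    shell_spacing: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.base_radius <= 0:
            raise ValueError("length and base_radius must be positive")
        if self.shell_spacing > self.base_radius:
            raise ValueError("atom spacing exceeds tube radius: infeasible shell")
        if not (0.0 < self.constriction_frac < 1.0):
            raise ValueError("constriction_frac must be in (0, 1)")


def _ring(radius: float, z: float, n: int, phase: float = 0.0) -> np.ndarray:
    theta = phase + 2 * np.pi * np.arange(n) / n
    return np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)], axis=1
    )


def suggested_start(spec: TunnelSpec) -> np.ndarray:
    """A start point on the tube axis, in front of the cofactor marker and
    below the constriction."""
    return np.array([0.0, 0.0, 0.30 * spec.length])


def _constriction_radii(spec: TunnelSpec, n_frames: int) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    r = np.array([float(spec.radius_fn(t)) for t in range(n_frames)])
    if np.any(r <= 0) or np.any(r > spec.base_radius):
        raise ValueError("constriction radius must lie in (0, base_radius]")
    if spec.noise_sd > 0:
        r = r + rng.normal(0.0, spec.noise_sd, size=n_frames)
        r = np.clip(r, 0.5, spec.base_radius)
    return r


def _tube_frame(
    spec: TunnelSpec, r_con: float, frame_index: int, blocked: bool
) -> StructureFrame:
    dz = spec.shell_spacing
    R = spec.base_radius
    L = spec.length
    zc = spec.constriction_frac * L
    n_wall = max(8, int(np.ceil(2 * np.pi * R / dz)))

    atoms: list[Atom] = []
    serial = 0

    def add(name, element, res_name, chain, res_seq, pos):
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(serial, name, element, res_name, chain, res_seq, "", np.asarray(pos, float))
        )

    # cofactor marker at the capped end: a pseudo-flavin C4X at the tube base
    add("C4X", "C", "FAD", "F", 900, [0.0, 0.0, 0.0])

    res = 0
    # cap: concentric rings at z = 0
    for rr in np.arange(dz, R + dz / 2, dz):
        for p in _ring(rr, 0.0, max(6, int(np.ceil(2 * np.pi * rr / dz)))):
            res += 1
            add("CA", "C", "GLY", "T", res, p)
    # wall: rings along z
    for z in np.arange(0.0, L + dz / 2, dz):
        for p in _ring(R, z, n_wall):
            res += 1
            add("CA", "C", "GLY", "T", res, p)
    # constriction washer at z = zc: rings from the moving inner radius out to
    # the wall (fixed count so topology is frame-invariant), angularly offset
    # so no atom coincides with a gate atom
    n_washer = max(2, int(np.ceil(R / dz)))
    for w in range(n_washer):
        frac = w / (n_washer - 1)
        rr = r_con + frac * (R - r_con)
        for p in _ring(rr, zc, n_wall, phase=np.pi / n_wall):
            res += 1
            add("CA", "C", "GLY", "T", res, p)

    # gate pseudo-residues diametrically across the constriction; their CA
    # atoms sit on the ring so the closest-heavy-atom choke diameter is
    # exactly 2*r_con - 2*r_vdw(C)
    tip_up = 1.2  # z-offset keeping side-chain tips off the choke axis (open form)
    add("CA", "C", "ARG", GATE_BASIC[0], GATE_BASIC[1], [r_con, 0.0, zc])
    add("CA", "C", "GLU", GATE_ACIDIC[0], GATE_ACIDIC[1], [-r_con, 0.0, zc])
    if blocked:
        # salt-bridge tips reach across the lumen: N-O distance 3.0 A always
        add("NH1", "N", "ARG", GATE_BASIC[0], GATE_BASIC[1], [1.5, 0.0, zc])
        add("OE1", "O", "GLU", GATE_ACIDIC[0], GATE_ACIDIC[1], [-1.5, 0.0, zc])
    else:
        add("NH1", "N", "ARG", GATE_BASIC[0], GATE_BASIC[1], [r_con, 0.0, zc + tip_up])
        add("OE1", "O", "GLU", GATE_ACIDIC[0], GATE_ACIDIC[1], [-r_con, 0.0, zc + tip_up])

    return StructureFrame(frame_index, atoms)


def make_tunnel_ensemble(spec: TunnelSpec, n_frames: int, blocked: bool = False) -> Ensemble:
    """Build the synthetic tube ensemble (see module docstring).

    Deterministic for a fixed ``(spec, n_frames, blocked)``; the constriction
    center radius of frame t is ``radius_fn(t)`` plus seeded ring noise.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    radii = _constriction_radii(spec, n_frames)
    return Ensemble([_tube_frame(spec, r, i, blocked) for i, r in enumerate(radii)])


def make_blocked_variant(spec: TunnelSpec, n_frames: int) -> Ensemble:
    """The channel-blocking double-mutant analogue of the tube: same topology,
    but the gate side-chain tips form a permanent 3.0 Å N–O contact spanning
    the lumen, so the salt-bridge persists in every frame and the choke-point
    diameter never opens."""
    return make_tunnel_ensemble(spec, n_frames, blocked=True)


def expected_gate_diameter(r_con: float) -> float:
    """Closed-form choke diameter of the open tube gates at center radius r."""
    return 2.0 * r_con - 2.0 * _R_C


# ---------------------------------------------------------------------------
# Reference active site


@dataclass(frozen=True)
class SiteSpec:
    """Target pairwise distance matrix for k site atoms, plus decoys."""

    distances: np.ndarray  # (k, k), symmetric, zero diagonal
    decoration: int = 10

    def __post_init__(self) -> None:
        D = np.asarray(self.distances, float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] < 2:
            raise ValueError("distance matrix must be square, k >= 2")
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "distances", D)


def _embed_distances(D: np.ndarray) -> np.ndarray:
    # classical multidimensional scaling into 3-space
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order[:3]], V[:, order[:3]]
    X = V * np.sqrt(np.clip(w, 0.0, None))
    D_hat = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    if np.max(np.abs(D_hat - D)) > 1e-6:
        raise ValueError(
            "distance matrix is not embeddable in 3-space to 1e-6 Å "
            "(triangle inequality violated or intrinsically > 3-dimensional)"
        )
    return X


def make_reference_site(spec: SiteSpec, seed: int = 0) -> tuple[StructureFrame, list[AtomSpec]]:
    """A frame whose first k atoms realize ``spec.distances`` exactly (to
    1e-6 Å), plus seeded decoy atoms at least 8 Å away from every site atom.

    Returns the frame and the :class:`AtomSpec` list addressing the site
    atoms, ready for ``build_descriptor``.
    """
    X = _embed_distances(spec.distances)
    k = X.shape[0]
    rng = np.random.default_rng(seed)
    atoms = []
    specs = []
    for i in range(k):
        atoms.append(Atom(i + 1, "CA", "C", "SIT", "A", i + 1, "", X[i]))
        specs.append(AtomSpec("A", i + 1, "CA"))
    center = X.mean(axis=0)
    span = np.max(np.linalg.norm(X - center, axis=1))
    for j in range(spec.decoration):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        pos = center + v * (span + 8.0 + rng.uniform(0.0, 4.0))
        atoms.append(Atom(k + j + 1, "CA", "C", "DEC", "B", j + 1, "", pos))
    return StructureFrame(0, atoms), specs


# ---------------------------------------------------------------------------
# Synthetic MSAs


def _dominant_prob_for_conservation(c: float) -> float:
    """Probability mass of the dominant residue so that a (p, rest-uniform)
    20-letter categorical has normalized entropy 1 − c."""
    if c >= 1.0:
        return 1.0
    if c <= 0.0:
        return 1.0 / 20.0

    target_H = (1.0 - c) * np.log(20.0)

    def H(p):
        rest = (1.0 - p) / 19.0
        h = -p * np.log(p)
        if rest > 0:
            h -= 19.0 * rest * np.log(rest)
        return h

    # H is monotonically decreasing in p on [1/20, 1)
    return brentq(lambda p: H(p) - target_H, 1.0 / 20.0, 1.0 - 1e-12)


def make_msa(n_seqs: int, profile: Sequence[float], seed: int = 0) -> MSA:
    """An MSA whose column c has expected normalized-entropy conservation
    ``profile[c]``: one seeded dominant residue with probability p(c), the
    remaining 19 equifrequent."""
    if n_seqs < 1:
        raise ValueError("need at least one sequence")
    profile = np.asarray(profile, float)
    if np.any((profile < 0) | (profile > 1)):
        raise ValueError("target conservation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(profile)
    cols = np.empty((L, n_seqs), dtype="<U1")
    aa = np.array(list(_AA))
    for c, target in enumerate(profile):
        p = _dominant_prob_for_conservation(float(target))
        dom = rng.integers(20)
        probs = np.full(20, (1.0 - p) / 19.0)
        probs[dom] = p
        cols[c] = aa[rng.choice(20, size=n_seqs, p=probs)]
    rows = tuple("".join(cols[:, s]) for s in range(n_seqs))
    ids = tuple(f"seq{s + 1}" for s in range(n_seqs))
    return MSA(ids, rows)
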