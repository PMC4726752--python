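"""Substrate-access tunnel detection and choke-point tracking.

Detection works on a clearance field: a regular grid is laid over the
structure's bounding box, each node is weighted by its distance to the nearest
heavy-atom van-der-Waals surface, nodes narrower than the probe are removed,
and a widest-path search (maximise the minimum clearance along the path) is
run from a start point placed in front of the cofactor.  A boundary node
counts as a tunnel exit when a sphere of radius ``shell_radius`` centred
``shell_depth`` outward of it contains no protein atoms — the shell criterion
that distinguishes bulk solvent from surface pockets.  Exits closer together
than ``shell_radius`` are merged, keeping the widest representative.

Choke points are tracked per frame through a residue pair flanking the
bottleneck: the diameter is the minimum heavy-atom surface-to-surface
distance between the two residues, which can go negative when the surfaces
interpenetrate (e.g. a formed salt bridge).  A channel is "open" in a frame
when that diameter clears a threshold, and "persistently blocked" when it
never does.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Ensemble, Selection, StructureFrame, vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "BottleneckSeries",
    "ChannelStateReport",
    "ResidueID",
    "TunnelProfile",
    "bottleneck_diameter",
    "classify_channel",
    "detect_tunnels",
    "diameter_series",
    "salt_bridge_present",
    "salt_bridge_series",
]

ResidueID = tuple  # (chain, res_seq) or (chain, res_seq, insertion)


def _res_id(res: ResidueID) -> tuple[str, int, str]:
    if len(res) == 2:
        return (res[0], int(res[1]), "")
    return (res[0], int(res[1]), res[2] or "")


@dataclass(frozen=True)
class TunnelProfile:
    """One detected tunnel: centerline points, free radius at each point, and
    the choke point (minimum free radius)."""

    centerline: np.ndarray          # (n, 3)
    radius_at: np.ndarray           # (n,)
    bottleneck_radius: float
    bottleneck_position: np.ndarray
    exit_point: np.ndarray
    probe_radius: float
    grid_spacing: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "bottleneck_radius": self.bottleneck_radius,
                "bottleneck_position": self.bottleneck_position.tolist(),
                "exit_point": self.exit_point.tolist(),
                "probe_radius": self.probe_radius,
                "grid_spacing": self.grid_spacing,
                "centerline": self.centerline.tolist(),
                "radius_at": self.radius_at.tolist(),
            }
        )


@dataclass(frozen=True)
class BottleneckSeries:
    """Per-frame choke-point diameter (Å) for one residue pair.

    In the default closest-heavy-atom mode, diameters are surface-to-surface
    and may be negative when side chains interpenetrate.
    """

    residue_pair: tuple[ResidueID, ResidueID]
    diameters: tuple[float, ...]
    mode: str = "closest-heavy-atom"

    def __len__(self) -> int:
        return len(self.diameters)

    def to_tsv(self) -> str:
        lines = ["frame\tdiameter"]
        lines += [f"{i}\t{d:.6f}" for i, d in enumerate(self.diameters)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ChannelStateReport:
    threshold: float
    open_flags: tuple[bool, ...]
    open_fraction: float
    blocked_persistently: bool


# ---------------------------------------------------------------------------
# Clearance field + widest path


def _heavy_coords_radii(frame: StructureFrame) -> tuple[np.ndarray, np.ndarray]:
    atoms = [a for a in frame.atoms if not a.is_hydrogen]
    if not atoms:
        raise ValueError("frame has no heavy atoms")
    coords = np.stack([a.position for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    return coords, radii


def _clearance(points: np.ndarray, tree: cKDTree, radii: np.ndarray) -> np.ndarray:
    # distance to nearest atom *surface*; radii vary, so check enough
    # neighbours that the true minimiser cannot be missed
    k = min(len(radii), 24)
    dist, idx = tree.query(points, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    return np.min(dist - radii[idx], axis=1)


def detect_tunnels(
    frame: StructureFrame,
    start: Sequence[float],
    probe_radius: float = 1.4,
    shell_radius: float = 6.0,
    shell_depth: float = 6.0,
    grid_spacing: float = 0.5,
) -> list[TunnelProfile]:
    """Detect substrate-access tunnels from *start* to bulk solvent.

    Returns tunnels sorted by descending bottleneck radius; an empty list
    means the start point is fully enclosed at this probe radius.
    """
    start = np.asarray(start, float)
    coords, radii = _heavy_coords_radii(frame)
    tree = cKDTree(coords)

    start_clear = float(_clearance(start[None, :], tree, radii)[0])
    if start_clear < probe_radius:
        raise ValueError(
            f"start point has clearance {start_clear:.2f} Å < probe "
            f"{probe_radius:.2f} Å; it must lie in free space (move it toward "
            f"open volume, e.g. along the cofactor's outward normal)"
        )

    pad = 2.0 * grid_spacing + probe_radius
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    lo = np.minimum(lo, start - grid_spacing)
    hi = np.maximum(hi, start + grid_spacing)
    axes = [np.arange(lo[d], hi[d] + grid_spacing / 2, grid_spacing) for d in range(3)]
    nx, ny, nz = (len(ax) for ax in axes)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    clear = _clearance(pts, tree, radii).reshape(nx, ny, nz)
    passable = clear >= probe_radius

    # start node = nearest passable node to the start point
    start_idx = tuple(
        int(np.clip(round((start[d] - lo[d]) / grid_spacing), 0, [nx, ny, nz][d] - 1))
        for d in range(3)
    )
    if not passable[start_idx]:
        # snap to the best passable node within one spacing
        best = None
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    cand = (start_idx[0] + di, start_idx[1] + dj, start_idx[2] + dk)
                    if all(0 <= c < n for c, n in zip(cand, (nx, ny, nz))) and passable[cand]:
                        if best is None or clear[cand] > clear[best]:
                            best = cand
        if best is None:
            raise ValueError("start point is not connected to any passable grid node")
        start_idx = best

    # widest-path (max-min clearance) search over 6-connected passable nodes
    bottleneck = np.full((nx, ny, nz), -np.inf)
    bottleneck[start_idx] = clear[start_idx]
    prev = {}
    heap = [(-clear[start_idx], start_idx)]
    neigh = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    while heap:
        negb, node = heapq.heappop(heap)
        b = -negb
        if b < bottleneck[node]:
            continue
        i, j, k = node
        for di, dj, dk in neigh:
            nb = (i + di, j + dj, k + dk)
            if not (0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz):
                continue
            if not passable[nb]:
                continue
            cand = min(b, clear[nb])
            if cand > bottleneck[nb]:
                bottleneck[nb] = cand
                prev[nb] = node
                heapq.heappush(heap, (-cand, nb))

    # boundary nodes reachable from start, tested against the shell criterion
    centroid = coords.mean(axis=0)
    exits = []
    boundary = np.zeros((nx, ny, nz), bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    cand_idx = np.argwhere(boundary & (bottleneck > -np.inf))
    for idx in cand_idx:
        node = tuple(int(v) for v in idx)
        pos = lo + np.array(node) * grid_spacing
        out = pos - centroid
        norm = np.linalg.norm(out)
        if norm == 0:
            continue
        shell_center = pos + out / norm * shell_depth
        if not tree.query_ball_point(shell_center, shell_radius):
            exits.append((float(bottleneck[node]), node, pos))

    exits.sort(key=lambda e: -e[0])
    tunnels: list[TunnelProfile] = []
    kept_exits: list[np.ndarray] = []
    for b, node, pos in exits:
        if any(np.linalg.norm(pos - p) < shell_radius for p in kept_exits):
            continue
        kept_exits.append(pos)
        path = [node]
        while path[-1] != start_idx:
            path.append(prev[path[-1]])
        path.reverse()
        centerline = lo + np.array(path, float) * grid_spacing
        radius_at = np.array([clear[p] for p in path])
        arg = int(np.argmin(radius_at))
        tunnels.append(
            TunnelProfile(
                centerline=centerline,
                radius_at=radius_at,
                bottleneck_radius=float(radius_at[arg]),
                bottleneck_position=centerline[arg],
                exit_point=pos,
                probe_radius=probe_radius,
                grid_spacing=grid_spacing,
            )
        )
    if not tunnels:
        logger.info("no tunnel found: start region is enclosed at probe %.2f Å", probe_radius)
    return tunnels


# ---------------------------------------------------------------------------
# Choke-point diameters


def _residue_heavy(frame: StructureFrame, res: ResidueID, sidechain_only: bool = False):
    chain, seq, ins = _res_id(res)
    atoms = frame.residue_atoms(chain, seq, ins, heavy_only=True)
    if sidechain_only:
        atoms = [a for a in atoms if a.name not in {"N", "CA", "C", "O"}]
    if not atoms:
        raise KeyError(f"residue {res} missing or has no heavy atoms in frame {frame.frame_index}")
    return atoms

def bottleneck_diameter(
    frame: StructureFrame,
    pair: tuple[ResidueID, ResidueID],
    mode: Literal["closest-heavy-atom", "sidechain-centroid"] = "closest-heavy-atom",
) -> float:
    """Choke-point diameter (Å) between the two bottleneck residues.

    ``closest-heavy-atom`` (default): minimum over all heavy-atom pairs of
    center distance minus both vdW radii — i.e. the free gap between the two
    residues' surfaces.  ``sidechain-centroid``: center-to-center distance of
    the side-chain centroids (no radii subtracted).
    """
    a_atoms = _residue_heavy(frame, pair[0], sidechain_only=(mode == "sidechain-centroid"))
    b_atoms = _residue_heavy(frame, pair[1], sidechain_only=(mode == "sidechain-centroid"))
    if mode == "sidechain-centroid":
        ca = np.mean([a.position for a in a_atoms], axis=0)
        cb = np.mean([a.position for a in b_atoms], axis=0)
        return float(np.linalg.norm(ca - cb))
    if mode != "closest-heavy-atom":
        raise ValueError(f"unknown mode {mode!r}")
    pa = np.stack([a.position for a in a_atoms])
    pb = np.stack([a.position for a in b_atoms])
    ra = np.array([vdw_radius(a.element) for a in a_atoms])
    rb = np.array([vdw_radius(a.element) for a in b_atoms])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    gap = d - ra[:, None] - rb[None, :]
    return float(gap.min())


def diameter_series(
    ensemble: Ensemble,
    pair: tuple[ResidueID, ResidueID],
    mode: Literal["closest-heavy-atom", "sidechain-centroid"] = "closest-heavy-atom",
) -> BottleneckSeries:
    """Choke-point diameter tracked over every frame, in frame order."""
    vals = []
    for frame in ensemble:
        try:
            vals.append(bottleneck_diameter(frame, pair, mode))
        except KeyError as exc:
            raise KeyError(f"frame {frame.frame_index}: {exc}") from exc
    return BottleneckSeries(pair, tuple(vals), mode)


def classify_channel(series: BottleneckSeries, threshold: float = 4.0) -> ChannelStateReport:
    """Open/closed classification of a diameter series against a threshold."""
    if len(series) == 0:
        raise ValueError("empty diameter series")
    flags = tuple(bool(d >= threshold) for d in series.diameters)
    frac = float(np.mean(flags))
    return ChannelStateReport(
        threshold=float(threshold),
        open_flags=flags,
        open_fraction=frac,
        blocked_persistently=(frac == 0.0),
    )


# ---------------------------------------------------------------------------
# Salt bridges

_BASIC_N = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ACIDIC_O = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


def _side_atoms(frame, res, table, kind):
    chain, seq, ins = _res_id(res)
    atoms = frame.residue_atoms(chain, seq, ins, heavy_only=True)
    if not atoms:
        raise KeyError(f"residue {res} not found in frame {frame.frame_index}")
    res_name = atoms[0].res_name
    wanted = table.get(res_name)
    if wanted is None:
        raise ValueError(
            f"residue {res} ({res_name}) is not a {kind} residue with the "
            f"required side-chain atoms ({sorted(table)})"
        )
    found = [a for a in atoms if a.name in wanted]
    if not found:
        raise ValueError(
            f"residue {res} ({res_name}) lacks side-chain atoms {wanted}; "
            f"model may be truncated"
        )
    return found


def salt_bridge_present(
    frame: StructureFrame,
    basic_res: ResidueID,
    acidic_res: ResidueID,
    cutoff: float = 4.0,
) -> tuple[bool, float]:
    """Is a salt bridge formed between a basic and an acidic side chain?

    Returns ``(present, min_NO_distance)`` where the distance is the minimum
    over the basic residue's side-chain nitrogens and the acidic residue's
    carboxylate oxygens; present iff that distance ≤ *cutoff*.
    """
    ns = _side_atoms(frame, basic_res, _BASIC_N, "basic")
    os_ = _side_atoms(frame, acidic_res, _ACIDIC_O, "acidic")
    dmin = min(
        float(np.linalg.norm(n.position - o.position)) for n in ns for o in os_
    )
    return (dmin <= cutoff, dmin)


def salt_bridge_series(
    ensemble: Ensemble,
    basic_res: ResidueID,
    acidic_res: ResidueID,
    cutoff: float = 4.0,
) -> tuple[list[bool], float]:
    """Per-frame salt-bridge flags and the persistence fraction (mean)."""
    flags = [
        salt_bridge_present(f, basic_res, acidic_res, cutoff)[0] for f in ensemble
    ]
    return flags, float(np.mean(flags))


def centerline_to_pdb(tunnel: TunnelProfile) -> str:
    """Render a tunnel centerline as a PDB pseudo-atom trace (HETATM, element
    X replaced by C so viewers accept it; free radius stored in B-factor)."""
    lines = []
    for i, (p, r) in enumerate(zip(tunnel.centerline, tunnel.radius_at), start=1):
        lines.append(
            f"HETATM{i:5d}  C   TUN T{i:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{r:6.2f}           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
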