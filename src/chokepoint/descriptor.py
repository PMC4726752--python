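"""Reference-based active-site geometric descriptor and scoring function.

The idea: when no enzyme–substrate co-crystal exists for the protein of
interest, borrow the catalytically competent active-site geometry from a
well-characterised homolog (for Coq6p, the pHBH–FAD–4-hydroxybenzoate complex).
A small set of site atoms — hydrogen-bonding partners of the substrate plus
the reactive flavin C4X atom — defines all pairwise distances d_ij(reference).
Each conformation of a substrate-free ensemble is then scored by

    S = Σ_pairs |d_ij(frame) − d_ij(reference)|   (Å)

A low S means the frame's active site closely reproduces the substrate-bound
reference geometry, and — combined with an open access channel — marks the
frame as a good docking receptor.  Deviations are summed as absolute values by
default so that opposite-signed distortions cannot cancel; a signed mode is
available for comparison experiments.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .structio import AtomSpec, Ensemble, StructureFrame, measure_distance

logger = logging.getLogger(__name__)

__all__ = [
    "ActiveSiteDescriptor",
    "DescriptorScore",
    "FrameSelection",
    "build_descriptor",
    "score_ensemble",
    "score_frame",
    "select_frames",
]


@dataclass(frozen=True)
class ActiveSiteDescriptor:
    """All k·(k−1)/2 pairwise reference distances among k site atoms.

    Immutable; ``pairs`` are derived deterministically (index order of
    ``site_atoms``) and ``ref_distances`` are strictly positive.
    """

    site_atoms: tuple[AtomSpec, ...]
    pairs: tuple[tuple[int, int], ...]
    ref_distances: tuple[float, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.site_atoms) < 2:
            raise ValueError("descriptor needs at least 2 site atoms")
        if any(d <= 0 for d in self.ref_distances):
            raise ValueError("reference distances must be strictly positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference_id": self.reference_id,
                "site_atoms": [str(s) for s in self.site_atoms],
                "pairs": [list(p) for p in self.pairs],
                "ref_distances": list(self.ref_distances),
            },
            indent=2,
        )


@dataclass(frozen=True)
class DescriptorScore:
    frame_index: int
    S: float
    per_pair_deviation: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.S - sum(abs(d) for d in self.per_pair_deviation)) > 1e-9:
            # signed mode stores signed deviations; S is then the signed sum
            if abs(self.S - sum(self.per_pair_deviation)) > 1e-9:
                raise ValueError("S inconsistent with per-pair deviations")


@dataclass(frozen=True)
class FrameSelection:
    """Frames selected for docking, best (lowest S) first, plus the rule that
    produced them."""

    frame_indices: tuple[int, ...]
    min_diameter: float
    n_requested: int
    ordering: str = "ascending S"


def build_descriptor(
    reference: StructureFrame,
    site_atoms: Sequence[AtomSpec],
    reference_id: str = "reference",
) -> ActiveSiteDescriptor:
    """Measure all pairwise site-atom distances in *reference*.

    For the Coq6p use case the site atoms are the serine/threonine side-chain
    oxygen and two backbone carbonyl oxygens that hydrogen-bond the substrate,
    plus the flavin C4X atom (k = 4, 6 pairs).
    """
    specs = tuple(site_atoms)
    if len(set(specs)) != len(specs):
        raise ValueError("duplicate site-atom specs")
    for s in specs:
        reference.resolve(s)  # raises LookupError_ naming the spec
    pairs = tuple(combinations(range(len(specs)), 2))
    refs = tuple(
        measure_distance(reference, specs[i], specs[j]) for i, j in pairs
    )
    return ActiveSiteDescriptor(specs, pairs, refs, reference_id)


def _map_spec(spec: AtomSpec, mapping: Mapping[AtomSpec, AtomSpec] | None) -> AtomSpec:
    if mapping is None:
        return spec
    return mapping.get(spec, spec)


def score_frame(
    descriptor: ActiveSiteDescriptor,
    frame: StructureFrame,
    mapping: Mapping[AtomSpec, AtomSpec] | None = None,
    signed: bool = False,
) -> DescriptorScore:
    """Score one frame against the descriptor.

    *mapping* translates reference-numbering site atoms into the frame's
    numbering (e.g. pHBH S212:OG → Coq6p T261:OG1); identity if ``None``.
    S is rigid-motion invariant since only internal distances enter.
    """
    specs = [_map_spec(s, mapping) for s in descriptor.site_atoms]
    pos = np.stack([frame.resolve(s).position for s in specs])
    devs = []
    for (i, j), ref in zip(descriptor.pairs, descriptor.ref_distances):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        devs.append((d - ref) if signed else abs(d - ref))
    S = float(sum(devs))
    return DescriptorScore(frame.frame_index, S, tuple(devs))


def score_ensemble(
    descriptor: ActiveSiteDescriptor,
    ensemble: Ensemble,
    mapping: Mapping[AtomSpec, AtomSpec] | None = None,
    signed: bool = False,
) -> list[DescriptorScore]:
    """Score every frame of the ensemble, preserving frame order."""
    out = []
    for frame in ensemble:
        try:
            out.append(score_frame(descriptor, frame, mapping, signed))
        except KeyError as exc:
            raise KeyError(f"frame {frame.frame_index}: {exc}") from exc
    return out


def select_frames(
    scores: Sequence[DescriptorScore],
    diameters: Sequence[float],
    min_diameter: float = 4.0,
    n: int = 1,
) -> FrameSelection:
    """Pick docking receptor frames: channel open enough, active site closest
    to the reference geometry.

    Frames whose choke-point diameter is below *min_diameter* are excluded;
    the survivors are ranked by ascending S (ties broken by lower frame
    index) and the top *n* returned.  Fewer eligible frames than requested is
    reported with a warning, not an error.
    """
    if len(scores) != len(diameters):
        raise ValueError(
            f"scores cover {len(scores)} frames but diameters cover {len(diameters)}"
        )
    eligible = [
        (s.S, s.frame_index)
        for s, d in zip(scores, diameters)
        if d >= min_diameter
    ]
    eligible.sort()
    chosen = tuple(idx for _, idx in eligible[:n])
    if not eligible:
        warnings.warn(
            f"no frame has choke-point diameter >= {min_diameter} Å; empty selection"
        )
    elif len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} frames eligible (requested {n}); returning all"
        )
    return FrameSelection(chosen, float(min_diameter), int(n))


def scores_to_tsv(scores: Sequence[DescriptorScore]) -> str:
    """TSV rendering: frame, S, per-pair deviations."""
    lines = ["frame\tS\tper_pair_deviations"]
    for s in scores:
        devs = ",".join(f"{d:.6f}" for d in s.per_pair_deviation)
        lines.append(f"{s.frame_index}\t{s.S:.6f}\t{devs}")
    return "\n".join(lines) + "\n"
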