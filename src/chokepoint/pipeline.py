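"""End-to-end workflow: score every frame, track choke-point diameters,
classify open/closed and salt-bridge state, select docking receptor frames,
and write machine-readable reports.

The run is driven by a single JSON config document; the effective
configuration is echoed into every output for provenance, and reruns with
identical config and inputs reproduce all numeric columns exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .channels import (
    BottleneckSeries,
    classify_channel,
    diameter_series,
    salt_bridge_series,
)
from .descriptor import build_descriptor, score_ensemble, select_frames
from .structio import AtomSpec, Ensemble, read_structure, write_structure

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "parse_atom_spec", "parse_residue", "run_analysis"]


def parse_atom_spec(text: str) -> AtomSpec:
    """Parse ``"A:212:OG"`` (chain:resseq[ins]:atom_name) into an AtomSpec."""
    parts = text.split(":")
    if len(parts) != 3:
        raise ValueError(f"bad atom spec {text!r}; expected chain:resseq:name")
    chain, res, name = parts
    ins = ""
    if res and not res[-1].isdigit():
        res, ins = res[:-1], res[-1]
    return AtomSpec(chain, int(res), name, ins)


def parse_residue(text: str) -> tuple:
    """Parse ``"A:248"`` into a residue identifier tuple."""
    chain, _, res = text.partition(":")
    if not res:
        raise ValueError(f"bad residue {text!r}; expected chain:resseq")
    if res[-1].isdigit():
        return (chain, int(res))
    return (chain, int(res[:-1]), res[-1])


@dataclass
class RunConfig:
    """Everything one analysis run needs; serializable to/from JSON."""

    ensemble_path: str
    reference_path: str
    site_atoms: list[str]                   # reference-frame atom specs
    site_mapping: dict[str, str] = field(default_factory=dict)  # ref spec -> ensemble spec
    choke_pairs: list[list[str]] = field(default_factory=list)  # [["A:248","A:382"], ...]
    salt_bridge_pair: list[str] | None = None  # [basic, acidic]
    open_threshold: float = 4.0
    min_diameter: float = 4.0
    selection_n: int = 5
    probe_radius: float = 1.4
    shell_radius: float = 6.0
    shell_depth: float = 6.0
    grid_spacing: float = 0.5
    output_dir: str = "chokepoint_run"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)

    def validate(self) -> list[str]:
        """Collect every problem, not just the first."""
        problems = []
        for label, p in (("ensemble", self.ensemble_path), ("reference", self.reference_path)):
            if not Path(p).is_file():
                problems.append(f"{label} file not found: {p}")
        if len(self.site_atoms) < 2:
            problems.append("need at least 2 site atoms for a descriptor")
        for s in list(self.site_atoms) + list(self.site_mapping.values()):
            try:
                parse_atom_spec(s)
            except ValueError as exc:
                problems.append(str(exc))
        if not self.choke_pairs:
            problems.append("need at least one choke residue pair")
        for pair in self.choke_pairs:
            if len(pair) != 2:
                problems.append(f"choke pair must have 2 residues: {pair}")
        if self.selection_n < 1:
            problems.append("selection_n must be >= 1")
        for name in ("probe_radius", "shell_radius", "shell_depth", "grid_spacing"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        return problems


@dataclass
class RunReport:
    config: dict
    version: str
    n_frames: int
    scores: list[float]
    diameters: dict[str, list[float]]       # pair label -> per-frame series
    failed_pairs: dict[str, str]
    open_flags: dict[str, list[bool]]
    open_fraction: dict[str, float]
    blocked_persistently: dict[str, bool]
    salt_bridge_flags: list[bool] | None
    salt_bridge_persistence: float | None
    selected_frames: list[int]
    wall_time_s: float

    def frame_table_tsv(self) -> str:
        pair_labels = list(self.diameters)
        header = ["frame", "S"] + [f"diam[{p}]" for p in pair_labels] + [
            f"open[{p}]" for p in pair_labels
        ]
        if self.salt_bridge_flags is not None:
            header.append("salt_bridge")
        lines = ["\t".join(header)]
        for i in range(self.n_frames):
            row = [str(i), f"{self.scores[i]:.6f}"]
            row += [f"{self.diameters[p][i]:.6f}" for p in pair_labels]
            row += [str(int(self.open_flags[p][i])) for p in pair_labels]
            if self.salt_bridge_flags is not None:
                row.append(str(int(self.salt_bridge_flags[i])))
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def summary_json(self) -> str:
        doc = asdict(self)
        doc.pop("wall_time_s")  # timestamps/durations excluded for determinism
        return json.dumps(doc, indent=2, default=str)


def run_analysis(config: RunConfig) -> RunReport:
    """Execute the full workflow and write reports under ``config.output_dir``.

    Stage order: load → descriptor scoring → choke-pair diameter tracking →
    open/closed classification → optional salt-bridge tracking → frame
    selection → report.  A failure in one choke pair is recorded and does not
    abort the others.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("loading ensemble %s", config.ensemble_path)
    ensemble = read_structure(config.ensemble_path)
    reference = read_structure(config.reference_path)[0]

    logger.info("scoring %d frames", len(ensemble))
    site = [parse_atom_spec(s) for s in config.site_atoms]
    mapping = {
        parse_atom_spec(k): parse_atom_spec(v) for k, v in config.site_mapping.items()
    } or None
    desc = build_descriptor(reference, site, reference_id=config.reference_path)
    scores = score_ensemble(desc, ensemble, mapping)

    diameters: dict[str, list[float]] = {}
    failed: dict[str, str] = {}
    open_flags: dict[str, list[bool]] = {}
    open_fraction: dict[str, float] = {}
    blocked: dict[str, bool] = {}
    series_by_label: dict[str, BottleneckSeries] = {}
    for pair in config.choke_pairs:
        label = f"{pair[0]}-{pair[1]}"
        try:
            series = diameter_series(
                ensemble, (parse_residue(pair[0]), parse_residue(pair[1]))
            )
        except (KeyError, ValueError) as exc:
            logger.error("choke pair %s failed: %s (continuing)", label, exc)
            failed[label] = str(exc)
            continue
        series_by_label[label] = series
        report = classify_channel(series, config.open_threshold)
        diameters[label] = list(series.diameters)
        open_flags[label] = list(report.open_flags)
        open_fraction[label] = report.open_fraction
        blocked[label] = report.blocked_persistently

    sb_flags = sb_persist = None
    if config.salt_bridge_pair:
        basic, acidic = (parse_residue(r) for r in config.salt_bridge_pair)
        flags, persist = salt_bridge_series(ensemble, basic, acidic)
        sb_flags, sb_persist = list(flags), persist

    if series_by_label:
        first_label = next(iter(series_by_label))
        selection = select_frames(
            scores,
            series_by_label[first_label].diameters,
            min_diameter=config.min_diameter,
            n=config.selection_n,
        )
        selected = list(selection.frame_indices)
    else:
        logger.warning("all choke pairs failed; selecting on score alone is refused")
        selected = []

    report = RunReport(
        config=asdict(config),
        version=__version__,
        n_frames=len(ensemble),
        scores=[s.S for s in scores],
        diameters=diameters,
        failed_pairs=failed,
        open_flags=open_flags,
        open_fraction=open_fraction,
        blocked_persistently=blocked,
        salt_bridge_flags=sb_flags,
        salt_bridge_persistence=sb_persist,
        selected_frames=selected,
        wall_time_s=time.monotonic() - t0,
    )

    (out / "frames.tsv").write_text(report.frame_table_tsv())
    (out / "summary.json").write_text(report.summary_json())
    (out / "descriptor.json").write_text(desc.to_json())
    if selected:
        write_structure(
            Ensemble([ensemble[i].with_coords(ensemble[i].coords, j)
                      for j, i in enumerate(selected)]),
            out / "selected.pdb",
        )
        logger.info("wrote %d selected frames for docking", len(selected))
    return report
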