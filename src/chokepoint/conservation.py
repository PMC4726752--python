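"""Sequence conservation and cross-homolog residue mapping.

Three jobs, all feeding structure-level interpretation:

* per-column conservation of a multiple sequence alignment, scored as
  normalized Shannon entropy, ``score = 1 − H/log(20)`` with gaps excluded
  from the frequencies — a deliberately simple, dependency-free stand-in for
  tree-aware evolutionary-rate methods (ConSurf-style), adequate for ranking
  columns as conserved/variable;
* pairwise global alignment (affine gaps, BLOSUM62 by default) producing a
  :class:`ResidueMap` between two homologs, used to transfer residue numbers
  (e.g. a disease mutation reported in the human enzyme onto the yeast
  numbering) and to pair residues for cross-protein superposition;
* projection of per-column scores onto a structure's B-factor column so any
  molecular viewer can color by conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import StructureFrame

logger = logging.getLogger(__name__)

__all__ = [
    "MSA",
    "ConservationProfile",
    "ResidueMap",
    "align_pair",
    "column_conservation",
    "map_residue",
    "project_profile",
    "read_msa",
    "write_msa",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(_AA) | {"-", "X"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class MSA:
    """Aligned sequences: parallel ``ids`` and ``rows`` (all of length L)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA has no sequences")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"record {rid!r} has length {len(row)}, expected {L} (ragged MSA)"
                )
            bad = set(row) - _ALPHABET
            if bad:
                raise ValueError(f"record {rid!r} contains invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in MSA") from None


def read_msa(path, fmt: str = "fasta") -> MSA:
    """Read an aligned FASTA file; lowercase residues are uppercased (logged)."""
    if fmt != "fasta":
        raise ValueError(f"unsupported MSA format {fmt!r}")
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if s != s.upper():
            logger.info("record %r: lowercase residues uppercased", rec.id)
            s = s.upper()
        ids.append(rec.id)
        rows.append(s)
    if not ids:
        raise ValueError(f"{path}: no FASTA records found")
    return MSA(tuple(ids), tuple(rows))


def write_msa(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation in [0, 1]; NaN for all-gap columns.

    ``unreliable`` flags columns whose gap fraction exceeds 0.5.
    """

    scores: np.ndarray
    gap_fraction: np.ndarray
    method: str = "normalized-entropy"

    @property
    def unreliable(self) -> np.ndarray:
        return self.gap_fraction > 0.5

    def to_tsv(self) -> str:
        lines = ["column\tscore\tgap_fraction\tunreliable"]
        for i, (s, g) in enumerate(zip(self.scores, self.gap_fraction), start=1):
            sv = "NA" if np.isnan(s) else f"{s:.6f}"
            lines.append(f"{i}\t{sv}\t{g:.6f}\t{int(g > 0.5)}")
        return "\n".join(lines) + "\n"


def column_conservation(msa: MSA, method: str = "normalized-entropy") -> ConservationProfile:
    """Score every column as ``1 − H/log(20)``.

    H is the Shannon entropy (natural log) of the amino-acid frequencies in
    the column, gaps and 'X' excluded.  A monomorphic column scores 1, a
    column with 20 equifrequent residues scores 0, an all-gap column is NaN.
    """
    if method != "normalized-entropy":
        raise ValueError(f"unknown conservation method {method!r}")
    L = msa.length
    n = len(msa.rows)
    scores = np.empty(L)
    gapf = np.empty(L)
    aa_index = {a: i for i, a in enumerate(_AA)}
    for c in range(L):
        counts = np.zeros(20)
        gaps = 0
        for row in msa.rows:
            ch = row[c]
            if ch == "-":
                gaps += 1
            elif ch in aa_index:
                counts[aa_index[ch]] += 1
        gapf[c] = gaps / n
        total = counts.sum()
        if total == 0:
            scores[c] = np.nan
            continue
        p = counts[counts > 0] / total
        H = float(-(p * np.log(p)).sum())
        scores[c] = 1.0 - H / np.log(20.0)
    unreliable = int((gapf > 0.5).sum())
    if unreliable:
        logger.warning("%d columns have gap fraction > 0.5 (flagged unreliable)", unreliable)
    return ConservationProfile(scores, gapf)


# ---------------------------------------------------------------------------
# Pairwise alignment / residue mapping


@dataclass(frozen=True)
class ResidueMap:
    """Aligned-position correspondence between two ungapped sequences.

    ``pairs`` are 1-based (position in A, position in B), strictly increasing
    in both coordinates; only match/mismatch columns produce pairs.  Gap
    parameters are recorded for provenance: a gap of length L costs
    ``gap_open + (L − 1)·gap_extend``.
    """

    pairs: tuple[tuple[int, int], ...]
    score: float
    len_a: int
    len_b: int
    gap_open: float
    gap_extend: float
    substitution: str

    def __post_init__(self) -> None:
        prev = (0, 0)
        for a, b in self.pairs:
            if not (a > prev[0] and b > prev[1]):
                raise ValueError("residue map must be strictly increasing")
            prev = (a, b)

    def forward(self) -> dict[int, int]:
        return {a: b for a, b in self.pairs}

    def backward(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs}


def align_pair(
    seq_a: str,
    seq_b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match_score: float | None = None,
    mismatch_score: float | None = None,
) -> ResidueMap:
    """Optimal global alignment of two ungapped sequences with affine gaps.

    Pass ``match_score``/``mismatch_score`` to use a simple scoring scheme
    instead of a substitution matrix.  Gap penalties are given as positive
    costs.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    for name, s in (("A", seq_a), ("B", seq_b)):
        bad = set(s) - (set(_AA) | {"X"})
        if bad:
            raise ValueError(f"sequence {name} contains invalid symbols {sorted(bad)}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if match_score is not None:
        aligner.match_score = float(match_score)
        aligner.mismatch_score = float(mismatch_score if mismatch_score is not None else 0.0)
        sub_name = f"match/mismatch {aligner.match_score:g}/{aligner.mismatch_score:g}"
    else:
        aligner.substitution_matrix = substitution_matrices.load(substitution)
        sub_name = substitution
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)

    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    pairs = []
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for off in range(a1 - a0):
            pairs.append((int(a0 + off + 1), int(b0 + off + 1)))
    return ResidueMap(
        pairs=tuple(pairs),
        score=float(aln.score),
        len_a=len(seq_a),
        len_b=len(seq_b),
        gap_open=float(gap_open),
        gap_extend=float(gap_extend),
        substitution=sub_name,
    )


def map_residue(residue_map: ResidueMap, pos_a: int) -> int | None:
    """Partner position in sequence B of position *pos_a* in sequence A, or
    ``None`` if the position sits opposite a gap."""
    if not (1 <= pos_a <= residue_map.len_a):
        raise IndexError(
            f"position {pos_a} out of range 1..{residue_map.len_a} for sequence A"
        )
    return residue_map.forward().get(pos_a)


# ---------------------------------------------------------------------------
# Projection onto structure


SENTINEL_B_FACTOR = -1.0


def project_profile(
    profile: ConservationProfile,
    msa: MSA,
    target_id: str,
    frame: StructureFrame,
    chain: str,
) -> tuple[StructureFrame, list[int]]:
    """Write per-residue conservation scores into the B-factor column.

    The target sequence's ungapped positions are matched 1:1, in order, to
    the residues of *chain* in file order.  Residues beyond the target length
    (or in all-gap columns) get the sentinel B-factor −1 and are returned in
    the unmapped list.  Residue-type mismatches between structure and
    sequence are logged, not fatal.
    """
    row = msa.row(target_id)
    # ungapped position (1-based) -> alignment column (0-based)
    pos_to_col = {}
    p = 0
    for col, ch in enumerate(row):
        if ch != "-":
            p += 1
            pos_to_col[p] = col

    residues: list[tuple[str, int, str]] = []
    seen = set()
    for a in frame.atoms:
        if a.chain != chain:
            continue
        key = (a.chain, a.res_seq, a.insertion)
        if key not in seen:
            seen.add(key)
            residues.append(key)

    b = np.array([a.b_factor for a in frame.atoms])
    unmapped: list[int] = []
    for i, (ch, seq_num, ins) in enumerate(residues, start=1):
        col = pos_to_col.get(i)
        score = profile.scores[col] if col is not None else np.nan
        if col is None or np.isnan(score):
            score = SENTINEL_B_FACTOR
            unmapped.append(seq_num)
        else:
            res_atoms = frame.residue_atoms(ch, seq_num, ins, heavy_only=False)
            one = _THREE_TO_ONE.get(res_atoms[0].res_name)
            if one is not None and one != row[col] != "X":
                logger.warning(
                    "residue %s%d is %s in structure but %s in sequence %r",
                    ch, seq_num, one, row[col], target_id,
                )
        for j, a in enumerate(frame.atoms):
            if a.chain == ch and a.res_seq == seq_num and a.insertion == ins:
                b[j] = score
    if unmapped:
        logger.warning("%d residues unmapped; sentinel B-factor %.1f used",
                       len(unmapped), SENTINEL_B_FACTOR)
    return frame.with_b_factors(b), unmapped
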