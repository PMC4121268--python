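"""Variability-hotspot detection and substitution localization.

Between-taxon 18S variation concentrates in a contiguous hypervariable
stretch of the V4/V9 regions, while technical errors scatter uniformly.
Given a reference alignment spanning the taxon's clades, this module scores
per-column variability, delimits the hotspot interval(s), and classifies
each substitution a minor variant carries relative to the cell's dominant
sequence as falling inside or outside the hotspot.  Substitutions outside
(in otherwise conserved columns) are suspect artifacts.

Coordinates are 0-based, half-open, in reference-alignment column space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .align import global_identity, identity
from .model import Amplicon, SampleSet

__all__ = [
    "ReferenceAlignment",
    "SubstitutionCall",
    "HotspotAnnotation",
    "column_variability",
    "find_hotspots",
    "classify_substitutions",
]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceAlignment:
    """An equal-length gapped reference alignment (>= 2 sequences)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("a reference alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceAlignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls([rec.id for rec in aln], [str(rec.seq).upper() for rec in aln])


def column_variability(ra: ReferenceAlignment, metric: str = "modal") -> np.ndarray:
    """Per-column variability scores in [0, 1].

    ``modal`` (default): 1 minus the frequency of the modal non-gap residue
    among non-gap entries — simple and monotone in diversity.  ``entropy``:
    Shannon entropy of the non-gap residues, normalized by log2(4).
    All-gap columns score 0 under both metrics.
    """
    if metric not in ("modal", "entropy"):
        raise ValueError(f"unknown variability metric {metric!r}")
    scores = np.zeros(ra.n_columns)
    for c in range(ra.n_columns):
        residues = [row[c] for row in ra.rows if row[c] != "-"]
        if not residues:
            continue
        counts = [residues.count(b) for b in set(residues)]
        n = len(residues)
        if metric == "modal":
            scores[c] = 1.0 - max(counts) / n
        else:
            scores[c] = -sum((k / n) * math.log2(k / n) for k in counts) / 2.0
    return scores


def find_hotspots(
    scores: np.ndarray,
    min_score: float = 0.3,
    min_run: int = 10,
    max_gap: int = 2,
) -> list[tuple[int, int]]:
    """Maximal high-variability runs as half-open column intervals.

    A run is a stretch of columns scoring >= ``min_score`` in which at most
    ``max_gap`` consecutive columns fall below the threshold; runs shorter
    than ``min_run`` columns are dropped.  Runs start and end on
    above-threshold columns, so appending all-gap (score 0) columns can
    never change the result.
    """
    above = np.flatnonzero(np.asarray(scores) >= min_score)
    if above.size == 0:
        return []
    intervals: list[tuple[int, int]] = []
    start = prev = int(above[0])
    for c in above[1:]:
        c = int(c)
        if c - prev - 1 <= max_gap:
            prev = c
        else:
            intervals.append((start, prev + 1))
            start = prev = c
    intervals.append((start, prev + 1))
    return [(s, e) for s, e in intervals if e - s >= min_run]


@dataclass(frozen=True)
class SubstitutionCall:
    """One classified difference of a minor variant vs the dominant."""

    variant_id: str
    column: int  # reference-alignment column
    kind: str  # "sub" | "indel"
    base: str  # variant base ("-" for deletions)
    inside: bool


@dataclass
class HotspotAnnotation:
    """Hotspot intervals plus per-substitution inside/outside calls."""

    scores: np.ndarray
    intervals: list[tuple[int, int]]
    calls: list[SubstitutionCall]
    excluded: list[str]

    @property
    def n_inside(self) -> int:
        return sum(c.inside for c in self.calls)

    @property
    def n_outside(self) -> int:
        return len(self.calls) - self.n_inside

    @property
    def fraction_outside(self) -> float:
        return self.n_outside / len(self.calls) if self.calls else 0.0


def _inside(col: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= col < e for s, e in intervals)


def _column_map_to_alignment(dominant: str, ra: ReferenceAlignment) -> list[int]:
    """Map each dominant-sequence position to a reference-alignment column.

    The dominant is globally aligned to its highest-identity reference;
    positions inserted relative to that reference inherit the column of the
    left-flanking aligned base.
    """
    best_row, best_ident = None, -1.0
    for row in sorted(ra.rows):
        ref = row.replace("-", "")
        if not ref:
            continue
        ident = identity(dominant, ref)
        if ident > best_ident:
            best_row, best_ident = row, ident
    ref_pos_to_col = [c for c, ch in enumerate(best_row) if ch != "-"]
    ref = best_row.replace("-", "")
    aln = global_identity(dominant, ref)
    colmap: list[int] = []
    i = j = 0
    last_col = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            last_col = ref_pos_to_col[j]
            colmap.append(last_col)
            i += 1
            j += 1
        elif ca != "-":  # insertion in dominant: left-flank column
            colmap.append(last_col)
            i += 1
        else:
            last_col = ref_pos_to_col[j]
            j += 1
    return colmap


def classify_substitutions(
    minor: SampleSet,
    dominant: Amplicon,
    ra: ReferenceAlignment,
    intervals: list[tuple[int, int]],
    min_identity: float = 0.7,
) -> HotspotAnnotation:
    """Label every minor-variant difference inside/outside the hotspot.

    Each minor variant is aligned to the dominant sequence; substitutions map
    through the dominant-to-alignment column map, indels are classified by
    the column of their left-flanking dominant base.  Variants below
    ``min_identity`` to the dominant are excluded with a warning.
    """
    colmap = _column_map_to_alignment(dominant.seq, ra)
    calls: list[SubstitutionCall] = []
    excluded: list[str] = []
    for v in minor.amplicons:
        if v.seq == dominant.seq:
            continue
        if identity(v.seq, dominant.seq) < min_identity:
            logger.warning("variant %s below %.0f%% identity to dominant; excluded",
                           v.id, 100 * min_identity)
            excluded.append(v.id)
            continue
        aln = global_identity(v.seq, dominant.seq)
        dpos = 0
        for cv, cd in zip(aln.aligned_a, aln.aligned_b):
            if cv != "-" and cd != "-":
                if cv != cd:
                    col = colmap[dpos]
                    calls.append(SubstitutionCall(v.id, col, "sub", cv, _inside(col, intervals)))
                dpos += 1
            elif cd != "-":  # deletion in variant
                col = colmap[dpos]
                calls.append(SubstitutionCall(v.id, col, "indel", "-", _inside(col, intervals)))
                dpos += 1
            else:  # insertion in variant: left-flanking dominant base
                col = colmap[max(dpos - 1, 0)]
                calls.append(SubstitutionCall(v.id, col, "indel", cv, _inside(col, intervals)))
    scores = column_variability(ra)
    return HotspotAnnotation(scores, intervals, calls, excluded)
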