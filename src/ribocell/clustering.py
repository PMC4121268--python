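"""Greedy abundance-ordered OTU clustering and identity-threshold sweeps.

Mirrors the classic greedy centroid algorithm: amplicons are processed in
decreasing abundance (ties broken lexicographically by sequence) and each
joins the FIRST existing centroid, in centroid creation order, whose pairwise
identity reaches the threshold; otherwise it founds a new OTU.  "First hit"
rather than "best hit" joining is deliberate and documented so clusterings
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import identity
from .model import Amplicon, SampleSet

__all__ = [
    "OTU",
    "SweepResult",
    "greedy_cluster",
    "sweep",
    "default_threshold_grid",
    "dominant_otu_fraction",
    "assign_best_hit",
]

#: tolerance for identity-vs-threshold comparisons (identity is an exact
#: rational matches/columns rendered as a float)
_EPS = 1e-9


@dataclass
class OTU:
    """A cluster of amplicons around its most abundant member."""

    centroid: Amplicon
    members: list[Amplicon] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(m.abundance for m in self.members)


def greedy_cluster(s: SampleSet, threshold: float) -> list[OTU]:
    """Cluster a dereplicated set at one identity threshold.

    Returns OTUs sorted by decreasing size (ties keep creation order).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not s.is_dereplicated:
        raise ValueError("greedy_cluster requires a dereplicated set")
    otus: list[OTU] = []
    for amp in sorted(s.amplicons, key=lambda a: (-a.abundance, a.seq)):
        for otu in otus:
            if identity(amp.seq, otu.centroid.seq) + _EPS >= threshold:
                otu.members.append(amp)
                break
        else:
            otus.append(OTU(centroid=amp, members=[amp]))
    otus.sort(key=lambda o: -o.size)
    return otus


def default_threshold_grid() -> list[float]:
    """The default sweep grid: 80% to 99% identity in 1% steps, descending."""
    return [round(0.99 - 0.01 * k, 2) for k in range(20)]


@dataclass
class SweepResult:
    """OTU clusterings of one set across a descending grid of thresholds."""

    otus: dict[float, list[OTU]]

    @property
    def thresholds(self) -> list[float]:
        return sorted(self.otus, reverse=True)

    def counts(self) -> dict[float, int]:
        return {t: len(self.otus[t]) for t in self.thresholds}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.thresholds:
            for rank, otu in enumerate(self.otus[t], 1):
                rows.append(
                    {
                        "threshold": t,
                        "otu_rank": rank,
                        "centroid_id": otu.centroid.id,
                        "size": otu.size,
                        "n_members": len(otu.members),
                    }
                )
        return pd.DataFrame(rows, columns=["threshold", "otu_rank", "centroid_id", "size", "n_members"])


def sweep(s: SampleSet, thresholds: list[float] | None = None) -> SweepResult:
    """Cluster independently at each threshold (default grid 0.80-0.99)."""
    if thresholds is None:
        thresholds = default_threshold_grid()
    if any(not 0.0 < t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    return SweepResult({t: greedy_cluster(s, t) for t in thresholds})


def dominant_otu_fraction(otus: list[OTU]) -> float:
    """Fraction of total abundance held by the largest OTU."""
    if not otus:
        raise ValueError("dominant_otu_fraction of an empty clustering")
    sizes = [o.size for o in otus]
    return max(sizes) / sum(sizes)


def assign_best_hit(q: Amplicon, refs: SampleSet) -> tuple[str, float]:
    """Naive closest-reference assignment by exhaustive global identity.

    Ties are broken by lexicographically smaller reference id.
    """
    if not refs.amplicons:
        raise ValueError("assign_best_hit requires a non-empty reference set")
    best_id, best_ident = None, -1.0
    for ref in sorted(refs.amplicons, key=lambda r: r.id):
        ident = identity(q.seq, ref.seq)
        if ident > best_ident + _EPS:
            best_id, best_ident = ref.id, ident
    return best_id, best_ident
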