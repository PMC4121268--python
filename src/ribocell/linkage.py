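"""The linkage method: per-read SNP combinations and redundancy filtering.

Each read is compared to a per-cell majority consensus; the exact combination
of SNPs it carries (its "pattern") is the unit of analysis.  True ribotypes
produce the same multi-site pattern over and over, whereas random PCR and
sequencing errors almost never recur as identical multi-site combinations,
so patterns observed without redundancy (support below ``min_support``) are
discarded.  Sliding windows along the sequence annotate where a pattern's
sites fall; under the default full-site-set matching the windows are
reporting granularity only and never split a pattern (this avoids assembling
chimeric patterns from fragments of different reads; per-window fragment
matching is available behind a flag for comparison).

Column coordinates are defined by the cell's most abundant read (the
anchor).  Reads whose alignment to the anchor contains indels have ambiguous
column coordinates and are excluded from pattern grouping but counted
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import global_identity
from .model import SampleSet

__all__ = [
    "ConsensusProfile",
    "SnpCalls",
    "VariantPattern",
    "PatternReport",
    "build_consensus",
    "call_snps",
    "window_patterns",
    "filter_patterns",
    "pattern_overlap",
]

_BASE_ORDER = "ACGT"  # tie-break order for consensus columns


@dataclass
class ConsensusProfile:
    """Per-column base counts and the majority consensus of one cell."""

    consensus: str
    counts: np.ndarray  # (length, 4) abundance-weighted counts over A,C,G,T
    anchor: str
    anchored: dict[str, str | None] = field(default_factory=dict)
    """Column-anchored sequence per read id; None marks indel-bearing reads."""


def _anchor_read(seq: str, anchor: str) -> str | None:
    """Column-anchored copy of ``seq``, or None if gaps are required."""
    if seq == anchor:
        return seq
    if len(seq) == len(anchor):
        # same length: the optimal alignment is gapless unless compensating
        # indels pay off; verify with a full alignment
        aln = global_identity(seq, anchor)
        return seq if "-" not in aln.aligned_a and "-" not in aln.aligned_b else None
    return None


def build_consensus(s: SampleSet) -> ConsensusProfile:
    """Abundance-weighted column-majority consensus of a dereplicated set.

    The most abundant read (ties: lexicographically smaller sequence) is the
    anchor defining column coordinates; ties between bases in a column are
    broken in the order A < C < G < T.
    """
    if not s.amplicons:
        raise ValueError("build_consensus requires a non-empty set")
    if not s.is_dereplicated:
        raise ValueError("build_consensus requires a dereplicated set")
    anchor = min(s.amplicons, key=lambda a: (-a.abundance, a.seq)).seq
    L = len(anchor)
    counts = np.zeros((L, 4), dtype=np.int64)
    anchored: dict[str, str | None] = {}
    for a in s.amplicons:
        row = _anchor_read(a.seq, anchor)
        anchored[a.id] = row
        if row is None:
            continue
        idx = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        for b, code in enumerate(b"ACGT"):
            counts[idx == code, b] += a.abundance
    consensus = "".join(_BASE_ORDER[int(np.argmax(counts[c]))] for c in range(L))
    return ConsensusProfile(consensus, counts, anchor, anchored)


@dataclass
class SnpCalls:
    """Per-read deviations from the consensus, in anchor coordinates."""

    sites: dict[str, tuple[tuple[int, str], ...]]
    """read id -> ordered (column, base) substitutions vs the consensus."""
    indel_reads: set[str]
    """reads excluded from pattern grouping (indels vs the anchor)."""
    anchor: str


def call_snps(s: SampleSet, c: ConsensusProfile) -> SnpCalls:
    """List each read's (column, base) deviations from the consensus."""
    sites: dict[str, tuple[tuple[int, str], ...]] = {}
    indel_reads: set[str] = set()
    cons = c.consensus
    for a in s.amplicons:
        row = c.anchored.get(a.id, None) if a.id in c.anchored else _anchor_read(a.seq, c.anchor)
        if row is None:
            indel_reads.add(a.id)
            continue
        sites[a.id] = tuple(
            (col, row[col]) for col in range(len(cons)) if row[col] != cons[col]
        )
    return SnpCalls(sites, indel_reads, c.anchor)


@dataclass(frozen=True)
class VariantPattern:
    """A group of reads sharing exactly one SNP-combination signature."""

    sites: tuple[tuple[int, str], ...]
    read_ids: tuple[str, ...]
    window_hits: tuple[int, ...]
    support: int

    @property
    def is_consensus(self) -> bool:
        return not self.sites


def _window_starts(window: int, step: int, length: int) -> list[int]:
    starts = []
    s = 0
    while True:
        starts.append(s)
        if s + window >= length:
            break
        s += step
    return starts


def window_patterns(
    calls: SnpCalls,
    s: SampleSet,
    window: int = 50,
    step: int = 25,
    length: int | None = None,
    fragment_by_window: bool = False,
) -> list[VariantPattern]:
    """Group reads by exact site-set equality; annotate window hits.

    Windows of ``window`` columns tile ``[0, length)`` at ``step`` (the last
    window is truncated at the sequence end).  Support is the abundance sum
    of the reads sharing the site set; the empty site set is the consensus
    pattern.  Patterns are returned sorted by decreasing support.

    With ``fragment_by_window=True`` reads are instead grouped window by
    window on the subset of their sites falling in each window (one pattern
    per (window, fragment) pair, the comparison variant of the method); the
    default full-set grouping never splits a read's signature.
    """
    if not (1 <= step <= window):
        raise ValueError("window >= step >= 1 required")
    if length is None:
        length = len(calls.anchor)
    if window > length:
        raise ValueError("window longer than the anchored sequence")
    starts = _window_starts(window, step, length)
    abundance = {a.id: a.abundance for a in s.amplicons}
    if fragment_by_window:
        frag_groups: dict[tuple[int, tuple[tuple[int, str], ...]], list[str]] = {}
        for rid, sites in calls.sites.items():
            for w, st in enumerate(starts):
                sub = tuple(x for x in sites if st <= x[0] < min(st + window, length))
                if sub:
                    frag_groups.setdefault((w, sub), []).append(rid)
        out = [
            VariantPattern(
                sites=sub,
                read_ids=tuple(sorted(rids)),
                window_hits=(w,),
                support=sum(abundance.get(r, 1) for r in rids),
            )
            for (w, sub), rids in frag_groups.items()
        ]
        out.sort(key=lambda p: (-p.support, p.window_hits, p.sites))
        return out
    groups: dict[tuple[tuple[int, str], ...], list[str]] = {}
    for rid, sites in calls.sites.items():
        groups.setdefault(sites, []).append(rid)
    patterns = []
    for sites, rids in groups.items():
        hits = tuple(
            w for w, st in enumerate(starts)
            if any(st <= col < min(st + window, length) for col, _ in sites)
        )
        patterns.append(
            VariantPattern(
                sites=sites,
                read_ids=tuple(sorted(rids)),
                window_hits=hits,
                support=sum(abundance.get(r, 1) for r in rids),
            )
        )
    patterns.sort(key=lambda p: (-p.support, p.sites))
    return patterns


@dataclass
class PatternReport:
    """Retained amplicon patterns of one cell plus discard accounting."""

    retained: list[VariantPattern]
    n_discarded: int
    discarded_support: int
    anchor: str
    min_support: int

    @property
    def n_patterns(self) -> int:
        """The cell's "amplicon pattern" count."""
        return len(self.retained)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("pattern_id\tn_sites\tsites\tsupport\twindow_hits\n")
            for k, p in enumerate(self.retained):
                sites = ",".join(f"{c}:{b}" for c, b in p.sites) or "consensus"
                hits = ",".join(map(str, p.window_hits))
                fh.write(f"{k}\t{len(p.sites)}\t{sites}\t{p.support}\t{hits}\n")


def filter_patterns(
    patterns: list[VariantPattern], min_support: int = 2, anchor: str = ""
) -> PatternReport:
    """Discard patterns without redundancy (support < ``min_support``).

    The consensus (empty) pattern is always retained when present.
    ``anchor`` records the coordinate system for later overlap checks.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    retained, discarded = [], []
    for p in patterns:
        if p.support >= min_support or p.is_consensus:
            retained.append(p)
        else:
            discarded.append(p)
    return PatternReport(
        retained=retained,
        n_discarded=len(discarded),
        discarded_support=sum(p.support for p in discarded),
        anchor=anchor,
        min_support=min_support,
    )


def pattern_overlap(a: PatternReport, b: PatternReport) -> int:
    """Count retained patterns with identical site sets in both reports.

    Both reports must be built on the same anchor (column coordinate system).
    """
    if a.anchor and b.anchor and a.anchor != b.anchor:
        raise ValueError("pattern reports use different anchor coordinate systems")
    sites_a = {p.sites for p in a.retained}
    sites_b = {p.sites for p in b.retained}
    return len(sites_a & sites_b)
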