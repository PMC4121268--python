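"""The three-step amplicon filter: primers, abundance denoising, chimeras.

Step 1 screens for both primers (exact IUPAC-aware match, no mismatch
tolerance — amplicons lacking the exact distal primer are artifact-prone
partial reads) and trims them.  Step 2 is an abundance-based denoiser in the
frequency-plus-distance spirit of published amplicon denoisers: rare
sequences one edit away from a more abundant sequence are folded into it.
Step 3 is a de novo two-parent chimera detector: a query is explained as a
prefix of one more-abundant sequence joined to a suffix of another at the
best single crossover, and flagged when the chimeric model beats the best
single-parent model decisively on both sides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .model import IUPAC_SETS, Amplicon, PrimerPair, SampleSet

__all__ = [
    "FilterReport",
    "primer_filter",
    "abundance_denoise",
    "detect_chimeras",
    "three_step_filter",
]


@dataclass
class FilterReport:
    """Read counts at each consecutive filtering stage, with reasons.

    ``counts`` maps stage name to (total reads, unique sequences); counts are
    monotonically non-increasing across stages.  ``reasons`` records one
    rejection reason per removed amplicon id.
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)
    stage_order: list[str] = field(default_factory=list)

    def record(self, stage: str, s: SampleSet) -> None:
        self.counts[stage] = (s.total_abundance, len({a.seq for a in s.amplicons}))
        self.stage_order.append(stage)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\ttotal_amplicons\tunique_sequences\n")
            for stage in self.stage_order:
                t, u = self.counts[stage]
                fh.write(f"{stage}\t{t}\t{u}\n")


def _iupac_regex(primer: str) -> str:
    return "".join(
        c if len(IUPAC_SETS[c]) == 1 else "[" + IUPAC_SETS[c] + "]" for c in primer
    )


def primer_filter(
    s: SampleSet, p: PrimerPair, report: FilterReport | None = None
) -> SampleSet:
    """Keep reads carrying both exact primers; trim the primers off.

    Primer IUPAC codes match their base sets; an ``N`` in the read matches
    nothing.  Reads containing ``N`` after trimming, or empty after trimming,
    are removed.  Zero mismatches are tolerated on either primer.
    """
    fwd_re = re.compile("^" + _iupac_regex(p.forward))
    rev_re = re.compile(_iupac_regex(p.reverse) + "$")
    kept: list[Amplicon] = []
    for a in s.amplicons:
        m = fwd_re.match(a.seq)
        if m is None:
            if report is not None:
                report.reasons[a.id] = "missing_forward_primer"
            continue
        rest = a.seq[m.end():]
        m2 = rev_re.search(rest)
        if m2 is None:
            if report is not None:
                report.reasons[a.id] = "missing_reverse_primer"
            continue
        core = rest[: m2.start()]
        if not core:
            if report is not None:
                report.reasons[a.id] = "empty_after_trim"
            continue
        if "N" in core:
            if report is not None:
                report.reasons[a.id] = "ambiguous_base"
            continue
        kept.append(replace(a, seq=core))
    return SampleSet(kept, s.provenance + [f"primer_filter({p.region or 'custom'})"])


def abundance_denoise(
    s: SampleSet, min_abundance: int = 2, max_parent_dist: int = 1
) -> SampleSet:
    """Fold rare sequences into nearby abundant parents.

    Every unique amplicon with abundance < ``min_abundance`` whose sequence
    lies within edit distance <= ``max_parent_dist`` of a strictly more
    abundant amplicon is merged into the closest such parent (ties: higher
    parent abundance, then lexicographically smaller sequence).  Merge
    decisions use the pre-pass abundances, so the pass is order-independent;
    total abundance is conserved.  ``min_abundance=1`` disables the filter.
    """
    if min_abundance < 1:
        raise ValueError("min_abundance must be >= 1")
    if not s.is_dereplicated:
        raise ValueError("abundance_denoise requires a dereplicated set")
    entries = sorted(s.amplicons, key=lambda a: (-a.abundance, a.seq))
    gains: dict[str, int] = {}
    kept: list[Amplicon] = []
    for a in entries:
        if a.abundance >= min_abundance:
            kept.append(a)
            continue
        best: tuple[int, int, str] | None = None  # (dist, -parent_ab, parent_seq)
        for parent in entries:
            if parent.abundance <= a.abundance:
                break  # sorted: no more strictly-more-abundant parents follow
            if abs(len(parent.seq) - len(a.seq)) > max_parent_dist:
                continue
            d = edlib.align(a.seq, parent.seq, task="distance", k=max_parent_dist)[
                "editDistance"
            ]
            if d < 0:
                continue
            cand = (d, -parent.abundance, parent.seq)
            if best is None or cand < best:
                best = cand
        if best is None:
            kept.append(a)
        else:
            gains[best[2]] = gains.get(best[2], 0) + a.abundance
    merged = [
        replace(a, abundance=a.abundance + gains.get(a.seq, 0)) if a.seq in gains else a
        for a in kept
    ]
    merged.sort(key=lambda a: (-a.abundance, a.seq))
    return SampleSet(
        merged,
        s.provenance + [f"abundance_denoise(min_abundance={min_abundance}, max_parent_dist={max_parent_dist})"],
    )


def _encode_rows(seqs: list[str]) -> np.ndarray:
    arr = np.zeros((len(seqs), max(len(x) for x in seqs)), dtype=np.uint8)
    for i, x in enumerate(seqs):
        arr[i, : len(x)] = np.frombuffer(x.encode("ascii"), dtype=np.uint8)
    return arr


def detect_chimeras(
    s: SampleSet,
    min_div: int = 2,
    min_score_gain: int = 3,
    report: FilterReport | None = None,
) -> tuple[SampleSet, SampleSet]:
    """De novo two-parent chimera detection on a dereplicated set.

    Queries are processed in decreasing abundance.  Candidate parents are the
    strictly more abundant sequences of the same length still retained (the
    position-wise prefix/suffix comparison that scores crossovers requires a
    common coordinate system; length-changing chimeras are outside this
    detector's model).  A query is flagged when the best chimeric model
    improves on the best single parent by >= ``min_score_gain`` mismatches
    and each parent contributes >= ``min_div`` diagnostic positions (query
    matches that parent where the parents disagree).  Flagged sequences are
    removed before later queries are tested.
    """
    if not s.is_dereplicated:
        raise ValueError("detect_chimeras requires a dereplicated set")
    entries = sorted(s.amplicons, key=lambda a: (-a.abundance, a.seq))
    if not entries:
        return SampleSet([], s.provenance), SampleSet([], s.provenance)
    seqs = [a.seq for a in entries]
    lengths = np.array([len(x) for x in seqs])
    abund = np.array([a.abundance for a in entries])
    rows = _encode_rows(seqs)
    retained = np.ones(len(entries), dtype=bool)
    flagged_idx: list[int] = []

    for qi in range(len(entries)):
        L = int(lengths[qi])
        cand = np.flatnonzero(retained[:qi] & (lengths[:qi] == L) & (abund[:qi] > abund[qi]))
        if cand.size < 2:
            continue
        q = rows[qi, :L]
        mism = (rows[cand][:, :L] != q).astype(np.int32)
        prefix = np.concatenate(
            (np.zeros((cand.size, 1), np.int32), np.cumsum(mism, axis=1)), axis=1
        )
        total = prefix[:, -1]
        best_single = int(total.min())
        suffix = total[:, None] - prefix
        best_pre = prefix.min(axis=0)
        best_suf = suffix.min(axis=0)
        chim = best_pre[1:L] + best_suf[1:L]  # crossover c in 1..L-1
        if best_single - int(chim.min()) < min_score_gain:
            continue
        flagged = False
        for c_off in np.argsort(chim, kind="stable"):
            c = int(c_off) + 1
            if best_single - int(chim[c_off]) < min_score_gain:
                break
            i = int(prefix[:, c].argmin())
            j = int(suffix[:, c].argmin())
            if i == j:
                continue
            A, B = rows[cand[i], :L], rows[cand[j], :L]
            parents_differ = A != B
            div_a = int(np.count_nonzero(parents_differ[:c] & (q[:c] == A[:c])))
            div_b = int(np.count_nonzero(parents_differ[c:] & (q[c:] == B[c:])))
            if div_a >= min_div and div_b >= min_div:
                flagged = True
                if report is not None:
                    report.reasons[entries[qi].id] = (
                        f"chimera(parents={entries[cand[i]].id},{entries[cand[j]].id},crossover={c})"
                    )
                break
        if flagged:
            retained[qi] = False
            flagged_idx.append(qi)

    clean = [entries[i] for i in range(len(entries)) if retained[i]]
    flags = [entries[i] for i in flagged_idx]
    prov = s.provenance + [f"detect_chimeras(min_div={min_div}, min_score_gain={min_score_gain})"]
    return SampleSet(clean, prov), SampleSet(flags, list(s.provenance))


def three_step_filter(
    s: SampleSet,
    p: PrimerPair,
    min_abundance: int = 2,
    max_parent_dist: int = 1,
    min_div: int = 2,
    min_score_gain: int = 3,
    denoise: bool = True,
) -> tuple[SampleSet, SampleSet, FilterReport]:
    """Primer screen, optional abundance denoise, then chimera removal.

    Returns ``(clean, flagged_chimeras, report)``.  Input may be raw reads;
    the set is dereplicated after primer trimming.
    """
    from .model import dereplicate

    report = FilterReport()
    report.record("raw", s)
    after_primer = dereplicate(primer_filter(s, p, report))
    report.record("after_primer", after_primer)
    if denoise:
        after_denoise = abundance_denoise(after_primer, min_abundance, max_parent_dist)
    else:
        after_denoise = after_primer
    report.record("after_denoise", after_denoise)
    clean, flagged = detect_chimeras(after_denoise, min_div, min_score_gain, report)
    report.record("after_chimera", clean)
    return clean, flagged, report
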