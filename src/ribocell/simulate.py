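"""Synthetic single-cell amplicon reads with full ground truth.

Emulates what a 454 pyrosequencing run of one protist cell's rDNA looks
like: a template pool of one dominant ribotype plus optional low-abundance
true variants (differing only inside a designated variability hotspot), a
per-read error channel combining PCR and sequencing substitutions, two-parent
PCR chimeras with a single crossover, and the homopolymer-run indels typical
of pyrosequencing chemistry.  Technical replicates are two independent draws
from the same template pool, mirroring a split DNA extract amplified and
sequenced twice.

The generator collapses multi-cycle PCR into one effective per-read error
channel and all nuclei into one template pool; effective rates are what the
downstream denoising claims depend on.  Every emitted read has exactly one
truth record, so acceptance tests can score any filter against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import Amplicon, PrimerPair, SampleSet, reverse_complement

__all__ = [
    "Ribotype",
    "ErrorModel",
    "TruthRecord",
    "TruthTable",
    "DEFAULT_PRIMERS",
    "default_template",
    "default_hotspot",
    "make_ribotype_pool",
    "simulate_reads",
    "simulate_replicates",
    "make_reference_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: Eukaryote-generalist V4/V9 primer pairs in read orientation (the reverse
#: entry is the reverse-complement of the reverse primer oligo).
DEFAULT_PRIMERS: dict[str, PrimerPair] = {
    "V4": PrimerPair(
        forward="CCAGCASCYGCGGTAATTCC",
        reverse=reverse_complement("ACTTTCGTTCTTGATYRA"),
        region="V4",
    ),
    "V9": PrimerPair(
        forward="TTGTACACACCGCCC",
        reverse=reverse_complement("CCTTCYGCAGGTTCACCTAC"),
        region="V9",
    ),
}

#: Total template lengths (primers included): ~130 bp V9-like, ~380 bp V4-like.
DEFAULT_TEMPLATE_LENGTH = {"V9": 130, "V4": 380}


@dataclass(frozen=True)
class Ribotype:
    """One true template sequence (primers included) and its pool fraction."""

    id: str
    seq: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"ribotype {self.id}: fraction must be in (0,1]")


@dataclass(frozen=True)
class ErrorModel:
    """Effective per-read error channel for PCR + pyrosequencing.

    ``sub_rate``: per-base substitution probability (uniform over the three
    alternative bases).  ``homopolymer_indel_rate``: per-homopolymer-run
    probability scaled by (run length - 1) of inserting or deleting one base
    of the run (coin flip).  ``chimera_rate``: per-read probability of being
    a two-parent chimera joined at a uniform interior crossover.  All
    randomness flows from ``seed``.
    """

    sub_rate: float = 0.002
    homopolymer_indel_rate: float = 0.005
    chimera_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "homopolymer_indel_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0,1), got {v}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    templates: tuple[str, ...]
    subs: tuple[tuple[int, str, str], ...] = ()  # (position, from, to) on the read's template
    indels: tuple[tuple[int, str], ...] = ()  # (run start position, "ins"|"del")
    is_chimera: bool = False
    crossover: int | None = None

    @property
    def has_error(self) -> bool:
        return bool(self.subs or self.indels) or self.is_chimera


@dataclass
class TruthTable:
    """One truth record per emitted read, with TSV export."""

    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, TruthRecord]:
        return {r.read_id: r for r in self.records}

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("read_id\ttemplate_ids\tn_subs\tn_indels\tis_chimera\tcrossover\n")
            for r in self.records:
                fh.write(
                    f"{r.read_id}\t{','.join(r.templates)}\t{len(r.subs)}\t"
                    f"{len(r.indels)}\t{int(r.is_chimera)}\t"
                    f"{'' if r.crossover is None else r.crossover}\n"
                )


def default_template(region: str = "V9", seed: int = 0) -> str:
    """A random template of realistic length with real primer flanks."""
    primers = DEFAULT_PRIMERS[region]
    core_len = DEFAULT_TEMPLATE_LENGTH[region] - len(primers.forward) - len(primers.reverse)
    rng = np.random.default_rng(seed)
    core = rng.choice(_BASES, size=core_len).tobytes().decode("ascii")
    return _disambiguate(primers.forward) + core + _disambiguate(primers.reverse)


def _disambiguate(primer: str) -> str:
    """Resolve IUPAC ambiguity codes to one concrete base (first of the set)."""
    from .model import IUPAC_SETS

    return "".join(IUPAC_SETS[c][0] for c in primer)


def default_hotspot(region: str = "V9") -> tuple[int, int]:
    """A hotspot interval in template coordinates, clear of both primers."""
    primers = DEFAULT_PRIMERS[region]
    length = DEFAULT_TEMPLATE_LENGTH[region]
    lo = len(primers.forward)
    hi = length - len(primers.reverse)
    span = hi - lo
    return (lo + span // 3, hi - span // 3)


def make_ribotype_pool(
    base_seq: str,
    n_minor: int = 0,
    k_subs: int = 3,
    minor_fracs: Sequence[float] = (),
    hotspot: tuple[int, int] | None = None,
    seed: int = 0,
) -> list[Ribotype]:
    """Build a dominant ribotype plus minor true variants.

    Each minor variant differs from ``base_seq`` at exactly ``k_subs``
    positions drawn uniformly (without replacement) from the hotspot
    interval — true intragenomic variation concentrates in the variability
    hotspot, unlike uniformly scattered technical errors.
    """
    if len(base_seq) < 60:
        raise ValueError("base_seq must be at least 60 bp")
    if len(minor_fracs) != n_minor:
        raise ValueError("minor_fracs must have n_minor entries")
    if sum(minor_fracs) >= 1.0:
        raise ValueError("minor fractions must sum to < 1")
    if hotspot is None:
        lo, hi = len(base_seq) // 4, 3 * len(base_seq) // 4
    else:
        lo, hi = hotspot
    if not 0 <= lo < hi <= len(base_seq):
        raise ValueError(f"hotspot {hotspot} outside template bounds")
    if hi - lo < k_subs:
        raise ValueError("hotspot shorter than the number of substitutions requested")
    rng = np.random.default_rng(seed)
    pool = [Ribotype("rt0", base_seq, 1.0 - float(sum(minor_fracs)))]
    seen = {base_seq}
    for m in range(n_minor):
        while True:
            positions = rng.choice(np.arange(lo, hi), size=k_subs, replace=False)
            seq = list(base_seq)
            for p in sorted(int(p) for p in positions):
                alt = rng.integers(1, 4)
                seq[p] = "ACGT"[(_BASE_INDEX[seq[p]] + int(alt)) % 4]
            variant = "".join(seq)
            if variant not in seen:  # overlapping draws across variants: redraw
                seen.add(variant)
                break
        pool.append(Ribotype(f"rt{m + 1}", variant, float(minor_fracs[m])))
    return pool


def _find_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Homopolymer runs of length >= 2 as (start, length)."""
    boundaries = np.flatnonzero(row[1:] != row[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    lengths = np.diff(np.concatenate((starts, [row.size])))
    return [(int(s), int(l)) for s, l in zip(starts, lengths) if l >= 2]


def simulate_reads(
    pool: list[Ribotype],
    n_reads: int,
    model: ErrorModel,
    sample: str = "sim",
    replicate: str = "",
    region: str = "V9",
) -> tuple[SampleSet, TruthTable]:
    """Draw reads from the template pool through the error channel.

    Per read: a template is chosen by pool fractions; with probability
    ``chimera_rate`` (and at least two templates in the pool) the read is
    instead a single-crossover chimera of two distinct templates; then
    substitutions land i.i.d. per base; finally each homopolymer run of the
    substituted sequence may gain or lose one base, at most once per run.
    """
    if not pool:
        raise ValueError("simulate_reads requires a non-empty pool")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    fracs = np.array([r.fraction for r in pool])
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("pool fractions must sum to 1")
    rng = np.random.default_rng(model.seed)
    template_idx = rng.choice(len(pool), size=n_reads, p=fracs)
    chimeric = (
        rng.random(n_reads) < model.chimera_rate
        if len(pool) >= 2
        else np.zeros(n_reads, dtype=bool)
    )

    amplicons: list[Amplicon] = []
    records: list[TruthRecord] = []
    for i in range(n_reads):
        rid = f"{sample}{('-' + replicate) if replicate else ''}_{i:05d}"
        if chimeric[i]:
            a_idx = int(template_idx[i])
            while True:
                b_idx = int(rng.choice(len(pool), p=fracs))
                if b_idx != a_idx:
                    break
            pa, pb = pool[a_idx].seq, pool[b_idx].seq
            cross = int(rng.integers(1, min(len(pa), len(pb))))
            base = pa[:cross] + pb[cross:]
            templates = (pool[a_idx].id, pool[b_idx].id)
            is_chimera, crossover = True, cross
        else:
            base = pool[int(template_idx[i])].seq
            templates = (pool[int(template_idx[i])].id,)
            is_chimera, crossover = False, None

        row = np.frombuffer(base.encode("ascii"), dtype=np.uint8).copy()
        subs: list[tuple[int, str, str]] = []
        if model.sub_rate > 0.0:
            mask = rng.random(row.size) < model.sub_rate
            hit = np.flatnonzero(mask)
            if hit.size:
                offsets = rng.integers(1, 4, size=hit.size)
                for p, off in zip(hit, offsets):
                    old = chr(row[p])
                    new = "ACGT"[(_BASE_INDEX[old] + int(off)) % 4]
                    subs.append((int(p), old, new))
                    row[p] = ord(new)

        indels: list[tuple[int, str]] = []
        if model.homopolymer_indel_rate > 0.0:
            edits: list[tuple[int, int, str]] = []  # (start, length, kind)
            for start, length in _find_runs(row):
                if rng.random() < model.homopolymer_indel_rate * (length - 1):
                    kind = "ins" if rng.random() < 0.5 else "del"
                    edits.append((start, length, kind))
            for start, length, kind in reversed(edits):  # right-to-left keeps coords
                if kind == "ins":
                    row = np.insert(row, start, row[start])
                else:
                    row = np.delete(row, start)
                indels.append((start, kind))
            indels.reverse()

        amplicons.append(
            Amplicon(rid, row.tobytes().decode("ascii"), 1, sample, replicate, region)
        )
        records.append(
            TruthRecord(rid, templates, tuple(subs), tuple(indels), is_chimera, crossover)
        )
    return (
        SampleSet(amplicons, [f"simulate_reads(n={n_reads}, seed={model.seed})"]),
        TruthTable(records),
    )


def simulate_replicates(
    pool: list[Ribotype],
    n_reads: int,
    model: ErrorModel,
    sample: str = "sim",
    region: str = "V9",
) -> tuple[SampleSet, SampleSet, TruthTable, TruthTable]:
    """Two independent draws from one pool, labelled replicates "1" and "2".

    Replicate seeds are ``seed`` and ``seed + 1`` (kept below 2**31).
    """
    m1 = model
    m2 = replace(model, seed=(model.seed + 1) % (2**31 - 1))
    rep1, t1 = simulate_reads(pool, n_reads, m1, sample, "1", region)
    rep2, t2 = simulate_reads(pool, n_reads, m2, sample, "2", region)
    return rep1, rep2, t1, t2


def make_reference_panel(
    base_seq: str,
    n_refs: int = 8,
    hotspot: tuple[int, int] | None = None,
    div_inside: float = 0.4,
    div_outside: float = 0.01,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """A synthetic gapless reference alignment with a planted hotspot.

    Stands in for a curated multi-clade reference alignment: columns inside
    ``hotspot`` vary between references at rate ``div_inside``, columns
    outside at ``div_outside``.  Returns ``(ids, rows)`` of equal-length
    ungapped strings (a trivially valid alignment).
    """
    if hotspot is None:
        hotspot = (len(base_seq) // 4, 3 * len(base_seq) // 4)
    lo, hi = hotspot
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    base_row = np.frombuffer(base_seq.encode("ascii"), dtype=np.uint8)
    for r in range(n_refs):
        row = base_row.copy()
        rates = np.full(row.size, div_outside)
        rates[lo:hi] = div_inside
        mask = rng.random(row.size) < rates
        for p in np.flatnonzero(mask):
            old = chr(row[p])
            row[p] = ord("ACGT"[(_BASE_INDEX[old] + int(rng.integers(1, 4))) % 4])
        ids.append(f"ref{r}")
        rows.append(row.tobytes().decode("ascii"))
    return ids, rows
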