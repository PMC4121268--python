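"""Core domain types and FASTA I/O for single-cell amplicon sets.

An :class:`Amplicon` is one (possibly dereplicated) read of a marker region
(V4 or V9 of the 18S rRNA gene) from one cell.  A :class:`SampleSet` is the
collection of amplicons from one sequencing run of one cell/replicate.  The
FASTA dialect carries copy counts as usearch-style ``;size=N`` suffixes on
record ids, the de-facto standard for dereplicated amplicon files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Amplicon",
    "PrimerPair",
    "SampleSet",
    "read_fasta",
    "write_fasta",
    "dereplicate",
    "unique_and_singleton_counts",
    "IUPAC_SETS",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGTN]+$")
_SIZE_RE = re.compile(r";size=(\d+);?$")

#: IUPAC nucleotide ambiguity codes mapped to the plain bases they stand for.
#: ``N`` in a *primer* matches any base; ``N`` in a *read* matches nothing.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Amplicon:
    """A marker-gene read with its copy count and provenance labels.

    ``abundance`` is the number of strictly identical raw reads merged into
    this record; a *singleton* has abundance 1.  ``replicate`` is ``""`` when
    the sample has no technical replicate.
    """

    id: str
    seq: str
    abundance: int = 1
    sample: str = ""
    replicate: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"amplicon {self.id!r}: empty sequence")
        if not _DNA_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(
                f"amplicon {self.id!r}: non-DNA symbol(s) {','.join(bad)}"
            )
        if self.abundance < 1:
            raise ValueError(
                f"amplicon {self.id!r}: abundance must be >= 1, got {self.abundance}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity key of a dereplicated amplicon."""
        return (self.sample, self.replicate, self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primer as they appear *on the read*.

    ``reverse`` is given in read orientation, i.e. the reverse-complement of
    the reverse primer oligo, so a valid amplicon is
    ``forward + insert + reverse``.
    """

    forward: str
    reverse: str
    region: str = ""

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{name} primer shorter than 10 bases: {p!r}")
            bad = sorted(set(p) - set(IUPAC_SETS))
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC symbol(s) {bad}")


@dataclass
class SampleSet:
    """An ordered collection of amplicons from one marker region.

    The set may hold raw reads (duplicate sequences, abundance 1 each) or a
    dereplicated set (one entry per distinct sequence).  ``provenance`` is a
    free-text audit trail of the I/O and filtering steps applied.
    """

    amplicons: list[Amplicon] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        regions = {a.region for a in self.amplicons}
        if len(regions) > 1:
            raise ValueError(f"mixed region labels in one SampleSet: {sorted(regions)}")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSet):
            return NotImplemented
        return sorted(self.amplicons) == sorted(other.amplicons)

    @property
    def total_abundance(self) -> int:
        return sum(a.abundance for a in self.amplicons)

    @property
    def is_dereplicated(self) -> bool:
        keys = [a.key for a in self.amplicons]
        return len(keys) == len(set(keys))

    def with_provenance(self, note: str) -> "SampleSet":
        return SampleSet(list(self.amplicons), self.provenance + [note])


def _strip_size(record_id: str) -> tuple[str, int | None]:
    m = _SIZE_RE.search(record_id)
    if m is None:
        return record_id, None
    return record_id[: m.start()], int(m.group(1))


def read_fasta(
    path: str | Path,
    sample: str = "",
    replicate: str = "",
    region: str = "",
) -> SampleSet:
    """Read amplicons from a FASTA file (wrapped or unwrapped lines).

    Abundance is parsed from a ``;size=N`` suffix on the record id when
    present (trailing semicolon tolerated), else 1.  Sequences are
    uppercased; ``N`` is allowed and only removed later, at the filtering
    stage.  Sample/replicate/region labels are supplied by the caller, never
    parsed from record ids.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i for i, line in enumerate(text.splitlines(), 1) if line.strip()
        )
        raise ValueError(f"{path}: not FASTA — line {first_bad} does not start a record")
    amplicons: list[Amplicon] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, size = _strip_size(rec.id)
        seq = str(rec.seq).upper()
        if size is not None and size < 1:
            raise ValueError(f"{path}: record {rec.id!r} has size < 1")
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if not _DNA_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(
                f"{path}: record {rec.id!r} has non-DNA symbol(s) {','.join(bad)}"
            )
        amplicons.append(
            Amplicon(rid, seq, size if size is not None else 1, sample, replicate, region)
        )
    if not amplicons:
        logger.warning("%s: no FASTA records found, returning an empty set", path)
    return SampleSet(amplicons, [f"read_fasta({path})"])


def write_fasta(s: SampleSet, path: str | Path) -> None:
    """Write a SampleSet as unwrapped FASTA with ``;size=N`` annotations.

    Records are emitted in decreasing abundance, ties broken lexicographically
    by sequence, so output is deterministic and round-trips with
    :func:`read_fasta` bit-exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        for a in sorted(s.amplicons, key=lambda a: (-a.abundance, a.seq)):
            fh.write(f">{a.id};size={a.abundance}\n{a.seq}\n")


def dereplicate(s: SampleSet) -> SampleSet:
    """Merge strictly identical sequences, summing abundances.

    One entry is kept per distinct ``(sample, replicate, seq)``; its id is
    the id of the most abundant contributing read (ties by id).  Total
    abundance is conserved and the operation is idempotent.
    """
    groups: dict[tuple[str, str, str], list[Amplicon]] = {}
    for a in s.amplicons:
        groups.setdefault(a.key, []).append(a)
    merged = []
    for members in groups.values():
        rep = min(members, key=lambda a: (-a.abundance, a.id))
        merged.append(replace(rep, abundance=sum(a.abundance for a in members)))
    merged.sort(key=lambda a: (-a.abundance, a.seq))
    return SampleSet(merged, s.provenance + ["dereplicate"])


def unique_and_singleton_counts(s: SampleSet) -> tuple[int, int, int]:
    """Return ``(total, unique, singletons)`` of a dereplicated set.

    ``total`` sums abundances, ``unique`` counts distinct sequences and
    ``singletons`` counts entries with abundance 1.
    """
    if not s.is_dereplicated:
        raise ValueError("unique_and_singleton_counts requires a dereplicated set")
    total = s.total_abundance
    unique = len(s.amplicons)
    singletons = sum(1 for a in s.amplicons if a.abundance == 1)
    return total, unique, singletons
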