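"""Technical-replicate cross-validation of unique amplicons.

Two independent PCR + sequencing runs of the same single-cell DNA extract
share their true ribotypes with near certainty, while independently arisen
error sequences rarely coincide.  Partitioning the unique amplicons of the
two replicates into common / replicate-only sets therefore separates signal
from noise without abundance thresholds: keeping only the common set is a
denoising step in itself, and the OTU inflation of the non-common set
measures how much artifactual diversity the replicates disagree on.

Sharing is decided by exact sequence equality (after primer trimming) on
unique amplicons; near-match sharing is deliberately out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .clustering import greedy_cluster
from .model import Amplicon, SampleSet

__all__ = ["VennPartition", "CrossvalReport", "venn_partition", "crossval_denoise", "crossval_report"]

logger = logging.getLogger(__name__)


@dataclass
class VennPartition:
    """Common / A-only / B-only unique amplicons of a replicate pair."""

    common: SampleSet
    only_a: SampleSet
    only_b: SampleSet

    @property
    def pct_common(self) -> float:
        """Common unique amplicons as a percentage of the union's uniques."""
        n = len(self.common) + len(self.only_a) + len(self.only_b)
        return 100.0 * len(self.common) / n if n else 0.0


@dataclass
class CrossvalReport:
    """Sharing statistics and the OTU inflation of non-common amplicons."""

    pct_common: float
    threshold: float
    otus_common: int
    otus_noncommon: int

    @property
    def inflation_ratio(self) -> float:
        """OTUs(non-common) / OTUs(common).

        NaN when either side has no OTUs: a ratio over an empty partition
        (identical or fully disjoint replicates) carries no information.
        """
        if self.otus_common == 0 or self.otus_noncommon == 0:
            return math.nan
        return self.otus_noncommon / self.otus_common


def _check_pair(rep1: SampleSet, rep2: SampleSet) -> None:
    for name, rep in (("rep1", rep1), ("rep2", rep2)):
        if not rep.is_dereplicated:
            raise ValueError(f"{name} must be dereplicated")
    s1 = {a.sample for a in rep1} | {a.sample for a in rep2}
    if len(s1) > 1:
        raise ValueError(f"replicates come from different samples: {sorted(s1)}")
    regions = {a.region for a in rep1} | {a.region for a in rep2}
    if len(regions) > 1:
        raise ValueError(f"replicates target different regions: {sorted(regions)}")
    r1 = {a.replicate for a in rep1}
    r2 = {a.replicate for a in rep2}
    if "" in r1 | r2:
        raise ValueError("cross-validation requires labelled technical replicates")
    if r1 and r2 and r1 == r2:
        raise ValueError(f"replicate labels must differ, both are {r1}")


def venn_partition(rep1: SampleSet, rep2: SampleSet) -> VennPartition:
    """Split two dereplicated replicates by exact sequence membership.

    Common amplicons get their abundances summed across replicates and a
    combined replicate label; the three sets are disjoint by sequence and
    together cover the union's unique amplicons.
    """
    _check_pair(rep1, rep2)
    by_seq_2 = {a.seq: a for a in rep2}
    seqs_1 = {a.seq for a in rep1}
    common, only_a = [], []
    for a in rep1.amplicons:
        if a.seq in by_seq_2:
            b = by_seq_2[a.seq]
            common.append(
                replace(a, abundance=a.abundance + b.abundance,
                        replicate=f"{a.replicate}+{b.replicate}")
            )
        else:
            only_a.append(a)
    only_b = [b for b in rep2.amplicons if b.seq not in seqs_1]
    prov = rep1.provenance + rep2.provenance
    part = VennPartition(
        SampleSet(sorted(common, key=lambda a: (-a.abundance, a.seq)), prov + ["venn:common"]),
        SampleSet(only_a, prov + ["venn:only_a"]),
        SampleSet(only_b, prov + ["venn:only_b"]),
    )
    return part


def crossval_denoise(rep1: SampleSet, rep2: SampleSet) -> SampleSet:
    """Retain only the amplicons observed in both replicates."""
    part = venn_partition(rep1, rep2)
    if not part.common.amplicons:
        logger.warning("cross-validation retained no amplicons (disjoint replicates)")
    return part.common.with_provenance("crossval_denoise")


def crossval_report(rep1: SampleSet, rep2: SampleSet, threshold: float = 0.97) -> CrossvalReport:
    """Cluster common and non-common amplicons separately at one threshold."""
    part = venn_partition(rep1, rep2)
    otus_common = len(greedy_cluster(part.common, threshold)) if part.common.amplicons else 0
    noncommon = SampleSet(
        part.only_a.amplicons + part.only_b.amplicons,
        part.only_a.provenance + ["venn:noncommon"],
    )
    otus_noncommon = len(greedy_cluster(noncommon, threshold)) if noncommon.amplicons else 0
    return CrossvalReport(part.pct_common, threshold, otus_common, otus_noncommon)
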