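"""End-to-end per-cell pipeline and run configuration.

Reads a manifest (one FASTA per sample x replicate x region), applies the
three-step filter, cross-validates technical replicates when a pair exists,
sweeps OTU thresholds, runs the linkage method, and (when a reference
alignment is supplied) localizes minor-variant substitutions relative to
the variability hotspot.  One :class:`CellReport` is produced per
cell x region, in the shape of a per-cell amplicon summary table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import crossval as cv
from . import linkage as lk
from .clustering import default_threshold_grid, sweep
from .filtering import primer_filter, three_step_filter
from .hotspot import ReferenceAlignment, classify_substitutions, column_variability, find_hotspots
from .model import (
    PrimerPair,
    SampleSet,
    dereplicate,
    read_fasta,
    unique_and_singleton_counts,
    write_fasta,
)
from .simulate import DEFAULT_PRIMERS

__all__ = ["PipelineParams", "RunConfig", "CellReport", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable stage parameter, with the documented defaults."""

    denoise: bool = True
    min_abundance: int = 2
    max_parent_dist: int = 1
    min_div: int = 2
    min_score_gain: int = 3
    thresholds: tuple[float, ...] = tuple(default_threshold_grid())
    crossval_threshold: float = 0.97
    window: int = 50
    step: int = 25
    min_support: int = 2
    hotspot_min_score: float = 0.3
    hotspot_min_run: int = 10
    hotspot_max_gap: int = 2


@dataclass
class ManifestRow:
    sample: str
    replicate: str
    region: str
    path: Path


@dataclass
class RunConfig:
    """A validated pipeline run: inputs, primers, parameters, output dir."""

    rows: list[ManifestRow]
    primers: dict[str, PrimerPair] = field(default_factory=lambda: dict(DEFAULT_PRIMERS))
    params: PipelineParams = field(default_factory=PipelineParams)
    reference_alignment: Path | None = None
    outdir: Path = Path("ribocell_out")
    seed: int = 0

    def validate(self) -> None:
        if not self.rows:
            raise ValueError("manifest has no rows")
        for row in self.rows:
            if not row.path.exists():
                raise FileNotFoundError(f"manifest references a missing file: {row.path}")
            if row.region not in self.primers:
                raise ValueError(f"no primer pair defined for region {row.region!r}")
        if self.reference_alignment is not None and not self.reference_alignment.exists():
            raise FileNotFoundError(f"reference alignment not found: {self.reference_alignment}")


def read_manifest(path: str | Path) -> list[ManifestRow]:
    """TSV with header sample/replicate/region/path; paths resolve relative
    to the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample", "replicate", "region", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = path.parent
    return [
        ManifestRow(r["sample"], r["replicate"], r["region"], (base / r["path"]).resolve())
        for _, r in df.iterrows()
    ]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (manifest path, primers, parameters)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    rows = read_manifest((path.parent / raw["manifest"]).resolve())
    primers = dict(DEFAULT_PRIMERS)
    for region, spec in (raw.get("primers") or {}).items():
        primers[region] = PrimerPair(spec["forward"], spec["reverse"], region)
    pfields = {f.name for f in dataclasses.fields(PipelineParams)}
    overrides = {k: v for k, v in (raw.get("params") or {}).items() if k in pfields}
    if "thresholds" in overrides:
        overrides["thresholds"] = tuple(float(t) for t in overrides["thresholds"])
    ref = raw.get("reference_alignment")
    return RunConfig(
        rows=rows,
        primers=primers,
        params=PipelineParams(**overrides),
        reference_alignment=(path.parent / ref).resolve() if ref else None,
        outdir=Path(raw.get("outdir", "ribocell_out")),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class CellReport:
    """Per cell x region summary in the shape of a per-cell count table."""

    sample: str
    region: str
    raw: int
    after_primer: int
    after_denoise: int
    after_chimera: int
    total: int
    unique: int
    singletons: int
    otu_counts: dict[float, int]
    n_patterns: int
    n_indel_reads: int
    pct_common: float | None = None
    otus_common: int | None = None
    otus_noncommon: int | None = None
    inflation_ratio: float | None = None
    hotspot_intervals: list[tuple[int, int]] | None = None
    substitutions_outside_pct: float | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["otu_counts"] = {f"{t:.2f}": n for t, n in self.otu_counts.items()}
        return d


def _pool_replicates(filtered: dict[str, SampleSet]) -> SampleSet:
    """Merge per-replicate filtered sets into one per-cell set."""
    pooled = [replace(a, replicate="") for s in filtered.values() for a in s.amplicons]
    regions = {a.region for a in pooled}
    return dereplicate(SampleSet(pooled, [f"pooled({','.join(sorted(filtered))})"]))


def _run_cell(
    sample: str,
    region: str,
    rows: list[ManifestRow],
    cfg: RunConfig,
    outdir: Path,
) -> CellReport:
    params = cfg.params
    primers = cfg.primers[region]
    raw_total = 0
    filtered: dict[str, SampleSet] = {}
    primer_only: dict[str, SampleSet] = {}
    counts = {"after_primer": 0, "after_denoise": 0, "after_chimera": 0}
    for row in sorted(rows, key=lambda r: r.replicate):
        reads = read_fasta(row.path, sample=sample, replicate=row.replicate, region=region)
        raw_total += reads.total_abundance
        clean, flagged, report = three_step_filter(
            reads,
            primers,
            min_abundance=params.min_abundance,
            max_parent_dist=params.max_parent_dist,
            min_div=params.min_div,
            min_score_gain=params.min_score_gain,
            denoise=params.denoise,
        )
        tag = f"{sample}_{row.replicate or 'u'}_{region}"
        report.to_tsv(outdir / f"{tag}.filter_report.tsv")
        write_fasta(clean, outdir / f"{tag}.filtered.fasta")
        if flagged.amplicons:
            write_fasta(flagged, outdir / f"{tag}.chimeras.fasta")
        filtered[row.replicate] = clean
        # replicate cross-validation is run on primer-screened but otherwise
        # un-denoised reads, so the two denoising routes stay comparable
        primer_only[row.replicate] = dereplicate(primer_filter(reads, primers))
        for key in counts:
            counts[key] += report.counts[key][0]

    pooled = _pool_replicates(filtered)
    total, unique, singletons = unique_and_singleton_counts(pooled)

    pct_common = otus_common = otus_noncommon = inflation = None
    if len(rows) == 2:
        reps = sorted(primer_only)
        cvr = cv.crossval_report(
            primer_only[reps[0]], primer_only[reps[1]], params.crossval_threshold
        )
        pct_common = cvr.pct_common
        otus_common, otus_noncommon = cvr.otus_common, cvr.otus_noncommon
        inflation = cvr.inflation_ratio

    otu_counts: dict[float, int] = {}
    n_patterns = n_indel = 0
    if pooled.amplicons:
        sw = sweep(pooled, list(params.thresholds))
        otu_counts = sw.counts()
        sw.to_frame().to_csv(outdir / f"{sample}_{region}.otus.tsv", sep="\t", index=False)
        profile = lk.build_consensus(pooled)
        calls = lk.call_snps(pooled, profile)
        patterns = lk.window_patterns(
            calls, pooled, window=min(params.window, len(profile.anchor)), step=params.step
        )
        pat_report = lk.filter_patterns(patterns, params.min_support, anchor=profile.anchor)
        pat_report.to_tsv(outdir / f"{sample}_{region}.patterns.tsv")
        n_patterns = pat_report.n_patterns
        n_indel = len(calls.indel_reads)

    intervals = outside_pct = None
    if cfg.reference_alignment is not None and pooled.amplicons:
        ra = ReferenceAlignment.from_fasta(cfg.reference_alignment)
        scores = column_variability(ra)
        intervals = find_hotspots(
            scores, params.hotspot_min_score, params.hotspot_min_run, params.hotspot_max_gap
        )
        dominant = max(pooled.amplicons, key=lambda a: (a.abundance, a.seq))
        minors = SampleSet([a for a in pooled.amplicons if a.seq != dominant.seq])
        ann = classify_substitutions(minors, dominant, ra, intervals)
        outside_pct = 100.0 * ann.fraction_outside if ann.calls else None

    return CellReport(
        sample=sample,
        region=region,
        raw=raw_total,
        after_primer=counts["after_primer"],
        after_denoise=counts["after_denoise"],
        after_chimera=counts["after_chimera"],
        total=total,
        unique=unique,
        singletons=singletons,
        otu_counts=otu_counts,
        n_patterns=n_patterns,
        n_indel_reads=n_indel,
        pct_common=pct_common,
        otus_common=otus_common,
        otus_noncommon=otus_noncommon,
        inflation_ratio=inflation,
        hotspot_intervals=intervals,
        substitutions_outside_pct=outside_pct,
    )


def run_pipeline(cfg: RunConfig) -> dict[tuple[str, str], CellReport]:
    """Run every cell x region in the manifest; one failing cell does not
    abort the others.  Outputs (per-stage FASTA/TSV, a JSON summary and a
    combined TSV report) are written under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[str, str], list[ManifestRow]] = {}
    for row in cfg.rows:
        groups.setdefault((row.sample, row.region), []).append(row)
    reports: dict[tuple[str, str], CellReport] = {}
    for (sample, region), rows in sorted(groups.items()):
        try:
            reports[(sample, region)] = _run_cell(sample, region, rows, cfg, outdir)
        except Exception as exc:  # keep processing the remaining cells
            logger.error("cell %s/%s failed: %s", sample, region, exc)
            reports[(sample, region)] = CellReport(
                sample, region, 0, 0, 0, 0, 0, 0, 0, {}, 0, 0, error=str(exc)
            )
    summary = {f"{s}|{r}": rep.to_dict() for (s, r), rep in reports.items()}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    frame_rows = []
    for rep in reports.values():
        row = {
            "sample": rep.sample, "region": rep.region, "raw": rep.raw,
            "total": rep.total, "unique": rep.unique, "singletons": rep.singletons,
            "patterns": rep.n_patterns,
        }
        row.update({f"otus_{t:.2f}": n for t, n in sorted(rep.otu_counts.items(), reverse=True)})
        frame_rows.append(row)
    pd.DataFrame(frame_rows).to_csv(outdir / "cell_report.tsv", sep="\t", index=False)
    return reports
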