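# Methods

`ribocell` asks a single question of single-cell amplicon data: of the
distinct V4/V9 18S rRNA sequences recovered from one protist cell, how many
are real intragenomic ribotypes and how many are PCR/sequencing artifacts?
It answers it four independent ways — abundance structure after filtering,
OTU behaviour across identity thresholds, agreement between technical
replicates, and the spatial distribution of substitutions relative to the
region's variability hotspot — and ships a ground-truthed simulator so every
route can be tested without sequencing data.

## The data model

An *amplicon* is a read of a primer-delimited marker region carrying a copy
count (`abundance`); a *unique amplicon* is the result of merging strictly
identical reads, and a *singleton* has abundance 1. Dereplication is exact
string merging — no tolerance — because downstream logic (replicate
cross-validation, linkage patterns) depends on exact recurrence being a
strong signal. Copy counts ride on FASTA ids as `;size=N`, the de-facto
standard for dereplicated amplicon files, so every stage's output is
self-describing and re-ingestable.

## Pairwise identity

All clustering decisions reduce to one number: global alignment identity.
The aligner is Needleman–Wunsch with match +1, mismatch −1, linear gap −2,
and a fully deterministic traceback (diagonal, then gap in the second
sequence, then gap in the first). Identity is matching columns over
alignment columns with terminal-gap columns excluded from both counts:
amplicons are primer-delimited, so length differences at the ends are indel
noise rather than missing sequence, and internal gap columns count as
mismatches. One consequence is accepted deliberately: a sequence that is a
flush contiguous substring of another scores identity 1.0. Scoring
parameters are pinned for bit-reproducibility, though identity (not score)
drives all decisions. The DP kernel is numba-compiled; a pure-Python DP
oracle and a Biopython `PairwiseAligner` score cross-check guard it in the
test suite.

## The three-step filter

1. **Primer screen.** Reads must begin with the exact forward primer and
   end with the exact reverse primer (IUPAC codes in the primer match their
   base sets; `N` in a read matches nothing); both primers are then
   trimmed, and reads containing `N` after trimming are dropped. Exactness
   is enforced on *both* primers — the conservative reading of requiring
   the distal primer — because a read that failed to reach its distal
   primer is a truncated, artifact-prone molecule.
2. **Abundance denoise.** A stand-in for frequency-based denoisers: any
   unique amplicon with abundance < 2 lying within edit distance 1 (edlib)
   of a strictly more abundant amplicon is folded into the closest such
   parent (ties: higher parent abundance, then lexicographic sequence).
   Decisions use pre-pass abundances, so the pass is order-independent and
   conserves total abundance. `min_abundance=1` disables the stage.
3. **Chimera removal.** A de novo two-parent detector. Processing
   dereplicated reads in decreasing abundance, each query is modelled as a
   prefix of one strictly more abundant retained sequence joined to a
   suffix of another at the best single crossover. The query is flagged
   when the chimeric model beats the best single-parent model by at least
   `min_score_gain=3` mismatches and each parent contributes at least
   `min_div=2` diagnostic positions (positions where the parents disagree
   and the query matches that parent). Flagged sequences are removed before
   later queries are tested.

   Implementation: prefix/suffix mismatch counts are position-wise, so
   candidate parents must have the query's length; the optimal chimeric
   score over *all* parent pairs is obtained exactly by minimizing, per
   crossover, the best prefix parent plus the best suffix parent, and the
   diagnostic check is applied to the credited (argmin) pair per candidate
   crossover in score order. Two limitations follow. A chimera whose
   crossover leaves fewer than `min_div` diagnostic positions on one side
   is indistinguishable in principle from a point-mutated parent copy, so
   the detector's benchmark constructs chimeras with ≥3 diagnostic
   positions inherited from each parent. And homopolymer-indel variants can
   be "explained" as chimeras of other, more abundant indel variants: a
   frame shift looks like massive divergence position-wise, and a read with
   a deletion at position X matches an earlier-deletion variant perfectly
   after X and a later-deletion variant perfectly before X. Such reads are
   error reads and their removal is usually desirable, but the recorded
   flag reason ("chimera") is wrong in that case.

The stage order is primer → denoise → chimera; a `FilterReport` records
counts and per-read rejection reasons at each stage.

## OTU clustering and threshold sweeps

Greedy abundance-ordered centroid clustering: amplicons in decreasing
abundance (ties lexicographic) join the *first* centroid, in creation
order, reaching the identity threshold, else found a new OTU — first-hit
rather than best-hit, matching classic greedy clusterers and keeping runs
reproducible. The default sweep covers 80–99% identity in 1% steps.
Reported alongside: the dominant-OTU fraction (share of total abundance in
the largest OTU) and a naive exhaustive best-hit reference assignment.

A caveat discovered while validating: OTU-count monotonicity across a
descending threshold grid is *not* guaranteed by greedy first-hit
clustering. At a looser threshold a read may join an earlier centroid
instead of founding its own OTU, stranding satellites that only it could
have absorbed; with mutually ~25%-divergent inputs this is reproducible.
For the package's operating domain — one dominant template plus a
low-divergence error cloud — counts were nested in every seeded trial
(0 violations in 500 sets), and the acceptance suite asserts monotonicity
there; a unit test preserves the divergent-input counterexample.

## Replicate cross-validation

Two independent PCR + sequencing runs of one DNA extract share their true
ribotypes with near certainty; independently arisen errors coincide only by
collision. Unique amplicons of a replicate pair are partitioned by exact
sequence equality into common / A-only / B-only (common abundances summed),
`pct_common` is the common share of the union's uniques, and the two
partitions are clustered separately to measure how many extra OTUs the
non-common (suspect) amplicons would contribute. Cross-validation is run on
primer-screened but otherwise un-denoised reads, so it remains comparable
with the algorithmic denoisers as an independent route.

The collision caveat matters at depth: at 2000 reads per replicate with a
0.002/base substitution rate, a 130 bp amplicon offers only 390 distinct
single-substitution outcomes, so identical *single-error* sequences recur in
both replicates quite often (≈27% of unique error-bearing sequences are
shared at the default study conditions). Exact-sequence cross-validation is
therefore a high-precision filter for *multi-error* artifacts (<5% shared)
but not a guarantee against single-error ones. The simulator makes this
measurable; with real polymerases, whose errors are position-biased, sharing
of single-error sequences is likely higher still.

## The linkage method

Each read is compared to the cell's majority consensus (abundance-weighted,
per-column, ties A<C<G<T), built on coordinates anchored by the most
abundant read. A read's *pattern* is its exact ordered set of
(column, base) deviations; reads whose alignment to the anchor needs gaps
are excluded from grouping (their columns are ambiguous) and counted
separately. Sliding windows (default 50 columns, step 25) annotate where a
pattern's sites fall; pattern equality uses the full site set — windows
report, they do not define, patterns, which prevents assembling chimeric
patterns from fragments of different reads. A per-window fragment-matching
mode is available behind a flag for comparison. Patterns supported by fewer
than `min_support=2` reads (abundance-weighted) are discarded as
non-redundant noise; the consensus pattern is always kept. Pattern overlap
between replicates counts retained patterns with identical site sets, and
requires both reports to share an anchor.

The same collision caveat applies: redundancy filtering removes multi-site
error combinations essentially completely (≥99% abundance-weighted in the
tests) but retains recurring single-substitution errors at realistic depth,
so retained-pattern counts at high coverage overstate ribotype counts
unless patterns are further cross-validated between replicates.

## Hotspot localization

Given a reference alignment spanning the taxon's clades, per-column
variability is scored as 1 − (modal non-gap residue frequency), with
normalized Shannon entropy as an alternative; all-gap columns score 0.
Hotspots are maximal runs of columns scoring ≥ `min_score=0.3`, tolerating
≤ `max_gap=2` consecutive sub-threshold columns, of total length
≥ `min_run=10` — defaults tuned on the synthetic planted-hotspot panel,
since published hotspot figures delimit the region visually rather than
numerically. Runs start and end on above-threshold columns, so padding the
alignment with gap columns cannot change the result. Each minor variant is
aligned to the cell's dominant sequence; differences map through the
dominant's alignment to its nearest reference into column space (0-based,
half-open throughout) and are labelled inside/outside; indels take the
column of their left-flanking base; variants under 70% identity to the
dominant are excluded with a warning. Substitutions landing outside the
hotspot — in columns conserved across clades — are suspect artifacts.

## The simulator

The generator emulates what the analysis assumes about a pyrosequenced
single cell and nothing more:

- a **template pool**: one dominant ribotype plus minor variants differing
  at exactly `k_subs` positions drawn uniformly from a designated hotspot
  interval (true variation is hotspot-bound; errors are not);
- a **single effective per-read error channel** standing in for multi-cycle
  PCR plus sequencing: substitutions i.i.d. per base (default 0.002/base,
  uniform over the three alternatives), and for each homopolymer run of
  length L ≥ 2 of the substituted sequence, a one-base insertion or
  deletion (coin flip) with probability 0.005 × (L − 1), applied at most
  once per run to avoid indel cascades — the characteristic 454 error mode;
- **chimeras**: with probability 0.01 a read is instead two distinct
  templates joined at a single uniform interior crossover (inert for
  single-template pools);
- **technical replicates**: two fully independent draws from one pool,
  seeded `seed` and `seed+1`.

Default templates are ~130 bp (V9-like) and ~380 bp (V4-like) with real
eukaryote-generalist primer sequences at both ends; default depth is 2000
reads per replicate. All randomness flows from the one seed — reruns are
bit-identical — and every read gets a truth record (source template(s),
each substitution, each indel, chimera crossover) so filters can be scored
exactly.

What the simulator does *not* model, and hence what passing tests cannot
show: amplification-efficiency bias between templates (fractions are the
effective post-PCR pool), cycle-resolved PCR error accumulation,
position-dependent or motif-dependent error rates, quality scores and
flowgram-level effects, and per-nucleus copy-number structure in
multinucleated cells (all nuclei are collapsed into one pool). Real 454
error processes are position-biased, which makes error recurrence across
replicates more, not less, likely than the i.i.d. model predicts.

## Numerical and procedural choices

- Identity comparisons use an epsilon of 1e-9 so exact rationals like
  126/130 are not lost to float rounding at a 0.97 threshold.
- All tie-breaks are pinned: alignment traceback (diagonal/up/left),
  clustering processing order (abundance, then sequence), denoise parent
  choice (distance, parent abundance, sequence), consensus bases (A<C<G<T),
  best-hit references (identity, then id).
- Degenerate inputs: empty FASTA reads as an empty set with a warning;
  empty clusterings, empty common sets and zero-OTU partitions are reported
  (inflation ratio is NaN when either side has no OTUs) rather than raised.
- Problem sizes in the validation suite — 130 bp templates, 2000 reads per
  replicate, 100 simulation seeds per claim — are the package's documented
  study conditions; larger runs change nothing structurally.

## Known limitations

- Exact-sequence cross-validation and redundancy filtering are blind to
  recurring single-error sequences at high depth (quantified above).
- The chimera detector requires length-preserving chimeras and two
  detectable sides; it is de novo only.
- Hotspot boundaries on real reference alignments depend on a curated
  alignment the user supplies; the shipped panel is synthetic.
- Greedy first-hit clustering guarantees neither best-hit assignment nor
  threshold nestedness outside its operating domain (documented above).
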