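import pytest

from ribocell.filtering import (
    FilterReport,
    abundance_denoise,
    detect_chimeras,
    primer_filter,
    three_step_filter,
)
from ribocell.model import Amplicon, PrimerPair, SampleSet, dereplicate
from ribocell.simulate import (
    DEFAULT_PRIMERS,
    ErrorModel,
    default_template,
    make_ribotype_pool,
    simulate_reads,
)

from conftest import make_set, mutate, random_dna
from oracles import chimera_oracle

FWD = "ACGTACGTAC"
REV = "TTGGTTGGTT"
PAIR = PrimerPair(FWD, REV, "V9")


def wrap(core: str) -> str:
    return FWD + core + REV


class TestPrimerFilter:
    def test_exact_primers_retained_and_trimmed(self):
        s = make_set([(wrap("AAACCC"), 3)])
        out = primer_filter(s, PAIR)
        assert [(a.seq, a.abundance) for a in out] == [("AAACCC", 3)]

    def test_missing_last_base_of_distal_primer_rejected(self):
        # exact distal primer required: no mismatch/truncation tolerance
        s = make_set([(wrap("AAACCC")[:-1] + "A", 1)])
        report = FilterReport()
        out = primer_filter(s, PAIR, report)
        assert len(out) == 0
        assert set(report.reasons.values()) == {"missing_reverse_primer"}

    def test_missing_forward_primer_rejected(self):
        s = make_set([("T" + wrap("AAACCC")[1:], 1)])
        report = FilterReport()
        assert len(primer_filter(s, PAIR, report)) == 0
        assert set(report.reasons.values()) == {"missing_forward_primer"}

    def test_iupac_primer_code_matches_its_base_set(self):
        pair = PrimerPair("ACGTACGTAY", REV, "V9")  # Y = C or T
        for base, kept in (("C", True), ("T", True), ("A", False)):
            s = make_set([("ACGTACGTA" + base + "AAACCC" + REV, 1)])
            assert (len(primer_filter(s, pair)) == 1) == kept

    def test_read_n_matches_nothing_even_under_primer_n(self):
        pair = PrimerPair("ACGTACGTAN", REV, "V9")
        s = make_set([("ACGTACGTAN" + "AAACCC" + REV, 1)])
        assert len(primer_filter(s, pair)) == 0

    def test_n_in_core_removed(self):
        report = FilterReport()
        out = primer_filter(make_set([(wrap("AANCCC"), 1)]), PAIR, report)
        assert len(out) == 0
        assert set(report.reasons.values()) == {"ambiguous_base"}

    def test_empty_after_trim_rejected(self):
        report = FilterReport()
        out = primer_filter(make_set([(FWD + REV, 1)]), PAIR, report)
        assert len(out) == 0
        assert set(report.reasons.values()) == {"empty_after_trim"}


class TestAbundanceDenoise:
    def test_singleton_merged_into_close_parent(self):
        s = make_set([("ACGTACGT", 100), ("ACGTACGA", 1)])
        out = abundance_denoise(s, min_abundance=2, max_parent_dist=1)
        assert [(a.seq, a.abundance) for a in out] == [("ACGTACGT", 101)]

    def test_min_abundance_one_is_identity(self):
        s = make_set([("ACGTACGT", 100), ("ACGTACGA", 1)])
        assert abundance_denoise(s, min_abundance=1) == s

    def test_distant_singleton_kept(self):
        s = make_set([("AAAAAAAA", 100), ("TTTTTTTT", 1)])
        out = abundance_denoise(s)
        assert len(out) == 2

    def test_tie_broken_by_higher_parent_abundance(self):
        s = make_set([("AAAAAAAC", 50), ("AAAAAAAG", 80), ("AAAAAAAA", 1)])
        out = abundance_denoise(s)
        assert ("AAAAAAAG", 81) in {(a.seq, a.abundance) for a in out}

    def test_conserves_total_abundance(self, rng):
        base = random_dna(rng, 60)
        s = make_set(
            [(base, 500)]
            + [(mutate(rng, base, 1), 1) for _ in range(10)]
            + [(mutate(rng, base, 5), 3)]
        )
        s = dereplicate(s)
        out = abundance_denoise(s)
        assert out.total_abundance == s.total_abundance

    def test_invalid_min_abundance(self):
        with pytest.raises(ValueError):
            abundance_denoise(make_set([("ACGT", 1)]), min_abundance=0)

    def test_merged_reads_carry_true_errors(self):
        """Reads folded away by the denoiser are error copies, per truth."""
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 1, 3, [0.2], seed=2)
        merged_with_err = merged_total = 0
        for seed in range(20):
            reads, truth = simulate_reads(pool, 1000, ErrorModel(seed=seed))
            d = dereplicate(reads)
            out = abundance_denoise(d)
            kept = {a.seq for a in out}
            err_by_seq = {}
            for a, rec in zip(reads, truth.records):
                err_by_seq.setdefault(a.seq, []).append(rec.has_error)
            for a in d:
                if a.seq not in kept:
                    merged_total += 1
                    merged_with_err += all(err_by_seq[a.seq])
        assert merged_total > 0
        assert merged_with_err / merged_total >= 0.95


class TestChimeraDetector:
    def _build(self, rng, n_diffs=10, cross=60, length=130):
        A = random_dna(rng, length)
        B = mutate(rng, A, n_diffs)
        q = A[:cross] + B[cross:]
        return A, B, q

    def test_constructed_chimera_flagged_and_oracle_agrees(self, rng):
        A, B, q = self._build(rng)
        s = make_set([(A, 10), (B, 8), (q, 1)])
        clean, flagged = detect_chimeras(s, min_div=2, min_score_gain=3)
        assert [a.seq for a in flagged] == [q]
        assert {a.seq for a in clean} == {A, B}
        assert chimera_oracle(q, [A, B], 2, 3)

    def test_near_identical_copy_of_parent_is_clean(self, rng):
        # the chimeric model cannot beat a 1-diff single-parent explanation
        # by the required score gain
        A, B, _ = self._build(rng)
        q = mutate(rng, A, 1)
        s = make_set([(A, 10), (B, 8), (q, 1)])
        clean, flagged = detect_chimeras(s)
        assert len(flagged) == 0

    def test_most_abundant_read_always_clean(self, rng):
        A, B, q = self._build(rng)
        s = make_set([(q, 50), (A, 10), (B, 8)])
        clean, flagged = detect_chimeras(s)
        assert q in {a.seq for a in clean}

    def test_matches_exhaustive_oracle_on_random_sets(self, rng):
        """Flag/no-flag agrees with the exhaustive pair x crossover scan."""
        for trial in range(15):
            base = random_dna(rng, 80)
            A = base
            B = mutate(rng, base, rng.randint(4, 12))
            cross = rng.randint(10, 70)
            others = [mutate(rng, base, 1) for _ in range(2)]
            q = A[:cross] + B[cross:]
            if q in (A, B):
                continue
            entries = [(A, 20), (B, 15)] + [(o, 5) for o in others] + [(q, 1)]
            entries = list({seq: ab for seq, ab in entries}.items())
            s = make_set(entries)
            clean, flagged = detect_chimeras(s, 2, 3)
            parents = [seq for seq, ab in entries if ab > 1]
            assert (q in {a.seq for a in flagged}) == chimera_oracle(q, parents, 2, 3)

    def test_empty_input(self):
        clean, flagged = detect_chimeras(SampleSet([]))
        assert len(clean) == len(flagged) == 0


class TestThreeStepFilter:
    def test_zero_noise_rejects_nothing(self):
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 1, 3, [0.2], seed=2)
        model = ErrorModel(0.0, 0.0, 0.0, seed=1)
        reads, _ = simulate_reads(pool, 500, model)
        clean, flagged, report = three_step_filter(reads, DEFAULT_PRIMERS["V9"])
        assert clean.total_abundance == 500
        assert len(flagged) == 0
        assert len(clean) == len(pool)

    def test_counts_monotone_and_reasons_reconcile(self):
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 0, seed=2)
        reads, _ = simulate_reads(pool, 1000, ErrorModel(seed=9))
        clean, flagged, report = three_step_filter(reads, DEFAULT_PRIMERS["V9"])
        totals = [report.counts[s][0] for s in report.stage_order]
        assert totals == sorted(totals, reverse=True)
        # primer-stage losses reconcile with per-read reasons
        primer_reasons = sum(
            1 for r in report.reasons.values() if not r.startswith("chimera")
        )
        assert totals[0] - totals[1] == primer_reasons
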