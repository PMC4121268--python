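import pytest

from ribocell.linkage import (
    VariantPattern,
    _window_starts,
    build_consensus,
    call_snps,
    filter_patterns,
    pattern_overlap,
    window_patterns,
)
from ribocell.model import dereplicate
from ribocell.simulate import (
    ErrorModel,
    default_hotspot,
    default_template,
    make_ribotype_pool,
    simulate_reads,
    simulate_replicates,
)

from conftest import make_set, mutate, random_dna


class TestConsensus:
    def test_majority_wins(self):
        s = make_set([("ACGT", 10), ("ACGA", 1)])
        assert build_consensus(s).consensus == "ACGT"

    def test_column_tie_broken_in_base_order(self):
        s = make_set([("AACA", 5), ("AAGA", 5)])
        # column 2 ties C=5 vs G=5; C wins by A<C<G<T
        assert build_consensus(s).consensus == "AACA"

    def test_abundance_weighted(self):
        s = make_set([("AAAA", 3), ("AATA", 2), ("AACA", 2)])
        assert build_consensus(s).consensus == "AAAA"

    def test_empty_rejected(self):
        from ribocell.model import SampleSet

        with pytest.raises(ValueError):
            build_consensus(SampleSet([]))

    def test_recovers_template_from_noisy_reads(self):
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 0, seed=2)
        hits = 0
        for seed in range(20):
            reads, _ = simulate_reads(pool, 800, ErrorModel(seed=seed))
            profile = build_consensus(dereplicate(reads))
            hits += profile.consensus == template
        assert hits >= 19


class TestCallSnps:
    def test_consensus_read_has_empty_site_set(self, rng):
        base = random_dna(rng, 80)
        s = make_set([(base, 10), (mutate(rng, base, 2), 1)])
        profile = build_consensus(s)
        calls = call_snps(s, profile)
        assert calls.sites[s.amplicons[0].id] == ()

    def test_sites_listed_in_column_order(self):
        base = "A" * 100
        var = base[:12] + "C" + base[13:70] + "T" + base[71:]
        s = make_set([(base, 10), (var, 1)])
        calls = call_snps(s, build_consensus(s))
        assert calls.sites[s.amplicons[1].id] == ((12, "C"), (70, "T"))

    def test_indel_reads_flagged_separately(self, rng):
        base = random_dna(rng, 80)
        deleted = base[:40] + base[41:]
        s = make_set([(base, 10), (deleted, 1)])
        calls = call_snps(s, build_consensus(s))
        assert s.amplicons[1].id in calls.indel_reads
        assert s.amplicons[1].id not in calls.sites

    def test_called_sites_match_truth_for_indel_free_reads(self):
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 0, seed=2)
        reads, truth = simulate_reads(pool, 1000, ErrorModel(seed=4))
        d = dereplicate(reads)
        profile = build_consensus(d)
        calls = call_snps(d, profile)
        assert profile.consensus == template
        truth_by_id = truth.by_id()
        raw_by_seq = {}
        for a, rec in zip(reads, truth.records):
            raw_by_seq.setdefault(a.seq, rec)
        for a in d:
            if a.id in calls.indel_reads:
                continue
            rec = raw_by_seq[a.seq]
            if rec.indels:
                continue
            expected = tuple((p, to) for p, frm, to in sorted(rec.subs))
            assert calls.sites[a.id] == expected


class TestWindows:
    def test_default_tiling_on_130bp(self):
        assert _window_starts(50, 25, 130) == [0, 25, 50, 75, 100]

    def test_window_equal_length_single_window(self):
        assert _window_starts(60, 30, 60) == [0]

    def test_pattern_grouping_and_support(self, rng):
        base = random_dna(rng, 100)
        var = mutate(rng, base, 2)
        s = make_set([(base, 1500), (var, 2)])
        calls = call_snps(s, build_consensus(s))
        patterns = window_patterns(calls, s, window=50, step=25)
        assert len(patterns) == 2
        assert patterns[0].is_consensus and patterns[0].support == 1500
        assert patterns[1].support == 2
        assert patterns[0].window_hits == ()

    def test_window_hits_annotate_site_columns(self):
        base = "A" * 130
        var = base[:10] + "C" + base[11:120] + "G" + base[121:]
        s = make_set([(base, 10), (var, 1)])
        calls = call_snps(s, build_consensus(s))
        patterns = window_patterns(calls, s, window=50, step=25)
        hits = next(p for p in patterns if p.sites).window_hits
        assert hits == (0, 3, 4)  # col 10 in [0,50); col 120 in [75,125),[100,130)

    def test_supports_partition_total_abundance(self, rng):
        base = random_dna(rng, 90)
        entries = [(base, 50)] + [(mutate(rng, base, rng.randint(1, 3)), rng.randint(1, 4))
                                  for _ in range(8)]
        s = dereplicate(make_set(entries))
        calls = call_snps(s, build_consensus(s))
        patterns = window_patterns(calls, s, window=45, step=15)
        gapless_total = sum(
            a.abundance for a in s if a.id not in calls.indel_reads
        )
        assert sum(p.support for p in patterns) == gapless_total

    def test_per_window_fragmentation(self):
        base = "A" * 100
        v1 = base[:10] + "C" + base[11:80] + "G" + base[81:]
        v2 = base[:10] + "C" + base[11:]
        s = make_set([(base, 10), (v1, 1), (v2, 1)])
        calls = call_snps(s, build_consensus(s))
        frags = window_patterns(calls, s, window=50, step=50, fragment_by_window=True)
        # both variants share the col-10 fragment in window 0
        shared = next(p for p in frags if p.sites == ((10, "C"),))
        assert shared.support == 2


class TestFilterPatterns:
    def _pat(self, sites, support):
        return VariantPattern(tuple(sites), ("r",), (), support)

    def test_redundancy_rule(self):
        pats = [
            self._pat([], 1500),
            self._pat([(3, "C")], 2),
            self._pat([(5, "G")], 1),
            self._pat([(9, "T")], 1),
            self._pat([(2, "A")], 1),
        ]
        report = filter_patterns(pats, 2)
        assert report.n_patterns == 2
        assert report.n_discarded == 3
        assert report.discarded_support == 3

    def test_consensus_always_retained(self):
        pats = [self._pat([], 1), self._pat([(3, "C")], 1)]
        report = filter_patterns(pats, 2)
        assert report.n_patterns == 1
        assert report.retained[0].is_consensus

    def test_min_support_must_encode_redundancy(self):
        with pytest.raises(ValueError):
            filter_patterns([], 1)

    def test_zero_noise_two_ribotype_recovery(self):
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 1, 3, [0.2],
                                  hotspot=default_hotspot("V9"), seed=2)
        reads, _ = simulate_reads(pool, 500, ErrorModel(0.0, 0.0, 0.0, seed=3))
        d = dereplicate(reads)
        calls = call_snps(d, build_consensus(d))
        patterns = window_patterns(calls, d)
        report = filter_patterns(patterns, 2)
        assert report.n_patterns == 2
        minor = next(p for p in report.retained if p.sites)
        assert len(minor.sites) == 3

    def test_multisite_error_patterns_discarded(self):
        """Identical >=2-site error combinations essentially never recur, so
        redundancy filtering removes them (single-site collisions do recur
        at realistic depth and are the method's known blind spot)."""
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 0, seed=2)
        kept = discarded = 0
        for seed in range(10):
            reads, _ = simulate_reads(pool, 2000, ErrorModel(seed=seed))
            d = dereplicate(reads)
            calls = call_snps(d, build_consensus(d))
            patterns = window_patterns(calls, d)
            report = filter_patterns(patterns, 2)
            kept += sum(p.support for p in report.retained if len(p.sites) >= 2)
            discarded += sum(
                p.support for p in patterns
                if len(p.sites) >= 2 and p not in report.retained
            )
        assert discarded / (kept + discarded) >= 0.99


class TestOverlap:
    def test_identical_reports_fully_overlap(self, rng):
        base = random_dna(rng, 90)
        s = make_set([(base, 50), (mutate(rng, base, 2), 3)])
        calls = call_snps(s, build_consensus(s))
        report = filter_patterns(window_patterns(calls, s, 45, 15), 2, anchor=base)
        assert pattern_overlap(report, report) == report.n_patterns

    def test_incompatible_anchors_rejected(self, rng):
        r1 = filter_patterns([], 2, anchor="AAAA")
        r2 = filter_patterns([], 2, anchor="CCCC")
        with pytest.raises(ValueError, match="anchor"):
            pattern_overlap(r1, r2)

    def test_planted_pattern_overlaps_between_replicates(self):
        template = default_template("V9", seed=1)
        pool = make_ribotype_pool(template, 1, 3, [0.25],
                                  hotspot=default_hotspot("V9"), seed=2)
        hits = 0
        for seed in range(10):
            rep1, rep2, _, _ = simulate_replicates(pool, 1500, ErrorModel(seed=seed))
            reports = []
            for rep in (rep1, rep2):
                d = dereplicate(rep)
                profile = build_consensus(d)
                calls = call_snps(d, profile)
                pats = window_patterns(calls, d)
                reports.append(filter_patterns(pats, 2, anchor=profile.anchor))
            minor_sites = {
                tuple(
                    (i, pool[1].seq[i])
                    for i in range(len(template))
                    if pool[1].seq[i] != template[i]
                )
            }
            retained = [{p.sites for p in r.retained} for r in reports]
            if minor_sites <= retained[0] & retained[1]:
                hits += pattern_overlap(reports[0], reports[1]) >= 2
        assert hits >= 9
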