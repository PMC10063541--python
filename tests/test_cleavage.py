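"""Cleavage-site caller: profile construction, score arithmetic, class rules,
genome-wide scan against planted truth, and the off-target candidate filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nickedit import cleavage as clv
from nickedit import synthio as syn
from nickedit.sites import DigestionModel, hamming, revcomp


def reads_frame(rows):
    """rows: (start, length, is_reverse) on chr1."""
    return pd.DataFrame(
        {
            "contig": ["chr1"] * len(rows),
            "start": [r[0] for r in rows],
            "length": [r[1] for r in rows],
            "is_reverse": [r[2] for r in rows],
        }
    )


def profile_with(fwd=(), rev=(), depth_fwd=(), depth_rev=(), n=300):
    """Hand-built profile: sparse {pos: count} mappings."""
    p = clv.StrandStartProfile(
        contig="chr1", start=0, end=n,
        fwd_starts=np.zeros(n, np.int32), rev_starts=np.zeros(n, np.int32),
        fwd_depth=np.zeros(n, np.int32), rev_depth=np.zeros(n, np.int32),
    )
    for pos, c in dict(fwd).items():
        p.fwd_starts[pos] = c
    for pos, c in dict(rev).items():
        p.rev_starts[pos] = c
    for pos, c in dict(depth_fwd).items():
        p.fwd_depth[pos] = c
    for pos, c in dict(depth_rev).items():
        p.rev_depth[pos] = c
    return p


class TestBuildStartProfile:
    def test_empty_alignments_all_zero(self):
        prof = clv.build_start_profile(reads_frame([]), ("chr1", 0, 100))
        assert prof.fwd_starts.sum() == 0
        assert prof.rev_depth.sum() == 0

    def test_forward_reads_hand_counted(self):
        rows = [(100, 50, False)] * 5
        prof = clv.build_start_profile(reads_frame(rows), ("chr1", 0, 200))
        assert prof.fwd_starts[100] == 5
        assert prof.fwd_starts.sum() == 5
        assert prof.fwd_depth[120] == 5
        assert prof.fwd_depth[99] == 0 and prof.fwd_depth[150] == 0
        assert prof.rev_starts.sum() == 0 and prof.rev_depth.sum() == 0

    def test_reverse_read_five_prime_is_rightmost_base(self):
        prof = clv.build_start_profile(reads_frame([(200, 50, True)]), ("chr1", 0, 300))
        assert prof.rev_starts[249] == 1
        assert prof.rev_starts.sum() == 1
        assert prof.rev_depth[200] == 1 and prof.rev_depth[249] == 1
        assert prof.rev_depth[250] == 0

    def test_starts_never_exceed_depth(self, small_digest):
        genome, _, reads = small_digest
        prof = clv.build_start_profile(reads, ("chr1", 0, 100_000))
        assert (prof.fwd_starts <= prof.fwd_depth).all()
        assert (prof.rev_starts <= prof.rev_depth).all()

    def test_unknown_contig_rejected(self, small_digest):
        _, _, reads = small_digest
        with pytest.raises(ValueError, match="unknown contig"):
            clv.build_start_profile(reads, ("chrX", 0, 100))


class TestStrandScore:
    @pytest.mark.parametrize(
        "f,d,score,frac",
        [
            (0, 30, 0.0, 0.0),
            (20, 20, 20.0, 1.0),
            (4, 40, 0.4, 0.1),  # sub-threshold at the default 8.0
        ],
    )
    def test_score_arithmetic(self, f, d, score, frac):
        prof = profile_with(fwd={50: f}, depth_fwd={50: d})
        s, fr = clv.strand_cleavage_score(prof, 50, clv.FORWARD)
        assert s == pytest.approx(score)
        assert fr == pytest.approx(frac)

    def test_gates_zero_the_score_not_the_fraction(self):
        prof = profile_with(fwd={50: 2}, depth_fwd={50: 30})
        s, fr = clv.strand_cleavage_score(prof, 50, clv.FORWARD)  # F < 3
        assert s == 0.0 and fr == pytest.approx(2 / 30)
        prof = profile_with(fwd={50: 5}, depth_fwd={50: 5})
        s, fr = clv.strand_cleavage_score(prof, 50, clv.FORWARD)  # D < 10
        assert s == 0.0 and fr == 1.0

    def test_zero_depth_is_zero_not_nan(self):
        prof = profile_with()
        s, fr = clv.strand_cleavage_score(prof, 10, clv.REVERSE)
        assert s == 0.0 and fr == 0.0

    def test_position_outside_region_rejected(self):
        prof = profile_with(n=100)
        with pytest.raises(ValueError, match="outside profile region"):
            clv.strand_cleavage_score(prof, 100, clv.FORWARD)


class TestClassifyPosition:
    def make(self, f, r):
        # depth 20 on both strands at the paired positions
        return profile_with(
            fwd={100: f}, rev={99: r},
            depth_fwd={100: 20}, depth_rev={99: 20},
        )

    def test_decision_rules(self):
        # scores are F^2/20
        assert clv.classify_position(self.make(18, 16), 100).call_class == clv.DSB
        assert clv.classify_position(self.make(18, 2), 100).call_class == clv.NICK_FORWARD
        assert clv.classify_position(self.make(2, 16), 100).call_class == clv.NICK_REVERSE
        assert clv.classify_position(self.make(2, 2), 100).call_class == clv.NONE

    def test_dsb_requires_both_strands_at_threshold(self):
        # rev score 12.8 >= 8, fwd score 7.2 < 8 -> nick_reverse, not dsb
        call = clv.classify_position(self.make(12, 16), 100)
        assert call.score_fwd == pytest.approx(7.2)
        assert call.call_class == clv.NICK_REVERSE

    def test_pair_offset_tolerance_finds_shifted_rev_peak(self):
        prof = profile_with(fwd={100: 18}, rev={97: 16},
                            depth_fwd={100: 20}, depth_rev={97: 20})
        strict = clv.classify_position(prof, 100, clv.CallerParams())
        assert strict.call_class == clv.NICK_FORWARD
        loose = clv.classify_position(
            prof, 100, clv.CallerParams(pair_offset_tolerance=2)
        )
        assert loose.call_class == clv.DSB


class TestPartialTargetCleavageSweep:
    def test_reverse_score_monotone_and_single_class_transition(self):
        """Leaky-HNH phenotype: non-target strand always cut, target strand
        with probability q.  The reverse-strand score must rise with q and
        the class must cross nick_forward -> dsb exactly once."""
        qs = [0.0, 0.25, 0.5, 0.75, 1.0]
        for seed in (61, 62, 63):
            spec = syn.SiteSpec("s1", "chr1", 25_000, "+")
            g = syn.make_toy_genome(1, 50_000, [spec], seed=seed)
            cut = g.planted_sites[0].cut_pos
            rev_scores, classes = [], []
            for q in qs:
                reads = syn.simulate_digested_reads(
                    g, {"s1": DigestionModel(1.0, q)},
                    syn.FragmentationParams(depth=40, seed=seed),
                )
                prof = clv.build_start_profile(reads, ("chr1", 0, 50_000))
                call = clv.classify_position(prof, cut)
                rev_scores.append(call.score_rev)
                classes.append(call.call_class)
            assert all(b >= a for a, b in zip(rev_scores, rev_scores[1:]))
            rho = stats.spearmanr(qs, rev_scores).statistic
            assert rho >= 0.95
            transitions = sum(a != b for a, b in zip(classes, classes[1:]))
            assert classes[0] == clv.NICK_FORWARD
            assert classes[-1] == clv.DSB
            assert transitions == 1


class TestScanGenome:
    def test_recovers_planted_sites_exactly(self, small_digest):
        genome, models, reads = small_digest
        calls = clv.scan_genome(reads, genome)
        expected = {
            s.cut_pos: {"dsb": clv.DSB, "nickf": clv.NICK_FORWARD,
                        "nickr": clv.NICK_REVERSE}[s.name.split("_")[0]]
            for s in genome.planted_sites
        }
        assert {c.cut_pos: c.call_class for c in calls} == expected

    def test_no_enzyme_no_calls(self):
        specs, _ = syn.planted_site_layout("chr1", 60_000, 1, 1, 1, margin=3000)
        g = syn.make_toy_genome(1, 60_000, specs, seed=71)
        models = {s.name: DigestionModel(0.0, 0.0) for s in g.planted_sites}
        reads = syn.simulate_digested_reads(g, models, syn.FragmentationParams(seed=71))
        assert clv.scan_genome(reads, g) == []

    def test_scan_deterministic(self, small_digest):
        genome, _, reads = small_digest
        assert clv.scan_genome(reads, genome) == clv.scan_genome(reads, genome)

    def test_contig_mismatch_rejected(self, small_digest):
        _, _, reads = small_digest
        with pytest.raises(ValueError, match="chr1"):
            clv.scan_genome(reads, {"chr2": "ACGT" * 100})

    def test_sparse_scan_equals_dense_classification(self):
        """On a small region the sparse candidate scan must reproduce a
        brute-force classification of every coordinate."""
        spec = [syn.SiteSpec("a", "chr1", 3000, "+"), syn.SiteSpec("b", "chr1", 7000, "-")]
        g = syn.make_toy_genome(1, 10_000, spec, seed=81)
        models = {"a": DigestionModel.wt(), "b": DigestionModel.nickase()}
        reads = syn.simulate_digested_reads(g, models, syn.FragmentationParams(seed=81))
        sparse = clv.scan_genome(reads, g)

        prof = clv.build_start_profile(reads, ("chr1", 0, 10_000))
        dense = [
            c
            for cut in range(1, 10_000)
            for c in [clv.classify_position(prof, cut)]
            if c.call_class != clv.NONE
        ]
        merged = []
        for c in sorted(dense, key=lambda c: c.cut_pos):
            if merged and c.cut_pos - merged[-1].cut_pos <= 3:
                if c.max_score > merged[-1].max_score:
                    merged[-1] = c
            else:
                merged.append(c)
        assert sparse == merged

    def test_est_fraction_tracks_high_cleavage_probabilities(self):
        """Mean |est - truth| <= 0.1 at 30x for p in {0.9, 1.0} over 10 sites."""
        specs, _ = syn.planted_site_layout("chr1", 400_000, 10, 0, 0, margin=5000)
        g = syn.make_toy_genome(1, 400_000, specs, seed=91)
        probs = [0.9 if i % 2 == 0 else 1.0 for i in range(10)]
        models = {
            s.name: DigestionModel(p, p) for s, p in zip(g.planted_sites, probs)
        }
        reads = syn.simulate_digested_reads(g, models, syn.FragmentationParams(seed=91))
        prof = clv.build_start_profile(reads, ("chr1", 0, 400_000))
        errs = []
        for site, p in zip(g.planted_sites, probs):
            call = clv.classify_position(prof, site.cut_pos)
            errs.append(abs(call.est_fraction_fwd - p))
            errs.append(abs(call.est_fraction_rev - p))
        assert np.mean(errs) <= 0.1


class TestCallCounting:
    def make_call(self, cls, cut=100, s1=10.0, s2=10.0):
        return clv.CleavageCall("chr1", cut, s1, s2, cls, 0.5, 0.5)

    def test_empty(self):
        assert clv.count_calls_by_class([]) == {
            clv.DSB: 0, clv.NICK_FORWARD: 0, clv.NICK_REVERSE: 0, clv.NONE: 0
        }

    def test_mixed_list(self):
        calls = [self.make_call(clv.DSB)] * 2 + [self.make_call(clv.NICK_FORWARD)] * 3
        counts = clv.count_calls_by_class(calls)
        assert (counts[clv.DSB], counts[clv.NICK_FORWARD],
                counts[clv.NICK_REVERSE], counts[clv.NONE]) == (2, 3, 0, 0)

    def test_replicate_summary_sem_zero_for_identical_replicates(self):
        reps = [[self.make_call(clv.DSB)] * 4 for _ in range(3)]
        table = clv.summarize_replicate_calls(reps)
        assert table.loc[clv.DSB, "mean"] == 4
        assert table.loc[clv.DSB, "sem"] == 0


@pytest.fixture(scope="module")
def planted():
    specs = [syn.SiteSpec("on", "chr1", 10_000, "+")]
    offs = [
        syn.OfftargetSpec("ot6", "on", "chr1", 40_000, "+", mismatches=6),
        syn.OfftargetSpec("ot7", "on", "chr1", 70_000, "-", mismatches=7),
    ]
    return syn.make_toy_genome(1, 100_000, specs, offs, seed=101)


class TestOfftargetCandidates:

    def test_on_target_found_with_zero_mismatches(self, planted):
        g = planted
        spacer = g.planted_sites[0].protospacer
        hits = clv.find_offtarget_candidates(g, spacer, max_mismatch=6)
        on = [h for h in hits if h.site.cut_pos == g.planted_sites[0].cut_pos]
        assert len(on) == 1 and on[0].mismatch_count == 0
        assert on[0].site.protospacer == spacer

    def test_six_mismatch_found_seven_absent(self, planted):
        g = planted
        spacer = g.planted_sites[0].protospacer
        hits = clv.find_offtarget_candidates(g, spacer, max_mismatch=6)
        cuts = {h.site.cut_pos: h for h in hits}
        ot6 = g.site_by_name("ot6")
        ot7 = g.site_by_name("ot7")
        assert cuts[ot6.cut_pos].mismatch_count == 6
        assert ot7.cut_pos not in cuts
        # brute-force cross-check on the planted '-' site
        assert hamming(ot7.protospacer, spacer) == 7

    def test_minus_strand_site_found(self):
        specs = [syn.SiteSpec("on", "chr1", 5_000, "-")]
        g = syn.make_toy_genome(1, 20_000, specs, seed=102)
        site = g.planted_sites[0]
        hits = clv.find_offtarget_candidates(g, site.protospacer, max_mismatch=0)
        assert any(
            h.site.cut_pos == site.cut_pos and h.site.site_strand == "-" for h in hits
        )

    def test_genome_without_pam_yields_nothing(self):
        genome = {"chr1": "AT" * 500}
        assert clv.find_offtarget_candidates(genome, "A" * 20, 6) == []

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="20 nt"):
            clv.find_offtarget_candidates({"chr1": "A" * 100}, "ACGT", 6)
        with pytest.raises(ValueError, match="0..8"):
            clv.find_offtarget_candidates({"chr1": "A" * 100}, "A" * 20, 9)


class TestFilterAndAnnotate:
    def cand(self, cut, strand="+", mm=0, proto="A" * 20):
        from nickedit.sites import TargetSite

        site = TargetSite(f"c{cut}", "chr1", proto, "AGG", strand, cut)
        return clv.OfftargetCandidate(site, mm)

    def call(self, cut, cls=clv.DSB, score=12.0):
        return clv.CleavageCall("chr1", cut, score, score, cls, 1.0, 1.0)

    def test_score_below_threshold_excluded_at_boundary(self):
        cands = [self.cand(100)]
        kept = clv.filter_and_annotate(
            [clv.CleavageCall("chr1", 100, 7.9, 7.9, clv.DSB, 1, 1)], cands
        )
        assert kept == []
        kept = clv.filter_and_annotate(
            [clv.CleavageCall("chr1", 100, 8.0, 8.0, clv.DSB, 1, 1)], cands
        )
        assert len(kept) == 1

    def test_mismatch_cutoff_applied(self):
        calls = [self.call(100), self.call(500)]
        cands = [self.cand(100, mm=6), self.cand(500, mm=7)]
        kept = clv.filter_and_annotate(calls, cands, max_mismatch=6)
        assert [c.cut_pos for c in kept] == [100]
        assert kept[0].annotation.mismatch_count == 6

    def test_cut_position_tolerance(self):
        kept = clv.filter_and_annotate([self.call(102)], [self.cand(100)])
        assert len(kept) == 1  # within +/- 2 bp
        assert clv.filter_and_annotate([self.call(103)], [self.cand(100)]) == []

    def test_biological_strand_annotation(self):
        # nick on the forward genomic strand of a '-' site = target-strand nick
        kept = clv.filter_and_annotate(
            [self.call(100, clv.NICK_FORWARD)], [self.cand(100, strand="-")]
        )
        assert kept[0].annotation.nick_strand == "target"
        kept = clv.filter_and_annotate(
            [self.call(100, clv.NICK_FORWARD)], [self.cand(100, strand="+")]
        )
        assert kept[0].annotation.nick_strand == "non_target"
        kept = clv.filter_and_annotate(
            [self.call(100, clv.NICK_REVERSE)], [self.cand(100, strand="+")]
        )
        assert kept[0].annotation.nick_strand == "target"
        kept = clv.filter_and_annotate([self.call(100, clv.DSB)], [self.cand(100)])
        assert kept[0].annotation.nick_strand is None
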