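"""Gene calling: ORF enumeration, alpha scoring, starts, products, categories."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phagepipe as pp
from phagepipe.annotate import (
    GeneCall,
    GeneContext,
    AlphaScore,
    build_context,
    coding_potential,
    assign_tail_assembly_by_synteny,
)
from phagepipe.records import GenomeRecord


class TestEnumerateOrfs:
    def test_minimal_plus_strand_orf(self):
        g = GenomeRecord(id="x", seq="ATG" + "AAA" * 24 + "TAA", topology="linear")
        cands = pp.enumerate_orfs(g, min_len=60)
        plus = [c for c in cands if c.strand == "+"]
        assert len(plus) == 1
        assert plus[0].starts == [1]
        assert plus[0].stop == 78

    def test_truth_genes_all_enumerated(self, default_genome):
        genome, truth = default_genome
        cands = pp.enumerate_orfs(genome)
        keys = {(c.strand, c.stop): set(c.starts) for c in cands}
        for s, e, strand in truth.gene_intervals:
            key = (strand, e if strand == "+" else s)
            start = s if strand == "+" else e
            assert key in keys and start in keys[key]

    def test_min_len_respected(self, small_genome):
        genome, _ = small_genome
        for c in pp.enumerate_orfs(genome, min_len=75):
            assert all(c.length(s) >= 75 for s in c.starts)

    def test_orf_crossing_origin_found(self):
        body = "ATG" + "GCA" * 30 + "TAA"
        filler = "C" * 1000
        seq = body[50:] + filler + body[:50]  # gene wraps the origin
        g = GenomeRecord(id="x", seq=seq, topology="circular_permuted")
        cands = pp.enumerate_orfs(g, min_len=75)
        wrapped = [c for c in cands if c.strand == "+" and len(seq) - 50 + 1 in c.starts]
        assert wrapped


class TestCodingPotential:
    def test_truth_genes_high_coverage(self, default_genome):
        genome, truth = default_genome
        cands = pp.enumerate_orfs(genome)
        cov = coding_potential(genome, cands)
        truth_keys = {
            (strand, e if strand == "+" else s) for s, e, strand in truth.gene_intervals
        }
        truth_cov = [cov[k] for k in truth_keys]
        assert np.mean([c >= 0.8 for c in truth_cov]) >= 0.9

    def test_decoys_low_coverage(self, default_genome):
        genome, truth = default_genome
        cands = pp.enumerate_orfs(genome)
        cov = coding_potential(genome, cands)
        truth_keys = {
            (strand, e if strand == "+" else s) for s, e, strand in truth.gene_intervals
        }
        decoy_cov = [v for k, v in cov.items() if k not in truth_keys]
        assert np.median(decoy_cov) < 0.5

    def test_deterministic(self, small_genome):
        genome, _ = small_genome
        cands = pp.enumerate_orfs(genome)
        assert coding_potential(genome, cands) == coding_potential(genome, cands)


class TestAlphaScore:
    def test_maximal_evidence_scores_23(self):
        cand = pp.OrfCandidate(genome_id="g", strand="+", stop=1200, starts=[1])
        ev = {"caller_count": 6, "coding_coverage": 1.0, "best_hit": (1e-30, 150, "portal protein")}
        ctx = GeneContext(prev_gap=150, next_gap=-4, operon_overlap=True)
        score = pp.score_orf_alpha(cand, ev, ctx)
        assert (score.a, score.b, score.c, score.d, score.e) == (6, 5, 5, 5, 2)
        assert score.total == 23

    def test_zero_evidence_scores_low(self):
        cand = pp.OrfCandidate(genome_id="g", strand="+", stop=300, starts=[1])
        score = pp.score_orf_alpha(
            cand, {"caller_count": 0, "coding_coverage": 0.0, "best_hit": None}, GeneContext()
        )
        assert score.a == score.b == score.c == score.e == 0

    def test_heavy_overlap_zeroes_d(self):
        cand = pp.OrfCandidate(genome_id="g", strand="+", stop=300, starts=[1])
        score = pp.score_orf_alpha(
            cand, {"caller_count": 0, "coding_coverage": 0.0, "best_hit": None},
            GeneContext(prev_gap=-40),
        )
        assert score.d == 0

    def test_monotone_in_every_evidence_dimension(self):
        """alpha never decreases as any single evidence component improves."""
        cand = pp.OrfCandidate(genome_id="g", strand="+", stop=600, starts=[1])
        ctx = GeneContext()
        callers = range(0, 7)
        coverages = [0.0, 0.25, 0.5, 0.75, 1.0]
        hits = [None, (1e-2, 80, "p"), (1e-4, 80, "p"), (1e-8, 80, "p"),
                (1e-12, 80, "p"), (1e-25, 80, "p"), (1e-25, 150, "p")]

        def total(cc, cov, hit):
            return pp.score_orf_alpha(
                cand, {"caller_count": cc, "coding_coverage": cov, "best_hit": hit}, ctx
            ).total

        for cov in coverages:
            for hit in hits:
                vals = [total(cc, cov, hit) for cc in callers]
                assert vals == sorted(vals)
        for cc in callers:
            for hit in hits:
                vals = [total(cc, cov, hit) for cov in coverages]
                assert vals == sorted(vals)
        for cc in callers:
            for cov in coverages:
                vals = [total(cc, cov, hit) for hit in hits]
                assert vals == sorted(vals)


class TestSelectGenes:
    def _cand(self, lo, hi, strand="+"):
        if strand == "+":
            return pp.OrfCandidate(genome_id="g", strand="+", stop=hi, starts=[lo])
        return pp.OrfCandidate(genome_id="g", strand="-", stop=lo, starts=[hi])

    def _alpha(self, total):
        return AlphaScore(a=min(total, 6), b=max(0, min(total - 6, 5)), c=max(0, total - 11))

    def test_alpha_at_cutoff_kept(self):
        kept, _ = pp.select_genes([(self._cand(1, 300), self._alpha(8))], cutoff=8)
        assert len(kept) == 1

    def test_below_cutoff_dropped(self):
        kept, _ = pp.select_genes([(self._cand(1, 300), self._alpha(7))], cutoff=8)
        assert kept == []

    def test_conflict_resolved_by_alpha(self):
        a = self._cand(1, 600)
        b = self._cand(500, 1100)  # 101-bp overlap with a
        kept, _ = pp.select_genes([(a, self._alpha(9)), (b, self._alpha(15))], cutoff=8)
        assert [c.stop for c, _ in kept] == [1100]

    def test_short_single_caller_flagged(self):
        cand = self._cand(1, 150)
        score = AlphaScore(a=1, b=5, c=5)  # alpha 11, one caller, short
        kept, report = pp.select_genes([(cand, score)], cutoff=8, genome_len=2000)
        assert len(kept) == 1
        assert report["flagged_single_caller"] == [("+", 150)]
        assert report["flagged_short"] == [("+", 150)]

    def test_large_coding_gap_reported(self):
        kept, report = pp.select_genes(
            [(self._cand(1, 300), self._alpha(12)), (self._cand(551, 900), self._alpha(12))],
            cutoff=8,
            genome_len=900,
        )
        assert report["coding_gaps"] == [(301, 550)]


class TestShineDalgarno:
    def test_perfect_consensus(self):
        upstream = "C" * 7 + "AGGAGG" + "C" * 7  # spacer 7
        assert pp.shine_dalgarno_score(upstream) == 6

    def test_all_c_window_zero(self):
        assert pp.shine_dalgarno_score("C" * 20) == 0

    def test_spacer_2_only_partial_credit(self):
        # motif sits at spacer 2, outside the allowed 4-14 range: the best
        # in-range placement catches only part of the consensus
        upstream = "C" * 12 + "AGGAGG" + "CC"
        brute = max(
            sum(x == y for x, y in zip(upstream[20 - sp - 6 : 20 - sp], "AGGAGG"))
            for sp in range(4, 15)
        )
        score = pp.shine_dalgarno_score(upstream)
        assert score < 6
        assert score == brute

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=20))
    def test_matches_brute_force_over_placements(self, upstream):
        brute = 0
        for spacer in range(4, 15):
            hi = 20 - spacer
            lo = hi - 6
            if lo < 0:
                seg = upstream[0:hi]
                cons = "AGGAGG"[-len(seg):]
            else:
                seg = upstream[lo:hi]
                cons = "AGGAGG"
            brute = max(brute, sum(x == y for x, y in zip(seg, cons)))
        assert pp.shine_dalgarno_score(upstream) == brute


class TestSelectStart:
    def test_single_start_trivial(self, small_genome):
        genome, _ = small_genome
        cand = pp.OrfCandidate(genome_id=genome.id, strand="+", stop=300, starts=[100])
        ev = pp.EvidenceBundle()
        chosen, table = pp.select_start(cand, ev, genome, [])
        assert chosen == 100

    def test_behind_rise_penalized(self, small_genome):
        genome, _ = small_genome
        cand = pp.OrfCandidate(genome_id=genome.id, strand="+", stop=400, starts=[100, 160])
        ev = pp.EvidenceBundle()
        ev.behind_rise[("+", 400, 160)] = True  # downstream start behind the rise
        chosen, _ = pp.select_start(cand, ev, genome, [])
        assert chosen == 100

    def test_exact_start_recovery_with_strong_evidence(self, default_genome, strong_evidence):
        genome, truth = default_genome
        genes, _ = pp.annotate_genome(genome, strong_evidence)
        truth_iv = {(s, e, strand) for s, e, strand in truth.gene_intervals}
        matched = [
            g for g in genes
            if (min(g.start, g.stop), max(g.start, g.stop), g.strand) in truth_iv
        ]
        truth_stops = {
            (strand, e if strand == "+" else s) for s, e, strand in truth.gene_intervals
        }
        found = [g for g in genes if (g.strand, g.stop) in truth_stops]
        assert len(matched) / max(1, len(found)) >= 0.90


class TestCodingFraction:
    def test_single_gene_direct(self):
        genes = [GeneCall(genome_id="g", start=1, stop=900, strand="+", alpha=AlphaScore())]
        assert pp.coding_fraction(1000, genes) == pytest.approx(0.90)

    def test_full_tiling_is_one(self):
        genes = [
            GeneCall(genome_id="g", start=1, stop=500, strand="+", alpha=AlphaScore()),
            GeneCall(genome_id="g", start=501, stop=1000, strand="+", alpha=AlphaScore()),
        ]
        assert pp.coding_fraction(1000, genes) == 1.0

    def test_out_of_bounds_rejected(self):
        genes = [GeneCall(genome_id="g", start=1, stop=1200, strand="+", alpha=AlphaScore())]
        with pytest.raises(ValueError):
            pp.coding_fraction(1000, genes)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 500), st.integers(0, 120)), max_size=12))
    def test_equals_position_bitmap_oracle(self, spans):
        L = 700
        genes = []
        bitmap = np.zeros(L, dtype=bool)
        for lo, ln in spans:
            hi = min(L, lo + ln)
            genes.append(
                GeneCall(genome_id="g", start=lo, stop=hi, strand="+", alpha=AlphaScore())
            )
            bitmap[lo - 1 : hi] = True
        assert pp.coding_fraction(L, genes) == pytest.approx(bitmap.mean())


class TestFunctionAssignment:
    @pytest.mark.parametrize(
        "hits,expected",
        [
            ([(1e-50, "hypothetical protein"), (1e-20, "portal protein")], "portal protein"),
            ([(1e-2, "portal protein")], "hypothetical protein"),
            ([], "hypothetical protein"),
            (
                [(1e-9, "tail fiber protein"), (1e-12, "holin"), (1e-4, "integrase")],
                "holin",
            ),
        ],
    )
    def test_lowest_e_non_hypothetical(self, hits, expected):
        assert pp.assign_function(hits) == expected

    def test_tail_assembly_synteny_applied(self):
        def mk(lo, hi, product):
            return GeneCall(
                genome_id="g", start=lo, stop=hi, strand="+",
                alpha=AlphaScore(), product=product,
            )

        genes = [
            mk(1, 600, "major tail protein"),
            mk(650, 900, "hypothetical protein"),
            mk(950, 1200, "hypothetical protein"),
            mk(1250, 4000, "tail tape measure protein"),
        ]
        out = assign_tail_assembly_by_synteny(genes)
        assert [g.product for g in out[1:3]] == ["tail assembly protein"] * 2

    def test_tail_assembly_synteny_not_met_with_three_between(self):
        def mk(lo, hi, product):
            return GeneCall(
                genome_id="g", start=lo, stop=hi, strand="+",
                alpha=AlphaScore(), product=product,
            )

        genes = [
            mk(1, 600, "major tail protein"),
            mk(650, 900, "hypothetical protein"),
            mk(950, 1100, "hypothetical protein"),
            mk(1150, 1300, "hypothetical protein"),
            mk(1350, 4000, "tail tape measure protein"),
        ]
        out = assign_tail_assembly_by_synteny(genes)
        assert all(g.product == "hypothetical protein" for g in out[1:4])

    def test_tail_assembly_anchors_absent_unchanged(self):
        g = GeneCall(
            genome_id="g", start=1, stop=300, strand="+",
            alpha=AlphaScore(), product="hypothetical protein",
        )
        assert assign_tail_assembly_by_synteny([g])[0].product == "hypothetical protein"

    @pytest.mark.parametrize(
        "product,category",
        [
            ("N-acetylmuramoyl-l-alanine amidase", "lysis"),
            ("XRE family transcriptional regulator", "regulation"),
            ("large terminase", "assembly"),
            ("major capsid protein", "virion_particle"),
            ("tail assembly protein", "assembly"),
            ("DNA polymerase", "replication"),
            ("HicA toxin", "host_related"),
            ("tRNA-Pro", "tRNA"),
            ("gp77 unknown widget", "unknown"),
        ],
    )
    def test_category_rules(self, product, category):
        assert pp.categorize_function(product) == category


class TestAnnotateGenome:
    def test_sensitivity_and_precision_on_strong_evidence(self, default_genome, strong_evidence):
        genome, truth = default_genome
        genes, report = pp.annotate_genome(genome, strong_evidence)
        truth_iv = {(s, e, strand) for s, e, strand in truth.gene_intervals}
        called_iv = {
            (min(g.start, g.stop), max(g.start, g.stop), g.strand) for g in genes
        }
        tp = len(truth_iv & called_iv)
        assert tp / len(truth_iv) >= 0.95
        assert tp / len(called_iv) >= 0.95

    def test_no_large_same_strand_overlaps(self, default_genome, strong_evidence):
        genome, _ = default_genome
        genes, _ = pp.annotate_genome(genome, strong_evidence)
        by_strand = {}
        for g in genes:
            by_strand.setdefault(g.strand, []).append(g.interval)
        for ivs in by_strand.values():
            ivs.sort()
            for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
                assert min(hi1, hi2) - lo2 + 1 <= 30

    def test_coding_fraction_close_to_truth(self, default_genome, strong_evidence):
        genome, truth = default_genome
        _, report = pp.annotate_genome(genome, strong_evidence)
        covered = np.zeros(len(genome), dtype=bool)
        for s, e, _ in truth.gene_intervals:
            covered[s - 1 : e] = True
        assert abs(report["coding_fraction"] - covered.mean()) < 0.05
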