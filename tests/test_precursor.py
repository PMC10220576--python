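import random

import numpy as np
import pytest

from mirphase.folding import fold
from mirphase.formats import RunConfig, revcomp
from mirphase.precursor import (
    GenomeHit,
    extract_candidate,
    find_clusters,
    find_precursors,
    locate_star,
    map_to_genome,
    score_candidate,
    trim_to_pre,
    _candidate_from_hit,
)
from mirphase.simulate import PLANTED_MATURES, hairpin_cassette

from oracles import brute_genome_scan

QUERY = PLANTED_MATURES["miR156"]


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMapToGenome:
    def test_exact_planting_single_hit(self):
        rng = random.Random(0)
        contig = _random_seq(rng, 5000) + QUERY + _random_seq(rng, 5000)
        hits = map_to_genome(QUERY, {"c": contig})
        exact = [h for h in hits if h.mismatches == 0 and h.gaps == 0]
        assert len(exact) == 1
        assert (exact[0].start, exact[0].end, exact[0].strand) == (5000, 5021, "+")

    def test_reverse_complement_planting_found_on_minus(self):
        rng = random.Random(1)
        contig = _random_seq(rng, 2000) + revcomp(QUERY) + _random_seq(rng, 2000)
        hits = [h for h in map_to_genome(QUERY, {"c": contig}) if h.gaps == 0]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert contig[hits[0].start : hits[0].end] == revcomp(QUERY)

    def test_substituted_plantings_all_found(self):
        rng = random.Random(2)
        variants = []
        for _ in range(3):
            v = list(QUERY)
            for i in rng.sample(range(len(v)), 2):
                v[i] = rng.choice([b for b in "ACGT" if b != v[i]])
            variants.append("".join(v))
        contig = _random_seq(rng, 500)
        starts = []
        for v in variants:
            starts.append(len(contig))
            contig += v + _random_seq(rng, 500)
        hits = [h for h in map_to_genome(QUERY, {"c": contig}) if h.strand == "+" and h.gaps == 0]
        assert {h.start for h in hits} >= set(starts)
        assert all(h.mismatches <= 2 for h in hits)

    def test_ungapped_hits_equal_sliding_window_oracle(self):
        rng = random.Random(3)
        contig = _random_seq(rng, 3000)
        for _ in range(5):  # plant exact + mutated copies
            pos = rng.randrange(0, 2900)
            v = list(QUERY)
            for i in rng.sample(range(len(v)), rng.randint(0, 2)):
                v[i] = rng.choice("ACGT")
            contig = contig[:pos] + "".join(v) + contig[pos + len(v):]
        got = {
            (h.start, h.end, h.mismatches)
            for h in map_to_genome(QUERY, {"c": contig})
            if h.strand == "+" and h.gaps == 0
        }
        expect = set(brute_genome_scan(QUERY, contig))
        assert got == expect

    def test_single_gap_plantings_found(self):
        rng = random.Random(4)
        deleted = QUERY[:8] + QUERY[9:]  # genome missing one base
        inserted = QUERY[:12] + "G" + QUERY[12:]  # genome carrying an extra base
        contig = (
            _random_seq(rng, 1000) + deleted + _random_seq(rng, 1000)
            + inserted + _random_seq(rng, 1000)
        )
        hits = map_to_genome(QUERY, {"c": contig})
        gapped = [h for h in hits if h.gaps == 1 and h.strand == "+"]
        assert any(h.start == 1000 and h.end - h.start == len(QUERY) - 1 for h in gapped)
        assert any(h.end - h.start == len(QUERY) + 1 for h in gapped)

    def test_short_contig_skipped(self):
        assert map_to_genome(QUERY, {"tiny": "ACGT"}) == []


class TestExtract:
    def test_internal_window_arithmetic(self):
        contig = "A" * 1000
        hit = GenomeHit("c", 500, 521, "+", 0)
        window, span, ws, we = extract_candidate(hit, contig, flank=100)
        assert len(window) == 221
        assert span == (100, 121)
        assert (ws, we) == (400, 621)

    def test_edge_clipping_uses_available_sequence(self):
        contig = "A" * 1000
        hit = GenomeHit("c", 10, 31, "+", 0)
        window, span, ws, we = extract_candidate(hit, contig, flank=100)
        assert ws == 0 and span == (10, 31)

    def test_minus_strand_window_is_reverse_complement(self):
        rng = random.Random(5)
        contig = _random_seq(rng, 400)
        hit = GenomeHit("c", 150, 171, "-", 0)
        window, span, ws, we = extract_candidate(hit, contig, flank=50)
        assert window == revcomp(contig[100:221])
        assert window[span[0] : span[1]] == revcomp(contig[150:171])


class TestStarAndTrim:
    def test_perfect_stem_star_matches_mature_length(self):
        db = "(" * 24 + "." * 8 + ")" * 24
        star = locate_star(db, (2, 22))
        assert star is not None
        assert star[1] - star[0] == 20
        assert star[0] >= 22  # 3' arm

    def test_mature_in_terminal_loop_has_no_star(self):
        db = "(" * 10 + "." * 24 + ")" * 10
        assert locate_star(db, (12, 32)) is None

    def test_star_span_follows_pairing_partners_through_bulge(self):
        # stem with a 2-nt bulge on the 3' arm inside the mature pairing region
        db = "(" * 20 + "....." + ")" * 10 + ".." + ")" * 10
        pt_star = locate_star(db, (0, 20))
        assert pt_star is not None
        s, e = pt_star
        # partners span positions 25..46; the 2-nt overhang shift is clipped
        # at the window edge, so the span is (25+2, min(47, 46+3))
        assert (s, e) == (27, 47)
        assert 18 <= e - s <= 22  # |mature| +/- bulge width

    def test_trim_cuts_after_first_bulge_beyond_duplex(self):
        # layout: outer stem 5 | bulge 3 | inner stem 7 | mature 20 | loop 6
        #         | star 20 | inner 7 | outer 5
        db = (
            "(" * 5 + "." * 3 + "(" * 7 + "(" * 20 + "." * 6
            + ")" * 20 + ")" * 7 + ")" * 5
        )
        mature = (15, 35)
        star = locate_star(db, mature)
        bounds = trim_to_pre(db, mature, star)
        assert bounds == (5, 68)  # bulge retained, resumed outer stem cut

    def test_clean_stem_to_window_edge_trims_at_edge(self):
        db = "(" * 30 + "." * 6 + ")" * 30
        mature = (5, 25)
        star = locate_star(db, mature)
        assert trim_to_pre(db, mature, star) == (0, 66)


class TestScoring:
    def _stub(self, seq, db, mfe, mature=(0, 21), star=(40, 61)):
        from mirphase.folding import FoldedStructure
        from mirphase.precursor import PrecursorCandidate

        return PrecursorCandidate(
            contig_id="c", strand="+", start=0, end=len(seq),
            pre_sequence=seq, structure=FoldedStructure(seq, db, mfe),
            mature_span=mature, star_span=star,
            hit=GenomeHit("c", 0, len(seq), "+", 0),
        )

    def test_mfei_formula(self):
        # MFE -50 kcal/mol over 100 nt at 50% GC -> AMFE 50, MFEI 1.0
        seq = ("GC" * 25 + "AU" * 25)
        db = "(" * 25 + "." * 50 + ")" * 25
        cand = self._stub(seq, db, -50.0)
        cand = score_candidate(cand)
        assert cand.amfe == pytest.approx(50.0)
        assert cand.gc_percent == pytest.approx(50.0)
        assert cand.mfei == pytest.approx(1.0)

    def test_mfei_scales_inversely_with_gc(self):
        seq_hi = "GC" * 50
        seq_lo = "GC" * 25 + "AU" * 25
        db = "." * 100
        hi = score_candidate(self._stub(seq_hi, db, -50.0))
        lo = score_candidate(self._stub(seq_lo, db, -50.0))
        assert hi.amfe == lo.amfe
        assert hi.mfei == pytest.approx(lo.mfei / 2)

    def test_mfei_just_below_threshold_fails(self):
        seq = "GC" * 25 + "AU" * 25  # GC 50%
        db = "(" * 21 + "." * 58 + ")" * 21
        cand = score_candidate(self._stub(seq, db, -42.0), RunConfig())
        assert cand.mfei == pytest.approx(0.84)
        assert not cand.passes
        assert "MFEI" in cand.fail_reason

    def test_zero_gc_fails_with_reason(self):
        seq = "AU" * 50
        cand = score_candidate(self._stub(seq, "." * 100, -10.0))
        assert not cand.passes
        assert "zero GC" in cand.fail_reason

    def test_designed_hairpin_cassette_passes(self):
        rng = random.Random(6)
        mature = PLANTED_MATURES["miR166"]
        cass, ms, me = hairpin_cassette(mature)
        contig = _random_seq(rng, 300) + cass + _random_seq(rng, 300)
        hit = GenomeHit("c", 300 + ms, 300 + me, "+", 0)
        cand = _candidate_from_hit(hit, contig, RunConfig(), None)
        cand = score_candidate(cand, RunConfig())
        assert cand.mfei >= 0.85
        assert cand.ds_segment_len >= 19
        assert cand.passes


class TestClusters:
    def _cands(self, specs):
        out = []
        for contig, start, end in specs:
            rng = random.Random(start)
            seq = _random_seq(rng, 60).replace("T", "U")
            from mirphase.folding import FoldedStructure
            from mirphase.precursor import PrecursorCandidate

            out.append(
                PrecursorCandidate(
                    contig_id=contig, strand="+", start=start, end=end,
                    pre_sequence=seq,
                    structure=FoldedStructure(seq, "." * 60, 0.0),
                    mature_span=(0, 21), star_span=None,
                    hit=GenomeHit(contig, start, end, "+", 0),
                )
            )
        return out

    def test_tandem_copies_form_one_cluster(self):
        cands = self._cands([("c1", 1000, 1100), ("c1", 1600, 1700), ("c1", 2200, 2300)])
        clusters = find_clusters(cands, max_gap=10_000)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_different_contigs_never_cluster(self):
        cands = self._cands([("c1", 1000, 1100), ("c2", 1200, 1300)])
        assert find_clusters(cands) == []

    def test_gap_threshold(self):
        cands = self._cands([("c1", 1000, 1100), ("c1", 51_200, 51_300)])
        assert find_clusters(cands, max_gap=10_000) == []


def test_end_to_end_recovery_on_synthetic_genome(toy_study, config):
    """Planted valid hairpins pass; shuffled/low-GC decoys fail."""
    from mirphase.formats import read_fasta

    d, manifest = toy_study
    genome = read_fasta(d / "genome.fa")
    queries = {f"{fam}_g1": (fam, seq) for fam, seq in PLANTED_MATURES.items()}
    cands = find_precursors(queries, genome, config)

    def hit_at(p):
        return [
            c for c in cands
            if c.contig_id == p.contig and min(c.end, p.end) - max(c.start, p.start) > 0
        ]

    valid = [p for p in manifest.planted_precursors if p.is_valid_hairpin]
    decoys = [p for p in manifest.planted_precursors if not p.is_valid_hairpin]
    assert len(valid) >= 20 and len(decoys) >= 20
    sens = np.mean([any(c.passes for c in hit_at(p)) for p in valid])
    decoy_rate = np.mean([any(c.passes for c in hit_at(p)) for p in decoys])
    assert sens >= 0.9
    assert decoy_rate <= 0.1


def test_shuffled_precursors_score_below_threshold(toy_study, config):
    """Dinucleotide-shuffled versions of passing precursors lose the MFEI signal."""
    rng = np.random.default_rng(7)
    mature = PLANTED_MATURES["miR156"]
    cass, ms, me = hairpin_cassette(mature)
    pre = cass[10:-10]
    fails = 0
    n = 20
    for _ in range(n):
        dinucs = [pre[i : i + 2] for i in range(0, len(pre) - 1, 2)]
        rng.shuffle(dinucs)
        shuf = "".join(dinucs)[: len(pre)]
        fs = fold(shuf)
        gc = 100 * sum(shuf.count(b) for b in "GC") / len(shuf)
        mfei = (abs(fs.mfe) / len(shuf) * 100) / gc
        if mfei < 0.85:
            fails += 1
    assert fails / n >= 0.8
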