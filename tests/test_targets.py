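import random

import pytest

from mirphase.formats import RunConfig, revcomp
from mirphase.simulate import PLANTED_MATURES, designed_site
from mirphase.targets import scan_transcripts, score_duplex

from oracles import brute_target_sites

MIR = PLANTED_MATURES["miR156"]  # 21 nt


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        exp, smm, aln = score_duplex(MIR, revcomp(MIR))
        assert exp == 0.0 and smm == 0
        assert set(aln[1]) == {"|"}

    def test_seed_mismatch_doubled(self):
        # one mismatch at miRNA position 5 -> penalty 1 x seed multiplier 2
        site = list(revcomp(MIR))
        k = len(MIR)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[MIR[4]]
        wob = {"G": "T", "T": "G"}.get(MIR[4])
        site[k - 5] = next(b for b in "ACGT" if b != comp and b != wob)
        exp, smm, _ = score_duplex(MIR, "".join(site))
        assert exp == 2.0 and smm == 1

    def test_wobble_outside_seed_half_point(self):
        # single G:U at miRNA position 16 (outside the 2-13 seed)
        k = len(MIR)
        assert MIR[15] in "GT"  # wobble-capable base at position 16
        site = list(revcomp(MIR))
        site[k - 16] = {"G": "T", "T": "G"}[MIR[15]]
        exp, smm, aln = score_duplex(MIR, "".join(site))
        assert exp == 0.5 and smm == 0
        assert "o" in aln[1]

    def test_mirna_bulge_penalty(self):
        # miRNA position 15 unpaired: gap penalty 2, outside seed
        site = revcomp(MIR[:14] + MIR[15:])
        exp, smm, aln = score_duplex(MIR, site, mir_gap_after=14, gap_len=1)
        assert exp == 2.0 and smm == 0
        assert "-" in aln[0]

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            score_duplex("", "ACGT")

    def test_added_mismatch_never_decreases_expectation(self):
        rng = random.Random(11)
        for _ in range(50):
            site = list(revcomp(MIR))
            base_exp, _, _ = score_duplex(MIR, "".join(site))
            i = rng.randrange(len(site))
            site[i] = rng.choice([b for b in "ACGT" if b != site[i]])
            worse_exp, _, _ = score_duplex(MIR, "".join(site))
            assert worse_exp >= base_exp


class TestScan:
    CFG = RunConfig()

    def test_planted_perfect_site_single_hit(self):
        rng = random.Random(0)
        t = _random_seq(rng, 150) + revcomp(MIR) + _random_seq(rng, 150)
        hits = scan_transcripts({"m": MIR}, {"t": t}, self.CFG)
        exact = [h for h in hits if h.expectation == 0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.target_start, h.target_end) == (151, 150 + len(MIR))
        # reported coordinates slice the transcript to the site
        assert t[h.target_start - 1 : h.target_end] == revcomp(MIR)

    def test_three_seed_mismatches_rejected(self):
        site = list(revcomp(MIR))
        k = len(MIR)
        for pos in (3, 6, 9):
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[MIR[pos - 1]]
            wob = {"G": "T", "T": "G"}.get(MIR[pos - 1])
            site[k - pos] = next(b for b in "ACGT" if b != comp and b != wob)
        rng = random.Random(1)
        t = _random_seq(rng, 100) + "".join(site) + _random_seq(rng, 100)
        hits = scan_transcripts({"m": MIR}, {"t": t}, self.CFG)
        assert all(
            not (h.target_start - 1 < 100 + k and h.target_end > 100) for h in hits
        )

    def test_gapless_sites_match_brute_force_oracle(self):
        rng = random.Random(2)
        mirnas = {f: PLANTED_MATURES[f] for f in ("miR156", "miR166", "miR396")}
        for rep in range(5):
            t = _random_seq(rng, 400)
            fam = rng.choice(list(mirnas))
            site, achieved = designed_site(mirnas[fam], rng.choice([0.0, 2.0, 3.5]))
            pos = rng.randrange(50, 300)
            t = t[:pos] + site + t[pos + len(site):]
            hits = scan_transcripts(mirnas, {"t": t}, self.CFG)
            for m_id, mir in mirnas.items():
                oracle = brute_target_sites(mir, t, self.CFG.expectation_cutoff)
                reported = [h for h in hits if h.mirna_id == m_id]
                for (s, e, exp, smm) in oracle:
                    covering = [
                        h for h in reported if h.target_start - 1 < e and h.target_end > s
                    ]
                    assert covering, f"oracle site at {s} missed for {m_id}"
                    assert min(h.expectation for h in covering) <= exp
                # reported gapless hits agree with the oracle's arithmetic
                for h in reported:
                    if "-" not in h.alignment[0] and "-" not in h.alignment[2]:
                        match = [
                            o for o in oracle
                            if (o[0], o[1]) == (h.target_start - 1, h.target_end)
                        ]
                        assert match and match[0][2] == h.expectation

    def test_overlapping_sites_deduplicated_to_best(self):
        rng = random.Random(3)
        t = _random_seq(rng, 80) + revcomp(MIR) + _random_seq(rng, 80)
        hits = scan_transcripts({"m": MIR}, {"t": t}, self.CFG)
        spans = [(h.target_start, h.target_end) for h in hits]
        for i, a in enumerate(spans):
            for b in spans[i + 1:]:
                assert min(a[1], b[1]) - max(a[0], b[0]) <= 0  # no overlaps survive


def test_planted_site_recall_on_toy_transcripts(toy_study, config):
    """Every planted site of designed expectation <= 5 is recovered; designed
    negatives (expectation 6) are excluded by the cutoff."""
    from mirphase.formats import read_fasta

    d, manifest = toy_study
    transcripts = read_fasta(d / "transcripts.fa")
    hits = scan_transcripts(PLANTED_MATURES, transcripts, config)
    for t in manifest.planted_targets:
        covering = [
            h for h in hits
            if h.mirna_id == t.family and h.transcript_id == t.transcript
            and h.target_start - 1 < t.end and h.target_end > t.start
        ]
        if t.expectation_designed <= config.expectation_cutoff:
            assert covering, f"missed planted site {t.transcript}"
            assert min(h.expectation for h in covering) <= t.expectation_designed
        else:
            assert not covering, f"negative site reported: {t.transcript}"
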