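import random

import pytest

from mirphase.formats import LibraryDesign, ReferenceMiRNA, RunConfig
from mirphase.homology import (
    assign_all,
    build_groups,
    match_tag,
    summarize_families,
)
from mirphase.preprocess import UniqueTag

from oracles import brute_match

REF = "TTGACAGAAGATAGAGAGCAC"


def _ref(acc, seq, family=None):
    fam = family or ("miR" + "".join(ch for ch in acc.split("-")[1] if ch.isdigit()))
    return ReferenceMiRNA(accession=acc, family=fam, species_code=acc[:3], mature_sequence=seq)


def _tag(seq, **counts):
    return UniqueTag(sequence=seq, counts=counts or {"L1": 10})


class TestMatchTag:
    def test_identity(self):
        assert match_tag(REF, REF) == (0, 0, 0)

    def test_three_substitutions_rejected(self):
        tag = "AAA" + REF[3:]
        assert REF[:3] != "AAA"
        assert match_tag(tag, REF, max_mismatches=2) is None

    def test_end_offsets_with_internal_substitution(self):
        # drop the reference's first base, add one 3' base, one substitution
        tag = REF[1:] + "G"
        tag = tag[:5] + ("C" if tag[5] != "C" else "G") + tag[6:]
        assert match_tag(tag, REF) == (1, -1, 1)

    def test_overhanging_bases_not_counted_as_mismatches(self):
        tag = "GG" + REF  # two 5' overhang bases
        assert match_tag(tag, REF) == (0, 2, 0)

    def test_matches_exhaustive_enumeration_on_random_pairs(self):
        rng = random.Random(1234)
        for _ in range(1000):
            ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(19, 24)))
            tag = list(rng.choice([ref, ref[1:], ref + "A", "T" + ref[:-1]]))
            for _ in range(rng.randint(0, 3)):
                i = rng.randrange(len(tag))
                tag[i] = rng.choice("ACGT")
            tag = "".join(tag)
            if not 15 <= len(tag) <= 30:
                continue
            got = match_tag(tag, ref)
            expect = brute_match(tag, ref)
            assert (got is None) == (expect is None)
            if got is not None:
                assert tuple(got) == expect


class TestAssignAll:
    def test_equidistant_same_family_is_ambiguous(self):
        # two references differing at one position; the tag carries a third
        # base there, so it sits one mismatch from each (a tie).
        others = [b for b in "ACGT" if b != REF[10]]
        ra = _ref("gma-miR156a", REF)
        rb = _ref("gma-miR156b", REF[:10] + others[0] + REF[11:])
        tag_seq = REF[:10] + others[1] + REF[11:]
        a = assign_all([_tag(tag_seq)], [ra, rb])[0]
        assert a.family == "miR156"
        assert a.ambiguous
        assert set(a.best_references) == {"gma-miR156a", "gma-miR156b"}

    def test_identical_sequence_in_two_species_not_ambiguous(self):
        refs = [_ref("gma-miR156a", REF), _ref("ath-miR156a", REF)]
        a = assign_all([_tag(REF)], refs)[0]
        assert a.ambiguous is False
        assert len(a.best_references) == 2

    def test_no_match_is_unannotated(self):
        a = assign_all([_tag("A" * 21)], [_ref("gma-miR156a", REF)])[0]
        assert not a.annotated

    def test_unique_assignments_match_brute_force(self):
        rng = random.Random(9)
        refs = [
            _ref(f"gma-miR{n}a", "".join(rng.choice("ACGT") for _ in range(21)))
            for n in (156, 166, 396)
        ]
        tags = [_tag(r.mature_sequence[1:] + "A") for r in refs]
        out = assign_all(tags, refs)
        for a, r in zip(out, refs):
            assert a.family == r.family
            assert not a.ambiguous
            assert brute_match(a.tag.sequence, r.mature_sequence) == (
                a.mismatches, a.offset_5p, a.offset_3p,
            )

    def test_reference_order_does_not_change_assignments(self):
        rng = random.Random(5)
        refs = [
            _ref(f"gma-miR{n}a", "".join(rng.choice("ACGT") for _ in range(21)))
            for n in (156, 166, 396, 482)
        ]
        tags = [_tag("".join(rng.choice("ACGT") for _ in range(21))) for _ in range(30)]
        tags += [_tag(r.mature_sequence) for r in refs]
        fwd = assign_all(tags, refs)
        rev = assign_all(tags, refs[::-1])
        assert [(a.family, a.ambiguous, sorted(a.best_references)) for a in fwd] == [
            (a.family, a.ambiguous, sorted(a.best_references)) for a in rev
        ]

    def test_empty_reference_set_is_error(self):
        with pytest.raises(ValueError):
            assign_all([_tag(REF)], [])


class TestGroupsAndSummaries:
    DESIGN = [
        LibraryDesign("R1", "REV"), LibraryDesign("R2", "REV"),
        LibraryDesign("J1", "JUV"), LibraryDesign("J2", "JUV"),
    ]

    def test_group_count_conservation(self):
        refs = [_ref("gma-miR156a", REF)]
        tags = [
            _tag(REF, R1=5, J1=3),
            _tag(REF[1:] + "A", R2=4),
            _tag("G" * 21, J2=9),  # unannotated
        ]
        assignments = assign_all(tags, refs)
        groups = build_groups(assignments, refs)
        grouped = sum(g.total_count for g in groups)
        unannotated = sum(a.tag.total_count for a in assignments if not a.annotated)
        assert grouped + unannotated == sum(t.total_count for t in tags)
        assert groups[0].per_group_counts == {"R1": 5, "J1": 3, "R2": 4}

    def test_consensus_is_majority_base(self):
        refs = [_ref("gma-miR156a", REF)]
        variant = ("A" if REF[0] != "A" else "C") + REF[1:]
        tags = [_tag(REF, R1=10), _tag(variant, R2=2)]
        groups = build_groups(assign_all(tags, refs), refs)
        assert groups[0].consensus == REF

    def test_presence_sets_from_counts(self):
        refs = [_ref("gma-miR156a", REF), _ref("gma-miR166a", "TCGGACCAGGCTTCATTCCCC")]
        tags = [_tag(REF, R1=5), _tag("TCGGACCAGGCTTCATTCCCC", J1=2, R2=1)]
        summaries = summarize_families(assign_all(tags, refs), self.DESIGN)
        by_fam = {s.family: s for s in summaries}
        assert by_fam["miR156"].present_in == {"REV"}
        assert by_fam["miR166"].present_in == {"REV", "JUV"}
        assert by_fam["miR156"].n_isomirs_per_group == {"REV": 1, "JUV": 0}

    def test_unknown_library_in_counts_is_error(self):
        refs = [_ref("gma-miR156a", REF)]
        with pytest.raises(ValueError, match="absent from design"):
            summarize_families(assign_all([_tag(REF, X9=3)], refs), self.DESIGN)
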