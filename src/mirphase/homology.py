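"""Conserved-miRNA annotation of unique tags.

Tags are compared to miRBase mature reference sequences allowing up to
two mismatches and up to two additional or missing nucleotides at
either end (no internal gaps).  Ties across distinct reference mature
sequences are flagged as ambiguous, matching the convention of
reporting an isomiR as ambiguously annotated when it is similar to the
mature regions of two different reference sequences.  Tags sharing a
best reference mature sequence are merged into isomiR groups (connected
components over reference sequences within a family) with a
majority-base consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

from mirphase.formats import LibraryDesign, ReferenceMiRNA, RunConfig, groups_of
from mirphase.preprocess import UniqueTag


class MatchResult(NamedTuple):
    """Best ungapped placement of a tag against a reference mature sequence.

    offset_5p / offset_3p are signed end offsets in nucleotides: positive
    means the tag carries additional bases beyond the reference end,
    negative means it is missing reference bases at that end.
    """

    mismatches: int
    offset_5p: int
    offset_3p: int


def match_tag(
    tag_sequence: str,
    reference_mature: str,
    max_mismatches: int = 2,
    max_overhang: int = 2,
) -> MatchResult | None:
    """Best ungapped overlap placement of a tag against a reference.

    All placements where each end of the tag overhangs or falls short of
    the reference by at most ``max_overhang`` nucleotides are enumerated;
    the placement minimizing mismatches in the overlap (ties broken by
    smallest total absolute offset, then 5'-most placement) is returned,
    or None when the minimum exceeds ``max_mismatches``.  Overhanging tag
    bases are not counted as mismatches.
    """
    best = _best_placement(tag_sequence, reference_mature, max_overhang)
    if best is None or best.mismatches > max_mismatches:
        return None
    return best


def _best_placement(tag: str, ref: str, max_overhang: int) -> MatchResult | None:
    lt, lr = len(tag), len(ref)
    best: tuple[int, int, int] | None = None  # (mismatches, |off5|+|off3|, shift)
    result: MatchResult | None = None
    # shift s: tag position 0 sits at reference coordinate s
    for s in range(-max_overhang, max_overhang + 1):
        off5 = -s
        off3 = s + lt - lr
        if abs(off3) > max_overhang:
            continue
        lo = max(0, -s)
        hi = min(lt, lr - s)
        if hi <= lo:
            continue
        mism = sum(1 for i in range(lo, hi) if tag[i] != ref[s + i])
        key = (mism, abs(off5) + abs(off3), s)
        if best is None or key < best:
            best = key
            result = MatchResult(mism, off5, off3)
    return result


@dataclass
class TagAssignment:
    """A tag's best reference(s), family and isomiR-group membership."""

    tag: UniqueTag
    best_references: list[str]  # accessions at the joint best score
    family: str | None  # None = unannotated
    mismatches: int | None
    offset_5p: int | None
    offset_3p: int | None
    ambiguous: bool
    group_id: str | None = None

    @property
    def annotated(self) -> bool:
        return self.family is not None


@dataclass
class IsomiRGroup:
    """A set of tags assigned to one conserved miRNA group within a family."""

    group_id: str
    family: str
    members: list[TagAssignment]
    consensus: str
    per_group_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.per_group_counts.values())


@dataclass
class FamilySummary:
    family: str
    n_isomirs: int
    n_isomirs_per_group: dict[str, int]
    read_count_per_group: dict[str, int]
    present_in: set[str]


def assign_all(
    tags: Sequence[UniqueTag],
    references: Sequence[ReferenceMiRNA],
    config: RunConfig | None = None,
) -> list[TagAssignment]:
    """Assign every tag to its best reference mature sequence(s).

    The best score is (fewest mismatches, smallest total |offset|); all
    references achieving it are recorded.  A tie across >=2 distinct
    reference mature sequences sets the ambiguous flag.  A tie across
    families assigns the tag to the lexicographically smallest family
    (deterministic, order-independent) with ambiguous=True.  Tags
    matching nothing within tolerance are returned unannotated.
    """
    if not references:
        raise ValueError("empty reference set")
    config = config or RunConfig()
    mature_refs = [r for r in references if r.kind == "mature"]
    out: list[TagAssignment] = []
    for tag in tags:
        best_key: tuple[int, int] | None = None
        hits: list[tuple[ReferenceMiRNA, MatchResult]] = []
        for ref in mature_refs:
            m = match_tag(
                tag.sequence,
                ref.mature_sequence,
                config.max_mismatches_annotation,
                config.max_overhang,
            )
            if m is None:
                continue
            key = (m.mismatches, abs(m.offset_5p) + abs(m.offset_3p))
            if best_key is None or key < best_key:
                best_key = key
                hits = [(ref, m)]
            elif key == best_key:
                hits.append((ref, m))
        if not hits:
            out.append(
                TagAssignment(tag, [], None, None, None, None, ambiguous=False)
            )
            continue
        distinct_seqs = {r.mature_sequence for r, _ in hits}
        families = sorted({r.family for r, _ in hits})
        family = families[0]
        ambiguous = len(distinct_seqs) >= 2
        fam_hits = sorted(
            (h for h in hits if h[0].family == family),
            key=lambda h: h[0].accession,
        )
        match = fam_hits[0][1]
        out.append(
            TagAssignment(
                tag=tag,
                best_references=sorted(r.accession for r, _ in hits),
                family=family,
                mismatches=match.mismatches,
                offset_5p=match.offset_5p,
                offset_3p=match.offset_3p,
                ambiguous=ambiguous,
            )
        )
    return out


def build_groups(
    assignments: Sequence[TagAssignment],
    references: Sequence[ReferenceMiRNA],
) -> list[IsomiRGroup]:
    """Merge annotated tags into isomiR groups.

    Groups are connected components over reference mature sequences of
    the tag's assigned family: two references fall in one group when
    some tag has both among its best hits.  Group ids are deterministic
    (``<family>_g<n>``, numbered by the component's smallest reference
    sequence) and per-group counts are the element-wise sums of member
    tag counts.
    """
    ref_by_acc = {r.accession: r for r in references}
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    tag_links: dict[int, list[str]] = {}
    for i, a in enumerate(assignments):
        if not a.annotated:
            continue
        # link only references of the assigned family, keyed by mature sequence
        seqs = sorted(
            {
                ref_by_acc[acc].mature_sequence
                for acc in a.best_references
                if acc in ref_by_acc and ref_by_acc[acc].family == a.family
            }
        )
        tag_links[i] = seqs
        for s in seqs[1:]:
            union(seqs[0], s)

    components: dict[str, list[int]] = {}
    for i, seqs in tag_links.items():
        if seqs:
            components.setdefault(find(seqs[0]), []).append(i)

    groups: list[IsomiRGroup] = []
    fam_counter: dict[str, int] = {}
    for root in sorted(components):
        member_idx = components[root]
        family = assignments[member_idx[0]].family
        fam_counter[family] = fam_counter.get(family, 0) + 1
        group_id = f"{family}_g{fam_counter[family]}"
        members = [assignments[i] for i in member_idx]
        members.sort(key=lambda a: (-a.tag.total_count, a.tag.sequence))
        counts: dict[str, int] = {}
        for m in members:
            for lib, c in m.tag.counts.items():
                counts[lib] = counts.get(lib, 0) + c
        consensus = _consensus(members, root)
        for m in members:
            m.group_id = group_id
        groups.append(
            IsomiRGroup(
                group_id=group_id,
                family=family,
                members=members,
                consensus=consensus,
                per_group_counts=counts,
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def _consensus(members: Sequence[TagAssignment], ref_seq: str) -> str:
    """Majority base per position, members aligned to the component reference.

    Votes are weighted by tag total count; ties resolved alphabetically
    for determinism.  Columns are reference coordinates extended by
    member overhangs.
    """
    votes: dict[int, dict[str, int]] = {}
    for m in members:
        placed = _best_placement(m.tag.sequence, ref_seq, max_overhang=4)
        s = -placed.offset_5p if placed is not None else 0
        w = max(1, m.tag.total_count)
        for i, base in enumerate(m.tag.sequence):
            col = votes.setdefault(s + i, {})
            col[base] = col.get(base, 0) + w
    cols = sorted(votes)
    return "".join(
        sorted(votes[c].items(), key=lambda kv: (-kv[1], kv[0]))[0][0] for c in cols
    )


def summarize_families(
    assignments: Sequence[TagAssignment],
    design: Sequence[LibraryDesign],
) -> list[FamilySummary]:
    """Per-family isomiR and read-count summaries by sample group.

    A family is present in a sample group iff any member tag has a
    nonzero count in any library of that group.
    """
    lib_group = {d.library_id: d.sample_group for d in design}
    group_names = list(dict.fromkeys(d.sample_group for d in design))
    fams: dict[str, list[TagAssignment]] = {}
    for a in assignments:
        if not a.annotated:
            continue
        for lib in a.tag.counts:
            if lib not in lib_group:
                raise ValueError(f"library {lib!r} in counts absent from design")
        fams.setdefault(a.family, []).append(a)

    out: list[FamilySummary] = []
    for family in sorted(fams):
        members = fams[family]
        per_group_iso: dict[str, int] = {g: 0 for g in group_names}
        per_group_reads: dict[str, int] = {g: 0 for g in group_names}
        for a in members:
            seen_groups = set()
            for lib, c in a.tag.counts.items():
                g = lib_group[lib]
                per_group_reads[g] += c
                if c > 0:
                    seen_groups.add(g)
            for g in seen_groups:
                per_group_iso[g] += 1
        present = {g for g, c in per_group_reads.items() if c > 0}
        out.append(
            FamilySummary(
                family=family,
                n_isomirs=len(members),
                n_isomirs_per_group=per_group_iso,
                read_count_per_group=per_group_reads,
                present_in=present,
            )
        )
    return out


def write_assignment_table(assignments: Sequence[TagAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sequence\ttotal_count\tfamily\tgroup_id\treferences\t"
            "mismatches\toffset_5p\toffset_3p\tambiguous\n"
        )
        for a in assignments:
            fh.write(
                "\t".join(
                    [
                        a.tag.sequence,
                        str(a.tag.total_count),
                        a.family or "unannotated",
                        a.group_id or ".",
                        ",".join(a.best_references) or ".",
                        str(a.mismatches if a.mismatches is not None else "."),
                        str(a.offset_5p if a.offset_5p is not None else "."),
                        str(a.offset_3p if a.offset_3p is not None else "."),
                        str(a.ambiguous).lower(),
                    ]
                )
                + "\n"
            )


def write_family_summary(
    summaries: Sequence[FamilySummary], design: Sequence[LibraryDesign], path: str | Path
) -> None:
    group_names = list(dict.fromkeys(d.sample_group for d in design))
    with open(path, "w") as fh:
        fh.write(
            "family\tn_isomirs\t"
            + "\t".join(f"isomirs_{g}" for g in group_names)
            + "\t"
            + "\t".join(f"reads_{g}" for g in group_names)
            + "\tpresent_in\n"
        )
        for s in summaries:
            fh.write(
                "\t".join(
                    [s.family, str(s.n_isomirs)]
                    + [str(s.n_isomirs_per_group.get(g, 0)) for g in group_names]
                    + [str(s.read_count_per_group.get(g, 0)) for g in group_names]
                    + [",".join(sorted(s.present_in))]
                )
                + "\n"
            )
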