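"""Genomic hairpin precursor prediction with MFEI filtering.

Mature miRNA sequences are mapped to genome contigs on both strands
(<=2 mismatches, <=1 single-nucleotide gap), ~100 nt flanks are
extracted and folded, the miRNA* arm is located from the pair table
(2-nt 3' overhang Dicer convention), the window is trimmed to the
pre-miRNA at the first bulge or interior loop beyond the mature/star
duplex, and each candidate is scored: MFE, AMFE (=|MFE|/length x 100),
MFEI (=AMFE/GC%), GC and AU content, base pairs, and the length of the
longest double-stranded segment.  A candidate passes when MFEI >= 0.85,
the double-stranded segment is >= 19 nt, both arms are 19-25 nt and the
hairpin has a single terminal loop — thresholds that separate miRNA
precursors (MFEI >= 0.85) from tRNA/rRNA (MFEI 0.59-0.66).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mirphase.folding import FoldedStructure, fold, n_hairpin_loops, pair_table, to_rna
from mirphase.formats import RunConfig, revcomp


@dataclass(frozen=True)
class GenomeHit:
    """A mature-miRNA match on a genome contig (forward-axis coordinates)."""

    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # "+" or "-"
    mismatches: int
    gaps: int = 0


@dataclass
class PrecursorCandidate:
    """A trimmed, folded and scored genomic hairpin candidate."""

    contig_id: str
    strand: str
    start: int  # trimmed pre-miRNA bounds, 0-based half-open, forward axis
    end: int
    pre_sequence: str  # RNA, mature arm 5'->3'
    structure: FoldedStructure
    mature_span: tuple[int, int]  # within pre_sequence
    star_span: tuple[int, int] | None
    hit: GenomeHit
    mfe: float = 0.0
    amfe: float = 0.0
    mfei: float = 0.0
    gc_percent: float = 0.0
    au_percent: float = 0.0
    n_base_pairs: int = 0
    ds_segment_len: int = 0
    passes: bool = False
    fail_reason: str = ""
    family: str = ""
    group_id: str = ""

    @property
    def mature_contig_span(self) -> tuple[int, int]:
        return self._to_contig(self.mature_span)

    @property
    def star_contig_span(self) -> tuple[int, int] | None:
        return self._to_contig(self.star_span) if self.star_span else None

    def _to_contig(self, span: tuple[int, int]) -> tuple[int, int]:
        s, e = span
        if self.strand == "+":
            return self.start + s, self.start + e
        return self.end - e, self.end - s


@dataclass
class PrecursorCluster:
    """>=2 precursor candidates within ``max_gap`` nt on one contig."""

    contig_id: str
    members: list[PrecursorCandidate]
    max_gap: int


_BASE_ORD = {b: np.uint8(i) for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def map_to_genome(
    mature_sequence: str,
    genome: Mapping[str, str],
    config: RunConfig | None = None,
) -> list[GenomeHit]:
    """All genome hits of a mature miRNA within the mapping tolerances.

    Both strands are scanned exhaustively; minus-strand hits are
    reported with forward-axis coordinates.  Ungapped hits allow up to
    ``max_mismatches_genome`` mismatches; additionally alignments with
    one single- nucleotide gap (on either sequence) are found when
    ``max_gaps_genome`` >= 1.  Gapped hits overlapping an ungapped hit
    at the same locus are suppressed.  Contigs shorter than the query
    are skipped.
    """
    config = config or RunConfig()
    query = mature_sequence.upper().replace("U", "T")
    hits: list[GenomeHit] = []
    for contig_id, seq in genome.items():
        if len(seq) < len(query):
            continue
        carr = _encode(seq)
        for strand, q in (("+", query), ("-", revcomp(query))):
            raw = _scan_contig(carr, _encode(q), config)
            hits.extend(
                GenomeHit(contig_id, s, e, strand, mm, g) for s, e, mm, g in raw
            )
    return _dedup_hits(hits, len(query))


def _scan_contig(carr: np.ndarray, qarr: np.ndarray, config: RunConfig) -> list[tuple[int, int, int, int]]:
    L, lq = len(carr), len(qarr)
    maxmm = config.max_mismatches_genome
    out: list[tuple[int, int, int, int]] = []

    # ungapped
    n = L - lq + 1
    mm = np.zeros(n, dtype=np.int16)
    for i in range(lq):
        mm += carr[i : i + n] != qarr[i]
    for p in np.flatnonzero(mm <= maxmm):
        out.append((int(p), int(p) + lq, int(mm[p]), 0))

    if config.max_gaps_genome >= 1 and L >= lq + 1:
        # one extra genome base at interior offset g (alignment spans lq+1)
        n2 = L - lq
        A = np.zeros((lq + 1, n2), dtype=np.int16)  # prefix sums over i<g of c[p+i]!=q[i]
        B = np.zeros((lq + 1, n2), dtype=np.int16)  # suffix sums over i>=g of c[p+i+1]!=q[i]
        for i in range(lq):
            A[i + 1] = A[i] + (carr[i : i + n2] != qarr[i])
        for i in range(lq - 1, -1, -1):
            B[i] = B[i + 1] + (carr[i + 1 : i + 1 + n2] != qarr[i])
        for g in range(1, lq):
            mg = A[g] + B[g]
            for p in np.flatnonzero(mg <= maxmm):
                out.append((int(p), int(p) + lq + 1, int(mg[p]), 1))

        # one unaligned query base at interior position g (alignment spans lq-1)
        if L >= lq - 1:
            n3 = L - (lq - 1) + 1
            A2 = np.zeros((lq + 1, n3), dtype=np.int16)
            B2 = np.zeros((lq + 1, n3), dtype=np.int16)
            for i in range(lq - 1):
                A2[i + 1] = A2[i] + (carr[i : i + n3] != qarr[i])
            for i in range(lq - 1, 0, -1):
                B2[i] = B2[i + 1] + (carr[i - 1 : i - 1 + n3] != qarr[i])
            for g in range(1, lq - 1):
                mg = A2[g] + B2[g + 1]
                for p in np.flatnonzero(mg <= maxmm):
                    out.append((int(p), int(p) + lq - 1, int(mg[p]), 1))
    return out


def _dedup_hits(hits: list[GenomeHit], lq: int) -> list[GenomeHit]:
    """Suppress gapped hits overlapping a kept lower-gap hit at the same locus."""
    kept: list[GenomeHit] = []
    for h in sorted(hits, key=lambda h: (h.gaps, h.mismatches, h.contig_id, h.strand, h.start)):
        clash = any(
            k.contig_id == h.contig_id
            and k.strand == h.strand
            and k.gaps < h.gaps
            and min(k.end, h.end) - max(k.start, h.start) >= lq - 3
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return kept


def extract_candidate(
    hit: GenomeHit, contig_seq: str, flank: int = 100
) -> tuple[str, tuple[int, int], int, int]:
    """Extract the folding window around a genome hit.

    Returns (window_sequence, mature_span_in_window, window_start,
    window_end).  The window is [start - flank, end + flank) clipped to
    the contig; at contig edges the entire available sequence is used.
    Minus-strand windows are reverse-complemented so the mature arm
    reads 5'->3'.
    """
    ws = max(0, hit.start - flank)
    we = min(len(contig_seq), hit.end + flank)
    window = contig_seq[ws:we]
    if hit.strand == "+":
        span = (hit.start - ws, hit.end - ws)
    else:
        window = revcomp(window)
        span = (we - hit.end, we - hit.start)
    return window, span, ws, we


def locate_star(structure: FoldedStructure | str, mature_span: tuple[int, int]) -> tuple[int, int] | None:
    """Locate the miRNA* arm from the pair table.

    The star arm spans the pairing partners of the mature arm, shifted
    by the 2-nt 3' overhang each strand leaves in the Dicer duplex.
    Returns None when fewer than 60% of mature positions are paired or
    when the arms would overlap.
    """
    db = structure.dotbracket if isinstance(structure, FoldedStructure) else structure
    pt = pair_table(db)
    ms, me = mature_span
    partners = [int(pt[i]) for i in range(ms, me) if pt[i] >= 0]
    if len(partners) < 0.6 * (me - ms):
        return None
    pmin, pmax = min(partners), max(partners)
    if pmin >= me:  # star on the 3' arm: shift downstream by the 2-nt overhang
        span = (pmin + 2, pmax + 3)
    elif pmax < ms:  # star on the 5' arm: shift upstream
        span = (pmin - 2, pmax - 1)
    else:
        return None
    span = (max(0, span[0]), min(len(db), span[1]))
    if span[1] <= span[0] or (span[0] < me and span[1] > ms):
        return None
    return span


def trim_to_pre(
    structure: FoldedStructure | str,
    mature_span: tuple[int, int],
    star_span: tuple[int, int],
) -> tuple[int, int]:
    """Pre-miRNA bounds within the folding window.

    Starting from the outermost base pair of the mature/star duplex the
    stem is walked outward; the precursor is cut immediately after the
    first bulge or interior loop beyond the duplex (the interrupting
    unpaired bases are retained, the resumed stem is not), or at the
    window end when the stem runs clean to the edge.
    """
    db = structure.dotbracket if isinstance(structure, FoldedStructure) else structure
    pt = pair_table(db)
    L = len(db)
    d5 = min(mature_span[0], star_span[0])
    d3 = max(mature_span[1], star_span[1])
    a = b = -1
    for i in range(d5, d3):
        p = int(pt[i])
        if p > i and p < d3:
            a, b = i, p
            break
    if a < 0:
        return d5, d3
    while True:
        x = -1
        for cand in range(a - 1, -1, -1):
            if pt[cand] > b:
                x = cand
                break
        if x < 0:
            return 0, L
        y = int(pt[x])
        if x == a - 1 and y == b + 1:
            a, b = x, y
        else:
            return x + 1, y


def score_candidate(cand: PrecursorCandidate, config: RunConfig | None = None) -> PrecursorCandidate:
    """Fill MFE/AMFE/MFEI, composition and the pass/fail verdict.

    AMFE is the MFE magnitude per 100 nt; MFEI = AMFE / GC% with GC on
    the 0-100 scale (reported positive).  The double-stranded segment is
    the longest uninterrupted run of paired positions on one arm.
    """
    config = config or RunConfig()
    seq = cand.pre_sequence
    db = cand.structure.dotbracket
    n = len(seq)
    gc = 100.0 * sum(seq.count(b) for b in "GC") / n
    au = 100.0 * sum(seq.count(b) for b in "AU") / n
    pt = pair_table(db)
    cand.gc_percent = gc
    cand.au_percent = au
    cand.mfe = cand.structure.mfe
    cand.n_base_pairs = int((pt >= 0).sum()) // 2
    cand.amfe = abs(cand.mfe) / n * 100.0
    cand.ds_segment_len = _longest_paired_run(db)

    reasons: list[str] = []
    if gc <= 0:
        cand.mfei = float("nan")
        reasons.append("zero GC")
    else:
        cand.mfei = cand.amfe / gc
        if cand.mfei < config.mfei_threshold:
            reasons.append(f"MFEI {cand.mfei:.2f} < {config.mfei_threshold}")
    if cand.ds_segment_len < config.min_ds_segment:
        reasons.append(f"ds segment {cand.ds_segment_len} < {config.min_ds_segment}")
    mature_len = cand.mature_span[1] - cand.mature_span[0]
    if not (config.arm_min <= mature_len <= config.arm_max):
        reasons.append(f"mature arm {mature_len} nt outside [{config.arm_min},{config.arm_max}]")
    if cand.star_span is None:
        reasons.append("no star arm")
    else:
        star_len = cand.star_span[1] - cand.star_span[0]
        if not (config.arm_min <= star_len <= config.arm_max):
            reasons.append(f"star arm {star_len} nt outside [{config.arm_min},{config.arm_max}]")
    if n_hairpin_loops(db) != 1:
        reasons.append(f"{n_hairpin_loops(db)} terminal loops")
    cand.passes = not reasons
    cand.fail_reason = "; ".join(reasons)
    return cand


def _longest_paired_run(db: str) -> int:
    best = run = 0
    prev = "."
    for c in db:
        if c != "." and c == prev:
            run += 1
        elif c != ".":
            run = 1
        else:
            run = 0
        best = max(best, run)
        prev = c
    return best


def find_precursors(
    queries: Mapping[str, tuple[str, str]],
    genome: Mapping[str, str],
    config: RunConfig | None = None,
    engine: str | None = None,
) -> list[PrecursorCandidate]:
    """Full precursor search for a set of mature sequences.

    ``queries`` maps group_id -> (family, mature DNA sequence).  One
    candidate is produced per genome hit; candidates from nearby hits
    that trim to identical contig coordinates are deduplicated.
    """
    config = config or RunConfig()
    out: list[PrecursorCandidate] = []
    for group_id in sorted(queries):
        family, mature = queries[group_id]
        cands: list[PrecursorCandidate] = []
        for hit in map_to_genome(mature, genome, config):
            cand = _candidate_from_hit(hit, genome[hit.contig_id], config, engine)
            if cand is None:
                continue
            cand.family, cand.group_id = family, group_id
            cands.append(score_candidate(cand, config))
        out.extend(_dedup_candidates(cands))
    out.sort(key=lambda c: (c.contig_id, c.start, c.group_id))
    return out


def _dedup_candidates(cands: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """One candidate per locus: a hairpin found from both the mature-arm
    hit and the star-arm (reverse-complement) hit trims to overlapping
    coordinates; the better-supported copy is kept."""
    kept: list[PrecursorCandidate] = []
    order = sorted(
        cands,
        key=lambda c: (c.hit.gaps, c.hit.mismatches, c.strand != "+", c.contig_id, c.start),
    )
    for c in order:
        dup = any(
            k.contig_id == c.contig_id
            and min(k.end, c.end) - max(k.start, c.start)
            > 0.5 * min(k.end - k.start, c.end - c.start)
            for k in kept
        )
        if not dup:
            kept.append(c)
    return kept


def _candidate_from_hit(
    hit: GenomeHit, contig_seq: str, config: RunConfig, engine: str | None
) -> PrecursorCandidate | None:
    window, wspan, ws, we = extract_candidate(hit, contig_seq, config.flank)
    if len(window) < 15:
        return None
    folded = fold(window, engine)
    star = locate_star(folded, wspan)
    if star is None:
        pre_s, pre_e = wspan  # no duplex: keep a failing stub over the mature arm
        pre_s, pre_e = max(0, pre_s - 10), min(len(window), pre_e + 10)
    else:
        pre_s, pre_e = trim_to_pre(folded, wspan, star)
    pre_seq = window[pre_s:pre_e]
    if len(pre_seq) < 15:
        return None
    refolded = fold(pre_seq, engine)
    mature_pre = (wspan[0] - pre_s, wspan[1] - pre_s)
    star_pre = locate_star(refolded, mature_pre)
    # pre bounds on the forward contig axis
    if hit.strand == "+":
        cstart, cend = ws + pre_s, ws + pre_e
    else:
        cstart, cend = we - pre_e, we - pre_s
    return PrecursorCandidate(
        contig_id=hit.contig_id,
        strand=hit.strand,
        start=cstart,
        end=cend,
        pre_sequence=to_rna(pre_seq),
        structure=refolded,
        mature_span=mature_pre,
        star_span=star_pre,
        hit=hit,
    )


def find_clusters(
    candidates: Sequence[PrecursorCandidate], max_gap: int = 10_000
) -> list[PrecursorCluster]:
    """Chain same-contig candidates within ``max_gap`` nt into clusters (>=2)."""
    by_contig: dict[str, list[PrecursorCandidate]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig_id, []).append(c)
    clusters: list[PrecursorCluster] = []
    for contig_id in sorted(by_contig):
        cands = sorted(by_contig[contig_id], key=lambda c: (c.start, c.end))
        chain: list[PrecursorCandidate] = []
        for c in cands:
            if chain and c.start - chain[-1].end > max_gap:
                if len(chain) >= 2:
                    clusters.append(PrecursorCluster(contig_id, chain, max_gap))
                chain = []
            chain.append(c)
        if len(chain) >= 2:
            clusters.append(PrecursorCluster(contig_id, chain, max_gap))
    return clusters


def write_precursor_table(candidates: Sequence[PrecursorCandidate], path: str | Path) -> None:
    cols = (
        "contig\tstrand\tstart\tend\tlength\tfamily\tgroup_id\tmfe\tamfe\tmfei\t"
        "gc_percent\tau_percent\tn_base_pairs\tds_segment\tpasses\tfail_reason\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in candidates:
            fh.write(
                f"{c.contig_id}\t{c.strand}\t{c.start}\t{c.end}\t{len(c.pre_sequence)}\t"
                f"{c.family}\t{c.group_id}\t{c.mfe:.2f}\t{c.amfe:.2f}\t{c.mfei:.4f}\t"
                f"{c.gc_percent:.2f}\t{c.au_percent:.2f}\t{c.n_base_pairs}\t"
                f"{c.ds_segment_len}\t{str(c.passes).lower()}\t{c.fail_reason}\n"
            )
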