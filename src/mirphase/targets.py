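"""Complementarity-based miRNA target prediction.

Implements the psRNATarget-style expectation score: a miRNA is aligned
antiparallel to a transcript site; each position contributes 0 for a
perfect Watson-Crick pair, 0.5 for a G:U wobble, 1 for a mismatch and
2 per gapped position, with penalties doubled inside the seed region
(miRNA positions 2-13 by default).  The expectation is the total
penalty; sites are reported when expectation <= 5 and the seed carries
<= 2 mismatches+gaps.  A single bulge of at most 2 nt on either strand
is allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mirphase.formats import RunConfig, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# wobble: miRNA G pairs target U(T); miRNA U(T) pairs target G
_WOBBLE = {"G": "T", "T": "G"}

MAX_BULGE = 2


@dataclass(frozen=True)
class TargetHit:
    """A scored miRNA-transcript complementary site."""

    mirna_id: str
    transcript_id: str
    target_start: int  # 1-based inclusive on the transcript
    target_end: int
    expectation: float
    seed_mismatches: int
    alignment: tuple[str, str, str]  # target 5'->3', pairing symbols, miRNA 3'->5'


def _penalty(mir_base: str, t_base: str) -> tuple[float, str]:
    """(penalty, symbol) for one aligned position; symbols: | pair, o wobble, space mismatch."""
    if _COMP.get(mir_base) == t_base:
        return 0.0, "|"
    if _WOBBLE.get(mir_base) == t_base:
        return 0.5, "o"
    return 1.0, " "


def score_duplex(
    mirna: str,
    target_site: str,
    config: RunConfig | None = None,
    mir_gap_after: int | None = None,
    gap_len: int = 0,
    target_gap_after: int | None = None,
) -> tuple[float, int, tuple[str, str, str]]:
    """Score one miRNA/target-site duplex.

    ``mirna`` is 5'->3'; ``target_site`` is the transcript slice 5'->3',
    which pairs the miRNA antiparallel (miRNA position 1 against the
    site's last base).  An optional single bulge is described by either
    ``mir_gap_after`` (unpaired miRNA bases following that 1-based miRNA
    position) or ``target_gap_after`` (extra target bases at that miRNA
    gap slot), with ``gap_len`` in 1..2.  Gapless scoring requires equal
    lengths.  Returns (expectation, seed_mismatches, alignment rows).
    """
    if not mirna or not target_site:
        raise ValueError("empty duplex input")
    config = config or RunConfig()
    k = len(mirna)
    ts = target_site[::-1]  # now index p pairs miRNA position p+1
    seed = range(config.seed_start, config.seed_end + 1)

    def mult(pos: int) -> float:
        return 2.0 if pos in seed else 1.0

    expectation = 0.0
    seed_mm = 0
    row_t: list[str] = []
    row_s: list[str] = []
    row_m: list[str] = []
    ti = 0
    for pos in range(1, k + 1):
        if mir_gap_after is not None and mir_gap_after < pos <= mir_gap_after + gap_len:
            expectation += 2.0 * mult(pos)
            if pos in seed:
                seed_mm += 1
            row_t.append("-")
            row_s.append(" ")
            row_m.append(mirna[pos - 1])
            continue
        if ti >= len(ts):
            raise ValueError("target site shorter than alignment")
        pen, sym = _penalty(mirna[pos - 1], ts[ti])
        expectation += pen * mult(pos)
        if sym == " " and pos in seed:
            seed_mm += 1
        row_t.append(ts[ti])
        row_s.append(sym)
        row_m.append(mirna[pos - 1])
        ti += 1
        if target_gap_after is not None and pos == target_gap_after:
            for _ in range(gap_len):
                expectation += 2.0 * mult(pos)
                if pos in seed:
                    seed_mm += 1
                row_t.append(ts[ti])
                row_s.append(" ")
                row_m.append("-")
                ti += 1
    if ti != len(ts):
        raise ValueError("target site length inconsistent with gap description")
    # rows were built miRNA 5'->3' = target 3'->5'; flip for target 5'->3' display
    return (
        expectation,
        seed_mm,
        ("".join(row_t)[::-1], "".join(row_s)[::-1], "".join(row_m)[::-1]),
    )


def scan_transcripts(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    config: RunConfig | None = None,
) -> list[TargetHit]:
    """Scan transcripts for complementary sites of each miRNA.

    All gapless windows plus all single-bulge (1-2 nt, either strand)
    alignments are scored; sites with expectation <= cutoff and <= 2
    seed mismatches are kept, and overlapping sites of the same
    miRNA-transcript pair are deduplicated to the best-scoring one.
    Output order is (transcript, position, miRNA).
    """
    config = config or RunConfig()
    hits: list[TargetHit] = []
    for t_id in transcripts:
        t_seq = transcripts[t_id]
        t_arr = np.frombuffer(t_seq.encode(), dtype=np.uint8)
        for m_id in sorted(mirnas):
            raw = _scan_one(mirnas[m_id], t_arr, config)
            best = _dedup_sites(raw)
            for start, end, gap_kind, gap_after, gap_len in best:
                exp, smm, aln = score_duplex(
                    mirnas[m_id],
                    t_seq[start:end],
                    config,
                    mir_gap_after=gap_after if gap_kind == "m" else None,
                    target_gap_after=gap_after if gap_kind == "t" else None,
                    gap_len=gap_len,
                )
                hits.append(
                    TargetHit(m_id, t_id, start + 1, end, exp, smm, aln)
                )
    hits.sort(key=lambda h: (h.transcript_id, h.target_start, h.mirna_id))
    return hits


def _scan_one(mirna: str, t_arr: np.ndarray, config: RunConfig):
    """Enumerate candidate sites: (start, end, gap_kind, gap_after, gap_len, expectation, seed_mm).

    Vectorized over all windows.  gap_kind: "" none, "m" miRNA bulge,
    "t" target bulge.
    """
    k = len(mirna)
    L = len(t_arr)
    seed = range(config.seed_start, config.seed_end + 1)
    cutoff = config.expectation_cutoff
    results = []

    comp = np.frombuffer(revcomp(mirna).encode(), dtype=np.uint8)  # site 5'->3' canonical
    # wobble partner of each site position (or 0 when none)
    wob = np.zeros(k, dtype=np.uint8)
    for p in range(k):
        mb = mirna[k - 1 - p]  # miRNA base pairing site position p (of window, 5'->3')
        if mb in _WOBBLE:
            wob[p] = ord(_WOBBLE[mb])
    mults = np.array([2.0 if (k - p) in seed else 1.0 for p in range(k)])
    in_seed = np.array([(k - p) in seed for p in range(k)])

    def accumulate(window_len: int, site_idx: np.ndarray, base_pen: float, base_smm: np.ndarray | int, kind: str, gap_after: int | None, gap_len: int):
        n = L - window_len + 1
        if n <= 0:
            return
        exp = np.full(n, base_pen)
        smm = np.zeros(n, dtype=np.int16)
        if isinstance(base_smm, int):
            smm += base_smm
        for p, si in enumerate(site_idx):
            if si < 0:
                continue  # miRNA-bulged position, already in base_pen
            col = t_arr[si : si + n]
            is_pair = col == comp[p]
            is_wob = (wob[p] != 0) & (col == wob[p])
            exp += np.where(is_pair, 0.0, np.where(is_wob, 0.5, 1.0)) * mults[p]
            if in_seed[p]:
                smm += (~is_pair & ~is_wob).astype(np.int16)
        ok = np.flatnonzero((exp <= cutoff) & (smm <= 2))
        for w in ok:
            results.append(
                (int(w), int(w) + window_len, kind, gap_after, gap_len, float(exp[w]), int(smm[w]))
            )

    # gapless: site position p (window coords) pairs miRNA position k-p
    accumulate(k, np.arange(k), 0.0, 0, "", None, 0)

    for g in range(1, MAX_BULGE + 1):
        # target bulge: g extra target bases after miRNA position 'a' (1-based);
        # window length k+g; site index of miRNA-paired position p:
        #   window coords run 3'->5' of miRNA; extra bases sit between
        #   miRNA positions a and a+1, i.e. window offset k-a stays for p<k-a..
        for a in range(1, k):
            site_idx = np.empty(k, dtype=int)
            for p in range(k):
                mir_pos = k - p
                site_idx[p] = p if mir_pos > a else p + g
            base = 2.0 * g * (2.0 if (a in seed) else 1.0)
            smm0 = g if a in seed else 0
            accumulate(k + g, site_idx, base, smm0, "t", a, g)
        # miRNA bulge: miRNA positions a+1..a+g unpaired; window length k-g
        for a in range(1, k - g):
            site_idx = np.full(k, -1, dtype=int)
            base = 0.0
            smm0 = 0
            shift = 0
            for p in range(k - 1, -1, -1):  # walk miRNA 5'->3'
                mir_pos = k - p
                if a < mir_pos <= a + g:
                    base += 2.0 * (2.0 if mir_pos in seed else 1.0)
                    if mir_pos in seed:
                        smm0 += 1
                    shift += 1
                    site_idx[p] = -1
                else:
                    site_idx[p] = p - (g - shift)
            accumulate(k - g, site_idx, base, smm0, "m", a, g)
    return results


def _dedup_sites(raw):
    """Greedy best-first selection of non-overlapping sites."""
    kept = []
    for cand in sorted(raw, key=lambda r: (r[5], r[6], r[0], r[2])):
        if any(min(k[1], cand[1]) - max(k[0], cand[0]) > 0 for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda r: r[0])
    return [(s, e, kind, ga, gl) for s, e, kind, ga, gl, _, _ in kept]


def write_target_table(hits: Sequence[TargetHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna\ttranscript\ttarget_start\ttarget_end\texpectation\t"
            "seed_mismatches\ttarget_5to3\tpairing\tmirna_3to5\n"
        )
        for h in hits:
            fh.write(
                f"{h.mirna_id}\t{h.transcript_id}\t{h.target_start}\t{h.target_end}\t"
                f"{h.expectation:g}\t{h.seed_mismatches}\t"
                f"{h.alignment[0]}\t{h.alignment[1]}\t{h.alignment[2]}\n"
            )
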