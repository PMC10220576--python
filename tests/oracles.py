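"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the simplest possible code
(explicit python loops, exhaustive enumeration) so they stay
independent of the vectorized/DP implementations they check.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
WOBBLE = {"G": "T", "T": "G"}
RNA_PAIR_E = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def brute_match(tag: str, ref: str, maxmm: int = 2, maxover: int = 2):
    """Exhaustive placement enumeration for the tag/reference matcher."""
    best_key = None
    best = None
    for s in range(-maxover, maxover + 1):
        off5 = -s
        off3 = s + len(tag) - len(ref)
        if abs(off3) > maxover:
            continue
        lo, hi = max(0, -s), min(len(tag), len(ref) - s)
        if hi <= lo:
            continue
        mm = sum(tag[i] != ref[s + i] for i in range(lo, hi))
        key = (mm, abs(off5) + abs(off3), s)
        if best_key is None or key < best_key:
            best_key, best = key, (mm, off5, off3)
    if best_key is None or best_key[0] > maxmm:
        return None
    return best


def brute_genome_scan(query: str, contig: str, maxmm: int = 2):
    """Ungapped sliding-window scan (forward strand only)."""
    out = []
    lq = len(query)
    for p in range(len(contig) - lq + 1):
        mm = sum(contig[p + i] != query[i] for i in range(lq))
        if mm <= maxmm:
            out.append((p, p + lq, mm))
    return out


def brute_target_sites(mirna: str, transcript: str, cutoff: float = 5.0,
                       seed_start: int = 2, seed_end: int = 13):
    """All gapless complementary sites with expectation <= cutoff and <=2 seed mismatches."""
    k = len(mirna)
    out = []
    for w in range(len(transcript) - k + 1):
        site = transcript[w : w + k]
        exp, smm = 0.0, 0
        for pos in range(1, k + 1):
            mb, tb = mirna[pos - 1], site[k - pos]  # antiparallel pairing
            if COMP[mb] == tb:
                pen = 0.0
            elif WOBBLE.get(mb) == tb:
                pen = 0.5
            else:
                pen = 1.0
            mult = 2.0 if seed_start <= pos <= seed_end else 1.0
            exp += pen * mult
            if pen == 1.0 and seed_start <= pos <= seed_end:
                smm += 1
        if exp <= cutoff and smm <= 2:
            out.append((w, w + k, exp, smm))
    return out


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return adj


def enumerate_min_energy(rna: str, min_loop: int = 3, stack_bonus: float = -1.0) -> float:
    """Minimum energy over ALL non-crossing structures (tiny sequences only).

    Same energy model as the builtin folding engine: per-pair energies
    plus a bonus for each directly stacked pair.
    """
    n = len(rna)

    def pairable(i, j):
        return (rna[i], rna[j]) in RNA_PAIR_E and j - i > min_loop

    def structures(i, j):
        if j - i <= min_loop:
            yield frozenset()
            return
        yield from structures(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if pairable(i, k):
                for left in structures(i + 1, k - 1):
                    for right in structures(k + 1, j):
                        yield left | right | {(i, k)}

    def energy(struct):
        e = sum(RNA_PAIR_E[(rna[i], rna[j])] for i, j in struct)
        e += stack_bonus * sum(1 for i, j in struct if (i + 1, j - 1) in struct)
        return e

    return min(energy(s) for s in set(structures(0, n - 1)))
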