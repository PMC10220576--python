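"""RNA secondary-structure folding engines.

Folding is exposed through a pluggable engine contract:
``engine(sequence) -> (dotbracket, mfe_kcal_mol)``.  The default engine
is ViennaRNA's thermodynamic nearest-neighbor model (via its python
bindings).  A built-in fallback implements weighted base-pair
maximization with stacking bonuses — a Nussinov-style dynamic program
over a simple energy model (GC -3, AU -2, GU -1 kcal/mol per pair,
-1 for each stacked pair, minimum hairpin loop 3) — so the package
remains usable and hermetically testable without the thermodynamic
library.  Pseudoknots are never produced; MFE is <= 0, with 0 meaning
no structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

MIN_LOOP = 3
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
STACK_BONUS = -1.0

MIN_FOLD_LEN = 15


@dataclass(frozen=True)
class FoldedStructure:
    """An RNA sequence with its MFE dot-bracket structure."""

    sequence: str  # RNA alphabet
    dotbracket: str
    mfe: float  # kcal/mol, <= 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("structure length != sequence length")
        pair_table(self.dotbracket)  # raises if unbalanced


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@lru_cache(maxsize=1)
def _vienna_module():
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError:
        return None
    return RNA


def default_engine_name() -> str:
    return "vienna" if _vienna_module() is not None else "builtin"


def fold(sequence: str, engine: str | None = None) -> FoldedStructure:
    """Minimum-free-energy structure of an RNA (or DNA; T->U) sequence.

    ``engine`` is "vienna", "builtin", or None for the best available.
    Sequences shorter than 15 nt are rejected.
    """
    rna = to_rna(sequence)
    if len(rna) < MIN_FOLD_LEN:
        raise ValueError(f"sequence of {len(rna)} nt too short to fold (min {MIN_FOLD_LEN})")
    engine = engine or default_engine_name()
    if engine == "vienna":
        mod = _vienna_module()
        if mod is None:
            raise RuntimeError("ViennaRNA bindings not importable")
        db, mfe = mod.fold(rna)
        mfe = float(mfe)
        if "(" not in db:
            mfe = 0.0
        return FoldedStructure(rna, db, mfe)
    if engine == "builtin":
        db, mfe = fold_builtin(rna)
        return FoldedStructure(rna, db, mfe)
    raise ValueError(f"unknown folding engine {engine!r}")


def pair_table(dotbracket: str) -> np.ndarray:
    """Partner index per position (-1 = unpaired); rejects unbalanced input."""
    pt = np.full(len(dotbracket), -1, dtype=int)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def n_hairpin_loops(dotbracket: str) -> int:
    """Number of terminal (hairpin) loops: '(' ... ')' with only dots between."""
    n = 0
    last_open = -1
    for i, c in enumerate(dotbracket):
        if c == "(":
            last_open = i
        elif c == ")":
            if last_open >= 0:
                n += 1
            last_open = -1
    return n


# ---------------------------------------------------------------------------
# builtin engine


def _pair_e(a: str, b: str) -> float:
    return PAIR_ENERGY.get((a, b), 0.0)


def fold_builtin(rna: str) -> tuple[str, float]:
    """Weighted pair-maximization fold with stacking bonuses.

    Two-matrix dynamic program: V[i,j] is the optimum given (i,j)
    paired, W[i,j] the unconstrained optimum on [i,j].  Stacked pairs
    ((i,j) directly enclosing (i+1,j-1)) earn STACK_BONUS.
    """
    n = len(rna)
    INF = 1e9
    V = np.full((n, n), INF)
    W = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pe = _pair_e(rna[i], rna[j])
            if pe < 0.0:
                inner = W[i + 1, j - 1]
                if V[i + 1, j - 1] < INF / 2:
                    inner = min(inner, V[i + 1, j - 1] + STACK_BONUS)
                V[i, j] = pe + inner
            best = min(W[i + 1, j], W[i, j - 1], V[i, j])
            if span >= 2:
                ks = np.arange(i, j)
                best = min(best, float(np.min(W[i, ks] + W[ks + 1, j])))
            W[i, j] = best
    db = ["."] * n
    _traceback(rna, V, W, 0, n - 1, db)
    return "".join(db), float(W[0, n - 1]) if n > 1 else 0.0


def _traceback(rna: str, V: np.ndarray, W: np.ndarray, i: int, j: int, db: list[str], paired: bool = False) -> None:
    stack = [(i, j, paired)]
    while stack:
        i, j, paired = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if paired:
            db[i], db[j] = "(", ")"
            pe = _pair_e(rna[i], rna[j])
            target = V[i, j] - pe
            if V[i + 1, j - 1] < 1e8 and abs(V[i + 1, j - 1] + STACK_BONUS - target) < 1e-9:
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        w = W[i, j]
        if w == 0.0:
            continue
        if abs(V[i, j] - w) < 1e-9:
            stack.append((i, j, True))
        elif abs(W[i + 1, j] - w) < 1e-9:
            stack.append((i + 1, j, False))
        elif abs(W[i, j - 1] - w) < 1e-9:
            stack.append((i, j - 1, False))
        else:
            for k in range(i, j):
                if abs(W[i, k] + W[k + 1, j] - w) < 1e-9:
                    stack.append((i, k, False))
                    stack.append((k + 1, j, False))
                    break


def write_vienna(records: list[tuple[str, FoldedStructure]], path) -> None:
    """Write folded records in Vienna format (header, sequence, structure+energy)."""
    with open(path, "w") as fh:
        for name, fs in records:
            fh.write(f">{name}\n{fs.sequence}\n{fs.dotbracket} ({fs.mfe:.2f})\n")
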