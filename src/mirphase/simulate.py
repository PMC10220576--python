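"""Seeded synthetic study generator with a ground-truth manifest.

From a single seed this module generates a complete toy phase-change
study: a contig genome with planted hairpin precursor loci and decoys,
a miRBase-style reference set, per-library small-RNA FASTQ reads with
isomiR variation and negative-binomial count noise around planted
group means, transcripts carrying complementary target sites of
designed expectation, and a qPCR Ct table with two reference genes.
Every planted item is recorded in a manifest so each pipeline stage can
be checked against known truth.  All generators are pure functions of
(parameters, seed).

The default study mirrors the four-group design of in vitro
phase-change experiments (rejuvenated REV, mature in vitro IVM,
juvenile seedling JUV, mature tree MAT; four libraries each, ~20k reads
per library) with phase-change-typical expression patterns: miR156/miR169/miR394
high in juvenile samples, miR166 high in mature samples, miR172
uniformly low, miR159 flat.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from mirphase.formats import (
    DEFAULT_GROUPS,
    LibraryDesign,
    RunConfig,
    revcomp,
    write_design,
    write_fasta,
)

# canonical mature sequences of the planted conserved families (DNA alphabet)
PLANTED_MATURES: dict[str, str] = {
    "miR156": "TTGACAGAAGATAGAGAGCAC",
    "miR159": "TTTGGATTGAAGGGAGCTCTA",
    "miR166": "TCGGACCAGGCTTCATTCCCC",
    "miR169": "CAGCCAAGGATGACTTGCCGA",
    "miR171": "TGATTGAGCCGCGCCAATATC",
    "miR172": "AGAATCTTGATGATGCTGCAT",
    "miR394": "TTGGCATTCTGTCCACCTCCA",
    "miR396": "TTCCACAGCTTTCTTGAACTG",
    "miR398": "TGTGTTCTCAGGTCACCCCTT",
    "miR408": "ATGCACTGCCTCTTCCCTGGC",
}

# expected counts per library by sample group; flat rows are null families
PLANTED_MEANS: dict[str, dict[str, float]] = {
    "miR156": {"REV": 240, "IVM": 60, "JUV": 400, "MAT": 25},
    "miR159": {"REV": 150, "IVM": 150, "JUV": 150, "MAT": 150},
    "miR166": {"REV": 150, "IVM": 250, "JUV": 40, "MAT": 500},
    "miR169": {"REV": 120, "IVM": 60, "JUV": 300, "MAT": 20},
    "miR171": {"REV": 180, "IVM": 160, "JUV": 40, "MAT": 35},
    "miR172": {"REV": 3, "IVM": 3, "JUV": 3, "MAT": 3},
    "miR394": {"REV": 180, "IVM": 50, "JUV": 200, "MAT": 40},
    "miR396": {"REV": 80, "IVM": 60, "JUV": 160, "MAT": 30},
    "miR398": {"REV": 100, "IVM": 90, "JUV": 150, "MAT": 30},
    "miR408": {"REV": 200, "IVM": 80, "JUV": 150, "MAT": 20},
}

SECOND_MATURES = {  # extra distinct mature per family, for ambiguity/grouping
    "miR166": "TCTCGGACCAGGCTTCATTCC",
}

DE_DESIGN_FC = 4.0  # a family is planted-DE when its extreme group ratio >= this

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
NB_DISPERSION = 0.2
ISOMIR_PROBS = {"canonical": 0.6, "length": 0.3, "substitution": 0.1}

# hairpin cassette parts; the bulge interrupts the outer stem so precursor
# trimming has a defined cut site
_OUT5 = "GCACGGTCAG"
_BULGE5 = "AAC"
_HELPER5 = "GCTGGCAG"
_LOOP = "ATTTCA"


@dataclass
class PlantedPrecursor:
    locus_id: str
    family: str
    contig: str
    start: int  # mature-arm span, 0-based half-open, forward axis
    end: int
    strand: str
    is_valid_hairpin: bool


@dataclass
class PlantedTarget:
    family: str
    transcript: str
    start: int  # 0-based half-open
    end: int
    expectation_designed: float


@dataclass
class TruthManifest:
    seed: int
    preset: str
    library_depth: int
    planted_families: list[dict] = field(default_factory=list)
    planted_precursors: list[PlantedPrecursor] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    isomir_profile: dict = field(default_factory=lambda: dict(ISOMIR_PROBS))
    design: list[dict] = field(default_factory=list)

    @property
    def de_families(self) -> list[str]:
        return [f["family"] for f in self.planted_families if f["is_de"]]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        data = json.loads(Path(path).read_text())
        data["planted_precursors"] = [PlantedPrecursor(**p) for p in data["planted_precursors"]]
        data["planted_targets"] = [PlantedTarget(**t) for t in data["planted_targets"]]
        return cls(**data)


def default_design(n_libs: int = 4, groups=DEFAULT_GROUPS) -> list[LibraryDesign]:
    return [
        LibraryDesign(library_id=f"{g}{i + 1}", sample_group=g, fastq_path=f"reads/{g}{i + 1}.fastq")
        for g in groups
        for i in range(n_libs)
    ]


def reference_records(families: dict[str, str] | None = None) -> dict[str, str]:
    """miRBase-style reference mature FASTA records (two species per family)."""
    families = families or PLANTED_MATURES
    recs: dict[str, str] = {}
    for fam in sorted(families):
        num = fam.replace("miR", "")
        recs[f"ath-miR{num}a"] = families[fam]
        recs[f"gma-miR{num}a"] = families[fam]
        if fam in SECOND_MATURES:
            recs[f"ath-miR{num}b"] = SECOND_MATURES[fam]
    return recs


def hairpin_cassette(mature: str) -> tuple[str, int, int]:
    """A valid pre-miRNA cassette around a mature sequence.

    Layout: outer stem | 3-nt bulge | inner stem | mature | loop |
    star (= reverse complement of mature) | inner stem' | outer stem'.
    Returns (cassette, mature_start, mature_end) within the cassette.
    """
    five = _OUT5 + _BULGE5 + _HELPER5
    cassette = five + mature + _LOOP + revcomp(mature) + revcomp(_HELPER5) + revcomp(_OUT5)
    return cassette, len(five), len(five) + len(mature)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def make_genome(
    seed: int,
    n_contigs: int = 10,
    contig_len: int = 50_000,
    families: dict[str, str] | None = None,
) -> tuple[dict[str, str], list[PlantedPrecursor]]:
    """Random contigs with planted valid hairpin cassettes and decoy loci.

    Each family gets two valid cassettes and two decoys (the mature
    sequence in shuffled cassette context and in low-GC unstructured
    context); one family additionally gets a tandem triple within 500 nt
    gaps to exercise precursor clustering.
    """
    families = families or PLANTED_MATURES
    rng = np.random.default_rng(seed)
    min_cassette = 1000
    if contig_len < min_cassette:
        raise ValueError("contig_len must be >= 1 kb")
    contigs = {
        f"contig{i + 1}": list(_random_seq(rng, contig_len)) for i in range(n_contigs)
    }
    contig_ids = sorted(contigs)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_ids}

    def place(contig: str, length: int, near: int | None = None) -> int:
        for _ in range(200):
            if near is not None and 100 <= near <= contig_len - length - 100:
                pos = near
            else:
                pos = int(rng.integers(200, contig_len - length - 200))
            span = (pos - 100, pos + length + 100)
            if all(e <= span[0] or s >= span[1] for s, e in occupied[contig]):
                occupied[contig].append((pos, pos + length))
                return pos
            near = None
        raise RuntimeError("could not place cassette; contigs too small/crowded")

    planted: list[PlantedPrecursor] = []

    def plant(contig: str, cassette: str, mstart: int, mend: int, family: str, valid: bool, idx: int, near: int | None = None) -> int:
        pos = place(contig, len(cassette), near)
        contigs[contig][pos : pos + len(cassette)] = list(cassette)
        planted.append(
            PlantedPrecursor(
                locus_id=f"{family}_{'valid' if valid else 'decoy'}_{idx}",
                family=family,
                contig=contig,
                start=pos + mstart,
                end=pos + mend,
                strand="+",
                is_valid_hairpin=valid,
            )
        )
        return pos

    fam_list = sorted(families)
    cluster_family = fam_list[-1]  # tandem triple for one family
    for i, fam in enumerate(fam_list):
        mature = families[fam]
        cassette, ms, me = hairpin_cassette(mature)
        c1 = contig_ids[i % n_contigs]
        c2 = contig_ids[(i + 3) % n_contigs]
        plant(c1, cassette, ms, me, fam, True, 1)
        if fam == cluster_family:
            base = plant(c2, cassette, ms, me, fam, True, 2)
            for j, gap in enumerate((500, 1000), start=3):
                plant(c2, cassette, ms, me, fam, True, j, near=base + gap * (j - 2) + len(cassette))
        else:
            plant(c2, cassette, ms, me, fam, True, 2)
        # decoy 1: mature inside a base-shuffled cassette context
        context = list(cassette[:ms] + cassette[me:])
        rng.shuffle(context)
        half = len(context) // 2
        shuffled = "".join(context[:half]) + mature + "".join(context[half:])
        plant(contig_ids[(i + 5) % n_contigs], shuffled, half, half + len(mature), fam, False, 1)
        # decoy 2: mature in low-GC unstructured context
        low = _random_seq(rng, 40, gc=0.12) + mature + _random_seq(rng, 40, gc=0.12)
        plant(contig_ids[(i + 7) % n_contigs], low, 40, 40 + len(mature), fam, False, 2)

    genome = {c: "".join(contigs[c]) for c in contig_ids}
    planted.sort(key=lambda p: (p.contig, p.start))
    return genome, planted


def _isomir_read(rng: np.random.Generator, mature: str) -> str:
    kind = rng.choice(3, p=[ISOMIR_PROBS["canonical"], ISOMIR_PROBS["length"], ISOMIR_PROBS["substitution"]])
    if kind == 0:
        return mature
    if kind == 1:  # 3' length variant within +/-2 nt
        delta = int(rng.choice([-2, -1, 1, 2]))
        return mature[:delta] if delta < 0 else mature + "A" * delta
    pos = int(rng.integers(0, len(mature)))  # one internal substitution
    alt = "ACGT".replace(mature[pos], "")[int(rng.integers(0, 3))]
    return mature[:pos] + alt + mature[pos + 1 :]


def make_reads(
    seed: int,
    design: list[LibraryDesign] | None = None,
    depth: int = 20_000,
    means: dict[str, dict[str, float]] | None = None,
    families: dict[str, str] | None = None,
    background_fraction: float | None = None,
    adapter: str = ADAPTER,
) -> dict[str, list[str]]:
    """Per-library read lists (sequence only; FASTQ written by the caller).

    Planted family counts are drawn negative-binomially (dispersion 0.2)
    around the group means; isomiR variants follow the 60/30/10
    canonical/length/substitution profile; random background reads fill
    each library to ``depth`` (or to ``background_fraction`` of it).
    The adapter is appended to every read.
    """
    design = design or default_design()
    means = means or PLANTED_MEANS
    families = families or PLANTED_MATURES
    rng = np.random.default_rng(seed)
    r = 1.0 / NB_DISPERSION  # NB size parameter
    out: dict[str, list[str]] = {}
    for entry in design:
        reads: list[str] = []
        for fam in sorted(families):
            mu = means[fam][entry.sample_group]
            if mu <= 0:
                continue
            n = int(rng.negative_binomial(r, r / (r + mu)))
            reads.extend(_isomir_read(rng, families[fam]) for _ in range(n))
        if background_fraction is None:
            n_bg = max(0, depth - len(reads))
        else:
            n_bg = int(depth * background_fraction)
        lens = rng.integers(18, 26, size=n_bg)
        reads.extend(_random_seq(rng, int(l)) for l in lens)
        out[entry.library_id] = [s + adapter for s in reads]
    return out


def write_fastq(reads: dict[str, list[str]], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lib in sorted(reads):
        with open(outdir / f"{lib}.fastq", "w") as fh:
            for i, seq in enumerate(reads[lib]):
                fh.write(f"@{lib}_{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


def _mismatch_base(rng_or_none, mir_base: str) -> str:
    """A target base that neither pairs nor wobbles with the miRNA base."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[mir_base]
    wob = {"G": "T", "T": "G"}.get(mir_base)
    for b in "ACGT":
        if b != comp and b != wob:
            return b
    raise AssertionError


def designed_site(mature: str, expectation: float, seed_start: int = 2, seed_end: int = 13) -> tuple[str, float]:
    """A complementary site of (approximately) the requested expectation.

    Penalties are introduced deterministically: seed mismatches first
    (2.0 each), then non-seed mismatches (1.0), then one non-seed G:U
    wobble (0.5).  Returns (site 5'->3', achieved designed expectation).
    """
    k = len(mature)
    site = list(revcomp(mature))  # site index k - pos pairs miRNA position pos

    def set_mismatch(pos: int) -> None:
        site[k - pos] = _mismatch_base(None, mature[pos - 1])

    def set_wobble(pos: int) -> bool:
        wob = {"G": "T", "T": "G"}.get(mature[pos - 1])
        if wob is None:
            return False
        site[k - pos] = wob
        return True

    achieved = 0.0
    seed_positions = [5, 9]  # at most 2 seed mismatches allowed
    nonseed_positions = [p for p in range(seed_end + 2, k) if p <= k]
    si, ni = 0, 0
    while achieved + 2.0 <= expectation and si < len(seed_positions):
        set_mismatch(seed_positions[si])
        achieved += 2.0
        si += 1
    while achieved + 1.0 <= expectation and ni < len(nonseed_positions):
        set_mismatch(nonseed_positions[ni])
        achieved += 1.0
        ni += 1
    if achieved + 0.5 <= expectation and ni < len(nonseed_positions):
        if set_wobble(nonseed_positions[ni]):
            achieved += 0.5
    return "".join(site), achieved


def make_transcripts(
    seed: int,
    families: dict[str, str] | None = None,
    n_background: int = 60,
    transcript_len: int = 300,
) -> tuple[dict[str, str], list[PlantedTarget]]:
    """Transcripts with planted target sites of designed expectation.

    Per family: sites of expectation 0, 2 and 3.5 (reported at the
    default cutoff 5) and one negative of expectation 6, plus random
    background transcripts carrying no designed site.
    """
    families = families or PLANTED_MATURES
    rng = np.random.default_rng(seed)
    transcripts: dict[str, str] = {}
    targets: list[PlantedTarget] = []
    for fam in sorted(families):
        mature = families[fam]
        for label, wanted in (("e0", 0.0), ("e2", 2.0), ("e35", 3.5), ("e6", 6.0)):
            site, achieved = designed_site(mature, wanted)
            body = _random_seq(rng, transcript_len)
            pos = int(rng.integers(50, transcript_len - len(site) - 50))
            seq = body[:pos] + site + body[pos + len(site) :]
            name = f"t_{fam}_{label}"
            transcripts[name] = seq
            targets.append(
                PlantedTarget(
                    family=fam,
                    transcript=name,
                    start=pos,
                    end=pos + len(site),
                    expectation_designed=achieved,
                )
            )
    for i in range(n_background):
        transcripts[f"t_bg{i + 1}"] = _random_seq(rng, transcript_len)
    return transcripts, targets


def make_ct_table(
    seed: int,
    effects: dict[str, float] | None = None,
    target_gene: str = "pre-miR156",
    groups=DEFAULT_GROUPS,
    n_samples: int = 3,
    n_replicates: int = 3,
    sample_sd: float = 0.15,
    replicate_sd: float = 0.08,
) -> "pd.DataFrame":
    """A qPCR Ct table: target gene with per-group ddCt effects, two
    effect-free reference genes, three technical replicates.

    ``effects`` maps sample_group -> cycles added to the target Ct
    (negative = higher expression); default plants a -2 cycle effect in
    JUV relative to the MAT calibrator (RQ ~ 4).
    """
    import pandas as pd

    effects = effects if effects is not None else {"JUV": -2.0, "REV": -1.0, "IVM": -0.3, "MAT": 0.0}
    rng = np.random.default_rng(seed)
    baselines = {target_gene: 24.0, "actin": 20.0, "cyclophilin": 21.0}
    rows = []
    for g in groups:
        for s in range(1, n_samples + 1):
            sample_id = f"{g}_s{s}"
            shift = {gene: rng.normal(0.0, sample_sd) for gene in baselines}
            for gene, base in baselines.items():
                effect = effects.get(g, 0.0) if gene == target_gene else 0.0
                for rep in range(1, n_replicates + 1):
                    ct = base + effect + shift[gene] + rng.normal(0.0, replicate_sd)
                    rows.append((sample_id, g, gene, rep, round(float(ct), 4)))
    return pd.DataFrame(rows, columns=["sample_id", "sample_group", "gene_id", "replicate", "ct"])


def simulate_study(
    outdir: str | Path,
    seed: int = 0,
    preset: str = "default",
) -> TruthManifest:
    """Generate and write the complete toy study.

    Writes genome.fa, reference_mirnas.fa, transcripts.fa, design.tsv,
    ct_table.csv, reads/<library>.fastq and truth_manifest.json under
    ``outdir``.  ``preset`` is "default" (10 contigs x 50 kb, 16
    libraries x ~20k reads) or "tiny" (2 contigs x 6 kb, 8 libraries x
    ~3k reads, three planted families) for quick tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "default":
        families = dict(PLANTED_MATURES)
        means = PLANTED_MEANS
        n_contigs, contig_len, depth, n_libs = 10, 50_000, 20_000, 4
    elif preset == "tiny":
        families = {f: PLANTED_MATURES[f] for f in ("miR156", "miR166", "miR159")}
        means = {f: PLANTED_MEANS[f] for f in families}
        n_contigs, contig_len, depth, n_libs = 2, 6_000, 3_000, 2
    else:
        raise ValueError(f"unknown preset {preset!r}")

    design = default_design(n_libs=n_libs)
    genome, precursors = make_genome(seed, n_contigs, contig_len, families)
    reads = make_reads(seed + 1, design, depth, means, families)
    transcripts, targets = make_transcripts(seed + 2, families)
    ct = make_ct_table(seed + 3)

    write_fasta(genome, outdir / "genome.fa")
    write_fasta(reference_records(families), outdir / "reference_mirnas.fa")
    write_fasta(transcripts, outdir / "transcripts.fa")
    write_design(design, outdir / "design.tsv")
    write_fastq(reads, outdir / "reads")
    ct.to_csv(outdir / "ct_table.csv", index=False)

    manifest = TruthManifest(
        seed=seed,
        preset=preset,
        library_depth=depth,
        planted_families=[
            {
                "family": fam,
                "mature_sequence": families[fam],
                "means": {g: means[fam][g] for g in DEFAULT_GROUPS},
                "fold_changes": _pairwise_fcs(means[fam]),
                "is_de": _is_de(means[fam]),
            }
            for fam in sorted(families)
        ],
        planted_precursors=precursors,
        planted_targets=targets,
        design=[asdict(d) for d in design],
    )
    manifest.to_json(outdir / "truth_manifest.json")
    return manifest


def _pairwise_fcs(means: dict[str, float]) -> dict[str, float]:
    out = {}
    groups = [g for g in DEFAULT_GROUPS if g in means]
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            out[f"{a}_vs_{b}"] = round(means[a] / means[b], 4)
    return out


def _is_de(means: dict[str, float]) -> bool:
    vals = [means[g] for g in means]
    return max(vals) / max(min(vals), 1e-9) >= DE_DESIGN_FC
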