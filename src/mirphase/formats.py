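"""File formats and run configuration.

Covers every external format the pipeline touches: FASTQ small-RNA
reads, miRBase-style mature/hairpin FASTA, genome and transcript
multi-FASTA, the library design table, GFF3 output for predicted
precursors, and the flat-key YAML run configuration.

Coordinate convention: 0-based half-open everywhere in memory,
1-based inclusive in GFF3 output.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator

import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("REV", "IVM", "JUV", "MAT")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA input; DNA output alphabet kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_dna(seq: str) -> str:
    """Uppercase and convert U->T.  All sequences are held as DNA internally."""
    return seq.upper().replace("U", "T")


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the offending line."""


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline.

    Defaults are the published analysis settings: 18-25 nt length window,
    minimum total tag count 5, two mismatches and two-nucleotide end
    overhangs for family annotation, |fold change| >= 1.5 at FDR < 0.05,
    +/-100 nt precursor flanks, MFEI >= 0.85 with a >=19 nt double-stranded
    segment and 19-25 nt mature/star arms, and psRNATarget-style target
    scoring (seed 2-13, expectation cutoff 5).
    """

    min_len: int = 18
    max_len: int = 25
    min_total_count: int = 5
    max_mismatches_annotation: int = 2
    max_overhang: int = 2
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    flank: int = 100
    mfei_threshold: float = 0.85
    min_ds_segment: int = 19
    arm_min: int = 19
    arm_max: int = 25
    max_mismatches_genome: int = 2
    max_gaps_genome: int = 1
    cluster_max_gap: int = 10_000
    expectation_cutoff: float = 5.0
    seed_start: int = 2
    seed_end: int = 13
    adapter: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")
        if self.seed_start >= self.seed_end:
            raise ValueError("seed_start must be < seed_end")
        for name in (
            "min_len", "max_len", "min_total_count", "fc_threshold",
            "fdr_threshold", "flank", "mfei_threshold", "min_ds_segment",
            "arm_min", "arm_max", "expectation_cutoff", "cluster_max_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def updated(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# library design


@dataclass(frozen=True)
class LibraryDesign:
    """One sequencing library and the sample group it belongs to."""

    library_id: str
    sample_group: str
    fastq_path: str = ""


def read_design(path: str | Path) -> list[LibraryDesign]:
    """Read a TSV design table: library_id, sample_group[, fastq_path]."""
    entries: list[LibraryDesign] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("library_id", "sample_group"):
            if col not in idx:
                raise ValueError(f"design table missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            entries.append(
                LibraryDesign(
                    library_id=parts[idx["library_id"]],
                    sample_group=parts[idx["sample_group"]],
                    fastq_path=parts[idx["fastq_path"]] if "fastq_path" in idx else "",
                )
            )
    validate_design(entries)
    return entries


def write_design(entries: list[LibraryDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tsample_group\tfastq_path\n")
        for e in entries:
            fh.write(f"{e.library_id}\t{e.sample_group}\t{e.fastq_path}\n")


def validate_design(entries: list[LibraryDesign]) -> None:
    ids = [e.library_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_ids in design")
    if not entries:
        raise ValueError("empty design")


def groups_of(design: list[LibraryDesign]) -> dict[str, list[str]]:
    """Map sample_group -> list of library_ids (design order preserved)."""
    out: dict[str, list[str]] = {}
    for e in design:
        out.setdefault(e.sample_group, []).append(e.library_id)
    return out


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (read_id, sequence, quality) from a 4-line-record FASTQ.

    Sequences are uppercased with U->T normalization.  A malformed record
    raises :class:`FastqParseError` naming the approximate line number.
    """
    n = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ record near line {4 * n + 1}: {exc}"
                ) from exc
            n += 1
            yield title.split()[0], normalize_dna(seq), qual


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA into an ordered {id: uppercase DNA sequence} dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = normalize_dna(str(rec.seq))
    return out


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# miRBase-style references

# e.g. gma-miR156a, ath-miR172b-3p, osa-let-7, ppe-miR482a-2-5p
_MIRNA_NAME_RE = re.compile(
    r"^(?P<species>[a-z]{3,4})-"
    r"(?P<core>(?:miR|MIR)\d+|let-?7)"
    r"(?P<variant>[a-z]*(?:[-.]\d+)?)"
    r"(?:-(?P<arm>[35]p))?$",
    re.IGNORECASE,
)


def parse_mirna_name(name: str) -> tuple[str, str, str | None] | None:
    """Parse a miRBase mature name into (species_code, family, arm).

    The family is the core ``miR<number>`` (or ``let-7``): the species
    prefix, trailing variant letters/numbers and the -3p/-5p arm suffix
    are stripped, so gma-miR156a and ath-miR156j-5p both yield miR156.
    Returns None when no miR/let identifier can be parsed.
    """
    m = _MIRNA_NAME_RE.match(name.strip())
    if m is None:
        return None
    core = m.group("core")
    if core.lower().startswith("let"):
        family = "let-7"
    else:
        family = "miR" + re.sub(r"\D", "", core)
    return m.group("species").lower(), family, m.group("arm")


@dataclass(frozen=True)
class ReferenceMiRNA:
    """A miRBase reference sequence (mature or hairpin)."""

    accession: str
    family: str
    species_code: str
    mature_sequence: str
    kind: str = "mature"  # mature | hairpin
    arm: str | None = None

    def __post_init__(self) -> None:
        if not self.mature_sequence:
            raise ValueError("empty reference sequence")
        if set(self.mature_sequence) - set("ACGTN"):
            raise ValueError(f"non-DNA alphabet in {self.accession}")


def read_mirbase_fasta(path: str | Path, kind: str = "mature") -> list[ReferenceMiRNA]:
    """Read a miRBase-style FASTA of mature miRNAs (or hairpins).

    Headers whose first token does not carry a parseable miR/let
    identifier are skipped with a logged warning; duplicate accessions
    are an error.
    """
    refs: list[ReferenceMiRNA] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ValueError(f"duplicate accession {name!r} in {path}")
        seen.add(name)
        parsed = parse_mirna_name(name)
        if parsed is None:
            logger.warning("skipping reference with unparseable name %r", name)
            warnings.warn(f"skipping reference with unparseable name {name!r}")
            continue
        species, family, arm = parsed
        refs.append(
            ReferenceMiRNA(
                accession=name,
                family=family,
                species_code=species,
                mature_sequence=normalize_dna(str(rec.seq)),
                kind=kind,
                arm=arm,
            )
        )
    return refs


# ---------------------------------------------------------------------------
# GFF3 for predicted precursors


def write_gff3(precursors, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write precursor candidates as GFF3 (1-based inclusive coordinates).

    Each candidate becomes a ``pre_miRNA`` feature with ``miRNA`` (mature)
    and ``miRNA_star`` children; all coordinates are on the forward axis.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, cand in enumerate(precursors):
            if contig_lengths is not None:
                clen = contig_lengths.get(cand.contig_id)
                if clen is not None and (cand.start < 0 or cand.end > clen):
                    raise ValueError(
                        f"precursor {i} coordinates [{cand.start},{cand.end}) "
                        f"outside contig {cand.contig_id} length {clen}"
                    )
            pid = f"pre_miRNA_{i + 1}"
            attrs = (
                f"ID={pid};family={cand.family};group_id={cand.group_id};"
                f"mfei={cand.mfei:.4f};passes={str(cand.passes).lower()}"
            )
            fh.write(
                f"{cand.contig_id}\tmirphase\tpre_miRNA\t{cand.start + 1}\t{cand.end}\t"
                f".\t{cand.strand}\t.\t{attrs}\n"
            )
            for feat, span in (("miRNA", cand.mature_contig_span), ("miRNA_star", cand.star_contig_span)):
                if span is None:
                    continue
                s, e = span
                fh.write(
                    f"{cand.contig_id}\tmirphase\t{feat}\t{s + 1}\t{e}\t.\t"
                    f"{cand.strand}\t.\tID={pid}.{feat};Parent={pid}\n"
                )


@dataclass(frozen=True)
class Gff3Record:
    contig_id: str
    feature: str
    start: int  # 0-based half-open
    end: int
    strand: str
    attributes: dict[str, str]


def read_gff3(path: str | Path) -> list[Gff3Record]:
    """Read a GFF3 file back into records with 0-based half-open coordinates."""
    records: list[Gff3Record] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            records.append(
                Gff3Record(
                    contig_id=cols[0],
                    feature=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return records
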