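"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis flow of a conserved-miRNA phase-change
study: collapse -> annotate -> differential expression -> precursor and
target prediction (run on the differentially expressed isomiR groups
only) -> optional qPCR.  Every stage writes plain files into the run
directory and can be re-run independently; a run manifest records the
configuration echo, input checksums, stage timings and the headline
counts at each stage.  Given a fixed seed and configuration the stage
outputs are byte-identical across runs (the manifest's wall-clock
timings are the only non-deterministic output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from mirphase import diffexpr, homology, precursor, preprocess, qpcr, targets
from mirphase.folding import default_engine_name
from mirphase.formats import (
    LibraryDesign,
    RunConfig,
    read_design,
    read_fasta,
    read_fastq,
    read_mirbase_fasta,
    write_gff3,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineInputs:
    design_path: Path
    reference_path: Path
    genome_path: Path | None = None
    transcripts_path: Path | None = None
    ct_path: Path | None = None
    calibrator_group: str = "MAT"
    base_dir: Path | None = None  # fastq paths in the design are relative to this

    def __post_init__(self) -> None:
        self.design_path = Path(self.design_path)
        self.reference_path = Path(self.reference_path)
        if self.base_dir is None:
            self.base_dir = self.design_path.parent
        for name in ("genome_path", "transcripts_path", "ct_path"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    engine: str = ""
    input_checksums: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    error: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, inputs: PipelineInputs, outdir: str | Path) -> RunManifest:
    """Execute all applicable stages; see the module docstring for the flow.

    The precursor stage requires ``genome_path``; requesting it without
    one raises a StageError naming the missing input.  The run manifest
    is written (with the error recorded) even on partial failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={f.name: getattr(config, f.name) for f in dataclasses.fields(config)},
        engine=default_engine_name(),
    )
    for p in (inputs.design_path, inputs.reference_path, inputs.genome_path,
              inputs.transcripts_path, inputs.ct_path):
        if p is not None and p.exists():
            manifest.input_checksums[p.name] = _sha256(p)

    state: dict = {}
    stages = [
        ("collapse", _stage_collapse),
        ("annotate", _stage_annotate),
        ("de", _stage_de),
        ("precursors", _stage_precursors),
        ("targets", _stage_targets),
        ("qpcr", _stage_qpcr),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            fn(config, inputs, outdir, state, manifest)
            manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", name, manifest.stage_seconds[name])
    except Exception as exc:
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(outdir / "run_manifest.json")
        if isinstance(exc, StageError):
            raise
        raise StageError(name, exc) from exc
    manifest.write(outdir / "run_manifest.json")
    return manifest


def _stage_collapse(config, inputs, outdir, state, manifest) -> None:
    design = read_design(inputs.design_path)
    state["design"] = design
    reads = {}
    reads_in = {}
    for entry in design:
        path = Path(entry.fastq_path)
        if not path.is_absolute():
            path = inputs.base_dir / path
        seqs = [seq for _, seq, _ in read_fastq(path)]
        reads_in[entry.library_id] = len(seqs)
        reads[entry.library_id] = seqs
    all_tags = preprocess.collapse(reads, config, apply_min_count=False)
    state["library_sizes"] = {
        lib: sum(t.counts.get(lib, 0) for t in all_tags) for lib in reads
    }
    tags = [t for t in all_tags if t.total_count >= config.min_total_count]
    tags.sort(key=lambda t: (-t.total_count, t.sequence))
    state["tags"] = tags
    lib_ids = [d.library_id for d in design]
    preprocess.write_tag_table(tags, lib_ids, outdir / "tags.tsv")
    manifest.counts.update(
        reads_in=sum(reads_in.values()),
        reads_in_range=sum(state["library_sizes"].values()),
        unique_tags=len(all_tags),
        tags_retained=len(tags),
    )


def _stage_annotate(config, inputs, outdir, state, manifest) -> None:
    refs = read_mirbase_fasta(inputs.reference_path)
    state["refs"] = refs
    assignments = homology.assign_all(state["tags"], refs, config)
    groups = homology.build_groups(assignments, refs)
    summaries = homology.summarize_families(assignments, state["design"])
    state["assignments"], state["groups"] = assignments, groups
    homology.write_assignment_table(assignments, outdir / "assignments.tsv")
    homology.write_family_summary(summaries, state["design"], outdir / "family_summary.tsv")
    manifest.counts.update(
        conserved_isomirs=sum(1 for a in assignments if a.annotated),
        ambiguous_isomirs=sum(1 for a in assignments if a.ambiguous),
        isomir_groups=len(groups),
        families=len(summaries),
    )


def _stage_de(config, inputs, outdir, state, manifest) -> None:
    lib_ids = [d.library_id for d in state["design"]]
    matrix = diffexpr.counts_to_matrix(state["groups"], lib_ids)
    state["matrix"] = matrix
    results, union = diffexpr.run_all_comparisons(
        matrix, state["design"], config, state["library_sizes"]
    )
    state["de_results"], state["de_union"] = results, union
    cpm = diffexpr.normalize_cpm(matrix, state["library_sizes"])
    cpm.to_csv(outdir / "normalized_matrix.tsv", sep="\t", index_label="group_id")
    per_comp = {}
    for (a, b), df in results.items():
        df.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t", index_label="group_id")
        per_comp[f"{a}_vs_{b}"] = int(df["significant"].sum())
    manifest.counts.update(de_groups_per_comparison=per_comp, de_groups_union=len(union))


def _stage_precursors(config, inputs, outdir, state, manifest) -> None:
    if inputs.genome_path is None:
        return
    if not inputs.genome_path.exists():
        raise FileNotFoundError(f"genome input missing: {inputs.genome_path}")
    genome = read_fasta(inputs.genome_path)
    queries = _de_queries(state)
    cands = precursor.find_precursors(queries, genome, config)
    clusters = precursor.find_clusters(cands, config.cluster_max_gap)
    state["precursors"] = cands
    precursor.write_precursor_table(cands, outdir / "precursors.tsv")
    passing = [c for c in cands if c.passes]
    write_gff3(passing, outdir / "precursors.gff3", {c: len(s) for c, s in genome.items()})
    from mirphase.folding import write_vienna

    write_vienna(
        [(f"{c.group_id}|{c.contig_id}:{c.start + 1}-{c.end}({c.strand})", c.structure) for c in cands],
        outdir / "precursors.vienna",
    )
    manifest.counts.update(
        precursors_found=len(cands),
        precursors_passing=len(passing),
        precursor_clusters=len(clusters),
    )


def _stage_targets(config, inputs, outdir, state, manifest) -> None:
    if inputs.transcripts_path is None:
        return
    transcripts = read_fasta(inputs.transcripts_path)
    mirnas = {gid: seq for gid, (fam, seq) in _de_queries(state).items()}
    hits = targets.scan_transcripts(mirnas, transcripts, config)
    state["target_hits"] = hits
    targets.write_target_table(hits, outdir / "target_hits.tsv")
    manifest.counts.update(
        target_hits=len(hits),
        target_genes=len({h.transcript_id for h in hits}),
    )


def _stage_qpcr(config, inputs, outdir, state, manifest) -> None:
    if inputs.ct_path is None:
        return
    ct = qpcr.read_ct_csv(inputs.ct_path)
    ref_genes = qpcr.DEFAULT_REFERENCE_GENES
    results = []
    test_rows = []
    for gene in sorted(set(ct["gene_id"]) - set(ref_genes)):
        rqs = qpcr.delta_delta_ct(ct, gene, inputs.calibrator_group, ref_genes)
        results.extend(rqs)
        dct = qpcr.sample_delta_ct(ct, gene, ref_genes)
        anova_p, pw, degen = qpcr.group_tests(dct)
        for _, row in pw.iterrows():
            test_rows.append((gene, anova_p, row["group_a"], row["group_b"],
                              row["p_value"], row["fdr"], bool(row["significant"]), degen))
    qpcr.write_rq_table(results, outdir / "qpcr_rq.tsv")
    pd.DataFrame(
        test_rows,
        columns=["gene_id", "anova_p", "group_a", "group_b", "p_value", "fdr", "significant", "degenerate"],
    ).to_csv(outdir / "qpcr_tests.tsv", sep="\t", index=False)
    manifest.counts.update(qpcr_genes=len({r.gene_id for r in results}))


def _de_queries(state) -> dict[str, tuple[str, str]]:
    """group_id -> (family, representative mature sequence) for DE groups.

    Precursor and target prediction consume only the differentially
    expressed groups; the representative is the group's most abundant
    member tag.
    """
    by_id = {g.group_id: g for g in state["groups"]}
    out = {}
    for gid in sorted(state["de_union"]):
        g = by_id[gid]
        out[gid] = (g.family, g.members[0].tag.sequence)
    return out
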