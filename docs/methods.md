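# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic study generator does and does not
emulate, and the known limitations.

## Read collapsing

Reads are adapter-trimmed by removing the suffix starting at the leftmost
exact match of the adapter's first 8 bases (no mismatch-tolerant adapter
alignment; small-RNA adapters are long enough that an exact 8-mer seed is
specific). The length window defaults to 18–25 nt; 19 nt is a supported
alternative lower bound via `min_len`. Collapsing produces one tag per
distinct sequence with exact per-library counts; the minimum-count filter
(default 5) applies to the **total over all libraries**, not per library.
Output ordering (total count descending, then sequence) makes collapsing
invariant to read order. No quality-based filtering is applied.

## Conserved-miRNA annotation

A tag is compared to each reference mature sequence over all ungapped
placements in which either end overhangs or falls short of the reference
by ≤2 nt; the placement minimizing mismatches in the overlap wins, with
ties broken by smallest total |end offset| and then the 5′-most placement
— a deterministic, order-independent hierarchy. Overhanging tag bases are
free (they represent templated isomiR length variation, not errors).
Internal gaps are deliberately not allowed here; gaps are reserved for
genome mapping, where indel tolerance reflects genuine divergence between
species rather than isomiR biology.

Ambiguity follows the convention of counting a tag as ambiguously
annotated when two *distinct* reference mature sequences tie at the best
score; the same sequence deposited under several species accessions does
not create ambiguity. A tie across families assigns the tag once, to the
lexicographically smallest family.

"isomiR groups" are operationalized as connected components over
reference mature sequences within the assigned family: two references
belong to one group when some tag has both among its best hits. This is
finer than the family and captures the distinct-mature-variant structure
of large families (e.g. two miR166 matures differing by end shifts). The
group consensus is the count-weighted majority base per aligned column,
aligned against the component's lexicographically smallest reference.

## Differential expression

Counts are normalized to CPM against the per-library count of
length-filtered reads (not just the retained tags), so a library's
conserved-miRNA content does not distort normalization. The test is
Welch's *t* on log2(CPM + 1) — the upstream commercial tool used in the
original study does not document its internal test, so a robust,
dependency-light two-sample test was chosen and is documented as this
package's own convention. Fold changes use pseudocount-stabilized group
means, (mean_a + 1 CPM)/(mean_b + 1 CPM), because low-abundance families
(counts of 1–7) make raw ratios unstable; down-regulation is reported as
the negative reciprocal, matching the "≥1.5 or ≤ −1.5" convention.
Benjamini–Hochberg FDR is applied within each pairwise comparison, not
jointly across the six comparisons, matching per-comparison DE counting.
Zero-variance identical groups get p = 1. With fewer than two libraries
per group the test raises rather than silently producing p-values.

## Precursor prediction

Genome mapping is an exhaustive scan of both strands with ≤2 mismatches
plus, optionally, one single-nucleotide gap on either sequence
(vectorized prefix/suffix mismatch sums; completeness is checked against
a brute-force sliding window in the tests). Gapped hits overlapping an
ungapped hit at the same locus are suppressed.

Windows of ±100 nt (clipped at contig edges, where the entire available
sequence is used) are folded with the default engine — ViennaRNA's MFE
fold via its python bindings. A built-in fallback engine (weighted
base-pair maximization with stacking bonuses: GC −3, AU −2, GU −1,
−1 per stacked pair, minimum loop 3) keeps the package functional and
hermetically testable without the thermodynamic library; the engine used
is recorded in the run manifest, and no test asserts exact engine-specific
MFE values.

The miRNA\* arm is the pairing-partner span of the mature arm shifted by
the 2-nt 3′ overhang each strand carries in the Dicer duplex; star
location fails when <60% of mature positions are paired or the arms would
overlap. The precursor is trimmed by walking the stem outward from the
outermost duplex pair and cutting immediately after the first bulge or
interior loop (of ≥1 nt, on either side) beyond the duplex; the hairpin's
terminal loop never triggers trimming, and a clean stem runs to the
window edge. The trimmed sequence is refolded before scoring.

Scores: AMFE = |MFE|/length × 100; MFEI = AMFE / GC% (GC on the 0–100
scale, reported positive). A candidate passes when MFEI ≥ 0.85, the
longest uninterrupted run of paired positions on one arm is ≥ 19 nt,
both arms are 19–25 nt and the structure has exactly one terminal loop.
Sub-threshold candidates are reported with `passes = false` rather than
dropped, since borderline MFEI values are still informative. A hairpin
reached from both the mature-arm hit and the star-arm (reverse
complement) hit trims to the same locus; such duplicates are collapsed
to one candidate. Candidates within 10 kb on one contig form clusters
(≥2 members).

## Target prediction

The expectation score follows the published psRNATarget defaults: per
aligned position, Watson–Crick pair 0, G:U wobble 0.5, mismatch 1, gap 2;
penalties are doubled at miRNA positions 2–13 (the seed). Sites are kept
at expectation ≤ 5 with ≤ 2 seed mismatches+gaps. Because the server's
exact gap-extension constants have varied between versions, gap handling
is bounded — one bulge of ≤2 nt on either strand per duplex — and the
constants are configurable. Overlapping sites of one miRNA–transcript
pair are reduced to the best-scoring site (ties: fewest seed mismatches,
then leftmost, then gapless). Translation-inhibition classification is
not implemented; hits are reported score-only.

## qPCR quantification

Per sample, ΔCt = mean technical-replicate Ct(target) − mean of the two
reference genes' mean Cts; averaging reference Cts arithmetically equals
the geometric mean of their linear quantities, a standard two-reference
normalization. ΔΔCt per group is the group mean ΔCt minus the
calibrator's; RQ = 2^−ΔΔCt with RQmin = 2^−(ΔΔCt+SE) and
RQmax = 2^−(ΔΔCt−SE). SE is computed over biological samples (not
technical replicates) so the bounds reflect biological spread.
Amplification efficiency is fixed at 2.0. Degenerate (all-equal) inputs
yield p = 1 with a flag rather than NaN.

## Synthetic study generator

The generator emulates the study design the pipeline targets: 4 sample
groups × 4 libraries at ~20,000 reads per library, 10 genome contigs of
50 kb, 10 conserved families with group-mean expression patterns typical
of phase-change data (miR156/miR169/miR394/miR396/miR398 high in
juvenile samples, miR166 high in mature, miR172 uniformly near-zero,
miR159 flat as a null). Counts are negative-binomial with dispersion 0.2
(overdispersion typical of small-RNA libraries; it stresses the DE
test), isomiR variation is 60% canonical / 30% ±1–2 nt 3′ length
variants / 10% single substitutions, and random background reads fill
each library to its depth so CPM normalization is compositionally
balanced. Planted hairpin cassettes are perfect mature/star duplexes
with an 8-bp inner stem, a 6-nt loop, a designed 3-nt bulge and a 10-bp
outer stem, so trimming has a defined cut site; decoys embed the mature
sequence in base-shuffled cassette context and in low-GC unstructured
context. One family is planted as a tandem triple within ≤1 kb to
exercise cluster detection. Transcripts carry complementary sites built
to designed expectations (0, 2, 3.5 and a 6.0 negative) by introducing
penalties with known costs. Ct tables plant per-group cycle shifts on
the target gene only, with N(0, 0.15) sample and N(0, 0.08) replicate
noise.

What the generator does **not** emulate: platform-specific error
profiles, barcode loss, 5′ isomiR templated variants, multi-locus
families with divergent matures, compositional (library-size) biases,
and transcript secondary-structure effects on target accessibility.
Passing tests therefore demonstrate correctness of the algorithms under
controlled conditions, not performance on real libraries.

These toy sizes were chosen so the full test suite runs in about two
minutes on one CPU while leaving every recovery margin wide (planted
fold changes of ≥4 against a detection threshold of 1.5; hairpin MFEIs
near 1.6 against a threshold of 0.85).

## Determinism

All generators and stages are pure functions of (parameters, seed); two
runs with the same seed and configuration produce byte-identical study
files and stage outputs. The only exception is the run manifest's
wall-clock stage timings.

## Known limitations

- The Welch-on-log-CPM test is not a count-model test; for very low
  counts an exact/NB test would be better calibrated. The null
  false-positive rate is verified empirically instead (≤7% at the 0.05
  FDR threshold over 200 replicates).
- The builtin folding engine is not thermodynamic; MFEI values from it
  are on a different scale than ViennaRNA's and should not be compared
  against the 0.85 threshold in production use.
- Genome mapping is exhaustive-scan based and intended for
  contig-scale toy genomes and candidate regions, not for
  chromosome-scale assemblies (no index structure).
- Ambiguity between near-identical families (e.g. miR165/miR166) is
  resolved by best-hit with a deterministic tie-break, which may
  undercount shared reads relative to a both-hit convention.
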