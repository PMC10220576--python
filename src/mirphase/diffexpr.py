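"""Group-level differential expression of isomiR groups.

Counts are normalized to reads per million (CPM) per library; each
pairwise sample-group comparison is tested with Welch's t on
log2(CPM + 1), fold changes come from pseudocount-stabilized group mean
CPMs, and Benjamini-Hochberg FDR is applied within each comparison.  A
group is differentially expressed when |fold change| >= 1.5 and
FDR-corrected p < 0.05 (both thresholds configurable).

Fold changes use the signed-ratio convention: values >= 1 mean up in
the first group; down-regulation is reported as the negative reciprocal
(e.g. a halving is -2, never 0.5).
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirphase.formats import LibraryDesign, RunConfig, groups_of

PSEUDOCOUNT_CPM = 1.0


def normalize_cpm(
    matrix: pd.DataFrame, library_sizes: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Counts -> reads per million, per library.

    ``library_sizes`` defaults to the column sums; a zero size is an
    error.  Row order is preserved.
    """
    if library_sizes is None:
        library_sizes = matrix.sum(axis=0).to_dict()
    sizes = pd.Series({c: library_sizes[c] for c in matrix.columns}, dtype=float)
    if (sizes <= 0).any():
        bad = sizes[sizes <= 0].index.tolist()
        raise ValueError(f"zero library size for {bad}")
    return matrix.div(sizes, axis=1) * 1e6


def signed_fold_change(mean_a: float, mean_b: float, pseudocount: float = PSEUDOCOUNT_CPM) -> float:
    ratio = (mean_a + pseudocount) / (mean_b + pseudocount)
    return ratio if ratio >= 1 else -1.0 / ratio


def test_pairwise(
    matrix: pd.DataFrame,
    design: Sequence[LibraryDesign],
    group_a: str,
    group_b: str,
    config: RunConfig | None = None,
    library_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Differential expression for one ordered pair of sample groups.

    Returns a DataFrame (index: group_id) with mean CPM per group, the
    signed fold change (a vs b), Welch-t p-value on log2(CPM+1), BH FDR
    across all rows of this comparison, and the significance flag.
    """
    config = config or RunConfig()
    by_group = groups_of(list(design))
    for g in (group_a, group_b):
        if g not in by_group:
            raise ValueError(f"unknown sample group {g!r}")
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g!r} has <2 libraries; p-values undefined")
    libs_a = [l for l in by_group[group_a] if l in matrix.columns]
    libs_b = [l for l in by_group[group_b] if l in matrix.columns]
    cpm = normalize_cpm(matrix, library_sizes)
    xa = np.log2(cpm[libs_a].to_numpy() + PSEUDOCOUNT_CPM)
    xb = np.log2(cpm[libs_b].to_numpy() + PSEUDOCOUNT_CPM)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance, identical groups
    mean_a = cpm[libs_a].mean(axis=1).to_numpy()
    mean_b = cpm[libs_b].mean(axis=1).to_numpy()
    fc = np.array([signed_fold_change(a, b) for a, b in zip(mean_a, mean_b)])
    if len(pvals):
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        fdr = pvals
    significant = (np.abs(fc) >= config.fc_threshold) & (fdr < config.fdr_threshold)
    return pd.DataFrame(
        {
            "comparison": f"{group_a}_vs_{group_b}",
            f"mean_cpm_a": mean_a,
            f"mean_cpm_b": mean_b,
            "fold_change": fc,
            "p_value": pvals,
            "fdr": fdr,
            "significant": significant,
        },
        index=matrix.index,
    )


def run_all_comparisons(
    matrix: pd.DataFrame,
    design: Sequence[LibraryDesign],
    config: RunConfig | None = None,
    library_sizes: Mapping[str, int] | None = None,
) -> tuple[dict[tuple[str, str], pd.DataFrame], set[str]]:
    """All unordered pairwise comparisons plus the union of significant groups.

    Group pairs are taken in design order; the union counts distinct
    row ids significant in at least one comparison.
    """
    names = list(dict.fromkeys(d.sample_group for d in design))
    if len(names) < 2:
        raise ValueError("need >=2 sample groups")
    results: dict[tuple[str, str], pd.DataFrame] = {}
    union: set[str] = set()
    for a, b in itertools.combinations(names, 2):
        res = test_pairwise(matrix, design, a, b, config, library_sizes)
        results[(a, b)] = res
        union.update(res.index[res["significant"]])
    return results, union


def counts_to_matrix(groups, library_ids: Sequence[str]) -> pd.DataFrame:
    """Build the group x library count matrix from isomiR groups."""
    data = {
        g.group_id: [g.per_group_counts.get(lib, 0) for lib in library_ids]
        for g in groups
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(library_ids))
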