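"""qPCR relative quantification by the 2^-ddCt method.

Per sample, dCt is the mean technical-replicate Ct of the target gene
minus the average of the two reference genes' mean Cts (arithmetically
averaging reference Cts equals the geometric mean of their linear
quantities).  ddCt per sample group is the group mean dCt minus the
calibrator group's mean dCt; relative quantity RQ = 2^-ddCt with error
bounds RQmin = 2^-(ddCt+SE) and RQmax = 2^-(ddCt-SE), SE being the
standard error of dCt over biological samples within the group.
Group differences are assessed with one-way ANOVA on dCt plus pairwise
t-tests with Benjamini-Hochberg correction (threshold p < 0.05).
Amplification efficiency is assumed to be 2.0 (no efficiency
correction).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample_id", "sample_group", "gene_id", "replicate", "ct"]
DEFAULT_REFERENCE_GENES = ("actin", "cyclophilin")


@dataclass(frozen=True)
class RQResult:
    gene_id: str
    sample_group: str
    rq: float
    rq_min: float
    rq_max: float
    se_ddct: float
    ddct: float
    calibrator_group: str
    n_samples: int


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample_id, sample_group, gene_id, replicate, ct."""
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("non-positive Ct values")
    return df


def sample_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
) -> pd.DataFrame:
    """Per-sample dCt = mean Ct(target) - mean of reference genes' mean Cts.

    Samples missing the target or any reference gene are excluded with a
    warning.  Returns columns sample_id, sample_group, delta_ct.
    """
    mean_ct = (
        ct_table.groupby(["sample_id", "sample_group", "gene_id"])["ct"]
        .mean()
        .reset_index()
    )
    rows = []
    for (sample, group), sub in mean_ct.groupby(["sample_id", "sample_group"]):
        by_gene = dict(zip(sub["gene_id"], sub["ct"]))
        missing = [g for g in (*reference_genes, target_gene) if g not in by_gene]
        if missing:
            logger.warning("sample %s excluded: missing gene(s) %s", sample, missing)
            continue
        ref = float(np.mean([by_gene[g] for g in reference_genes]))
        rows.append((sample, group, by_gene[target_gene] - ref))
    return pd.DataFrame(rows, columns=["sample_id", "sample_group", "delta_ct"])


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    calibrator_group: str,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
) -> list[RQResult]:
    """2^-ddCt relative expression of ``target_gene`` per sample group.

    The calibrator group has RQ = 1 by construction.  SE is the
    standard error of dCt over biological samples within each group.
    """
    dct = sample_delta_ct(ct_table, target_gene, reference_genes)
    if dct.empty:
        raise ValueError(f"no usable samples for gene {target_gene!r}")
    groups = list(dict.fromkeys(dct["sample_group"]))
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    by_group = {g: dct.loc[dct["sample_group"] == g, "delta_ct"].to_numpy() for g in groups}
    for g, vals in by_group.items():
        if vals.size == 0:
            raise ValueError(f"group {g!r} empty after exclusions")
    cal_mean = float(np.mean(by_group[calibrator_group]))
    out: list[RQResult] = []
    for g in groups:
        vals = by_group[g]
        ddct = float(np.mean(vals)) - cal_mean
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out.append(
            RQResult(
                gene_id=target_gene,
                sample_group=g,
                rq=2.0 ** -ddct,
                rq_min=2.0 ** -(ddct + se),
                rq_max=2.0 ** -(ddct - se),
                se_ddct=se,
                ddct=ddct,
                calibrator_group=calibrator_group,
                n_samples=int(vals.size),
            )
        )
    return out


def group_tests(
    delta_cts: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, pd.DataFrame, bool]:
    """One-way ANOVA on dCt across groups plus BH-corrected pairwise t-tests.

    ``delta_cts`` needs columns sample_group and delta_ct, with >=2
    groups of >=2 samples.  Degenerate (zero-variance, equal-mean) input
    yields p = 1 with the degenerate flag set.  Returns
    (anova_p, pairwise DataFrame, degenerate).
    """
    groups = list(dict.fromkeys(delta_cts["sample_group"]))
    arrays = [delta_cts.loc[delta_cts["sample_group"] == g, "delta_ct"].to_numpy() for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 samples each")
    pooled = np.concatenate(arrays)
    degenerate = bool(np.allclose(pooled, pooled[0]))
    if degenerate:
        anova_p = 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            anova_p = float(stats.f_oneway(*arrays).pvalue)
        if np.isnan(anova_p):
            anova_p, degenerate = 1.0, True
    rows = []
    for (ga, xa), (gb, xb) in itertools.combinations(zip(groups, arrays), 2):
        if np.allclose(np.concatenate([xa, xb]), xa[0]):
            p = 1.0
        else:
            p = float(stats.ttest_ind(xa, xb).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append((ga, gb, p))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value"])
    if len(pw):
        _, fdr, _, _ = multipletests(pw["p_value"], method="fdr_bh")
        pw["fdr"] = fdr
        pw["significant"] = pw["fdr"] < alpha
    return anova_p, pw, degenerate


def write_rq_table(results: Sequence[RQResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsample_group\trq\trq_min\trq_max\tse_ddct\tddct\tcalibrator\tn\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.sample_group}\t{r.rq:.6g}\t{r.rq_min:.6g}\t"
                f"{r.rq_max:.6g}\t{r.se_ddct:.6g}\t{r.ddct:.6g}\t{r.calibrator_group}\t{r.n_samples}\n"
            )
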