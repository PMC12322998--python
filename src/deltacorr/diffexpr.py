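"""Differential abundance between tumor and normal samples.

This is the comparator the delta-corr statistic is contrasted with: a gene
can change abundance without changing its mRNA/protein coupling and vice
versa. Per gene and layer, a two-sided Wilcoxon rank-sum test and the mean
log2 fold-change (difference of means; inputs are contractually log2-scale)
are computed, p-values are BH-adjusted per layer per cohort, and a gene is
flagged differentially expressed when q < 0.05 and |log2FC| > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corr_core import CorrelationConfig
from .io_formats import AbundanceMatrix, CohortDesign
from .perm_inference import bh_adjust

DE_ALPHA = 0.05
DE_LFC_THRESHOLD = 1.0
_EXACT_MAX_N = 8


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have <= 8 observations and no ties
    span the groups; otherwise normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def log2_fold_change(x_tumor: np.ndarray, y_normal: np.ndarray) -> float:
    """Mean log2 fold-change: mean(tumor) - mean(normal) on log2 inputs."""
    x_tumor = np.asarray(x_tumor, dtype=float)
    y_normal = np.asarray(y_normal, dtype=float)
    if len(x_tumor) == 0 or len(y_normal) == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.mean(x_tumor) - np.mean(y_normal))


def differential_expression(
    matrix: AbundanceMatrix,
    design: CohortDesign,
    cohort: str,
    config: CorrelationConfig | None = None,
    linear_input: bool = False,
) -> pd.DataFrame:
    """Per-gene DE table for one layer of one cohort.

    Genes need at least ``min_n`` non-missing samples per condition (the same
    cutoff as the correlation analysis). ``linear_input=True`` log2-transforms
    values first for matrices stored on the linear scale.
    """
    config = config or CorrelationConfig()
    min_n = config.effective_min_n(cohort)
    tumor_ids = [s for s in design.samples_for("tumor", cohort) if s in matrix.data.columns]
    normal_ids = [s for s in design.samples_for("normal", cohort) if s in matrix.data.columns]
    data = matrix.data
    if linear_input:
        data = np.log2(data)
    rows = []
    for gene in matrix.genes:
        xt = data.loc[gene, tumor_ids].to_numpy(dtype=float)
        xn = data.loc[gene, normal_ids].to_numpy(dtype=float)
        xt = xt[~np.isnan(xt)]
        xn = xn[~np.isnan(xn)]
        if len(xt) < min_n or len(xn) < min_n:
            continue
        rows.append(
            {
                "gene": gene, "cohort": cohort, "layer": matrix.layer,
                "log2fc": log2_fold_change(xt, xn),
                "p": wilcoxon_rank_sum(xt, xn),
                "n_tumor": len(xt), "n_normal": len(xn),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "cohort", "layer", "log2fc", "p", "n_tumor", "n_normal"],
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    table["de_flag"] = (table["q"] < DE_ALPHA) & (table["log2fc"].abs() > DE_LFC_THRESHOLD)
    return table


def overlap_summary(
    de: pd.DataFrame, dc: pd.DataFrame, layer: str | None = None
) -> dict[str, int]:
    """Partition jointly evaluable genes into DE-only / delta-corr-only /
    both / neither.

    A gene counts as DE when flagged in either layer (the gene-set reading of
    the comparison); pass ``layer`` to restrict to one layer. Joint genes are
    those present in both tables for matching cohorts.
    """
    de_use = de if layer is None else de[de["layer"] == layer]
    de_genes_all = set(zip(de_use["gene"], de_use["cohort"]))
    dc_eval = dc[dc["delta_corr"].notna()]
    dc_genes_all = set(zip(dc_eval["gene"], dc_eval["cohort"]))
    joint = de_genes_all & dc_genes_all
    de_flagged = set(
        zip(de_use.loc[de_use["de_flag"], "gene"], de_use.loc[de_use["de_flag"], "cohort"])
    ) & joint
    dc_flagged = set(
        zip(dc_eval.loc[dc_eval["significant"], "gene"],
            dc_eval.loc[dc_eval["significant"], "cohort"])
    ) & joint
    both = de_flagged & dc_flagged
    return {
        "de_only": len(de_flagged - both),
        "delta_corr_only": len(dc_flagged - both),
        "both": len(both),
        "neither": len(joint) - len(de_flagged | dc_flagged),
    }
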