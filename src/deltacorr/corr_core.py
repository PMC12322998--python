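"""Gene-wise Spearman mRNA/protein correlations and the delta-corr statistic.

For each gene, mRNA and protein abundances are paired per sample
(pairwise-complete: a sample contributes iff both layers are quantified for
that gene), and Spearman's rank correlation is computed separately over tumor
and over normal samples. The statistic of interest is

    delta_corr = rho_tumor - rho_normal,

in [-2, 2]: positive means the protein tracks its transcript more tightly in
tumor tissue. A correlation is only reported when the condition has at least
``min_n`` paired data points for the gene (default 15; per-cohort overrides
allow smaller normal pools, e.g. 10 for endometrial cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceMatrix, CohortDesign

DEFAULT_MIN_N = 15


@dataclass(frozen=True)
class CorrelationConfig:
    """Minimum paired-sample cutoffs for reporting a correlation.

    ``min_n`` applies to every cohort unless ``min_n_override`` maps the
    cohort name to a different cutoff. Spearman needs at least 3 points.
    """

    min_n: int = DEFAULT_MIN_N
    min_n_override: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_n < 3:
            raise ValueError("min_n must be >= 3 (Spearman undefined below)")
        for cohort, n in self.min_n_override.items():
            if n < 3:
                raise ValueError(f"min_n override for {cohort!r} must be >= 3")

    def effective_min_n(self, cohort: str) -> int:
        return self.min_n_override.get(cohort, self.min_n)


@dataclass(frozen=True)
class PairedGeneSeries:
    """Per-gene paired (mRNA, protein) observations with sample annotations.

    Only samples where both layers are non-missing for this gene are kept.
    """

    gene: str
    sample_ids: tuple[str, ...]
    mrna: np.ndarray
    protein: np.ndarray
    condition: np.ndarray  # str array, "tumor"/"normal"
    stage: tuple[str | None, ...] = ()

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, mask: np.ndarray) -> "PairedGeneSeries":
        idx = np.flatnonzero(mask)
        return PairedGeneSeries(
            gene=self.gene,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            mrna=self.mrna[idx],
            protein=self.protein[idx],
            condition=self.condition[idx],
            stage=tuple(self.stage[i] for i in idx) if self.stage else (),
        )

    def n_condition(self, condition: str) -> int:
        return int(np.sum(self.condition == condition))


@dataclass(frozen=True)
class CorrelationRecord:
    gene: str
    cohort: str
    rho_tumor: float  # NaN when undefined
    n_tumor: int
    rho_normal: float
    n_normal: int


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def rowwise_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row pair of two 2-D arrays.

    Average ranks for ties, then Pearson on the ranks. Rows where either
    vector is constant yield NaN. This single code path serves both the
    scalar statistic and the vectorized permutation engine.
    """
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", rx, ry)
    den2 = np.einsum("ij,ij->i", rx, rx) * np.einsum("ij,ij->i", ry, ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / np.sqrt(den2)
    rho = np.where(den2 == 0.0, np.nan, rho)
    return np.clip(rho, -1.0, 1.0)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation of two paired vectors.

    Returns NaN when either vector is constant (the correlation is then
    undefined; reporting 0 would fabricate a signal). Requires equal lengths
    and at least 3 paired points; inputs must be free of missing values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("spearman expects 1-D vectors")
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired points, got {len(x)}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("inputs must not contain missing values")
    return float(rowwise_spearman(x[None, :], y[None, :])[0])


# ---------------------------------------------------------------------------
# Series construction and per-gene correlations
# ---------------------------------------------------------------------------

def build_series(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    design: CohortDesign,
    gene: str,
    cohort: str | None = None,
) -> PairedGeneSeries:
    """Pair the two layers for one gene over the samples shared by both
    matrices and the design, keeping samples where both values are present."""
    if gene not in mrna.data.index:
        raise KeyError(f"gene {gene!r} absent from mRNA matrix")
    if gene not in protein.data.index:
        raise KeyError(f"gene {gene!r} absent from protein matrix")
    design_tbl = design.table
    if cohort is not None:
        design_tbl = design_tbl[design_tbl["cohort"] == cohort]
    shared = [
        s for s in mrna.samples
        if s in protein.data.columns and s in design_tbl.index
    ]
    mv = mrna.data.loc[gene, shared].to_numpy(dtype=float)
    pv = protein.data.loc[gene, shared].to_numpy(dtype=float)
    keep = ~(np.isnan(mv) | np.isnan(pv))
    ids = tuple(s for s, k in zip(shared, keep) if k)
    cond = design_tbl.loc[list(ids), "condition"].to_numpy(dtype=object).astype(str) \
        if ids else np.array([], dtype=str)
    if "stage" in design_tbl.columns and ids:
        stage_raw = design_tbl.loc[list(ids), "stage"]
        stage = tuple(None if pd.isna(v) else str(v) for v in stage_raw)
    else:
        stage = tuple(None for _ in ids)
    return PairedGeneSeries(
        gene=gene,
        sample_ids=ids,
        mrna=mv[keep],
        protein=pv[keep],
        condition=cond,
        stage=stage,
    )


def gene_correlations(
    series: PairedGeneSeries, config: CorrelationConfig, cohort: str
) -> CorrelationRecord:
    """Tumor and normal Spearman correlations for one gene, applying the
    per-cohort minimum sample-size cutoff. Counts are always reported; a rho
    below the cutoff (or over a constant vector) is NaN."""
    min_n = config.effective_min_n(cohort)
    out = {}
    for condition in ("tumor", "normal"):
        mask = series.condition == condition
        n = int(mask.sum())
        if n >= min_n:
            rho = spearman(series.mrna[mask], series.protein[mask])
        else:
            rho = float("nan")
        out[condition] = (rho, n)
    return CorrelationRecord(
        gene=series.gene,
        cohort=cohort,
        rho_tumor=out["tumor"][0],
        n_tumor=out["tumor"][1],
        rho_normal=out["normal"][0],
        n_normal=out["normal"][1],
    )


def delta_corr(record: CorrelationRecord) -> float:
    """rho_tumor - rho_normal; NaN unless both correlations are defined."""
    if np.isnan(record.rho_tumor) or np.isnan(record.rho_normal):
        return float("nan")
    return record.rho_tumor - record.rho_normal


def correlate_cohort(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    design: CohortDesign,
    cohort: str,
    config: CorrelationConfig | None = None,
) -> pd.DataFrame:
    """CorrelationRecord table (with delta_corr) for every gene quantified in
    both layers of one cohort."""
    config = config or CorrelationConfig()
    genes = [g for g in mrna.genes if g in set(protein.genes)]
    rows = []
    for gene in genes:
        series = build_series(mrna, protein, design, gene, cohort=cohort)
        rec = gene_correlations(series, config, cohort)
        rows.append(
            {
                "gene": rec.gene,
                "cohort": rec.cohort,
                "rho_tumor": rec.rho_tumor,
                "n_tumor": rec.n_tumor,
                "rho_normal": rec.rho_normal,
                "n_normal": rec.n_normal,
                "delta_corr": delta_corr(rec),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "cohort", "rho_tumor", "n_tumor",
            "rho_normal", "n_normal", "delta_corr",
        ],
    )


def stage_correlations(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    design: CohortDesign,
    config: CorrelationConfig | None = None,
    stage_min_genes: int = 10,
) -> pd.DataFrame:
    """Spearman correlations stratified by (cohort, stage, condition, gene).

    Samples without a stage annotation are excluded here (they still count in
    the unstratified analysis). A (cohort, stage) stratum is dropped when it
    yields fewer than ``stage_min_genes`` genes with a defined correlation.
    """
    config = config or CorrelationConfig()
    if "stage" not in design.table.columns or design.table["stage"].isna().all():
        warnings.warn("no staged samples in design; stage table is empty")
        return pd.DataFrame(
            columns=["cohort", "stage", "condition", "gene", "rho", "n"]
        )
    shared_genes = [g for g in mrna.genes if g in set(protein.genes)]
    rows = []
    staged = design.table[design.table["stage"].notna()]
    for (cohort, stage), block in staged.groupby(["cohort", "stage"], sort=True):
        min_n = config.effective_min_n(cohort)
        stratum_rows = []
        for gene in shared_genes:
            for condition in ("tumor", "normal"):
                ids = [
                    s for s in block.index[block["condition"] == condition]
                    if s in mrna.data.columns and s in protein.data.columns
                ]
                if not ids:
                    continue
                mv = mrna.data.loc[gene, ids].to_numpy(dtype=float)
                pv = protein.data.loc[gene, ids].to_numpy(dtype=float)
                keep = ~(np.isnan(mv) | np.isnan(pv))
                n = int(keep.sum())
                if n < min_n:
                    continue
                rho = spearman(mv[keep], pv[keep])
                if np.isnan(rho):
                    continue
                stratum_rows.append(
                    {"cohort": cohort, "stage": stage, "condition": condition,
                     "gene": gene, "rho": rho, "n": n}
                )
        n_genes = len({r["gene"] for r in stratum_rows})
        if n_genes >= stage_min_genes:
            rows.extend(stratum_rows)
    return pd.DataFrame(
        rows, columns=["cohort", "stage", "condition", "gene", "rho", "n"]
    )
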