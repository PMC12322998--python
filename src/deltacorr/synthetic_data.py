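"""Synthetic proteogenomic cohorts with controlled mRNA/protein coupling.

Each gene's (mRNA, protein) pair is drawn per condition from a bivariate
Gaussian whose Pearson parameter is calibrated with r = 2*sin(pi*rho_s/6) so
the *population* Spearman correlation equals the requested target exactly —
which makes simulated delta_corr targets directly verifiable. Tumor samples
can carry abundance shifts (log2 fold-changes), stage labels, and somatic
"driver" mutations; mutation-linked genes switch their copula parameter
within mutant tumors, giving the trans-mutation screen a controllable
positive case. Missingness is masked independently per cell (MCAR).

Default cohort shape mirrors a typical tumor/normal proteogenomic study:
~100 tumor and ~30 normal samples, thousands of genes, per-gene Spearman
targets spanning weakly negative to strongly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, CohortDesign, MutationTable


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson parameter of a bivariate Gaussian with population Spearman
    correlation ``rho_s``: r = 2*sin(pi*rho_s/6). Requires |rho_s| < 1."""
    if abs(rho_s) >= 1.0:
        raise ValueError(f"|rho_s| must be < 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene: str
    rho_normal_target: float
    rho_tumor_target: float
    log2fc_mrna: float = 0.0
    log2fc_protein: float = 0.0
    mutation_linked: bool = False
    rho_mut_target: float | None = None  # coupling within mutant tumors

    def __post_init__(self) -> None:
        for r in (self.rho_normal_target, self.rho_tumor_target):
            if abs(r) >= 1.0:
                raise ValueError("rho targets must lie strictly inside (-1, 1)")
        if self.rho_mut_target is not None and abs(self.rho_mut_target) >= 1.0:
            raise ValueError("rho_mut_target must lie strictly inside (-1, 1)")

    @property
    def true_delta(self) -> float:
        return self.rho_tumor_target - self.rho_normal_target


@dataclass(frozen=True)
class SimConfig:
    """Cohort-shape and effect settings for :func:`simulate_cohort`."""

    n_genes: int = 5_000
    n_tumor: int = 100
    n_normal: int = 30
    fraction_shifted: float = 0.0
    effect_grid: tuple[float, ...] = (0.6,)
    missing_rate: float = 0.0
    n_stages: int = 0
    seed: int = 0
    cohort: str = "SYNTH"
    n_drivers: int = 3
    driver_mut_rate: float = 0.4

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor, self.n_normal) <= 0:
            raise ValueError("n_genes, n_tumor, n_normal must be positive")
        if not 0.0 <= self.fraction_shifted <= 1.0:
            raise ValueError("fraction_shifted must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.driver_mut_rate <= 1.0:
            raise ValueError("driver_mut_rate must be in [0, 1]")


# rho-target mixture roughly matching the wide, positively skewed shape of
# observed per-gene mRNA/protein correlations: a test fixture, not a claim
# about any real cohort.
_MIX_WEIGHTS = (0.60, 0.25, 0.15)
_MIX_BOUNDS = ((0.0, 0.7), (-0.2, 0.2), (-0.5, 0.0))


def draw_truths(config: SimConfig, rng: np.random.Generator) -> list[GeneTruth]:
    """Default ground truth: null genes share one rho in both conditions
    drawn from the background mixture; the first ``fraction_shifted`` of
    genes get (rho_normal=0, rho_tumor=effect) with effects cycling through
    ``effect_grid``."""
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    comp = rng.choice(len(_MIX_WEIGHTS), size=config.n_genes, p=_MIX_WEIGHTS)
    lo = np.array([b[0] for b in _MIX_BOUNDS])[comp]
    hi = np.array([b[1] for b in _MIX_BOUNDS])[comp]
    base = rng.uniform(lo, hi)
    n_shift = round(config.fraction_shifted * config.n_genes)
    truths = []
    for i, gene in enumerate(genes):
        if i < n_shift:
            effect = config.effect_grid[i % len(config.effect_grid)]
            truths.append(GeneTruth(gene, 0.0, float(effect)))
        else:
            truths.append(GeneTruth(gene, float(base[i]), float(base[i])))
    return truths


def _copula_block(
    r: np.ndarray, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(n_genes, n_samples) standard-normal pairs with per-cell Pearson r."""
    z1 = rng.standard_normal((r.shape[0], n_samples))
    z2 = rng.standard_normal((r.shape[0], n_samples))
    if r.ndim == 1:
        r = r[:, None]
    y = r * z1 + np.sqrt(1.0 - r**2) * z2
    return z1, y


def simulate_cohort(
    config: SimConfig, truths: list[GeneTruth] | None = None
) -> tuple[AbundanceMatrix, AbundanceMatrix, CohortDesign, MutationTable, list[GeneTruth]]:
    """Generate one synthetic cohort: mRNA and protein matrices, sample
    design, somatic mutation table, and the ground-truth list.

    The first ``n_drivers`` genes act as mutation drivers: each is mutated in
    a ``driver_mut_rate`` Bernoulli draw per tumor. Genes with
    ``mutation_linked=True`` use ``rho_mut_target`` instead of the tumor
    target within tumors carrying a mutation in the *first* driver.
    """
    rng = np.random.default_rng(config.seed)
    if truths is None:
        truths = draw_truths(config, rng)
    if len(truths) != config.n_genes:
        raise ValueError(f"expected {config.n_genes} truths, got {len(truths)}")
    genes = [t.gene for t in truths]
    tumor_ids = [f"T{i:04d}" for i in range(config.n_tumor)]
    normal_ids = [f"N{i:04d}" for i in range(config.n_normal)]

    # marginal locations per gene and layer (log2-abundance scale)
    mu_mrna = rng.normal(5.0, 2.0, size=config.n_genes)
    mu_prot = rng.normal(5.0, 2.0, size=config.n_genes)

    # driver mutations in tumors
    n_drivers = min(config.n_drivers, config.n_genes)
    driver_genes = genes[:n_drivers]
    mut_mask = rng.random((n_drivers, config.n_tumor)) < config.driver_mut_rate

    r_normal = np.array([spearman_to_pearson(t.rho_normal_target) for t in truths])
    r_tumor_1d = np.array([spearman_to_pearson(t.rho_tumor_target) for t in truths])
    r_tumor = np.tile(r_tumor_1d[:, None], (1, config.n_tumor))
    if n_drivers > 0:
        linked = [i for i, t in enumerate(truths)
                  if t.mutation_linked and t.rho_mut_target is not None]
        for i in linked:
            r_tumor[i, mut_mask[0]] = spearman_to_pearson(truths[i].rho_mut_target)

    zt_m, zt_p = _copula_block(r_tumor, config.n_tumor, rng)
    zn_m, zn_p = _copula_block(r_normal, config.n_normal, rng)

    lfc_m = np.array([t.log2fc_mrna for t in truths])[:, None]
    lfc_p = np.array([t.log2fc_protein for t in truths])[:, None]
    mrna_vals = np.hstack([zt_m + mu_mrna[:, None] + lfc_m, zn_m + mu_mrna[:, None]])
    prot_vals = np.hstack([zt_p + mu_prot[:, None] + lfc_p, zn_p + mu_prot[:, None]])

    samples = tumor_ids + normal_ids
    if config.missing_rate > 0.0:
        mrna_vals = np.where(
            rng.random(mrna_vals.shape) < config.missing_rate, np.nan, mrna_vals
        )
        prot_vals = np.where(
            rng.random(prot_vals.shape) < config.missing_rate, np.nan, prot_vals
        )

    mrna = AbundanceMatrix(
        layer="mRNA", data=pd.DataFrame(mrna_vals, index=genes, columns=samples)
    )
    protein = AbundanceMatrix(
        layer="protein", data=pd.DataFrame(prot_vals, index=genes, columns=samples)
    )

    design_rows = []
    stages = [_roman(i + 1) for i in range(config.n_stages)]
    stage_assign = (
        rng.integers(0, config.n_stages, size=config.n_tumor)
        if config.n_stages > 0 else None
    )
    for j, s in enumerate(tumor_ids):
        design_rows.append(
            {
                "sample_id": s, "condition": "tumor", "cohort": config.cohort,
                "stage": stages[stage_assign[j]] if stage_assign is not None else np.nan,
                "patient_id": f"P{j:04d}",
            }
        )
    for j, s in enumerate(normal_ids):
        design_rows.append(
            {
                "sample_id": s, "condition": "normal", "cohort": config.cohort,
                "stage": np.nan, "patient_id": f"P{config.n_tumor + j:04d}",
            }
        )
    design = CohortDesign(
        table=pd.DataFrame(design_rows).set_index("sample_id")
    )

    mut_rows = []
    for d, gene in enumerate(driver_genes):
        for j in np.flatnonzero(mut_mask[d]):
            mut_rows.append(
                {"gene": gene, "sample_id": tumor_ids[j], "variant_class": "Missense"}
            )
    mutations = MutationTable(
        records=pd.DataFrame(mut_rows, columns=["gene", "sample_id", "variant_class"])
    )
    return mrna, protein, design, mutations, truths


def truth_table(truths: list[GeneTruth]) -> pd.DataFrame:
    """Per-gene ground-truth table for recovery scoring."""
    return pd.DataFrame(
        [
            {
                "gene": t.gene,
                "rho_normal_target": t.rho_normal_target,
                "rho_tumor_target": t.rho_tumor_target,
                "true_delta_corr": t.true_delta,
                "log2fc_mrna": t.log2fc_mrna,
                "log2fc_protein": t.log2fc_protein,
                "de_mrna": abs(t.log2fc_mrna) > 1.0,
                "de_protein": abs(t.log2fc_protein) > 1.0,
                "mutation_linked": t.mutation_linked,
            }
            for t in truths
        ]
    )


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if 1 <= n <= len(numerals) else str(n)
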