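"""Effect of somatic mutations on the mRNA/protein coupling of other genes.

For each frequently mutated gene of a cohort, tumor samples are split into
mutant and wild-type groups, and for every other gene ("trans gene", plus the
mutated gene itself labeled "cis") delta_corr = rho(mutant) - rho(wild-type)
is tested with the same label-permutation machinery as the tumor/normal
analysis — only the grouping labels differ. BH correction is applied within
each mutated gene's trans set, and an effect is significant at q < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, CohortDesign, MutationTable
from .corr_core import build_series
from .perm_inference import (
    PermutationConfig,
    PermutationOutcome,
    bh_adjust,
    two_group_permutation_test,
)

TRANS_ALPHA = 0.05


def top_mutated_genes(
    mutations: MutationTable,
    design: CohortDesign,
    cohort: str,
    k: int = 10,
    min_n: int = 15,
) -> list[str]:
    """The up-to-k most frequently mutated genes of a cohort's tumors, among
    genes with at least ``min_n`` mutant AND ``min_n`` wild-type tumors.

    Ties are broken deterministically: mutant count descending, then gene
    symbol ascending. Fewer than k genes are returned when fewer qualify.
    """
    tumors = set(design.samples_for("tumor", cohort))
    if mutations.records.empty or not tumors:
        import warnings

        warnings.warn(f"no tumor mutation records for cohort {cohort!r}")
        return []
    n_tumor = len(tumors)
    counts: dict[str, int] = {}
    rec = mutations.records
    in_cohort = rec[rec["sample_id"].isin(tumors)]
    for gene, block in in_cohort.groupby("gene"):
        counts[gene] = block["sample_id"].nunique()
    eligible = [
        (g, c) for g, c in counts.items()
        if c >= min_n and (n_tumor - c) >= min_n
    ]
    eligible.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in eligible[:k]]


def trans_delta_test(
    mutated_gene: str,
    trans_gene: str,
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    design: CohortDesign,
    mutations: MutationTable,
    cohort: str,
    config: PermutationConfig,
) -> tuple[PermutationOutcome, int, int]:
    """Permutation test of delta_corr between mutant and wild-type tumors for
    one (mutated gene, trans gene) pair. Returns the outcome plus the mutant
    and wild-type pairwise-complete sample counts."""
    series = build_series(mrna, protein, design, trans_gene, cohort=cohort)
    tumor_mask = series.condition == "tumor"
    sub = series.subset(tumor_mask)
    mutated = mutations.mutated_samples(mutated_gene)
    in_mut = np.array([s in mutated for s in sub.sample_ids], dtype=bool)
    n_mut = int(in_mut.sum())
    n_wt = len(sub) - n_mut
    min_n = config.correlation_config().effective_min_n(cohort)
    if n_mut < min_n or n_wt < min_n:
        return (
            PermutationOutcome(
                delta_obs=float("nan"), perm_mean=float("nan"),
                perm_sd=float("nan"), z=float("nan"), p=float("nan"),
                p_empirical=float("nan"), n_null=0, method="untestable",
                testable=False,
            ),
            n_mut, n_wt,
        )
    outcome = two_group_permutation_test(
        sub.mrna, sub.protein, in_mut, config,
        stream_key=f"{mutated_gene}:{trans_gene}",
    )
    return outcome, n_mut, n_wt


def trans_mutation_analysis(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    design: CohortDesign,
    mutations: MutationTable,
    cohort: str,
    config: PermutationConfig | None = None,
    top_k: int = 10,
    trans_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Full mutant-vs-wildtype delta_corr screen for one cohort.

    Every gene quantified in both layers is tested against each top mutated
    gene (restrict with ``trans_genes``); q-values are BH within each mutated
    gene's set, never pooled across mutated genes. The mutated gene itself is
    labeled ``cis`` in the output.
    """
    config = config or PermutationConfig()
    min_n = config.correlation_config().effective_min_n(cohort)
    drivers = top_mutated_genes(mutations, design, cohort, k=top_k, min_n=min_n)
    if trans_genes is None:
        shared = set(protein.genes)
        trans_genes = [g for g in mrna.genes if g in shared]
    blocks = []
    for driver in drivers:
        rows = []
        for gene in trans_genes:
            outcome, n_mut, n_wt = trans_delta_test(
                driver, gene, mrna, protein, design, mutations, cohort, config
            )
            rows.append(
                {
                    "cohort": cohort,
                    "mutated_gene": driver,
                    "trans_gene": gene,
                    "relation": "cis" if gene == driver else "trans",
                    "delta_corr_mut_vs_wt": outcome.delta_obs,
                    "n_mut": n_mut,
                    "n_wt": n_wt,
                    "z": outcome.z,
                    "p": outcome.p,
                }
            )
        block = pd.DataFrame(rows)
        testable = block["p"].notna()
        q = np.full(len(block), np.nan)
        if testable.any():
            q[testable.to_numpy()] = bh_adjust(block.loc[testable, "p"].to_numpy())
        block["q"] = q
        block["significant"] = (block["q"] < TRANS_ALPHA).fillna(False)
        blocks.append(block)
    columns = [
        "cohort", "mutated_gene", "trans_gene", "relation",
        "delta_corr_mut_vs_wt", "n_mut", "n_wt", "z", "p", "q", "significant",
    ]
    if not blocks:
        return pd.DataFrame(columns=columns)
    return pd.concat(blocks, ignore_index=True)[columns]
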