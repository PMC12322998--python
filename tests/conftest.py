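"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately written from first
principles (pure-Python ranking, explicit step-up loops, combinatorial
enumeration) so they share no code with the package paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from deltacorr.io_formats import AbundanceMatrix, CohortDesign, MutationTable


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def average_ranks(values) -> list[float]:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson Spearman, fully independent of the package path."""
    return pearson_oracle(average_ranks(list(x)), average_ranks(list(y)))


def bh_oracle(pvalues) -> list[float]:
    """Step-up BH by the textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvalues[i] * m / rank_from_top)
        q[i] = running_min
    return [min(v, 1.0) for v in q]


def hypergeom_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact binomial-coefficient sums."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def exhaustive_null_oracle(x, y, n_tumor: int) -> list[float]:
    """Every possible delta_corr under label permutation, by brute-force
    enumeration of the C(n, n_tumor) tumor-label assignments."""
    n = len(x)
    deltas = []
    for combo in itertools.combinations(range(n), n_tumor):
        t = set(combo)
        xt = [x[i] for i in range(n) if i in t]
        yt = [y[i] for i in range(n) if i in t]
        xn = [x[i] for i in range(n) if i not in t]
        yn = [y[i] for i in range(n) if i not in t]
        deltas.append(spearman_oracle(xt, yt) - spearman_oracle(xn, yn))
    return deltas


def rank_sum_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    obs = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2.0
    stats = [
        sum(ranks[pooled[i]] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n1)
    ]
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean))
    return extreme / len(stats)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def tiny_cohort():
    """6 genes x (6 tumor + 6 normal) cohort with known values, no missing."""
    rng = np.random.default_rng(7)
    genes = [f"GENE{i}" for i in range(6)]
    samples = [f"T{i}" for i in range(6)] + [f"N{i}" for i in range(6)]
    mrna = AbundanceMatrix(
        "mRNA", pd.DataFrame(rng.normal(5, 1, (6, 12)), index=genes, columns=samples)
    )
    protein = AbundanceMatrix(
        "protein", pd.DataFrame(rng.normal(5, 1, (6, 12)), index=genes, columns=samples)
    )
    design = CohortDesign(
        table=pd.DataFrame(
            {
                "condition": ["tumor"] * 6 + ["normal"] * 6,
                "cohort": ["TOY"] * 12,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return mrna, protein, design


@pytest.fixture()
def toy_mutations():
    rec = pd.DataFrame(
        {
            "gene": ["TP53", "TP53", "KRAS", "KRAS", "TP53"],
            "sample_id": ["T0", "T1", "T0", "T2", "T0"],
            "variant_class": ["Missense", "Nonsense", "Missense", "Silent", "Missense"],
        }
    )
    return MutationTable(records=rec)
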