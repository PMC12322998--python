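"""Label-permutation significance test for delta-corr, with BH FDR.

The null hypothesis is that the tumor/normal label carries no information
about a gene's mRNA/protein coupling. It is materialized directly: tumor and
normal labels are reshuffled across the gene's paired observations (group
sizes preserved, the within-sample mRNA-protein pairing never broken), a
"false" delta_corr is computed for each relabeling, and the observed
delta_corr is standardized against that null:

    z = (delta_obs - mean(delta_null)) / sd(delta_null),   p = 2 * (1 - Phi(|z|)).

Per-gene q-values come from Benjamini-Hochberg over all testable genes of a
cohort. A gene is called significant when q < alpha and |delta_corr| >= the
effect-size threshold (defaults 0.05 and 0.2).

Two engine details worth knowing:

* Each random shuffle contributes an *antithetic pair* of null values: the
  tumor block is read once from the head and once from the tail of the
  shuffled sample order. Both members are uniform size-preserving
  relabelings, so the null law is unchanged, but the pooled null multiset
  exactly negates under a global swap of the tumor/normal labels — which
  makes the antisymmetry of the test (delta and z negate, p invariant) hold
  numerically, not just in distribution. ``n_perm`` is rounded up to even.
* When the number of distinct label assignments C(n, n_tumor) is small
  (<= ``exhaustive_cap``), the null is enumerated exhaustively instead of
  sampled; the z -> p mapping is the same code in both modes.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corr_core import (
    CorrelationConfig,
    PairedGeneSeries,
    build_series,
    rowwise_spearman,
    spearman,
)
from .io_formats import AbundanceMatrix, CohortDesign


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation test and significance calls.

    n_perm
        Number of null relabelings per gene (default 10,000; rounded up to
        even by the antithetic-pair engine).
    seed
        Global seed; each gene gets an independent stream derived from the
        seed and the gene symbol, so results do not depend on iteration order.
    alpha, delta_threshold
        FDR level and minimum |delta_corr| for the significance call.
    exhaustive
        "auto": enumerate all label assignments when C(n, n_t) <=
        exhaustive_cap; "never": always Monte Carlo; "always": enumerate or
        raise if the assignment count exceeds the cap.
    shared_permutations
        Derive the relabeling stream from the seed alone so genes with the
        same paired sample set see identical relabelings (preserves the
        inter-gene correlation of the null). Default: independent per gene.
    """

    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    delta_threshold: float = 0.2
    min_n: int = 15
    min_n_override: dict[str, int] = field(default_factory=dict)
    exhaustive: str = "auto"
    exhaustive_cap: int = 10_000
    redraw_factor: int = 10
    report_empirical: bool = False
    shared_permutations: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.delta_threshold < 0.0:
            raise ValueError("delta_threshold must be >= 0")
        if self.exhaustive not in ("auto", "never", "always"):
            raise ValueError("exhaustive must be 'auto', 'never' or 'always'")

    def correlation_config(self) -> CorrelationConfig:
        return CorrelationConfig(min_n=self.min_n, min_n_override=dict(self.min_n_override))


@dataclass(frozen=True)
class PermutationOutcome:
    delta_obs: float
    perm_mean: float
    perm_sd: float
    z: float
    p: float
    p_empirical: float
    n_null: int
    method: str  # "exhaustive" | "montecarlo" | "untestable"
    testable: bool


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def _gene_rng(config: PermutationConfig, gene: str) -> np.random.Generator:
    if config.shared_permutations:
        entropy = [int(config.seed)]
    else:
        entropy = [int(config.seed), zlib.crc32(gene.encode("utf-8"))]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


def _z_to_p(z: float) -> float:
    """Two-sided standard-normal tail, floored at the smallest positive
    normal float. Shared by the Monte-Carlo and exhaustive paths."""
    return max(2.0 * float(stats.norm.sf(abs(z))), float(np.finfo(float).tiny))


def _null_deltas_montecarlo(
    x: np.ndarray,
    y: np.ndarray,
    n_t: int,
    n_values: int,
    rng: np.random.Generator,
    max_draws: int,
) -> np.ndarray | None:
    """Sample null delta_corr values by antithetic label shuffles.

    Returns ``None`` when the redraw budget is exhausted before every shuffle
    yields defined correlations (constant-heavy degenerate genes).
    """
    n = len(x)
    n_n = n - n_t
    n_pairs = (n_values + 1) // 2
    firsts = np.full(n_pairs, np.nan)
    lasts = np.full(n_pairs, np.nan)
    need = np.arange(n_pairs)
    base = np.arange(n)
    drawn = 0
    while need.size and drawn < max_draws:
        k = int(need.size)
        idx = np.tile(base, (k, 1))
        rng.permuted(idx, axis=1, out=idx)
        drawn += 2 * k
        # head split: tumor = first n_t; tail split: tumor = last n_t
        d_head = (
            rowwise_spearman(x[idx[:, :n_t]], y[idx[:, :n_t]])
            - rowwise_spearman(x[idx[:, n_t:]], y[idx[:, n_t:]])
        )
        d_tail = (
            rowwise_spearman(x[idx[:, n_n:]], y[idx[:, n_n:]])
            - rowwise_spearman(x[idx[:, :n_n]], y[idx[:, :n_n]])
        )
        ok = ~(np.isnan(d_head) | np.isnan(d_tail))
        firsts[need[ok]] = d_head[ok]
        lasts[need[ok]] = d_tail[ok]
        need = need[~ok]
    if need.size:
        return None
    return np.concatenate([firsts, lasts])


def _null_deltas_exhaustive(x: np.ndarray, y: np.ndarray, n_t: int) -> np.ndarray:
    """delta_corr for every distinct assignment of n_t tumor labels."""
    n = len(x)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n_t)),
        dtype=np.intp,
    ).reshape(-1, n_t)
    mask = np.zeros((combos.shape[0], n), dtype=bool)
    np.put_along_axis(mask, combos, True, axis=1)
    # stable argsort of the tumor mask lists complement (False) indices first
    comp = mask.argsort(axis=1, kind="stable")[:, : n - n_t]
    deltas = (
        rowwise_spearman(x[combos], y[combos])
        - rowwise_spearman(x[comp], y[comp])
    )
    return deltas[~np.isnan(deltas)]


def two_group_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    in_group_a: np.ndarray,
    config: PermutationConfig,
    stream_key: str,
) -> PermutationOutcome:
    """Permutation test of delta_corr = rho(group A) - rho(group B).

    This is the one engine behind both the tumor-vs-normal test (A = tumor)
    and the mutant-vs-wildtype trans-gene test (A = mutant tumors); callers
    differ only in how they define the grouping mask.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    in_group_a = np.asarray(in_group_a, dtype=bool)
    n = len(x)
    n_a = int(in_group_a.sum())
    n_b = n - n_a

    untestable = PermutationOutcome(
        delta_obs=float("nan"), perm_mean=float("nan"), perm_sd=float("nan"),
        z=float("nan"), p=float("nan"), p_empirical=float("nan"),
        n_null=0, method="untestable", testable=False,
    )
    if n_a < 3 or n_b < 3:
        return untestable
    rho_a = spearman(x[in_group_a], y[in_group_a])
    rho_b = spearman(x[~in_group_a], y[~in_group_a])
    if math.isnan(rho_a) or math.isnan(rho_b):
        return untestable
    delta_obs = rho_a - rho_b

    n_assignments = math.comb(n, n_a)
    use_exhaustive = (
        config.exhaustive == "always"
        or (config.exhaustive == "auto" and n_assignments <= config.exhaustive_cap)
    )
    if config.exhaustive == "always" and n_assignments > config.exhaustive_cap:
        raise ValueError(
            f"exhaustive mode requested but C({n},{n_a})={n_assignments} "
            f"exceeds cap {config.exhaustive_cap}"
        )
    if use_exhaustive:
        null = _null_deltas_exhaustive(x, y, n_a)
        method = "exhaustive"
        if null.size < 2:
            return untestable
    else:
        rng = _gene_rng(config, stream_key)
        null = _null_deltas_montecarlo(
            x, y, n_a, config.n_perm, rng,
            max_draws=config.redraw_factor * config.n_perm,
        )
        method = "montecarlo"
        if null is None:
            return untestable

    perm_mean = float(np.mean(null))
    perm_sd = float(np.std(null, ddof=1))
    if perm_sd == 0.0:
        # point-mass null: conservative fallbacks instead of dividing by zero
        if delta_obs == perm_mean:
            z, p = 0.0, 1.0
        else:
            z = math.copysign(math.inf, delta_obs - perm_mean)
            p = 1.0 / (null.size + 1.0)
    else:
        z = (delta_obs - perm_mean) / perm_sd
        p = _z_to_p(z)
    p_emp = (1.0 + float(np.sum(np.abs(null) >= abs(delta_obs)))) / (null.size + 1.0)
    return PermutationOutcome(
        delta_obs=delta_obs, perm_mean=perm_mean, perm_sd=perm_sd,
        z=z, p=p, p_empirical=p_emp, n_null=int(null.size),
        method=method, testable=True,
    )


# ---------------------------------------------------------------------------
# Series-level API
# ---------------------------------------------------------------------------

def permute_labels(
    series: PairedGeneSeries, rng: np.random.Generator
) -> PairedGeneSeries:
    """One uniformly random tumor/normal relabeling of a paired series,
    preserving group sizes and the per-sample (mRNA, protein) pairing."""
    labels = np.array(series.condition, copy=True)
    rng.shuffle(labels)
    return replace(series, condition=labels)


def permutation_test(
    series: PairedGeneSeries,
    config: PermutationConfig,
    cohort: str | None = None,
) -> PermutationOutcome:
    """Tumor-vs-normal permutation test for one gene's paired series."""
    min_n = config.correlation_config().effective_min_n(cohort) if cohort \
        else config.min_n
    n_t = series.n_condition("tumor")
    n_n = series.n_condition("normal")
    if n_t < min_n or n_n < min_n:
        return PermutationOutcome(
            delta_obs=float("nan"), perm_mean=float("nan"),
            perm_sd=float("nan"), z=float("nan"), p=float("nan"),
            p_empirical=float("nan"), n_null=0, method="untestable",
            testable=False,
        )
    return two_group_permutation_test(
        series.mrna, series.protein, series.condition == "tumor",
        config, stream_key=series.gene,
    )


# ---------------------------------------------------------------------------
# Multiple testing and significance calls
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0.0) | (p > 1.0) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(results: pd.DataFrame, config: PermutationConfig) -> pd.DataFrame:
    """Attach BH q-values (over testable genes) and the significance flag
    (q < alpha and |delta_corr| >= delta_threshold)."""
    out = results.copy()
    testable = out["p"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["q"] = q
    out["significant"] = (
        (out["q"] < config.alpha)
        & (out["delta_corr"].abs() >= config.delta_threshold)
    ).fillna(False)
    return out


def analyze_cohort(
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    design: CohortDesign,
    cohort: str,
    config: PermutationConfig | None = None,
) -> pd.DataFrame:
    """Full delta-corr inference for one cohort: per-gene correlations,
    permutation p, BH q over all testable genes, significance flags."""
    config = config or PermutationConfig()
    corr_cfg = config.correlation_config()
    min_n = corr_cfg.effective_min_n(cohort)
    shared = set(protein.genes)
    rows = []
    for gene in mrna.genes:
        if gene not in shared:
            continue
        series = build_series(mrna, protein, design, gene, cohort=cohort)
        t_mask = series.condition == "tumor"
        n_t = int(t_mask.sum())
        n_n = len(series) - n_t
        row = {
            "gene": gene, "cohort": cohort,
            "rho_tumor": float("nan"), "n_tumor": n_t,
            "rho_normal": float("nan"), "n_normal": n_n,
            "delta_corr": float("nan"), "perm_mean": float("nan"),
            "perm_sd": float("nan"), "z": float("nan"), "p": float("nan"),
        }
        if config.report_empirical:
            row["p_empirical"] = float("nan")
        if n_t >= min_n:
            row["rho_tumor"] = spearman(series.mrna[t_mask], series.protein[t_mask])
        if n_n >= min_n:
            row["rho_normal"] = spearman(series.mrna[~t_mask], series.protein[~t_mask])
        if n_t >= min_n and n_n >= min_n:
            out = two_group_permutation_test(
                series.mrna, series.protein, t_mask, config, stream_key=gene
            )
            if out.testable:
                row.update(
                    delta_corr=out.delta_obs, perm_mean=out.perm_mean,
                    perm_sd=out.perm_sd, z=out.z, p=out.p,
                )
                if config.report_empirical:
                    row["p_empirical"] = out.p_empirical
        rows.append(row)
    columns = [
        "gene", "cohort", "rho_tumor", "n_tumor", "rho_normal", "n_normal",
        "delta_corr", "perm_mean", "perm_sd", "z", "p",
    ]
    if config.report_empirical:
        columns.append("p_empirical")
    table = pd.DataFrame(rows, columns=columns)
    return call_significant(table, config)
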