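"""Label-permutation engine, BH adjustment, significance calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import bh_oracle, exhaustive_null_oracle
from deltacorr.corr_core import PairedGeneSeries, build_series
from deltacorr.perm_inference import (
    PermutationConfig,
    analyze_cohort,
    bh_adjust,
    call_significant,
    permutation_test,
    permute_labels,
    two_group_permutation_test,
)
from deltacorr.synthetic_data import SimConfig, simulate_cohort


def _series(n_t, n_n, seed=0, gene="G"):
    rng = np.random.default_rng(seed)
    n = n_t + n_n
    return PairedGeneSeries(
        gene=gene,
        sample_ids=tuple(f"S{i}" for i in range(n)),
        mrna=rng.normal(size=n),
        protein=rng.normal(size=n),
        condition=np.array(["tumor"] * n_t + ["normal"] * n_n),
    )


class TestPermuteLabels:
    def test_group_sizes_conserved(self):
        series = _series(3, 3)
        rng = np.random.default_rng(0)
        for _ in range(10):
            out = permute_labels(series, rng)
            assert out.n_condition("tumor") == 3
            assert out.n_condition("normal") == 3
            # pairing untouched
            np.testing.assert_array_equal(out.mrna, series.mrna)
            np.testing.assert_array_equal(out.protein, series.protein)

    def test_relabelings_within_possible_assignments(self):
        series = _series(3, 3)
        possible = {
            frozenset(c) for c in itertools.combinations(range(6), 3)
        }
        assert len(possible) == 20
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(20):
            out = permute_labels(series, rng)
            seen.add(frozenset(np.flatnonzero(out.condition == "tumor").tolist()))
        assert seen <= possible
        assert len(seen) > 1

    def test_seed_reproducibility(self):
        series = _series(4, 4)
        seq1 = [permute_labels(series, np.random.default_rng(5)).condition.tolist()
                for _ in range(1)]
        seq2 = [permute_labels(series, np.random.default_rng(5)).condition.tolist()
                for _ in range(1)]
        assert seq1 == seq2


class TestPermutationTest:
    def test_exhaustive_matches_bruteforce_oracle(self):
        series = _series(3, 3, seed=2)
        cfg = PermutationConfig(min_n=3, exhaustive="always")
        out = permutation_test(series, cfg)
        null = exhaustive_null_oracle(
            list(series.mrna), list(series.protein), 3
        )
        assert out.method == "exhaustive"
        assert out.n_null == 20
        assert out.perm_mean == pytest.approx(np.mean(null), abs=1e-12)
        assert out.perm_sd == pytest.approx(np.std(null, ddof=1), abs=1e-12)
        z = (out.delta_obs - np.mean(null)) / np.std(null, ddof=1)
        assert out.z == pytest.approx(z, abs=1e-12)
        assert out.p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_point_mass_null_gives_p_one(self):
        # mrna == protein everywhere: every relabeling yields delta exactly 0
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        series = PairedGeneSeries(
            gene="G", sample_ids=tuple("abcdef"), mrna=x, protein=x.copy(),
            condition=np.array(["tumor"] * 3 + ["normal"] * 3),
        )
        out = permutation_test(series, PermutationConfig(min_n=3))
        assert out.perm_sd == 0.0
        assert out.delta_obs == 0.0
        assert out.p == 1.0 and out.z == 0.0

    def test_constant_group_untestable(self):
        series = _series(8, 8, seed=3)
        series.protein[series.condition == "tumor"] = 1.0
        out = permutation_test(series, PermutationConfig(min_n=3))
        assert not out.testable and np.isnan(out.p)

    def test_below_min_n_untestable(self):
        out = permutation_test(_series(10, 10), PermutationConfig(min_n=15))
        assert not out.testable

    def test_redraws_recover_full_null_count(self):
        # heavy ties: some permuted subsets are constant and must be redrawn
        mrna = np.array([1.0, 1, 1, 1, 2, 3, 1, 1, 2, 3])
        protein = np.arange(10, dtype=float)
        mask = np.array([True] * 5 + [False] * 5)
        cfg = PermutationConfig(n_perm=200, min_n=3, exhaustive="never", seed=4)
        out = two_group_permutation_test(mrna, protein, mask, cfg, "G")
        assert out.testable
        assert out.n_null == 200

    def test_determinism_same_seed(self):
        series = _series(16, 16, seed=6)
        cfg = PermutationConfig(n_perm=500, seed=9, min_n=15, exhaustive="never")
        a = permutation_test(series, cfg)
        b = permutation_test(series, cfg)
        assert a == b

    def test_antisymmetry_unequal_groups(self):
        series = _series(9, 6, seed=8)
        cfg = PermutationConfig(n_perm=400, seed=3, min_n=3, exhaustive="never")
        out = permutation_test(series, cfg)
        flipped = PairedGeneSeries(
            gene="G", sample_ids=series.sample_ids, mrna=series.mrna,
            protein=series.protein,
            condition=np.where(series.condition == "tumor", "normal", "tumor"),
        )
        out2 = permutation_test(flipped, cfg)
        assert out2.delta_obs == -out.delta_obs
        assert out2.z == pytest.approx(-out.z, abs=1e-12)
        assert out2.p == pytest.approx(out.p, abs=1e-12)

    def test_empirical_p_floor(self):
        series = _series(10, 10, seed=11)
        cfg = PermutationConfig(n_perm=200, min_n=3, exhaustive="never")
        out = permutation_test(series, cfg)
        assert out.p_empirical >= 1.0 / (out.n_null + 1)
        assert out.p_empirical <= 1.0

    def test_shared_permutations_stream(self):
        x = _series(10, 10, seed=12)
        y = PairedGeneSeries(
            gene="OTHER", sample_ids=x.sample_ids, mrna=x.mrna,
            protein=x.protein, condition=x.condition,
        )
        shared = PermutationConfig(n_perm=200, min_n=3, exhaustive="never",
                                   shared_permutations=True, seed=1)
        a = permutation_test(x, shared)
        b = permutation_test(y, shared)
        assert a.p == b.p  # same data, same relabeling stream
        per_gene = PermutationConfig(n_perm=200, min_n=3, exhaustive="never", seed=1)
        c = permutation_test(x, per_gene)
        d = permutation_test(y, per_gene)
        assert c.p != d.p  # independent per-gene streams


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04],
            atol=1e-12,
        )

    def test_single_and_ties(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])
        np.testing.assert_allclose(bh_adjust([0.05] * 10), [0.05] * 10, atol=1e-12)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.uniform(1e-12, 1.0, size=int(rng.integers(1, 60)))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(list(p)), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(1e-6, 1, 50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [float("nan")]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestCallSignificant:
    def _frame(self, p, delta):
        return pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(p))], "p": p, "delta_corr": delta}
        )

    def test_gates(self):
        cfg = PermutationConfig(alpha=0.05, delta_threshold=0.2)
        out = call_significant(
            self._frame([0.001, 0.001, 0.9], [0.5, 0.1, 0.8]), cfg
        )
        assert out["significant"].tolist() == [True, False, False]

    def test_untestable_rows_not_significant(self):
        cfg = PermutationConfig()
        out = call_significant(
            self._frame([0.01, float("nan")], [0.5, float("nan")]), cfg
        )
        assert not out.loc[1, "significant"]
        assert np.isnan(out.loc[1, "q"])


class TestAnalyzeCohort:
    def test_table_contract(self):
        cfg = SimConfig(n_genes=12, n_tumor=20, n_normal=20,
                        fraction_shifted=0.25, effect_grid=(0.7,), seed=5)
        mrna, protein, design, _, _ = simulate_cohort(cfg)
        pcfg = PermutationConfig(n_perm=200, seed=1, min_n=15,
                                 report_empirical=True)
        res = analyze_cohort(mrna, protein, design, "SYNTH", pcfg)
        assert len(res) == 12
        assert {"delta_corr", "z", "p", "q", "significant", "p_empirical"} <= set(res.columns)
        testable = res["p"].notna()
        assert (res.loc[testable, "q"] >= res.loc[testable, "p"] - 1e-15).all()
        assert res["delta_corr"].abs().max() <= 2.0
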