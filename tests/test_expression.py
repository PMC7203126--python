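"""Unit and property tests for RPKM, Welch testing and the silencing screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from bgcprof import (
    AnalysisThresholds,
    average_replicates,
    call_de,
    capped_log2fc,
    compute_rpkm,
    differential_expression,
    prioritize_for_deletion,
    relative_to_actin,
    screen_silent_core_genes,
    welch_test,
    welch_test_from_samples,
)

T = AnalysisThresholds()


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,library,expected",
        [
            (0, 1000, 1_000_000, 0.0),
            (10, 1000, 1_000_000, 10.0),
            (250, 2500, 5_000_000, 20.0),
        ],
    )
    def test_definition(self, count, length, library, expected):
        counts = pd.DataFrame({"s1": [count]}, index=["g1"])
        rpkm = compute_rpkm(
            counts,
            pd.Series([length], index=["g1"]),
            pd.Series([library], index=["s1"]),
        )
        assert rpkm.at["g1", "s1"] == pytest.approx(expected)

    def test_read_count_conservation(self):
        """Sum of RPKM * kb * (library/1e6) recovers the raw read count."""
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(4)],
        )
        lengths = pd.Series(rng.integers(200, 8000, size=30), index=counts.index)
        sizes = counts.sum(axis=0)
        rpkm = compute_rpkm(counts, lengths, sizes)
        recon = rpkm.mul(lengths / 1e3, axis=0).mul(sizes / 1e6, axis=1)
        for sample in counts.columns:
            assert recon[sample].sum() == pytest.approx(counts[sample].sum())

    def test_mismatched_genes_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            compute_rpkm(counts, pd.Series([100], index=["other"]))


class TestAverageReplicates:
    def test_mean_and_symmetry(self):
        expr = pd.DataFrame(
            {"a1": [2.0], "a2": [4.0], "b1": [5.0]}, index=["g"]
        )
        groups = {"a1": "A", "a2": "A", "b1": "B"}
        means = average_replicates(expr, groups)
        assert means.at["g", "A"] == pytest.approx(3.0)
        assert means.at["g", "B"] == pytest.approx(5.0)
        permuted = expr[["b1", "a2", "a1"]]
        assert average_replicates(permuted, groups).at["g", "A"] == pytest.approx(3.0)

    def test_unknown_sample_rejected(self):
        expr = pd.DataFrame({"a1": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            average_replicates(expr, {"a1": "A", "ghost": "B"})


class TestCappedLog2Fc:
    def test_silent_one_side_gets_cap(self):
        assert capped_log2fc(0.1, 5.0, T) == pytest.approx(7.0)
        assert capped_log2fc(5.0, 0.1, T) == pytest.approx(-7.0)

    def test_plain_ratio(self):
        assert capped_log2fc(2.0, 2.0, T) == pytest.approx(0.0)
        assert capped_log2fc(2.0, 8.0, T) == pytest.approx(2.0)

    def test_both_silent_excluded(self):
        assert capped_log2fc(0.1, 0.2, T) is None

    def test_extreme_ratio_clamped(self):
        assert capped_log2fc(0.3, 3e6, T) == pytest.approx(7.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            capped_log2fc(-1.0, 2.0, T)

    @given(
        a=st.floats(0.3, 1e4),
        b=st.floats(0.3, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, a, b):
        fab, fba = capped_log2fc(a, b, T), capped_log2fc(b, a, T)
        assert fab == pytest.approx(-fba, abs=1e-9)


class TestWelch:
    def test_chemostat_biomass_summary(self):
        """Printed steady-state biomass comparison reproduces p = 0.0034
        within one unit of its last printed digit (the inputs are
        themselves rounded summaries)."""
        _, _, p = welch_test(6.59, 0.153, 5, 6.98, 0.054, 7)
        assert p == pytest.approx(0.0034, abs=1e-4)

    def test_hand_computed_example(self):
        t, df, p = welch_test(0.0, 1.0, 4, 2.0, 1.0, 4)
        assert t == pytest.approx(2.8284, abs=1e-4)
        assert df == pytest.approx(6.0)
        assert p == pytest.approx(0.0300, abs=1e-3)

    def test_identical_groups(self):
        t, _, p = welch_test(3.0, 0.0, 4, 3.0, 0.0, 4)
        assert t == 0.0 and p == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            welch_test(0, 1, 1, 0, 1, 5)

    @pytest.mark.parametrize(
        "stats_pair",
        [
            (0.0, 1.0, 5, 0.5, 1.2, 7),
            (10.0, 2.0, 3, 11.5, 0.4, 9),
            (-1.0, 0.8, 12, 1.0, 3.0, 4),
            (100.0, 5.0, 6, 97.0, 5.0, 6),
        ],
    )
    def test_matches_numerical_t_cdf_oracle(self, stats_pair):
        """p agrees with direct numerical integration of the t density."""
        t_stat, df, p = welch_test(*stats_pair)
        tail, err = integrate.quad(lambda x: stats.t.pdf(x, df), abs(t_stat), np.inf)
        assert err < 1e-8
        assert p == pytest.approx(2 * tail, abs=1e-6)

    def test_type_one_error_rate(self):
        """Null rejection rate at alpha=0.05 over simulated gene pairs."""
        rng = np.random.default_rng(7)
        n_sim = 10_000
        a = rng.normal(size=(n_sim, 5))
        b = rng.normal(size=(n_sim, 7))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = float((p < 0.05).mean())
        bound = 3 * math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < bound + 1e-12

    def test_from_samples_matches_summary_path(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 7)
        t1 = welch_test_from_samples(a, b)
        t2 = welch_test(a.mean(), a.std(ddof=1), 5, b.mean(), b.std(ddof=1), 7)
        assert t1 == pytest.approx(t2)


class TestCallDe:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (0.25, 0.001, False),  # boundary is strict
            (0.5, 0.01, True),
            (3.0, 0.2, False),
            (7.0, math.nan, True),  # capped gene: DE by the cap alone
            (0.1, math.nan, False),
        ],
    )
    def test_rule(self, fc, p, expected):
        table = pd.DataFrame(
            {"log2_fc": [fc], "p_value": [p]}, index=["g"]
        )
        assert bool(call_de(table, T).at["g", "is_de"]) is expected


class TestDifferentialExpression:
    def test_pipeline_conventions(self):
        rpkm = pd.DataFrame(
            {
                "refr1": [10.0, 5.0, 0.1, 0.05],
                "refr2": [12.0, 5.2, 0.2, 0.1],
                "ko1": [40.0, 5.1, 6.0, 0.2],
                "ko2": [44.0, 5.3, 7.0, 0.1],
            },
            index=["up", "flat", "capped", "noise"],
        )
        groups = {"refr1": "ref", "refr2": "ref", "ko1": "ko", "ko2": "ko"}
        table = differential_expression(rpkm, groups, ("ref", "ko"), T)
        assert "noise" not in table.index  # silent in both strains
        assert table.at["capped", "log2_fc"] == pytest.approx(7.0)
        assert math.isnan(table.at["capped", "p_value"])
        assert bool(table.at["capped", "is_de"])
        assert table.at["up", "log2_fc"] == pytest.approx(
            math.log2(42.0 / 11.0)
        )
        assert not bool(table.at["flat", "is_de"])


class TestActinRelative:
    def test_values(self):
        assert relative_to_actin(200.0, 200.0) == 1.0
        assert relative_to_actin(24.0, 200.0) == pytest.approx(0.12)
        assert relative_to_actin(10.0, 200.0) == pytest.approx(0.05)

    def test_zero_actin_rejected(self):
        with pytest.raises(ValueError):
            relative_to_actin(1.0, 0.0)


class TestSilencingScreen:
    def _matrix(self, catalog, core_silent_in):
        """26-condition matrix; the first core gene is silent in
        ``core_silent_in`` conditions, actin level 100."""
        genes = catalog.gene_ids
        core = catalog.core_genes()[0].gene_id
        actin = catalog.actin_gene.gene_id
        data = pd.DataFrame(10.0, index=genes, columns=[f"c{i}" for i in range(26)])
        data.loc[actin] = 100.0
        row = np.full(26, 50.0)
        row[:core_silent_in] = 100.0 * 0.005  # below the 2% cutoff
        data.loc[core] = row
        return data, core

    @pytest.mark.parametrize("n_silent,expected", [(22, True), (21, False), (0, False)])
    def test_at_least_22_of_26_rule(self, handmade_catalog, n_silent, expected):
        matrix, core = self._matrix(handmade_catalog, n_silent)
        screen = screen_silent_core_genes(matrix, handmade_catalog, T)
        assert int(screen.at[core, "n_conditions_silent"]) == n_silent
        assert bool(screen.at[core, "is_silent"]) is expected

    def test_monotone_in_cutoff(self, handmade_catalog):
        """Lowering the silence cutoff never increases silent-condition counts."""
        rng = np.random.default_rng(3)
        genes = handmade_catalog.gene_ids
        matrix = pd.DataFrame(
            rng.uniform(0.1, 120, size=(len(genes), 26)),
            index=genes,
            columns=[f"c{i}" for i in range(26)],
        )
        matrix.loc[handmade_catalog.actin_gene.gene_id] = 100.0
        lo = AnalysisThresholds(actin_rel_silent=0.005)
        hi = AnalysisThresholds(actin_rel_silent=0.05)
        s_lo = screen_silent_core_genes(matrix, handmade_catalog, lo)
        s_hi = screen_silent_core_genes(matrix, handmade_catalog, hi)
        assert (
            s_lo["n_conditions_silent"] <= s_hi["n_conditions_silent"]
        ).all()

    def test_missing_actin_rejected(self, handmade_catalog):
        matrix = pd.DataFrame(
            1.0,
            index=[g for g in handmade_catalog.gene_ids if g != "gActin"],
            columns=["c1"],
        )
        with pytest.raises(ValueError):
            screen_silent_core_genes(matrix, handmade_catalog, T)

    def test_prioritization_ranks_by_median_level(self, handmade_catalog):
        matrix, core = self._matrix(handmade_catalog, 0)
        screen = screen_silent_core_genes(matrix, handmade_catalog, T)
        ranked = prioritize_for_deletion(screen)
        assert list(ranked.index) == [core]
        assert ranked.at[core, "median_actin_rel"] == pytest.approx(0.5)
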