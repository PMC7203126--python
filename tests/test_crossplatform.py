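"""Unit and property tests for the cross-platform z procedure."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bgcprof import (
    AnalysisThresholds,
    Compendium,
    bh_adjust,
    calibrate_threshold,
    classify_band,
    compute_z,
    coverage_filter,
    detect_clusters,
    enrich_hypergeometric,
)
from bgcprof.crossplatform import band_counts, divergent_singletons

T = AnalysisThresholds()


class TestCoverageFilter:
    @pytest.mark.parametrize("present,expected", [(13, True), (12, False), (0, False)])
    def test_half_of_26_boundary(self, present, expected):
        row = [0.1] * present + [math.nan] * (26 - present)
        assert coverage_filter(row, 26, T) is expected


class TestComputeZ:
    def test_zero_when_raw_equals_mean(self):
        _, _, _, z = compute_z(1.0, [0.5, 1.0, 1.5])
        assert z == pytest.approx(0.0)

    def test_hand_computed_values(self):
        mean, sd, n, z = compute_z(2.0, [0.5, 1.0, 1.5])
        assert (mean, sd, n) == (pytest.approx(1.0), pytest.approx(0.5), 3)
        assert z == pytest.approx(2.0)
        assert compute_z(-1.0, [0.5, 1.0, 1.5])[3] == pytest.approx(-4.0)

    def test_degenerate_population(self):
        assert compute_z(1.0, [0.7])[3] is None
        assert compute_z(1.0, [0.7, 0.7, 0.7])[3] is None

    def test_missing_values_dropped(self):
        full = compute_z(2.0, [0.5, 1.0, 1.5])
        with_nan = compute_z(2.0, [0.5, math.nan, 1.0, 1.5, math.nan])
        assert with_nan == full

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        raw=st.floats(-5, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_location_scale_equivariance(self, shift, scale, raw):
        pop = [0.2, -0.4, 1.1, 0.6]
        z0 = compute_z(raw, pop)[3]
        z1 = compute_z(raw * scale + shift, [v * scale + shift for v in pop])[3]
        assert z1 == pytest.approx(z0, rel=1e-6, abs=1e-9)


class TestBands:
    @pytest.mark.parametrize(
        "z,band",
        [
            (0.1, "similar"),
            (-0.19, "similar"),
            (0.2, "altered"),  # tie falls in altered
            (-0.5, "altered"),
            (1.25, "altered"),  # tie falls in altered
            (1.3, "divergent_pos"),
            (-1.26, "divergent_neg"),
        ],
    )
    def test_boundaries(self, z, band):
        assert classify_band(z, T) == band

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, z):
        assert classify_band(z, T) in {
            "similar",
            "altered",
            "divergent_pos",
            "divergent_neg",
        }


class TestCalibrateThreshold:
    STATS = [(0.0, 1.0, 10_000)] * 40

    def test_full_rate_gives_zero(self):
        assert calibrate_threshold(self.STATS, 1.0, n_sims=1000, seed=0) == 0.0

    def test_large_samples_reach_normal_quantile(self):
        thr = calibrate_threshold(self.STATS, 0.05, n_sims=5000, seed=1)
        assert thr == pytest.approx(stats.norm.ppf(0.975), abs=0.02)

    def test_small_samples_have_heavier_tails(self):
        small = [(0.0, 1.0, 8)] * 40
        thr = calibrate_threshold(small, 0.05, n_sims=5000, seed=2)
        assert thr > stats.norm.ppf(0.975) + 0.1

    def test_threshold_decreases_with_coverage(self):
        thrs = [
            calibrate_threshold([(0.0, 1.0, n)] * 40, 0.05, n_sims=4000, seed=3)
            for n in (5, 50, 10_000)
        ]
        assert thrs[0] > thrs[1] > thrs[2]

    def test_deterministic_and_warns_on_bad_genes(self):
        a = calibrate_threshold(self.STATS, 0.1, n_sims=500, seed=9)
        b = calibrate_threshold(self.STATS, 0.1, n_sims=500, seed=9)
        assert a == b
        with pytest.warns(UserWarning):
            calibrate_threshold(
                [(0.0, 0.0, 100), (0.0, 1.0, 100)], 0.1, n_sims=500, seed=9
            )


def _zmap_frame(zs, contigs=None):
    n = len(zs)
    contigs = contigs or ["c1"] * n
    return pd.DataFrame(
        {
            "contig": contigs,
            "position": range(1, n + 1),
            "z": zs,
            "band": ["x"] * n,
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestDetectClusters:
    def test_negative_run_detected(self):
        calls = detect_clusters(_zmap_frame([-2.0, -3.0, -1.5]), T, min_run=3)
        assert len(calls) == 1
        call = calls.iloc[0]
        assert (call["n_genes"], call["sign"]) == (3, "-")
        assert call["mean_z"] == pytest.approx(-2.1666667)

    def test_sign_flip_breaks_run(self):
        calls = detect_clusters(_zmap_frame([-2.0, 2.0, -2.0]), T, min_run=2)
        assert len(calls) == 0

    def test_uncovered_gene_breaks_run(self):
        calls = detect_clusters(
            _zmap_frame([-2.0, -2.0, math.nan, -2.0, -2.0]), T, min_run=3
        )
        assert len(calls) == 0

    def test_runs_do_not_span_contigs(self):
        frame = _zmap_frame(
            [-2.0, -2.0, -2.0, -2.0], contigs=["c1", "c1", "c2", "c2"]
        )
        assert len(detect_clusters(frame, T, min_run=3)) == 0
        assert len(detect_clusters(frame, T, min_run=2)) == 2

    def test_empty_input(self):
        assert len(detect_clusters(_zmap_frame([]), T, min_run=3)) == 0

    def test_singletons_reported_separately(self):
        frame = _zmap_frame([-2.0, 0.0, -3.0, -2.5, -2.2])
        frame["band"] = ["divergent_neg", "similar"] + ["divergent_neg"] * 3
        calls = detect_clusters(frame, T, min_run=3)
        assert len(calls) == 1
        single = divergent_singletons(frame, calls, T)
        assert list(single.index) == ["g0"]


class TestEnrichment:
    def brute_force_p(self, background, annotated, gene_set, category_members):
        """Enumerate all |gene_set|-subsets of the background."""
        k_obs = len(set(gene_set) & category_members)
        n = len(gene_set)
        hits = total = 0
        for combo in combinations(background, n):
            total += 1
            if len(set(combo) & category_members) >= k_obs:
                hits += 1
        return hits / total

    def test_hand_enumerated_example(self):
        background = [f"g{i}" for i in range(10)]
        members = set(background[:4])
        annotation = {g: {"cat"} if g in members else set() for g in background}
        gene_set = background[:4] + [background[5]]
        result = enrich_hypergeometric(gene_set, background, annotation, T)
        assert result.iloc[0]["p_value"] == pytest.approx(6 / 252)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_on_small_backgrounds(self, seed):
        rng = np.random.default_rng(seed)
        n_bg = int(rng.integers(4, 13))
        background = [f"g{i}" for i in range(n_bg)]
        members = set(
            rng.choice(background, size=int(rng.integers(0, n_bg + 1)), replace=False)
        )
        annotation = {g: ({"cat"} if g in members else set()) for g in background}
        n_set = int(rng.integers(1, n_bg + 1))
        gene_set = list(rng.choice(background, size=n_set, replace=False))
        result = enrich_hypergeometric(gene_set, background, annotation, T)
        if members:
            row = result.loc[result["category"] == "cat"].iloc[0]
            expected = self.brute_force_p(background, annotation, gene_set, members)
            assert row["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_certainty_cases(self):
        background = ["a", "b", "c"]
        annotation = {"a": {"cat"}, "b": {"cat"}, "c": {"cat"}}
        result = enrich_hypergeometric(background, background, annotation, T)
        assert result.iloc[0]["p_value"] == pytest.approx(1.0)
        empty_annot = {g: {"cat2"} for g in background}
        res2 = enrich_hypergeometric([], background, empty_annot, T)
        assert res2.iloc[0]["p_value"] == pytest.approx(1.0)
        assert res2.iloc[0]["k_in_set"] == 0

    def test_gene_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_hypergeometric(["x"], ["a"], {"a": set()}, T)


class TestBhAdjust:
    def test_hand_applications(self):
        assert bh_adjust([0.02]) == [pytest.approx(0.02)]
        assert bh_adjust([0.01, 0.02, 0.03]) == [pytest.approx(0.03)] * 3
        assert bh_adjust([0.01, 0.04]) == [pytest.approx(0.02), pytest.approx(0.04)]

    def test_order_preserved(self):
        q = bh_adjust([0.04, 0.01])
        assert q == [pytest.approx(0.04), pytest.approx(0.02)]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p(self, ps):
        q = bh_adjust(ps)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, ps))


class TestCompendium:
    def test_coverage(self):
        values = pd.DataFrame(
            {"d1": [1.0, math.nan], "d2": [math.nan, math.nan]}, index=["a", "b"]
        )
        comp = Compendium(values)
        assert comp.coverage()["a"] == pytest.approx(0.5)
        assert comp.coverage()["b"] == 0.0

    def test_needs_a_dataset(self):
        with pytest.raises(ValueError):
            Compendium(pd.DataFrame(index=["a"]))


class TestBandCounts:
    def test_partition_sums(self):
        frame = _zmap_frame([0.1, 0.5, 1.5, -2.0, math.nan])
        frame["band"] = ["similar", "altered", "divergent_pos", "divergent_neg", "uncovered"]
        counts = band_counts(frame)
        assert counts.sum() == len(frame)
        assert counts["uncovered"] == 1
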