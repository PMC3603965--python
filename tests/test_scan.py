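"""Windowed two-sample scan: windows, rank test, Hodges-Lehmann, full scan."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oracles import exact_rank_sum_two_sided, naive_hodges_lehmann, naive_window_indices
from tilescan import normalize, synthetic
from tilescan.io import IntensityMatrix
from tilescan.scan import (
    ScanConfig,
    collect_window,
    hodges_lehmann,
    scan_genome,
    wilcoxon_window,
)
from tilescan.synthetic import GenomePlan, NoiseModel, TruthTable


@pytest.fixture(scope="module")
def uniform_probes():
    return synthetic.build_probe_set(
        GenomePlan(segments=(("s", "c", 0, 5_000),), probe_spacing_bp=17)
    )


class TestCollectWindow:
    def test_spacing17_bandwidth77_gives_nine_probes(self, uniform_probes):
        idx = collect_window(uniform_probes, 50, 77)
        assert len(idx) == 9
        assert 50 in idx

    def test_bandwidth_zero_is_center_only(self, uniform_probes):
        assert list(collect_window(uniform_probes, 50, 0)) == [50]

    def test_chromosome_start_truncates_one_sided(self, uniform_probes):
        idx = collect_window(uniform_probes, 0, 77)
        assert len(idx) == 5  # center + 4 to the right only
        assert idx[0] == 0

    def test_matches_naive_oracle_everywhere(self, uniform_probes):
        chroms, centers = uniform_probes.chrom, uniform_probes.center
        for i in range(0, len(uniform_probes), 37):
            got = list(collect_window(uniform_probes, i, 77))
            assert got == naive_window_indices(chroms, centers, i, 77)


class TestWilcoxonWindow:
    def test_identical_groups_give_p_one(self):
        assert wilcoxon_window([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
        assert wilcoxon_window([5.0] * 4, [5.0] * 6) == 1.0

    def test_exact_small_sample(self):
        assert wilcoxon_window([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_complete_separation_nine_vs_nine(self):
        a = np.arange(9.0)
        p = wilcoxon_window(a + 10.0, a)
        assert p == pytest.approx(4.1135e-5, rel=1e-3)

    @given(
        st.lists(st.integers(0, 6), min_size=3, max_size=6),
        st.lists(st.integers(0, 6), min_size=3, max_size=6),
    )
    def test_exact_path_matches_enumeration_oracle_with_ties(self, a, b):
        a, b = [float(x) for x in a], [float(x) for x in b]
        if all(x == a[0] for x in a + b):
            return
        assert wilcoxon_window(a, b) == pytest.approx(
            exact_rank_sum_two_sided(a, b)
        )

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(size=30)
            b = rng.normal(0.3, size=25)
            expected = stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic").pvalue
            assert wilcoxon_window(a, b) == pytest.approx(float(expected), rel=1e-9)


class TestHodgesLehmann:
    def test_constant_shift(self):
        b = np.array([0.0, 1.0, 2.0])
        assert hodges_lehmann(b + 1.0, b) == 1.0

    def test_copy_ratio_7_44(self):
        a = np.full(5, np.log2(7.0))
        b = np.full(5, np.log2(44.0))
        assert hodges_lehmann(a, b) == pytest.approx(-2.652, abs=5e-4)

    def test_brute_force_pairwise_median(self):
        assert hodges_lehmann([0, 1, 4], [0, 0, 0]) == 1.0

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=12),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=12),
    )
    def test_matches_naive_oracle_and_antisymmetry(self, a, b):
        assert hodges_lehmann(a, b) == pytest.approx(naive_hodges_lehmann(a, b))
        assert hodges_lehmann(a, b) == pytest.approx(-hodges_lehmann(b, a))


def _matrix(probes, values, n_a, n_b, log_scale=True):
    return IntensityMatrix(
        probe_ids=probes.probe_id,
        sample_ids=[f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)],
        groups=np.array(["A"] * n_a + ["B"] * n_b, dtype=object),
        values=values,
        log_scale=log_scale,
    )


class TestScanGenome:
    def test_null_zero_noise_gives_p_one_everywhere(self, uniform_probes):
        n = len(uniform_probes)
        rng = np.random.default_rng(0)
        col = rng.normal(10, 1, size=n)
        m = _matrix(uniform_probes, np.tile(col[:, None], (1, 6)), 3, 3)
        res = scan_genome(m, uniform_probes, ScanConfig())
        assert np.all(res["p_value"] == 1.0)

    def test_group_swap_keeps_p_negates_log_ratio(self, uniform_probes):
        n = len(uniform_probes)
        rng = np.random.default_rng(1)
        v = rng.normal(10, 0.5, size=(n, 8))
        m = _matrix(uniform_probes, v, 4, 4)
        swapped = m.relabel(
            np.array(["B"] * 4 + ["A"] * 4, dtype=object)
        )
        r1 = scan_genome(m, uniform_probes, ScanConfig())
        r2 = scan_genome(swapped, uniform_probes, ScanConfig())
        assert np.allclose(r1["p_value"], r2["p_value"])
        assert np.allclose(r1["hl_log_ratio"], -r2["hl_log_ratio"])

    def test_larger_effects_give_smaller_center_p(self, uniform_probes):
        plan = GenomePlan(segments=(("s", "c", 0, 5_000),), probe_spacing_bp=17)
        center = np.argmin(np.abs(uniform_probes.center - 2_500))
        last_p = None
        for effect in (0.05, 0.2, 0.8):
            truth = TruthTable(divergent_intervals=(("c", 2_000, 3_000, effect, "A"),))
            m = synthetic.simulate_intensities(
                uniform_probes, truth, NoiseModel(sample_noise_sd=0.2),
                n_per_group=5, seed=7,
            )
            res = scan_genome(normalize.log_transform(m), uniform_probes, ScanConfig())
            p = res.loc[center, "p_value"]
            if last_p is not None:
                assert p < last_p
            last_p = p

    def test_high_density_bandwidth_applied(self, uniform_probes):
        n = len(uniform_probes)
        rng = np.random.default_rng(3)
        m = _matrix(uniform_probes, rng.normal(10, 0.5, size=(n, 6)), 3, 3)
        cfg = ScanConfig(
            bandwidth_bp=77, bandwidth_bp_high_density=22,
            high_density_regions=(("c", 0, 2_000),),
        )
        res = scan_genome(m, uniform_probes, cfg)
        inside = res[res["center"] < 1_900]
        outside = res[(res["center"] > 2_200) & (res["center"] < 4_700)]
        # 45 bp window holds 3 probes at 17 bp spacing, 155 bp window holds 9
        assert inside["n_A"].median() == 3 * 3
        assert outside["n_A"].median() == 9 * 3

    def test_insufficient_values_flagged_untested(self, uniform_probes):
        n = len(uniform_probes)
        m = _matrix(uniform_probes, np.random.default_rng(0).normal(size=(n, 4)), 2, 2)
        cfg = ScanConfig(bandwidth_bp=0, min_values_per_group=5)
        res = scan_genome(m, uniform_probes, cfg)
        assert not res["tested"].any()
        assert res["p_value"].isna().all()

    def test_requires_log_scale(self, uniform_probes):
        n = len(uniform_probes)
        m = _matrix(uniform_probes, np.ones((n, 4)), 2, 2, log_scale=False)
        with pytest.raises(ValueError, match="log"):
            scan_genome(m, uniform_probes, ScanConfig())
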