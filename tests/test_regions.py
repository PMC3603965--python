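"""SF calling, SDR merging, hit density, segment tallies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oracles import jaccard
from tilescan import synthetic
from tilescan.fdr import FdrResult
from tilescan.regions import (
    call_sfs,
    hit_density,
    merge_sdrs,
    summarize_role_matrix,
    tally_by_segment,
)
from tilescan.synthetic import GenomePlan


def fake_scan(starts, p, chrom="c", length=25):
    starts = np.asarray(starts)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
            "length": length,
            "center": starts + length // 2,
            "p_value": p,
            "hl_log_ratio": np.ones(len(starts)),
            "tested": True,
        }
    )


def fake_fdr(q, target=0.001):
    q = np.asarray(q, dtype=float)
    return FdrResult(pi0=1.0, q_values=q, p_threshold=0.0, target_fdr=target, m=len(q))


class TestCallSfs:
    def test_threshold_excluding_all_gives_empty(self):
        sr = fake_scan([0, 17], [0.5, 0.6])
        assert len(call_sfs(sr, fake_fdr([0.5, 0.6]))) == 0

    def test_all_significant_gives_all_probes(self):
        sr = fake_scan([0, 17, 34], [1e-9] * 3)
        assert len(call_sfs(sr, fake_fdr([1e-6] * 3))) == 3

    def test_sfs_concentrate_in_planted_regions(self, pipeline_run):
        sfs = pipeline_run["sfs"]
        truth = pipeline_run["truth"].truth_frame()
        inside = 0
        for sf in sfs.itertuples(index=False):
            if any(
                t.chrom == sf.chrom and t.start <= sf.center < t.end
                for t in truth.itertuples(index=False)
            ):
                inside += 1
        assert inside / len(sfs) >= 0.9

    def test_stricter_fdr_never_increases_sf_count(self, pipeline_run):
        counts = []
        for target in (0.01, 0.001, 0.0001):
            fr = FdrResult(
                pi0=pipeline_run["fdr"].pi0,
                q_values=pipeline_run["fdr"].q_values,
                p_threshold=0.0,
                target_fdr=target,
                m=pipeline_run["fdr"].m,
            )
            counts.append(len(call_sfs(pipeline_run["scan"], fr)))
        assert counts[0] >= counts[1] >= counts[2]


class TestMergeSdrs:
    def test_close_sfs_merge(self):
        sfs = fake_scan([100, 110], [0, 0]).assign(q_value=0.0)
        sdrs = merge_sdrs(sfs, max_gap_bp=155)
        assert len(sdrs) == 1
        assert sdrs.loc[0, "start"] == 100
        assert sdrs.loc[0, "end"] == 135  # last start + probe length

    def test_distant_sfs_stay_separate(self):
        sfs = fake_scan([100, 10_100], [0, 0]).assign(q_value=0.0)
        assert len(merge_sdrs(sfs, max_gap_bp=155)) == 2

    def test_singleton_sdr_spans_probe_length(self):
        sfs = fake_scan([500], [0]).assign(q_value=0.0)
        sdrs = merge_sdrs(sfs)
        assert (sdrs.loc[0, "end"] - sdrs.loc[0, "start"]) == 25

    def test_planted_region_recovered_with_high_jaccard(self, pipeline_run):
        truth = pipeline_run["truth"].truth_frame()
        sdrs = pipeline_run["sdrs"]
        for t in truth.itertuples(index=False):
            best = max(
                (
                    jaccard(t.start, t.end, s.start, s.end)
                    for s in sdrs.itertuples(index=False)
                    if s.chrom == t.chrom
                ),
                default=0.0,
            )
            assert best >= 0.8, (t.chrom, t.start, t.end)

    def test_segment_clipping_partitions_exactly(self):
        sfs = fake_scan([2_980, 3_010], [0, 0]).assign(q_value=0.0)
        segments = pd.DataFrame(
            [("left", "c", 0, 3_000), ("right", "c", 3_000, 6_000)],
            columns=["name", "chrom", "start", "end"],
        )
        sdrs = merge_sdrs(sfs, segments=segments)
        assert len(sdrs) == 2
        assert sdrs["end"].iloc[0] == 3_000
        assert sdrs["start"].iloc[1] == 3_000
        assert set(sdrs["segment"]) == {"left", "right"}


class TestHitDensity:
    def make_probes(self, n=90, spacing=100):
        return synthetic.build_probe_set(
            GenomePlan(segments=(("s", "c", 0, n * spacing),), probe_spacing_bp=spacing)
        )

    def test_no_sfs_gives_all_zero(self):
        probes = self.make_probes()
        track = hit_density(probes, fake_scan([], []).assign(q_value=[]), 1_000)
        assert (track["hit_density"] == 0).all()

    def test_all_sf_gives_all_one(self):
        probes = self.make_probes()
        sfs = pd.DataFrame({"chrom": probes.chrom, "start": probes.start})
        track = hit_density(probes, sfs, 1_000)
        assert (track["hit_density"] == 1).all()

    def test_fraction_in_window(self):
        probes = self.make_probes(n=90, spacing=100)
        # 9 SFs among the 90 probes, all inside the first window
        sfs = pd.DataFrame({"chrom": ["c"] * 9, "start": probes.start[:9]})
        track = hit_density(probes, sfs, width_bp=9_000, overlap_fraction=0.5)
        first = track.iloc[0]
        assert first["n_probes"] == 90
        assert first["hit_density"] == pytest.approx(9 / 90)

    def test_windows_step_by_half_width(self):
        probes = self.make_probes()
        track = hit_density(probes, fake_scan([], []).assign(q_value=[]), 2_000)
        starts = track[track["chrom"] == "c"]["start"].to_numpy()
        assert np.all(np.diff(starts) == 1_000)

    def test_rescaling_intensities_leaves_density_unchanged(self, pipeline_run):
        # density depends only on SF calls, not on the intensity scale
        probes, sfs = pipeline_run["probes"], pipeline_run["sfs"]
        t1 = hit_density(probes, sfs, 20_000)
        t2 = hit_density(probes, sfs.assign(hl_log_ratio=sfs["hl_log_ratio"] * 10), 20_000)
        assert np.allclose(t1["hit_density"], t2["hit_density"])


class TestTallies:
    def test_per_segment_totals_conserved(self, pipeline_run):
        tally = tally_by_segment(
            pipeline_run["sdrs"], pipeline_run["plan"].segments_frame()
        )
        total_row = tally[tally["segment"] == "Total"].iloc[0]
        assert (
            tally[tally["segment"] != "Total"]["sdr_bp"].sum() == total_row["sdr_bp"]
        )
        sdr_total = int((pipeline_run["sdrs"]["end"] - pipeline_run["sdrs"]["start"]).sum())
        assert total_row["sdr_bp"] == sdr_total

    def test_empty_sdr_list_gives_zeros(self):
        segments = pd.DataFrame(
            [("s", "c", 0, 1_000)], columns=["name", "chrom", "start", "end"]
        )
        tally = tally_by_segment(pd.DataFrame(columns=["chrom", "start", "end"]), segments)
        assert (tally["sdr_bp"] == 0).all()

    def test_boundary_spanning_sdr_split_between_segments(self):
        segments = pd.DataFrame(
            [("a", "c", 0, 500), ("b", "c", 500, 1_000)],
            columns=["name", "chrom", "start", "end"],
        )
        sdrs = pd.DataFrame([{"chrom": "c", "start": 400, "end": 700}])
        tally = tally_by_segment(sdrs, segments).set_index("segment")
        assert tally.loc["a", "sdr_bp"] == 100
        assert tally.loc["b", "sdr_bp"] == 200
        assert tally.loc["Total", "sdr_bp"] == 300

    def test_role_matrix_totals_and_percentages(self):
        role_bp = pd.DataFrame(
            {"s1": [10, 20], "s2": [30, 40]}, index=["exon", "intron"]
        )
        out = summarize_role_matrix(role_bp, {"s1": 1_000, "s2": 2_000})
        assert out.loc["exon", "Total"] == 40
        assert out.loc["Total", "s1"] == 30
        assert out.loc["Total", "Total"] == 100
        assert out.loc["pct_segment", "s1"] == pytest.approx(3.0)
        assert out.loc["pct_segment", "Total"] == pytest.approx(100 * 100 / 3_000)
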