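"""Significant features, significantly differentiated regions, hit density.

A *significant feature* (SF) is a single probe whose windowed two-sample
test survives the FDR threshold.  Adjacent SFs merge into *significantly
differentiated regions* (SDRs), the unit of all base-pair tallies.  The
*hit density* of a genomic window is the fraction of its probes that are
SFs; tracks use overlapping windows stepped by half their width.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ProbeSet

__all__ = [
    "call_sfs",
    "merge_sdrs",
    "hit_density",
    "tally_by_segment",
    "summarize_role_matrix",
    "DEFAULT_MAX_GAP_BP",
]

# Default merge gap = the 155 bp window span: adjacent windows that share
# probes should not fragment one region.
DEFAULT_MAX_GAP_BP = 155


def call_sfs(scan_result: pd.DataFrame, fdr_result) -> pd.DataFrame:
    """Probes with q <= target FDR, sorted by genomic position.

    Returns the scan rows of significant probes with a ``q_value`` column
    appended.
    """
    df = scan_result.copy()
    df["q_value"] = fdr_result.q_values
    sfs = df[df["tested"] & (df["q_value"] <= fdr_result.target_fdr)]
    return sfs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def merge_sdrs(
    sfs: pd.DataFrame,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    segments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge SFs into SDRs.

    Consecutive SFs on a chromosome whose centers are <= max_gap_bp apart
    join one region; the region spans from the first SF's start to the last
    SF's end, so a singleton SDR spans exactly one probe length.  When
    *segments* (columns name, chrom, start, end) are given, SDRs are clipped
    and split at segment boundaries and labeled with the segment name, so
    per-segment tallies partition the SDR total exactly.

    Returns columns: chrom, start, end, n_sfs, mean_lr, extreme_lr, segment.
    """
    rows = []
    for chrom, grp in sfs.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="mergesort")
        centers = grp["center"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = (grp["start"] + grp["length"]).to_numpy()
        lrs = grp["hl_log_ratio"].to_numpy()
        if len(grp) == 0:
            continue
        run_start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or centers[i] - centers[i - 1] > max_gap_bp:
                lr_run = lrs[run_start:i]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[run_start]),
                        "end": int(ends[i - 1]),
                        "n_sfs": i - run_start,
                        "mean_lr": float(lr_run.mean()),
                        "extreme_lr": float(lr_run[np.argmax(np.abs(lr_run))]),
                        "segment": None,
                    }
                )
                run_start = i
    sdrs = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sfs", "mean_lr", "extreme_lr", "segment"]
    )
    if segments is not None and len(sdrs):
        sdrs = _clip_to_segments(sdrs, segments)
    return sdrs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _clip_to_segments(sdrs: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    out = []
    for sdr in sdrs.itertuples(index=False):
        segs = segments[segments["chrom"] == sdr.chrom]
        for seg in segs.itertuples(index=False):
            lo = max(sdr.start, seg.start)
            hi = min(sdr.end, seg.end)
            if hi > lo:
                rec = sdr._asdict()
                rec.update(start=lo, end=hi, segment=seg.name)
                out.append(rec)
    return pd.DataFrame(out, columns=sdrs.columns)


def hit_density(
    probes: ProbeSet,
    sfs: pd.DataFrame,
    width_bp: int = 200_000,
    overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Fraction of significant probes per overlapping window.

    Windows of *width_bp* step by ``width_bp * (1 - overlap_fraction)``
    (default 50% overlap).  Windows containing no probes emit no row.
    Returns columns: chrom, start, end, n_probes, n_sf, hit_density.
    """
    if width_bp <= 0:
        raise ValueError("window width must be positive")
    step = int(round(width_bp * (1.0 - overlap_fraction)))
    if step <= 0:
        raise ValueError("overlap fraction too large")
    sf_keys = set(zip(sfs["chrom"], sfs["start"])) if len(sfs) else set()
    rows = []
    for chrom, sl in probes.chrom_slices().items():
        centers = probes.center[sl]
        starts = probes.start[sl]
        is_sf = np.fromiter(
            ((chrom, int(s)) in sf_keys for s in starts), dtype=bool, count=len(starts)
        )
        sf_cum = np.concatenate([[0], np.cumsum(is_sf)])
        last = int(centers.max())
        for w_start in range(0, last + 1, step):
            w_end = w_start + width_bp
            lo = int(np.searchsorted(centers, w_start, side="left"))
            hi = int(np.searchsorted(centers, w_end, side="left"))
            n = hi - lo
            if n == 0:
                continue
            n_sf = int(sf_cum[hi] - sf_cum[lo])
            rows.append(
                {
                    "chrom": chrom,
                    "start": w_start,
                    "end": w_end,
                    "n_probes": n,
                    "n_sf": n_sf,
                    "hit_density": n_sf / n,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_probes", "n_sf", "hit_density"]
    )


def tally_by_segment(sdrs: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Total SDR bp per segment and as % of segment size.

    *segments* columns: name, chrom, start, end.  SDRs spanning a segment
    boundary contribute only their overlap to each segment, so the grand
    total is conserved.  Returns one row per segment plus a Total row with
    columns: segment, sdr_bp, segment_bp, pct.
    """
    rows = []
    for seg in segments.itertuples(index=False):
        bp = 0
        sub = sdrs[sdrs["chrom"] == seg.chrom] if len(sdrs) else sdrs
        for sdr in sub.itertuples(index=False):
            bp += max(0, min(sdr.end, seg.end) - max(sdr.start, seg.start))
        seg_len = seg.end - seg.start
        rows.append(
            {
                "segment": seg.name,
                "sdr_bp": bp,
                "segment_bp": seg_len,
                "pct": 100.0 * bp / seg_len,
            }
        )
    total_sdr = sum(r["sdr_bp"] for r in rows)
    total_seg = sum(r["segment_bp"] for r in rows)
    rows.append(
        {
            "segment": "Total",
            "sdr_bp": total_sdr,
            "segment_bp": total_seg,
            "pct": 100.0 * total_sdr / total_seg if total_seg else 0.0,
        }
    )
    return pd.DataFrame(rows)


def summarize_role_matrix(
    role_bp: pd.DataFrame, segment_bp: pd.Series | dict
) -> pd.DataFrame:
    """Complete a role x segment bp matrix with row/column totals and
    percent-of-segment figures.

    *role_bp*: rows = genomic roles (exon, intron, ...), columns = segments,
    values = SDR bp.  *segment_bp*: total size of each segment in bp.
    Returns the matrix with an appended ``Total`` column (per-role genome
    sum), a ``Total`` row (per-segment SDR sum), and a ``pct_segment`` row
    (100 * segment SDR total / segment size, grand figure in the Total
    column).
    """
    seg_bp = pd.Series(segment_bp, dtype=float)
    missing = [c for c in role_bp.columns if c not in seg_bp.index]
    if missing:
        raise ValueError(f"no segment size for: {missing}")
    out = role_bp.copy().astype(float)
    out["Total"] = out.sum(axis=1)
    col_tot = out.sum(axis=0)
    out.loc["Total"] = col_tot
    pct = {
        c: 100.0 * col_tot[c] / (seg_bp[c] if c != "Total" else seg_bp[role_bp.columns].sum())
        for c in out.columns
    }
    out.loc["pct_segment"] = pd.Series(pct)
    return out
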