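"""Copy-number-variation candidates from high-log-ratio SF runs.

A sequence-divergence signal and a copy-number difference both perturb
hybridization strength; what distinguishes a duplication-number difference
is a sustained log2-ratio beyond +/-1 (a two-fold intensity change) over
multiple consecutive probes.  A run of consecutive significant probes, each
with |Hodges-Lehmann log-ratio| >= 1, spanning at least 300 bp is reported
as a CNV candidate.  Only direction (which group carries more copies) and
magnitude are emitted: absolute copy numbers cannot be recovered without
hybridizations of known copy number, and group-level copy-number
polymorphism makes non-integer ratios (e.g. log2(8/3) = 1.41,
-log2(7/44) = 2.65) the norm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["copy_ratio_log2", "call_cnv", "DEFAULT_MIN_SPAN_BP", "DEFAULT_MIN_ABS_LR"]

DEFAULT_MIN_SPAN_BP = 300
DEFAULT_MIN_ABS_LR = 1.0


def copy_ratio_log2(copies_a: int, copies_b: int) -> float:
    """Expected log2-ratio of a clean copy-number difference:
    log2(copies_a / copies_b)."""
    if copies_a < 1 or copies_b < 1:
        raise ValueError("copy numbers must be >= 1")
    # difference of logs keeps the a<->b antisymmetry exact in floating point
    return float(np.log2(copies_a) - np.log2(copies_b))


def _runs(lr: np.ndarray, min_abs_lr: float, max_interruptions: int):
    """Maximal runs of indices with |lr| >= min_abs_lr, permitting up to
    max_interruptions consecutive-probe dips below threshold inside a run.
    Runs never start or end on a sub-threshold probe."""
    above = np.abs(lr) >= min_abs_lr
    runs = []
    i = 0
    n = len(lr)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        interruptions = 0
        last_above = i
        while j + 1 < n:
            if above[j + 1]:
                j += 1
                last_above = j
            elif interruptions < max_interruptions:
                interruptions += 1
                j += 1
            else:
                break
        runs.append((i, last_above))
        i = last_above + 1
    return runs


def call_cnv(
    sdrs: pd.DataFrame,
    sfs: pd.DataFrame,
    min_span_bp: int = DEFAULT_MIN_SPAN_BP,
    min_abs_lr: float = DEFAULT_MIN_ABS_LR,
    max_interruptions: int = 0,
    annotation=None,
    proximity_bp: int = 250,
) -> pd.DataFrame:
    """Call CNV candidates inside SDRs.

    For each SDR, member SFs are walked in genomic order; maximal runs of
    consecutive SFs with |hl_log_ratio| >= min_abs_lr (allowing up to
    *max_interruptions* sub-threshold SFs inside a run) whose genomic span
    reaches *min_span_bp* become calls.  Direction is ``gain_A`` for
    positive median log-ratio (group A hybridizes stronger, i.e. carries
    more copies) and ``gain_B`` otherwise.  When *annotation* is given each
    call is categorized exon/intron/intergenic by majority of spanned bp
    (promoter/terminal flanks count as intergenic; ties go to the
    higher-precedence role).

    Returns columns: chrom, start, end, span_bp, n_probes, median_lr,
    direction, role, sdr_index.
    """
    rows = []
    for sdr_idx, sdr in enumerate(sdrs.itertuples(index=False)):
        members = sfs[
            (sfs["chrom"] == sdr.chrom)
            & (sfs["start"] >= sdr.start)
            & (sfs["start"] < sdr.end)
        ].sort_values("start", kind="mergesort")
        if not len(members):
            continue
        lr = members["hl_log_ratio"].to_numpy()
        starts = members["start"].to_numpy()
        ends = (members["start"] + members["length"]).to_numpy()
        for i, j in _runs(lr, min_abs_lr, max_interruptions):
            span = int(ends[j] - starts[i])
            if span < min_span_bp:
                continue
            med = float(np.median(lr[i : j + 1]))
            if abs(med) < min_abs_lr:
                continue
            rows.append(
                {
                    "chrom": sdr.chrom,
                    "start": int(starts[i]),
                    "end": int(ends[j]),
                    "span_bp": span,
                    "n_probes": j - i + 1,
                    "median_lr": med,
                    "direction": "gain_A" if med > 0 else "gain_B",
                    "role": None,
                    "sdr_index": sdr_idx,
                }
            )
    calls = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "span_bp", "n_probes",
            "median_lr", "direction", "role", "sdr_index",
        ],
    )
    if annotation is not None and len(calls):
        calls["role"] = _majority_role(calls, annotation, proximity_bp)
    return calls


def _majority_role(calls: pd.DataFrame, annotation, proximity_bp: int) -> list[str]:
    from .annotate import classify_bases

    partition = classify_bases(calls, annotation, proximity_bp=proximity_bp)
    out = []
    for _, row in partition.iterrows():
        three_way = {
            "exon": row["exon"],
            "intron": row["intron"],
            "intergenic": row["promoter"] + row["terminal"] + row["intergenic"],
        }
        best = max(three_way.values())
        for role in ("exon", "intron", "intergenic"):  # precedence on ties
            if three_way[role] == best:
                out.append(role)
                break
    return out
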