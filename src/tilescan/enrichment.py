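"""Enrichment and association statistics on called results.

Covers the three generic tests run on scan output: a 2x2 chi-squared
comparing SF rates in coding vs non-coding probes of a region (continuity-
corrected by default), a rank-sum test for concentration of hit density
inside inversion intervals, and a one-way ANOVA comparing role proportions
across chromosome segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CodingContingency",
    "CodingTestResult",
    "coding_noncoding_test",
    "inversion_association",
    "segment_proportion_comparison",
]


@dataclass(frozen=True)
class CodingContingency:
    """Probe and SF counts of one region split by coding status."""

    probes_noncoding: int
    probes_exon: int
    sf_noncoding: int
    sf_exon: int

    def __post_init__(self) -> None:
        for v in (self.probes_noncoding, self.probes_exon, self.sf_noncoding, self.sf_exon):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.sf_noncoding > self.probes_noncoding or self.sf_exon > self.probes_exon:
            raise ValueError("SF counts cannot exceed probe counts")


@dataclass(frozen=True)
class CodingTestResult:
    percent_sf_noncoding: float
    percent_sf_exon: float
    chi2: float
    p_value: float


def coding_noncoding_test(
    c: CodingContingency, correction: bool = True
) -> CodingTestResult:
    """Chi-squared test for skewed SF rates between exonic and non-coding
    probes of a region (SF vs non-SF x coding vs non-coding), with Yates
    continuity correction by default.  Zero SFs in both classes give
    chi2 = 0, p = 1."""
    if c.probes_noncoding <= 0 or c.probes_exon <= 0:
        raise ValueError("both probe counts must be positive")
    pct_nc = 100.0 * c.sf_noncoding / c.probes_noncoding
    pct_ex = 100.0 * c.sf_exon / c.probes_exon
    if c.sf_noncoding == 0 and c.sf_exon == 0:
        return CodingTestResult(pct_nc, pct_ex, 0.0, 1.0)
    if c.sf_noncoding == c.probes_noncoding and c.sf_exon == c.probes_exon:
        # every probe significant in both classes: no skew to test
        return CodingTestResult(pct_nc, pct_ex, 0.0, 1.0)
    table = np.array(
        [
            [c.sf_noncoding, c.probes_noncoding - c.sf_noncoding],
            [c.sf_exon, c.probes_exon - c.sf_exon],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return CodingTestResult(pct_nc, pct_ex, float(chi2), float(p))


def inversion_association(density: pd.DataFrame, inversions) -> float:
    """Two-sided rank-sum p-value comparing hit-density values of windows
    inside vs outside inversion intervals.

    A window counts as inside when its midpoint falls within an inversion.
    *inversions* is an iterable of (name, chrom, start, end) or
    (chrom, start, end) tuples.
    """
    mids = ((density["start"] + density["end"]) / 2).to_numpy()
    chroms = density["chrom"].to_numpy()
    inside = np.zeros(len(density), dtype=bool)
    for inv in inversions:
        chrom, start, end = inv[-3], inv[-2], inv[-1]
        inside |= (chroms == chrom) & (mids >= start) & (mids < end)
    x = density["hit_density"].to_numpy()[inside]
    y = density["hit_density"].to_numpy()[~inside]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("no windows in one of the classes")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(1.0, p)


def segment_proportion_comparison(role_matrix: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA across chromosome segments of per-role SDR proportions.

    *role_matrix*: rows = roles, columns = segments, values = proportions
    (or bp).  Each segment's column is one group of observations.  Returns
    (F, p); all-equal proportions give F = 0.
    """
    if role_matrix.shape[1] < 2 or role_matrix.shape[0] < 2:
        raise ValueError("need >= 2 segments and >= 2 role categories")
    cols = [role_matrix[c].to_numpy(dtype=float) for c in role_matrix.columns]
    flat = np.concatenate(cols)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*cols)
    return float(f), float(p)
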