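"""Storey pi0 / q-value false-discovery-rate control.

pi0 is the estimated proportion of truly null probe comparisons; reported as
a percentage it doubles as a genome-similarity summary (100% = no detectable
differentiation between the two groups).  q-values convert each probe's
p-value into the minimum FDR at which it would be called significant, and a
target FDR maps back to the largest acceptable p-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

__all__ = [
    "FdrResult",
    "estimate_pi0",
    "compute_qvalues",
    "p_threshold_for_fdr",
    "fdr_analysis",
    "pi0_similarity_report",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass
class FdrResult:
    pi0: float
    q_values: np.ndarray
    p_threshold: float
    target_fdr: float
    m: int

    @property
    def pi0_percent(self) -> float:
        return 100.0 * self.pi0


def estimate_pi0(p_values, lambda_grid=None) -> float:
    """Estimate the null proportion pi0 from a p-value vector.

    Computes pi0_hat(lambda) = #{p > lambda} / (m * (1 - lambda)) over the
    grid (default 0.05, 0.10, ..., 0.95), smooths it with a cubic smoothing
    spline against lambda, evaluates the smoother at the largest lambda and
    clips to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    m = p.size
    pi0_lam = np.array([(p > v).sum() / (m * (1.0 - v)) for v in lam])
    if lam.size < 4:
        pi0 = pi0_lam[-1]
    else:
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam.max()))
    return float(np.clip(pi0, 0.0, 1.0))


def compute_qvalues(p_values, pi0: float) -> np.ndarray:
    """q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j  (step-down monotonization
    on the sorted p-values).  NaN inputs (untested probes) yield NaN."""
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    q_sorted = pi0 * m * pv[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    out[ok] = q
    return out


def p_threshold_for_fdr(p_values, q_values, target: float) -> float:
    """Largest p with q <= target; 0.0 when no probe passes (zero SFs)."""
    if not 0.0 < target < 1.0:
        raise ValueError("target FDR must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    q = np.asarray(q_values, dtype=float)
    ok = ~np.isnan(p) & ~np.isnan(q) & (q <= target)
    if not ok.any():
        return 0.0
    return float(p[ok].max())


def fdr_analysis(p_values, target_fdr: float = 0.001, lambda_grid=None) -> FdrResult:
    """Full FDR step: pi0, q-values and the p-value threshold for the target
    FDR.  NaN p-values (untested probes) are excluded from m."""
    p = np.asarray(p_values, dtype=float)
    pi0 = estimate_pi0(p, lambda_grid=lambda_grid)
    q = compute_qvalues(p, pi0)
    thr = p_threshold_for_fdr(p, q, target_fdr)
    return FdrResult(
        pi0=pi0, q_values=q, p_threshold=thr, target_fdr=target_fdr,
        m=int((~np.isnan(p)).sum()),
    )


def pi0_similarity_report(
    matrix, probes, config=None, grouping: str = "between", seed: int | None = None
) -> float:
    """Genome-similarity summary: run the windowed scan under a grouping and
    report pi0 as a percentage.

    grouping:
        ``"between"`` uses the matrix's own A/B labels;
        ``"within:A"`` / ``"within:B"`` randomly split that group's samples
        into two pseudo-groups (seeded) — the within-form null comparison.
        A dict of sample_id -> "A"/"B" applies an explicit relabeling
        (e.g. a by-collection-date split).
    """
    from .io import IntensityMatrix
    from .normalize import log_transform, quantile_normalize
    from .scan import scan_genome

    def _rebuild(keep: list[str], relabel: dict[str, str]) -> IntensityMatrix:
        idx = [matrix.sample_ids.index(s) for s in keep]
        return IntensityMatrix(
            matrix.probe_ids, keep,
            np.array([relabel[s] for s in keep], dtype=object),
            matrix.values[:, idx], log_scale=matrix.log_scale,
        )

    if isinstance(grouping, dict):
        work = _rebuild([s for s in matrix.sample_ids if s in grouping], grouping)
    elif grouping == "between":
        work = matrix
    elif grouping in ("within:A", "within:B"):
        label = grouping.split(":")[1]
        members = [s for s, g in zip(matrix.sample_ids, matrix.groups) if g == label]
        if len(members) < 4:
            raise ValueError("need >= 4 samples for a within-group split")
        rng = np.random.default_rng(seed)
        half = len(members) // 2
        picked = set(rng.choice(members, size=half, replace=False).tolist())
        work = _rebuild(members, {s: ("A" if s in picked else "B") for s in members})
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    if not work.log_scale:
        work = log_transform(quantile_normalize(work))
    result = scan_genome(work, probes, config)
    p = result.loc[result["tested"], "p_value"].to_numpy()
    return 100.0 * estimate_pi0(p)
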