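"""Synthetic tiling-array data with known planted structure.

Real two-chip hybridization data for the Bamako/Savanna comparison sits
behind a database of CEL files; this module generates everything the
pipeline consumes — probe sets, gene annotations, segment and inversion
maps, and two-group intensity matrices — with a truth table of planted
divergent and CNV intervals, so every downstream stage can be tested for
recovery against known ground truth.

The generated probe intensity, on the log2 scale, is

    baseline + probe_affinity + cnv_term + divergence_term + noise

where ``probe_affinity ~ N(0, probe_affinity_sd)`` is fixed per probe
(shared across samples, so it cancels in two-sample comparisons),
``cnv_term = log2(copies_of_sample_group / copies_of_group_B)`` inside a
planted CNV interval, the divergence term subtracts the planted effect from
the *affected* group inside divergent intervals (sequence mismatch weakens
hybridization on a perfect-match array), and ``noise ~ N(0,
sample_noise_sd)`` is independent per probe and sample.  Matrices are
returned on the linear scale, as a scanner would deliver them.

The default genome plan mirrors the chromosome-segment sizes of the real
230.5 Mbp assembly scaled down 1000x (2R 61.5 kb ... X 21.4 kb plus the
3 kb centromere-proximal X3M segment), with one probe per 17 bp genome-wide
and one per 5 bp inside X3M, so the full pipeline runs in seconds while
keeping the probes-per-window geometry of the real array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import GeneAnnotation, IntensityMatrix, ProbeSet

__all__ = [
    "GenomePlan",
    "TruthTable",
    "NoiseModel",
    "default_plan",
    "default_truth",
    "build_probe_set",
    "simulate_intensities",
    "simulate_annotation",
    "plan_from_yaml",
    "plan_to_yaml",
]


@dataclass(frozen=True)
class GenomePlan:
    """Blueprint of the simulated genome.

    segments: (name, chrom, start, end) tuples, non-overlapping per
    chromosome.  high_density_regions: (chrom, start, end, spacing_bp)
    probe-spacing overrides.  inversions: (name, chrom, start, end).
    """

    segments: tuple = ()
    inversions: tuple = ()
    high_density_regions: tuple = ()
    probe_spacing_bp: int = 17
    probe_length_bp: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_spacing_bp < 1:
            raise ValueError("probe spacing must be >= 1")
        if self.probe_length_bp < 1:
            raise ValueError("probe length must be >= 1")
        for name, chrom, start, end in self.segments:
            if start >= end:
                raise ValueError(f"segment {name}: start must be < end")
        by_chrom: dict[str, list] = {}
        for name, chrom, start, end in self.segments:
            by_chrom.setdefault(chrom, []).append((start, end, name))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"segments {n1} and {n2} overlap on {chrom}")
        for intervals in (self.inversions,):
            for name, chrom, start, end in intervals:
                if start >= end:
                    raise ValueError(f"interval {name}: start must be < end")

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["name", "chrom", "start", "end"])

    def segment_sizes_bp(self) -> dict[str, int]:
        return {name: end - start for name, _, start, end in self.segments}


@dataclass(frozen=True)
class TruthTable:
    """Planted structure: divergent intervals (chrom, start, end,
    effect_log2, affected_group) and CNV intervals (chrom, start, end,
    copies_A, copies_B)."""

    divergent_intervals: tuple = ()
    cnv_intervals: tuple = ()

    def __post_init__(self) -> None:
        for chrom, start, end, effect, group in self.divergent_intervals:
            if start >= end:
                raise ValueError("divergent interval with start >= end")
            if not np.isfinite(effect):
                raise ValueError("effect size must be finite")
            if group not in ("A", "B"):
                raise ValueError(f"unknown affected group {group!r}")
        for chrom, start, end, ca, cb in self.cnv_intervals:
            if start >= end:
                raise ValueError("CNV interval with start >= end")
            if ca < 1 or cb < 1:
                raise ValueError("copy numbers must be >= 1")

    def validate_against(self, plan: GenomePlan) -> None:
        """Check every planted interval lies within a declared segment."""
        segs = [(c, s, e) for _, c, s, e in plan.segments]

        def contained(chrom, start, end):
            return any(c == chrom and s <= start and end <= e for c, s, e in segs)

        for iv in self.divergent_intervals:
            if not contained(iv[0], iv[1], iv[2]):
                raise ValueError(f"divergent interval {iv} outside declared segments")
        for iv in self.cnv_intervals:
            if not contained(iv[0], iv[1], iv[2]):
                raise ValueError(f"CNV interval {iv} outside declared segments")

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "start": s, "end": e, "kind": "divergent",
             "effect": eff, "group": g}
            for c, s, e, eff, g in self.divergent_intervals
        ] + [
            {"chrom": c, "start": s, "end": e, "kind": "cnv",
             "effect": float(np.log2(ca / cb)), "group": "A" if ca > cb else "B"}
            for c, s, e, ca, cb in self.cnv_intervals
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "effect", "group"])


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the log2 scale."""

    baseline_log2: float = 10.0
    probe_affinity_sd: float = 0.5
    sample_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.probe_affinity_sd < 0 or self.sample_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def default_plan(seed: int = 0) -> GenomePlan:
    """The 1000x-scaled default genome: five chromosome arms with the real
    segment-size ratios, X3M as a separate high-density segment."""
    return GenomePlan(
        segments=(
            ("2R", "2R", 0, 61_500),
            ("2L", "2L", 0, 49_400),
            ("3R", "3R", 0, 53_200),
            ("3L", "3L", 0, 42_000),
            ("X3M", "X", 0, 3_000),
            ("X", "X", 3_000, 24_400),
        ),
        inversions=(
            ("2Rj", "2R", 2_000, 16_000),
            ("2Rb", "2R", 18_000, 27_000),
            ("2Rc", "2R", 28_000, 32_500),
            ("2Ru", "2R", 33_000, 37_500),
            ("2La", "2L", 5_000, 26_000),
        ),
        high_density_regions=(("X", 0, 3_000, 5),),
        probe_spacing_bp=17,
        probe_length_bp=25,
        seed=seed,
    )


def default_truth(plan: GenomePlan | None = None) -> TruthTable:
    """Planted structure echoing the real study's geography: divergence near
    the j/b inversion breakpoints, in X3M and on X, two 3R hotspots, and
    CNVs at 8:3, 7:44 and 5:2 copy ratios."""
    return TruthTable(
        divergent_intervals=(
            ("2R", 2_200, 6_200, 2.0, "A"),     # 5' j breakpoint
            ("2R", 14_500, 18_500, 2.0, "A"),   # 3' j / 5' b breakpoints
            ("X", 400, 2_400, 2.0, "A"),        # inside X3M
            ("X", 8_000, 11_000, 2.0, "A"),
            ("3R", 34_000, 37_000, 2.0, "A"),   # 3R hotspot
        ),
        cnv_intervals=(
            ("2R", 22_000, 22_800, 8, 3),       # log2(8/3)  = +1.41, gain in A
            ("3R", 40_000, 40_700, 7, 44),      # log2(7/44) = -2.65, gain in B
            ("2L", 30_000, 30_600, 5, 2),       # log2(5/2)  = +1.32, gain in A
        ),
    )


def build_probe_set(plan: GenomePlan) -> ProbeSet:
    """Tile probes over every segment at the plan's spacing, with overridden
    spacing inside high-density regions.  Deterministic for a fixed plan."""
    if not plan.segments:
        raise ValueError("no segments")
    rows = []
    for name, chrom, seg_start, seg_end in plan.segments:
        pieces = _split_by_density(chrom, seg_start, seg_end, plan)
        for lo, hi, spacing in pieces:
            # probes start inside [lo, hi); a probe may overhang the segment
            # end by up to probe_length - 1 bp, as on a real tiled array
            for pos in range(lo, hi, spacing):
                rows.append((chrom, pos))
    df = pd.DataFrame(rows, columns=["chrom", "start"]).drop_duplicates()
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return ProbeSet(
        probe_id=np.array(
            [f"{c}_{s:09d}" for c, s in zip(df["chrom"], df["start"])], dtype=object
        ),
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        length=np.full(len(df), plan.probe_length_bp, dtype=np.int64),
    )


def _split_by_density(chrom, seg_start, seg_end, plan: GenomePlan):
    """Partition [seg_start, seg_end) into (lo, hi, spacing) pieces according
    to high-density overrides."""
    cuts = [(seg_start, seg_end, plan.probe_spacing_bp)]
    for hd_chrom, hd_start, hd_end, hd_spacing in plan.high_density_regions:
        if hd_chrom != chrom:
            continue
        new = []
        for lo, hi, spacing in cuts:
            a, b = max(lo, hd_start), min(hi, hd_end)
            if b <= a:
                new.append((lo, hi, spacing))
                continue
            if lo < a:
                new.append((lo, a, spacing))
            new.append((a, b, hd_spacing))
            if b < hi:
                new.append((b, hi, spacing))
        cuts = new
    return cuts


def simulate_intensities(
    probes: ProbeSet,
    truth: TruthTable,
    noise: NoiseModel,
    n_per_group: int = 7,
    seed: int = 0,
) -> IntensityMatrix:
    """Draw a two-group intensity matrix with the planted structure.

    Samples A1..An form group A, B1..Bn group B.  Values are returned on the
    linear scale; runs with identical seeds are bit-identical.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if len(probes) == 0:
        raise ValueError("empty probe set")
    rng = np.random.default_rng(seed)
    n_probes = len(probes)
    n_samples = 2 * n_per_group
    centers = probes.center

    affinity = rng.normal(0.0, noise.probe_affinity_sd, size=n_probes)
    log2v = noise.baseline_log2 + affinity[:, None] + np.zeros((n_probes, n_samples))

    group_of = np.array(["A"] * n_per_group + ["B"] * n_per_group, dtype=object)
    is_a = group_of == "A"

    for chrom, start, end, ca, cb in truth.cnv_intervals:
        inside = (probes.chrom == chrom) & (centers >= start) & (centers < end)
        # reference = group B copy number, so the A-B contrast is log2(ca/cb)
        log2v[np.ix_(inside, is_a)] += np.log2(ca / cb)
    for chrom, start, end, effect, group in truth.divergent_intervals:
        inside = (probes.chrom == chrom) & (centers >= start) & (centers < end)
        log2v[np.ix_(inside, group_of == group)] -= effect

    log2v += rng.normal(0.0, noise.sample_noise_sd, size=(n_probes, n_samples))

    sample_ids = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    return IntensityMatrix(
        probe_ids=probes.probe_id,
        sample_ids=sample_ids,
        groups=group_of,
        values=np.power(2.0, log2v),
    )


def simulate_annotation(
    plan: GenomePlan,
    seed: int = 0,
    mean_gene_length_bp: int = 1_200,
    mean_gene_spacing_bp: int = 2_500,
    exons_per_gene: tuple[int, int] = (2, 4),
) -> GeneAnnotation:
    """Random but reproducible gene models over the plan's segments.

    Genes are dropped along each segment with exponential spacing, each with
    a handful of exons separated by introns; strands alternate.  This gives
    downstream role classification realistic exon/intron/flank/intergenic
    structure without modeling any real gene set.
    """
    rng = np.random.default_rng(seed)
    genes, exons = [], []
    gid = 0
    for name, chrom, seg_start, seg_end in plan.segments:
        pos = seg_start + int(rng.exponential(mean_gene_spacing_bp / 2))
        while True:
            length = max(200, int(rng.exponential(mean_gene_length_bp)))
            if pos + length >= seg_end:
                break
            gid += 1
            gene_id = f"GENE{gid:05d}"
            strand = "+" if gid % 2 else "-"
            genes.append((gene_id, chrom, pos, pos + length, strand))
            n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
            bounds = np.sort(rng.choice(
                np.arange(1, length), size=min(2 * n_exons - 2, length - 2),
                replace=False,
            ))
            edges = np.concatenate([[0], bounds, [length]])
            for k in range(0, len(edges) - 1, 2):
                exons.append((gene_id, chrom, pos + int(edges[k]), pos + int(edges[k + 1])))
            pos = pos + length + int(rng.exponential(mean_gene_spacing_bp))
    return GeneAnnotation(
        genes=pd.DataFrame(
            genes, columns=["gene_id", "chrom", "start", "end", "strand"]
        ),
        exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
    )


# ---------------------------------------------------------------------------
# plan / truth / noise YAML round-trip
# ---------------------------------------------------------------------------

def plan_to_yaml(plan: GenomePlan, truth: TruthTable, noise: NoiseModel, path) -> None:
    doc = {
        "plan": {
            "segments": [list(s) for s in plan.segments],
            "inversions": [list(s) for s in plan.inversions],
            "high_density_regions": [list(s) for s in plan.high_density_regions],
            "probe_spacing_bp": plan.probe_spacing_bp,
            "probe_length_bp": plan.probe_length_bp,
            "seed": plan.seed,
        },
        "truth": {
            "divergent_intervals": [list(s) for s in truth.divergent_intervals],
            "cnv_intervals": [list(s) for s in truth.cnv_intervals],
        },
        "noise": {
            "baseline_log2": noise.baseline_log2,
            "probe_affinity_sd": noise.probe_affinity_sd,
            "sample_noise_sd": noise.sample_noise_sd,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def plan_from_yaml(path) -> tuple[GenomePlan, TruthTable, NoiseModel]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    p = doc.get("plan", {})
    plan = GenomePlan(
        segments=tuple(tuple(s) for s in p.get("segments", [])),
        inversions=tuple(tuple(s) for s in p.get("inversions", [])),
        high_density_regions=tuple(tuple(s) for s in p.get("high_density_regions", [])),
        probe_spacing_bp=p.get("probe_spacing_bp", 17),
        probe_length_bp=p.get("probe_length_bp", 25),
        seed=p.get("seed", 0),
    )
    t = doc.get("truth", {})
    truth = TruthTable(
        divergent_intervals=tuple(tuple(s) for s in t.get("divergent_intervals", [])),
        cnv_intervals=tuple(tuple(s) for s in t.get("cnv_intervals", [])),
    )
    n = doc.get("noise", {})
    noise = NoiseModel(
        baseline_log2=n.get("baseline_log2", 10.0),
        probe_affinity_sd=n.get("probe_affinity_sd", 0.5),
        sample_noise_sd=n.get("sample_noise_sd", 0.1),
    )
    return plan, truth, noise
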