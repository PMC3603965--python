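"""Genomic-role classification of SDRs against a gene annotation.

Every SDR base is assigned exactly one role with precedence
exon > intron > promoter > terminal > intergenic:

* exon — inside an annotated exon;
* intron — inside a gene span but not in an exon;
* promoter — within ``proximity_bp`` upstream of a gene's 5' end
  (strand-aware);
* terminal — within ``proximity_bp`` downstream of the 3' end;
* intergenic — none of the above, i.e. no gene within ``proximity_bp``.

The same 250 bp proximity constant drives both the promoter and terminal
flanks and the intergenic rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneAnnotation

__all__ = ["ROLES", "classify_bases", "genes_overlapping", "gene_density"]

ROLES = ("exon", "intron", "promoter", "terminal", "intergenic")
_CODE = {role: i for i, role in enumerate(ROLES)}


def _role_trees(annotation: GeneAnnotation, proximity_bp: int) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {
        r: {} for r in ("exon", "gene", "promoter", "terminal")
    }

    def add(kind: str, chrom: str, start: int, end: int) -> None:
        if end > start:
            trees[kind].setdefault(chrom, IntervalTree()).addi(start, end)

    for g in annotation.genes.itertuples(index=False):
        add("gene", g.chrom, g.start, g.end)
        if g.strand == "-":
            add("promoter", g.chrom, g.end, g.end + proximity_bp)
            add("terminal", g.chrom, g.start - proximity_bp, g.start)
        else:
            add("promoter", g.chrom, g.start - proximity_bp, g.start)
            add("terminal", g.chrom, g.end, g.end + proximity_bp)
    for e in annotation.exons.itertuples(index=False):
        add("exon", e.chrom, e.start, e.end)
    return trees


def _paint(span: np.ndarray, offset: int, tree: IntervalTree | None, lo: int, hi: int, code: int) -> None:
    if tree is None:
        return
    for iv in tree.overlap(lo, hi):
        a = max(iv.begin, lo) - offset
        b = min(iv.end, hi) - offset
        span[a:b] = code


def classify_bases(
    sdrs: pd.DataFrame, annotation: GeneAnnotation, proximity_bp: int = 250
) -> pd.DataFrame:
    """Partition each SDR's bases by genomic role.

    Returns one row per SDR (aligned to the input order) with one column per
    role holding assigned bp; the roles are mutually exclusive per base, so
    each row sums exactly to the SDR span.
    """
    trees = _role_trees(annotation, proximity_bp)
    # paint lowest precedence first so higher roles overwrite
    paint_order = [
        ("terminal", _CODE["terminal"]),
        ("promoter", _CODE["promoter"]),
        ("gene", _CODE["intron"]),
        ("exon", _CODE["exon"]),
    ]
    rows = []
    for sdr in sdrs.itertuples(index=False):
        lo, hi = int(sdr.start), int(sdr.end)
        span = np.full(hi - lo, _CODE["intergenic"], dtype=np.int8)
        for kind, code in paint_order:
            _paint(span, lo, trees[kind].get(sdr.chrom), lo, hi, code)
        counts = np.bincount(span, minlength=len(ROLES))
        rows.append({role: int(counts[_CODE[role]]) for role in ROLES})
    out = pd.DataFrame(rows, columns=list(ROLES))
    if len(sdrs):
        out.index = sdrs.index
    return out


def genes_overlapping(sdrs: pd.DataFrame, annotation: GeneAnnotation) -> pd.DataFrame:
    """Genes whose span intersects any SDR, flagged when the intersection
    touches one of their exons.

    Returns columns: gene_id, chrom, start, end, strand, n_sdrs,
    exon_overlap.
    """
    sdr_trees: dict[str, IntervalTree] = {}
    for sdr in sdrs.itertuples(index=False):
        if sdr.end > sdr.start:
            sdr_trees.setdefault(sdr.chrom, IntervalTree()).addi(int(sdr.start), int(sdr.end))
    exons_by_gene = (
        dict(tuple(annotation.exons.groupby("gene_id", sort=False)))
        if len(annotation.exons)
        else {}
    )
    rows = []
    for g in annotation.genes.itertuples(index=False):
        tree = sdr_trees.get(g.chrom)
        if tree is None:
            continue
        hits = tree.overlap(g.start, g.end)
        if not hits:
            continue
        exon_hit = False
        for e in exons_by_gene.get(g.gene_id, pd.DataFrame()).itertuples(index=False):
            if tree.overlap(e.start, e.end):
                exon_hit = True
                break
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "n_sdrs": len(hits),
                "exon_overlap": exon_hit,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "n_sdrs", "exon_overlap"],
    )


def gene_density(segment_length_bp: int, n_genes: int) -> float:
    """Gene spacing of a segment in kbp per gene (e.g. 3.00 Mbp holding 37
    genes -> ~81 kbp/gene)."""
    if n_genes <= 0:
        raise ValueError("segment has no genes; density undefined")
    return (segment_length_bp / 1000.0) / n_genes
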