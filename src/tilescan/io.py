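"""Core containers and file formats for the tiling-array pipeline.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open ``[start, end)``, the BED
convention.  GFF3 input/output is 1-based inclusive and is converted at the
boundary.  A probe's *position* for windowing purposes is its center,
``start + length // 2`` (start + 12 for the standard 25-mer).

File formats
------------
Probe sets, significant features, regions and CNV calls travel as BED;
per-probe log-ratio and hit-density tracks as bedGraph; intensity matrices
as TSV keyed by probe id with the sample→group map embedded in a
``# group:`` comment header; gene models as GFF3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeSet",
    "IntensityMatrix",
    "GeneAnnotation",
    "read_gff3",
    "write_gff3",
    "read_intensities",
    "write_intensities",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "write_tracks",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeSet:
    """Ordered genomic positions of short oligo probes.

    Probes are sorted by ``(chromosome, start)`` with unique ids; this
    ordering is the coordinate backbone of the windowed scan.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    length: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.probe_id)
        if not (len(self.chrom) == len(self.start) == len(self.length) == n):
            raise ValueError("probe set arrays have unequal lengths")
        if n == 0:
            raise ValueError("empty probe set")
        if np.any(self.length <= 0):
            raise ValueError("probe length must be positive")
        if len(set(self.probe_id.tolist())) != n:
            raise ValueError("probe ids are not unique")
        order = np.lexsort((self.start, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("probes must be sorted by (chromosome, start)")

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def center(self) -> np.ndarray:
        return self.start + self.length // 2

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome (probes are sorted)."""
        out: dict[str, slice] = {}
        chroms, starts = np.unique(self.chrom, return_index=True)
        bounds = np.sort(starts).tolist() + [len(self)]
        for i, s in enumerate(sorted(starts)):
            out[str(self.chrom[s])] = slice(bounds[i], bounds[i + 1])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "chrom": self.chrom,
                "start": self.start,
                "length": self.length,
                "center": self.center,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeSet":
        df = df.sort_values(["chrom", "start"], kind="mergesort")
        return cls(
            probe_id=df["probe_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            length=df["length"].to_numpy(dtype=np.int64),
        )

    def to_bed(self, path) -> None:
        bed = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.start + self.length,
                "name": self.probe_id,
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "ProbeSet":
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=range(4),
            dtype={"chrom": str, "name": str},
        )
        return cls.from_frame(
            pd.DataFrame(
                {
                    "probe_id": bed["name"],
                    "chrom": bed["chrom"],
                    "start": bed["start"],
                    "length": bed["end"] - bed["start"],
                }
            )
        )


@dataclass
class IntensityMatrix:
    """Probes x samples fluorescence values with a two-group design.

    ``values`` are strictly positive on the linear scale as read from disk;
    :func:`tilescan.normalize.log_transform` moves them to log2.  ``groups``
    assigns every sample to group ``"A"`` or ``"B"``; both groups must be
    non-empty.
    """

    probe_ids: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray
    values: np.ndarray
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match probes x samples")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("every sample needs a group label")
        labels = set(self.groups.tolist())
        if not labels <= {"A", "B"}:
            raise ValueError(f"unknown group label(s): {sorted(labels - {'A', 'B'})}")
        if "A" not in labels or "B" not in labels:
            raise ValueError("both groups must be non-empty")
        if not self.log_scale and np.any(self.values <= 0):
            raise ValueError("non-positive intensity")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def group_mask(self, label: str) -> np.ndarray:
        return self.groups == label

    def relabel(self, groups: dict[str, str] | np.ndarray) -> "IntensityMatrix":
        """Return a copy with new sample→group assignment (values shared)."""
        if isinstance(groups, dict):
            new = np.array([groups[s] for s in self.sample_ids], dtype=object)
        else:
            new = np.asarray(groups, dtype=object)
        return IntensityMatrix(self.probe_ids, list(self.sample_ids), new,
                               self.values, log_scale=self.log_scale)

    def subset_samples(self, keep: list[str]) -> "IntensityMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return IntensityMatrix(
            self.probe_ids, keep, self.groups[idx], self.values[:, idx],
            log_scale=self.log_scale,
        )


@dataclass
class GeneAnnotation:
    """Gene and exon models, internally 0-based half-open.

    ``genes`` columns: gene_id, chrom, start, end, strand.
    ``exons`` columns: gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.genes) and np.any(self.genes["end"] <= self.genes["start"]):
            raise ValueError("gene with end <= start")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> GeneAnnotation:
    """Load gene/exon features from a GFF3 file.

    Feature types other than gene and exon are ignored; exons are attached to
    their ancestor gene (direct ``Parent=gene`` or via an mRNA level).  Exons
    without a resolvable parent gene are skipped with a warning.
    """
    _validate_gff3_syntax(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_rows = []
    for g in db.features_of_type("gene"):
        strand = g.strand if g.strand in ("+", "-") else "+"
        if g.strand not in ("+", "-"):
            warnings.warn(f"gene {g.id} has no strand; assuming forward")
        gene_rows.append((g.id, g.seqid, g.start - 1, g.end, strand))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    exon_rows = []
    for e in db.features_of_type("exon"):
        parents = list(db.parents(e, featuretype="gene"))
        if not parents:
            warnings.warn(f"exon at {e.seqid}:{e.start}-{e.end} has no parent gene; skipped")
            continue
        exon_rows.append((parents[0].id, e.seqid, e.start - 1, e.end))
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation(genes=genes, exons=exons)


def _validate_gff3_syntax(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) < 9:
                raise ValueError(f"malformed GFF3 line {lineno}: {line[:60]!r}")


def write_gff3(annotation: GeneAnnotation, path) -> None:
    """Write gene/exon features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exons_by_gene = (
            dict(tuple(annotation.exons.groupby("gene_id", sort=False)))
            if len(annotation.exons)
            else {}
        )
        for g in annotation.genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\ttilescan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, e in enumerate(
                exons_by_gene.get(g.gene_id, pd.DataFrame()).itertuples(index=False), 1
            ):
                fh.write(
                    f"{e.chrom}\ttilescan\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.E{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# intensity TSV
# ---------------------------------------------------------------------------

def write_intensities(matrix: IntensityMatrix, path) -> None:
    group_map = " ".join(f"{s}={g}" for s, g in zip(matrix.sample_ids, matrix.groups))
    with open(path, "w") as fh:
        fh.write(f"# group: {group_map}\n")
        df = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
        df.insert(0, "probe_id", matrix.probe_ids)
        df.to_csv(fh, sep="\t", index=False)


def read_intensities(path, probes: ProbeSet) -> IntensityMatrix:
    """Read an intensity TSV and align its rows to *probes*.

    Rows may appear in any order on disk; the returned matrix row order
    matches the probe set exactly.  Probes missing from the file raise an
    error naming them.
    """
    group_map: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# group:"):
            for tok in first.removeprefix("# group:").split():
                s, _, g = tok.partition("=")
                group_map[s] = g
            df = pd.read_csv(fh, sep="\t", dtype={"probe_id": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"probe_id": str})
    df = df.set_index("probe_id")
    wanted = pd.Index(probes.probe_id)
    missing = wanted.difference(df.index)
    if len(missing):
        raise ValueError(f"intensity file missing probes: {', '.join(missing[:10])}")
    df = df.loc[wanted]
    sample_ids = list(df.columns)
    unknown = [s for s in sample_ids if s not in group_map]
    if unknown:
        raise ValueError(f"no group label for sample(s): {unknown}")
    groups = np.array([group_map[s] for s in sample_ids], dtype=object)
    values = df.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("non-positive intensity")
    return IntensityMatrix(probes.probe_id, sample_ids, groups, values)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, cols=("chrom", "start", "end")) -> None:
    extra = [c for c in df.columns if c not in cols and c in ("name", "score")]
    df[list(cols) + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "value") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def write_tracks(scan_result, sfs, sdrs, density, path_prefix) -> list[str]:
    """Export browser tracks: per-probe log-ratio bedGraph, SF and SDR BED,
    hit-density bedGraph.  Returns the written paths."""
    prefix = str(path_prefix)
    written = []
    tested = scan_result[scan_result["tested"]]
    lr = pd.DataFrame(
        {
            "chrom": tested["chrom"],
            "start": tested["start"],
            "end": tested["start"] + tested["length"],
            "value": tested["hl_log_ratio"],
        }
    )
    write_bedgraph(lr, prefix + ".logratio.bedGraph")
    written.append(prefix + ".logratio.bedGraph")
    if sfs is not None:
        sf_bed = pd.DataFrame(
            {
                "chrom": sfs["chrom"],
                "start": sfs["start"],
                "end": sfs["start"] + sfs["length"],
                "name": sfs["probe_id"],
                "score": sfs["hl_log_ratio"],
            }
        )
        write_bed(sf_bed, prefix + ".sf.bed")
        written.append(prefix + ".sf.bed")
    if sdrs is not None:
        write_bed(sdrs.assign(name=[f"SDR{i + 1}" for i in range(len(sdrs))]),
                  prefix + ".sdr.bed")
        written.append(prefix + ".sdr.bed")
    if density is not None:
        write_bedgraph(density.rename(columns={"hit_density": "value"}),
                       prefix + ".density.bedGraph")
        written.append(prefix + ".density.bedGraph")
    return written
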