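"""Readers and writers for external formats, plus the coordinate contract.

Coordinate contract used throughout the package:

* genomic coordinates are **1-based inclusive** internally; BED and bedGraph
  files are converted to/from their native 0-based half-open convention only
  at the I/O boundary;
* relative coordinates around a TSS skip zero (``..., -2, -1, +1, +2, ...``;
  the TSS base itself is ``+1``), matching the promoter literature;
* signed distance to an annotated TSS is measured on the transcribed strand,
  negative = upstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "revcomp",
    "GenomeSequence",
    "GeneModel",
    "CtssTable",
    "IntervalRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_ctss",
    "read_ctss_4col",
    "read_ctss_bedgraph",
    "write_ctss_4col",
    "write_ctss_bedgraph",
    "read_bed6",
    "write_bed6",
    "CATALOG_COLUMNS",
    "write_catalog",
    "read_catalog",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Per-chromosome nucleotide sequences with strand-aware window fetch.

    Sequences are stored uppercased.  ``fetch`` uses 1-based inclusive
    coordinates and returns the reverse complement for minus-strand queries;
    lookups outside ``[1, length]`` raise ``ValueError``.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in seqs.items():
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        length = len(self._seqs[chrom])
        if not (1 <= start <= end <= length):
            raise ValueError(
                f"window {chrom}:{start}-{end} outside [1, {length}]"
            )
        if strand not in "+-":
            raise ValueError(f"invalid strand: {strand!r}")
        seq = self._seqs[chrom][start - 1 : end]
        return revcomp(seq) if strand == "-" else seq


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased).

    Duplicate headers and non-nucleotide characters are rejected.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first.startswith(">"):
            raise ValueError(f"{path}: line 1: not a FASTA file (missing '>')")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r}: invalid sequence characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for chrom in genome.chroms:
            out.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _intersect(ivs: Sequence[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    for s, e in ivs:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return out


@dataclasses.dataclass
class GeneModel:
    """A gene reduced to one representative transcript.

    ``aTSS`` is the annotated TSS: the 5'-most exon boundary on the
    transcribed strand.  ``utr5``/``utr3`` are derived from exons minus the
    CDS span; both are empty for non-coding models.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    confidence: str = "high"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model with zero exons")
        self.exons = sorted(tuple(iv) for iv in self.exons)
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.cds = sorted(tuple(iv) for iv in self.cds)
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"{self.gene_id}: CDS interval ({s},{e}) not within exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def aTSS(self) -> int:
        return self.start if self.strand == "+" else self.end

    def signed_distance(self, pos: int) -> int:
        """Signed distance from ``pos`` to the aTSS on the transcribed strand.

        Negative = upstream of the aTSS, positive = downstream; the aTSS
        itself is at distance 0.
        """
        return pos - self.aTSS if self.strand == "+" else self.aTSS - pos

    @property
    def utr5(self) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        cs, ce = self.cds[0][0], self.cds[-1][1]
        if self.strand == "+":
            return _intersect(self.exons, self.start, cs - 1)
        return _intersect(self.exons, ce + 1, self.end)

    @property
    def utr3(self) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        cs, ce = self.cds[0][0], self.cds[-1][1]
        if self.strand == "+":
            return _intersect(self.exons, ce + 1, self.end)
        return _intersect(self.exons, self.start, cs - 1)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def feature_at(self, pos: int) -> str | None:
        """Gene-body feature at ``pos``: utr5, utr3, exon, intron, or None."""
        if not self.contains(pos):
            return None
        for s, e in self.utr5:
            if s <= pos <= e:
                return "utr5"
        for s, e in self.utr3:
            if s <= pos <= e:
                return "utr3"
        for s, e in self.exons:
            if s <= pos <= e:
                return "exon"
        return "intron"


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features).

    When a gene has several mRNAs, the representative is the one with the
    5'-most transcript start on the transcribed strand (ties: longest span).
    Child features whose Parent is missing, and mRNAs without exons, are
    errors.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise ValueError(
                    f"{path}: feature {feat.id!r} references missing parent {parent_id!r}"
                )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise ValueError(f"{path}: gene {gene.id!r} has no mRNA children")
        if gene.strand == "+":
            mrnas.sort(key=lambda m: (m.start, -(m.end - m.start)))
        else:
            mrnas.sort(key=lambda m: (-m.end, -(m.end - m.start)))
        rep = mrnas[0]
        exons = [(f.start, f.end) for f in db.children(rep, featuretype="exon")]
        if not exons:
            raise ValueError(f"{path}: mRNA {rep.id!r} has zero exons")
        cds = [(f.start, f.end) for f in db.children(rep, featuretype="CDS")]
        confidence = gene.attributes.get("confidence", ["high"])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                confidence=confidence,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 with one mRNA per gene."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};confidence={g.confidence}"
            out.write(
                f"{g.chrom}\tpromkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            out.write(
                f"{g.chrom}\tpromkit\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                out.write(
                    f"{g.chrom}\tpromkit\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                out.write(
                    f"{g.chrom}\tpromkit\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# CTSS tables
# ---------------------------------------------------------------------------

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]


@dataclasses.dataclass
class CtssTable:
    """Per-position capped-5' tag counts for one sample (stage x replicate).

    ``df`` holds one record per (chrom, pos, strand) with ``count >= 1``;
    ``library_size`` is the total number of mapped tags used for TPM
    normalization and may exceed the sum of stored counts.
    """

    df: pd.DataFrame
    library_size: int = 0

    def __post_init__(self) -> None:
        df = self.df.loc[:, CTSS_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["count"] = df["count"].astype(np.int64)
        if (df["count"] < 1).any():
            raise ValueError("CTSS counts must be >= 1")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("CTSS strand must be '+' or '-'")
        if (df["pos"] < 1).any():
            raise ValueError("CTSS positions must be >= 1")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) records in CTSS table")
        df = df.sort_values(["chrom", "strand", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df
        total = int(df["count"].sum())
        if self.library_size == 0:
            self.library_size = total
        if self.library_size < total:
            raise ValueError("library_size smaller than sum of stored counts")

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())

    @classmethod
    def pool(cls, tables: Sequence["CtssTable"]) -> "CtssTable":
        """Sum counts across samples; library sizes add."""
        if not tables:
            raise ValueError("cannot pool zero tables")
        df = pd.concat([t.df for t in tables], ignore_index=True)
        df = (
            df.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
            .sum()
        )
        return cls(df=df, library_size=sum(t.library_size for t in tables))


def read_ctss_4col(path: str | Path, library_size: int = 0) -> CtssTable:
    """Read 4-column CTSS text: chrom, 1-based position, strand, count."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=CTSS_COLUMNS,
        dtype={"chrom": str, "strand": str},
        comment="#",
    )
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return CtssTable(df=df, library_size=library_size)


def _expand_bedgraph(path: str | Path, strand: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "count"],
        dtype={"chrom": str},
        comment="#",
    )
    df = df[~df["chrom"].str.startswith("track")].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty or inverted bedGraph interval")
    widths = (df["end"] - df["start"]).to_numpy()
    # expand multi-base intervals to one record per base, 0-based -> 1-based
    idx = np.repeat(np.arange(len(df)), widths)
    offsets = np.arange(widths.sum()) - np.repeat(np.cumsum(widths) - widths, widths)
    pos = df["start"].to_numpy()[idx] + offsets + 1
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy()[idx],
            "pos": pos,
            "strand": strand,
            "count": df["count"].to_numpy()[idx],
        }
    )
    return out


def read_ctss_bedgraph(
    plus_path: str | Path, minus_path: str | Path, library_size: int = 0
) -> CtssTable:
    """Read a bedGraph pair (one file per strand) into a CTSS table.

    bedGraph 0-based starts are converted to 1-based positions and
    multi-base intervals expanded per base.
    """
    frames = [
        _expand_bedgraph(plus_path, "+"),
        _expand_bedgraph(minus_path, "-"),
    ]
    df = pd.concat(frames, ignore_index=True)
    df = df[df["count"] > 0].reset_index(drop=True)
    return CtssTable(df=df, library_size=library_size)


def read_ctss(
    paths,
    format: str = "ctss4",
    library_size: int = 0,
) -> CtssTable:
    """Dispatch reader: ``format='ctss4'`` (one path) or ``'bedgraph'``
    (pair of paths, plus/minus)."""
    if format == "ctss4":
        return read_ctss_4col(paths, library_size=library_size)
    if format == "bedgraph":
        plus_path, minus_path = paths
        return read_ctss_bedgraph(plus_path, minus_path, library_size=library_size)
    raise ValueError(f"unknown CTSS format: {format!r}")


def write_ctss_4col(table: CtssTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", header=False, index=False)


def write_ctss_bedgraph(
    table: CtssTable, plus_path: str | Path, minus_path: str | Path
) -> None:
    for strand, path in (("+", plus_path), ("-", minus_path)):
        sub = table.df[table.df["strand"] == strand]
        with open(path, "w") as out:
            for chrom, pos, count in zip(sub["chrom"], sub["pos"], sub["count"]):
                out.write(f"{chrom}\t{pos - 1}\t{pos}\t{count}\n")


# ---------------------------------------------------------------------------
# generic intervals (BED6)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class IntervalRecord:
    """1-based inclusive interval; written BED is 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start > end: {self}")


def write_bed6(records: Iterable[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in records:
            out.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
            )


def read_bed6(path: str | Path) -> list[IntervalRecord]:
    records = []
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {i}: fewer than 3 BED fields")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            records.append(
                IntervalRecord(
                    chrom=chrom, start=start0 + 1, end=end, strand=strand,
                    name=name, score=score,
                )
            )
    return records


# ---------------------------------------------------------------------------
# promoter catalog
# ---------------------------------------------------------------------------

#: Required columns of the consensus-promoter catalog TSV.  Per-stage columns
#: (``tpm_<stage>``, ``dominant_pos_<stage>``) are added per dataset.
CATALOG_COLUMNS = [
    "cluster_id",
    "chrom",
    "start",
    "end",
    "strand",
    "gene_id",
    "category",
    "is_primary",
    "signed_distance",
    "dominant_pos",
    "iqw",
    "architecture",
    "topscore",
    "tau",
]


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write the annotated consensus-cluster catalog as TSV.

    Raises ``ValueError`` listing any missing required columns.
    """
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog is missing required columns: {missing}")
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: catalog is missing required columns: {missing}")
    return df
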