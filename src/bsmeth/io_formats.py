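"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally all intervals are 0-based half-open. 1-based coordinates appear
only at format boundaries: the ``pos`` column of a cytosine (CX) report and
GFF3 start/end fields. GFF3 1-based closed intervals are converted on read
(``start-1, end``) and converted back on write.

The CX dialect is fixed: seven tab-separated columns, no header —
chrom, pos (1-based), strand (+/-), methylated count, unmethylated count,
context (CG/CHG/CHH/Unknown), trinucleotide (5'→3' on the cytosine's strand).
Zero-coverage rows are retained; their methylation level is undefined, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

CX_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_meth",
    "count_unmeth",
    "context",
    "trinucleotide",
]
VALID_CONTEXTS = ("CG", "CHG", "CHH", "Unknown")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: uppercase sequence} map.

    IUPAC ambiguity codes are preserved (uppercased, not stripped).
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected '>' FASTA header")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CX report


def read_cx_report(path) -> pd.DataFrame:
    """Read a 7-column cytosine report into a DataFrame sorted by (chrom, pos).

    Zero-coverage rows are retained. Raises :class:`FormatError` naming the
    first offending row for non-integer counts or unknown strand symbols.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CX_COLUMNS, [str, np.int64, str, np.int64, np.int64, str, str])})
    if df.shape[1] != len(CX_COLUMNS):
        raise FormatError(f"{path}: expected {len(CX_COLUMNS)} tab-separated columns")
    for col in ("pos", "count_meth", "count_unmeth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted.fillna(0)))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: row {row + 1}: non-integer value {df[col].iloc[row]!r} in column {col}"
            )
        df[col] = converted.astype(np.int64)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        row = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise FormatError(
            f"{path}: row {row + 1}: unknown strand symbol {df['strand'].iloc[row]!r}"
        )
    bad_ctx = ~df["context"].isin(VALID_CONTEXTS)
    if bad_ctx.any():
        row = int(np.flatnonzero(bad_ctx.to_numpy())[0])
        raise FormatError(
            f"{path}: row {row + 1}: unknown context {df['context'].iloc[row]!r}"
        )
    if (df["pos"] < 1).any() or (df[["count_meth", "count_unmeth"]] < 0).to_numpy().any():
        raise FormatError(f"{path}: positions must be >= 1 and counts >= 0")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_cx_report(sites: pd.DataFrame, path) -> None:
    sites[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Annotation


@dataclass
class Gene:
    """A gene with exon structure, internal 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValidationError(f"gene {self.gene_id}: empty span")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside gene span "
                    f"[{self.start}, {self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class AnnotationSet:
    """Genes plus repeat intervals; the promoter span is annotation-wide."""

    genes: list
    repeats: list  # (chrom, start, end), 0-based half-open
    promoter_span: int = 2000

    def promoter(self, gene: Gene) -> tuple[int, int]:
        """Strand-aware upstream promoter interval, clipped at the contig start."""
        if gene.strand == "+":
            return max(0, gene.start - self.promoter_span), gene.start
        return gene.end, gene.end + self.promoter_span

    def downstream(self, gene: Gene) -> tuple[int, int]:
        if gene.strand == "+":
            return gene.end, gene.end + self.promoter_span
        return max(0, gene.start - self.promoter_span), gene.start

    def genes_by_chrom(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


_REPEAT_TYPES = ("repeat_region", "dispersed_repeat", "transposable_element", "repeat")


def read_annotation(path, promoter_span: int = 2000, repeats_path=None) -> AnnotationSet:
    """Read gene/repeat annotation from GFF3 (or BED6/BED12 by suffix).

    GFF3 1-based closed coordinates become 0-based half-open. Genes without
    exon children become single-exon genes spanning the whole gene. An exon
    outside its gene span raises :class:`ValidationError` naming the gene.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        ann = _read_bed_genes(path, promoter_span)
    else:
        ann = _read_gff3(path, promoter_span)
    if repeats_path is not None:
        ann.repeats.extend(_read_bed_intervals(repeats_path))
    return ann


def _read_gff3(path, promoter_span) -> AnnotationSet:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g.id, featuretype="exon", order_by="start")
        ]
        genes.append(Gene(g.id, g.seqid, g.strand, g.start - 1, g.end, exons))
    repeats = []
    for ftype in _REPEAT_TYPES:
        for f in db.features_of_type(ftype):
            repeats.append((f.seqid, f.start - 1, f.end))
    return AnnotationSet(genes=genes, repeats=sorted(repeats), promoter_span=promoter_span)


def _read_bed_genes(path, promoter_span) -> AnnotationSet:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: need >= 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            exons = []
            if len(fields) >= 12:  # BED12 blocks
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(Gene(name, chrom, strand, start, end, exons))
    return AnnotationSet(genes=genes, repeats=[], promoter_span=promoter_span)


def _read_bed_intervals(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_annotation_gff3(ann: AnnotationSet, path) -> None:
    """Write genes (with exon children) and repeat_region features as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            fh.write(
                f"{g.chrom}\tbsmeth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tbsmeth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
        for chrom, s, e in ann.repeats:
            fh.write(f"{chrom}\tbsmeth\trepeat_region\t{s + 1}\t{e}\t.\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Track / result writers


def _bed_score(p: float) -> int:
    if not (p > 0):
        return 1000
    return min(1000, int(round(-10.0 * math.log10(p))))


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED6+ (0-based half-open): name = context:direction,
    score = min(1000, round(-10*log10 p)), then ml_a, ml_b, p, p_min, n_windows."""
    with open(path, "w") as fh:
        if dmrs is None or len(dmrs) == 0:
            return
        for row in dmrs.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        str(int(row.start)),
                        str(int(row.end)),
                        f"{row.context}:{row.direction}",
                        str(_bed_score(float(row.p))),
                        ".",
                        f"{row.ml_a:.4f}",
                        f"{row.ml_b:.4f}",
                        f"{row.p:.3e}",
                        f"{row.p_min:.3e}",
                        str(int(row.n_windows)),
                    ]
                )
                + "\n"
            )


def write_bedgraph(windows: pd.DataFrame, path, value: str = "weighted_ml") -> None:
    """Write one bedGraph track from a window table; undefined windows are skipped."""
    with open(path, "w") as fh:
        for row in windows.itertuples(index=False):
            v = getattr(row, value)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{v:.6f}\n")
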