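"""Readers and writers for the toolkit's file formats.

Two per-cytosine report dialects are supported as input:

* **CGmap** (BS-Seeker2): 8 tab-separated columns — chromosome, Watson
  nucleotide (``C`` for a Watson-strand cytosine, ``G`` for a Crick-strand
  cytosine), 1-based position, context (CG/CHG/CHH), dinucleotide context,
  methylation level, methylated-read count, total-read count.  Only covered
  sites appear in a CGmap.
* **CX_report** (Bismark genome-wide cytosine report): 7 columns —
  chromosome, position, strand, methylated count, unmethylated count,
  context, trinucleotide.  Every cytosine in the genome appears, covered
  or not.

Gene models come from GTF ``gene`` features; promoters are derived from the
strand-aware TSS.  Gene-level results are exchanged in the **mtable**
format: a tab-separated table with one row per gene and six measurement
columns, missing values written as the literal ``NaN``.

All readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd

from .core import (
    CONTEXTS,
    DEFAULT_PROMOTER_DOWNSTREAM,
    DEFAULT_PROMOTER_UPSTREAM,
    MEASUREMENTS,
    MethylationProfile,
    derive_promoter,
)

MTABLE_HEADER = ("gene_id",) + MEASUREMENTS


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class FormatError(ValueError):
    """A file's overall layout does not match the expected format."""


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine's methylation evidence.

    ``strand`` is '+' for a Watson-strand C and '-' for a Crick-strand C
    (a G on the Watson strand).  ``n_methylated`` counts reads calling C
    (non-converted); ``n_total`` counts all reads covering the site.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_methylated: int
    n_total: int


@dataclass(frozen=True)
class GeneModel:
    """A gene's body interval and its derived promoter (1-based, inclusive)."""

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    body_start: int
    body_end: int
    promoter_start: int
    promoter_end: int

    @property
    def tss(self) -> int:
        return self.body_start if self.strand == "+" else self.body_end


def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def _int_field(value: str, what: str, path: str | Path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-integer {what} {value!r}") from None


def parse_cgmap(path: str | Path) -> Iterator[CytosineSite]:
    """Stream cytosine sites from a BS-Seeker2 CGmap file.

    The nucleotide column sets the strand (C → '+', G → '-'); counts are
    taken from the last two columns and the precomputed level column is
    ignored.  Zero-coverage lines, should they occur, are dropped.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected 8 tab-separated columns, got {len(fields)}"
                )
            chrom, nuc, pos_s, context, _dinuc, _level, meth_s, total_s = fields
            if nuc == "C":
                strand = "+"
            elif nuc == "G":
                strand = "-"
            else:
                raise ParseError(f"{path}: line {lineno}: nucleotide column must be C or G, got {nuc!r}")
            if context not in CONTEXTS:
                raise ParseError(f"{path}: line {lineno}: unknown context {context!r}")
            pos = _int_field(pos_s, "position", path, lineno)
            meth = _int_field(meth_s, "methylated count", path, lineno)
            total = _int_field(total_s, "total count", path, lineno)
            if not 0 <= meth <= total:
                raise ParseError(
                    f"{path}: line {lineno}: methylated count {meth} outside [0, {total}]"
                )
            if total == 0:
                continue
            yield CytosineSite(chrom, pos, strand, context, meth, total)


def parse_cx_report(path: str | Path) -> Iterator[CytosineSite]:
    """Stream cytosine sites from a Bismark genome-wide cytosine report.

    Coverage is the sum of the methylated and unmethylated columns;
    uncovered sites (total 0) are retained — the coverage filter downstream
    removes them — so the full genome-wide report round-trips.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}: line {lineno}: expected 7 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context, _tri = fields
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            if context not in CONTEXTS:
                raise ParseError(f"{path}: line {lineno}: unknown context {context!r}")
            pos = _int_field(pos_s, "position", path, lineno)
            meth = _int_field(meth_s, "methylated count", path, lineno)
            unmeth = _int_field(unmeth_s, "unmethylated count", path, lineno)
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            yield CytosineSite(chrom, pos, strand, context, meth, meth + unmeth)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(
    path: str | Path,
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
) -> list[GeneModel]:
    """Load ``gene`` features from a GTF and derive their promoters.

    The gene body is the full feature span; the promoter runs from
    ``promoter_upstream`` bp upstream to ``promoter_downstream`` bp
    downstream of the TSS (feature start on '+', feature end on '-').
    Genes without a ``gene_biotype``/``biotype`` attribute get biotype
    ``"unknown"``.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}: line {lineno}: gene feature lacks gene_id")
            if gene_id in seen:
                raise FormatError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            start = _int_field(start_s, "start", path, lineno)
            end = _int_field(end_s, "end", path, lineno)
            tss = start if strand == "+" else end
            pstart, pend = derive_promoter(tss, strand, promoter_upstream, promoter_downstream)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    biotype=attr.get("gene_biotype", attr.get("biotype", "unknown")),
                    chrom=chrom,
                    strand=strand,
                    body_start=start,
                    body_end=end,
                    promoter_start=pstart,
                    promoter_end=pend,
                )
            )
    if not genes:
        raise FormatError(f"{path}: no gene features")
    return genes


def _format_cell(value: float) -> str:
    return "NaN" if math.isnan(value) else f"{value:.4f}"


def write_mtable(
    profiles: Iterable[MethylationProfile] | pd.DataFrame, path: str | Path
) -> None:
    """Write gene-level profiles as a tab-separated mtable.

    Values are serialized with 4 decimal places; missing cells as the
    literal ``NaN``.  Output is deterministic: the same input always
    produces a byte-identical file.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(MTABLE_HEADER) + "\n")
        if isinstance(profiles, pd.DataFrame):
            frame = profiles[list(MEASUREMENTS)]
            for gene_id, row in frame.iterrows():
                cells = [_format_cell(float(v)) for v in row.to_numpy()]
                fh.write(gene_id + "\t" + "\t".join(cells) + "\n")
        else:
            for prof in profiles:
                cells = [_format_cell(v) for v in prof.as_row()]
                fh.write(prof.gene_id + "\t" + "\t".join(cells) + "\n")


def read_mtable(path: str | Path, header: bool = True) -> pd.DataFrame:
    """Read an mtable into a DataFrame indexed by gene id.

    With ``header=True`` (default) the first line must match the canonical
    header; ``header=False`` accepts a headerless file with the canonical
    column order.
    """
    rows: dict[str, list[float]] = {}
    with _open_text(path) as fh:
        lines = iter(enumerate(fh, 1))
        if header:
            try:
                _, first = next(lines)
            except StopIteration:
                raise FormatError(f"{path}: empty file") from None
            if tuple(first.rstrip("\n").split("\t")) != MTABLE_HEADER:
                raise FormatError(
                    f"{path}: header mismatch; expected {' '.join(MTABLE_HEADER)!r}"
                )
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(MTABLE_HEADER):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(MTABLE_HEADER)} columns, got {len(fields)}"
                )
            gene_id, *cells = fields
            values = []
            for name, cell in zip(MEASUREMENTS, cells):
                if cell == "NaN":
                    values.append(math.nan)
                    continue
                try:
                    values.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: gene {gene_id!r}: non-numeric value {cell!r} in column {name}"
                    ) from None
            rows[gene_id] = values
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MEASUREMENTS)).rename_axis(
        "gene_id"
    )


def profiles_to_frame(profiles: Iterable[MethylationProfile]) -> pd.DataFrame:
    """Convert profiles to the DataFrame shape :func:`read_mtable` returns."""
    return pd.DataFrame.from_dict(
        {p.gene_id: p.as_row() for p in profiles}, orient="index", columns=list(MEASUREMENTS)
    ).rename_axis("gene_id")
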