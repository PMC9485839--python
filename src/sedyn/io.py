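"""Readers and writers for every external format the pipeline touches.

Formats: BED3+/BED6, ENCODE narrowPeak, bedGraph, JASPAR PFM text, FASTA,
tab-separated expression / annotation matrices, and GMT-style gene sets.
All parsers are strict about coordinates (0-based half-open) and raise
``FormatError`` with a line number on malformed input.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import CoverageTrack, GenomicInterval

__all__ = [
    "FormatError",
    "GeneAnnotation",
    "ExpressionMatrix",
    "MotifPFM",
    "parse_interval_file",
    "write_interval_file",
    "parse_coverage_file",
    "write_coverage_file",
    "parse_motif_file",
    "write_motif_file",
    "parse_expression_file",
    "write_expression_file",
    "parse_annotation_file",
    "write_annotation_file",
    "parse_gene_sets",
    "write_gene_sets",
    "read_fasta",
    "write_fasta",
]

_SKIP_PREFIXES = ("track", "browser", "#")


class FormatError(ValueError):
    """Malformed input file (message names the offending line where known)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if not (self.start <= self.tss < self.end):
            raise ValueError(
                f"TSS {self.tss} outside gene span [{self.start}, {self.end}) "
                f"for {self.gene_id}"
            )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id)


class GeneAnnotation:
    """Gene id -> (chrom, TSS, strand, span); gene ids unique."""

    def __init__(self, genes: Iterable[Gene]) -> None:
        self._genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise FormatError(f"duplicate gene id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    @property
    def genes(self) -> list[Gene]:
        return list(self._genes.values())

    def gene_ids(self) -> list[str]:
        return list(self._genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples count (or normalized) matrix with sample metadata.

    ``values`` is indexed by gene id with one column per sample id;
    ``samples`` is indexed by sample id with columns
    ``cell_line``, ``condition``, ``replicate``; ``library_sizes`` is a
    per-sample Series (defaults to column sums).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.values) < 0).any():
            raise ValueError("expression matrix contains negative entries")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing columns: {sorted(missing)}")
        if self.library_sizes is None:
            self.library_sizes = self.values.sum(axis=0).astype(float)
        self.library_sizes = self.library_sizes.loc[list(self.values.columns)]
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class MotifPFM:
    """Position frequency matrix: 4 x L non-negative base counts (rows A,C,G,T)."""

    motif_id: str
    counts: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"PFM must be 4 x L with L >= 1, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("PFM column sums must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))


# ---------------------------------------------------------------------------
# interval files (BED3+, narrowPeak)
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_coord(field_value: str, what: str, lineno: int) -> int:
    try:
        return int(field_value)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what} {field_value!r}") from None


def parse_interval_file(
    path: str | Path, dialect: str = "BED3+"
) -> list[GenomicInterval]:
    """Parse a BED3+ or narrowPeak file into intervals, in file order.

    ``dialect="narrowPeak"`` maps column 7 (signalValue) to ``signal``;
    the BED score column is never interpreted.  Extra columns are ignored.
    """
    if dialect not in ("BED3+", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = 10 if dialect == "narrowPeak" else 3
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < min_cols:
            raise FormatError(
                f"line {lineno}: expected >= {min_cols} columns, got {len(fields)}"
            )
        chrom = fields[0]
        start = _parse_coord(fields[1], "start", lineno)
        end = _parse_coord(fields[2], "end", lineno)
        if end <= start:
            raise FormatError(f"line {lineno}: end {end} <= start {start}")
        name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
        signal = None
        if dialect == "narrowPeak":
            try:
                signal = float(fields[6])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric signalValue {fields[6]!r}"
                ) from None
        try:
            out.append(GenomicInterval(chrom, start, end, signal=signal, name=name))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return out


def write_interval_file(
    path: str | Path, intervals: Sequence[GenomicInterval], dialect: str = "BED3+"
) -> None:
    """Write BED (chrom start end name score strand) or 10-column narrowPeak."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            if dialect == "narrowPeak":
                signal = iv.signal if iv.signal is not None else 0.0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t"
                    f"{signal:.6g}\t-1\t-1\t-1\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


def parse_coverage_file(path: str | Path) -> CoverageTrack:
    """Parse a 4-column bedGraph (possibly unsorted) into a CoverageTrack.

    Overlapping runs or negative depths are format errors; abutting runs of
    equal depth are merged.
    """
    runs: list[tuple[str, int, int, float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: bedGraph needs 4 columns")
        chrom = fields[0]
        start = _parse_coord(fields[1], "start", lineno)
        end = _parse_coord(fields[2], "end", lineno)
        try:
            depth = float(fields[3])
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric depth {fields[3]!r}") from None
        if depth < 0:
            raise FormatError(f"line {lineno}: negative depth {depth}")
        if end <= start:
            raise FormatError(f"line {lineno}: end {end} <= start {start}")
        runs.append((chrom, start, end, depth))
    try:
        return CoverageTrack.from_runs(runs)
    except ValueError as exc:
        raise FormatError(str(exc)) from None


def write_coverage_file(path: str | Path, track: CoverageTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in track.iter_all_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{depth:.6g}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------


def parse_motif_file(path: str | Path, format: str = "JASPAR") -> list[MotifPFM]:
    """Parse JASPAR 2016+ text: ``>ID name`` header then four bracketed rows
    in A, C, G, T order.  Counts are preserved exactly.
    """
    if format != "JASPAR":
        raise ValueError(f"unsupported motif format {format!r}")
    motifs: list[MotifPFM] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def _flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(
                f"line {lineno}: motif {header[0]!r} has {len(rows)} count rows, need 4"
            )
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"motif {header[0]!r}: row length mismatch {sorted(lengths)}")
        motifs.append(MotifPFM(header[0], np.array(rows, dtype=float), name=header[1]))
        header, rows = None, []

    last_lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            last_lineno = lineno
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"line {lineno}: empty motif header")
                header = (parts[0], parts[1] if len(parts) > 1 else "")
                rows = []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: counts before any header")
                body = line
                if body[:1].upper() in "ACGT" and ("[" in body or body[1:2].isspace()):
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                try:
                    rows.append([float(tok) for tok in body.split()])
                except ValueError:
                    raise FormatError(f"line {lineno}: non-numeric count row") from None
    _flush(last_lineno + 1)
    return motifs


def write_motif_file(path: str | Path, motifs: Sequence[MotifPFM]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}".rstrip() + "\n")
            for base, row in zip("ACGT", m.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# TSV matrices: expression and gene annotation
# ---------------------------------------------------------------------------


def parse_expression_file(
    path: str | Path, samples: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene id).

    Sample metadata may be embedded as ``#cell_line`` / ``#condition`` /
    ``#replicate`` comment lines (tab-separated, aligned with the header) or
    supplied via ``samples``.
    """
    meta_rows: dict[str, list[str]] = {}
    with open(path) as fh:
        text_lines = []
        for raw in fh:
            if raw.startswith("#"):
                fields = raw.rstrip("\n").split("\t")
                key = fields[0].lstrip("#")
                if key in ("cell_line", "condition", "replicate"):
                    meta_rows[key] = fields[1:]
                continue
            text_lines.append(raw)
    try:
        df = pd.read_csv(_io.StringIO("".join(text_lines)), sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"cannot parse expression matrix: {exc}") from None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise FormatError(f"non-numeric cells in columns {bad}")
    if samples is None:
        if meta_rows:
            samples = pd.DataFrame(meta_rows, index=list(df.columns))
        else:
            samples = pd.DataFrame(index=list(df.columns))
    try:
        return ExpressionMatrix(values=df, samples=samples)
    except ValueError as exc:
        raise FormatError(str(exc)) from None


def write_expression_file(path: str | Path, matrix: ExpressionMatrix) -> None:
    with open(path, "w") as fh:
        for key in ("cell_line", "condition", "replicate"):
            if key in matrix.samples.columns:
                vals = "\t".join(str(v) for v in matrix.samples.loc[matrix.sample_ids, key])
                fh.write(f"#{key}\t{vals}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


_ANNOTATION_COLUMNS = ["gene_id", "chrom", "tss", "strand", "start", "end"]


def parse_annotation_file(path: str | Path) -> GeneAnnotation:
    """Read the minimal gene-annotation TSV: gene_id chrom tss strand start end."""
    genes: list[Gene] = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields[: len(_ANNOTATION_COLUMNS)] != _ANNOTATION_COLUMNS:
                raise FormatError(
                    f"line {lineno}: annotation header must start with "
                    f"{_ANNOTATION_COLUMNS}"
                )
            header_seen = True
            continue
        if len(fields) < 6:
            raise FormatError(f"line {lineno}: expected 6 columns")
        try:
            genes.append(
                Gene(
                    gene_id=fields[0],
                    chrom=fields[1],
                    tss=_parse_coord(fields[2], "tss", lineno),
                    strand=fields[3],
                    start=_parse_coord(fields[4], "start", lineno),
                    end=_parse_coord(fields[5], "end", lineno),
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return GeneAnnotation(genes)


def write_annotation_file(path: str | Path, annotation: GeneAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for g in annotation.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.start}\t{g.end}\n")


# ---------------------------------------------------------------------------
# GMT-style gene sets
# ---------------------------------------------------------------------------


def parse_gene_sets(path: str | Path) -> dict[str, "GeneSetRecord"]:
    """GMT-like TSV: set_id <TAB> label <TAB> member1 <TAB> member2 ..."""
    sets: dict[str, GeneSetRecord] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: gene set needs id, label, >= 1 member")
        set_id, label, members = fields[0], fields[1], fields[2:]
        if set_id in sets:
            raise FormatError(f"line {lineno}: duplicate set id {set_id!r}")
        sets[set_id] = GeneSetRecord(set_id, label, tuple(dict.fromkeys(members)))
    return sets


@dataclass(frozen=True)
class GeneSetRecord:
    set_id: str
    label: str
    members: tuple[str, ...]


def write_gene_sets(path: str | Path, sets: Mapping[str, GeneSetRecord]) -> None:
    with open(path, "w") as fh:
        for rec in sets.values():
            fh.write("\t".join([rec.set_id, rec.label, *rec.members]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
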