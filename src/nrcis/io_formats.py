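"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention). Any
1-based source must be converted at the reader boundary so that a single
convention holds everywhere downstream.

Supported formats:

* peak sets — BED3 (``chrom  start  end``) or BED5 with the summit tag
  count in column 5 (``chrom  start  end  name  height``);
* gene models — refFlat-style 8-column TSV
  (``gene_id  symbol  chrom  strand  txStart  txEnd  exonStarts  exonEnds``);
* peak-region sequences — FASTA (via Bio.SeqIO, uppercased, ACGTN only);
* gene sets — GMT (``name  description  gene1  gene2 ...``);
* expression — 2-column TSV (``gene_id  intensity``).

Files are UTF-8, tab-separated, ``\\n`` line endings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "PeakRecord",
    "GeneRecord",
    "FormatError",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
]

_SEQ_ALPHABET = frozenset("ACGTN")
PEAK_DIALECTS = ("bed3", "bed5_height")


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class PeakRecord:
    """A called ChIP-seq peak: half-open genomic span plus summit tag count.

    ``height`` is the number of sequence tags at the peak summit, the
    per-peak enrichment signal. Peaks read from BED3 carry height 0 (never
    missing) so that downstream medians stay total.
    """

    chrom: str
    start: int
    end: int
    height: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.height < 0:
            raise ValueError(f"height must be >= 0, got {self.height}")

    @property
    def center(self) -> int:
        """Integer midpoint, floor((start+end)/2) — the peak position used
        for every distance computation."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene model with exon structure.

    The strand-aware TSS anchor is ``tx_start`` for '+' genes and
    ``tx_end`` for '-' genes; the transcript 3' end is the opposite edge.
    Exon lists are parallel, ascending in genomic coordinates, and
    contained in ``[tx_start, tx_end)``.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...] = field(default=())
    exon_ends: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"tx_start must be < tx_end, got [{self.tx_start}, {self.tx_end})"
            )
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError("exon_starts and exon_ends must have equal length")
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not s < e:
                raise ValueError(f"exon [{s}, {e}) is empty or inverted")
            if s < prev_end:
                raise ValueError("exons must be ascending and non-overlapping")
            prev_end = e
        if self.exon_starts and (
            self.exon_starts[0] < self.tx_start or self.exon_ends[-1] > self.tx_end
        ):
            raise ValueError("exons must lie within [tx_start, tx_end)")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site coordinate."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def three_prime_end(self) -> int:
        """Strand-aware transcript 3' end (downstream anchor)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)


def _open_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.splitlines()


def read_peaks(path: str | Path, dialect: str = "bed5_height") -> list[PeakRecord]:
    """Read a peak set from a BED-like file, preserving input order.

    ``dialect`` is ``"bed3"`` (three columns, height set to 0) or
    ``"bed5_height"`` (five columns with the summit tag count in column 5).
    Blank lines and ``track``/``#`` lines are skipped. Any malformed line
    raises :class:`FormatError` naming its 1-based line number.
    """
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {PEAK_DIALECTS}")
    records: list[PeakRecord] = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if dialect == "bed3":
                if len(fields) < 3:
                    raise ValueError(f"expected >=3 columns, got {len(fields)}")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                rec = PeakRecord(chrom, start, end, height=0.0)
            else:
                if len(fields) < 5:
                    raise ValueError(f"expected >=5 columns, got {len(fields)}")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                rec = PeakRecord(
                    chrom, start, end, height=float(fields[4]), name=fields[3]
                )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_peaks(path: str | Path, peaks: Iterable[PeakRecord]) -> None:
    """Write peaks as BED5 with the height in column 5 (score slot)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, p in enumerate(peaks):
            name = p.name if p.name is not None else f"peak_{i + 1}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{_fmt_num(p.height)}\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_gene_models(path: str | Path) -> list[GeneRecord]:
    """Read refFlat-style 8-column gene models, preserving input order.

    Columns: gene_id, symbol, chrom, strand, txStart, txEnd,
    exonStarts (comma list), exonEnds (comma list). Exon lists may carry a
    trailing comma (refFlat habit).
    """
    records: list[GeneRecord] = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if len(fields) < 8:
                raise ValueError(f"expected 8 columns, got {len(fields)}")
            starts = tuple(int(x) for x in fields[6].rstrip(",").split(",") if x)
            ends = tuple(int(x) for x in fields[7].rstrip(",").split(",") if x)
            rec = GeneRecord(
                gene_id=fields[0],
                symbol=fields[1],
                chrom=fields[2],
                strand=fields[3],
                tx_start=int(fields[4]),
                tx_end=int(fields[5]),
                exon_starts=starts,
                exon_ends=ends,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_gene_models(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            starts = ",".join(str(x) for x in g.exon_starts)
            ends = ",".join(str(x) for x in g.exon_ends)
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t{starts}\t{ends}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered mapping name -> uppercase sequence.

    Sequences are restricted to A, C, G, T, N; duplicate names and empty
    records are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        out[rec.id] = seq
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path: str | Path) -> list[tuple[str, str, set[str]]]:
    """Read a GMT gene-set collection: (set_name, description, gene ids).

    Duplicate gene ids within a set are deduplicated; a set with no genes
    is an error.
    """
    out: list[tuple[str, str, set[str]]] = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: expected >=3 tab-separated columns"
            )
        genes = {g for g in fields[2:] if g}
        if not genes:
            raise FormatError(f"{path}: line {lineno}: gene set {fields[0]!r} is empty")
        out.append((fields[0], fields[1], genes))
    return out


def write_gmt(path: str | Path, sets: Sequence[tuple[str, str, Iterable[str]]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *sorted(set(genes))]) + "\n")


def read_expression(path: str | Path) -> dict[str, float]:
    """Read a 2-column gene expression table: gene_id -> intensity.

    Intensities are normalised array intensities and must be non-negative;
    duplicate gene ids are errors.
    """
    out: dict[str, float] = {}
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        gene = fields[0]
        try:
            value = float(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        if gene in out:
            raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
        if value < 0:
            raise FormatError(f"{path}: line {lineno}: negative intensity {value}")
        out[gene] = value
    return out


def write_expression(path: str | Path, table: dict[str, float]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, value in table.items():
            fh.write(f"{gene}\t{_fmt_num(value)}\n")
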