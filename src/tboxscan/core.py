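"""Shared domain types and readers/writers for the genomic and tabular formats
the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open (BED convention). Ensembl-style
gene tables are 1-based inclusive and are converted on read. Strand is encoded
as +1 / -1 (gene-table convention); ``0`` means unstranded, and ``.`` on input
is mapped to unstranded. Peak scores are stored as -log10 of the peak p-value
throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: strand codes
FORWARD, REVERSE, UNSTRANDED = 1, -1, 0


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a scaffold."""

    scaffold: str
    start: int
    end: int
    strand: int = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in (FORWARD, REVERSE, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with body coordinates and optional exon/UTR structure.

    The TSS is ``body.start`` on the + strand and ``body.end - 1`` on the -
    strand (the last base of the half-open interval).
    """

    gene_id: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.body.strand == UNSTRANDED:
            raise ValueError(f"gene {self.gene_id}: body must be stranded")
        for exon in self.exons:
            if exon.scaffold != self.body.scaffold:
                raise ValueError(f"gene {self.gene_id}: exon on wrong scaffold")
            if exon.start < self.body.start or exon.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon outside body")
        srt = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(srt, srt[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == FORWARD else self.body.end - 1

    @property
    def tes(self) -> int:
        return self.body.end - 1 if self.body.strand == FORWARD else self.body.start


@dataclass(frozen=True)
class Peak:
    """One binding event: an interval with a summit and a -log10 p score."""

    interval: GenomicInterval
    summit: int
    score: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError(f"negative score {self.score}")

    @property
    def scaffold(self) -> str:
        return self.interval.scaffold


@dataclass
class ExpressionRecord:
    """Per-gene differential expression summary.

    ``fold_change`` follows the signed convention: magnitude >= 1, with a
    negative sign marking downregulation (a -2.0 means halved expression).
    """

    gene_id: str
    fold_change: float
    replicate_values: dict[str, list[float]] = field(default_factory=dict)
    p_value: float = 1.0
    fdr: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")
        if abs(self.fold_change) < 1.0:
            raise ValueError(
                f"signed fold change magnitude must be >= 1, got {self.fold_change}"
            )


_STRAND_CODES = {"1": FORWARD, "+1": FORWARD, "+": FORWARD,
                 "-1": REVERSE, "−1": REVERSE, "-": REVERSE}


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a tab-separated Ensembl-style gene table.

    Expected columns: gene id, scaffold, start, end, strand (1/-1),
    description. Coordinates are 1-based inclusive and converted to 0-based
    half-open. Rows with start >= end are rejected.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
            gene_id, scaffold, start_s, end_s, strand_s = fields[:5]
            symbol = fields[5] if len(fields) > 5 else ""
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if strand_s not in _STRAND_CODES:
                raise ParseError(f"{path}:{lineno}: malformed strand {strand_s!r}")
            if start1 >= end1:
                raise ParseError(f"{path}:{lineno}: start >= end")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            body = GenomicInterval(scaffold, start1 - 1, end1,
                                   _STRAND_CODES[strand_s])
            genes.append(GeneModel(gene_id=gene_id, body=body, symbol=symbol))
    if not genes:
        logger.warning("gene table %s is empty", path)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes in the 1-based inclusive tab-separated convention."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.body.scaffold}\t{g.body.start + 1}"
                f"\t{g.body.end}\t{g.body.strand}\t{g.symbol}\n"
            )


def write_exon_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write the exon/UTR structure as a 1-based inclusive table:
    gene_id, feature (exon/utr5/utr3), start, end."""
    with open(path, "w") as fh:
        for g in genes:
            for feature, intervals in (("exon", g.exons), ("utr5", g.utr5),
                                       ("utr3", g.utr3)):
                for iv in intervals:
                    fh.write(f"{g.gene_id}\t{feature}\t{iv.start + 1}"
                             f"\t{iv.end}\n")


def read_exon_table(path: str | Path,
                    genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Attach exon/UTR structure from a 1-based inclusive feature table to
    existing gene models (matched by gene_id; unknown ids are an error)."""
    by_id = {g.gene_id: g for g in genes}
    features: dict[str, dict[str, list[GenomicInterval]]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            gene_id, feature, start_s, end_s = fields
            if gene_id not in by_id:
                raise ParseError(f"{path}:{lineno}: unknown gene "
                                 f"{gene_id!r}")
            if feature not in ("exon", "utr5", "utr3"):
                raise ParseError(f"{path}:{lineno}: unknown feature "
                                 f"{feature!r}")
            scaffold = by_id[gene_id].body.scaffold
            iv = GenomicInterval(scaffold, int(start_s) - 1, int(end_s))
            features.setdefault(gene_id, {"exon": [], "utr5": [],
                                          "utr3": []})[feature].append(iv)
    out = []
    for g in genes:
        f = features.get(g.gene_id)
        if f is None:
            out.append(g)
        else:
            out.append(GeneModel(
                gene_id=g.gene_id, body=g.body,
                exons=tuple(sorted(f["exon"], key=lambda e: e.start)),
                utr5=tuple(f["utr5"]), utr3=tuple(f["utr3"]),
                symbol=g.symbol))
    return out


def read_peaks(path: str | Path, label: str = "") -> list[Peak]:
    """Read a BED / narrowPeak-style peak table.

    Columns: scaffold, start, end, name, score, [strand], [... , summit
    offset as last column when >= 7 columns]. BED is 0-based half-open; the
    score column is interpreted as -log10 p. When a summit-offset column is
    present (narrowPeak column 10, or our 7th column), summit = start +
    offset; otherwise the floor midpoint is used. Records whose summit falls
    outside the interval are rejected with a warning.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            scaffold = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            score = float(fields[4]) if len(fields) > 4 else 0.0
            if len(fields) >= 7:
                offset = int(fields[-1])
                summit = start + offset if offset >= 0 else (start + end) // 2
            else:
                summit = (start + end) // 2
            interval = GenomicInterval(scaffold, start, end, UNSTRANDED)
            if not interval.contains(summit):
                warnings.warn(
                    f"{path}:{lineno}: summit {summit} outside interval; "
                    f"record rejected"
                )
                continue
            peaks.append(Peak(interval=interval, summit=summit, score=score,
                              label=label or name))
    return peaks


def write_bed(
    peaks: Sequence[Peak],
    path: str | Path,
    extend_bp: int = 0,
    with_summit: bool = True,
) -> None:
    """Write peaks as BED with name, score, strand and summit-offset columns.

    ``extend_bp`` widens both interval edges (clamped at 0 on the left), the
    convention used to make short motif features legible on a genome browser.
    The summit offset is kept relative to the written (possibly extended)
    start so that a round trip through :func:`read_peaks` preserves the
    summit position exactly.
    """
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            start = max(0, pk.interval.start - extend_bp)
            end = pk.interval.end + extend_bp
            name = pk.label or f"peak_{i}"
            cols = [pk.scaffold, str(start), str(end), name, repr(pk.score), "."]
            if with_summit:
                cols.append(str(pk.summit - start))
            fh.write("\t".join(cols) + "\n")


def scale_score_to_bed(raw: float, lo: float, hi: float) -> int:
    """Map a raw score in [lo, hi] onto the BED 0-1000 display range.

    Out-of-range values are clamped with a warning.
    """
    if raw < lo or raw > hi:
        warnings.warn(f"score {raw} outside [{lo}, {hi}]; clamped")
        raw = min(max(raw, lo), hi)
    return round(1000.0 * (raw - lo) / (hi - lo))


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    """Read an expression CSV with at least a gene_id column."""
    df = pd.read_csv(path)
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing gene_id column")
    return df


def read_binding_curve_csv(path: str | Path) -> tuple[list[float], list[float]]:
    """Read an SPR-style CSV of (concentration_molar, response) pairs."""
    df = pd.read_csv(path)
    for col in ("concentration_molar", "response"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df["concentration_molar"].tolist(), df["response"].tolist()
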