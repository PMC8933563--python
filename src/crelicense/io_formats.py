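"""Readers and writers for the plain-text genomic formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention) throughout the
package. Supported formats: BED3/BED6 peak files, 4-column bedGraph signal,
and tab-separated gene tables / count matrices. Lines starting with ``#``
are treated as comments everywhere. Invalid records always raise
:class:`FormatError` naming the offending line — nothing is silently
clamped or skipped.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised for malformed input files; message names the file and line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named/scored/stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class PeakSet:
    """A collection of peaks from one assay in one cell state."""

    assay: str
    state: str
    intervals: tuple[GenomicInterval, ...]

    def __init__(self, assay: str, state: str, intervals: Iterable[GenomicInterval]):
        if not assay or not state:
            raise ValueError("assay and state labels must be non-empty")
        object.__setattr__(self, "assay", assay)
        object.__setattr__(self, "state", state)
        object.__setattr__(self, "intervals", tuple(intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-derived transcription start site.

    The TSS is the 5' end of the gene body: ``body.start`` on the plus
    strand, ``body.end`` on the minus strand.
    """

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.body.strand!r}")

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end

    @property
    def chrom(self) -> str:
        return self.body.chrom


class SignalTrack:
    """Per-chromosome coverage: sorted, non-overlapping (start, end, value) segments.

    Gaps between segments are implicit zero coverage. Values must be
    non-negative. Built either from an iterable of
    ``(chrom, start, end, value)`` tuples or read from bedGraph.
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, float]] = ()):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}-{end}")
            if end <= start or start < 0:
                raise ValueError(f"invalid segment {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._segments: dict[str, list[tuple[int, int, float]]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s0, e0, _), (s1, e1, _) in zip(segs, segs[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping segments on {chrom}: ({s0},{e0}) and ({s1},{e1})"
                    )
            self._segments[chrom] = segs
            self._starts[chrom] = [s for s, _, _ in segs]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._segments)

    def segments(self, chrom: str) -> list[tuple[int, int, float]]:
        return list(self._segments.get(chrom, []))

    def iter_segments(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            for start, end, value in self._segments[chrom]:
                yield chrom, start, end, value

    def weighted_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x overlapped-bp over [start, end) on chrom."""
        segs = self._segments.get(chrom)
        if not segs:
            return 0.0
        # first segment that could overlap: the one before the insertion point
        i = max(0, bisect_right(self._starts[chrom], start) - 1)
        total = 0.0
        for s, e, v in segs[i:]:
            if s >= end:
                break
            ov = min(e, end) - max(s, start)
            if ov > 0:
                total += v * ov
        return total

    def covered_bp(self, chrom: str, start: int, end: int) -> int:
        """Number of bases in [start, end) covered by any segment."""
        segs = self._segments.get(chrom)
        if not segs:
            return 0
        i = max(0, bisect_right(self._starts[chrom], start) - 1)
        total = 0
        for s, e, _ in segs[i:]:
            if s >= end:
                break
            total += max(0, min(e, end) - max(s, start))
        return total

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return self._segments == other._segments

    def __len__(self) -> int:
        return sum(len(v) for v in self._segments.values())


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#") or line.startswith("track "):
                continue
            yield lineno, line


def read_bed(
    path: str | Path,
    assay: str = "other",
    state: str = "unknown",
    min_score: float | None = None,
) -> PeakSet:
    """Read a BED3/BED6 file into a PeakSet with caller-supplied labels.

    ``min_score`` optionally drops peaks whose score column is present and
    below the threshold (unscored peaks are always kept).
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path} line {lineno}: expected >= 3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path} line {lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score: float | None = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: non-numeric score") from exc
        strand = fields[5] if len(fields) > 5 else "."
        try:
            iv = GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
        except ValueError as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from exc
        if min_score is not None and score is not None and score < min_score:
            continue
        intervals.append(iv)
    return PeakSet(assay=assay, state=state, intervals=intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6; missing name/score written as '.'."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in peaks:
            score = "." if iv.score is None else f"{iv.score:.10g}"
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene table (gene_id, chrom, start, end, strand) into GeneModels."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate gene_id(s) {sorted(set(dupes))}")
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {row.gene_id}: strand must be + or -, got {row.strand!r}")
        try:
            body = GenomicInterval(row.chrom, int(row.start), int(row.end), strand=row.strand)
        except ValueError as exc:
            raise FormatError(f"{path}: gene {row.gene_id}: {exc}") from exc
        genes.append(GeneModel(gene_id=row.gene_id, body=body))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.body.strand}\n")


_SAMPLE_RE = re.compile(r"^(?P<stage>.+)_(?P<replicate>[^_]+)$")


def parse_sample_label(label: str) -> tuple[str, str]:
    """Split a '<stage>_<replicate>' column label; the last underscore separates."""
    m = _SAMPLE_RE.match(label)
    if m is None:
        raise FormatError(f"sample column {label!r} does not match <stage>_<replicate>")
    return m.group("stage"), m.group("replicate")


def read_counts(path: str | Path):
    """Read a raw counts TSV (first column gene_id, then <stage>_<rep> columns)."""
    from .expression import CountsMatrix  # avoid import cycle at module load

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id, got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id rows")
    for col in df.columns:
        parse_sample_label(col)  # raises on bad pattern
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            raise FormatError(f"{path}: non-numeric count in column {col}")
        if (series < 0).any():
            raise FormatError(f"{path}: negative count in column {col}")
        if not (series == series.round()).all():
            raise FormatError(f"{path}: non-integer count in column {col}")
        df[col] = series.astype("int64")
    return CountsMatrix(values=df)


def write_counts(matrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (sorted, non-overlapping)."""
    segments: list[tuple[str, int, int, float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path} line {lineno}: expected 4 tab-separated fields")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path} line {lineno}: bad coordinates or value") from exc
        if value < 0:
            raise FormatError(f"{path} line {lineno}: negative value {value}")
        if end <= start or start < 0:
            raise FormatError(f"{path} line {lineno}: invalid interval {start}-{end}")
        segments.append((chrom, start, end, value))
    try:
        return SignalTrack(segments)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, value in track.iter_segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")
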