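"""Readers and writers for the plain-text genomics formats the pipeline touches.

All coordinates are BED-convention: 0-based, half-open ``[start, end)``.
Interactions are intra-chromosomal only and stored with the leftmost anchor
first, so "first peak" always means the upstream anchor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "InteractionRecord",
    "ReadTrack",
    "MotifHit",
    "BedParseError",
    "read_peaks",
    "read_interactions",
    "write_interactions",
    "read_reads",
    "read_fasta",
    "read_motif_hits",
    "write_contact_map",
    "read_contact_map",
]


class BedParseError(ValueError):
    """Raised for a malformed line in a BED-family file; names the line number."""


@dataclass(frozen=True, order=True)
class Peak:
    """A genomic interval (anchor peak), 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must exceed start ({self.start}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor((start+end)/2)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "Peak") -> bool:
        """At least 1 bp of overlap under the half-open convention."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class InteractionRecord:
    """An intra-chromosomal anchor pair with an integer PET-count strength.

    Anchors are kept in coordinate order (``anchor1.start <= anchor2.start``).
    """

    anchor1: Peak
    anchor2: Peak
    strength: float

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("interaction anchors must share a chromosome")
        if self.strength < 0:
            raise ValueError(f"negative interaction strength {self.strength}")
        if self.anchor1.start > self.anchor2.start:
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom


@dataclass
class ReadTrack:
    """Per-chromosome ChIP-Seq read intervals with per-chromosome totals.

    Reads are stored as (start, end) tuples; duplicates are retained (no
    deduplication is applied anywhere in the pipeline).
    """

    reads: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def total_reads_per_chrom(self) -> dict[str, int]:
        return {chrom: len(rs) for chrom, rs in self.reads.items()}

    def add(self, chrom: str, start: int, end: int) -> None:
        self.reads.setdefault(chrom, []).append((start, end))

    def midpoints(self, chrom: str) -> list[int]:
        return [(s + e) // 2 for s, e in self.reads.get(chrom, [])]


@dataclass(frozen=True)
class MotifHit:
    """A stranded CTCF motif occurrence with its scanner score."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _data_lines(handle: TextIO) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping comments/track/blank lines."""
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t")


def _parse_interval(fields: list[str], lineno: int, path: str) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or end <= start:
        raise BedParseError(
            f"{path}:{lineno}: invalid interval [{start}, {end}) on {chrom}"
        )
    return chrom, start, end


def read_peaks(path: str) -> list[Peak]:
    """Read a BED3+ file of peaks, in file order."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            chrom, start, end = _parse_interval(fields, lineno, path)
            peaks.append(Peak(chrom, start, end))
    return peaks


def read_interactions(path: str, strength_column: int = 7) -> list[InteractionRecord]:
    """Read a BEDPE-like interactions file.

    Columns 1-6 hold the two anchors; ``strength_column`` (1-based, default 7)
    holds the integer PET count. Inter-chromosomal rows are dropped with a
    logged count; anchors are reordered so anchor1 is leftmost.
    """
    records: list[InteractionRecord] = []
    n_inter = 0
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < strength_column:
                raise BedParseError(
                    f"{path}:{lineno}: missing strength column {strength_column}"
                )
            c1, s1, e1 = _parse_interval(fields[0:3], lineno, path)
            c2, s2, e2 = _parse_interval(fields[3:6], lineno, path)
            if c1 != c2:
                n_inter += 1
                continue
            try:
                strength = float(fields[strength_column - 1])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-numeric strength"
                ) from exc
            if strength < 0:
                raise BedParseError(f"{path}:{lineno}: negative strength {strength}")
            records.append(
                InteractionRecord(Peak(c1, s1, e1), Peak(c2, s2, e2), strength)
            )
    if n_inter:
        logger.info("dropped %d inter-chromosomal interaction(s) from %s", n_inter, path)
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str) -> None:
    """Write interactions as 7-column BEDPE (anchor1, anchor2, strength)."""
    with open(path, "w") as fh:
        for r in records:
            s = r.strength
            s_txt = str(int(s)) if float(s).is_integer() else repr(float(s))
            fh.write(
                f"{r.anchor1.chrom}\t{r.anchor1.start}\t{r.anchor1.end}\t"
                f"{r.anchor2.chrom}\t{r.anchor2.start}\t{r.anchor2.end}\t{s_txt}\n"
            )


def read_reads(path: str) -> ReadTrack:
    """Read a BED3+/tagAlign file of sequenced reads into a ReadTrack."""
    track = ReadTrack()
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            chrom, start, end = _parse_interval(fields, lineno, path)
            track.add(chrom, start, end)
    return track


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}.

    The key is the header token before the first whitespace. Duplicate names
    are an error.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        genome[record.id] = str(record.seq).upper()
    return genome


def read_motif_hits(path: str) -> list[MotifHit]:
    """Read a BED6 file of stranded motif hits (score col 5, strand col 6).

    Hits with strand '.' (unknown) are discarded with a warning; any other
    non +/- strand is an error.
    """
    hits: list[MotifHit] = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end = _parse_interval(fields, lineno, path)
            strand = fields[5]
            if strand == ".":
                warnings.warn(
                    f"{path}:{lineno}: motif hit with unknown strand discarded",
                    stacklevel=2,
                )
                continue
            if strand not in ("+", "-"):
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            hits.append(MotifHit(chrom, start, end, strand, score))
    return hits


def write_contact_map(cmap, path: str) -> None:
    """Serialize a ContactMap as sparse upper-triangle triplets.

    Header line records chromosome, bin size and bin count; rows are
    chrom, bin_i, bin_j, value (i <= j).
    """
    from scipy.sparse import triu

    coo = triu(cmap.matrix).tocoo()
    with open(path, "w") as fh:
        fh.write(f"#chrom={cmap.chrom}\tbin_size={cmap.bin_size_bp}\tn_bins={cmap.n_bins}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{cmap.chrom}\t{i}\t{j}\t{v:g}\n")


def read_contact_map(path: str):
    """Read a contact map written by :func:`write_contact_map`."""
    from scipy.sparse import coo_matrix

    from .contact_maps import ContactMap

    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(item.split("=") for item in header.split("\t"))
        rows, cols, vals = [], [], []
        for line in fh:
            _, i, j, v = line.split("\t")
            i, j, v = int(i), int(j), float(v)
            rows.append(i)
            cols.append(j)
            vals.append(v)
            if i != j:
                rows.append(j)
                cols.append(i)
                vals.append(v)
    n = int(meta["n_bins"])
    mat = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return ContactMap(chrom=meta["chrom"], bin_size_bp=int(meta["bin_size"]), matrix=mat)
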