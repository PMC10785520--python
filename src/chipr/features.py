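"""Feature extraction for anchor-pair interaction records.

Six named features describe a pair of interacting anchor peaks:

* genomic distance between peak centers (kb),
* RAD21 ChIP-Seq RPKM at each anchor,
* H3K27ac ChIP-Seq RPKM at each anchor,
* H3K27me3 ChIP-Seq RPKM at each anchor,
* GC content (%) of each anchor,
* a binary CTCF motif convergence flag.

The full schema expands to 10 numeric columns; the minimal schema keeps
RAD21, distance, GC and the flag (6 columns), dropping both histone marks.
ChIP-Seq signal is normalized as RPKM with a per-chromosome per-million
scaling factor. Reads are assigned to a peak when their midpoint lies in
``[start, end)``.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import InteractionRecord, MotifHit, Peak, ReadTrack

__all__ = [
    "FULL_COLUMNS",
    "MINIMAL_COLUMNS",
    "FeatureSchema",
    "genomic_distance_kb",
    "count_reads_in_peak",
    "rpkm",
    "gc_content_percent",
    "assign_motif_to_peak",
    "ctcf_orientation_flag",
    "build_feature_matrix",
]

FULL_COLUMNS = (
    "distance_kb",
    "rad21_p1",
    "rad21_p2",
    "h3k27ac_p1",
    "h3k27ac_p2",
    "h3k27me3_p1",
    "h3k27me3_p2",
    "gc_p1",
    "gc_p2",
    "ctcf_flag",
)
MINIMAL_COLUMNS = (
    "distance_kb",
    "rad21_p1",
    "rad21_p2",
    "gc_p1",
    "gc_p2",
    "ctcf_flag",
)
_HISTONE_COLUMNS = ("h3k27ac_p1", "h3k27ac_p2", "h3k27me3_p1", "h3k27me3_p2")


@dataclass(frozen=True)
class FeatureSchema:
    """Which feature columns a model consumes, in a fixed order.

    mode "full" = all six features (10 columns); "minimal" = RAD21 signal,
    distance, GC and CTCF flag only (6 columns).
    """

    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "minimal"):
            raise ValueError(f"unknown schema mode {self.mode!r}")

    @property
    def columns(self) -> tuple[str, ...]:
        return FULL_COLUMNS if self.mode == "full" else MINIMAL_COLUMNS


def genomic_distance_kb(p1: Peak, p2: Peak) -> float:
    """Linear genomic distance between peak centers, in kilobases.

    Centers are ``floor((start + end) / 2)``. Peaks must share a chromosome.
    """
    if p1.chrom != p2.chrom:
        raise ValueError(
            f"distance undefined across chromosomes ({p1.chrom} vs {p2.chrom})"
        )
    return abs(p1.center - p2.center) / 1000.0


class _MidpointIndex:
    """Sorted per-chromosome read midpoints for O(log n) interval counting."""

    def __init__(self, track: ReadTrack):
        self._mids = {c: sorted(track.midpoints(c)) for c in track.reads}
        self.totals = track.total_reads_per_chrom

    def count(self, p: Peak) -> int:
        mids = self._mids.get(p.chrom)
        if mids is None:
            warnings.warn(f"chromosome {p.chrom} absent from read track", stacklevel=3)
            return 0
        return bisect_left(mids, p.end) - bisect_left(mids, p.start)


def count_reads_in_peak(track: ReadTrack, p: Peak) -> int:
    """Number of reads whose midpoint lies in ``[p.start, p.end)``.

    A chromosome absent from the track counts 0 with a warning.
    """
    if p.chrom not in track.reads:
        warnings.warn(f"chromosome {p.chrom} absent from read track", stacklevel=2)
        return 0
    mids = sorted(track.midpoints(p.chrom))
    return bisect_left(mids, p.end) - bisect_left(mids, p.start)


def rpkm(read_count: int, total_chrom_reads: int, peak_length_bp: int) -> float:
    """Reads per kilobase per million, with a per-chromosome scaling factor.

    ``read_count / (total_chrom_reads / 1e6) / (peak_length_bp / 1000)``.
    """
    if total_chrom_reads <= 0:
        raise ValueError("per-chromosome read total must be positive for RPKM")
    if peak_length_bp <= 0:
        raise ValueError("peak length must be positive")
    return read_count / (total_chrom_reads / 1e6) / (peak_length_bp / 1000.0)


def gc_content_percent(sequence: str) -> float:
    """Percentage of G and C bases; ambiguous bases count in the denominator only."""
    if not sequence:
        raise ValueError("GC content of an empty sequence is undefined")
    s = sequence.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def assign_motif_to_peak(hits: list[MotifHit], p: Peak) -> MotifHit | None:
    """Highest-scoring motif hit whose midpoint lies within the peak.

    Mirrors scanners that report one occurrence per peak (the best one).
    Score ties break toward the leftmost start.
    """
    inside = [
        h for h in hits if h.chrom == p.chrom and p.start <= h.center < p.end
    ]
    if not inside:
        return None
    return min(inside, key=lambda h: (-h.score, h.start))


def ctcf_orientation_flag(
    hit_left: MotifHit | None, hit_right: MotifHit | None
) -> int:
    """1 iff the two anchors carry a convergent CTCF motif pair.

    Convergent means '+' in the leftmost anchor and '-' in the rightmost.
    Divergent, tandem, or a motif absent from either anchor all give 0.
    """
    if hit_left is None or hit_right is None:
        return 0
    return int(hit_left.strand == "+" and hit_right.strand == "-")


@dataclass
class _MotifIndex:
    hits_by_chrom: dict[str, list[MotifHit]] = field(default_factory=dict)

    @classmethod
    def build(cls, hits: list[MotifHit]) -> "_MotifIndex":
        idx = cls()
        for h in hits:
            idx.hits_by_chrom.setdefault(h.chrom, []).append(h)
        for hs in idx.hits_by_chrom.values():
            hs.sort(key=lambda h: h.center)
        return idx

    def best_in_peak(self, p: Peak) -> MotifHit | None:
        hs = self.hits_by_chrom.get(p.chrom, [])
        centers = [h.center for h in hs]
        lo = bisect_left(centers, p.start)
        hi = bisect_right(centers, p.end - 1)
        inside = hs[lo:hi]
        if not inside:
            return None
        return min(inside, key=lambda h: (-h.score, h.start))


def _anchor_rpkm(index: _MidpointIndex, p: Peak, track_name: str) -> float:
    total = index.totals.get(p.chrom, 0)
    if total == 0:
        raise ValueError(
            f"no {track_name} reads on chromosome {p.chrom}: RPKM undefined"
        )
    return rpkm(index.count(p), total, p.length)


def build_feature_matrix(
    interactions: list[InteractionRecord],
    tracks: dict[str, ReadTrack],
    genome: dict[str, str],
    motifs: list[MotifHit],
    schema: FeatureSchema = FeatureSchema("full"),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the model design matrix and PET-count target vector.

    One row per interaction, in input order; columns follow the schema.
    ``tracks`` must supply 'rad21' always and both histone tracks for the
    full schema. Anchors extending past the chromosome sequence are an error.
    """
    needed = ("rad21",) if schema.mode == "minimal" else (
        "rad21", "h3k27ac", "h3k27me3"
    )
    missing = [t for t in needed if t not in tracks]
    if missing:
        raise ValueError(f"missing read tracks: {missing}")
    indexes = {name: _MidpointIndex(tracks[name]) for name in needed}
    motif_index = _MotifIndex.build(motifs)

    rows = np.empty((len(interactions), len(schema.columns)))
    targets = np.empty(len(interactions))
    col_pos = {c: i for i, c in enumerate(schema.columns)}

    for i, rec in enumerate(interactions):
        for p in (rec.anchor1, rec.anchor2):
            seq = genome.get(p.chrom)
            if seq is None or p.end > len(seq):
                raise ValueError(
                    f"anchor {p.chrom}:{p.start}-{p.end} beyond genome sequence"
                )
        row = {
            "distance_kb": genomic_distance_kb(rec.anchor1, rec.anchor2),
            "gc_p1": gc_content_percent(
                genome[rec.anchor1.chrom][rec.anchor1.start : rec.anchor1.end]
            ),
            "gc_p2": gc_content_percent(
                genome[rec.anchor2.chrom][rec.anchor2.start : rec.anchor2.end]
            ),
            "ctcf_flag": ctcf_orientation_flag(
                motif_index.best_in_peak(rec.anchor1),
                motif_index.best_in_peak(rec.anchor2),
            ),
        }
        for name in needed:
            row[f"{name}_p1"] = _anchor_rpkm(indexes[name], rec.anchor1, name)
            row[f"{name}_p2"] = _anchor_rpkm(indexes[name], rec.anchor2, name)
        for col, j in col_pos.items():
            rows[i, j] = row[col]
        targets[i] = rec.strength

    return pd.DataFrame(rows, columns=list(schema.columns)), targets
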