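"""Binned contact maps built from peak-level interactions.

A contact map is a symmetric per-chromosome matrix whose entry (i, j) is the
summed strength of all interactions whose anchor centers fall in bins i and
j. Maps are held sparsely; smoothing densifies only the window arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from .io_formats import InteractionRecord

__all__ = ["ContactMap", "bin_interactions", "smooth_map", "stratify"]


@dataclass
class ContactMap:
    """Symmetric binned interaction-strength matrix for one chromosome."""

    chrom: str
    bin_size_bp: int
    matrix: csr_matrix

    def __post_init__(self) -> None:
        if self.bin_size_bp <= 0:
            raise ValueError("bin size must be positive")
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact map must be square")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def total_mass(self) -> float:
        """Sum over the upper triangle plus the diagonal (= total PET strength)."""
        dense = self.dense()
        return float(np.triu(dense).sum())


def bin_interactions(
    interactions: list[InteractionRecord], bin_size_bp: int, chrom_length: int
) -> ContactMap:
    """Aggregate one chromosome's interactions into a binned map.

    Each anchor maps to bin ``floor(center / bin_size)``; the strengths of
    all interactions hitting the same bin pair are summed. Total map mass
    equals total input strength exactly.
    """
    if bin_size_bp <= 0:
        raise ValueError("bin size must be positive")
    chroms = {r.chrom for r in interactions}
    if len(chroms) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else "NA"
    n_bins = int(np.ceil(chrom_length / bin_size_bp))

    rows, cols, vals = [], [], []
    for rec in interactions:
        c1, c2 = rec.anchor1.center, rec.anchor2.center
        if c1 >= chrom_length or c2 >= chrom_length:
            raise ValueError(
                f"anchor center beyond chromosome length {chrom_length}"
            )
        i, j = c1 // bin_size_bp, c2 // bin_size_bp
        rows.append(i)
        cols.append(j)
        vals.append(rec.strength)
        if i != j:
            rows.append(j)
            cols.append(i)
            vals.append(rec.strength)
    mat = coo_matrix((vals, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    return ContactMap(chrom=chrom, bin_size_bp=bin_size_bp, matrix=mat)


def smooth_map(cmap: ContactMap, h: int) -> ContactMap:
    """Mean-filter a map with a (2h+1)x(2h+1) window.

    Border cells average over the in-bounds part of the window only, so a
    constant matrix is a fixed point for any h; h=0 is the identity.
    """
    if h < 0:
        raise ValueError("window half-size h must be non-negative")
    if h == 0:
        return ContactMap(cmap.chrom, cmap.bin_size_bp, cmap.matrix.copy())
    dense = cmap.dense()
    n = dense.shape[0]
    # integral image: windowed sums by four-corner subtraction, one division
    # per cell (keeps count-valued maps exact, so rank ties survive smoothing)
    integral = np.zeros((n + 1, n + 1))
    integral[1:, 1:] = dense.cumsum(axis=0).cumsum(axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    sums = (
        integral[np.ix_(hi, hi)]
        - integral[np.ix_(lo, hi)]
        - integral[np.ix_(hi, lo)]
        + integral[np.ix_(lo, lo)]
    )
    counts = np.outer(hi - lo, hi - lo)
    smoothed = sums / counts
    return ContactMap(cmap.chrom, cmap.bin_size_bp, csr_matrix(smoothed))


def stratify(cmap: ContactMap, max_distance_bp: int) -> list[np.ndarray]:
    """Split a map into constant-genomic-distance strata (diagonals).

    Stratum k holds entries (i, i+k) for k = 0 .. floor(max_distance/bin_size),
    capped at n_bins - 1 diagonals.
    """
    if max_distance_bp < cmap.bin_size_bp:
        raise ValueError("max distance must be at least one bin")
    k_max = min(max_distance_bp // cmap.bin_size_bp, cmap.n_bins - 1)
    dense = cmap.dense()
    return [np.diagonal(dense, offset=k).copy() for k in range(k_max + 1)]
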