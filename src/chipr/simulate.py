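"""Self-contained synthetic fixtures with known ground truth.

Emulates the structure of a cohesin ChIA-PET study at desk scale: random
genome sequence with isochore-like GC blocks, non-overlapping anchor peaks,
ChIP-Seq read pileups enriched at peaks (RAD21 plus an anti-correlated
H3K27ac/H3K27me3 pair), stranded CTCF motif placements, CTCF ChIP peaks over
a subset of motif-bearing anchors, and negative-binomially distributed
interaction strengths whose mean decays exponentially with genomic distance
and rises with anchor RAD21 signal and motif convergence:

    mu = mu0 * exp(-d_kb / lambda_kb) * (1 + beta * mean anchor RAD21 RPKM)
             * (1 + gamma * ctcf_flag),      strength ~ NB(mean mu, dispersion k)

with Var = mu + mu^2 / k. Every random component draws from an independent
named substream of one master seed, so parts can be regenerated in isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import count_reads_in_peak, rpkm
from .io_formats import (
    InteractionRecord,
    MotifHit,
    Peak,
    ReadTrack,
    write_interactions,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_peaks_and_tracks",
    "simulate_interactions",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.array(["A", "C", "G", "T"])
# substream labels -> offsets mixed into the master seed
_STREAMS = {"genome": 1, "peaks": 2, "reads": 3, "motifs": 4, "interactions": 5}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults sketch a small mammalian-like setup: a handful of 1-Mbp
    chromosomes, ~2-kbp anchor peaks, 50k reads per chromosome per track with
    10-fold enrichment at peaks, and 5,000 interactions whose mean strength
    starts at mu0 near-adjacent and decays with scale lambda_kb.
    """

    n_chromosomes: int = 4
    chrom_length_bp: int = 1_000_000
    n_peaks_per_chrom: int = 80
    peak_length_bp: int = 2_000
    reads_per_chrom: int = 50_000
    read_length_bp: int = 36
    enrichment_fold: float = 10.0
    motif_prob: float = 0.7
    plus_strand_prob: float = 0.5
    ctcf_chip_frac: float = 0.8
    gc_block_bp: int = 100_000
    n_interactions: int = 5_000
    mu0: float = 30.0
    lambda_kb: float = 300.0
    beta: float = 2e-4
    gamma: float = 1.0
    dispersion_k: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda_kb", "dispersion_k", "mu0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("motif_prob", "plus_strand_prob", "ctcf_chip_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Random genome with block-wise GC content varying in [30, 70]%.

    Returns the sequence mapping and, per chromosome, the array of per-block
    GC targets (fractions) actually used.
    """
    rng = config.rng("genome")
    genome: dict[str, str] = {}
    gc_targets: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        n_blocks = int(np.ceil(config.chrom_length_bp / config.gc_block_bp))
        targets = rng.uniform(0.30, 0.70, size=n_blocks)
        parts = []
        remaining = config.chrom_length_bp
        for gc in targets:
            block_len = min(config.gc_block_bp, remaining)
            probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            parts.append("".join(rng.choice(_BASES, size=block_len, p=probs)))
            remaining -= block_len
        genome[chrom] = "".join(parts)
        gc_targets[chrom] = targets
    return genome, gc_targets


@dataclass
class _PeakAnnotation:
    """Per-peak latent intensities driving read placement."""

    rad21: np.ndarray
    h3k27ac: np.ndarray
    h3k27me3: np.ndarray


def _place_peaks(config: SimConfig, rng: np.random.Generator) -> dict[str, list[Peak]]:
    slot = config.chrom_length_bp // config.n_peaks_per_chrom
    if slot <= config.peak_length_bp:
        raise ValueError(
            "peaks cannot fit without overlap: reduce n_peaks_per_chrom or "
            "peak_length_bp"
        )
    peaks: dict[str, list[Peak]] = {}
    for chrom in config.chrom_names:
        offsets = rng.integers(0, slot - config.peak_length_bp,
                               size=config.n_peaks_per_chrom)
        peaks[chrom] = [
            Peak(chrom, int(i * slot + off), int(i * slot + off + config.peak_length_bp))
            for i, off in enumerate(offsets)
        ]
    return peaks


def _scatter_reads(
    config: SimConfig,
    rng: np.random.Generator,
    peaks: dict[str, list[Peak]],
    intensities: dict[str, np.ndarray],
) -> ReadTrack:
    """Uniform background plus intensity-weighted extra reads inside peaks.

    The peak-read fraction w solves in-peak/background density = enrichment_fold
    on average: w = (E-1)f / (1 + (E-1)f) with f the genomic peak fraction.
    """
    track = ReadTrack()
    f = (config.n_peaks_per_chrom * config.peak_length_bp) / config.chrom_length_bp
    e = config.enrichment_fold
    w = (e - 1) * f / (1 + (e - 1) * f)
    for chrom in config.chrom_names:
        n_peak_reads = rng.binomial(config.reads_per_chrom, w)
        n_bg = config.reads_per_chrom - n_peak_reads
        starts = list(rng.integers(0, config.chrom_length_bp - config.read_length_bp,
                                   size=n_bg))
        weights = intensities[chrom] / intensities[chrom].sum()
        which = rng.choice(len(peaks[chrom]), size=n_peak_reads, p=weights)
        for k in which:
            p = peaks[chrom][k]
            starts.append(rng.integers(p.start, p.end - config.read_length_bp))
        for s in starts:
            track.add(chrom, int(s), int(s) + config.read_length_bp)
    return track


def simulate_peaks_and_tracks(
    config: SimConfig, genome: dict[str, str]
) -> tuple[
    list[Peak], dict[str, ReadTrack], list[MotifHit], list[Peak]
]:
    """Peaks, the three read tracks, motif hits and CTCF ChIP peaks.

    RAD21 intensity per peak is lognormal; H3K27ac and H3K27me3 intensities
    are anti-correlated (u vs 1-u plus noise). Motifs (19 bp) are dropped
    into peaks with the configured probability and strand bias; CTCF ChIP
    peaks cover a random subset of motif-bearing anchors.
    """
    rng_peaks = config.rng("peaks")
    rng_reads = config.rng("reads")
    rng_motifs = config.rng("motifs")
    peaks_by_chrom = _place_peaks(config, rng_peaks)

    annotations: dict[str, _PeakAnnotation] = {}
    for chrom in config.chrom_names:
        n = config.n_peaks_per_chrom
        u = rng_peaks.uniform(0.05, 0.95, size=n)
        annotations[chrom] = _PeakAnnotation(
            rad21=rng_peaks.lognormal(0.0, 0.5, size=n),
            h3k27ac=u + rng_peaks.normal(0, 0.02, size=n),
            h3k27me3=(1.0 - u) + rng_peaks.normal(0, 0.02, size=n),
        )
        np.clip(annotations[chrom].h3k27ac, 0.01, None, out=annotations[chrom].h3k27ac)
        np.clip(annotations[chrom].h3k27me3, 0.01, None, out=annotations[chrom].h3k27me3)

    tracks = {
        "rad21": _scatter_reads(
            config, rng_reads, peaks_by_chrom,
            {c: a.rad21 for c, a in annotations.items()},
        ),
        "h3k27ac": _scatter_reads(
            config, rng_reads, peaks_by_chrom,
            {c: a.h3k27ac for c, a in annotations.items()},
        ),
        "h3k27me3": _scatter_reads(
            config, rng_reads, peaks_by_chrom,
            {c: a.h3k27me3 for c, a in annotations.items()},
        ),
    }

    motif_len = 19
    motifs: list[MotifHit] = []
    ctcf_peaks: list[Peak] = []
    for chrom in config.chrom_names:
        for p in peaks_by_chrom[chrom]:
            if rng_motifs.random() >= config.motif_prob:
                continue
            start = int(rng_motifs.integers(p.start, p.end - motif_len))
            strand = "+" if rng_motifs.random() < config.plus_strand_prob else "-"
            score = float(rng_motifs.uniform(5.0, 15.0))
            motifs.append(MotifHit(chrom, start, start + motif_len, strand, score))
            if rng_motifs.random() < config.ctcf_chip_frac:
                ctcf_peaks.append(Peak(chrom, p.start, p.end))

    all_peaks = [p for chrom in config.chrom_names for p in peaks_by_chrom[chrom]]
    return all_peaks, tracks, motifs, ctcf_peaks


def _rad21_rpkm_per_peak(
    peaks: list[Peak], rad21: ReadTrack
) -> dict[Peak, float]:
    totals = rad21.total_reads_per_chrom
    mids = {c: np.sort(np.asarray(rad21.midpoints(c))) for c in rad21.reads}
    out = {}
    for p in peaks:
        m = mids.get(p.chrom)
        count = 0 if m is None else int(
            np.searchsorted(m, p.end) - np.searchsorted(m, p.start)
        )
        out[p] = rpkm(count, totals[p.chrom], p.length)
    return out


def _motif_strand_per_peak(
    peaks: list[Peak], motifs: list[MotifHit]
) -> dict[Peak, str | None]:
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in motifs:
        by_chrom.setdefault(h.chrom, []).append(h)
    out: dict[Peak, str | None] = {}
    for p in peaks:
        best = None
        for h in by_chrom.get(p.chrom, []):
            if p.start <= h.center < p.end:
                if best is None or (h.score, -h.start) > (best.score, -best.start):
                    best = h
        out[p] = best.strand if best else None
    return out


def simulate_interactions(
    config: SimConfig,
    peaks: list[Peak],
    rad21_rpkm: dict[Peak, float],
    motif_strand: dict[Peak, str | None],
) -> tuple[list[InteractionRecord], pd.DataFrame]:
    """Sample anchor pairs and draw NB strengths from the generative mean.

    Pairs are distinct within each chromosome; the returned ground-truth
    table records, per interaction, the generative mean mu and the features
    it was built from.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for ps in by_chrom.values():
        ps.sort()
        if len(ps) < 2:
            raise ValueError("need at least 2 peaks per chromosome")

    rng = config.rng("interactions")
    chroms = sorted(by_chrom)
    per_chrom = np.full(len(chroms), config.n_interactions // len(chroms))
    per_chrom[: config.n_interactions % len(chroms)] += 1

    records: list[InteractionRecord] = []
    truth_rows = []
    for chrom, n_want in zip(chroms, per_chrom):
        ps = by_chrom[chrom]
        n = len(ps)
        n_pairs = n * (n - 1) // 2
        n_take = min(n_want, n_pairs)
        flat = rng.choice(n_pairs, size=n_take, replace=False)
        # unrank the flat index into (i, j), i < j
        iu, ju = np.triu_indices(n, k=1)
        for fi in flat:
            p1, p2 = ps[iu[fi]], ps[ju[fi]]
            d_kb = abs(p1.center - p2.center) / 1000.0
            mean_signal = 0.5 * (rad21_rpkm[p1] + rad21_rpkm[p2])
            flag = int(motif_strand[p1] == "+" and motif_strand[p2] == "-")
            mu = (
                config.mu0
                * np.exp(-d_kb / config.lambda_kb)
                * (1.0 + config.beta * mean_signal)
                * (1.0 + config.gamma * flag)
            )
            k = config.dispersion_k
            strength = int(rng.negative_binomial(k, k / (k + mu)))
            records.append(InteractionRecord(p1, p2, strength))
            truth_rows.append(
                {
                    "chrom": chrom,
                    "start1": p1.start,
                    "start2": p2.start,
                    "distance_kb": d_kb,
                    "rad21_mean_rpkm": mean_signal,
                    "ctcf_flag": flag,
                    "mu": mu,
                    "strength": strength,
                }
            )
    return records, pd.DataFrame(truth_rows)


@dataclass
class SimulatedDataset:
    """Everything one fixture provides, with its ground truth."""

    config: SimConfig
    genome: dict[str, str]
    gc_targets: dict[str, np.ndarray]
    peaks: list[Peak]
    tracks: dict[str, ReadTrack]
    motifs: list[MotifHit]
    ctcf_peaks: list[Peak]
    interactions: list[InteractionRecord]
    ground_truth: pd.DataFrame


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Run the whole generator under one config (optionally reseeded)."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    genome, gc_targets = simulate_genome(config)
    peaks, tracks, motifs, ctcf_peaks = simulate_peaks_and_tracks(config, genome)
    rad21_rpkm = _rad21_rpkm_per_peak(peaks, tracks["rad21"])
    motif_strand = _motif_strand_per_peak(peaks, motifs)
    interactions, truth = simulate_interactions(config, peaks, rad21_rpkm, motif_strand)
    return SimulatedDataset(
        config=config,
        genome=genome,
        gc_targets=gc_targets,
        peaks=peaks,
        tracks=tracks,
        motifs=motifs,
        ctcf_peaks=ctcf_peaks,
        interactions=interactions,
        ground_truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Write FASTA, BED, BED6, BEDPE and the ground-truth table to a directory."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "peaks": os.path.join(outdir, "peaks.bed"),
        "motifs": os.path.join(outdir, "ctcf_motifs.bed"),
        "ctcf_peaks": os.path.join(outdir, "ctcf_chip_peaks.bed"),
        "interactions": os.path.join(outdir, "interactions.bedpe"),
        "ground_truth": os.path.join(outdir, "ground_truth.tsv"),
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in ds.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["peaks"], "w") as fh:
        for p in ds.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
    with open(paths["motifs"], "w") as fh:
        for h in ds.motifs:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\tCTCF\t{h.score:.3f}\t{h.strand}\n")
    with open(paths["ctcf_peaks"], "w") as fh:
        for p in ds.ctcf_peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
    write_interactions(ds.interactions, paths["interactions"])
    ds.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    for name, track in ds.tracks.items():
        path = os.path.join(outdir, f"{name}_reads.bed")
        paths[f"{name}_reads"] = path
        with open(path, "w") as fh:
            for chrom, reads in track.reads.items():
                for s, e in reads:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
    return paths
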