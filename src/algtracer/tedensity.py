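"""Transposable-element density profiling.

TE occurrences are counted by their start coordinate into fixed-width bins
(10 kb or 50 kb) and normalized to counts per 10 kb, so that regions,
chromosomes and whole genomes are directly comparable.  The headline
statistic is the percent difference between a gene-cluster region (e.g. a
Hox cluster span) and the rest of its chromosome: positive values mean the
cluster is TE-poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomeio import TE_CLASSES, TETrack

__all__ = [
    "TEBinSpec",
    "ClusterRegion",
    "bin_counts",
    "region_density",
    "percent_difference",
    "genome_density",
]


@dataclass(frozen=True)
class TEBinSpec:
    bin_bp: int = 10_000
    norm_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.bin_bp <= 0 or self.norm_bp <= 0:
            raise ValueError("bin sizes must be positive")


@dataclass(frozen=True)
class ClusterRegion:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def bin_counts(track: TETrack, chrom: str, chrom_length: int,
               spec: TEBinSpec = TEBinSpec(),
               classes=None) -> tuple[np.ndarray, int]:
    """Histogram of TE start counts per bin; returns (counts, last_bin_bp).

    A TE belongs to the bin containing its start.  The final partial bin is
    reported raw together with its covered length.
    """
    if chrom_length <= 0:
        raise ValueError(f"unknown or zero-length chromosome {chrom!r}")
    starts = np.array([s for s, _, _ in track.on(chrom, classes)], dtype=int)
    n_bins = int(np.ceil(chrom_length / spec.bin_bp))
    counts = np.zeros(n_bins, dtype=int)
    if starts.size:
        idx = starts // spec.bin_bp
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    last_bin_bp = chrom_length - (n_bins - 1) * spec.bin_bp
    return counts, last_bin_bp


def region_density(track: TETrack, region: ClusterRegion,
                   classes=None, norm_bp: int = 10_000) -> float:
    """TE starts per ``norm_bp`` within a region."""
    n = sum(1 for s, _, _ in track.on(region.chrom, classes)
            if region.start <= s < region.end)
    return n * norm_bp / region.length


def percent_difference(non_cluster_density: float, cluster_density: float) -> float:
    """(non_cluster - cluster) / non_cluster * 100; positive = cluster TE-poor."""
    if non_cluster_density <= 0:
        raise ValueError("non-cluster baseline density must be positive")
    return (non_cluster_density - cluster_density) / non_cluster_density * 100.0


def genome_density(track: TETrack, chrom_lengths: dict[str, int],
                   classes=None, norm_bp: int = 10_000) -> tuple[dict[str, float], float]:
    """Per-chromosome and overall TE density per ``norm_bp``."""
    keep = set(TE_CLASSES if classes is None else classes)
    per_chrom: dict[str, float] = {}
    total_n = 0
    for chrom, length in chrom_lengths.items():
        n = sum(1 for ch, s, e, c in track.intervals if ch == chrom and c in keep)
        per_chrom[chrom] = n * norm_bp / length
        total_n += n
    total_len = sum(chrom_lengths.values())
    return per_chrom, total_n * norm_bp / total_len


def cluster_contrast(track: TETrack, region: ClusterRegion, chrom_length: int,
                     classes=None, norm_bp: int = 10_000) -> dict[str, float]:
    """Cluster density, non-cluster density of the same chromosome, and the
    percent difference — the columns of a cluster TE-depletion summary."""
    cluster = region_density(track, region, classes, norm_bp)
    n_all = sum(1 for s, _, _ in track.on(region.chrom, classes))
    n_in = sum(1 for s, _, _ in track.on(region.chrom, classes)
               if region.start <= s < region.end)
    rest_len = chrom_length - region.length
    if rest_len <= 0:
        raise ValueError("cluster region covers the whole chromosome")
    non_cluster = (n_all - n_in) * norm_bp / rest_len
    return {
        "cluster_density": cluster,
        "non_cluster_density": non_cluster,
        "percent_difference": percent_difference(non_cluster, cluster),
    }
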