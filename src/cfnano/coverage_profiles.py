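"""Mononucleosome coverage tracks and reference-point metaplots.

CTCF binding evicts the central nucleosome and phases ~10 nucleosomes on
either side; a coverage metaplot of 130-155 bp fragments around such sites
shows a central dip with ~190 bp-spaced peaks.  Coverage is normalised RPGC
(reads per genomic content: mean 1 over an effective genome), so the mean
profile reads directly as fold change vs genome-average coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragmentomics import Fragment

EFFECTIVE_GENOME_SIZE_GRCH38 = 2_913_022_398
NUCLEOSOMAL_RANGE = (130, 155)


@dataclass
class CoverageTrack:
    """Binned per-base coverage over the analysed chromosomes.

    ``bins`` maps chromosome to a float array of per-bin mean per-base
    coverage; ``chrom_sizes`` gives the analysed span of each chromosome.
    """

    bins: dict[str, np.ndarray]
    bin_width: int
    chrom_sizes: dict[str, int]
    normalization: str = "raw"  # {raw, RPGC}
    effective_genome_size: int | None = None


def select_nucleosomal(
    fragments,
    min_len: int = NUCLEOSOMAL_RANGE[0],
    max_len: int = NUCLEOSOMAL_RANGE[1],
) -> list[Fragment]:
    """Keep deduplicated fragments of mononucleosomal size (inclusive bounds).

    Duplicates — identical (chrom, start, end, strand) — collapse to one.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[Fragment] = []
    for f in fragments:
        key = (f.chrom, f.start, f.end, f.strand)
        if key in seen:
            continue
        seen.add(key)
        if min_len <= f.length <= max_len:
            out.append(f)
    return out


def coverage_track(
    fragments, chrom_sizes: dict[str, int], bin_width: int = 10
) -> CoverageTrack:
    """Raw per-base pileup of fragment reference spans, averaged per bin."""
    bins: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1)
        for f in fragments:
            if f.chrom != chrom:
                continue
            lo, hi = max(0, f.start), min(size, f.end)
            if hi > lo:
                diff[lo] += 1
                diff[hi] -= 1
        per_base = np.cumsum(diff[:-1])
        n_bins = int(np.ceil(size / bin_width))
        padded = np.full(n_bins * bin_width, np.nan)
        padded[:size] = per_base
        bins[chrom] = np.nanmean(padded.reshape(n_bins, bin_width), axis=1)
    return CoverageTrack(bins, bin_width, dict(chrom_sizes), "raw")


def rpgc_normalize(
    track: CoverageTrack, effective_genome_size: int | None = None
) -> CoverageTrack:
    """Scale a raw track to RPGC: genome-wide mean coverage 1.

    The scale factor is ``effective_genome_size / total covered bases``
    (sum of per-base coverage over the track), so doubling every fragment
    leaves the normalised track unchanged.  By default the effective genome
    size is the total analysed span.
    """
    if track.normalization == "RPGC":
        return track
    if effective_genome_size is None:
        effective_genome_size = sum(track.chrom_sizes.values())
    total = sum(
        float(np.nansum(arr)) * track.bin_width for arr in track.bins.values()
    )
    if total == 0:
        raise ValueError("zero total coverage; cannot RPGC-normalize")
    scale = effective_genome_size / total
    return CoverageTrack(
        {chrom: arr * scale for chrom, arr in track.bins.items()},
        track.bin_width,
        dict(track.chrom_sizes),
        "RPGC",
        effective_genome_size,
    )


@dataclass
class ReferencePointMatrix:
    """Sites x signed-distance-bins matrix of normalised coverage."""

    matrix: np.ndarray  # NaN where a window leaves the chromosome
    bin_centers: np.ndarray

    @property
    def mean_profile(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance": self.bin_centers, "mean_coverage": self.mean_profile}
        )


def profile_extrema_centroids(
    bin_centers, values, threshold: float, above: bool = True
) -> list[float]:
    """Locate metaplot peaks (or troughs) as centroids of threshold runs.

    Nucleosome-protected coverage is plateau-shaped (a fragment covers its
    whole span), so a raw argmax is ill-defined; the centroid of each
    contiguous run above (below) the threshold, weighted by excess over the
    threshold, recovers the symmetric plateau's center instead.
    """
    values = np.asarray(values, dtype=float)
    centers = np.asarray(bin_centers, dtype=float)
    excess = np.where(np.isnan(values), 0.0, values - threshold)
    if not above:
        excess = -excess
    mask = excess > 0
    out: list[float] = []
    i = 0
    while i < len(mask):
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < len(mask) and mask[j]:
            j += 1
        w = excess[i:j]
        out.append(float(np.sum(w * centers[i:j]) / np.sum(w)))
        i = j
    return out


def reference_point_matrix(
    track: CoverageTrack, sites, half_window: int = 1000
) -> ReferencePointMatrix:
    """Coverage rows per site at signed distances from the site center.

    Bin width is the track's; windows exceeding chromosome bounds are padded
    with NaN.  On an RPGC track the mean profile is fold change vs the
    genome-average coverage.
    """
    if not sites:
        raise ValueError("site set is empty")
    bw = track.bin_width
    n_side = half_window // bw
    centers = (np.arange(-n_side, n_side) + 0.5) * bw
    rows = []
    for site in sites:
        chrom, center = (site.chrom, site.center) if hasattr(site, "center") else site[:2]
        row = np.full(2 * n_side, np.nan)
        arr = track.bins.get(chrom)
        if arr is not None:
            center_bin = center // bw
            lo = center_bin - n_side
            hi = center_bin + n_side
            src_lo, src_hi = max(0, lo), min(len(arr), hi)
            if src_hi > src_lo:
                row[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        rows.append(row)
    return ReferencePointMatrix(np.vstack(rows), centers)
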