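"""Region-level methylation analyses.

Three views of where methylation change happens in plasma DNA:

* flank-normalised metaplots of beta values around transcription-factor
  binding sites (open chromatin is hypomethylated, so tumor-derived DNA
  leaves a dip at tumor-lineage TFBS);
* partially-methylated-domain (PMD) hypomethylation summarised as the mean
  solo-WCGW beta of each 10-Mbp bin minus the genome-wide mean beta;
* copy-number stratification of those bins, because amplified regions carry
  proportionally more tumor DNA and hence deeper hypomethylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meth_io import CpGCall
from .stats import wilcoxon_rank_sum

PMD_BIN_SIZE = 10_000_000


@dataclass(frozen=True)
class TFBSSite:
    chrom: str
    center: int
    strand: str = "+"
    score: float = 0.0


@dataclass
class MetaProfile:
    """Binned signed-distance methylation profile around a site set."""

    bin_centers: np.ndarray
    mean_beta: np.ndarray  # NaN where a bin has no CpGs
    fold_change: np.ndarray
    flank_mean: float
    n_cpgs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.bin_centers,
                "mean_beta": self.mean_beta,
                "fold_change": self.fold_change,
                "n_cpgs": self.n_cpgs,
            }
        )


@dataclass(frozen=True)
class CNSegment:
    chrom: str
    start: int
    end: int
    log2ratio: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")


@dataclass
class PMDBin:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    bin_beta: float
    delta: float  # NaN when n_cpgs < min_cpgs
    cn_status: str = "NA"  # {gain, neutral, loss, NA}


def highest_score_motif_per_peak(motif_hits, peaks) -> list[TFBSSite]:
    """Reduce motif hits to one site per peak: the highest-scoring hit
    (leftmost on ties); peaks without hits are dropped.

    ``motif_hits`` are TFBSSite-like records; ``peaks`` are (chrom, start,
    end) intervals, 0-based half-open.
    """
    sites: list[TFBSSite] = []
    for chrom, start, end in peaks:
        in_peak = [
            h for h in motif_hits if h.chrom == chrom and start <= h.center < end
        ]
        if not in_peak:
            continue
        best = max(in_peak, key=lambda h: (h.score, -h.center))
        sites.append(best)
    return sites


def tfbs_meta_profile(
    calls,
    sites,
    half_window: int = 1000,
    bin_width: int = 20,
    flank_inner: int = 800,
) -> MetaProfile:
    """Pool CpG betas by signed distance to site centers and normalise to the
    outer flanks.

    Every CpG within ``half_window`` of a site center contributes its beta to
    the signed-distance bin; bin means are pooled across all sites.  The
    flank mean is the mean of bin means over bins lying entirely within
    [-half_window, -flank_inner] or [flank_inner, half_window], and the fold
    change per bin is ``mean_beta / flank_mean``.
    """
    if not sites:
        raise ValueError("site set is empty")
    edges = np.arange(-half_window, half_window + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    sums = np.zeros(len(centers))
    counts = np.zeros(len(centers), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for c in calls:
        pos, beta = (c.pos, c.beta) if isinstance(c, CpGCall) else (c[1], c[2])
        chrom = c.chrom if isinstance(c, CpGCall) else c[0]
        by_chrom.setdefault(chrom, []).append((pos, beta))
    chrom_arrays = {
        chrom: (np.array([p for p, _ in v]), np.array([b for _, b in v]))
        for chrom, v in by_chrom.items()
    }
    for site in sites:
        chrom = site.chrom if isinstance(site, TFBSSite) else site[0]
        center = site.center if isinstance(site, TFBSSite) else site[1]
        if chrom not in chrom_arrays:
            continue
        pos, beta = chrom_arrays[chrom]
        dist = pos - center
        in_win = (dist >= -half_window) & (dist < half_window)
        idx = np.clip(((dist[in_win] + half_window) // bin_width), 0, len(centers) - 1)
        np.add.at(sums, idx.astype(int), beta[in_win])
        np.add.at(counts, idx.astype(int), 1)
    with np.errstate(invalid="ignore"):
        mean_beta = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    flank = (np.abs(centers) >= flank_inner) & (np.abs(centers) <= half_window)
    flank_vals = mean_beta[flank]
    flank_vals = flank_vals[~np.isnan(flank_vals)]
    if flank_vals.size == 0 or np.nanmean(flank_vals) == 0:
        warnings.warn("flank mean undefined or zero; fold change not computed")
        flank_mean = np.nan
        fold = np.full_like(mean_beta, np.nan)
    else:
        flank_mean = float(np.mean(flank_vals))
        fold = mean_beta / flank_mean
    return MetaProfile(centers, mean_beta, fold, flank_mean, counts)


def pmd_bin_deltas(
    calls,
    solo_wcgw_cpgs: set[tuple[str, int]],
    pmd_bins,
    min_cpgs: int = 10,
) -> list[PMDBin]:
    """Per-10-Mbp-bin solo-WCGW methylation delta.

    The genome mean is computed over ALL CpG calls; each bin's value is the
    mean beta of its covered solo-WCGW CpGs, and ``delta`` is bin mean minus
    genome mean (negative means hypomethylation).  Bins covering fewer than
    ``min_cpgs`` solo-WCGW CpGs are emitted with a missing delta.
    """
    if not solo_wcgw_cpgs:
        raise ValueError("solo-WCGW CpG set is empty")
    calls = list(calls)
    betas = np.array([c.beta for c in calls])
    if betas.size == 0:
        raise ValueError("no methylation calls")
    genome_mean = float(betas.mean())
    sums = np.zeros(len(pmd_bins))
    counts = np.zeros(len(pmd_bins), dtype=np.int64)
    starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {b[0] for b in pmd_bins}:
        idx = np.array([i for i, b in enumerate(pmd_bins) if b[0] == chrom])
        starts = np.array([pmd_bins[i][1] for i in idx])
        ends = np.array([pmd_bins[i][2] for i in idx])
        order = np.argsort(starts)
        starts_by_chrom[chrom] = (starts[order], ends[order], idx[order])
    for c in calls:
        if (c.chrom, c.pos) not in solo_wcgw_cpgs or c.chrom not in starts_by_chrom:
            continue
        starts, ends, idx = starts_by_chrom[c.chrom]
        j = int(np.searchsorted(starts, c.pos, side="right")) - 1
        if j >= 0 and c.pos < ends[j]:
            sums[idx[j]] += c.beta
            counts[idx[j]] += 1
    out: list[PMDBin] = []
    for i, (chrom, start, end) in enumerate(pmd_bins):
        n = int(counts[i])
        bin_beta = sums[i] / n if n else np.nan
        delta = bin_beta - genome_mean if n >= min_cpgs else np.nan
        out.append(PMDBin(chrom, start, end, n, bin_beta, delta))
    return out


def assign_cn_status(
    bins: list[PMDBin],
    segments: list[CNSegment],
    gain_cut: float = 0.10,
    loss_cut: float = -0.10,
) -> list[PMDBin]:
    """Attach copy-number status to bins from segment log2 ratios.

    A bin's log2 ratio is the overlap-length-weighted mean over overlapping
    segments; gain if above ``gain_cut``, loss if below ``loss_cut``, else
    neutral; NA with no overlap.
    """
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
    out: list[PMDBin] = []
    for b in bins:
        weight = 0.0
        acc = 0.0
        for seg in by_chrom.get(b.chrom, []):
            ov = min(b.end, seg.end) - max(b.start, seg.start)
            if ov > 0:
                weight += ov
                acc += ov * seg.log2ratio
        if weight == 0:
            status = "NA"
        else:
            l2r = acc / weight
            status = "gain" if l2r > gain_cut else ("loss" if l2r < loss_cut else "neutral")
        out.append(PMDBin(b.chrom, b.start, b.end, b.n_cpgs, b.bin_beta, b.delta, status))
    return out


def compare_bins(group_a_deltas, group_b_deltas, alternative: str = "less") -> float:
    """One-sided Wilcoxon rank-sum p-value between two delta distributions."""
    a = np.asarray([d for d in group_a_deltas if not np.isnan(d)], dtype=float)
    b = np.asarray([d for d in group_b_deltas if not np.isnan(d)], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return wilcoxon_rank_sum(a, b, alternative).p_value


def tumor_fraction_floor(
    tf_estimate: float,
    segments: list[CNSegment],
    genome_size: int,
    gain_cut: float = 0.10,
    loss_cut: float = -0.10,
) -> float:
    """Zero out an unstable tumor-fraction estimate.

    When the fraction of the genome covered by copy-number-altered segments
    (log2 ratio beyond the gain/loss cutoffs) is below 15%, the estimate is
    considered unstable and set to 0; otherwise it is returned unchanged.
    """
    if tf_estimate < 0:
        raise ValueError("tf_estimate must be >= 0")
    altered = sum(
        seg.end - seg.start
        for seg in segments
        if seg.log2ratio > gain_cut or seg.log2ratio < loss_cut
    )
    return 0.0 if altered / genome_size < 0.15 else tf_estimate


def read_seg(path) -> dict[str, list[CNSegment]]:
    """Read a SEG TSV (sample, chrom, start, end, log2ratio), with or without
    a header line, into per-sample segment lists."""
    per_sample: dict[str, list[CNSegment]] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                start, end, l2r = int(fields[2]), int(fields[3]), float(fields[4])
            except ValueError:
                continue  # header
            per_sample.setdefault(fields[0], []).append(
                CNSegment(fields[1], start, end, l2r)
            )
    return per_sample


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) from a BED file, 0-based half-open."""
    out = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
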