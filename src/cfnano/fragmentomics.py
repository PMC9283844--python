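"""cfDNA fragment filtering, length statistics and 4-mer end motifs.

Plasma DNA circulates mostly as mono- (~167 bp) and di-nucleosome (~330 bp)
protected fragments; tumor-derived fragments skew shorter in both classes,
and the reference bases at the fragment 5' end carry a biased 4-mer
composition (CCCA depletion marks tumor DNA).  This module computes the
short-mononucleosome ratio (100-150 over 100-220 bp), the short-dinucleosome
ratio (275-325 over 275-400 bp), unit-width length densities, reference-based
end-motif tables and per-motif differential statistics.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust

logger = logging.getLogger(__name__)

MONO_SHORT = (100, 150)
MONO_ALL = (100, 220)
DI_SHORT = (275, 325)
DI_ALL = (275, 400)

ALL_4MERS = tuple("".join(m) for m in itertools.product("ACGT", repeat=4))
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("MI=X")
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class Fragment:
    """One aligned cfDNA molecule."""

    chrom: str
    start: int
    end: int
    length: int
    mapq: int
    strand: str
    is_primary: bool = True
    softclip_start: bool = False
    softclip_end: bool = False
    barcode_both_ends: bool = True
    end_motif: str | None = None


@dataclass(frozen=True)
class FilterConfig:
    """Default fragment filters used throughout the study's analyses."""

    min_mapq: int = 20
    max_len: int = 700
    require_primary: bool = True
    require_double_barcode: bool = True
    drop_softclipped: bool = True


def fragment_length_from_cigar(cigar: str) -> int:
    """Molecule length from a CIGAR string.

    Sums query-consuming operations (M, I, =, X); deletions and introns
    consume reference only.  Clipped reads are excluded upstream of this.
    """
    consumed = 0
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"invalid CIGAR token at offset {pos} in {cigar!r}")
        pos = m.end()
        if m.group(2) in _QUERY_OPS:
            consumed += int(m.group(1))
    if pos != len(cigar) or not cigar:
        raise ValueError(f"invalid CIGAR string {cigar!r}")
    return consumed


def filter_fragments(fragments, config: FilterConfig = FilterConfig()) -> list[Fragment]:
    """Apply the study's fragment filters; removal counts are logged per rule."""
    removed = {"mapq": 0, "length": 0, "not_primary": 0, "softclip": 0, "barcode": 0}
    survivors: list[Fragment] = []
    for f in fragments:
        if config.require_primary and not f.is_primary:
            removed["not_primary"] += 1
        elif f.mapq < config.min_mapq:
            removed["mapq"] += 1
        elif f.length > config.max_len:
            removed["length"] += 1
        elif config.drop_softclipped and (f.softclip_start or f.softclip_end):
            removed["softclip"] += 1
        elif config.require_double_barcode and not f.barcode_both_ends:
            removed["barcode"] += 1
        else:
            survivors.append(f)
    logger.info(
        "filter_fragments: %d in, %d kept, removed %s",
        len(survivors) + sum(removed.values()),
        len(survivors),
        removed,
    )
    return survivors


def _range_ratio(lengths, short_range, all_range) -> float:
    lengths = np.asarray(list(lengths))
    denom = int(np.sum((lengths >= all_range[0]) & (lengths <= all_range[1])))
    if denom == 0:
        warnings.warn(f"no fragments in {all_range[0]}-{all_range[1]} bp; ratio undefined")
        return float("nan")
    numer = int(np.sum((lengths >= short_range[0]) & (lengths <= short_range[1])))
    return numer / denom


def short_mono_ratio(lengths) -> float:
    """Short mononucleosome ratio: fragments 100-150 bp over 100-220 bp (inclusive)."""
    return _range_ratio(lengths, MONO_SHORT, MONO_ALL)


def short_di_ratio(lengths) -> float:
    """Short dinucleosome ratio: fragments 275-325 bp over 275-400 bp (inclusive)."""
    return _range_ratio(lengths, DI_SHORT, DI_ALL)


def length_histogram(lengths, bin_width: int = 1, length_range=(0, 700)) -> pd.DataFrame:
    """Unit-normalised fragment-length histogram (densities sum to 1)."""
    lengths = np.asarray(list(lengths))
    edges = np.arange(length_range[0], length_range[1] + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    total = counts.sum()
    density = counts / total if total > 0 else counts.astype(float)
    return pd.DataFrame({"length": edges[:-1], "count": counts, "density": density})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def end_motif(
    fragment: Fragment, reference, revcomp_minus: bool = True
) -> str | None:
    """Extract the 4 reference bases at the fragment's 5' end (end1).

    ``reference`` maps chromosome name to sequence (a dict of strings or a
    pyfaidx.Fasta).  Plus strand: bases [start, start+4).  Minus strand:
    bases [end-4, end), reverse-complemented by default so the motif reads
    5'->3' on the molecule.  Motifs containing non-ACGT bases are missing.
    """
    if fragment.length < 4:
        warnings.warn("fragment shorter than 4 bp; end motif missing")
        return None
    seq = reference[fragment.chrom]
    if fragment.strand == "+":
        window = str(seq[fragment.start : fragment.start + 4])
    else:
        window = str(seq[fragment.end - 4 : fragment.end])
        if revcomp_minus:
            window = reverse_complement(window)
    window = window.upper()
    if len(window) != 4 or any(b not in "ACGT" for b in window):
        return None
    return window


@dataclass
class MotifTable:
    """Counts and frequencies for all 256 4-mers (zero-filled)."""

    counts: pd.Series
    frequencies: pd.Series
    n_total: int

    def top(self, k: int = 25) -> pd.Series:
        return self.frequencies.sort_values(ascending=False).head(k)


def motif_frequencies(motifs) -> MotifTable:
    """Tabulate 4-mer frequencies; all 256 motifs are always present."""
    counts = pd.Series(0, index=list(ALL_4MERS), dtype=np.int64)
    observed = pd.Series(list(motifs), dtype=object).value_counts()
    bad = set(observed.index) - set(ALL_4MERS)
    if bad:
        raise ValueError(f"invalid 4-mers: {sorted(bad)[:5]}")
    counts.loc[observed.index] = observed.to_numpy()
    return motif_table_from_counts(counts)


def motif_table_from_counts(counts) -> MotifTable:
    """Build a :class:`MotifTable` from a 256-vector of motif counts."""
    counts = pd.Series(np.asarray(counts, dtype=np.int64), index=list(ALL_4MERS))
    n_total = int(counts.sum())
    if n_total > 0:
        freqs = counts / n_total
    else:
        freqs = pd.Series(np.nan, index=counts.index)
    return MotifTable(counts, freqs, n_total)


def motif_differential(group_a_tables, group_b_tables) -> pd.DataFrame:
    """Per-motif two-tailed t-test of per-sample frequencies between groups.

    Each sample contributes one frequency per motif; Benjamini-Hochberg
    q-values are computed across all 256 motifs.  Output is sorted by
    ascending p-value.
    """
    if len(group_a_tables) < 2 or len(group_b_tables) < 2:
        raise ValueError("each group needs >= 2 samples")
    from scipy import stats as sps

    a = np.column_stack([t.frequencies.to_numpy() for t in group_a_tables])
    b = np.column_stack([t.frequencies.to_numpy() for t in group_b_tables])
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision-loss warning; they are
        # overwritten below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=True, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    stats = np.asarray(res.statistic, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pvals[degenerate] = 1.0
    stats[degenerate] = 0.0
    out = pd.DataFrame(
        {
            "motif": list(ALL_4MERS),
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "statistic": stats,
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
        }
    ).set_index("motif")
    return out.sort_values("p_value", kind="mergesort")


FRAGMENT_COLUMNS = [
    "chrom", "start", "end", "mapq", "strand", "cigar",
    "is_primary", "softclip_start", "softclip_end", "barcode_both_ends",
]


def read_fragment_table(path) -> list[Fragment]:
    """Read the package's fragment TSV (header per ``FRAGMENT_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    frags = []
    for row in df.itertuples(index=False):
        cigar = getattr(row, "cigar", None)
        length = (
            fragment_length_from_cigar(cigar)
            if isinstance(cigar, str) and cigar != "*"
            else int(row.end) - int(row.start)
        )
        frags.append(
            Fragment(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                length=length,
                mapq=int(row.mapq),
                strand=str(row.strand),
                is_primary=bool(row.is_primary),
                softclip_start=bool(row.softclip_start),
                softclip_end=bool(row.softclip_end),
                barcode_both_ends=bool(row.barcode_both_ends),
            )
        )
    return frags


def write_fragment_table(fragments, path) -> None:
    rows = [
        {
            "chrom": f.chrom, "start": f.start, "end": f.end, "mapq": f.mapq,
            "strand": f.strand, "cigar": f"{f.length}M",
            "is_primary": f.is_primary, "softclip_start": f.softclip_start,
            "softclip_end": f.softclip_end, "barcode_both_ends": f.barcode_both_ends,
        }
        for f in fragments
    ]
    pd.DataFrame(rows, columns=FRAGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def fragments_from_sam(path) -> list[Fragment]:
    """SAM-text ingestion adapter producing Fragment records.

    Flags 0x100/0x800 mark non-primary alignments, 0x4 unmapped (skipped);
    soft-clip flags come from the CIGAR ends; barcodes-at-both-ends is read
    from an optional ``XB:i`` tag (1 = both ends), defaulting to True.
    """
    import pysam

    frags: list[Fragment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.cigarstring is None:
                continue
            ops = read.cigartuples
            frags.append(
                Fragment(
                    chrom=read.reference_name,
                    start=read.reference_start,
                    end=read.reference_end,
                    length=fragment_length_from_cigar(read.cigarstring),
                    mapq=read.mapping_quality,
                    strand="-" if read.is_reverse else "+",
                    is_primary=not (read.is_secondary or read.is_supplementary),
                    softclip_start=ops[0][0] == 4,
                    softclip_end=ops[-1][0] == 4,
                    barcode_both_ends=bool(read.get_tag("XB")) if read.has_tag("XB") else True,
                )
            )
    return frags
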