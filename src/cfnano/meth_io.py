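"""Per-CpG methylation IO: modbam2bed-dialect BED parsing, strand collapsing
onto array probes, coverage downsampling and bedgraph round-tripping.

All coordinates are 0-based half-open.  A CpG observed with zero confident
reads is absent, never carried with a sentinel beta.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Number of CpG dinucleotides in the human genome used to convert an average
#: genomic coverage into an observation count when downsampling.
N_CPGS_GENOME = 28_217_005


class ModbedParseError(ValueError):
    """A malformed line in a modbam2bed-dialect BED file."""


@dataclass(frozen=True, order=True)
class CpGCall:
    """One strand-specific CpG observation set.

    ``beta`` is the fraction of reads calling the cytosine methylated, in
    [0, 1].  A call with ``n_reads == 0`` is never constructed; zero-coverage
    positions are dropped at parse time.
    """

    chrom: str
    pos: int
    strand: str
    n_reads: int
    beta: float

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError(f"CpGCall requires n_reads >= 1, got {self.n_reads}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta outside [0,1]: {self.beta}")
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")

    @property
    def n_methylated(self) -> int:
        """Integer methylated-read count reconstructed from the stored fraction."""
        return int(round(self.beta * self.n_reads))


@dataclass(frozen=True)
class ProbeBeta:
    """Unstranded beta value for one array probe (both CpG strands combined)."""

    probe_id: str
    beta: float
    n_reads: int


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_modbed(lines: Iterable[str]) -> list[CpGCall]:
    """Parse modbam2bed-dialect BED lines into :class:`CpGCall` records.

    The dialect stores the read count implicitly: column 5 is a score,
    column 10 the coverage field, and the confident read count is
    ``round(col5 * col10 / 1000)``.  Column 11 is the percent of reads
    methylated.  Positions with zero confident reads are dropped.
    """
    calls: list[CpGCall] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ModbedParseError(
                f"line {lineno}: expected >= 11 tab-separated columns, got {len(fields)}"
            )
        try:
            chrom = fields[0]
            pos = int(fields[1])
            strand = fields[5]
            col5 = float(fields[4])
            col10 = float(fields[9])
            col11 = float(fields[10])
        except ValueError as exc:
            raise ModbedParseError(f"line {lineno}: {exc}") from None
        if not (0.0 <= col11 <= 100.0):
            raise ModbedParseError(
                f"line {lineno}: percent methylated {col11} outside [0, 100]"
            )
        if strand not in ("+", "-"):
            raise ModbedParseError(f"line {lineno}: bad strand {strand!r}")
        n_reads = int(round(col5 * col10 / 1000.0))
        if n_reads == 0:
            continue
        calls.append(CpGCall(chrom, pos, strand, n_reads, col11 / 100.0))
    return sorted(calls, key=lambda c: (c.chrom, c.pos, c.strand))


def read_modbed(path) -> list[CpGCall]:
    with _open_text(path) as handle:
        return parse_modbed(handle)


def read_probe_map(path) -> dict[str, tuple[str, int]]:
    """Read a probe map TSV (probe_id, chrom, pos of the forward-strand C).

    The reverse-strand C of the same CpG sits at ``pos + 1``.
    """
    probe_map: dict[str, tuple[str, int]] = {}
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            probe_id, chrom, pos = line.rstrip("\n").split("\t")[:3]
            probe_map[probe_id] = (chrom, int(pos))
    _validate_probe_map(probe_map)
    return probe_map


def _validate_probe_map(probe_map: Mapping[str, tuple[str, int]]) -> None:
    seen: dict[tuple[str, int], str] = {}
    for probe_id, (chrom, pos) in probe_map.items():
        for p in (pos, pos + 1):
            key = (chrom, p)
            if key in seen and seen[key] != probe_id:
                raise ValueError(
                    f"probe map position collision at {chrom}:{p} "
                    f"between {seen[key]} and {probe_id}"
                )
            seen[key] = probe_id


def collapse_strands(
    calls: Sequence[CpGCall], probe_map: Mapping[str, tuple[str, int]]
) -> list[ProbeBeta]:
    """Combine the two strands of each CpG into one unstranded probe beta.

    Per strand the methylated read count is reconstructed as
    ``round(beta * n_reads)``; the probe beta is the summed methylated count
    over the summed total count.  A probe covered on one strand only uses that
    strand alone; probes with no covered strand are absent from the output.
    """
    _validate_probe_map(probe_map)
    by_pos: dict[tuple[str, int], CpGCall] = {}
    for call in calls:
        by_pos[(call.chrom, call.pos)] = call
    out: list[ProbeBeta] = []
    for probe_id in sorted(probe_map):
        chrom, pos = probe_map[probe_id]
        n_total = 0
        m_total = 0
        for p in (pos, pos + 1):
            call = by_pos.get((chrom, p))
            if call is not None:
                n_total += call.n_reads
                m_total += call.n_methylated
        if n_total > 0:
            out.append(ProbeBeta(probe_id, m_total / n_total, n_total))
    return out


def downsample_coverage(
    calls: Sequence[CpGCall],
    target_cov: float,
    n_cpgs_genome: int = N_CPGS_GENOME,
    seed: int | np.random.Generator | None = None,
) -> list[CpGCall]:
    """Downsample to an average genomic coverage by resampling observations.

    Every read at every CpG is one observation; a call contributes ``n_reads``
    observations of which ``round(beta * n_reads)`` are methylated.  Exactly
    ``k = round(target_cov * n_cpgs_genome)`` observations are drawn uniformly
    without replacement; per-CpG counts and betas are recomputed from the
    drawn observations.  If ``k`` is at least the available total the input is
    returned unchanged.
    """
    if target_cov <= 0:
        raise ValueError(f"target_cov must be > 0, got {target_cov}")
    rng = np.random.default_rng(seed)
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.strand))
    meth = np.array([c.n_methylated for c in calls], dtype=np.int64)
    unmeth = np.array([c.n_reads for c in calls], dtype=np.int64) - meth
    total = int(meth.sum() + unmeth.sum())
    if total < 1:
        raise ValueError("no observations to downsample")
    k = int(round(target_cov * n_cpgs_genome))
    if k >= total:
        return list(calls)
    # Sampling k observations without replacement from the pooled library is a
    # multivariate hypergeometric draw over the 2*n (CpG, state) pools.
    colors = np.concatenate([meth, unmeth])
    drawn = rng.multivariate_hypergeometric(colors, k, method="marginals")
    new_meth = drawn[: len(calls)]
    new_unmeth = drawn[len(calls):]
    out: list[CpGCall] = []
    for call, m, u in zip(calls, new_meth, new_unmeth):
        n = int(m + u)
        if n == 0:
            continue
        out.append(CpGCall(call.chrom, call.pos, call.strand, n, m / n))
    return out


def write_bedgraph(records, path_or_handle) -> None:
    """Write betas as a 4-column bedgraph (chrom, start, start+1, beta).

    Records must already be sorted by (chrom, pos); unsorted input is an
    error.  Betas are written with six decimal places so that a write/read
    round trip is bit-exact at that precision.
    """
    rows = []
    for rec in records:
        if isinstance(rec, CpGCall):
            rows.append((rec.chrom, rec.pos, rec.beta))
        else:
            chrom, pos, beta = rec
            rows.append((chrom, int(pos), float(beta)))
    keys = [(chrom, pos) for chrom, pos, _ in rows]
    if keys != sorted(keys):
        raise ValueError("bedgraph records must be sorted by (chrom, pos)")
    own = not hasattr(path_or_handle, "write")
    handle = open(path_or_handle, "wt") if own else path_or_handle
    try:
        for chrom, pos, beta in rows:
            handle.write(f"{chrom}\t{pos}\t{pos + 1}\t{beta:.6f}\n")
    finally:
        if own:
            handle.close()


def read_bedgraph(path_or_handle) -> list[tuple[str, int, float]]:
    """Read a 4-column beta bedgraph into (chrom, pos, beta) tuples."""
    own = not hasattr(path_or_handle, "read")
    handle = _open_text(path_or_handle) if own else path_or_handle
    try:
        out = []
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, _end, beta = line.rstrip("\n").split("\t")[:4]
            out.append((chrom, int(start), float(beta)))
        return out
    finally:
        if own:
            handle.close()
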