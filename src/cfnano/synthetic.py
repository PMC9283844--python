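"""Truth-known synthetic cfDNA data generators.

Each generator emits records with the statistical structure the analysis
stages assume — marker-structured beta atlases, read-sampled plasma
mixtures, copy-number-dependent PMD hypomethylation, bimodal mono/di
nucleosome length mixtures with a tumor short-shift, class-specific 4-mer
end-motif multinomials, and phased-nucleosome coverage around CTCF-like
sites — together with a ``SimTruth`` record so every downstream estimate can
be checked against ground truth.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import ReferenceAtlas
from .fragmentomics import ALL_4MERS, Fragment, reverse_complement
from .meth_io import CpGCall
from .regional_meth import CNSegment, TFBSSite


@dataclass
class SimTruth:
    """Ground truth paired with a generator's output."""

    fractions: dict | None = None
    marker_probes: dict | None = None
    class_labels: list | None = None
    site_effects: dict | None = None
    bin_tumor_proportion: dict | None = None
    end_motifs: list | None = None
    params: dict = field(default_factory=dict)


@dataclass
class FragmentLengthParams:
    """Mono/di-nucleosome length mixture, per class.

    Healthy plasma fragments peak at the chromatosome length (~167 bp) with
    a dinucleosome shoulder (~335 bp); tumor-derived fragments are shifted
    ~20-30 bp shorter in both classes.
    """

    healthy_mono_mode: float = 167.0
    healthy_mono_sd: float = 12.0
    tumor_mono_mode: float = 147.0
    tumor_mono_sd: float = 12.0
    healthy_di_mode: float = 335.0
    healthy_di_sd: float = 25.0
    tumor_di_mode: float = 305.0
    tumor_di_sd: float = 25.0
    mono_weight: float = 0.85


def default_motif_probs(ccca: float = 0.019) -> np.ndarray:
    """A 256-motif multinomial with CCCA set to ``ccca`` and the remaining
    mass spread uniformly (healthy plasma has CCCA ~ 1.9%, tumor ~ 1.7%)."""
    probs = np.full(256, (1.0 - ccca) / 255.0)
    probs[ALL_4MERS.index("CCCA")] = ccca
    return probs


def simulate_atlas(
    n_components: int = 5,
    n_probes: int = 12_000,
    markers_per_component: int = 1000,
    noise_sd: float = 0.02,
    seed=None,
) -> tuple[ReferenceAtlas, SimTruth]:
    """Synthetic reference atlas with planted hypo/hyper marker probes.

    Each component owns ``markers_per_component`` hypomethylated (beta ~ 0.1)
    and hypermethylated (beta ~ 0.9) marker probes against a 0.5 background,
    plus truncated-Gaussian beta noise.  The default marker count matches the
    top-1000-per-direction selection used for real-atlas deconvolution.
    """
    rng = np.random.default_rng(seed)
    needed = 2 * markers_per_component * n_components
    if n_probes < needed:
        raise ValueError(f"need >= {needed} probes for the requested markers")
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    comps = [f"celltype_{k}" for k in range(n_components)]
    betas = np.full((n_probes, n_components), 0.5)
    marker_probes: dict[str, dict[str, list[str]]] = {}
    cursor = 0
    for k, comp in enumerate(comps):
        hypo = list(range(cursor, cursor + markers_per_component))
        cursor += markers_per_component
        hyper = list(range(cursor, cursor + markers_per_component))
        cursor += markers_per_component
        betas[hypo, k] = 0.1
        betas[hyper, k] = 0.9
        marker_probes[comp] = {
            "hypo": [probe_ids[i] for i in hypo],
            "hyper": [probe_ids[i] for i in hyper],
        }
    if noise_sd > 0:
        betas = np.clip(betas + rng.normal(0, noise_sd, betas.shape), 0.0, 1.0)
    atlas = ReferenceAtlas(pd.DataFrame(betas, index=probe_ids, columns=comps))
    return atlas, SimTruth(
        marker_probes=marker_probes,
        params={"n_components": n_components, "noise_sd": noise_sd},
    )


def probe_positions(atlas: ReferenceAtlas, chrom: str = "chr1") -> dict[str, tuple[str, int]]:
    """Deterministic synthetic genomic placement of atlas probes: forward C
    of probe i at position 2*i (reverse C at 2*i + 1)."""
    return {p: (chrom, 2 * i) for i, p in enumerate(atlas.probe_ids)}


def simulate_mixture_calls(
    atlas: ReferenceAtlas,
    fractions,
    coverage: float = 30.0,
    seed=None,
) -> tuple[list[CpGCall], SimTruth]:
    """Read-sampled plasma mixture of the atlas components.

    Per probe the read count is Poisson(``coverage``); each read comes from
    component k with probability ``fractions[k]`` and is methylated with
    probability that component's probe beta.  Emitted as forward-strand
    CpG calls at the :func:`probe_positions` placement.
    """
    rng = np.random.default_rng(seed)
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise ValueError("fractions must be a simplex weight vector")
    betas = np.nan_to_num(atlas.betas.to_numpy(dtype=float), nan=0.5)
    n_probes, n_comp = betas.shape
    pos_map = probe_positions(atlas)
    n_reads = rng.poisson(coverage, n_probes)
    # reads per (probe, component), then methylated reads per cell
    comp_counts = rng.multinomial(n_reads, fractions)
    meth = rng.binomial(comp_counts, betas).sum(axis=1)
    calls: list[CpGCall] = []
    for i, probe in enumerate(atlas.probe_ids):
        n = int(n_reads[i])
        if n == 0:
            continue
        chrom, pos = pos_map[probe]
        calls.append(CpGCall(chrom, pos, "+", n, int(meth[i]) / n))
    truth = SimTruth(
        fractions={c: f for c, f in zip(atlas.component_names, fractions)},
        params={"coverage": coverage},
    )
    return calls, truth


def mixture_probe_betas(calls, atlas: ReferenceAtlas) -> pd.Series:
    """Collapse simulated mixture calls back onto probe ids (forward-strand
    placement, so this is a direct position lookup)."""
    pos_map = {v: k for k, v in probe_positions(atlas).items()}
    data = {
        pos_map[(c.chrom, c.pos)]: c.beta
        for c in calls
        if (c.chrom, c.pos) in pos_map
    }
    return pd.Series(data, dtype=float)


def local_tumor_proportion(copy_number: float, tumor_fraction: float) -> float:
    """Proportion of tumor-derived DNA in a region where the tumor genome
    carries ``copy_number`` copies: ``c*tf / (c*tf + 2*(1 - tf))``."""
    c, tf = copy_number, tumor_fraction
    denom = c * tf + 2.0 * (1.0 - tf)
    return c * tf / denom if denom > 0 else 0.0


def simulate_pmd_genome(
    tumor_fraction: float = 0.3,
    beta_healthy_pmd: float = 0.8,
    beta_tumor_pmd: float = 0.4,
    n_bins: int = 30,
    cpgs_per_bin: int = 50,
    background_ratio: float = 20.0,
    coverage: float = 6.0,
    cn_states=(1, 2, 3),
    bin_size: int = 10_000_000,
    seed=None,
) -> tuple[list[CpGCall], list[CNSegment], list[tuple[str, int, int]], set, SimTruth]:
    """PMD genome with copy-number-dependent hypomethylation.

    Bins cycle through tumor copy numbers ``cn_states``.  A bin with copy
    number c has local tumor proportion p = c*tf / (c*tf + 2(1-tf)); its
    solo-WCGW CpGs have expected beta ``(1-p)*beta_healthy + p*beta_tumor``
    with binomial read sampling at Poisson(``coverage``) depth.  Non-PMD
    background CpGs — ``background_ratio`` of them per solo-WCGW CpG, as in
    a real genome where PMD solo-WCGW CpGs are a small minority — keep
    ``beta_healthy_pmd`` in both genomes, anchoring the genome-wide mean.
    Matching segments carry ``log2ratio = log2((c*tf + 2(1-tf)) / 2)``.

    Returns (calls, segments, pmd_bins, solo_wcgw_positions, truth).
    """
    rng = np.random.default_rng(seed)
    tf = tumor_fraction
    calls: list[CpGCall] = []
    segments: list[CNSegment] = []
    pmd_bins: list[tuple[str, int, int]] = []
    solo: set[tuple[str, int]] = set()
    bin_p: dict[tuple[str, int], float] = {}
    chrom = "chr1"

    def sample_calls(positions, expected_beta):
        depth = rng.poisson(coverage, len(positions))
        for pos, n in zip(positions, depth):
            if n == 0:
                continue
            m = rng.binomial(n, expected_beta)
            calls.append(CpGCall(chrom, int(pos), "+", int(n), m / n))

    for b in range(n_bins):
        start = b * bin_size
        end = start + bin_size
        c = cn_states[b % len(cn_states)]
        p = local_tumor_proportion(c, tf)
        expected = (1.0 - p) * beta_healthy_pmd + p * beta_tumor_pmd
        positions = start + rng.choice(bin_size, size=cpgs_per_bin, replace=False)
        for pos in positions:
            solo.add((chrom, int(pos)))
        sample_calls(sorted(positions), expected)
        pmd_bins.append((chrom, start, end))
        mixture_copies = c * tf + 2.0 * (1.0 - tf)
        segments.append(CNSegment(chrom, start, end, float(np.log2(mixture_copies / 2.0))))
        bin_p[(chrom, start)] = p
    # background (non-PMD, non-solo) CpGs on a separate chromosome
    bg_chrom = "chr2"
    background_cpgs = int(round(background_ratio * n_bins * cpgs_per_bin))
    bg_positions = np.sort(rng.choice(n_bins * bin_size, size=background_cpgs, replace=False))
    depth = rng.poisson(coverage, background_cpgs)
    for pos, n in zip(bg_positions, depth):
        if n == 0:
            continue
        m = rng.binomial(n, beta_healthy_pmd)
        calls.append(CpGCall(bg_chrom, int(pos), "+", int(n), m / n))
    truth = SimTruth(
        bin_tumor_proportion=bin_p,
        params={
            "tumor_fraction": tf,
            "beta_healthy_pmd": beta_healthy_pmd,
            "beta_tumor_pmd": beta_tumor_pmd,
            "cn_states": tuple(cn_states),
        },
    )
    return calls, segments, pmd_bins, solo, truth


def simulate_fragments(
    n_fragments: int = 2000,
    tumor_proportion: float = 0.0,
    length_params: FragmentLengthParams | None = None,
    motif_probs_healthy: np.ndarray | None = None,
    motif_probs_tumor: np.ndarray | None = None,
    chrom: str = "chrS",
    seed=None,
) -> tuple[list[Fragment], dict[str, str], SimTruth]:
    """Fragment set with class-dependent lengths and planted end motifs.

    Lengths come from a mono/di normal mixture per class (tumor modes
    shifted shorter); each fragment's 4-mer end motif is drawn from its
    class multinomial and written into a synthetic reference so that
    :func:`cfnano.fragmentomics.end_motif` re-derives the drawn motif
    exactly, on both strands.

    Returns (fragments, {chrom: sequence}, truth).
    """
    rng = np.random.default_rng(seed)
    lp = length_params or FragmentLengthParams()
    mh = motif_probs_healthy if motif_probs_healthy is not None else default_motif_probs(0.019)
    mt = motif_probs_tumor if motif_probs_tumor is not None else default_motif_probs(0.017)
    is_tumor = rng.random(n_fragments) < tumor_proportion
    is_di = rng.random(n_fragments) >= lp.mono_weight
    modes = np.where(
        is_di,
        np.where(is_tumor, lp.tumor_di_mode, lp.healthy_di_mode),
        np.where(is_tumor, lp.tumor_mono_mode, lp.healthy_mono_mode),
    )
    sds = np.where(
        is_di,
        np.where(is_tumor, lp.tumor_di_sd, lp.healthy_di_sd),
        np.where(is_tumor, lp.tumor_mono_sd, lp.healthy_mono_sd),
    )
    lengths = np.maximum(np.round(rng.normal(modes, sds)).astype(int), 50)
    strands = np.where(rng.random(n_fragments) < 0.5, "+", "-")
    motif_idx = np.where(
        is_tumor,
        rng.choice(256, n_fragments, p=mt),
        rng.choice(256, n_fragments, p=mh),
    )
    spacing = 720  # > max length + motif window; fragments never overlap
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(
        base_codes[rng.integers(0, 4, n_fragments * spacing + spacing)].tobytes()
    )
    fragments: list[Fragment] = []
    drawn_motifs: list[str] = []
    for i in range(n_fragments):
        start = i * spacing
        end = start + int(lengths[i])
        motif = ALL_4MERS[motif_idx[i]]
        drawn_motifs.append(motif)
        if strands[i] == "+":
            seq[start : start + 4] = motif.encode()
        else:
            seq[end - 4 : end] = reverse_complement(motif).encode()
        fragments.append(
            Fragment(
                chrom=chrom,
                start=start,
                end=end,
                length=int(lengths[i]),
                mapq=60,
                strand=str(strands[i]),
            )
        )
    reference = {chrom: seq.decode("ascii")}
    truth = SimTruth(
        class_labels=["tumor" if t else "healthy" for t in is_tumor],
        end_motifs=drawn_motifs,
        params={"tumor_proportion": tumor_proportion},
    )
    return fragments, reference, truth


def simulate_ctcf_coverage(
    n_sites: int = 30,
    spacing: int = 190,
    n_phased: int = 5,
    depletion_depth: float = 1.0,
    fragments_per_nucleosome: int = 12,
    background_per_site: int = 600,
    fragment_length: int = 142,
    jitter_sd: float = 8.0,
    site_spacing: int = 12_000,
    chrom: str = "chrC",
    seed=None,
) -> tuple[list[Fragment], list[TFBSSite], SimTruth]:
    """Phased-nucleosome coverage around CTCF-like sites.

    Mononucleosome-length fragments are centered at site +/- k*spacing
    (k = 1..n_phased on both sides, with Gaussian jitter), over a uniform
    background spanning the whole chromosome (so the RPGC baseline is the
    genome-average coverage); the central +/- 80 bp of each site is depleted
    of background fragments in proportion to ``depletion_depth``.
    """
    rng = np.random.default_rng(seed)
    sites = [
        TFBSSite(chrom, (i + 1) * site_spacing, "+", 1.0) for i in range(n_sites)
    ]
    site_centers = np.array([s.center for s in sites])
    half = fragment_length // 2
    span = (n_sites + 1) * site_spacing
    fragments: list[Fragment] = []
    for site in sites:
        for k in range(1, n_phased + 1):
            for sign in (-1, 1):
                centers = site.center + sign * k * spacing + rng.normal(
                    0, jitter_sd, fragments_per_nucleosome
                )
                for c in centers:
                    start = int(round(c)) - half
                    fragments.append(
                        Fragment(chrom, start, start + fragment_length,
                                 fragment_length, 60, "+")
                    )
    bg_centers = rng.integers(half, span - half, background_per_site * n_sites)
    nearest = np.clip(np.round(bg_centers / site_spacing), 1, n_sites).astype(int)
    dist_to_site = np.abs(bg_centers - nearest * site_spacing)
    keep = (dist_to_site > 80) | (rng.random(len(bg_centers)) >= depletion_depth)
    for c in bg_centers[keep]:
        start = int(c) - half
        fragments.append(
            Fragment(chrom, start, start + fragment_length,
                     fragment_length, 60, "+")
        )
    truth = SimTruth(
        site_effects={
            "spacing": spacing,
            "n_phased": n_phased,
            "depletion_depth": depletion_depth,
            "nucleosome_offsets": [k * spacing for k in range(1, n_phased + 1)],
        },
        params={"fragment_length": fragment_length},
    )
    return fragments, sites, truth


def simulate_tfbs_methylation(
    n_sites: int = 50,
    signal_fraction: float = 0.5,
    beta_bg: float = 0.85,
    beta_low: float = 0.05,
    cpg_spacing: int = 20,
    half_window: int = 1000,
    dip_halfwidth: int = 200,
    coverage: float = 10.0,
    site_spacing: int = 10_000,
    chrom: str = "chrT",
    seed=None,
) -> tuple[list[CpGCall], list[TFBSSite], SimTruth]:
    """Read-sampled methylation dip around TFBS-like sites.

    CpGs every ``cpg_spacing`` bp across +/- ``half_window`` of each site;
    within +/- ``dip_halfwidth`` the expected beta is the two-component
    mixture ``(1-f)*beta_bg + f*beta_low`` with f = ``signal_fraction``,
    ``beta_bg`` outside.
    """
    rng = np.random.default_rng(seed)
    sites = [TFBSSite(chrom, (i + 2) * site_spacing, "+", 1.0) for i in range(n_sites)]
    calls: list[CpGCall] = []
    for site in sites:
        for offset in range(-half_window, half_window + 1, cpg_spacing):
            expected = (
                (1.0 - signal_fraction) * beta_bg + signal_fraction * beta_low
                if abs(offset) <= dip_halfwidth
                else beta_bg
            )
            n = int(rng.poisson(coverage))
            if n == 0:
                continue
            m = rng.binomial(n, expected)
            calls.append(CpGCall(chrom, site.center + offset, "+", n, m / n))
    calls.sort(key=lambda c: (c.chrom, c.pos))
    truth = SimTruth(
        site_effects={
            "signal_fraction": signal_fraction,
            "beta_bg": beta_bg,
            "beta_low": beta_low,
            "dip_halfwidth": dip_halfwidth,
            "expected_center_fold": ((1 - signal_fraction) * beta_bg
                                     + signal_fraction * beta_low) / beta_bg,
        }
    )
    return calls, sites, truth
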