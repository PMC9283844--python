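# cfnano

Analysis of cell-free DNA (cfDNA) from native Nanopore whole-genome
sequencing: cell-type and tumor-fraction deconvolution from CpG methylation,
partially-methylated-domain (PMD) hypomethylation, transcription-factor
binding site (TFBS) methylation metaplots, fragment-length and end-motif
statistics, and nucleosome-coverage profiling — together with truth-known
synthetic generators so every stage is testable without access to patient
sequencing data.

It is aimed at liquid-biopsy method developers who want the standard
shallow-WGS cfDNA read-outs (tissue of origin, circulating tumor DNA
burden, fragmentomics) as composable, tested library functions over plain
text formats (stranded methylation BED, bedgraph, fragment TSV/SAM, BED
intervals, SEG copy-number segments, atlas CSV).

## The models

**Methylation deconvolution.**  A plasma methylome Y (per-CpG beta values
collapsed onto array probes) is modelled as a non-negative mixture of
reference cell-type methylomes X:

    β̂ = argmin_β ‖Xβ − Y‖₂  s.t.  β ≥ 0        (NNLS)

with cell-type fractions β̂/Σβ̂, fitted on the union of top-ranked
hyper-/hypomethylated marker CpGs per cell type.  A two-component variant
(target tissue X̄₁ vs healthy plasma X̄₂) reports the tissue fraction
β₁/(β₁+β₂); bulk tumor references are first purity-corrected by inverting
the mixing equation M_m = M_c·β + M_l·(1−β).

**PMD hypomethylation.**  Tumor-derived DNA hypomethylates solo-WCGW CpGs
inside PMDs.  Each 10-Mbp bin overlapping a PMD is scored as
Δ = mean solo-WCGW beta − genome-wide mean beta, stratified by copy-number
status (gain/neutral/loss from segment log2 ratios at ±0.10), because a
region at tumor copy number c carries tumor-DNA proportion
p = c·tf / (c·tf + 2(1−tf)) — amplified regions hypomethylate deeper.

**Fragmentomics.**  Short-mononucleosome (100–150 / 100–220 bp) and
short-dinucleosome (275–325 / 275–400 bp) ratios rise with circulating
tumor DNA; 4-mer end motifs, read from the reference at the fragment 5′
end, shift in composition (CCCA depletion) in cancer.

**Nucleosome coverage.**  130–155 bp fragments, RPGC-normalised (genome
mean 1), profiled around reference points (CTCF sites) reveal the central
nucleosome eviction and ~190-bp phasing.

## Worked example

```python
import numpy as np
from cfnano import synthetic
from cfnano.deconvolution import nnls_fractions
from cfnano.fragmentomics import short_mono_ratio, short_di_ratio

# a 5-cell-type atlas and a read-sampled plasma mixture at 30x per CpG
atlas, _ = synthetic.simulate_atlas(n_components=5, seed=7)
w = [0.05, 0.10, 0.25, 0.60, 0.0]          # true fractions
calls, _ = synthetic.simulate_mixture_calls(atlas, w, coverage=30, seed=8)
sample = synthetic.mixture_probe_betas(calls, atlas)

result = nnls_fractions(sample, atlas)
print(result.summary().round(4))

healthy, _, _ = synthetic.simulate_fragments(20000, tumor_proportion=0.0, seed=9)
tumor, _, _ = synthetic.simulate_fragments(20000, tumor_proportion=0.5, seed=10)
for name, frags in [("healthy", healthy), ("tumor 50%", tumor)]:
    L = [f.length for f in frags]
    print(f"{name}: short-mono {short_mono_ratio(L):.3f}  short-di {short_di_ratio(L):.3f}")
```

prints

```
            coefficient  fraction
celltype_3       0.5989    0.5977
celltype_2       0.2499    0.2494
celltype_1       0.0987    0.0985
celltype_0       0.0545    0.0544
celltype_4       0.0000    0.0000
healthy: short-mono 0.085  short-di 0.348
tumor 50%: short-mono 0.354  short-di 0.570
```

The recovered fractions match the planted (0.60, 0.25, 0.10, 0.05, 0)
mixture to within the 30×-coverage sampling noise, and both fragment-length
ratios rise sharply when half the fragments are tumor-derived.

A command-line interface mirrors the library (`cfnano simulate | deconvolve
| pmd | tfbs | fragmentomics | endmotifs | ctcf`); every subcommand writes
TSV outputs plus a JSON parameter echo and is deterministic given `--seed`.

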