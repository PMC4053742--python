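# caninecnv

Copy-number-variant discovery, genotyping and population analysis from
array-CGH log2 ratios, built around the study design used for genome-wide
CNV surveys of domestic dog breeds: tens of samples from many breeds
hybridized against one male reference on a ~1 kb probe grid.

The package is aimed at analysts who have per-probe log2 test/reference
ratios (or want to simulate them) and need the full path from raw ratios
to population-level statements: which loci vary, who carries what, how
variation is apportioned among breeds, and what sequence features sit at
CNV breakpoints.

## What it computes

**Calling.** Per-chromosome centering (median baseline; the X chromosome's
pseudo-autosomal region is centered separately against the male
reference), 11-point triangular smoothing, and exact fused-lasso
segmentation — minimize ½Σ(yᵢ−βᵢ)² + λ₁Σ|βᵢ| + λ₂Σ|βᵢ−βᵢ₋₁| — followed by
a three-stage selection: per-sample discovery at a stringent threshold,
cross-sample merging of overlapping calls into loci (breakpoints are the
outermost call boundaries), and per-sample genotyping at a lenient
threshold. Both thresholds combine a fixed copy-deviation cutoff (0.65
copies for discovery, 0.5 for genotyping) with a variance-adaptive cutoff
(σ·Φ⁻¹(1−q/2), q = 0.1% / 5%) per sample and chromosome; discovery takes
the max of the two, genotyping the min. Copy number is 2^(1+m̄) rounded to
an integer; samples whose mean signal is small but whose mean |signal| is
large are genotyped *complex* (unresolved adjacent deletion+duplication).
Calls need ≥10 consecutive probes (~9 kb at 1 kb spacing).

**Population analysis.** Breed summaries (multi-breed vs breed-specific,
polymorphic vs fixed, private loci), folded site-frequency spectra with
the minor allele fixed from the two-sample breeds, loci fixed for
alternative states between breeds, pairwise state-mismatch distances, and
Saitou–Nei neighbor-joining trees (exact on additive distances).

**Breakpoint features.** GC-peak detection (500 bp window ≥1.5× its 10 kb
background), annotation enrichment in 10 kb breakpoint windows against
per-chromosome randomization nulls, repeat-family excess tables,
longest-perfect-homology scans between breakpoint windows (suffix
automaton) with a simulated null, gene-overlap classification
(intergenic / whole-gene / partial, stop-codon removal), and bootstrap
comparisons between segmental-duplication strata.

**Simulation.** A generator that emulates the whole study — jittered probe
grid, 430 implanted loci in a 226:104:100 deletion:duplication:both mix
with breed-structured sharing, per-block Gaussian noise, and a synthetic
genome with planted GC peaks, repeats and breakpoint homology — and
returns the ground truth for validation.

## Worked example

```python
import numpy as np
from caninecnv import (
    SimLayout, SimNoise, build_probe_grid, draw_truth_set,
    render_ratio_matrix, center_by_chromosome,
    SegmentationParams, segment_matrix, call_cnvs,
)
from caninecnv.preprocess import smooth_matrix

layout = SimLayout(
    chromosomes=[(f"chr{i+1}", 2_000_000) for i in range(5)],
    samples=[(f"B{b}_{i}", f"B{b}", "M") for b in range(10) for i in range(2)],
    seed=11,
)
probes = build_probe_grid(layout)
truth = draw_truth_set(layout, n_loci=60, seed=12)
ratios = render_ratio_matrix(probes, truth, SimNoise(sd=0.1), seed=13, layout=layout)

centered = center_by_chromosome(ratios)
smoothed = smooth_matrix(centered)
segments = segment_matrix(smoothed, SegmentationParams())
loci, genotypes = call_cnvs(smoothed, segments, raw=centered)

print(len(loci), "loci:", loci["class"].value_counts().to_dict())
first = loci.locus_id.iloc[0]
print(genotypes[genotypes.locus_id == first]
      .query("state != 'ref'")[["sample", "state", "cn"]])
```

prints

```
56 loci: {'deletion': 32, 'duplication': 15, 'both': 9}
   sample state  cn
6    B3_0   del   1
14   B7_0   del   1
```

— 56 CNV loci called from the 60 implanted (the remainder fall under the
10-probe rule or are carried only as unresolved complex events), split
into deletion/duplication/both classes, and for the first locus the two
non-reference samples, both hemizygous deletions (`cn = 1`; complex
samples would show state `complex` with no copy number).

The same pipeline is available from the shell:

```sh
caninecnv simulate --outdir study/
caninecnv preprocess --ratios study/ratios.tsv --samples study/samples.tsv \
    --out study/smoothed.tsv --out-centered study/centered.tsv
caninecnv segment --smoothed study/smoothed.tsv --samples study/samples.tsv --out study/segments.tsv
caninecnv call --smoothed study/smoothed.tsv --segments study/segments.tsv \
    --samples study/samples.tsv --centered study/centered.tsv \
    --out-loci study/loci.bed --out-genotypes study/genotypes.tsv
caninecnv summarize --genotypes study/genotypes.tsv --samples study/samples.tsv --out-prefix study/pop
caninecnv features --loci study/loci.bed --genome study/genome.fa \
    --repeats study/repeats.tsv --genes study/genes.tsv --out-prefix study/bp
```

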