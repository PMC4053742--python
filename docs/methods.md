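# Methods

This note documents the models, numerical procedures and design choices
behind `caninecnv`, in the order the pipeline applies them.

## Signal model

Array-CGH reports, per probe, the log2 ratio of a test sample's
hybridization intensity to a common reference sample. For a diploid
reference, a segment at true copy number `c` has expected log2 ratio
`log2(c/2)`: a hemizygous deletion sits at −1, a three-copy duplication at
+0.585, a four-copy gain at +1. Copy number is recovered from a called
segment as `2^(1 + m)` with `m` the mean log2 ratio, rounded half away
from zero. Homozygous deletions (`c = 0`) are rendered and modelled at a
finite floor of −4 rather than −∞, since array signal saturates.

## Preprocessing

Each (sample, chromosome) block is centered to remove per-chip intensity
biases; the default location statistic is the *median*, which aligns the
diploid baseline at zero without being dragged by the block's own CNV
signal (a sample carrying several deletions — worst of all a homozygous
deletion rendered at −4 — shifts the block mean enough on compact
chromosomes to bias every other locus's genotype; `stat="mean"` restores
plain mean removal, equivalent on CNV-sparse chromosomes). The X
chromosome is split at the
pseudo-autosomal boundary and the two parts centered separately, because
against a male reference the pseudo-autosomal region is diploid in every
sample while the rest of X differs by sex. When female samples are
present the boundary can be estimated: each female's raw X ratios show a
single step (one extra copy beyond the PAR), located by an exhaustive
two-segment least-squares changepoint scan, and the per-female positions
are averaged.

Ratios are then smoothed with an 11-point triangular filter, weights
(1,2,…,6,…,2,1)/36. At chromosome ends the window is truncated and the
weights renormalized — zero-padding would shrink telomeric signal toward
zero. Smoothing never crosses a chromosome boundary. The smoothed values
feed segmentation, thresholding and all downstream means; the centered
raw values are retained for breakpoint refinement (below).

## Segmentation

Segmentation fits the fused-lasso signal approximator: minimize
½Σ(yᵢ−βᵢ)² + λ₁Σ|βᵢ| + λ₂Σ|βᵢ−βᵢ₋₁|. The solution is piecewise constant;
maximal runs of equal β are the segments. The total-variation part is
solved exactly by a dynamic program on the derivative of the running
value function: the derivative is piecewise linear and nondecreasing,
each data term adds a unit-slope line, the inf-convolution with λ₂|·|
clips it to ±λ₂, and backtracking through the recorded clip positions
recovers β. The λ₁ part separates for the identity design and is applied
as elementwise soft-thresholding of the fused fit. λ₁ defaults to 0:
discovery thresholds, not sparsity, decide calls, which keeps
segmentation and selection responsibilities separate.

The test suite checks the solver against an independent oracle — the
box-constrained dual least-squares problem solved by
`scipy.optimize.lsq_linear` — to 1e−8 on random inputs up to n = 200.

λ₂ = "auto" uses a universal-threshold rule, λ₂ = ½·σ·√(2 log n) with σ
the block standard deviation of the smoothed values. At this scale noise
fluctuations fuse into long flat runs while jumps of the magnitude the
calling thresholds target (≥ 0.32 in log2 units) survive. We initially
tried selecting λ₂ by stability of the changepoint count under a
residual sign-flip refit, but that criterion is satisfied trivially at
very small λ₂ (both fits chase noise equally), so the direct rule was
adopted.

Segment *boundaries* come from β; segment *levels* used by the caller are
re-estimated as the data mean over each run, the standard post-fused-lasso
refit. The shrinkage of the raw β levels (λ₂ divided by run length)
otherwise pushes three-copy duplications — expected +0.585, barely above
the 0.567 discovery cutoff — below threshold.

## Calling: discovery, merging, genotyping

Thresholds are set per (sample, chromosome) block and per direction, each
as a combination of a fixed copy-deviation cutoff and a variance-adaptive
cutoff:

* fixed cutoffs: a 0.65-copy deviation for discovery
  (gain log2(2.65/2) = 0.406, loss |log2(1.35/2)| = 0.567) and a 0.5-copy
  deviation for genotyping (0.322 / 0.415). They are asymmetric because
  log2 is nonlinear in copies.
* adaptive cutoffs: σ·Φ⁻¹(1 − q/2) with q = 0.1% (discovery) and 5%
  (genotyping) — two-tailed, since calls occur in both directions.
* discovery threshold = max(fixed, adaptive); genotyping = min(fixed,
  adaptive). Noisy blocks therefore discover conservatively; quiet blocks
  genotype leniently. Discovery ≥ genotyping is asserted per block.

σ is estimated robustly as MAD/Φ⁻¹(¾) of the block's smoothed values. On
compact synthetic chromosomes a sample's own CNVs would inflate a naive
standard deviation enough for the adaptive threshold to mask the very
signal it guards; the MAD estimates the noise bulk — the "theoretical
normal distribution" the thresholds refer to — unaffected by the CNV
tails. `sigma_estimator="std"` restores the naive estimate.

Discovery works per sample with hysteresis: segments whose level reaches
the lenient fixed genotyping cutoff are candidates; maximal runs of
adjacent same-sign candidates form one putative call; the call is emitted
if its pooled mean passes the stringent discovery threshold and it spans
at least 10 probes (the min-probe rule that sets the ~9 kb resolution
floor at 1 kb spacing). The two-level rule keeps a mid-locus dip from
splitting a single event without letting long near-zero stretches dilute
real signal.

Each call edge is then refined by an exhaustive single-changepoint fit on
the centered raw values in a ±6-probe window around the provisional edge.
Smoothing spreads each true edge symmetrically over the filter width, so
segment edges land 1–3 probes outside the event; the raw step is sharp
and the refit restores probe-level boundaries.

Calls from all samples are merged by single-linkage chaining of ≥1 bp
overlaps (half-open intervals: abutting calls stay separate). Locus
boundaries are the outermost boundaries of contributing calls. Every
sample is genotyped at every locus: with `m` the mean smoothed log2 over
the locus and `a` the mean absolute value, `m` beyond a genotyping cutoff
gives dup/del; otherwise `a` beyond the smaller cutoff gives *complex* —
the signature of adjacent deletion+duplication that segmentation did not
resolve (mean near zero, deviation large); otherwise ref. Mean |value|
was chosen over RMS for "deviation from zero"; both readings are
monotone in each other for the cases that matter. Complex samples get no
copy number. A locus is classed deletion / duplication / both from its
simple non-ref states; complex samples flag the locus complex but only
decide the class (both) when no simple non-ref state exists.

## Population analyses

A sample is a carrier at a locus when its state differs from ref. Breed
summaries count, per breed: loci carried by ≥1 sample (total), split into
multi-breed vs breed-specific and into polymorphic (some samples) vs
fixed (all samples), with private splits; the identities
total = MB + BS = polymorphic + fixed are asserted on every run. The
site frequency spectrum fixes each locus's minor allele from the
two-sample-breed samples (the rarer of ref/carrier; ties go to carrier)
and histograms minor-allele counts either across all two-sample breeds or
within one breed. Fixed differences between breeds are loci where every
two-sample breed is internally monomorphic in exact state and at least
two states occur across breeds.

Pairwise distance between samples is the fraction of loci with unequal
states, complex counting as its own state (the literal reading of
"pairwise differences at all loci"). Neighbor joining is the standard
Saitou–Nei agglomeration: minimize Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ, ties
broken by the lowest index pair, branch lengths from the usual formulas
with negative lengths clamped to zero and the deficit moved to the sister
edge. NJ is exact on additive distances; the suite verifies topology and
branch lengths against random additive trees and cross-checks against
scikit-bio. Trees can be built at sample level or on breed-averaged
distances. Fisher's exact test (two-sided, minimum-likelihood rule) backs
the contingency comparisons via `scipy.stats.fisher_exact`.

## Breakpoint sequence features

GC peaks: two windows slide together (step 100 bp) — a 10 kb background
window and a 500 bp peak window centered in it. A peak is marked over the
500 bp window when its GC fraction is ≥1.5× the background's; overlapping
marks merge. The background includes the center (exclusion changes the
fold by <3% at these widths); N bases are excluded from numerator and
denominator; the 100 bp step cannot miss a ≥500 bp peak except at fold
margins below ~3%. The scanner is tested against a literal per-offset
brute-force scan.

Breakpoint windows are 10 kb intervals centered on each locus boundary
(clipped at chromosome ends), acknowledging that smoothing and noise
blur the true breakpoint position. Enrichment of annotations in these
windows is tested against a per-chromosome randomization null: each
window keeps its chromosome and length and is redistributed uniformly,
1000 times by default. This redistributes the windows rather than the
features — equivalent under exchangeability and it preserves the window
length spectrum per chromosome. Observed/expected uses the null mean;
empirical p-values carry the (1+x)/(1+reps) correction and are never
zero. Statistics offered: windows overlapping ≥1 feature, feature count
in windows, and feature base coverage in windows (the most nearly
continuous, used for calibration tests). Repeat-family excess normalizes
observed window content by the genome-wide density scaled to the summed
window length; base coverage is the default normalization, counts an
option.

Perfect homology between the two breakpoint windows of a locus is the
longest exact common substring, computed with a suffix automaton
(O(n + m)); N never matches, and a strand-aware option also scans the
reverse complement. The null simulates datasets preserving each locus's
chromosome and breakpoint separation at uniform random positions and
compares dataset means. The suite checks the automaton against an O(nm)
dynamic-programming oracle on 1000 random pairs and checks that both
randomization engines produce Uniform(0,1) p-values under null
constructions (Kolmogorov–Smirnov).

Bootstrap comparisons (percentile CI, two-sided p with floor 1/(reps+1))
back the stratified contrasts of CNVs overlapping segmental duplications
vs not; SD intervals are consumed as input, never detected.

## Synthetic data generator

The generator emulates the statistical structure of a 53-sample,
17-breed + wolves aCGH panel against a male Boxer reference:

* probe grid: floor(length/spacing) probes per chromosome with gaps
  spacing×U(0.5, 1.5), rescaled to fit — reproducing a *median* ~1 kb
  spacing rather than an exact grid;
* truth set: 430 loci by default in a 226:104:100
  deletion:duplication:both mix, log-normal sizes (σ = 0.6) with class
  medians 19/29.5/27.8 kb clipped to [9 kb, 1.6 Mb], placed
  non-overlapping with ≥5 probe spacings between loci so that merging
  cannot chain distinct implants;
* breed sharing: a two-point mixture — with probability 0.21 a locus is
  private to one breed, otherwise a shared carrier frequency drawn from
  Beta(0.9, 2.6) (mean ≈ 0.26) applies across breeds; class-dependent
  fractions of loci (8%, 15%, 42%) carry one complex sample rendered as
  two abutting opposite-sign half-events;
* signal: expected log2 per probe from the truth copy numbers plus
  Gaussian noise, per-(sample, chromosome) sd, optional heavy-tailed
  outliers from a 5×sd Gaussian; female samples get a +1 baseline on
  non-PAR X;
* genome: i.i.d. sequence at 41% GC with planted GC peaks, CpG islands,
  N-gap runs, repeat families copied from a consensus with per-copy
  divergence, exact homology tracts copied into both breakpoint windows
  of chosen loci, and random non-overlapping gene models with
  strand-dependent stop codons.

The noise level is a calibration choice (the real arrays' noise is not
known to us); sd = 0.1 makes the fixed thresholds bind for most blocks,
which is the regime the dual-threshold design targets. What the
generator does *not* emulate: hybridization chemistry, GC-wave artifacts,
dye bias beyond per-chromosome offsets, pedigree inheritance, linkage
between loci, and real genome sequence composition. Passing tests
demonstrate the pipeline's correctness under this model, not performance
on real arrays.

## Problem sizes

Property suites run at sizes chosen to exercise every code path while
keeping the full test run fast: recovery on 20 samples × 5 chromosomes ×
2000 probes with 60 implanted loci at sd 0.1; null control on CNV-free
panels at sd 0.12 over 20 seeds; calibration at 100 trials × 200
replicates. `scripts/acceptance.py` runs the full 53-sample roster with
430 loci on a 16 × 3 Mb (48 Mb) genome — the probe count and genome are
scaled down from a 2.1M-probe, 2.4 Gb study while keeping per-locus probe
counts, noise and thresholds at study values; homology nulls there use
2 kb windows and 100 replicates.

## Known limitations

* Absolute copy number on X is relative to the male reference only.
* The complex/simple distinction inherits the resolution of segmentation:
  adjacent events shorter than the min-probe rule per side are reported
  at whatever granularity discovery achieves.
* Enrichment nulls treat windows as independent; overlapping windows from
  nearby loci are randomized independently.
* The fused-lasso solver is exact but single-series; no shared-changepoint
  information is borrowed across samples.
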