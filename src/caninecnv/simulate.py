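"""Synthetic multi-breed aCGH study generator with ground truth.

Emulates the statistical structure of a dog-breed aCGH panel: a jittered
~1 kb probe grid, per-sample log2-ratio tracks with additive Gaussian noise
and implanted deletion/duplication/complex loci whose sharing is structured
by breed, plus synthetic genome sequence with planted GC peaks, repeat
copies, CpG islands, assembly gaps and exact homology tracts at chosen
breakpoints. Everything is deterministic given the seed.

The default panel mirrors the study design this package targets: 15 breeds
with two dogs each, two breeds with ten dogs, three wolves (53 test
samples), hybridized against a male Boxer reference; 430 CNV loci in a
226:104:100 deletion:duplication:both class mix with log-normal sizes whose
class medians sit near 19/29.5/27.8 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from caninecnv.io import IntervalSet, ProbeSet, RatioMatrix

# Breed roster of the emulated panel: (code, n_samples).
DEFAULT_BREEDS: list[tuple[str, int]] = [
    ("BTe", 2), ("Box", 2), ("CCS", 2), ("Chi", 2), ("Dac", 2),
    ("ECS", 2), ("ESS", 2), ("FSp", 2), ("GSh", 2), ("LRe", 2),
    ("NSD", 2), ("Pdl", 2), ("Sar", 2), ("Sch", 2), ("Elk", 2),
    ("GRe", 10), ("IrW", 10), ("Wlf", 3),
]

# Default complex-rendering probability per locus class (fraction of loci
# carrying at least one adjacent del+dup sample).
COMPLEX_FRAC = {"deletion": 19 / 226, "duplication": 16 / 104, "both": 42 / 100}

# Class size medians in bp (deletion, duplication, both).
SIZE_MEDIANS = {"deletion": 19_000, "duplication": 29_500, "both": 27_800}

LOG2_FLOOR = -4.0  # rendered log2 ratio for homozygous deletions (CN=0)


@dataclass
class SimLayout:
    """Study layout: chromosomes, samples, reference, probe spacing."""

    chromosomes: list[tuple[str, int]]
    samples: list[tuple[str, str, str]]  # (sample_id, breed, sex)
    reference_sample_id: str = "Box_ref"
    reference_sex: str = "M"
    probe_spacing_median: int = 1000
    x_chrom: str | None = None
    par_boundary: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")
        ids = [s for s, _, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if self.reference_sex != "M":
            raise ValueError("reference sample must be male")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.samples]

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["sample_id", "breed", "sex"])

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


def default_layout(
    n_chrom: int = 8,
    chrom_length: int = 3_000_000,
    probe_spacing: int = 1000,
    with_x: bool = False,
    seed: int = 0,
) -> SimLayout:
    """The default desk-scale panel: full breed roster, compact genome."""
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]
    x_chrom = None
    par_boundary = 0
    if with_x:
        x_chrom = "chrX"
        par_boundary = chrom_length // 5
        chroms.append((x_chrom, chrom_length))
    rng = np.random.default_rng(seed)
    samples = []
    for breed, n in DEFAULT_BREEDS:
        for i in range(n):
            sex = "F" if rng.random() < 0.5 else "M"
            samples.append((f"{breed}_{i + 1}", breed, sex))
    return SimLayout(
        chromosomes=chroms,
        samples=samples,
        probe_spacing_median=probe_spacing,
        x_chrom=x_chrom,
        par_boundary=par_boundary,
        seed=seed,
    )


@dataclass
class TruthCnv:
    """An implanted CNV locus with per-sample true copy numbers.

    ``cn`` maps sample_id -> copy number; non-carriers are omitted
    (implicitly diploid). A complex locus is rendered as two abutting
    sub-intervals split at ``mid``; complex carriers map to an
    (left CN, right CN) pair on opposite sides of 2.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    cn: dict[str, int | tuple[int, int]]
    locus_class: str = "deletion"
    complex_flag: bool = False
    mid: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not self.cn:
            raise ValueError("at least one carrier required")
        if self.complex_flag and self.mid is None:
            self.mid = self.start + (self.end - self.start) // 2

    def carrier_samples(self) -> list[str]:
        return list(self.cn)


@dataclass
class SimNoise:
    """Additive Gaussian noise on log2 ratios.

    ``sd``: scalar base standard deviation, or a mapping from sample_id or
    (sample_id, chrom) to block-specific values. ``outlier_rate``: per-probe
    probability of drawing the noise from a 5x-sd Gaussian instead.
    """

    sd: float | dict = 0.1
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.sd, (int, float)) and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be in [0, 1]")

    def block_sd(self, sample: str, chrom: str) -> float:
        if isinstance(self.sd, dict):
            if (sample, chrom) in self.sd:
                return float(self.sd[(sample, chrom)])
            if sample in self.sd:
                return float(self.sd[sample])
            raise KeyError(f"no noise sd for {sample}")
        return float(self.sd)


@dataclass
class SyntheticGenomeSpec:
    """Recipe for synthetic genome sequence and annotations."""

    background_gc: float = 0.41
    gc_peaks: list[tuple[str, int, int, float]] = field(default_factory=list)
    repeat_catalog: list[tuple[str, int, float]] = field(default_factory=list)
    repeat_copies: dict[str, int] = field(default_factory=dict)
    # per family: fraction of copies placed near a truth-locus breakpoint
    # (younger repeat families cluster at rearrangement breakpoints)
    repeat_breakpoint_frac: dict[str, float] = field(default_factory=dict)
    homology_plants: list[tuple[str, int]] = field(default_factory=list)
    cpg_islands: list[tuple[str, int, int]] = field(default_factory=list)
    gaps: list[tuple[str, int, int]] = field(default_factory=list)
    cpg_gc: float = 0.65

    def __post_init__(self) -> None:
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")
        for _, _, _, gc in self.gc_peaks:
            if not 0 < gc < 1:
                raise ValueError("GC-peak fractions must be in (0, 1)")


# ---------------------------------------------------------------------------
# probe grid


def build_probe_grid(layout: SimLayout, seed: int | None = None) -> ProbeSet:
    """Jittered probe grid with the requested median spacing.

    Each chromosome gets floor(length / spacing) probes; inter-probe gaps
    are spacing * Uniform(0.5, 1.5) increments rescaled to fit the
    chromosome, reproducing a *median* (not exact) spacing.
    """
    rng = np.random.default_rng(layout.seed if seed is None else seed)
    spacing = layout.probe_spacing_median
    rows = []
    for chrom, length in sorted(layout.chromosomes):
        n = length // spacing
        if n < 2:
            raise ValueError(f"{chrom}: length {length} shorter than 2x spacing")
        gaps = spacing * rng.uniform(0.5, 1.5, size=n)
        pos = np.cumsum(gaps)
        pos *= (length - 1) / pos[-1]  # fit the chromosome exactly
        pos = np.unique(np.maximum.accumulate(np.round(pos).astype(np.int64)))
        for i, p in enumerate(pos):
            rows.append((chrom, int(p), f"{chrom}_p{i:06d}"))
    return ProbeSet(pd.DataFrame(rows, columns=["chrom", "pos", "probe_id"]))


# ---------------------------------------------------------------------------
# expected signal and rendering


def expected_log2(true_cn: int, reference_cn: int = 2, floor: float = LOG2_FLOOR) -> float:
    """Noise-free log2 ratio for a true vs. reference copy number.

    Inverse of the copy-number quantification 2**(1 + mean log2 ratio)
    for a diploid reference. CN=0 maps to a finite floor because array
    signal saturates rather than vanishing.
    """
    if true_cn < 0:
        raise ValueError("copy number must be >= 0")
    if reference_cn <= 0:
        raise ValueError("reference copy number must be > 0")
    if true_cn == 0:
        return floor
    return math.log2(true_cn / reference_cn)


def render_ratio_matrix(
    probes: ProbeSet,
    truth: list[TruthCnv],
    noise: SimNoise | None = None,
    seed: int = 0,
    layout: SimLayout | None = None,
) -> RatioMatrix:
    """Render the noisy log2-ratio matrix implied by the truth set.

    Probe expected value = expected_log2(sample CN at probe, reference CN)
    plus Gaussian(0, block sd) noise (plus optional heavy-tailed outliers);
    probes outside every truth interval have expected value 0. On a
    non-PAR X block, female samples get a +1 log2 baseline against the
    male reference.
    """
    noise = noise or SimNoise()
    if layout is None:
        raise ValueError("layout required to enumerate samples")
    rng = np.random.default_rng(seed)
    sample_tbl = layout.sample_table()
    sample_ids = list(sample_tbl["sample_id"])
    known = set(sample_ids)
    for t in truth:
        for s in t.cn:
            if s not in known:
                raise ValueError(f"truth sample {s!r} absent from layout")
    n = len(probes)
    values = np.zeros((n, len(sample_ids)))
    chrom_slices = {c: probes.chrom_slice(c) for c in probes.chroms}
    sex = dict(zip(sample_tbl["sample_id"], sample_tbl["sex"]))

    # baseline: X non-PAR shift for females vs male reference
    if layout.x_chrom in chrom_slices:
        sl = chrom_slices[layout.x_chrom]
        pos = probes.positions(layout.x_chrom)
        nonpar = pos >= layout.par_boundary
        for j, s in enumerate(sample_ids):
            if sex[s] == "F":
                values[sl, j][nonpar] = 1.0  # log2(2/1)

    for t in truth:
        if t.chrom not in chrom_slices:
            raise ValueError(f"truth chromosome {t.chrom!r} not on probe grid")
        sl = chrom_slices[t.chrom]
        pos = probes.positions(t.chrom)
        for s, cn in t.cn.items():
            j = sample_ids.index(s)
            if isinstance(cn, tuple):
                left = (pos >= t.start) & (pos < (t.mid or t.start))
                right = (pos >= (t.mid or t.start)) & (pos < t.end)
                values[sl, j][left] = expected_log2(cn[0])
                values[sl, j][right] = expected_log2(cn[1])
            else:
                inside = (pos >= t.start) & (pos < t.end)
                values[sl, j][inside] = expected_log2(int(cn))

    # noise per (sample, chromosome) block, outliers from 5x-sd Gaussian
    for chrom in probes.chroms:
        sl = chrom_slices[chrom]
        m = sl.stop - sl.start
        for j, s in enumerate(sample_ids):
            sd = noise.block_sd(s, chrom)
            eps = rng.normal(0.0, sd, size=m) if sd > 0 else np.zeros(m)
            if noise.outlier_rate > 0 and sd > 0:
                mask = rng.random(m) < noise.outlier_rate
                eps[mask] = rng.normal(0.0, 5 * sd, size=int(mask.sum()))
            values[sl, j] += eps

    df = pd.DataFrame(values, columns=sample_ids)
    return RatioMatrix(probes, df, sample_tbl)


# ---------------------------------------------------------------------------
# truth set


def _draw_sizes(rng: np.random.Generator, n: int, median: float, sigma: float = 0.6) -> np.ndarray:
    """Log-normal sizes with the given median; clipped to [9 kb, 1.6 Mb]."""
    sizes = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.clip(sizes, 9_000, 1_600_000).astype(np.int64)


def draw_truth_set(
    layout: SimLayout,
    n_loci: int = 430,
    class_mix: tuple[int, int, int] = (226, 104, 100),
    size_medians: dict[str, float] | None = None,
    p_private: float = 0.21,
    shared_freq_beta: tuple[float, float] = (0.9, 2.6),
    breed_kappa: float = 2.0,
    complex_frac: dict[str, float] | None = None,
    seed: int | None = None,
    min_gap: int | None = None,
    autosomes_only: bool = True,
) -> list[TruthCnv]:
    """Draw a breed-structured truth set of CNV loci.

    Loci are placed non-overlapping (separated by several probe
    spacings); the class mix deletion:duplication:both defaults to
    226:104:100. Per-breed carrier status follows a two-point mixture:
    with probability ``p_private`` a locus is private to one breed;
    otherwise a global carrier frequency f is drawn (Beta) and each breed
    gets its own carrier probability from Beta(kappa*f, kappa*(1-f)) —
    the overdispersion (breed_kappa) creates the within-breed sharing
    that makes breeds cohere in distance-based analyses. A
    class-dependent fraction of loci is rendered complex (two abutting
    opposite-sign sub-events in carrier samples).
    """
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    rng = np.random.default_rng(layout.seed + 1 if seed is None else seed)
    size_medians = size_medians or SIZE_MEDIANS
    complex_frac = complex_frac if complex_frac is not None else COMPLEX_FRAC
    if n_loci == 0:
        return []

    mix = np.array(class_mix, dtype=float)
    counts = np.floor(mix / mix.sum() * n_loci).astype(int)
    while counts.sum() < n_loci:
        counts[int(np.argmax(mix / mix.sum() * n_loci - counts))] += 1
    classes = (
        ["deletion"] * counts[0] + ["duplication"] * counts[1] + ["both"] * counts[2]
    )
    rng.shuffle(classes)

    chroms = [
        (c, length)
        for c, length in layout.chromosomes
        if not (autosomes_only and c == layout.x_chrom)
    ]
    total_len = sum(length for _, length in chroms)
    # keep loci separated by several probe spacings so that cross-sample
    # merging cannot chain distinct implants through boundary blur
    min_gap = 5 * layout.probe_spacing_median if min_gap is None else min_gap

    sizes = {
        cls: iter(_draw_sizes(rng, classes.count(cls), size_medians[cls]))
        for cls in ("deletion", "duplication", "both")
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in chroms}
    breeds = list(dict.fromkeys(b for _, b, _ in layout.samples))
    by_breed: dict[str, list[str]] = {}
    for sid, breed, _ in layout.samples:
        by_breed.setdefault(breed, []).append(sid)

    truth: list[TruthCnv] = []
    for i, cls in enumerate(classes):
        size = int(next(sizes[cls]))
        placed = False
        for _attempt in range(200):
            # chromosome chosen proportional to length
            r = rng.integers(0, total_len)
            acc = 0
            for c, length in chroms:
                acc += length
                if r < acc:
                    chrom, clen = c, length
                    break
            if size + 2 * min_gap >= clen:
                continue
            start = int(rng.integers(min_gap, clen - size - min_gap))
            end = start + size
            if all(
                end + min_gap <= s or start >= e + min_gap for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, end))
                placed = True
                break
        if not placed:
            raise ValueError("genome too small for requested loci")

        # breed-structured carriers
        carriers: list[str] = []
        if rng.random() < p_private:
            breed = breeds[int(rng.integers(len(breeds)))]
            pool = by_breed[breed]
            carriers = [s for s in pool if rng.random() < 0.7]
            if not carriers:
                carriers = [pool[int(rng.integers(len(pool)))]]
        else:
            f = float(rng.beta(*shared_freq_beta))
            f = min(max(f, 0.02), 0.98)
            carriers = []
            for b in breeds:
                p_b = float(rng.beta(breed_kappa * f, breed_kappa * (1 - f)))
                carriers.extend(s for s in by_breed[b] if rng.random() < p_b)
            breed_of = {sid: b for sid, b, _ in layout.samples}
            if len({breed_of[s] for s in carriers}) < 2:
                # force sharing across at least two breeds
                extra = [b for b in breeds if not any(s in carriers for s in by_breed[b])]
                if extra:
                    b = extra[int(rng.integers(len(extra)))]
                    carriers.append(by_breed[b][int(rng.integers(len(by_breed[b])))])
            if not carriers:
                carriers = [layout.sample_ids[int(rng.integers(len(layout.sample_ids)))]]

        is_complex = rng.random() < complex_frac.get(cls, 0.0)
        cn: dict[str, int | tuple[int, int]] = {}
        complex_carrier = carriers[int(rng.integers(len(carriers)))] if is_complex else None
        for s in carriers:
            if s == complex_carrier:
                cn[s] = (1, 3) if rng.random() < 0.5 else (3, 1)
                continue
            if cls == "deletion":
                cn[s] = 0 if rng.random() < 0.05 else 1
            elif cls == "duplication":
                cn[s] = 4 if rng.random() < 0.05 else 3
            else:
                cn[s] = 1 if rng.random() < 0.5 else 3
        if cls == "both":
            simple = [s for s in carriers if s != complex_carrier]
            if len(simple) >= 2:
                cn[simple[0]] = 1
                cn[simple[1]] = 3
        truth.append(
            TruthCnv(
                locus_id=f"truth_{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                cn=cn,
                locus_class=cls,
                complex_flag=is_complex,
            )
        )
    return truth


# ---------------------------------------------------------------------------
# genome sequence


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random base array (dtype S1) with expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def synthesize_genome(
    spec: SyntheticGenomeSpec,
    truth: list[TruthCnv],
    layout: SimLayout,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, IntervalSet]]:
    """Generate genome sequence and annotations per the recipe.

    Returns ({chrom: sequence}, annotations) where annotations holds
    IntervalSets under keys 'repeats', 'cpg', 'gaps', 'gc_peaks_planted'.
    Homology plants copy an identical tract into both 10 kb breakpoint
    windows of the referenced locus. Overlapping incompatible plants
    (a gap on top of a homology tract) are rejected.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {}
    for chrom, length in layout.chromosomes:
        seqs[chrom] = _random_seq(rng, length, spec.background_gc)

    peak_rows = []
    for chrom, center, width, gc in spec.gc_peaks:
        start = max(0, center - width // 2)
        end = min(layout.chrom_length(chrom), start + width)
        seqs[chrom][start:end] = _random_seq(rng, end - start, gc)
        peak_rows.append((chrom, start, end, f"gc{gc:.2f}"))

    cpg_rows = []
    for chrom, start, end in spec.cpg_islands:
        seqs[chrom][start:end] = _random_seq(rng, end - start, spec.cpg_gc)
        cpg_rows.append((chrom, start, end, "CpG"))

    repeat_rows = []
    truth_by_id = {t.locus_id: t for t in truth}
    breakpoints = [(t.chrom, b) for t in truth for b in (t.start, t.end)]
    for family, unit_len, divergence in spec.repeat_catalog:
        consensus = _random_seq(rng, unit_len, spec.background_gc)
        n_copies = spec.repeat_copies.get(family, 50)
        bp_frac = spec.repeat_breakpoint_frac.get(family, 0.0)
        chrom_names = [c for c, _ in layout.chromosomes]
        lengths = np.array([length for _, length in layout.chromosomes], dtype=float)
        for _ in range(n_copies):
            if breakpoints and rng.random() < bp_frac:
                chrom, b = breakpoints[int(rng.integers(len(breakpoints)))]
                clen = layout.chrom_length(chrom)
                if clen <= unit_len:
                    continue
                start = int(
                    np.clip(b + rng.integers(-4000, 4001), 0, clen - unit_len)
                )
            else:
                ci = int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
                chrom = chrom_names[ci]
                clen = layout.chrom_length(chrom)
                if clen <= unit_len:
                    continue
                start = int(rng.integers(0, clen - unit_len))
            copy = consensus.copy()
            mut = rng.random(unit_len) < divergence
            copy[mut] = _BASES[rng.integers(0, 4, size=int(mut.sum()))]
            seqs[chrom][start : start + unit_len] = copy
            repeat_rows.append((chrom, start, start + unit_len, family, divergence))

    homology_guard: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in layout.chromosomes}
    for locus_id, tract_len in spec.homology_plants:
        t = truth_by_id[locus_id]
        if tract_len >= (t.end - t.start):
            raise ValueError("homology tract must be shorter than the locus")
        tract = _random_seq(rng, tract_len, spec.background_gc)
        clen = layout.chrom_length(t.chrom)
        for b in (t.start, t.end):
            s = min(max(0, b - tract_len // 2), clen - tract_len)
            seqs[t.chrom][s : s + tract_len] = tract
            homology_guard[t.chrom].append((s, s + tract_len))

    gap_rows = []
    for chrom, start, end in spec.gaps:
        for gs, ge in homology_guard.get(chrom, []):
            if start < ge and gs < end:
                raise ValueError("gap overlaps a homology plant")
        seqs[chrom][start:end] = b"N"
        gap_rows.append((chrom, start, end, "gap"))

    annotations = {
        "repeats": IntervalSet(
            pd.DataFrame(
                repeat_rows, columns=["chrom", "start", "end", "name", "divergence"]
            )
            if repeat_rows
            else pd.DataFrame(columns=["chrom", "start", "end", "name", "divergence"])
        ),
        "cpg": IntervalSet(
            pd.DataFrame(cpg_rows, columns=["chrom", "start", "end", "name"])
            if cpg_rows
            else pd.DataFrame(columns=["chrom", "start", "end", "name"])
        ),
        "gaps": IntervalSet(
            pd.DataFrame(gap_rows, columns=["chrom", "start", "end", "name"])
            if gap_rows
            else pd.DataFrame(columns=["chrom", "start", "end", "name"])
        ),
        "gc_peaks_planted": IntervalSet(
            pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])
            if peak_rows
            else pd.DataFrame(columns=["chrom", "start", "end", "name"])
        ),
    }
    return {c: s.tobytes().decode("ascii") for c, s in seqs.items()}, annotations


def place_genes(
    layout: SimLayout,
    n_per_mb: float = 8.0,
    gene_len_median: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random non-overlapping gene models with stop-codon coordinates.

    Returns a table chrom, start, end, name, strand, stop_start, stop_end;
    the stop codon sits at the 3' end of the gene span (strand-dependent).
    """
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for chrom, length in layout.chromosomes:
        n = int(round(n_per_mb * length / 1e6))
        taken: list[tuple[int, int]] = []
        for _ in range(n):
            size = int(np.clip(rng.lognormal(math.log(gene_len_median), 0.8), 1_000, 300_000))
            for _attempt in range(50):
                start = int(rng.integers(0, max(1, length - size)))
                end = start + size
                if all(end <= s or start >= e for s, e in taken):
                    taken.append((start, end))
                    strand = "+" if rng.random() < 0.5 else "-"
                    stop_start = end - 3 if strand == "+" else start
                    rows.append(
                        (chrom, start, end, f"gene{gid:05d}", strand, stop_start, stop_start + 3)
                    )
                    gid += 1
                    break
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "strand", "stop_start", "stop_end"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)


def genome_spec_for_truth(
    layout: SimLayout,
    truth: list[TruthCnv],
    rng: np.random.Generator,
    breakpoint_peak_frac: float = 0.2,
    background_peaks_per_mb: float = 2.0,
    homology_frac: float = 0.2,
    homology_tract: int = 120,
    peak_gc: float = 0.70,
    background_gc: float = 0.41,
) -> SyntheticGenomeSpec:
    """Build a genome recipe enriched at the truth set's breakpoints.

    A fraction of loci get a GC peak near one breakpoint and a fraction get
    an exact homology tract spanning both breakpoints; background peaks are
    scattered uniformly so enrichment is measurable rather than absolute.
    """
    gc_peaks: list[tuple[str, int, int, float]] = []
    homology: list[tuple[str, int]] = []
    for t in truth:
        if rng.random() < breakpoint_peak_frac:
            b = t.start if rng.random() < 0.5 else t.end
            center = int(b + rng.integers(-2000, 2001))
            gc_peaks.append((t.chrom, max(500, center), 500, peak_gc))
        if rng.random() < homology_frac and (t.end - t.start) > 3 * homology_tract:
            homology.append((t.locus_id, homology_tract))
    for chrom, length in layout.chromosomes:
        for _ in range(int(background_peaks_per_mb * length / 1e6)):
            gc_peaks.append((chrom, int(rng.integers(5000, length - 5000)), 500, peak_gc))
    repeat_catalog = [
        ("L1_Cf", 1192, 0.035),
        ("L1_Canis", 799, 0.088),
        ("L1_Carn", 525, 0.168),
    ]
    total_mb = sum(length for _, length in layout.chromosomes) / 1e6
    repeat_copies = {
        "L1_Cf": int(8 * total_mb),
        "L1_Canis": int(30 * total_mb),
        "L1_Carn": int(55 * total_mb),
    }
    return SyntheticGenomeSpec(
        background_gc=background_gc,
        gc_peaks=gc_peaks,
        repeat_catalog=repeat_catalog,
        repeat_copies=repeat_copies,
        repeat_breakpoint_frac={"L1_Cf": 0.5, "L1_Canis": 0.25},
        homology_plants=homology,
    )
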