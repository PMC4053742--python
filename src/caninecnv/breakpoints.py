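"""Sequence- and annotation-level analysis of CNV breakpoints.

GC-peak detection by dual sliding windows, breakpoint windows with
per-chromosome randomization nulls for annotation enrichment, repeat-family
excess tables, GC-peak distance profiles, longest-perfect-homology scans
with a simulated null, gene-overlap classification, and bootstrap
comparisons of CNV properties between strata.

All randomized operations take an explicit seed and record both the seed
and the replicate count in their results; empirical p-values use the
(1 + x) / (1 + reps) correction and are therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from caninecnv.io import IntervalSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GcPeakParams:
    """Dual sliding-window GC-peak scan parameters.

    A peak is marked when the GC fraction of the 500 bp center window is at
    least ``fold`` (1.5) times the GC fraction of the surrounding 10 kb
    background window (which includes the center). Ambiguous bases (N) are
    excluded from numerator and denominator of both windows.
    """

    background_window: int = 10_000
    peak_window: int = 500
    fold: float = 1.5
    step: int = 100

    def __post_init__(self) -> None:
        if self.peak_window >= self.background_window:
            raise ValueError("peak window must be smaller than background window")
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class EnrichmentResult:
    """Observed vs. randomized-null overlap statistics."""

    statistic: str
    observed: float
    null: np.ndarray
    oe: float
    p_upper: float
    p_lower: float
    reps: int
    seed: int


@dataclass
class HomologyResult:
    """Perfect-homology scan results with simulated null."""

    per_locus: pd.DataFrame  # locus_id, chrom, match_len
    mean_length: float
    null_means: np.ndarray
    p: float | None
    n_gt_75: int
    n_gt_1kb: int
    reps: int
    seed: int
    window: int


# ---------------------------------------------------------------------------
# GC peaks


def _gc_cumsums(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    gc = np.cumsum(np.concatenate([[0], ((arr == b"G") | (arr == b"C")).astype(np.int64)]))
    valid = np.cumsum(np.concatenate([[0], (arr != b"N").astype(np.int64)]))
    return gc, valid


def find_gc_peaks(
    sequence: str, params: GcPeakParams | None = None, chrom: str = "chr"
) -> IntervalSet:
    """Scan one chromosome for GC peaks; overlapping marks are merged.

    The background window slides with the given step; the peak window is
    centered inside it. All-N windows are skipped; a positive peak GC over
    a zero background GC counts as a peak.
    """
    params = params or GcPeakParams()
    n = len(sequence)
    if n < params.background_window:
        raise ValueError("sequence shorter than the background window")
    gc, valid = _gc_cumsums(sequence)
    bw, pw = params.background_window, params.peak_window
    offs = np.arange(0, n - bw + 1, params.step)
    ps = offs + (bw - pw) // 2
    bg_gc = gc[offs + bw] - gc[offs]
    bg_valid = valid[offs + bw] - valid[offs]
    pk_gc = gc[ps + pw] - gc[ps]
    pk_valid = valid[ps + pw] - valid[ps]
    ok = (bg_valid > 0) & (pk_valid > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bg_frac = np.where(bg_valid > 0, bg_gc / np.maximum(bg_valid, 1), 0.0)
        pk_frac = np.where(pk_valid > 0, pk_gc / np.maximum(pk_valid, 1), 0.0)
        is_peak = ok & (
            np.where(bg_frac > 0, pk_frac / np.maximum(bg_frac, 1e-300), np.inf)
            >= params.fold
        ) & (pk_frac > 0)
    rows = []
    cur = None
    for s in ps[is_peak]:
        e = int(s) + pw
        if cur and s <= cur[1]:
            cur[1] = e
        else:
            if cur:
                rows.append((chrom, cur[0], cur[1], "gc_peak"))
            cur = [int(s), e]
    if cur:
        rows.append((chrom, cur[0], cur[1], "gc_peak"))
    return IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        if rows
        else pd.DataFrame(columns=["chrom", "start", "end", "name"])
    )


def find_gc_peaks_genome(
    genome: dict[str, str], params: GcPeakParams | None = None
) -> IntervalSet:
    """GC-peak scan over every chromosome of a genome."""
    frames = []
    for chrom, seq in genome.items():
        if len(seq) < (params or GcPeakParams()).background_window:
            continue
        peaks = find_gc_peaks(seq, params, chrom=chrom)
        if len(peaks):
            frames.append(peaks.table)
    if not frames:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
    return IntervalSet(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# breakpoint windows and overlap machinery


def breakpoint_windows(
    loci: pd.DataFrame, chrom_lengths: dict[str, int], width: int = 10_000
) -> pd.DataFrame:
    """Two width-bp windows per locus, centered on each breakpoint.

    Windows are clipped at chromosome ends. ``side`` records which
    breakpoint (left/right); for the left breakpoint "inside" the CNV is
    rightward.
    """
    rows = []
    for _, locus in loci.iterrows():
        clen = chrom_lengths[locus["chrom"]]
        for side, b in (("left", locus["start"]), ("right", locus["end"])):
            s = max(0, int(b) - width // 2)
            e = min(clen, int(b) + width // 2)
            rows.append(
                {
                    "locus_id": locus["locus_id"],
                    "chrom": locus["chrom"],
                    "start": s,
                    "end": e,
                    "side": side,
                    "breakpoint": int(b),
                }
            )
    return pd.DataFrame(rows)


class _ChromFeatures:
    """Per-chromosome merged-interval index for overlap queries."""

    def __init__(self, intervals: pd.DataFrame):
        starts = intervals["start"].values.astype(np.int64)
        ends = intervals["end"].values.astype(np.int64)
        order = np.argsort(starts, kind="mergesort")
        self.raw_starts = np.sort(starts)
        self.raw_ends = np.sort(ends)
        # merge into disjoint intervals
        ms, me = [], []
        for s, e in zip(starts[order], ends[order]):
            if me and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        self.ms = np.array(ms, dtype=np.int64)
        self.me = np.array(me, dtype=np.int64)
        self.cumcov = np.concatenate([[0], np.cumsum(self.me - self.ms)])

    def count_in(self, ws: np.ndarray, we: np.ndarray) -> np.ndarray:
        """Number of (unmerged) features overlapping each window."""
        a = np.searchsorted(self.raw_starts, we, side="left")
        b = np.searchsorted(self.raw_ends, ws, side="right")
        return a - b

    def coverage_in(self, ws: np.ndarray, we: np.ndarray) -> np.ndarray:
        """Merged-feature base coverage inside each window."""
        out = np.zeros(ws.size, dtype=np.int64)
        i0 = np.searchsorted(self.me, ws, side="right")
        i1 = np.searchsorted(self.ms, we, side="left")
        for k in range(ws.size):
            lo, hi = i0[k], i1[k]
            if hi <= lo:
                continue
            cov = self.cumcov[hi] - self.cumcov[lo]
            cov -= max(0, ws[k] - self.ms[lo])
            cov -= max(0, self.me[hi - 1] - we[k])
            out[k] = max(cov, 0)
        return out


def _index_features(features: IntervalSet) -> dict[str, _ChromFeatures]:
    return {
        chrom: _ChromFeatures(grp)
        for chrom, grp in features.table.groupby("chrom", sort=False)
    }


def _window_stats(
    windows: pd.DataFrame, index: dict[str, _ChromFeatures]
) -> dict[str, float]:
    n_with = 0
    n_feat = 0
    cov = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        ws = grp["start"].values.astype(np.int64)
        we = grp["end"].values.astype(np.int64)
        if chrom not in index:
            continue
        idx = index[chrom]
        counts = idx.count_in(ws, we)
        n_with += int((counts > 0).sum())
        n_feat += int(counts.sum())
        cov += int(idx.coverage_in(ws, we).sum())
    return {"windows": float(n_with), "features": float(n_feat), "coverage": float(cov)}


def _randomize_windows(
    windows: pd.DataFrame, chrom_lengths: dict[str, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Redistribute each window uniformly on its own chromosome (length kept)."""
    out = windows.copy()
    lens = out["end"].values - out["start"].values
    new_starts = np.empty(len(out), dtype=np.int64)
    for i, (chrom, ln) in enumerate(zip(out["chrom"].values, lens)):
        clen = chrom_lengths[chrom]
        if clen <= ln:
            new_starts[i] = 0
        else:
            new_starts[i] = rng.integers(0, clen - ln)
    out["start"] = new_starts
    out["end"] = new_starts + lens
    return out


def annotation_enrichment(
    windows: pd.DataFrame,
    features: IntervalSet,
    chrom_lengths: dict[str, int],
    reps: int = 1000,
    seed: int = 0,
    statistic: str = "windows",
) -> EnrichmentResult:
    """Feature enrichment in breakpoint windows vs. a randomized null.

    The null keeps every window's chromosome and length but redraws its
    position uniformly (windows may overlap each other). ``statistic``:
    "windows" (windows overlapping >= 1 feature), "features" (feature count
    within windows) or "coverage" (feature base coverage within windows).
    O/E is observed over the null mean; empirical p-values carry the
    +1/+1 correction.
    """
    if statistic not in ("windows", "features", "coverage"):
        raise ValueError(f"unknown statistic {statistic!r}")
    too_long = [
        i
        for i, row in windows.iterrows()
        if chrom_lengths[row["chrom"]] < (row["end"] - row["start"])
    ]
    if too_long:
        import warnings

        warnings.warn(f"excluding {len(too_long)} windows longer than their chromosome")
        windows = windows.drop(index=too_long)
    index = _index_features(features)
    observed = _window_stats(windows, index)[statistic]
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        rnd = _randomize_windows(windows, chrom_lengths, rng)
        null[r] = _window_stats(rnd, index)[statistic]
    mean_null = float(null.mean()) if reps else float("nan")
    oe = observed / mean_null if reps and mean_null > 0 else float("nan")
    p_upper = (1 + int((null >= observed).sum())) / (reps + 1) if reps else float("nan")
    p_lower = (1 + int((null <= observed).sum())) / (reps + 1) if reps else float("nan")
    return EnrichmentResult(
        statistic=statistic,
        observed=observed,
        null=null,
        oe=oe,
        p_upper=p_upper,
        p_lower=p_lower,
        reps=reps,
        seed=seed,
    )


def repeat_excess_table(
    windows: pd.DataFrame,
    rmsk: IntervalSet,
    chrom_lengths: dict[str, int],
    method: str = "coverage",
) -> pd.DataFrame:
    """Per-repeat-family excess of breakpoint-window content.

    excess = observed family content inside windows / expected content,
    expected scaling genome-wide density by the summed window length.
    ``method`` "coverage" normalizes by base coverage (default);
    "count" normalizes by repeat counts. Families absent from the genome
    report NA. Also tallies repeats-in-windows and windows-with-repeats.
    """
    if method not in ("coverage", "count"):
        raise ValueError(f"unknown method {method!r}")
    genome_len = sum(chrom_lengths.values())
    window_len = int((windows["end"] - windows["start"]).sum())
    rows = []
    for family, grp in rmsk.table.groupby("name", sort=True):
        fam = IntervalSet(grp.reset_index(drop=True))
        index = _index_features(fam)
        stats = _window_stats(windows, index)
        n_in_bp = int(stats["features"])
        n_bp_with = int(stats["windows"])
        if method == "coverage":
            observed = stats["coverage"]
            expected = fam.total_length() / genome_len * window_len
        else:
            observed = stats["features"]
            expected = len(fam) / genome_len * window_len
        if expected == 0:
            excess = float("nan")
        else:
            excess = observed / expected
        rows.append(
            {
                "family": family,
                "excess": excess,
                "n_in_genome": len(fam),
                "n_in_breakpoints": n_in_bp,
                "n_breakpoints_with": n_bp_with,
                "divergence": float(grp["divergence"].mean())
                if "divergence" in grp.columns
                else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values("family").reset_index(drop=True)


def gc_distance_profile(
    loci: pd.DataFrame,
    peaks: IntervalSet,
    chrom_lengths: dict[str, int],
    max_dist: int = 50_000,
    bin_width: int = 5_000,
    reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """O/E of GC-peak base coverage by signed distance from breakpoints.

    Distance is measured from the breakpoint; negative bins lie inside the
    CNV, positive bins outside. The null redistributes each locus on its
    own chromosome (length preserved) and recomputes, giving a per-bin
    expectation. Empty peak sets yield zero observed coverage in all bins.
    """
    index = _index_features(peaks) if len(peaks) else {}
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width)

    def bin_coverage(loci_tbl: pd.DataFrame) -> np.ndarray:
        cov = np.zeros(edges.size - 1)
        for _, locus in loci_tbl.iterrows():
            chrom = locus["chrom"]
            if chrom not in index:
                continue
            clen = chrom_lengths[chrom]
            idx = index[chrom]
            for side, b in (("left", int(locus["start"])), ("right", int(locus["end"]))):
                for k in range(edges.size - 1):
                    lo, hi = int(edges[k]), int(edges[k + 1])
                    if side == "left":
                        # inside (negative d) is rightward: genomic [b-hi, b-lo)
                        gs, ge = b - hi, b - lo
                    else:
                        # right bp: inside (negative d) is leftward: [b+lo, b+hi)
                        gs, ge = b + lo, b + hi
                    gs, ge = max(0, gs), min(clen, ge)
                    if ge > gs:
                        cov[k] += float(
                            idx.coverage_in(np.array([gs]), np.array([ge]))[0]
                        )
        return cov

    observed = bin_coverage(loci)
    rng = np.random.default_rng(seed)
    null = np.zeros((reps, edges.size - 1))
    for r in range(reps):
        rnd = loci.copy()
        lens = rnd["end"].values - rnd["start"].values
        starts = np.empty(len(rnd), dtype=np.int64)
        for i, (chrom, ln) in enumerate(zip(rnd["chrom"].values, lens)):
            clen = chrom_lengths[chrom]
            starts[i] = rng.integers(0, max(1, clen - ln))
        rnd["start"] = starts
        rnd["end"] = starts + lens
        null[r] = bin_coverage(rnd)
    expected = null.mean(axis=0) if reps else np.full(edges.size - 1, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, observed / np.maximum(expected, 1e-300), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame(
        {"distance": centers, "observed": observed, "expected": expected, "oe": oe}
    )


# ---------------------------------------------------------------------------
# perfect homology


def _lcs_automaton(a: str, b: str) -> int:
    """Longest common substring length via a suffix automaton of ``a``."""
    # suffix automaton: arrays of link, length, transition dicts
    trans: list[dict[str, int]] = [{}]
    link = [-1]
    length = [0]
    last = 0
    for ch in a:
        cur = len(trans)
        trans.append({})
        length.append(length[last] + 1)
        link.append(-1)
        p = last
        while p != -1 and ch not in trans[p]:
            trans[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = trans[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(trans)
                trans.append(dict(trans[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and trans[p].get(ch) == q:
                    trans[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur
    best = 0
    v, cur_len = 0, 0
    for ch in b:
        while v != 0 and ch not in trans[v]:
            v = link[v]
            cur_len = length[v]
        if ch in trans[v]:
            v = trans[v][ch]
            cur_len += 1
            if cur_len > best:
                best = cur_len
        else:
            v, cur_len = 0, 0
    return best


def longest_perfect_match(seq_a: str, seq_b: str, strand_aware: bool = False) -> int:
    """Length of the longest exact common substring of two sequences.

    N bases never match (including N against N). With ``strand_aware`` the
    reverse complement of ``seq_b`` is also scanned and the maximum
    returned. Empty input gives 0.
    """
    if not seq_a or not seq_b:
        return 0
    a = seq_a.upper().replace("N", "#")
    b = seq_b.upper().replace("N", "$")
    best = _lcs_automaton(a, b)
    if strand_aware:
        rc = seq_b.upper().translate(_COMPLEMENT)[::-1].replace("N", "$")
        best = max(best, _lcs_automaton(a, rc))
    return best


def homology_scan_and_null(
    loci: pd.DataFrame,
    genome: dict[str, str],
    width: int = 10_000,
    reps: int = 1000,
    seed: int = 0,
    strand_aware: bool = False,
) -> HomologyResult:
    """Longest perfect homology between the two breakpoint windows per locus.

    Each null replicate keeps every locus's chromosome and breakpoint
    separation, draws a uniform random start, and recomputes the dataset
    mean; p is the (+1/+1)-corrected fraction of null means at or above
    the observed mean (None when reps = 0). Loci longer than their
    chromosome are excluded with a warning.
    """
    import warnings

    chrom_lengths = {c: len(s) for c, s in genome.items()}
    keep = []
    for _, locus in loci.iterrows():
        if (locus["end"] - locus["start"]) >= chrom_lengths[locus["chrom"]]:
            warnings.warn(f"locus {locus['locus_id']} longer than its chromosome; excluded")
            continue
        keep.append(locus)
    loci_kept = pd.DataFrame(keep)

    def window(chrom: str, b: int) -> str:
        clen = chrom_lengths[chrom]
        s = max(0, b - width // 2)
        e = min(clen, b + width // 2)
        return genome[chrom][s:e]

    def scan(tbl: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(tbl))
        for i, (_, locus) in enumerate(tbl.iterrows()):
            chrom = locus["chrom"]
            out[i] = longest_perfect_match(
                window(chrom, int(locus["start"])),
                window(chrom, int(locus["end"])),
                strand_aware=strand_aware,
            )
        return out

    obs = scan(loci_kept)
    per_locus = pd.DataFrame(
        {
            "locus_id": loci_kept["locus_id"].values,
            "chrom": loci_kept["chrom"].values,
            "match_len": obs.astype(int),
        }
    )
    mean_len = float(obs.mean()) if len(obs) else 0.0
    rng = np.random.default_rng(seed)
    null_means = np.empty(reps)
    for r in range(reps):
        rnd_rows = []
        for _, locus in loci_kept.iterrows():
            chrom = locus["chrom"]
            sep = int(locus["end"] - locus["start"])
            clen = chrom_lengths[chrom]
            start = int(rng.integers(0, clen - sep))
            rnd_rows.append(
                {"locus_id": locus["locus_id"], "chrom": chrom, "start": start, "end": start + sep}
            )
        null_means[r] = scan(pd.DataFrame(rnd_rows)).mean()
    if reps:
        p = (1 + int((null_means >= mean_len).sum())) / (reps + 1)
    else:
        p = None
    return HomologyResult(
        per_locus=per_locus,
        mean_length=mean_len,
        null_means=null_means,
        p=p,
        n_gt_75=int((obs > 75).sum()),
        n_gt_1kb=int((obs > 1000).sum()),
        reps=reps,
        seed=seed,
        window=width,
    )


# ---------------------------------------------------------------------------
# gene overlap


def classify_gene_overlap(
    loci: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify loci by gene overlap and tabulate counts per locus class.

    Per locus: intergenic (no gene overlap), whole-gene (>= 1 gene fully
    inside the locus) or partial-gene; partial loci are flagged
    stop-codon-removing when an overlapped gene's stop codon lies inside
    the locus while the gene is not fully contained. Genes without a stop
    annotation leave the flag NA. Returns (per-locus table, count table
    with rows total/deletion/duplication/both and a deletion:duplication
    ratio row).
    """
    per_rows = []
    for _, locus in loci.iterrows():
        g = genes[
            (genes["chrom"] == locus["chrom"])
            & (genes["start"] < locus["end"])
            & (genes["end"] > locus["start"])
        ]
        if len(g) == 0:
            cls, stop_flag = "intergenic", False
        else:
            whole = (g["start"] >= locus["start"]) & (g["end"] <= locus["end"])
            if whole.any():
                cls, stop_flag = "whole-gene", False
            else:
                cls = "partial-gene"
                if "stop_start" in g.columns:
                    inside = (
                        (g["stop_start"] >= locus["start"])
                        & (g["stop_end"] <= locus["end"])
                    )
                    stop_flag = bool(inside.any())
                else:
                    stop_flag = None
        per_rows.append(
            {
                "locus_id": locus["locus_id"],
                "class": locus.get("class", "deletion"),
                "overlap_class": cls,
                "stop_codon_removed": stop_flag,
                "n_genes": len(g),
            }
        )
    per = pd.DataFrame(per_rows)

    def tally(sub: pd.DataFrame) -> dict[str, int]:
        intr = sub["overlap_class"] != "intergenic"
        partial = sub["overlap_class"] == "partial-gene"
        return {
            "total": len(sub),
            "intergenic": int((~intr).sum()),
            "intragenic": int(intr.sum()),
            "whole_gene": int((sub["overlap_class"] == "whole-gene").sum()),
            "partial": int(partial.sum()),
            "stop_codon": int((partial & (sub["stop_codon_removed"] == True)).sum()),  # noqa: E712
        }

    counts = {"total": tally(per)}
    for cls_name, key in (("deletion", "deletion"), ("duplication", "duplication"), ("both", "both")):
        counts[cls_name] = tally(per[per["class"] == key])
    tbl = pd.DataFrame(counts).T
    dele, dup = tbl.loc["deletion"], tbl.loc["duplication"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = {
            c: (dele[c] / dup[c]) if dup[c] else float("nan") for c in tbl.columns
        }
    tbl.loc["del_dup_ratio"] = pd.Series(ratio)
    return per, tbl


# ---------------------------------------------------------------------------
# bootstrap comparisons


def bootstrap_compare(
    group_a,
    group_b,
    statistic: str = "mean",
    reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Percentile-bootstrap comparison of a statistic between two groups.

    Returns the point difference (A - B), the 95% percentile CI of the
    bootstrap differences, and a two-sided p = 2 * min(P(diff <= 0),
    P(diff >= 0)) with the 1/(reps+1) floor.
    """
    import warnings

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if reps < 100:
        warnings.warn("fewer than 100 bootstrap replicates")
    stat = {"mean": np.mean, "median": np.median}[statistic]
    diff = float(stat(a) - stat(b))
    rng = np.random.default_rng(seed)
    diffs = np.empty(reps)
    for r in range(reps):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        diffs[r] = stat(ra) - stat(rb)
    lo, hi = (np.percentile(diffs, [2.5, 97.5]) if reps else (np.nan, np.nan))
    p_le = (1 + int((diffs <= 0).sum())) / (reps + 1)
    p_ge = (1 + int((diffs >= 0).sum())) / (reps + 1)
    p = min(1.0, 2 * min(p_le, p_ge))
    return {
        "difference": diff,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": p,
        "reps": reps,
        "seed": seed,
        "statistic": statistic,
    }


def sd_overlap_stats(
    loci: pd.DataFrame,
    sds: IntervalSet,
    genotypes: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare CNV properties between SD-overlapping and non-SD loci.

    Partitions loci by >= 1 bp overlap with segmental duplications
    (half-open, so exact abutment does not overlap) and reports per
    stratum: locus count, median size, complex fraction, carrier frequency
    (when genotypes given) and gene-overlap fraction (when genes given),
    each with a bootstrap p for the between-stratum difference.
    """
    index = _index_features(sds) if len(sds) else {}
    in_sd = np.zeros(len(loci), dtype=bool)
    for i, (_, locus) in enumerate(loci.iterrows()):
        chrom = locus["chrom"]
        if chrom in index:
            cnt = index[chrom].count_in(
                np.array([locus["start"]]), np.array([locus["end"]])
            )[0]
            in_sd[i] = cnt > 0
    loci = loci.assign(in_sd=in_sd)
    strata = {"sd": loci[loci["in_sd"]], "non_sd": loci[~loci["in_sd"]]}

    props: dict[str, dict[str, np.ndarray]] = {}
    for name, sub in strata.items():
        p: dict[str, np.ndarray] = {
            "size": (sub["end"] - sub["start"]).values.astype(float),
            "complex": sub["complex_flag"].values.astype(float)
            if "complex_flag" in sub.columns
            else np.array([]),
        }
        if genotypes is not None and len(sub):
            freq = carrier_freq_by_locus(genotypes)
            p["frequency"] = freq.reindex(sub["locus_id"]).values
        if genes is not None and len(sub):
            per, _ = classify_gene_overlap(sub, genes)
            p["genic"] = (per["overlap_class"] != "intergenic").values.astype(float)
        props[name] = p

    rows = []
    for prop in props["sd"]:
        a, b = props["sd"].get(prop), props["non_sd"].get(prop)
        if a is None or b is None or a.size == 0 or b.size == 0:
            continue
        stat = "median" if prop == "size" else "mean"
        cmp = bootstrap_compare(a, b, statistic=stat, reps=reps, seed=seed)
        rows.append(
            {
                "property": prop,
                "sd_value": float(np.median(a) if stat == "median" else np.mean(a)),
                "non_sd_value": float(np.median(b) if stat == "median" else np.mean(b)),
                "n_sd": int(a.size),
                "n_non_sd": int(b.size),
                "difference": cmp["difference"],
                "p": cmp["p"],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_sd_loci"] = int(in_sd.sum())
    out.attrs["n_non_sd_loci"] = int((~in_sd).sum())
    return out


def carrier_freq_by_locus(genotypes: pd.DataFrame) -> pd.Series:
    """Fraction of samples with a non-ref state, per locus."""
    states = genotypes.pivot(index="locus_id", columns="sample", values="state")
    return (states != "ref").mean(axis=1)

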