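"""Three-stage CNV selection: discovery, cross-sample merging, genotyping.

Discovery uses a stringent per-(sample, chromosome) threshold to find
candidate CNVs in single samples; overlapping calls from all samples are
merged into loci whose breakpoints are the outermost call boundaries; each
sample is then genotyped at every locus with a lenient threshold.

Both thresholds combine a fixed copy-deviation cutoff with a
variance-adaptive cutoff derived from the block's standard deviation:
noisy blocks are protected by the higher of the two at discovery, quiet
blocks profit from the lower of the two at genotyping. Copy number is
quantified as 2**(1 + mean log2 ratio), rounded half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from caninecnv.io import RatioMatrix
from caninecnv.preprocess import _best_single_changepoint


@dataclass
class CallingParams:
    """Thresholding constants of the dual-threshold selection.

    d_disc, d_geno : fixed copy-number deviations from the diploid
        reference for discovery (0.65) and genotyping (0.5).
    q_disc, q_geno : two-tailed normal tail mass for the variance-adaptive
        thresholds (0.1% discovery, 5% genotyping).
    min_probes : minimum consecutive probes supporting a call.
    """

    d_disc: float = 0.65
    d_geno: float = 0.5
    q_disc: float = 0.001
    q_geno: float = 0.05
    min_probes: int = 10
    sigma_estimator: str = "mad"

    def __post_init__(self) -> None:
        if self.sigma_estimator not in ("mad", "std"):
            raise ValueError("sigma_estimator must be 'mad' or 'std'")
        if not (0 < self.d_geno <= self.d_disc < 2):
            raise ValueError("need 0 < d_geno <= d_disc < 2")
        if not (0 < self.q_disc <= self.q_geno < 1):
            raise ValueError("need 0 < q_disc <= q_geno < 1")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


def fixed_log2_threshold(d: float, direction: str) -> float:
    """Log2-ratio cutoff for a fixed copy deviation d from diploid.

    gain: log2((2+d)/2); loss: |log2((2-d)/2)|. Asymmetric because log2 is
    nonlinear in copies.
    """
    if not 0 <= d < 2:
        raise ValueError("copy deviation must be in [0, 2)")
    if direction == "gain":
        return math.log2((2 + d) / 2)
    if direction == "loss":
        return abs(math.log2((2 - d) / 2))
    raise ValueError(f"unknown direction {direction!r}")


def sd_threshold(sigma: float, q: float) -> float:
    """Variance-adaptive cutoff: sigma times the two-tailed normal quantile
    leaving total mass q outside (z = Phi^-1(1 - q/2))."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(sigma * norm.ppf(1 - q / 2))


def compute_thresholds(smoothed: RatioMatrix, params: CallingParams | None = None) -> pd.DataFrame:
    """Per-(sample, chromosome) discovery and genotyping thresholds.

    discovery = max(fixed, sd-based) and genotyping = min(fixed, sd-based),
    per direction. Blocks with fewer than 2 probes have undefined sigma and
    use the fixed values alone. Threshold ordering (discovery >= genotyping
    in each direction) is asserted on every block.

    sigma describes the noise bulk of the block — the normal distribution
    CNV signal should stand clear of — so the default estimate is the
    robust MAD / Phi^-1(3/4), which real CNVs in the block do not inflate;
    sigma_estimator="std" gives the naive standard deviation instead.
    """
    params = params or CallingParams()
    z75 = float(norm.ppf(0.75))
    rows = []
    for chrom in smoothed.probes.chroms:
        sl = smoothed.probes.chrom_slice(chrom)
        for s in smoothed.sample_ids:
            block = smoothed.values[s].values[sl]
            if block.size < 2:
                sigma = None
            elif params.sigma_estimator == "mad":
                sigma = float(np.median(np.abs(block - np.median(block))) / z75)
            else:
                sigma = float(np.std(block, ddof=1))
            row = {"sample": s, "chrom": chrom, "sigma": sigma}
            for direction in ("gain", "loss"):
                fx_d = fixed_log2_threshold(params.d_disc, direction)
                fx_g = fixed_log2_threshold(params.d_geno, direction)
                if sigma is None:
                    disc, geno = fx_d, fx_g
                else:
                    disc = max(fx_d, sd_threshold(sigma, params.q_disc))
                    geno = min(fx_g, sd_threshold(sigma, params.q_geno))
                assert disc >= geno
                row[f"disc_{direction}"] = disc
                row[f"geno_{direction}"] = geno
            rows.append(row)
    return pd.DataFrame(rows)


def discover(
    segments: pd.DataFrame,
    thresholds: pd.DataFrame,
    smoothed: RatioMatrix,
    params: CallingParams | None = None,
    raw: RatioMatrix | None = None,
) -> pd.DataFrame:
    """Per-sample discovery calls from segmented, smoothed ratios.

    Candidate segments are those whose data mean (mean of the smoothed
    values over the segment's probes — the level estimate, free of the
    fused-lasso shrinkage) reaches the lenient *fixed* genotyping cutoff
    (0.5 copies); maximal runs of adjacent same-sign candidates form one
    putative call.
    The call is emitted when its pooled mean over all run probes exceeds
    the stringent discovery threshold for its sign and the run spans at
    least ``min_probes`` probes. Coordinates run from the first to one
    past the last probe position of the run.
    """
    params = params or CallingParams()
    thr = thresholds.set_index(["sample", "chrom"])
    cand_gain = fixed_log2_threshold(params.d_geno, "gain")
    cand_loss = fixed_log2_threshold(params.d_geno, "loss")
    rows = []
    for (s, chrom), grp in segments.groupby(["sample", "chrom"], sort=False):
        t = thr.loc[(s, chrom)]
        grp = grp.sort_values("start_idx")
        vals = smoothed.block(s, chrom)
        refine_vals = raw.block(s, chrom) if raw is not None else vals
        pos = smoothed.probes.positions(chrom)
        candidates = []
        for _, seg in grp.iterrows():
            i0, i1 = int(seg["start_idx"]), int(seg["end_idx"])
            m = float(vals[i0 : i1 + 1].mean())
            if m >= cand_gain:
                candidates.append(("gain", i0, i1))
            elif m <= -cand_loss:
                candidates.append(("loss", i0, i1))
            else:
                candidates.append(None)

        def refine(i0: int, i1: int) -> tuple[int, int]:
            # smoothing spreads each true edge symmetrically over the
            # window, so the SSE-optimal single changepoint of the local
            # values re-locates the edge at probe resolution
            half = 6
            w0, w1 = max(0, i0 - half), min(refine_vals.size, i0 + half)
            if w1 - w0 >= 4:
                i0 = w0 + _best_single_changepoint(refine_vals[w0:w1])
            w0, w1 = max(0, i1 + 1 - half), min(refine_vals.size, i1 + 1 + half)
            if w1 - w0 >= 4:
                i1 = w0 + _best_single_changepoint(refine_vals[w0:w1]) - 1
            return i0, i1

        def flush(run: list, run_sign: str | None) -> None:
            if not run:
                return
            i0, i1 = refine(run[0][1], run[-1][2])
            n = i1 - i0 + 1
            if n < params.min_probes:
                return
            mean = float(vals[i0 : i1 + 1].mean())
            if run_sign == "gain" and mean < t["disc_gain"]:
                return
            if run_sign == "loss" and mean > -t["disc_loss"]:
                return
            rows.append(
                {
                    "sample": s,
                    "chrom": chrom,
                    "start": int(pos[i0]),
                    "end": int(pos[i1]) + 1,
                    "sign": run_sign,
                    "n_probes": n,
                    "mean_log2": mean,
                    "start_idx": i0,
                    "end_idx": i1,
                }
            )

        run: list = []
        run_sign = None
        for item in candidates:
            if item is None:
                flush(run, run_sign)
                run, run_sign = [], None
                continue
            sign, i0, i1 = item
            if sign != run_sign and run:
                flush(run, run_sign)
                run = []
            run_sign = sign
            run.append(item)
        flush(run, run_sign)
    cols = ["sample", "chrom", "start", "end", "sign", "n_probes", "mean_log2", "start_idx", "end_idx"]
    return pd.DataFrame(rows, columns=cols)


def merge_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge per-sample calls into cross-sample CNV locus skeletons.

    Single-linkage chaining: calls overlapping by >= 1 bp (any sign, any
    sample) join one locus; locus boundaries are the outermost boundaries
    of the contributing calls. Half-open intervals, so abutting calls do
    not merge.
    """
    loci = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        members: list[int] = []
        for idx, row in grp.iterrows():
            if cur_end is None:
                cur_start, cur_end, members = row["start"], row["end"], [idx]
            elif row["start"] < cur_end:  # >=1 bp overlap
                cur_end = max(cur_end, row["end"])
                members.append(idx)
            else:
                loci.append((chrom, int(cur_start), int(cur_end), list(members)))
                cur_start, cur_end, members = row["start"], row["end"], [idx]
        if cur_end is not None:
            loci.append((chrom, int(cur_start), int(cur_end), list(members)))
    out = pd.DataFrame(loci, columns=["chrom", "start", "end", "call_indices"])
    out.insert(0, "locus_id", [f"cnv_{i:04d}" for i in range(len(out))])
    return out


def genotype_locus(
    locus: pd.Series,
    smoothed: RatioMatrix,
    thresholds: pd.DataFrame,
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Genotype every sample at one locus with the lenient thresholds.

    With m the mean smoothed log2 ratio over the locus probes and a the
    mean absolute value: m above the gain cutoff -> dup; m below the loss
    cutoff -> del; otherwise a above the smaller cutoff -> complex (the
    adjacent deletion+duplication signature); else ref. Copy number is
    round-half-away-from-zero of 2**(1+m); complex samples get CN = NA.
    """
    params = params or CallingParams()
    thr = thresholds.set_index(["sample", "chrom"])
    chrom = locus["chrom"]
    sl = smoothed.probes.chrom_slice(chrom)
    pos = smoothed.probes.positions(chrom)
    mask = (pos >= locus["start"]) & (pos < locus["end"])
    rows = []
    for s in smoothed.sample_ids:
        block = smoothed.values[s].values[sl][mask]
        m = float(block.mean())
        a = float(np.abs(block).mean())
        t = thr.loc[(s, chrom)]
        # strict-sign guards keep degenerate zero thresholds (sigma = 0
        # blocks) from genotyping a perfectly flat sample as non-ref
        if m >= t["geno_gain"] and m > 0:
            state = "dup"
        elif m <= -t["geno_loss"] and m < 0:
            state = "del"
        elif a > min(t["geno_gain"], t["geno_loss"]) and a > 0:
            state = "complex"
        else:
            state = "ref"
        if state == "complex":
            cn: float | None = None
        else:
            x = 2.0 ** (1.0 + m)
            cn = int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
        rows.append(
            {
                "locus_id": locus["locus_id"],
                "sample": s,
                "state": state,
                "cn": cn,
                "mean_log2": m,
                "mean_abs_log2": a,
            }
        )
    return pd.DataFrame(rows)


def classify_locus(genotypes: pd.DataFrame) -> tuple[str, bool]:
    """Classify one locus from its per-sample states.

    deletion if all simple non-ref states are del, duplication if all dup,
    both otherwise. Complex samples set the complex flag but do not decide
    the class unless no simple non-ref state exists (then: both).
    """
    states = genotypes["state"]
    if (states == "ref").all():
        raise ValueError("all-ref locus cannot be classified")
    complex_flag = bool((states == "complex").any())
    simple = set(states) & {"del", "dup"}
    if simple == {"del"}:
        cls = "deletion"
    elif simple == {"dup"}:
        cls = "duplication"
    else:
        cls = "both"
    return cls, complex_flag


def call_cnvs(
    smoothed: RatioMatrix,
    segments: pd.DataFrame,
    params: CallingParams | None = None,
    raw: RatioMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full three-stage calling; returns (loci, genotypes) tables.

    loci: locus_id, chrom, start, end, n_probes, class, complex_flag.
    genotypes: locus_id, sample, state, cn, mean_log2, mean_abs_log2.
    Loci where every sample genotypes ref under the lenient threshold
    (possible when the discovery call was borderline) are dropped.
    """
    params = params or CallingParams()
    thresholds = compute_thresholds(smoothed, params)
    calls = discover(segments, thresholds, smoothed, params, raw=raw)
    if not len(calls):
        empty_loci = pd.DataFrame(
            columns=["locus_id", "chrom", "start", "end", "n_probes", "class", "complex_flag"]
        )
        empty_gt = pd.DataFrame(
            columns=["locus_id", "sample", "state", "cn", "mean_log2", "mean_abs_log2"]
        )
        return empty_loci, empty_gt
    loci = merge_calls(calls)
    gt_frames = []
    locus_rows = []
    for _, locus in loci.iterrows():
        gt = genotype_locus(locus, smoothed, thresholds, params)
        # samples contributing a discovery call must genotype non-ref;
        # guaranteed because genotyping thresholds never exceed discovery.
        if (gt["state"] == "ref").all():
            continue
        cls, complex_flag = classify_locus(gt)
        chrom = locus["chrom"]
        pos = smoothed.probes.positions(chrom)
        n_probes = int(((pos >= locus["start"]) & (pos < locus["end"])).sum())
        locus_rows.append(
            {
                "locus_id": locus["locus_id"],
                "chrom": chrom,
                "start": int(locus["start"]),
                "end": int(locus["end"]),
                "n_probes": n_probes,
                "class": cls,
                "complex_flag": complex_flag,
            }
        )
        gt_frames.append(gt)
    loci_out = pd.DataFrame(
        locus_rows,
        columns=["locus_id", "chrom", "start", "end", "n_probes", "class", "complex_flag"],
    )
    genotypes = (
        pd.concat(gt_frames, ignore_index=True)
        if gt_frames
        else pd.DataFrame(columns=["locus_id", "sample", "state", "cn", "mean_log2", "mean_abs_log2"])
    )
    return loci_out, genotypes
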