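"""Piecewise-constant segmentation of smoothed log2 ratios by fused lasso.

The signal approximator minimizes

    1/2 * sum_i (y_i - b_i)^2 + lam1 * sum_i |b_i| + lam2 * sum_i |b_i - b_{i-1}|

whose solution is piecewise constant along the chromosome; maximal runs of
equal fitted values are reported as segments. The total-variation part
(lam1 = 0) is solved *exactly* by dynamic programming over the derivative
of the Bellman value function, which stays piecewise linear and is clipped
at +/-lam2 at every step; the sparsity part separates and is applied as
elementwise soft-thresholding of the fused solution.

lam2 may be given as "auto": the smallest value on a logarithmic grid whose
changepoint count is stable under a residual sign-flip refit is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from caninecnv.io import RatioMatrix


@dataclass
class SegmentationParams:
    """Tuning for the fused-lasso fit.

    lam1 : sparsity penalty (default 0 — discovery thresholds, not
        sparsity, decide calls downstream).
    lam2 : fusion penalty, a float or "auto".
    window : smoothing window carried for provenance (must be odd).
    """

    lam1: float = 0.0
    lam2: float | str = "auto"
    window: int = 11

    def __post_init__(self) -> None:
        if self.lam1 < 0:
            raise ValueError("lam1 must be >= 0")
        if not isinstance(self.lam2, str) and self.lam2 < 0:
            raise ValueError("lam2 must be >= 0")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")


def tv_denoise(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact 1D total-variation denoising (fused lasso with lam1 = 0).

    Dynamic program on the derivative of the running value function: the
    derivative is piecewise linear and nondecreasing; the inf-convolution
    with lam*|.| clips it to [-lam, +lam], and each data term adds the line
    b - y_k. Clip positions are recorded and the fit recovered by
    backtracking. Exact up to float rounding for any n.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return y.copy()
    if n == 1 or lam == 0:
        return y.copy()
    if lam < 0:
        raise ValueError("lam must be >= 0")

    # derivative of f_k: knots xs with values vs, linear between; slope 1
    # on both tails (each step adds a unit-slope line after clipping).
    xs = np.array([y[0]])
    vs = np.array([0.0])
    lo = np.empty(n - 1)
    hi = np.empty(n - 1)

    for k in range(1, n):
        # clip derivative at -lam (left) and +lam (right); tails have slope 1
        if vs[0] <= -lam:
            i = int(np.searchsorted(vs, -lam, side="left"))
            if i == 0:
                x_lo = xs[0]
            elif i == len(xs):  # crossing on the right tail (slope 1)
                x_lo = xs[-1] + (-lam - vs[-1])
            else:  # interpolate within piece [i-1, i]
                x_lo = float(np.interp(-lam, vs[i - 1 : i + 1], xs[i - 1 : i + 1]))
        else:
            i = 0
            x_lo = xs[0] - (vs[0] + lam)  # left tail slope 1
        if vs[-1] >= lam:
            j = int(np.searchsorted(vs, lam, side="right"))
            if j == len(xs):
                x_hi = xs[-1]
            elif j == 0:  # crossing on the left tail (slope 1)
                x_hi = xs[0] - (vs[0] - lam)
            else:
                x_hi = float(np.interp(lam, vs[j - 1 : j + 1], xs[j - 1 : j + 1]))
        else:
            j = len(xs)
            x_hi = xs[-1] + (lam - vs[-1])
        lo[k - 1] = x_lo
        hi[k - 1] = x_hi
        keep = slice(i, j)
        inner = (xs[keep] > x_lo) & (xs[keep] < x_hi)
        xs = np.concatenate([[x_lo], xs[keep][inner], [x_hi]])
        vs = np.concatenate([[-lam], vs[keep][inner], [lam]])
        # add data term derivative (b - y[k])
        vs = vs + (xs - y[k])

    # root of final derivative (slope-1 tails guarantee a root)
    if vs[0] > 0:
        b = xs[0] - vs[0]
    elif vs[-1] < 0:
        b = xs[-1] - vs[-1]
    else:
        i = int(np.searchsorted(vs, 0.0, side="left"))
        if i == 0:
            b = xs[0]
        else:
            b = np.interp(0.0, vs[i - 1 : i + 1], xs[i - 1 : i + 1])

    beta = np.empty(n)
    beta[-1] = b
    for k in range(n - 2, -1, -1):
        beta[k] = min(max(beta[k + 1], lo[k]), hi[k])
    return beta


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def fused_lasso_fit(y: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    """Fitted values of the fused-lasso signal approximator.

    The identity-design fused lasso separates: solve the pure fusion
    problem, then soft-threshold the fit by lam1.
    """
    beta = tv_denoise(y, lam2)
    if lam1 > 0:
        beta = soft_threshold(beta, lam1)
    return beta


def _runs(beta: np.ndarray, atol: float = 1e-9) -> list[tuple[int, int, float]]:
    """Maximal runs of equal fitted values -> (start_idx, end_idx, value)."""
    n = beta.size
    if n == 0:
        return []
    breaks = np.flatnonzero(np.abs(np.diff(beta)) > atol)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [n - 1]])
    return [(int(s), int(e), float(beta[s : e + 1].mean())) for s, e in zip(starts, ends)]


def auto_lambda2(y: np.ndarray, lam1: float = 0.0, c: float = 0.5) -> float:
    """Universal-threshold fusion penalty for one chromosome block.

    lam2 = c * sigma_block * sqrt(2 log n), with sigma_block the standard
    deviation of the (smoothed) block. At this scale noise fluctuations
    fuse into long flat runs while copy-number steps of the magnitudes the
    calling thresholds target survive as separate segments.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        return 1.0
    sigma = float(np.std(y, ddof=1))
    if sigma == 0.0:
        return 1.0
    return float(c * sigma * np.sqrt(2.0 * np.log(n)))


def segment_fused_lasso(
    values: np.ndarray, params: SegmentationParams | None = None
) -> list[tuple[int, int, float]]:
    """Segment one chromosome's values; returns (start, end, value) runs.

    ``end`` is inclusive. Adjacent runs have distinct fitted values by
    construction; the runs partition the probe index range.
    """
    params = params or SegmentationParams()
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    lam2 = params.lam2
    if isinstance(lam2, str):
        if lam2 != "auto":
            raise ValueError(f"unknown lam2 mode {lam2!r}")
        lam2 = auto_lambda2(values, params.lam1)
    beta = fused_lasso_fit(values, params.lam1, float(lam2))
    return _runs(beta)


def segment_matrix(
    smoothed: RatioMatrix, params: SegmentationParams | None = None
) -> pd.DataFrame:
    """Segment every (sample, chromosome) block of a smoothed matrix.

    Returns a table with one row per segment: sample, chrom, start_idx,
    end_idx (inclusive, chromosome-local), start_bp, end_bp (half-open bp
    span from first to one-past-last probe position), value, n_probes.
    """
    params = params or SegmentationParams()
    rows = []
    for chrom in smoothed.probes.chroms:
        pos = smoothed.probes.positions(chrom)
        for s in smoothed.sample_ids:
            block = smoothed.block(s, chrom)
            for start, end, value in segment_fused_lasso(block, params):
                rows.append(
                    (s, chrom, start, end, int(pos[start]), int(pos[end]) + 1, value, end - start + 1)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "chrom",
            "start_idx",
            "end_idx",
            "start_bp",
            "end_bp",
            "value",
            "n_probes",
        ],
    )
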