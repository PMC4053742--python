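"""Per-chromosome centering and triangular smoothing of log2 ratios.

Centering removes per-chip, per-chromosome intensity biases by subtracting
each (sample, chromosome) block's mean. The X chromosome is handled
specially against a male reference: the pseudo-autosomal region (PAR) is
diploid in both sexes while the rest of X differs in relative copy number,
so the two parts are centered separately, with the PAR boundary either
supplied or estimated from the female samples' raw X ratios.
"""

from __future__ import annotations

import warnings

import numpy as np

from caninecnv.io import RatioMatrix

TRI_WEIGHTS = np.array([1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1], dtype=float) / 36.0


def triangular_smooth(values: np.ndarray, window: int = 11) -> np.ndarray:
    """11-point triangular weighted smoothing of one chromosome's ratios.

    Weights rise linearly to the center ((1,2,...,6,...,2,1)/36 for the
    default window). At chromosome edges the window is truncated and the
    weights renormalized, so constant signal is preserved everywhere and
    telomeric signal is not shrunk toward zero.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return values.copy()
    half = window // 2
    ramp = np.arange(1, half + 2, dtype=float)
    w = np.concatenate([ramp, ramp[-2::-1]])
    w /= w.sum()
    # full convolution, then renormalize truncated edge windows; the
    # explicit slice also handles blocks shorter than the window
    num = np.convolve(values, w, mode="full")[half : half + n]
    den = np.convolve(np.ones(n), w, mode="full")[half : half + n]
    return num / den


def center_by_chromosome(
    matrix: RatioMatrix,
    par_boundary: int | None = None,
    x_chrom: str = "chrX",
    stat: str = "median",
) -> RatioMatrix:
    """Center each (sample, chromosome) block on its median (or mean).

    The median aligns the diploid baseline at zero without being dragged
    by the block's own CNV signal; ``stat="mean"`` restores plain mean
    removal (equivalent on CNV-sparse chromosomes). On ``x_chrom``,
    probes strictly before ``par_boundary`` (the PAR) and from it onward
    are centered separately per sample. If the matrix contains female
    samples and X probes, a boundary must be supplied or discoverable via
    :func:`locate_par_boundary`.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    loc = np.median if stat == "median" else np.mean
    out = matrix.copy()
    arr = out.values.to_numpy(copy=True)
    for chrom in out.probes.chroms:
        sl = out.probes.chrom_slice(chrom)
        if sl.stop == sl.start:
            warnings.warn(f"empty chromosome block {chrom}", stacklevel=2)
            continue
        if chrom == x_chrom and par_boundary is None:
            females = list(
                matrix.samples.loc[matrix.samples["sex"] == "F", "sample_id"]
            )
            females = [s for s in females if s in matrix.sample_ids]
            if females:
                par_boundary = locate_par_boundary(matrix, x_chrom=x_chrom)
        block = arr[sl]
        if chrom == x_chrom and par_boundary is not None:
            pos = out.probes.positions(chrom)
            par = pos < par_boundary
            for mask in (par, ~par):
                if mask.any():
                    block[mask] = block[mask] - loc(block[mask], axis=0)
        else:
            block -= loc(block, axis=0)
    out.values = type(out.values)(arr, columns=out.values.columns)
    return out


def _best_single_changepoint(values: np.ndarray) -> int:
    """Index k (1..n-1) minimizing two-segment SSE: [0,k) vs [k,n)."""
    n = values.size
    if n < 2:
        raise ValueError("need >= 2 probes to locate a changepoint")
    c = np.cumsum(values)
    c2 = np.cumsum(values**2)
    k = np.arange(1, n)
    sse_left = c2[k - 1] - c[k - 1] ** 2 / k
    sum_r = c[-1] - c[k - 1]
    sse_right = (c2[-1] - c2[k - 1]) - sum_r**2 / (n - k)
    return int(k[np.argmin(sse_left + sse_right)])


def locate_par_boundary(matrix: RatioMatrix, x_chrom: str = "chrX") -> int:
    """Estimate the pseudo-autosomal boundary on X from female samples.

    Against a male reference, females carry one extra X copy outside the
    PAR, so each female's raw X ratios show a single step. For every female
    the position of the best two-segment changepoint is found exhaustively;
    the boundary is the average of those positions (as an integer bp).
    """
    females = list(matrix.samples.loc[matrix.samples["sex"] == "F", "sample_id"])
    females = [s for s in females if s in matrix.sample_ids]
    if not females:
        raise ValueError("no female samples; supply the PAR boundary explicitly")
    pos = matrix.probes.positions(x_chrom)
    if pos.size < 2:
        raise ValueError(f"no probes on {x_chrom}")
    boundaries = []
    for s in females:
        block = matrix.block(s, x_chrom)
        k = _best_single_changepoint(block)
        boundaries.append(pos[k])
    return int(round(float(np.mean(boundaries))))


def smooth_matrix(matrix: RatioMatrix, window: int = 11) -> RatioMatrix:
    """Apply triangular smoothing per sample per chromosome."""
    out = matrix.copy()
    arr = out.values.to_numpy(copy=True)
    for chrom in out.probes.chroms:
        sl = out.probes.chrom_slice(chrom)
        for j in range(arr.shape[1]):
            arr[sl, j] = triangular_smooth(arr[sl, j], window)
    out.values = type(out.values)(arr, columns=out.values.columns)
    return out


def preprocess(
    matrix: RatioMatrix,
    par_boundary: int | None = None,
    window: int = 11,
    x_chrom: str = "chrX",
    stat: str = "median",
) -> RatioMatrix:
    """Center per chromosome (PAR-aware) then smooth; the standard order."""
    return smooth_matrix(
        center_by_chromosome(
            matrix, par_boundary=par_boundary, x_chrom=x_chrom, stat=stat
        ),
        window=window,
    )
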