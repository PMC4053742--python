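"""Shared fixtures: a compact synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from caninecnv.io import ProbeSet, RatioMatrix
from caninecnv.simulate import SimLayout, SimNoise, build_probe_grid, draw_truth_set, render_ratio_matrix


@pytest.fixture(scope="session")
def small_layout() -> SimLayout:
    chroms = [(f"chr{i + 1}", 500_000) for i in range(2)]
    samples = [(f"B{b}_{i}", f"B{b}", "M") for b in range(4) for i in range(2)]
    return SimLayout(chromosomes=chroms, samples=samples, seed=5)


@pytest.fixture(scope="session")
def small_probes(small_layout) -> ProbeSet:
    return build_probe_grid(small_layout)


@pytest.fixture(scope="session")
def small_study(small_layout, small_probes):
    """Layout, probes, truth and a noisy ratio matrix (sd = 0.08)."""
    truth = draw_truth_set(small_layout, n_loci=8, seed=6)
    ratios = render_ratio_matrix(
        small_probes, truth, SimNoise(sd=0.08), seed=7, layout=small_layout
    )
    return small_layout, small_probes, truth, ratios


def make_matrix(values_by_chrom: dict[str, np.ndarray], sample: str = "s1") -> RatioMatrix:
    """Build a single-sample RatioMatrix from per-chromosome value arrays."""
    rows = []
    vals = []
    for chrom, arr in values_by_chrom.items():
        for i, v in enumerate(arr):
            rows.append((chrom, 1000 * (i + 1), f"{chrom}_p{i}"))
            vals.append(v)
    probes = ProbeSet(pd.DataFrame(rows, columns=["chrom", "pos", "probe_id"]))
    values = pd.DataFrame({sample: vals})
    samples = pd.DataFrame({"sample_id": [sample], "breed": ["X"], "sex": ["M"]})
    return RatioMatrix(probes, values, samples)
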