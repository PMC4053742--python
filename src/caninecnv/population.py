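"""Breed-level population analyses of CNV genotypes.

Breed summaries (total / multi-breed / breed-specific loci, polymorphic vs
fixed, private loci), minor-allele site frequency spectra, detection of
loci fixed for alternative states between breeds, pairwise CNV-sharing
distances, a Saitou-Nei neighbor-joining tree, and Fisher's exact test for
the contingency comparisons.

A sample is a *carrier* at a locus when its genotype state differs from
ref (del, dup or complex all count). A locus is *in* a breed when at least
one of the breed's samples carries it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from caninecnv.io import TreeNode


def _state_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pivot genotypes to a locus x sample state matrix."""
    return genotypes.pivot(index="locus_id", columns="sample", values="state")


def carrier_frequency(
    genotypes: pd.DataFrame, breeds: pd.DataFrame | None = None, scope: str = "samples"
) -> pd.Series:
    """Per-locus carrier frequency over samples or over breeds.

    samples: fraction of samples with state != ref. breeds: fraction of
    breeds with at least one carrier sample (requires a sample sheet).
    """
    states = _state_matrix(genotypes)
    if states.shape[1] == 0:
        raise ValueError("empty scope")
    carrier = states != "ref"
    if scope == "samples":
        return carrier.mean(axis=1)
    if scope == "breeds":
        if breeds is None:
            raise ValueError("breed scope requires a sample sheet")
        breed_of = dict(zip(breeds["sample_id"], breeds["breed"]))
        grouped = carrier.T.groupby([breed_of[s] for s in carrier.columns]).any()
        return grouped.mean(axis=0)
    raise ValueError(f"unknown scope {scope!r}")


def breed_summary(genotypes: pd.DataFrame, breeds: pd.DataFrame) -> pd.DataFrame:
    """Per-breed locus accounting.

    Columns: n_samples; total (loci with >=1 carrier in the breed); mb
    (also carried in another breed) and bs (breed-specific), with
    total = mb + bs; avg_total/avg_mb/avg_bs per-sample averages;
    matching_ref (loci with no carrier in the breed); polymorphic (carried
    by some but not all of the breed's samples) and fixed (carried by all),
    with total = polymorphic + fixed; and the private splits
    private_polymorphic / private_fixed. Internal identities are asserted.
    """
    states = _state_matrix(genotypes)
    carrier = states != "ref"
    breed_of = dict(zip(breeds["sample_id"], breeds["breed"]))
    missing = [s for s in carrier.columns if s not in breed_of]
    if missing:
        raise ValueError(f"samples without breed: {missing}")
    by_breed: dict[str, list[str]] = {}
    for s in carrier.columns:
        by_breed.setdefault(breed_of[s], []).append(s)
    in_breed = pd.DataFrame(
        {b: carrier[cols].any(axis=1) for b, cols in by_breed.items()}
    )
    n_breeds_with = in_breed.sum(axis=1)

    rows = []
    for b, cols in by_breed.items():
        if not cols:
            raise ValueError(f"breed {b} has zero samples")
        sub = carrier[cols]
        present = in_breed[b]
        total = int(present.sum())
        bs = int((present & (n_breeds_with == 1)).sum())
        mb = total - bs
        fixed = sub.all(axis=1) & present
        poly = present & ~fixed
        private = present & (n_breeds_with == 1)
        per_sample = sub.sum(axis=0)
        mb_loci = present & (n_breeds_with > 1)
        avg_mb = float(sub[sub.columns].loc[mb_loci].sum(axis=0).mean()) if total else 0.0
        avg_bs = float(sub.loc[private].sum(axis=0).mean()) if total else 0.0
        row = {
            "breed": b,
            "n_samples": len(cols),
            "total": total,
            "mb": mb,
            "bs": bs,
            "avg_total": float(per_sample.mean()),
            "avg_mb": avg_mb,
            "avg_bs": avg_bs,
            "matching_ref": int((~present).sum()),
            "polymorphic": int(poly.sum()),
            "fixed": int(fixed.sum()),
            "shared_polymorphic": int((poly & mb_loci).sum()),
            "shared_fixed": int((fixed & mb_loci).sum()),
            "private_polymorphic": int((poly & private).sum()),
            "private_fixed": int((fixed & private).sum()),
        }
        assert row["total"] == row["mb"] + row["bs"]
        assert row["total"] == row["polymorphic"] + row["fixed"]
        assert row["matching_ref"] + row["total"] == len(states)
        rows.append(row)
    return pd.DataFrame(rows).set_index("breed")


def summary_averages(summary: pd.DataFrame) -> pd.DataFrame:
    """Group-wise means of the breed summary by sample size (2 vs 10 dogs)."""
    out = {}
    for n in sorted(summary["n_samples"].unique()):
        grp = summary[summary["n_samples"] == n]
        out[f"{n}-sample breeds"] = grp.drop(columns="n_samples").mean(numeric_only=True)
    return pd.DataFrame(out).T


def sfs(
    genotypes: pd.DataFrame,
    breeds: pd.DataFrame,
    scope: str = "two_sample",
) -> pd.Series:
    """Folded (minor-allele) site frequency spectrum.

    The minor allele of each locus is fixed from the samples of two-sample
    breeds: the rarer of {ref, carrier}; ties go to the carrier allele.
    scope "two_sample" counts minor-allele samples across all two-sample
    breeds (bins 1..n/2); a breed name counts them within that breed.
    Loci with zero minor-allele samples in scope are excluded.
    """
    states = _state_matrix(genotypes)
    carrier = states != "ref"
    breed_of = dict(zip(breeds["sample_id"], breeds["breed"]))
    sizes = breeds.groupby("breed")["sample_id"].count()
    two_sample = [
        s for s in carrier.columns if sizes.get(breed_of[s], 0) == 2
    ]
    if not two_sample:
        raise ValueError("no two-sample breeds in scope")
    n_ts = len(two_sample)
    carrier_count = carrier[two_sample].sum(axis=1)
    # minor allele identity: carrier when carrier_count <= n/2 (tie -> carrier)
    minor_is_carrier = carrier_count <= n_ts / 2

    if scope == "two_sample":
        cols = two_sample
        max_bin = n_ts // 2
    else:
        cols = [s for s in carrier.columns if breed_of[s] == scope]
        if not cols:
            raise ValueError(f"unknown breed scope {scope!r}")
        max_bin = len(cols)
    sub = carrier[cols]
    minor_count = sub.sum(axis=1).where(minor_is_carrier, (~sub).sum(axis=1))
    minor_count = minor_count[minor_count > 0]
    bins = np.arange(1, max_bin + 1)
    hist = pd.Series(0, index=bins, name="loci")
    vc = minor_count.value_counts()
    for k, v in vc.items():
        if k in hist.index:
            hist.loc[k] = int(v)
    return hist


def fixed_differences(genotypes: pd.DataFrame, breeds: pd.DataFrame) -> pd.DataFrame:
    """Loci fixed for alternative states between two-sample breeds.

    Restricted to two-sample breeds: reports loci where every breed is
    internally monomorphic (both samples in the identical state) and at
    least two states occur across breeds, with the partition of non-ref
    breeds.
    """
    states = _state_matrix(genotypes)
    breed_of = dict(zip(breeds["sample_id"], breeds["breed"]))
    sizes = breeds.groupby("breed")["sample_id"].count()
    two_breeds = [b for b in sizes.index if sizes[b] == 2]
    cols_by_breed = {
        b: [s for s in states.columns if breed_of.get(s) == b] for b in two_breeds
    }
    cols_by_breed = {b: c for b, c in cols_by_breed.items() if len(c) == 2}
    rows = []
    for locus, row in states.iterrows():
        breed_states = {}
        mono = True
        for b, (s1, s2) in cols_by_breed.items():
            if row[s1] != row[s2]:
                mono = False
                break
            breed_states[b] = row[s1]
        if not mono:
            continue
        distinct = set(breed_states.values())
        if len(distinct) < 2:
            continue
        nonref = sorted(b for b, st in breed_states.items() if st != "ref")
        rows.append(
            {
                "locus_id": locus,
                "nonref_breeds": ",".join(nonref),
                "n_nonref_breeds": len(nonref),
                "states": ",".join(sorted(distinct)),
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "nonref_breeds", "n_nonref_breeds", "states"])


def pairwise_distance(genotypes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """State-mismatch distances between samples over all loci.

    d(i, j) = fraction of loci where the two samples' states differ
    (complex is its own state). Returns (fractions, raw mismatch counts).
    """
    states = _state_matrix(genotypes)
    samples = list(states.columns)
    arr = states.values
    codes = pd.factorize(arr.ravel())[0].reshape(arr.shape)
    n = len(samples)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = (codes[:, i][:, None] != codes).sum(axis=0)
        counts[i] = diff
    frac = counts / len(states) if len(states) else counts.astype(float)
    d = pd.DataFrame(frac, index=samples, columns=samples)
    c = pd.DataFrame(counts, index=samples, columns=samples)
    return d, c


def breed_distance(dist: pd.DataFrame, breeds: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a sample-level distance matrix to breed level.

    Breed-pair distance is the mean over all cross-breed sample pairs
    (within-breed: mean over distinct pairs; 0 for singleton breeds).
    """
    breed_of = dict(zip(breeds["sample_id"], breeds["breed"]))
    groups: dict[str, list[str]] = {}
    for s in dist.index:
        groups.setdefault(breed_of[s], []).append(s)
    names = list(groups)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            block = dist.loc[groups[a], groups[b]].values
            if a == b:
                m = block.shape[0]
                val = block[np.triu_indices(m, k=1)].mean() if m > 1 else 0.0
            else:
                val = block.mean()
            out.loc[a, b] = out.loc[b, a] = float(val)
        out.loc[a, a] = 0.0
    return out


def neighbor_joining(dist: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining from a symmetric distance matrix.

    Standard Q-criterion; ties broken by the lexicographically lowest
    index pair. Branch lengths from the usual formulas; a negative length
    is clamped to zero with the deficit transferred to its sister edge.
    Exact (topology and branch lengths) for additive distances. Returns an
    unrooted tree stored with a trifurcating root.
    """
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(dist.values, dist.values.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=str(t)) for t in dist.index]
    D = dist.values.astype(float).copy()
    active = list(range(len(nodes)))

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = float(li), float(lj)
        parent = TreeNode(children=[ni, nj])
        # grow the distance matrix with the new node
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    a = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    b = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    c = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lengths = [a, b, c]
    for idx, node_idx in enumerate(active):
        nodes[node_idx].length = float(max(lengths[idx], 0.0))
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of counts.

    Sums hypergeometric probabilities no larger than the observed table's
    (the standard minimum-likelihood rule). Zero-margin tables give p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(_scipy_fisher(t, alternative="two-sided")[1])
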