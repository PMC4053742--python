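"""Readers and writers for the pipeline's on-disk formats.

Tab-delimited probe/ratio tables, BED-style interval files (plain BED4 and a
RepeatMasker-derived dialect with family and divergence columns), FASTA
sequence, and newick trees. All genomic coordinates are 0-based half-open
internally; BED files are read and written without conversion.

Readers reject malformed input (with the offending row number where
applicable) rather than silently coercing; writers are deterministic
byte-for-byte for equal inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ProbeSet:
    """Ordered array probes: one row per probe with chrom, pos, probe_id.

    Probes are sorted by (chrom, pos); probe_ids are unique. ``pos`` is the
    0-based coordinate of the probe's mapped position.
    """

    table: pd.DataFrame  # columns: chrom, pos, probe_id

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:3]) != ["chrom", "pos", "probe_id"]:
            raise ValueError("probe table needs columns chrom, pos, probe_id")
        if t["probe_id"].duplicated().any():
            dup = t["probe_id"][t["probe_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r}")
        srt = t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if not (srt[["chrom", "pos"]].values == t[["chrom", "pos"]].values).all():
            warnings.warn("probes out of order; sorting", stacklevel=2)
        self.table = srt

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous row slice of one chromosome's probes."""
        idx = np.flatnonzero((self.table["chrom"] == chrom).values)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions(self, chrom: str) -> np.ndarray:
        return self.table["pos"].values[self.chrom_slice(chrom)]


@dataclass
class RatioMatrix:
    """Per-sample log2 test/reference ratios aligned to a ProbeSet.

    ``values`` has one row per probe (same order as ``probes``) and one
    column per sample. ``samples`` carries sample_id, breed and sex.
    """

    probes: ProbeSet
    values: pd.DataFrame
    samples: pd.DataFrame  # columns: sample_id, breed, sex

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probes):
            raise ValueError("value rows must match probe count")
        if not np.isfinite(self.values.values).all():
            raise FormatError("non-finite log2 ratios")
        missing = set(self.values.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def block(self, sample: str, chrom: str) -> np.ndarray:
        """One sample's ratios on one chromosome, probe-ordered."""
        return self.values[sample].values[self.probes.chrom_slice(chrom)]

    def copy(self) -> "RatioMatrix":
        return RatioMatrix(self.probes, self.values.copy(), self.samples.copy())


@dataclass
class IntervalSet:
    """Generic genomic intervals with BED semantics (0-based half-open)."""

    table: pd.DataFrame  # columns: chrom, start, end [, name, ...]

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "start", "end"):
            if col not in t.columns:
                raise ValueError(f"interval table missing column {col!r}")
        if len(t) and not (t["end"] > t["start"]).all():
            bad = t.index[t["end"] <= t["start"]][0]
            raise FormatError(f"interval with start >= end at row {bad}")
        self.table = t.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.table)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def total_length(self) -> int:
        if not len(self.table):
            return 0
        return int((self.table["end"] - self.table["start"]).sum())


# ---------------------------------------------------------------------------
# ratio tables


def read_ratio_table(path, samples: pd.DataFrame | None = None) -> RatioMatrix:
    """Read a tab-delimited probe ratio table.

    Layout: header ``chrom  pos  probe_id  <sample1> <sample2> ...``; one row
    per probe. Rows out of order are sorted with a warning. Non-numeric
    ratios, duplicate probe ids and missing columns are rejected with the
    offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "probe_id"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos", "probe_id")]
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based + header
            raise FormatError(f"non-numeric ratio in column {col!r} at line {row}")
        df[col] = vals.astype(float)
    probes = ProbeSet(df[["chrom", "pos", "probe_id"]].copy())
    # reorder value rows to match the (sorted) probe table
    order = (
        df[["chrom", "pos", "probe_id"]]
        .reset_index()
        .sort_values(["chrom", "pos"], kind="mergesort")["index"]
        .values
    )
    values = df.loc[order, sample_cols].reset_index(drop=True)
    if samples is None:
        samples = pd.DataFrame(
            {"sample_id": sample_cols, "breed": "unknown", "sex": "unknown"}
        )
    return RatioMatrix(probes, values, samples)


def write_ratio_table(matrix: RatioMatrix, path) -> None:
    out = pd.concat([matrix.probes.table.reset_index(drop=True), matrix.values], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a tab-delimited sample sheet with sample_id, breed, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "breed", "sex"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals


def read_intervals(path, dialect: str = "bed") -> IntervalSet:
    """Read intervals from a BED or RepeatMasker-derived TSV file.

    ``bed``: whitespace-delimited chrom, start, end [, name]. ``rmsk``:
    tab-delimited with header including chrom, start, end, family,
    divergence (divergence as a fraction, retained for repeat age binning).
    """
    if dialect == "bed":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise FormatError(f"line {lineno}: expected >=3 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-integer coordinate") from exc
                if start >= end:
                    raise FormatError(f"line {lineno}: start >= end")
                name = parts[3] if len(parts) > 3 else "."
                rows.append((parts[0], start, end, name))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))
    if dialect == "rmsk":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for col in ("chrom", "start", "end", "family", "divergence"):
            if col not in df.columns:
                raise FormatError(f"rmsk file missing column {col!r}")
        df = df.rename(columns={"family": "name"})
        df["divergence"] = df["divergence"].astype(float)
        return IntervalSet(df[["chrom", "start", "end", "name", "divergence"]])
    raise ValueError(f"unknown dialect {dialect!r}")


def write_bed(intervals: IntervalSet, path) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in intervals.table.columns:
        cols.append("name")
    intervals.table[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}; duplicate ids are rejected."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"duplicate FASTA id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees / newick


@dataclass
class TreeNode:
    """Node of an unrooted (stored rooted) phylogeny with branch lengths."""

    name: str | None = None
    length: float | None = None  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name or "" for lf in self.leaves()]

    def to_newick(self) -> str:
        return _newick_str(self) + ";"

    def leaf_distances(self) -> pd.DataFrame:
        """All pairwise leaf-to-leaf path lengths (sums of branch lengths)."""
        names = self.leaf_names()
        dist = pd.DataFrame(0.0, index=names, columns=names)

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name or "": 0.0}
            below: list[dict[str, float]] = []
            for child in node.children:
                d = walk(child)
                below.append({k: v + (child.length or 0.0) for k, v in d.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            dist.loc[a, b] = dist.loc[b, a] = da + db
            merged: dict[str, float] = {}
            for d in below:
                merged.update(d)
            return merged

        walk(self)
        return dist


def _newick_str(node: TreeNode) -> str:
    if node.is_leaf():
        s = node.name or ""
    else:
        s = "(" + ",".join(_newick_str(c) for c in node.children) + ")"
        if node.name:
            s += node.name
    if node.length is not None:
        s += f":{node.length:g}"
    return s


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
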