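"""Reading and writing bisulfite methylation call files.

Input dialects are the two standard per-cytosine outputs of the Bismark
aligner: the 7-column cytosine/CpG report and the 6-column coverage file.
Per-sample tables are assembled into a single wide :class:`MethylationMatrix`
(one depth column and one methylated-fraction column per sample), which is
the universal input to the scoring pipeline.

Coordinates are 1-based inclusive throughout the package (the Bismark
convention); BED output is converted to 0-based half-open on write.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CYTOSINE_REPORT_COLUMNS = [
    "chrom", "pos", "strand", "count_methylated", "count_unmethylated",
    "context", "trinucleotide",
]
COVERAGE_COLUMNS = [
    "chrom", "start", "end", "percent_methylation",
    "count_methylated", "count_unmethylated",
]

GROUP_LABELS = ("treatment", "control")


def _numeric_or_raise(df: pd.DataFrame, columns: Sequence[str], path) -> pd.DataFrame:
    """Convert columns to numeric, raising with a 1-based line number on failure."""
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(
                f"{path}: malformed value {df[col].iloc[lineno - 1]!r} in column "
                f"{col!r} at line {lineno}"
            )
        if converted.isna().any():
            lineno = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 1
            raise ValueError(f"{path}: missing field in column {col!r} at line {lineno}")
        df[col] = converted
    return df


def _finalize_calls(df: pd.DataFrame, path) -> pd.DataFrame:
    """Derive depth and methylated fraction from counts; drop zero-depth loci."""
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        bad = (df["count_methylated"] < 0) | (df["count_unmethylated"] < 0)
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: negative read count at line {lineno}")
    df["depth"] = df["count_methylated"] + df["count_unmethylated"]
    df = df[df["depth"] > 0].copy()
    df["meth_frac"] = df["count_methylated"] / df["depth"]
    cols = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated",
            "depth", "meth_frac"]
    return df[cols].reset_index(drop=True)


def read_cytosine_report(path, context_filter: str | None = "CpG") -> pd.DataFrame:
    """Read a Bismark cytosine/CpG report (tab-separated, optionally gzipped).

    Columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context, trinucleotide.  Loci with zero total depth
    are dropped.  If ``context_filter`` is given (default ``"CpG"``), rows
    whose context differs are dropped; pass ``None`` to keep all contexts.

    Returns a per-sample call table with columns chrom, pos, strand,
    count_methylated, count_unmethylated, depth, meth_frac.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=CYTOSINE_REPORT_COLUMNS,
                     dtype=str, comment=None)
    if df.shape[1] != len(CYTOSINE_REPORT_COLUMNS):
        raise ValueError(f"{path}: expected {len(CYTOSINE_REPORT_COLUMNS)} columns")
    df = _numeric_or_raise(df, ["pos", "count_methylated", "count_unmethylated"], path)
    if (df["pos"] < 1).any():
        lineno = int(np.flatnonzero((df["pos"] < 1).to_numpy())[0]) + 1
        raise ValueError(f"{path}: position < 1 at line {lineno}")
    if context_filter is not None:
        df = df[df["context"] == context_filter]
    df = df.astype({"pos": np.int64, "count_methylated": np.int64,
                    "count_unmethylated": np.int64})
    return _finalize_calls(df, path)


def read_bismark_cov(path) -> pd.DataFrame:
    """Read a Bismark coverage file (chrom, start, end, %meth, n_meth, n_unmeth).

    The position is the 1-based start; strand is unknown (recorded as ``"."``).
    The methylated fraction is always recomputed from the counts; if the
    printed percent disagrees with the counts by more than one percentage
    point a warning is emitted and the counts win.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=COVERAGE_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count_methylated",
                                     "count_unmethylated", "depth", "meth_frac"])
    df = _numeric_or_raise(
        df, ["start", "end", "percent_methylation",
             "count_methylated", "count_unmethylated"], path)
    df = df.astype({"start": np.int64, "count_methylated": np.int64,
                    "count_unmethylated": np.int64})
    depth = df["count_methylated"] + df["count_unmethylated"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_from_counts = 100.0 * df["count_methylated"] / depth
    disagree = (depth > 0) & ((df["percent_methylation"] - pct_from_counts).abs() > 1.0)
    if disagree.any():
        warnings.warn(
            f"{path}: percent-methylation column disagrees with counts by >1 point "
            f"on {int(disagree.sum())} line(s); counts win", stacklevel=2)
    out = df.rename(columns={"start": "pos"})
    out["strand"] = "."
    return _finalize_calls(out, path)


class MethylationMatrix:
    """Wide loci x samples table of read depth and methylated fraction.

    ``data`` holds columns chrom, pos, strand followed by ``"<sample>.depth"``
    and ``"<sample>.meth"`` (fraction in [0, 1]) for each sample, sorted by
    (chrom, pos).  Missing calls are NaN in both per-sample columns.  ``groups``
    maps each sample to ``"treatment"`` or ``"control"``.
    """

    def __init__(self, data: pd.DataFrame, samples: Sequence[str],
                 groups: Mapping[str, str]):
        self.samples = list(samples)
        self.groups = dict(groups)
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = {g for g in self.groups.values()} - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; "
                             f"expected {GROUP_LABELS}")
        for lab in GROUP_LABELS:
            if not any(self.groups[s] == lab for s in self.samples):
                raise ValueError(f"group {lab!r} has no samples")
        data = data.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if data.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) after assembly")
        self.data = data

    @property
    def n_loci(self) -> int:
        return len(self.data)

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == label]

    def depth_matrix(self) -> np.ndarray:
        """loci x samples array of read depths (NaN where missing)."""
        return self.data[[f"{s}.depth" for s in self.samples]].to_numpy(float)

    def meth_matrix(self) -> np.ndarray:
        """loci x samples array of methylated fractions (NaN where missing)."""
        return self.data[[f"{s}.meth" for s in self.samples]].to_numpy(float)

    # -- wide TSV round trip ------------------------------------------------

    def to_wide_tsv(self, path) -> None:
        """Write the documented wide input format.

        First line is a ``# groups:`` comment mapping samples to conditions;
        then a header row chrom, pos, strand and per sample ``<s>.depth`` and
        ``<s>.pct_meth`` (percent, 0-100).
        """
        with open(path, "w") as fh:
            pairs = " ".join(f"{s}={self.groups[s]}" for s in self.samples)
            fh.write(f"# groups: {pairs}\n")
            out = self.data[["chrom", "pos", "strand"]].copy()
            for s in self.samples:
                out[f"{s}.depth"] = self.data[f"{s}.depth"]
                out[f"{s}.pct_meth"] = (100.0 * self.data[f"{s}.meth"]).round(6)
            out.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_wide_tsv(cls, path) -> "MethylationMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# groups:"):
                raise ValueError(f"{path}: missing '# groups:' header line")
            groups = dict(tok.split("=", 1) for tok in first.split(":", 1)[1].split())
            df = pd.read_csv(fh, sep="\t")
        samples = [c[:-len(".depth")] for c in df.columns if c.endswith(".depth")]
        data = df[["chrom", "pos", "strand"]].copy()
        for s in samples:
            data[f"{s}.depth"] = df[f"{s}.depth"]
            data[f"{s}.meth"] = df[f"{s}.pct_meth"] / 100.0
        return cls(data, samples, groups)


def assemble_matrix(tables: Sequence[pd.DataFrame], names: Sequence[str],
                    groups: Mapping[str, str],
                    merge_strands: bool = False) -> MethylationMatrix:
    """Join per-sample call tables into one :class:`MethylationMatrix`.

    Loci present in at least one sample are retained, with missing calls
    recorded as NaN (resolved later by the depth filter; nothing is imputed
    here).  With ``merge_strands``, a minus-strand call at position ``p`` is
    pooled (counts summed) with the plus-strand call at ``p - 1`` and reported
    at the plus position, per sample, before joining.
    """
    if len(tables) != len(names):
        raise ValueError("one table per sample name required")
    if len(set(names)) != len(names):
        raise ValueError("sample names must be unique")
    per_sample = []
    for name, tab in zip(names, tables):
        tab = tab.copy()
        if tab.duplicated(["chrom", "pos", "strand"]).any():
            dup = tab[tab.duplicated(["chrom", "pos", "strand"])].iloc[0]
            raise ValueError(
                f"sample {name!r}: duplicate call at "
                f"{dup['chrom']}:{dup['pos']}({dup['strand']})")
        if merge_strands and len(tab):
            minus = tab["strand"] == "-"
            tab.loc[minus, "pos"] -= 1
            tab = (tab.groupby(["chrom", "pos"], as_index=False)
                      .agg(count_methylated=("count_methylated", "sum"),
                           count_unmethylated=("count_unmethylated", "sum")))
            tab["strand"] = "+"
            tab["depth"] = tab["count_methylated"] + tab["count_unmethylated"]
            tab["meth_frac"] = tab["count_methylated"] / tab["depth"]
        sub = tab.set_index(["chrom", "pos"])
        per_sample.append(pd.DataFrame({
            f"{name}.depth": sub["depth"].astype(float),
            f"{name}.meth": sub["meth_frac"].astype(float),
            f"_strand.{name}": sub["strand"],
        }))
    joined = pd.concat(per_sample, axis=1, join="outer")
    strand_cols = [f"_strand.{n}" for n in names]
    strand = joined[strand_cols].bfill(axis=1).iloc[:, 0].fillna(".")
    data = joined.drop(columns=strand_cols).reset_index()
    data.insert(2, "strand", strand.to_numpy())
    return MethylationMatrix(data, names, groups)


def write_dmr_bed(dmrs: pd.DataFrame, bed_path, tsv_path=None) -> None:
    """Write DMR calls as BED6 (0-based half-open) plus an optional stats TSV.

    The BED score is ``min(1000, round(-10 * log10(q)))`` (0 for q = 1,
    capped at 1000 for q = 0); the name column is a running DMR id.
    """
    with open(bed_path, "w") as fh:
        for i, row in enumerate(dmrs.itertuples(index=False), start=1):
            q = float(row.q)
            score = 1000 if q <= 0 else min(1000, round(-10.0 * math.log10(q)))
            fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t"
                     f"DMR_{i}\t{score}\t.\n")
    if tsv_path is not None:
        out = dmrs.copy()
        out.insert(0, "name", [f"DMR_{i}" for i in range(1, len(dmrs) + 1)])
        out.to_csv(tsv_path, sep="\t", index=False)
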