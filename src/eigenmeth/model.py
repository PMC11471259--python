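"""Model/results interface tying the pipeline together.

:class:`DifferentialMethylation` is built from a :class:`MethylationMatrix`
(or the wide TSV / Bismark files behind it); ``fit()`` filters loci, runs
the PCA and returns a :class:`DifferentialMethylationResults` carrying the
eigenvector scores and rank table, from which DMLs, DMRs, region tests and
metagene profiles are derived.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dml as _dml
from . import dmr as _dmr
from . import regions as _regions
from .eigen import (EigenScores, RankTable, compute_eigen_scores, filter_loci,
                    rank_loci)
from .io import (MethylationMatrix, assemble_matrix, read_bismark_cov,
                 read_cytosine_report)


class DifferentialMethylation:
    """Two-condition differential-methylation model over a methylation matrix.

    Parameters
    ----------
    matrix : MethylationMatrix
        Wide per-locus table with group labels.
    min_depth : int
        Minimum read depth required in every sample (complete cases).
    pc : int, optional
        1-based principal component to use; by default the component that
        best delineates treatment from control is chosen automatically.
    """

    def __init__(self, matrix: MethylationMatrix, min_depth: int = 10,
                 pc: int | None = None):
        self.matrix = matrix
        self.min_depth = min_depth
        self.pc = pc

    @classmethod
    def from_wide(cls, path, **kwargs) -> "DifferentialMethylation":
        return cls(MethylationMatrix.from_wide_tsv(path), **kwargs)

    @classmethod
    def from_bismark(cls, paths: Sequence, names: Sequence[str],
                     groups: Mapping[str, str], fmt: str = "cov",
                     merge_strands: bool = False,
                     **kwargs) -> "DifferentialMethylation":
        reader = {"cov": read_bismark_cov,
                  "cytosine": read_cytosine_report}.get(fmt)
        if reader is None:
            raise ValueError(f"unknown format {fmt!r}; use 'cov' or 'cytosine'")
        tables = [reader(p) for p in paths]
        m = assemble_matrix(tables, names, groups, merge_strands=merge_strands)
        return cls(m, **kwargs)

    def fit(self) -> "DifferentialMethylationResults":
        filtered = filter_loci(self.matrix, min_depth=self.min_depth)
        scores = compute_eigen_scores(filtered, pc=self.pc)
        rt = rank_loci(scores, filtered)
        return DifferentialMethylationResults(self, filtered, scores, rt)


class DifferentialMethylationResults:
    """Fitted eigenvector scores plus the calls derived from them."""

    def __init__(self, model: DifferentialMethylation,
                 filtered: MethylationMatrix, eigen: EigenScores,
                 rank_table: RankTable):
        self.model = model
        self.filtered = filtered
        self.eigen = eigen
        self.rank_table = rank_table

    # -- DML layer ---------------------------------------------------------

    def estimate_cutoff(self, method: str = "intersect",
                        **kwargs) -> _dml.CutoffEstimate:
        return _dml.estimate_cutoff(self.rank_table, method=method, **kwargs)

    def call_dmls(self, cutoff=None, method: str = "intersect") -> pd.DataFrame:
        if cutoff is None:
            cutoff = self.estimate_cutoff(method=method)
        return _dml.call_dmls(self.rank_table, cutoff)

    # -- DMR layer ---------------------------------------------------------

    def call_dmrs(self, params: _dmr.DMRParams | None = None,
                  **kwargs) -> _dmr.DMRResult:
        if params is None:
            params = _dmr.DMRParams(**kwargs)
        elif kwargs:
            raise ValueError("pass either params or keyword overrides, not both")
        return _dmr.call_dmrs(self.rank_table, params)

    # -- region layer ------------------------------------------------------

    def test_region(self, chrom: str, start: int, end: int, name=None,
                    n_perm: int = 1000, bg_span: int = 1_000_000,
                    rng=None) -> _regions.RegionResult:
        q = _regions.RegionQuery(chrom, start, end, name=name)
        return _regions.test_region(q, self.rank_table, n_perm=n_perm,
                                    bg_span=bg_span, rng=rng)

    def metagene(self, queries, n_bins: int = 50, flank_frac: float = 0.5,
                 value: str = "score"):
        return _regions.metagene(queries, self.rank_table, n_bins=n_bins,
                                 flank_frac=flank_frac, value=value)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        e = self.eigen
        m = self.model.matrix
        lines = [
            "Differential methylation (eigenvector scoring)",
            "=" * 55,
            f"loci (input)            {m.n_loci:>12,}",
            f"loci (depth >= {self.model.min_depth:<2})      "
            f"{self.filtered.n_loci:>12,}",
            f"samples                 {len(m.samples):>12}"
            f"   ({len(m.group_samples('treatment'))} treatment, "
            f"{len(m.group_samples('control'))} control)",
            f"delineating component   {'PC' + str(e.pc_index):>12}",
            f"group separation        {e.separation:>12.3f}"
            + ("   (perfect)" if e.perfect_separation else ""),
            f"variance explained      {e.explained_var_ratio[e.pc_index - 1]:>12.1%}",
            "-" * 55,
            "per-sample projections on the delineating component:",
        ]
        proj = self.eigen.sample_scores[f"PC{e.pc_index}"]
        for s in m.samples:
            lines.append(f"  {s:<10} {m.groups[s]:<10} {proj[s]:>10.3f}")
        top = self.rank_table.by_rank().head(5)
        lines.append("-" * 55)
        lines.append("top-ranked loci (score, treatment-control difference):")
        for row in top.itertuples(index=False):
            lines.append(f"  {row.chrom}:{row.pos:<10} rank {row.rank:<6} "
                         f"score {row.score:+.4f}  diff {row.meth_diff:+.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<DifferentialMethylationResults: {self.rank_table.n} loci, "
                f"PC{self.eigen.pc_index}>")
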