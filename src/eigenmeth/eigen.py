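"""Per-locus eigenvector scores from the condition-delineating principal component.

The premise: when a PCA of the samples (observations) over all measured loci
(features) separates treatment from control on some component, each locus's
entry in that component's loading vector measures how much the locus
contributes to the between-group variation.  The signed loading is the
locus's *eigenvector score*; its magnitude drives every downstream call and
its sign gives the direction (positive = hyper-methylated in treatment).

Loci are centered across samples but not variance-scaled: methylated
fractions already share a common [0, 1] scale, and scaling would inflate
near-invariant loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationMatrix


def filter_loci(m: MethylationMatrix, min_depth: int = 10,
                require_all_samples: bool = True) -> MethylationMatrix:
    """Retain loci adequately covered in the samples.

    With ``require_all_samples`` (the default) a locus is kept only if a call
    exists with depth >= ``min_depth`` in *every* sample, yielding the
    complete-case matrix the PCA needs.  Otherwise only loci with a present
    call below ``min_depth`` are dropped and missing calls are tolerated
    (downstream scoring will still refuse incomplete rows).
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depth = m.depth_matrix()
    ok = depth >= min_depth
    if require_all_samples:
        keep = ok.all(axis=1)
    else:
        keep = (ok | np.isnan(depth)).all(axis=1) & ~np.isnan(depth).all(axis=1)
    if not keep.any():
        raise ValueError(
            f"no loci retained at min_depth={min_depth}; lower min_depth "
            "or check coverage")
    data = m.data.loc[keep].reset_index(drop=True)
    return MethylationMatrix(data, m.samples, m.groups)


@dataclass
class EigenScores:
    """Signed per-locus scores on the delineating principal component."""

    loci: pd.DataFrame                 # chrom, pos, strand
    score: np.ndarray                  # unit loading vector entries, signed
    pc_index: int                      # 1-based component index used
    sample_scores: pd.DataFrame        # samples x components projections
    orientation_flipped: bool          # True if the raw SVD sign was flipped
    separation: float                  # standardized group-mean difference
    perfect_separation: bool
    explained_var_ratio: np.ndarray = field(repr=False, default=None)


def select_delineating_pc(sample_scores: np.ndarray, groups: np.ndarray) -> int:
    """Pick the component that best delineates treatment from control.

    ``sample_scores`` is samples x components; ``groups`` is a boolean mask,
    True for treatment.  The criterion is |mean(treat) - mean(control)|
    divided by the pooled within-group standard deviation (floored at 1e-12);
    ties break toward the lower index.  Returns a 1-based component index.
    """
    t = sample_scores[groups]
    c = sample_scores[~groups]
    nt, nc = len(t), len(c)
    diff = np.abs(t.mean(axis=0) - c.mean(axis=0))
    vt = t.var(axis=0, ddof=1) if nt > 1 else np.zeros(sample_scores.shape[1])
    vc = c.var(axis=0, ddof=1) if nc > 1 else np.zeros(sample_scores.shape[1])
    dof = max(nt + nc - 2, 1)
    pooled = np.sqrt(((nt - 1) * vt + (nc - 1) * vc) / dof)
    crit = diff / np.maximum(pooled, 1e-12)
    return int(np.argmax(crit)) + 1


def _delineation_stats(sample_scores: np.ndarray, groups: np.ndarray,
                       k: int) -> tuple[float, bool]:
    t = sample_scores[groups, k - 1]
    c = sample_scores[~groups, k - 1]
    nt, nc = len(t), len(c)
    vt = t.var(ddof=1) if nt > 1 else 0.0
    vc = c.var(ddof=1) if nc > 1 else 0.0
    pooled = np.sqrt(((nt - 1) * vt + (nc - 1) * vc) / max(nt + nc - 2, 1))
    sep = abs(t.mean() - c.mean()) / max(pooled, 1e-12)
    perfect = (t.min() > c.max()) or (c.min() > t.max())
    return float(sep), bool(perfect)


def compute_eigen_scores(m: MethylationMatrix, pc: int | None = None) -> EigenScores:
    """Compute signed eigenvector scores for every locus.

    Builds the samples x loci matrix of methylated fractions, centers each
    locus across samples, and takes the thin SVD.  The right singular vector
    of the chosen component supplies the per-locus scores (a unit vector);
    per-sample projections are ``U @ diag(S)``.  If ``pc`` is not given the
    delineating component is chosen by :func:`select_delineating_pc`.  The
    sign is fixed so that a positive score means hyper-methylation in the
    treatment group.
    """
    X = m.meth_matrix().T  # samples x loci
    if np.isnan(X).any():
        raise ValueError("matrix has missing calls; run filter_loci first")
    gmask = np.array([m.groups[s] == "treatment" for s in m.samples])
    if gmask.sum() < 2 or (~gmask).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc ** 2).sum())
    if total_var == 0.0:
        raise ValueError("methylation matrix is constant; no variance to decompose")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    sample_scores = U * S  # samples x components
    if pc is None:
        pc = select_delineating_pc(sample_scores, gmask)
    if not 1 <= pc <= len(S):
        raise ValueError(f"pc must be in 1..{len(S)}")
    score = Vt[pc - 1].copy()
    flipped = False
    if sample_scores[gmask, pc - 1].mean() < sample_scores[~gmask, pc - 1].mean():
        score = -score
        sample_scores = sample_scores.copy()
        sample_scores[:, pc - 1] = -sample_scores[:, pc - 1]
        flipped = True
    sep, perfect = _delineation_stats(sample_scores, gmask, pc)
    ss_df = pd.DataFrame(sample_scores, index=m.samples,
                         columns=[f"PC{i}" for i in range(1, len(S) + 1)])
    with np.errstate(invalid="ignore"):
        evr = S ** 2 / (S ** 2).sum()
    return EigenScores(loci=m.data[["chrom", "pos", "strand"]].copy(),
                       score=score, pc_index=pc, sample_scores=ss_df,
                       orientation_flipped=flipped, separation=sep,
                       perfect_separation=perfect, explained_var_ratio=evr)


class RankTable:
    """Loci ordered by absolute eigenvector score.

    ``df`` stays in genomic order (chrom, pos) and carries columns
    score, abs_score, rank (1 = largest |score|; ties broken by genomic
    order), per-group mean methylated fraction and their difference
    (treatment - control).
    """

    COLUMNS = ["chrom", "pos", "strand", "score", "abs_score", "rank",
               "mean_treatment", "mean_control", "meth_diff"]

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self._chrom_cache: dict[str, dict[str, np.ndarray]] = {}

    @property
    def n(self) -> int:
        return len(self.df)

    def by_rank(self) -> pd.DataFrame:
        return self.df.sort_values("rank", kind="mergesort").reset_index(drop=True)

    def abs_by_rank(self) -> np.ndarray:
        """abs_score indexed by rank-1 (position r-1 holds the rank-r score)."""
        out = np.empty(self.n)
        out[self.df["rank"].to_numpy() - 1] = self.df["abs_score"].to_numpy()
        return out

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_arrays(self, chrom: str) -> dict[str, np.ndarray]:
        """Position-sorted numpy views of one chromosome (cached)."""
        if chrom not in self._chrom_cache:
            sub = self.df[self.df["chrom"] == chrom]
            self._chrom_cache[chrom] = {
                "pos": sub["pos"].to_numpy(np.int64),
                "rank": sub["rank"].to_numpy(np.int64),
                "score": sub["score"].to_numpy(float),
                "abs_score": sub["abs_score"].to_numpy(float),
                "meth_diff": sub["meth_diff"].to_numpy(float),
            }
        return self._chrom_cache[chrom]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RankTable":
        df = pd.read_csv(path, sep="\t")
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: rank table missing columns {sorted(missing)}")
        return cls(df)


def rank_loci(s: EigenScores, m: MethylationMatrix) -> RankTable:
    """Attach ranks and group means to the scored loci.

    Rank 1 is the largest absolute score; ties are broken by (chrom, pos)
    ascending so the ordering is fully deterministic.
    """
    df = s.loci.copy()
    df["score"] = s.score
    df["abs_score"] = np.abs(s.score)
    chrom_codes = pd.factorize(df["chrom"], sort=True)[0]
    order = np.lexsort((df["pos"].to_numpy(), chrom_codes,
                        -df["abs_score"].to_numpy()))
    rank = np.empty(len(df), dtype=np.int64)
    rank[order] = np.arange(1, len(df) + 1)
    df["rank"] = rank
    meth = m.meth_matrix()
    gmask = np.array([m.groups[x] == "treatment" for x in m.samples])
    df["mean_treatment"] = meth[:, gmask].mean(axis=1)
    df["mean_control"] = meth[:, ~gmask].mean(axis=1)
    df["meth_diff"] = df["mean_treatment"] - df["mean_control"]
    return RankTable(df[RankTable.COLUMNS])
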