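"""Direct region queries and metagene profiles.

Instead of intersecting features of interest with called DMRs, a region can
be tested directly: the mean signed eigenvector score of its loci is
compared against contiguous equally-sized locus runs drawn from the local
background.  The test is two-sided because a user-supplied region has no a
priori direction (the DMR caller's bootstrap is one-sided, its direction
being fixed by the seed sign).

Metagene profiles rescale every region to a common relative coordinate
(0 = start, 1 = end, flanks on either side) and average a chosen per-locus
value in bins across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eigen import RankTable


@dataclass
class RegionQuery:
    chrom: str
    start: int          # 1-based inclusive
    end: int
    name: str | None = None
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.name or ''} has start > end")


@dataclass
class RegionResult:
    query: RegionQuery
    n_loci: int
    mean_score: float | None
    mean_meth_diff: float | None
    p: float | None           # two-sided permutation p; None when n_loci == 0
    direction: str | None


def read_region_bed(path) -> list[RegionQuery]:
    """Read BED (0-based half-open) regions into 1-based inclusive queries."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 and pd.notna(row[3]) else f"region_{i+1}"
        strand = str(row[5]) if df.shape[1] > 5 and row[5] in ("+", "-") else "+"
        out.append(RegionQuery(str(row[0]), int(row[1]) + 1, int(row[2]),
                               name=name, strand=strand))
    return out


def test_region(q: RegionQuery, r: RankTable, n_perm: int = 1000,
                bg_span: int = 1_000_000,
                rng: np.random.Generator | None = None,
                exhaustive: bool = False) -> RegionResult:
    """Two-sided permutation test of a region against its local background.

    Observed statistic: mean signed score of the region's loci.  Null draws:
    mean signed score of random contiguous runs of the same locus count from
    the loci within ``bg_span`` bp (region excluded).
    ``p = (1 + #{|null| >= |observed|}) / (n_draws + 1)``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if q.chrom not in set(r.df["chrom"]):
        return RegionResult(q, 0, None, None, None, None)
    arr = r.chrom_arrays(q.chrom)
    pos, score = arr["pos"], arr["score"]
    l = int(np.searchsorted(pos, q.start, side="left"))
    rr = int(np.searchsorted(pos, q.end, side="right")) - 1
    if l > rr:
        return RegionResult(q, 0, None, None, None, None)
    m = rr - l + 1
    obs = float(score[l:rr + 1].mean())
    mdiff = float(arr["meth_diff"][l:rr + 1].mean())
    t0 = int(np.searchsorted(pos, q.start - bg_span, side="left"))
    t1 = int(np.searchsorted(pos, q.end + bg_span, side="right"))
    bg = np.concatenate([score[t0:l], score[rr + 1:t1]])
    if len(bg) < m:
        bg = np.concatenate([score[:l], score[rr + 1:]])
    if len(bg) < m:
        return RegionResult(q, m, obs, mdiff, 1.0,
                            "hyper" if obs > 0 else "hypo")
    csum = np.concatenate([[0.0], np.cumsum(bg)])
    n_starts = len(bg) - m + 1
    starts = (np.arange(n_starts) if exhaustive
              else rng.integers(0, n_starts, size=n_perm))
    null = (csum[starts + m] - csum[starts]) / m
    p = (1.0 + float(np.sum(np.abs(null) >= abs(obs)))) / (len(starts) + 1.0)
    return RegionResult(q, m, obs, mdiff, p, "hyper" if obs > 0 else "hypo")


def metagene(queries: list[RegionQuery], r: RankTable, n_bins: int = 50,
             flank_frac: float = 0.5, value: str = "score"
             ) -> tuple[pd.DataFrame, np.ndarray]:
    """Binned average of a per-locus value over rescaled regions plus flanks.

    Each region's loci map to relative coordinates (0 = start, 1 = end);
    flanks of ``flank_frac`` x region length on each side map to
    [-flank_frac, 0) and (1, 1 + flank_frac], binned proportionally (so
    flank bins have the same relative width as body bins).  Minus-strand
    regions are mirrored, making profiles 5'->3'.  Per-bin means are
    averaged across regions ignoring empty bins.

    Returns (profile DataFrame with bin midpoints, mean value and the number
    of contributing regions; regions x bins matrix with NaN for empty bins).
    """
    if not queries:
        raise ValueError("metagene needs at least one region")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if value not in ("score", "meth_diff"):
        raise ValueError("value must be 'score' or 'meth_diff'")
    n_flank_bins = int(round(flank_frac * n_bins))
    total_bins = n_bins + 2 * n_flank_bins
    edges = np.concatenate([
        np.linspace(-flank_frac, 0.0, n_flank_bins, endpoint=False),
        np.linspace(0.0, 1.0, n_bins, endpoint=False),
        np.linspace(1.0, 1.0 + flank_frac, n_flank_bins + 1),
    ])
    mat = np.full((len(queries), total_bins), np.nan)
    chrom_set = set(r.df["chrom"])
    for qi, q in enumerate(queries):
        if q.chrom not in chrom_set:
            continue
        arr = r.chrom_arrays(q.chrom)
        span = max(q.end - q.start, 1)
        flank_bp = flank_frac * span
        lo = q.start - flank_bp
        hi = q.end + flank_bp
        l = int(np.searchsorted(arr["pos"], lo, side="left"))
        h = int(np.searchsorted(arr["pos"], hi, side="right"))
        if l >= h:
            continue
        rel = (arr["pos"][l:h] - q.start) / span
        vals = arr[value][l:h]
        # half-open bins [edge_i, edge_{i+1}); a locus exactly at the region
        # start lands in the first body bin, one exactly at the end in the last
        idx = np.searchsorted(edges, rel, side="right") - 1
        idx[rel == 1.0] = n_flank_bins + n_bins - 1
        idx = np.clip(idx, 0, total_bins - 1)
        if q.strand == "-":
            # mirror the bins, not the coordinates: profiles read 5'->3' and
            # strand-flipped regions reverse exactly, including edge loci
            idx = total_bins - 1 - idx
        sums = np.bincount(idx, weights=vals, minlength=total_bins)
        counts = np.bincount(idx, minlength=total_bins)
        with np.errstate(invalid="ignore"):
            mat[qi] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2.0
    n_contrib = np.sum(~np.isnan(mat), axis=0)
    sums = np.nansum(np.where(np.isnan(mat), 0.0, mat), axis=0)
    profile = np.where(n_contrib > 0, sums / np.maximum(n_contrib, 1), np.nan)
    prof_df = pd.DataFrame({"bin_mid": mids, "mean_value": profile,
                            "n_regions": n_contrib})
    return prof_df, mat


def plot_metagene(profile: pd.DataFrame, path, value_label: str = "score") -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile["bin_mid"], profile["mean_value"], lw=1.5)
    ax.axvline(0.0, color="0.6", ls="--", lw=0.8)
    ax.axvline(1.0, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel("relative position (0 = start, 1 = end)")
    ax.set_ylabel(f"mean {value_label}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
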