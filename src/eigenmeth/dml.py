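"""Rank-cutoff estimation and DML calling.

Loci are ranked by absolute eigenvector score; no per-locus p-value is
computed.  The cutoff separating true variation from background noise is
estimated on the rank vs |score| curve, which empirically decays steeply
over the truly differential loci and then flattens into background:

* ``intersect`` — fit one least-squares line to the highest-ranking loci
  (true variation) and one to the bottom half (background noise); the cutoff
  is the rank where the two lines cross.
* ``strict`` — the midpoint between the intersect cutoff and the largest
  rank used in the true-variation fit; recommended for very low-variation
  datasets.  By construction strict <= intersect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eigen import RankTable


@dataclass
class CutoffEstimate:
    method: str                       # "intersect" or "strict"
    cutoff_rank: int
    head_fit: tuple[float, float]     # (slope, intercept) of true-variation line
    tail_fit: tuple[float, float]     # (slope, intercept) of background line
    head_window: tuple[int, int]      # rank range used for the head fit
    tail_window: tuple[int, int]


def _fit_line(ranks: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(ranks, values, 1)
    return float(slope), float(intercept)


def _intersect_fits(r: RankTable, head_frac: float, tail_frac: float):
    n = r.n
    if n < 100:
        raise ValueError("cutoff estimation needs at least 100 loci")
    head_max = max(100, math.ceil(head_frac * n))
    # bottom tail_frac of ranks: the last floor(tail_frac * n) ranks
    tail_start = n - math.floor(tail_frac * n) + 1
    if not 0 < head_max < tail_start:
        raise ValueError(
            f"head window (1..{head_max}) must end before the tail window "
            f"({tail_start}..{n}); adjust head_frac/tail_frac")
    y = r.abs_by_rank()
    ranks = np.arange(1, n + 1)
    head = _fit_line(ranks[:head_max], y[:head_max])
    tail = _fit_line(ranks[tail_start - 1:], y[tail_start - 1:])
    if head[0] >= 0:
        warnings.warn("true-variation fit has non-negative slope; the rank "
                      "curve may not have the expected shape", stacklevel=3)
    if abs(head[0] - tail[0]) <= 1e-12 * max(1.0, abs(head[0]), abs(tail[0])):
        raise ValueError("head and tail fits are parallel; no intersection — "
                         "supply a manual cutoff")
    x_star = (tail[1] - head[1]) / (head[0] - tail[0])
    if x_star < 1:
        warnings.warn(f"fitted-line intersection at rank {x_star:.1f} lies left "
                      "of rank 1; cutoff clamped", stacklevel=3)
    cutoff = int(min(max(round(x_star), 1), n))
    return cutoff, head, tail, (1, head_max), (tail_start, n)


def estimate_cutoff_intersect(r: RankTable, head_frac: float = 0.005,
                              tail_frac: float = 0.5) -> CutoffEstimate:
    """Rank cutoff at the crossing of the true-variation and background fits.

    The head window covers ranks ``1..max(100, ceil(head_frac * n))``; the
    tail window covers the bottom ``tail_frac`` of ranks.  Both fits are
    ordinary least squares on (rank, |score|).
    """
    cutoff, head, tail, hw, tw = _intersect_fits(r, head_frac, tail_frac)
    return CutoffEstimate("intersect", cutoff, head, tail, hw, tw)


def estimate_cutoff_strict(r: RankTable, head_frac: float = 0.005,
                           tail_frac: float = 0.5) -> CutoffEstimate:
    """Halfway between the intersect cutoff and the head window's last rank."""
    cutoff, head, tail, hw, tw = _intersect_fits(r, head_frac, tail_frac)
    strict = int(round((cutoff + hw[1]) / 2.0))
    strict = min(strict, cutoff)
    return CutoffEstimate("strict", strict, head, tail, hw, tw)


def estimate_cutoff(r: RankTable, method: str = "intersect",
                    head_frac: float = 0.005, tail_frac: float = 0.5) -> CutoffEstimate:
    if method == "intersect":
        return estimate_cutoff_intersect(r, head_frac, tail_frac)
    if method == "strict":
        return estimate_cutoff_strict(r, head_frac, tail_frac)
    raise ValueError(f"unknown cutoff method {method!r}")


def call_dmls(r: RankTable, cutoff: CutoffEstimate | int) -> pd.DataFrame:
    """All loci at or above the cutoff rank, best rank first.

    Each call carries its direction (sign of the eigenvector score) and the
    treatment - control methylation difference.
    """
    c = cutoff.cutoff_rank if isinstance(cutoff, CutoffEstimate) else int(cutoff)
    if not 1 <= c <= r.n:
        raise ValueError(f"cutoff {c} outside 1..{r.n}")
    out = r.by_rank().head(c).copy()
    out["direction"] = np.where(out["score"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


def plot_rank_cutoff(r: RankTable, est: CutoffEstimate, path,
                     max_points: int = 20000) -> None:
    """Diagnostic plot: rank vs |score| with both fitted lines and the cutoff."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    y = r.abs_by_rank()
    n = r.n
    idx = np.unique(np.linspace(0, n - 1, min(n, max_points)).astype(int))
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(idx + 1, y[idx], ".", ms=2, color="0.4", label="loci")
    xs = np.array([1, n])
    for fit, lab, col in ((est.head_fit, "true variation", "tab:red"),
                          (est.tail_fit, "background", "tab:blue")):
        ax.plot(xs, fit[0] * xs + fit[1], col, lw=1.2, label=lab)
    ax.axvline(est.cutoff_rank, color="k", ls="--", lw=1,
               label=f"{est.method} cutoff = {est.cutoff_rank}")
    ax.set_xlabel("rank")
    ax.set_ylabel("|eigenvector score|")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
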