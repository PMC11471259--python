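import numpy as np
import pandas as pd
import pytest

import eigenmeth as em
from eigenmeth.eigen import RankTable


def make_rank_table(abs_by_rank, signs=None, spacing=10, chrom="chr1"):
    """Build a RankTable whose rank-r locus has |score| = abs_by_rank[r-1].

    Loci are laid out in genomic order with the given spacing; the score
    ordering along the genome is shuffled deterministically so genomic and
    rank order differ.
    """
    n = len(abs_by_rank)
    rng = np.random.default_rng(1234)
    perm = rng.permutation(n)            # rank of the locus at genomic index i
    abs_by_rank = np.asarray(abs_by_rank, float)
    signs = np.ones(n) if signs is None else np.asarray(signs, float)
    score = signs[perm] * abs_by_rank[perm]
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, n + 1) * spacing,
        "strand": "+",
        "score": score,
        "abs_score": np.abs(score),
        "rank": perm + 1,
        "mean_treatment": 0.5 + score,
        "mean_control": 0.5 - score,
        "meth_diff": 2 * score,
    })
    return RankTable(df)


def make_positional_rank_table(pos, ranks, scores=None, chrom="chr1"):
    """RankTable at explicit positions with explicit ranks (genomic order)."""
    pos = np.asarray(pos, np.int64)
    ranks = np.asarray(ranks, np.int64)
    n = len(pos)
    if scores is None:
        # higher rank number -> smaller |score|, consistent with the contract
        scores = 1.0 / ranks
    scores = np.asarray(scores, float)
    df = pd.DataFrame({
        "chrom": chrom, "pos": pos, "strand": "+",
        "score": scores, "abs_score": np.abs(scores), "rank": ranks,
        "mean_treatment": 0.5, "mean_control": 0.5, "meth_diff": 0.0,
    })
    return RankTable(df)


@pytest.fixture(scope="session")
def sim_medium():
    """One reduced medium-variation genome shared across tests."""
    matrix, truth, sidecar = em.simulate_genome("medium", seed=1, scale=12)
    return matrix, truth, sidecar


@pytest.fixture(scope="session")
def fitted_medium(sim_medium):
    matrix, truth, sidecar = sim_medium
    res = em.DifferentialMethylation(matrix).fit()
    return res, truth
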