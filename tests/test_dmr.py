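import numpy as np
import pandas as pd
import pytest

import eigenmeth as em
from eigenmeth.dmr import (DMRParams, call_dmrs, compress_seeds, expand_seed,
                           score_dmr, select_seeds, trim_tails)
from .conftest import make_positional_rank_table, make_rank_table


def seeds_df(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions, np.int64)})


class TestSelectSeeds:
    def test_extremes(self):
        rt = make_rank_table(np.linspace(1, 0.01, 200))
        one = select_seeds(rt, 1)
        assert len(one) == 1 and one.iloc[0]["rank"] == 1
        assert len(select_seeds(rt, 200)) == 200

    def test_genomic_order(self):
        rt = make_rank_table(np.linspace(1, 0.01, 200))
        s = select_seeds(rt, 50)
        assert (np.diff(s.pos) > 0).all()


class TestCompressSeeds:
    def test_median_of_three(self):
        out, n_splits = compress_seeds(seeds_df([100, 300, 900]), 1000, 5000)
        assert n_splits == 0
        assert len(out) == 1
        assert out[0].pos == 300 and out[0].n_members == 3

    def test_distant_seeds_stay_apart(self):
        out, _ = compress_seeds(seeds_df([100, 5000]), 1000, 5000)
        assert [c.pos for c in out] == [100, 5000]

    def test_even_cluster_takes_lower_middle_member(self):
        out, _ = compress_seeds(seeds_df([10, 20, 30, 40]), 1000, 5000)
        assert out[0].pos == 20

    def test_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(8)
        pos = np.unique(rng.integers(0, 100_000, 200))
        gap = 700
        out, _ = compress_seeds(seeds_df(pos), gap, 10 ** 9)
        # brute force: two seeds share a cluster iff a chain of <= gap hops
        # connects them; on sorted positions that is consecutive-gap grouping,
        # verified here via an explicit union-find over all pairs
        parent = list(range(len(pos)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(int(pos[i]) - int(pos[j])) <= gap:
                    parent[find(i)] = find(j)
        clusters = {}
        for i, p in enumerate(pos):
            clusters.setdefault(find(i), []).append(int(p))
        expected = sorted(sorted(v) for v in clusters.values())
        got = []
        i = 0
        for c in out:
            got.append(sorted(pos[i:i + c.n_members].tolist()))
            i += c.n_members
        assert sorted(got) == expected

    def test_overcompression_safeguard_splits_wide_clusters(self):
        pos = np.arange(0, 12_000, 900)         # one chain spanning 11,100 bp
        with pytest.warns(UserWarning, match="overcompression"):
            out, n_splits = compress_seeds(seeds_df(pos), 1000, 5000)
        assert n_splits == len(out) - 1 >= 1
        assert all(c.span <= 5000 for c in out)


class TestExpandSeed:
    def _rt_with_variable(self, var_pos, noise_pos, chrom="chr1"):
        pos = np.sort(np.concatenate([var_pos, noise_pos]))
        ranks = np.empty(len(pos), np.int64)
        is_var = np.isin(pos, var_pos)
        ranks[is_var] = np.arange(1, is_var.sum() + 1)
        ranks[~is_var] = np.arange(is_var.sum() + 1, len(pos) + 1)
        return make_positional_rank_table(pos, ranks, chrom=chrom)

    def test_symmetric_grid_takes_smaller_start(self):
        var = np.arange(0, 100, 10) + 10_000     # 10 sites, spans of 9 tie
        rt = self._rt_with_variable(var, np.array([5000, 20_000]))
        from eigenmeth.dmr import CompressedSeed
        cs = CompressedSeed("chr1", 10_040, 10, 90)
        region = expand_seed(cs, rt, cutoff_rank=10,
                             p=DMRParams(max_dmr_size=5000))
        assert region == (10_000, 10_080)        # required 9, tie -> low start

    def test_single_variable_site(self):
        rt = self._rt_with_variable(np.array([10_000]),
                                    np.array([9000, 11_000]))
        from eigenmeth.dmr import CompressedSeed
        cs = CompressedSeed("chr1", 10_000, 1, 0)
        assert expand_seed(cs, rt, 1, DMRParams()) == (10_000, 10_000)

    def test_no_variable_sites_returns_none(self):
        rt = self._rt_with_variable(np.array([100_000]), np.array([9000]))
        from eigenmeth.dmr import CompressedSeed
        cs = CompressedSeed("chr1", 9000, 1, 0)
        assert expand_seed(cs, rt, 0, DMRParams()) is None

    def test_matches_exhaustive_interval_search(self):
        rng = np.random.default_rng(17)
        var = np.sort(rng.choice(np.arange(8000, 13_000), 30, replace=False))
        rt = self._rt_with_variable(var, np.array([1000, 20_000]))
        from eigenmeth.dmr import CompressedSeed
        p = DMRParams(max_dmr_size=5000, containment_frac=0.9)
        cs = CompressedSeed("chr1", 10_500, 30, 0)
        got = expand_seed(cs, rt, 30, p)
        # brute force over every consecutive window of the in-window sites
        half = p.max_dmr_size / 2
        win = var[(var >= cs.pos - half) & (var <= cs.pos + half)]
        req = int(np.ceil(0.9 * len(win)))
        best = None
        for i in range(len(win) - req + 1):
            iv = (int(win[i]), int(win[i + req - 1]))
            if best is None or iv[1] - iv[0] < best[1] - best[0]:
                best = iv
        assert got == best


class TestTrimTails:
    def _rt(self, pos, abs_scores):
        order = np.argsort(np.argsort(-np.asarray(abs_scores)))
        return make_positional_rank_table(pos, order + 1,
                                          scores=np.asarray(abs_scores))

    def test_strong_candidate_unchanged(self):
        pos = np.arange(1000, 1100, 10)
        rt = self._rt(np.concatenate([[100], pos, [5000]]),
                      np.concatenate([[0.1], np.full(10, 0.9), [0.1]]))
        p = DMRParams(trim_window=3)
        assert trim_tails((1000, 1090), "chr1", rt, p) == (1000, 1090)

    def test_background_candidate_vanishes(self):
        pos = np.arange(1000, 1100, 10)
        rt = self._rt(np.concatenate([[100, 200], pos, [5000, 6000]]),
                      np.concatenate([[0.9, 0.9], np.full(10, 0.01),
                                      [0.9, 0.9]]))
        assert trim_tails((1000, 1090), "chr1", rt, DMRParams()) is None

    def test_low_tails_trimmed_to_core(self):
        # 3 weak loci each side of a strong 4-locus core; flanks are weak too
        pos = np.arange(1000, 1100, 10)          # 10 candidate loci
        scores = np.array([0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
        rt = self._rt(np.concatenate([[100], pos, [9000]]),
                      np.concatenate([[0.2], scores, [0.2]]))
        p = DMRParams(trim_window=1)
        assert trim_tails((1000, 1090), "chr1", rt, p) == (1030, 1060)

    def test_no_flanks_falls_back_to_genome_median(self):
        pos = np.arange(1000, 1100, 10)
        rt = self._rt(pos, np.full(10, 0.5))
        with pytest.warns(UserWarning, match="genome-wide"):
            out = trim_tails((1000, 1090), "chr1", rt, DMRParams())
        assert out == (1000, 1090)


class TestScoreDmr:
    def test_best_region_hits_p_floor(self):
        # region holds the m best ranks; no background run can do better
        pos = np.arange(0, 3000, 10)
        n = len(pos)
        ranks = np.arange(1, n + 1)              # best ranks at the left end
        rt = make_positional_rank_table(pos, ranks)
        p = DMRParams(n_boot=200)
        out = score_dmr((0, 90), "chr1", rt, p, np.random.default_rng(0))
        assert out["p"] == pytest.approx(1 / 201)
        assert out["n_loci"] == 10

    @pytest.mark.parametrize("stat", ["mean", "median"])
    def test_exhaustive_enumeration_oracle(self, stat):
        """p on a 20-locus chromosome equals direct enumeration over pairs."""
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(10_000, 20, replace=False))
        ranks = rng.permutation(20) + 1
        rt = make_positional_rank_table(pos, ranks)
        l = 7
        region = (int(pos[l]), int(pos[l + 1]))  # m = 2
        p = DMRParams(stat=stat)
        out = score_dmr(region, "chr1", rt, p, np.random.default_rng(0),
                        exhaustive=True)
        # oracle: enumerate every contiguous pair of background loci
        obs = (ranks[l] + ranks[l + 1]) / 2
        bg = np.concatenate([ranks[:l], ranks[l + 2:]])
        stats = [(bg[i] + bg[i + 1]) / 2 for i in range(len(bg) - 1)]
        expected = (1 + sum(s <= obs for s in stats)) / (len(stats) + 1)
        assert out["p"] == pytest.approx(expected)

    def test_null_region_p_is_uniform(self):
        """Mean p over 200 random null regions sits near 0.5."""
        rng = np.random.default_rng(10)
        n = 4000
        pos = np.arange(n) * 10
        ranks = rng.permutation(n) + 1
        rt = make_positional_rank_table(pos, ranks)
        p = DMRParams(n_boot=200, stat="mean")
        draw = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            l = int(draw.integers(0, n - 20))
            out = score_dmr((int(pos[l]), int(pos[l + 14])), "chr1", rt, p,
                            draw)
            ps.append(out["p"])
        assert 0.45 <= np.mean(ps) <= 0.55

    def test_insufficient_background_flags_p_one(self):
        pos = np.arange(0, 50, 10)
        rt = make_positional_rank_table(pos, np.arange(1, 6))
        p = DMRParams()
        with pytest.warns(UserWarning, match="widened"):
            out = score_dmr((0, 30), "chr1", rt, p, np.random.default_rng(0))
        assert out["insufficient_background"] and out["p"] == 1.0


class TestCallDmrs:
    def test_q_at_least_p_and_sorted(self, fitted_medium):
        res, _ = fitted_medium
        dr = res.call_dmrs(rng_seed=1)
        assert (dr.calls.q >= dr.calls.p - 1e-12).all()
        assert (np.diff(dr.calls.q) >= -1e-12).all()

    def test_every_call_contains_a_seed_locus(self, fitted_medium):
        res, _ = fitted_medium
        dr = res.call_dmrs(rng_seed=1)
        assert (dr.calls.n_seed_loci >= 1).all()

    def test_direction_matches_mean_score_sign(self, fitted_medium):
        res, _ = fitted_medium
        dr = res.call_dmrs(rng_seed=1)
        assert (np.sign(dr.calls.mean_score)
                == np.where(dr.calls.direction == "hyper", 1, -1)).all()

    def test_identical_seed_identical_output(self, fitted_medium):
        res, _ = fitted_medium
        a = res.call_dmrs(rng_seed=9)
        b = res.call_dmrs(rng_seed=9)
        assert a.calls.to_csv() == b.calls.to_csv()
        assert a.scored.to_csv() == b.scored.to_csv()

    def test_more_seeds_never_fewer_compressed_seeds(self, fitted_medium):
        res, _ = fitted_medium
        rt = res.rank_table
        counts = []
        for n_seeds in (500, 1000, 2000):
            dr = call_dmrs(rt, DMRParams(n_seeds=n_seeds, n_boot=100,
                                         rng_seed=1))
            counts.append(dr.log["n_compressed_seeds"])
        assert counts == sorted(counts)

    def test_region_recovery_against_truth(self, fitted_medium):
        res, truth = fitted_medium
        dr = res.call_dmrs(rng_seed=1)
        ev = em.evaluate_calls(dr.calls, truth, "dmr_region")
        assert ev["precision"] >= 0.8
        assert ev["recall"] >= 0.6
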