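"""Simulated WGBS genomes with exact ground truth.

Each genome is 24 Mb over three 8 Mb chromosomes with 1.2 million measured
CpG loci at roughly 30x coverage, three treatment vs three control samples.
Three variation levels set the differential budget:

====== ========= ====== ======
level  true DMLs stray  DMRs
====== ========= ====== ======
low       8358    1000    45
medium   18774    3000   106
high     37192    6000   192
====== ========= ====== ======

True DMLs are primarily placed inside non-overlapping "true" DMR intervals
of uniform random length 100-4000 bp; the stray remainder (counted within
the total, roughly 15%) is scattered outside all intervals with random
direction, mimicking the isolated differential loci seen in real WGBS.
Every locus draws a site-level seed methylation fraction from a truncated
normal — NS(mu 0.5, sd 0.1, [0.25, 0.75]), hyper(0.55, 0.1, [0.35, 0.85]),
hypo(0.45, 0.1, [0.15, 0.65]) — shared by all samples.  A per-site intensity
modifier m drawn from {0.25, 0.5, 0.75} moves the treatment success
probability a fraction m toward the extreme (hyper: b + m(1-b); hypo:
b - m*b).  Reads are then sampled per sample per locus: depth ~ Poisson(30)
floored at 1, methylated reads ~ Binomial(depth, probability).

All class counts are exact by construction, for every seed; only positions
and read draws vary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationMatrix

LEVEL_TABLE = {
    "low": {"n_dml_total": 8358, "n_stray": 1000, "n_dmr": 45},
    "medium": {"n_dml_total": 18774, "n_stray": 3000, "n_dmr": 106},
    "high": {"n_dml_total": 37192, "n_stray": 6000, "n_dmr": 192},
}

#: (mu, sd, lower, upper) of the site-seed truncated normals, by class
CLASS_DISTS = {
    "NS": (0.5, 0.1, 0.25, 0.75),
    "hyper": (0.55, 0.1, 0.35, 0.85),
    "hypo": (0.45, 0.1, 0.15, 0.65),
}

MODIFIERS = (0.25, 0.5, 0.75)


@dataclass
class SimGenomeSpec:
    level: str
    n_dml_total: int
    n_stray: int
    n_dmr: int
    n_chroms: int = 3
    chrom_len: int = 8_000_000
    n_loci: int = 1_200_000
    dmr_len_min: int = 100
    dmr_len_max: int = 4000
    depth_mean: float = 30.0
    n_treat: int = 3
    n_ctrl: int = 3
    modifiers: tuple = MODIFIERS

    def __post_init__(self):
        if self.n_stray > self.n_dml_total:
            raise ValueError("n_stray cannot exceed n_dml_total")
        if self.n_dml_total > self.n_loci:
            raise ValueError("more true DMLs than loci")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chroms + 1)]

    def scaled(self, factor: int) -> "SimGenomeSpec":
        """A reduced genome for fast runs: one chromosome, budgets / factor.

        The locus density (loci per bp) and all distributional parameters
        are preserved; only sizes shrink.
        """
        total_bp = self.n_chroms * self.chrom_len
        return dataclasses.replace(
            self, n_chroms=1, chrom_len=total_bp // factor,
            n_loci=round(self.n_loci / factor),
            n_dml_total=round(self.n_dml_total / factor),
            n_stray=round(self.n_stray / factor),
            n_dmr=max(1, round(self.n_dmr / factor)) if self.n_dmr else 0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_spec(level: str) -> SimGenomeSpec:
    """The published parameter set for a variation level (low/medium/high)."""
    if level not in LEVEL_TABLE:
        raise ValueError(f"unknown level {level!r}; expected one of "
                         f"{sorted(LEVEL_TABLE)}")
    return SimGenomeSpec(level=level, **LEVEL_TABLE[level])


def null_spec(n_loci: int = 100_000, chrom_len: int = 2_000_000) -> SimGenomeSpec:
    """A genome with zero true differential sites (for null calibration)."""
    return SimGenomeSpec(level="null", n_dml_total=0, n_stray=0, n_dmr=0,
                         n_chroms=1, chrom_len=chrom_len, n_loci=n_loci)


@dataclass
class SimGenomeTruth:
    """Ground truth: per-locus class table and the true DMR intervals."""

    loci: pd.DataFrame       # chrom, pos, cls, modifier, stray, dmr_id
    dmrs: pd.DataFrame       # dmr_id, chrom, start, end, length, direction, n_loci
    spec: SimGenomeSpec = field(repr=False, default=None)

    @property
    def n_true(self) -> int:
        return int((self.loci["cls"] != "NS").sum())


def _place_intervals(rng: np.random.Generator, chrom_len: int,
                     lengths: np.ndarray) -> np.ndarray:
    """Non-overlapping 1-based starts for the given lengths within one chromosome."""
    k = len(lengths)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    free = chrom_len - int(lengths.sum())
    if free < 0:
        raise ValueError("cannot pack DMR intervals into chromosome")
    order = rng.permutation(k)  # random left-to-right order of the intervals
    cuts = np.sort(rng.integers(0, free + 1, size=k))
    starts = np.empty(k, dtype=np.int64)
    offset = 0
    for i, j in enumerate(order):
        starts[j] = cuts[i] + offset + 1
        offset += lengths[j]
    return starts


def generate_truth(spec: SimGenomeSpec, rng: np.random.Generator) -> SimGenomeTruth:
    """Place true DMR intervals, in-DMR DMLs, background loci and stray DMLs.

    Class counts match the spec exactly for every seed: the in-DMR budget
    (n_dml_total - n_stray) is allocated across intervals multinomially in
    proportion to interval length (capped at interval capacity) and realized
    by uniform sampling without replacement inside each interval; remaining
    loci fall uniformly outside all intervals, with n_stray of them upgraded
    to stray DMLs of random direction.
    """
    n_in_dmr = spec.n_dml_total - spec.n_stray
    if spec.n_dmr > 0 and n_in_dmr <= 0:
        raise ValueError("DMR intervals requested but the in-DMR DML budget "
                         "(n_dml_total - n_stray) is empty")
    # -- intervals --------------------------------------------------------
    lengths = rng.integers(spec.dmr_len_min, spec.dmr_len_max + 1,
                           size=spec.n_dmr).astype(np.int64)
    chrom_probs = np.full(spec.n_chroms, 1.0 / spec.n_chroms)
    chrom_of = rng.choice(spec.n_chroms, size=spec.n_dmr, p=chrom_probs)
    dmr_rows = []
    for ci, cname in enumerate(spec.chrom_names):
        mask = chrom_of == ci
        starts = _place_intervals(rng, spec.chrom_len, lengths[mask])
        for ln, st in zip(lengths[mask], starts):
            dmr_rows.append({"chrom": cname, "start": int(st),
                             "end": int(st + ln - 1), "length": int(ln)})
    dmrs = (pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "length"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))
    dmrs.insert(0, "dmr_id", np.arange(len(dmrs)))
    dmrs["direction"] = rng.choice(["hyper", "hypo"], size=len(dmrs))

    # -- in-DMR DML allocation -------------------------------------------
    if spec.n_dmr > 0:
        cap = dmrs["length"].to_numpy(np.int64)
        probs = cap / cap.sum()
        alloc = rng.multinomial(n_in_dmr, probs)
        # cap at interval capacity; push any excess to intervals with room
        excess = int(np.maximum(alloc - cap, 0).sum())
        alloc = np.minimum(alloc, cap)
        while excess > 0:
            room = cap - alloc
            open_idx = np.flatnonzero(room > 0)
            take = rng.choice(open_idx, size=min(excess, len(open_idx)),
                              replace=False)
            alloc[take] += 1
            excess -= len(take)
    else:
        alloc = np.zeros(0, dtype=np.int64)

    loci_parts = []
    for i, row in dmrs.iterrows():
        k = int(alloc[i])
        if k == 0:
            continue
        offs = rng.choice(int(row["length"]), size=k, replace=False)
        loci_parts.append(pd.DataFrame({
            "chrom": row["chrom"], "pos": (row["start"] + offs).astype(np.int64),
            "cls": row["direction"], "stray": False, "dmr_id": row["dmr_id"]}))
    dmrs["n_loci"] = alloc if len(alloc) else 0

    # -- background loci outside every interval --------------------------
    n_outside = spec.n_loci - int(alloc.sum())
    avail = []
    for cname in spec.chrom_names:
        mask = np.zeros(spec.chrom_len, dtype=bool)
        for _, row in dmrs[dmrs["chrom"] == cname].iterrows():
            mask[row["start"] - 1:row["end"]] = True
        avail.append(np.flatnonzero(~mask) + 1)  # 1-based free positions
    n_avail = np.array([len(a) for a in avail], dtype=np.int64)
    out_alloc = rng.multinomial(n_outside, n_avail / n_avail.sum())
    if (out_alloc > n_avail).any():  # vanishingly rare; shift to roomier chroms
        over = out_alloc - np.minimum(out_alloc, n_avail)
        out_alloc = np.minimum(out_alloc, n_avail)
        for _ in range(int(over.sum())):
            j = int(np.argmax(n_avail - out_alloc))
            out_alloc[j] += 1
    for cname, a, k in zip(spec.chrom_names, avail, out_alloc):
        if k == 0:
            continue
        pos = rng.choice(a, size=int(k), replace=False).astype(np.int64)
        loci_parts.append(pd.DataFrame({
            "chrom": cname, "pos": pos, "cls": "NS", "stray": False,
            "dmr_id": -1}))
    loci = pd.concat(loci_parts, ignore_index=True)

    # -- stray DMLs -------------------------------------------------------
    outside_idx = loci.index[loci["dmr_id"] == -1].to_numpy()
    if spec.n_stray > len(outside_idx):
        raise ValueError("not enough outside loci to host stray DMLs")
    if spec.n_stray:
        stray_idx = rng.choice(outside_idx, size=spec.n_stray, replace=False)
        loci.loc[stray_idx, "cls"] = rng.choice(["hyper", "hypo"],
                                                size=spec.n_stray)
        loci.loc[stray_idx, "stray"] = True

    true_mask = loci["cls"] != "NS"
    loci["modifier"] = np.nan
    loci.loc[true_mask, "modifier"] = rng.choice(spec.modifiers,
                                                 size=int(true_mask.sum()))
    loci = (loci.sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
            [["chrom", "pos", "cls", "modifier", "stray", "dmr_id"]])
    assert int((loci["cls"] != "NS").sum()) == spec.n_dml_total
    assert int(loci["stray"].sum()) == spec.n_stray
    assert len(loci) == spec.n_loci
    return SimGenomeTruth(loci=loci, dmrs=dmrs, spec=spec)


def _truncnorm_rvs(params: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    mu, sd, lo, hi = params
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def generate_samples(truth: SimGenomeTruth, spec: SimGenomeSpec,
                     rng: np.random.Generator
                     ) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Draw site seeds and per-sample reads; return the matrix and a sidecar.

    The sidecar extends the truth table with the site seed fraction and the
    treatment/control success probabilities actually used, so accuracy tests
    can condition on them.
    """
    loci = truth.loci
    n = len(loci)
    seed_frac = np.empty(n)
    for cls, params in CLASS_DISTS.items():
        mask = (loci["cls"] == cls).to_numpy()
        if mask.any():
            seed_frac[mask] = _truncnorm_rvs(params, int(mask.sum()), rng)
    mod = loci["modifier"].to_numpy(float)
    cls_arr = loci["cls"].to_numpy()
    p_ctrl = seed_frac.copy()
    p_treat = seed_frac.copy()
    hyper = cls_arr == "hyper"
    hypo = cls_arr == "hypo"
    p_treat[hyper] = seed_frac[hyper] + mod[hyper] * (1.0 - seed_frac[hyper])
    p_treat[hypo] = seed_frac[hypo] - mod[hypo] * seed_frac[hypo]
    p_treat = np.clip(p_treat, 0.0, 1.0)

    names = ([f"T{i}" for i in range(1, spec.n_treat + 1)] +
             [f"C{i}" for i in range(1, spec.n_ctrl + 1)])
    groups = {s: ("treatment" if s.startswith("T") else "control") for s in names}
    data = loci[["chrom", "pos"]].copy()
    data["strand"] = "+"
    for s in names:
        prob = p_treat if groups[s] == "treatment" else p_ctrl
        depth = np.maximum(rng.poisson(spec.depth_mean, size=n), 1)
        meth = rng.binomial(depth, prob)
        data[f"{s}.depth"] = depth.astype(float)
        data[f"{s}.meth"] = meth / depth
    matrix = MethylationMatrix(data, names, groups)
    sidecar = loci.copy()
    sidecar["seed_frac"] = seed_frac
    sidecar["p_treat"] = p_treat
    sidecar["p_ctrl"] = p_ctrl
    return matrix, sidecar


def simulate_genome(level: str, seed: int, scale: int = 1
                    ) -> tuple[MethylationMatrix, SimGenomeTruth, pd.DataFrame]:
    """Convenience wrapper: spec -> truth -> samples from one integer seed."""
    spec = build_spec(level)
    if scale > 1:
        spec = spec.scaled(scale)
    ss = np.random.SeedSequence(seed)
    rng_truth, rng_samples = (np.random.default_rng(c) for c in ss.spawn(2))
    truth = generate_truth(spec, rng_truth)
    matrix, sidecar = generate_samples(truth, spec, rng_samples)
    return matrix, truth, sidecar


# -- accuracy evaluation ---------------------------------------------------

def evaluate_calls(calls, truth: SimGenomeTruth, mode: str) -> dict:
    """Confusion summary of DML or DMR calls against the simulated truth.

    ``dml``: locus-exact TP/FP/FN.  ``dmr_region``: a call is a true
    positive if it overlaps >= 1 bp of any true interval; a true interval is
    found if overlapped by >= 1 call.  ``dmr_base``: per-bp TP/FP/FN over
    the union footprint of calls and truth.
    """
    if mode == "dml":
        true_set = set(map(tuple, truth.loci.loc[truth.loci["cls"] != "NS",
                                                 ["chrom", "pos"]].itertuples(index=False)))
        call_set = set(map(tuple, calls[["chrom", "pos"]].itertuples(index=False)))
        tp = len(call_set & true_set)
        fp = len(call_set - true_set)
        fn = len(true_set - call_set)
    elif mode in ("dmr_region", "dmr_base"):
        tdf = truth.dmrs
        cdf = calls
        if mode == "dmr_region":
            tp = fp = 0
            found = np.zeros(len(tdf), dtype=bool)
            tarr = {c: tdf[tdf["chrom"] == c] for c in tdf["chrom"].unique()}
            for row in cdf.itertuples(index=False):
                sub = tarr.get(row.chrom)
                if sub is None:
                    fp += 1
                    continue
                hits = (sub["start"] <= row.end) & (sub["end"] >= row.start)
                if hits.any():
                    tp += 1
                    found[sub.index[hits]] = True
                else:
                    fp += 1
            fn = int((~found).sum())
        else:
            tp = fp = fn = 0
            chroms = set(tdf["chrom"]) | set(cdf["chrom"])
            for chrom in chroms:
                t_iv = tdf[tdf["chrom"] == chrom]
                c_iv = cdf[cdf["chrom"] == chrom]
                hi = max([*t_iv["end"], *c_iv["end"], 0]) + 1
                t_mask = np.zeros(hi, dtype=bool)
                c_mask = np.zeros(hi, dtype=bool)
                for row in t_iv.itertuples(index=False):
                    t_mask[row.start - 1:row.end] = True
                for row in c_iv.itertuples(index=False):
                    c_mask[row.start - 1:row.end] = True
                tp += int((t_mask & c_mask).sum())
                fp += int((~t_mask & c_mask).sum())
                fn += int((t_mask & ~c_mask).sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"mode": mode, "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall}


# -- file output -----------------------------------------------------------

def write_genome(outdir, matrix: MethylationMatrix, truth: SimGenomeTruth,
                 sidecar: pd.DataFrame | None = None) -> None:
    """Write per-sample Bismark-coverage files, the wide table and the truth."""
    import os
    import yaml

    os.makedirs(outdir, exist_ok=True)
    for s in matrix.samples:
        depth = matrix.data[f"{s}.depth"]
        frac = matrix.data[f"{s}.meth"]
        meth = (frac * depth).round().astype(np.int64)
        unmeth = depth.astype(np.int64) - meth
        cov = pd.DataFrame({
            "chrom": matrix.data["chrom"], "start": matrix.data["pos"],
            "end": matrix.data["pos"],
            "pct": (100.0 * frac).round(6), "meth": meth, "unmeth": unmeth})
        cov.to_csv(os.path.join(outdir, f"{s}.cov"), sep="\t", index=False,
                   header=False)
    matrix.to_wide_tsv(os.path.join(outdir, "methylation_wide.tsv"))
    (sidecar if sidecar is not None else truth.loci).to_csv(
        os.path.join(outdir, "truth_loci.tsv"), sep="\t", index=False)
    truth.dmrs.to_csv(os.path.join(outdir, "truth_dmrs.tsv"), sep="\t",
                      index=False)
    with open(os.path.join(outdir, "truth_dmrs.bed"), "w") as fh:
        for row in truth.dmrs.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                     f"DMR_{row.dmr_id}\t0\t.\n")
    if truth.spec is not None:
        with open(os.path.join(outdir, "sim_spec.yaml"), "w") as fh:
            yaml.safe_dump(truth.spec.to_dict(), fh)
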