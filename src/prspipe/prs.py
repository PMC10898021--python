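"""Clumping + thresholding polygenic risk scores.

The score for individual *i* is the weighted mean

    PRS_i = ( sum_j beta_j * x_ij ) / M

over the M SNPs that survive LD clumping and the p-value threshold p_T,
with beta_j the discovery-GWAS log-odds and x_ij the counted-allele
dosage.  Variants of the score used downstream:

* ``incAPOE`` — all clumped SNPs;
* ``noAPOE``  — after removing ±500 kb around the APOE top hit
  (chr19:45,403,412 by default);
* ``nochr19`` — after removing all of chromosome 19;
* ``adjLD``   — noAPOE after collapsing each external-LD block
  (pairwise r² > 0.5, plus any SNP positioned inside the block span)
  to its single lowest-p member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prspipe.errors import DegenerateDataError, IncompleteLDTableError, PrsPipeError
from prspipe.io_genotype import GenotypeMatrix, SummaryStats

#: the p_T grid scanned when selecting the optimal threshold
THRESHOLD_GRID = (5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.5, 1.0)

#: APOE-region top hit (GRCh37) used as the default exclusion center
APOE_CHROM = "19"
APOE_CENTER_BP = 45_403_412
APOE_FLANK_BP = 500_000


@dataclass
class ClumpParams:
    """Greedy clumping parameters (PLINK-style defaults)."""

    window_kb: int = 250
    r2_max: float = 0.1
    p_max: float = 1.0

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0,1]")


@dataclass
class ExclusionRegion:
    """A chrom:center ± flank exclusion window; ``flank_bp=None`` drops
    the whole chromosome."""

    chrom: str = APOE_CHROM
    center_pos: int = APOE_CENTER_BP
    flank_bp: int | None = APOE_FLANK_BP

    def __post_init__(self) -> None:
        if self.flank_bp is not None and self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive (or None for whole-chromosome)")


@dataclass
class PRSProfile:
    """Per-sample scores at one threshold.

    ``scores`` is indexed by sample id; ``m`` counts the SNPs entering
    the score (the divisor), ``snp_ids`` lists them.
    """

    scores: pd.Series
    m: int
    p_threshold: float
    snp_ids: list[str]
    variant_flag: str = "incAPOE"

    def __post_init__(self) -> None:
        if self.m != len(self.snp_ids) or self.m < 1:
            raise PrsPipeError("M must equal the number of SNPs used and be >= 1")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise PrsPipeError("non-finite PRS scores")


def ld_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns (pairwise-complete)."""
    a, b = g.dosage[:, i], g.dosage[:, j]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("LD undefined for a monomorphic variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(stats: SummaryStats, g: GenotypeMatrix, params: ClumpParams | None = None) -> list[str]:
    """Greedy LD clumping: returns index-SNP ids in genome-position order.

    SNPs are visited in ascending p (ties: ascending position); each
    unclaimed SNP becomes an index and claims all unclaimed SNPs within
    ``window_kb`` on the same chromosome with r² above ``r2_max``.
    Indices with p ≤ p_max are returned.
    """
    params = params or ClumpParams()
    t = stats.table
    if t.empty:
        return []
    gidx = g.variant_index(t["snp_id"])
    pos = t["pos"].to_numpy()
    chrom = t["chrom"].to_numpy()
    pval = t["pvalue"].to_numpy()

    order = np.lexsort((pos, pval))
    claimed = np.zeros(len(t), dtype=bool)
    is_index = np.zeros(len(t), dtype=bool)
    window_bp = params.window_kb * 1000
    d = g.dosage

    # per-variant mean-imputed, centered columns for fast correlation
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean[None, :], d)
    filled = filled - filled.mean(axis=0)
    norms = np.sqrt((filled**2).sum(axis=0))

    for k in order:
        if claimed[k]:
            continue
        is_index[k] = True
        near = (
            ~claimed
            & ~is_index
            & (chrom == chrom[k])
            & (np.abs(pos - pos[k]) <= window_bp)
        )
        cand = np.flatnonzero(near)
        if cand.size:
            gi = gidx[k]
            gj = gidx[cand]
            denom = norms[gi] * norms[gj]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (filled[:, gj].T @ filled[:, gi]) / denom
            r2 = np.where(denom > 0, r * r, 0.0)
            claimed[cand[r2 > params.r2_max]] = True

    kept = is_index & (pval <= params.p_max)
    kept_idx = np.flatnonzero(kept)
    kept_idx = kept_idx[np.lexsort((pos[kept_idx], chrom[kept_idx]))]
    return t["snp_id"].iloc[kept_idx].tolist()


def exclude_region(stats: SummaryStats, region: ExclusionRegion) -> SummaryStats:
    """Remove SNPs inside the region (boundary inclusive), or the whole
    chromosome when ``flank_bp`` is None."""
    t = stats.table
    on_chrom = t["chrom"] == str(region.chrom)
    if region.flank_bp is None:
        drop = on_chrom
    else:
        drop = on_chrom & ((t["pos"] - region.center_pos).abs() <= region.flank_bp)
    return SummaryStats(t.loc[~drop].reset_index(drop=True), stats.n_dropped)


def compute_prs(
    g: GenotypeMatrix,
    stats: SummaryStats,
    snp_ids: list[str],
    p_threshold: float = 1.0,
    variant_flag: str = "incAPOE",
) -> PRSProfile:
    """Score each sample over the given SNPs with p ≤ p_threshold.

    Missing genotypes are mean-imputed per SNP (center-neutral); the
    divisor M counts SNPs in the score, not per-sample non-missing calls.
    """
    t = stats.table.set_index("snp_id")
    ids = [s for s in snp_ids if t.loc[s, "pvalue"] <= p_threshold]
    if not ids:
        raise DegenerateDataError(f"no SNPs at p_T={p_threshold}: empty score")
    beta = t.loc[ids, "beta"].to_numpy()
    d = g.dosage[:, g.variant_index(ids)]
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    d = np.where(np.isnan(d), col_mean[None, :], d)
    m = len(ids)
    scores = pd.Series(d @ beta / m, index=pd.Index(g.samples, name="sample_id"), name="prs")
    return PRSProfile(scores, m, p_threshold, ids, variant_flag)


def adjust_ld(
    snp_ids: list[str],
    stats: SummaryStats,
    ld_table: pd.DataFrame | None = None,
    g: GenotypeMatrix | None = None,
    r2_cut: float = 0.5,
    consecutive_only: bool = False,
    strict: bool = False,
) -> list[str]:
    """Collapse external-LD blocks to their minimum-p SNP (the adjLD rule).

    Blocks are built from pairs with r² > ``r2_cut`` (edges), then any
    SNP positioned between two linked SNPs joins their block, merging
    overlapping spans.  Per block exactly the lowest-p SNP survives
    (ties: lowest position).  ``ld_table`` needs columns
    ``snp_a, snp_b, r2``; when absent, cohort LD from ``g`` is used.
    ``consecutive_only`` restricts edges to consecutive retained SNPs.
    ``strict`` raises when a same-chromosome pair inside a block span has
    no r² entry (default: such SNPs join the block by position).
    """
    t = stats.table.set_index("snp_id").loc[snp_ids]
    t = t.sort_values(["chrom", "pos"], kind="mergesort")
    ids = t.index.to_list()

    def lookup_r2(a: str, b: str) -> float | None:
        if ld_table is not None:
            hit = ld_table[
                ((ld_table["snp_a"] == a) & (ld_table["snp_b"] == b))
                | ((ld_table["snp_a"] == b) & (ld_table["snp_b"] == a))
            ]
            if len(hit):
                return float(hit["r2"].iloc[0])
            if g is None:
                return None
        if g is not None:
            try:
                i, j = g.variant_index([a, b])
                return ld_r2(g, i, j)
            except (KeyError, DegenerateDataError):
                return None
        return None

    kept: list[str] = []
    for chrom, sub in t.groupby("chrom", sort=False):
        cids = sub.index.to_list()
        pos = sub["pos"].to_numpy()
        n = len(cids)
        # collect linked pairs as position intervals
        intervals = []
        pairs = (
            [(i, i + 1) for i in range(n - 1)]
            if consecutive_only
            else [(i, j) for i in range(n) for j in range(i + 1, n)]
        )
        missing_pairs = set()
        for i, j in pairs:
            r2 = lookup_r2(cids[i], cids[j])
            if r2 is None:
                missing_pairs.add((i, j))
            elif r2 > r2_cut:
                intervals.append((pos[i], pos[j]))
        # merge overlapping intervals into block spans
        intervals.sort()
        merged: list[list[int]] = []
        for lo, hi in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        assigned = np.full(n, -1)
        for b, (lo, hi) in enumerate(merged):
            inside = (pos >= lo) & (pos <= hi)
            assigned[inside] = b
            if strict:
                members = np.flatnonzero(inside)
                for a_i in members:
                    for a_j in members:
                        if a_i < a_j and (a_i, a_j) in missing_pairs:
                            raise IncompleteLDTableError(
                                f"no r2 for {cids[a_i]}–{cids[a_j]} inside block "
                                f"{chrom}:{lo}-{hi}"
                            )
        for b in range(len(merged)):
            members = np.flatnonzero(assigned == b)
            block = sub.iloc[members]
            winner = block.sort_values(["pvalue", "pos"], kind="mergesort").index[0]
            kept.append(winner)
        kept.extend(np.array(cids, dtype=object)[assigned == -1].tolist())

    kept_t = t.loc[kept].sort_values(["chrom", "pos"], kind="mergesort")
    return kept_t.index.to_list()


def standardize(profile: PRSProfile) -> PRSProfile:
    """Z-score the profile (mean 0, SD 1 with the n−1 denominator)."""
    s = profile.scores
    if len(s) < 2:
        raise DegenerateDataError("standardization requires at least 2 samples")
    sd = s.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant PRS distribution cannot be standardized")
    return PRSProfile(
        (s - s.mean()) / sd, profile.m, profile.p_threshold,
        profile.snp_ids, profile.variant_flag,
    )
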