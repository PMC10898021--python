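"""Marker and sample quality control.

The filter cascade mirrors standard array-QC practice for case-control
genetics: duplicate-position removal, marker missingness, Hardy–Weinberg
exact test in controls, minor-allele-frequency cutoff; then sample
missingness, autosomal heterozygosity deviation (|F_het|), and greedy
removal of one member of each related pair (pi-hat from PLINK-style
method-of-moments IBD on LD-pruned markers).  Ancestry components come
from PCA of the frequency-standardized dosage matrix or classical MDS of
its Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from prspipe.errors import DegenerateDataError, PrsPipeError
from prspipe.io_genotype import GenotypeMatrix, PhenoTable


@dataclass
class QCThresholds:
    """Filter thresholds; defaults follow common array-QC practice.

    marker_missing_max : maximum per-marker missing fraction (call rate ≥ 95%)
    hwe_p_min          : HWE exact p below this (in controls) removes a marker
    maf_min            : minimum minor-allele frequency
    sample_missing_max : maximum per-sample missing fraction (call rate ≥ 99%)
    fhet_abs_max       : |F_het| at or above this removes a sample
    pihat_max          : pi-hat above this flags a related pair
    """

    marker_missing_max: float = 0.05
    hwe_p_min: float = 1e-5
    maf_min: float = 0.01
    sample_missing_max: float = 0.01
    fhet_abs_max: float = 0.2
    pihat_max: float = 0.2

    def __post_init__(self) -> None:
        for name in ("marker_missing_max", "hwe_p_min", "maf_min",
                     "sample_missing_max", "pihat_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0,1)")
        if self.fhet_abs_max <= 0:
            raise ValueError("fhet_abs_max must be positive")


@dataclass
class QCReport:
    """Per-stage removal counts plus the retained identifiers."""

    stages: list[dict] = field(default_factory=list)
    retained_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {"stage": stage, "n_in": n_in, "n_removed": n_removed,
             "n_retained": n_in - n_removed}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test (Wigginton et al. 2005).

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed configuration (no mid-p correction).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DegenerateDataError("HWE test undefined for zero total count")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    # heterozygote counts share the parity of the rare-allele count
    het_lo = n_rare % 2
    probs = {}
    # recurrence from the mid heterozygote count outward, in ratio form
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != het_lo:
        mid += 1
    probs[mid] = 1.0
    # P(h-2)/P(h) = h(h-1) / ((r/2 - h/2 + 1)(c - r/2 - h/2 + 1)) with
    # r = rare count, c = common count; derived from the hypergeometric-type pmf
    h = mid
    while h >= het_lo + 2:
        hom_r = (n_rare - h) // 2          # rare homozygotes at h
        hom_c = n - h - hom_r              # common homozygotes at h
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= n_rare:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def _allele_freq(dosage: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per variant, ignoring missing calls."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosage, axis=0) / 2.0


def marker_qc(
    g: GenotypeMatrix, pheno: PhenoTable, t: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker filters in order: duplicate position, missingness,
    HWE in controls, MAF.  All markers at a duplicated chrom:pos are
    removed (conservative)."""
    t = t or QCThresholds()
    report = QCReport()
    keep = np.ones(g.n_variants, dtype=bool)

    dup = g.variants.duplicated(subset=["chrom", "pos"], keep=False).to_numpy()
    report.add("duplicate_position", int(keep.sum()), int(dup[keep].sum()))
    keep &= ~dup

    miss = np.isnan(g.dosage).mean(axis=0)
    fail = keep & (miss > t.marker_missing_max)
    report.add("marker_missingness", int(keep.sum()), int(fail.sum()))
    keep &= ~fail

    pheno_ids = pheno.table.set_index("sample_id")["diagnosis"]
    control_mask = np.array(
        [pheno_ids.get(s) == "CU" for s in g.samples], dtype=bool
    )
    if control_mask.sum() == 0:
        report.warnings.append("no control samples: HWE stage skipped")
        report.add("hwe_controls", int(keep.sum()), 0)
    else:
        d = g.dosage[control_mask]
        n_aa = np.nansum(d == 0, axis=0)
        n_het = np.nansum(d == 1, axis=0)
        n_AA = np.nansum(d == 2, axis=0)
        fail = np.zeros(g.n_variants, dtype=bool)
        for j in np.flatnonzero(keep):
            total = n_AA[j] + n_het[j] + n_aa[j]
            if total == 0:
                continue
            fail[j] = hwe_exact_test(int(n_AA[j]), int(n_het[j]), int(n_aa[j])) < t.hwe_p_min
        report.add("hwe_controls", int(keep.sum()), int(fail.sum()))
        keep &= ~fail

    freq = _allele_freq(g.dosage)
    maf = np.minimum(freq, 1 - freq)
    fail = keep & (maf < t.maf_min)
    report.add("maf", int(keep.sum()), int(fail.sum()))
    keep &= ~fail

    out = g.subset(variant_idx=np.flatnonzero(keep))
    report.retained_ids = out.variants["snp_id"].tolist()
    return out, report


# ---------------------------------------------------------------------------
# sample QC


def heterozygosity_f(g: GenotypeMatrix) -> np.ndarray:
    """Per-sample F = 1 − observed het / expected het across markers.

    Expected heterozygosity uses cohort allele frequencies, summed over
    the markers non-missing in each sample.
    """
    d = g.dosage
    freq = _allele_freq(d)
    exp_het_per_snp = 2.0 * freq * (1.0 - freq)
    nonmiss = ~np.isnan(d)
    obs = np.nansum(d == 1, axis=1).astype(float)
    exp = nonmiss @ exp_het_per_snp
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(exp > 0, 1.0 - obs / exp, 0.0)


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2) -> np.ndarray:
    """Greedy window-based LD pruning (indices of retained variants).

    Slides a ``window``-marker window by ``step``; within each window,
    pairs with r² above ``r2_max`` lose the later-positioned member.
    """
    m = g.n_variants
    keep = np.ones(m, dtype=bool)
    d = g.dosage
    order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
    for start in range(0, m, step):
        idx = order[start:start + window]
        idx = idx[keep[idx]]
        if len(idx) < 2:
            continue
        sub = d[:, idx]
        sub = np.where(np.isnan(sub), np.nanmean(sub, axis=0), sub)
        sd = sub.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        c = np.corrcoef(sub[:, ok].T) ** 2
        live = idx[ok]
        for a in range(len(live)):
            if not keep[live[a]]:
                continue
            for b in range(a + 1, len(live)):
                if keep[live[b]] and c[a, b] > r2_max:
                    keep[live[b]] = False
    return np.flatnonzero(keep)


def pi_hat_matrix(g: GenotypeMatrix) -> np.ndarray:
    """PLINK-style method-of-moments IBD estimate for every sample pair.

    Counts IBS0/IBS1/IBS2 markers per pair, converts to P(IBD=0,1,2) via
    the expected IBS|IBD proportions under Hardy–Weinberg, clamps to
    [0,1], and returns pi-hat = P(IBD=2) + P(IBD=1)/2.
    """
    d = g.dosage
    freq = _allele_freq(d)
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    d = d[:, poly]
    p = freq[poly]
    q = 1 - p
    filled = np.where(np.isnan(d), -9.0, d)
    A = np.stack([(filled == k).astype(float) for k in (0.0, 1.0, 2.0)])
    nonmiss = A.sum(axis=0)

    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    ibs2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    pairs_nonmiss = nonmiss @ nonmiss.T  # markers non-missing in both
    ibs1 = pairs_nonmiss - ibs0 - ibs2

    # expected per-marker IBS proportions given IBD state (summed over markers)
    e0_ibd0 = np.sum(2 * p**2 * q**2)
    e1_ibd0 = np.sum(4 * p**3 * q + 4 * p * q**3)
    e1_ibd1 = np.sum(2 * p * q)
    # scale expectations by each pair's non-missing fraction
    m_poly = d.shape[1]
    frac = pairs_nonmiss / m_poly
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ibd0 = ibs0 / (e0_ibd0 * frac)
        p_ibd1 = (ibs1 - e1_ibd0 * frac * p_ibd0) / (e1_ibd1 * frac)
    p_ibd0 = np.clip(np.nan_to_num(p_ibd0), 0, 1)
    p_ibd1 = np.clip(np.nan_to_num(p_ibd1), 0, 1 - p_ibd0)
    p_ibd2 = 1.0 - p_ibd0 - p_ibd1
    return p_ibd2 + 0.5 * p_ibd1


def sample_qc(
    g: GenotypeMatrix, t: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample filters: missingness, |F_het|, relatedness.

    For each pair with pi-hat above threshold the later-listed sample is
    removed (deterministic).  With fewer than 2 samples the relatedness
    stage is skipped.  A sex check would require X-chromosome genotypes
    and is recorded as skipped.
    """
    t = t or QCThresholds()
    report = QCReport()
    report.warnings.append("sex_check skipped: no X-chromosome genotypes modeled")
    keep = np.ones(g.n_samples, dtype=bool)

    miss = np.isnan(g.dosage).mean(axis=1)
    fail = miss > t.sample_missing_max
    report.add("sample_missingness", int(keep.sum()), int(fail.sum()))
    keep &= ~fail

    sub = g.subset(sample_idx=np.flatnonzero(keep))
    f = heterozygosity_f(sub)
    fail_local = np.abs(f) >= t.fhet_abs_max
    report.add("heterozygosity_f", int(keep.sum()), int(fail_local.sum()))
    live = np.flatnonzero(keep)
    keep[live[fail_local]] = False

    if keep.sum() < 2:
        report.warnings.append("fewer than 2 samples: relatedness stage skipped")
        report.add("relatedness", int(keep.sum()), 0)
    else:
        sub = g.subset(sample_idx=np.flatnonzero(keep))
        pruned = ld_prune(sub, r2_max=0.2)
        pihat = pi_hat_matrix(sub.subset(variant_idx=pruned))
        n = pihat.shape[0]
        drop_local = np.zeros(n, dtype=bool)
        for i in range(n):
            if drop_local[i]:
                continue
            for j in range(i + 1, n):
                if not drop_local[j] and pihat[i, j] > t.pihat_max:
                    drop_local[j] = True
        report.add("relatedness", int(keep.sum()), int(drop_local.sum()))
        live = np.flatnonzero(keep)
        keep[live[drop_local]] = False

    out = g.subset(sample_idx=np.flatnonzero(keep))
    report.retained_ids = out.samples
    return out, report


# ---------------------------------------------------------------------------
# ancestry components


def _standardized_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Mean-impute, center, and scale each variant by sqrt(2p(1-p))."""
    d = g.dosage.copy()
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    out = np.zeros_like(d)
    out[:, ok] = (d[:, ok] - mean[ok]) / scale[ok]
    return out


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each component positive."""
    for k in range(scores.shape[1]):
        col = scores[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -col
    return scores


def ancestry_components(g: GenotypeMatrix, k: int, method: str = "pca") -> np.ndarray:
    """First ``k`` ancestry components of the cohort.

    ``method='pca'``: principal-component scores of the centered,
    frequency-standardized dosage matrix.  ``method='mds'``: classical
    (Torgerson) MDS of the Euclidean distance matrix of the same
    standardized dosages — identical to PCA up to sign.  The sign of each
    component is fixed by making its largest-magnitude score positive.
    """
    if k == 0:
        return np.empty((g.n_samples, 0))
    if k < 0:
        raise ValueError("k must be non-negative")
    x = _standardized_dosage(g)
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        # no variance at all (e.g. identical samples): components are zero
        return np.zeros((g.n_samples, k))
    rank = np.linalg.matrix_rank(xc)
    if k > rank:
        raise PrsPipeError(f"requested {k} components but matrix rank is {rank}")
    if method == "pca":
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        scores = u[:, :k] * s[:k]
    elif method == "mds":
        # double-centered squared-distance matrix; eigvecs scaled by sqrt(eigvals)
        sq = (xc**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * xc @ xc.T
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        w, v = np.linalg.eigh(b)
        order = np.argsort(w)[::-1]
        w, v = w[order[:k]], v[:, order[:k]]
        scores = v * np.sqrt(np.clip(w, 0, None))
    else:
        raise ValueError(f"unknown method {method!r}")
    return _fix_signs(scores)
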