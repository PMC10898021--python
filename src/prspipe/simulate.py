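"""Synthetic cohort generator.

Emulates the data structure the pipeline consumes: LD-blocked biallelic
genotypes (Gaussian-copula haplotypes with AR(1) within-block
correlation, Hardy–Weinberg by construction), a European-discovery-style
summary-statistic file (per-SNP marginal logistic betas and p-values
from a simulated case-control GWAS), a liability-threshold phenotype
with one major APOE-like locus on chromosome 19 plus a polygenic
background, censored MCI-to-AD conversion times whose hazard depends on
the PRS stratum (by default only in APOE ε4 noncarriers), and Gaussian
CSF-ratio-like endophenotypes linearly related to the true polygenic
score in the MCI stratum.

Default cohort structure: 145 CU / 220 MCI / 139 ADD target samples,
12000 discovery samples, 120 LD blocks of 6 SNPs, 20 causal SNPs with
liability-scale h² 0.25, major-locus odds ratio 3.0, conversion hazard
ratio 2.22 (high vs low PRS tertile), 36-month administrative censoring
on a 6-month visit grid, and endophenotype slope 0.235 per PRS SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from prspipe.io_genotype import GenotypeMatrix, PhenoTable, SummaryStats
from prspipe.prs import APOE_CENTER_BP, APOE_CHROM
from prspipe.qc import ancestry_components

#: logit→probit scale factor for converting an odds ratio to a liability effect
_LOGIT_TO_PROBIT = 1.81


@dataclass
class SimConfig:
    """Generator parameters; defaults define the study conditions."""

    n_discovery: int = 12000
    group_sizes: tuple[int, int, int] = (145, 220, 139)  # CU, MCI, ADD
    n_blocks: int = 120
    block_size: int = 6
    within_block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 20
    h2_polygenic: float = 0.25
    major_locus_or: float = 3.0
    prevalence: float = 0.2
    hr_high_vs_low: float = 2.22
    hr_noncarriers_only: bool = True
    baseline_36m_conversion: float = 0.35
    endophenotype_slope: float = 0.235
    endophenotype_mci_only: bool = True
    censor_months: float = 36.0
    visit_months: float | None = 6.0
    dropout_rate: float = 0.01  # per-month exponential drop-out hazard
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0,1)")
        if not 0 <= self.h2_polygenic < 1:
            raise ValueError("h2_polygenic must be in [0,1)")
        if min(self.group_sizes) <= 0 or self.n_blocks <= 0 or self.block_size <= 0:
            raise ValueError("counts must be positive")

    @property
    def n_target(self) -> int:
        return int(sum(self.group_sizes))


def _variant_map(cfg: SimConfig) -> pd.DataFrame:
    """Genome layout: polygenic blocks on chr 1–18 plus one APOE-like
    block on chr 19 centered at the APOE top-hit position."""
    rows = []
    for b in range(cfg.n_blocks):
        chrom = str((b % 18) + 1)
        base = 1_000_000 + (b // 18) * 20_000_000
        for j in range(cfg.block_size):
            rows.append(
                {"snp_id": f"rs{b:03d}_{j:02d}", "chrom": chrom,
                 "pos": base + j * 1000, "block": b}
            )
    major_block = cfg.n_blocks
    for j in range(cfg.block_size):
        rows.append(
            {"snp_id": f"rs19_{j:02d}", "chrom": APOE_CHROM,
             "pos": APOE_CENTER_BP + (j - cfg.block_size // 2) * 1000,
             "block": major_block}
        )
    df = pd.DataFrame(rows)
    df["a1"] = "A"  # counted (risk-scored) allele
    df["a2"] = "G"
    return df


def simulate_genotypes(
    cfg: SimConfig, n: int, rng: np.random.Generator, vmap: pd.DataFrame, maf: np.ndarray
) -> GenotypeMatrix:
    """Draw ``n`` diploid genotypes via the haplotype Gaussian copula.

    Each haplotype's latent vector is AR(1) with parameter rho inside a
    block, independent across blocks; an allele is carried when the
    latent value falls below the MAF quantile, so single-SNP genotypes
    are Hardy–Weinberg by construction and within-block dosages are
    correlated.
    """
    rho = cfg.within_block_rho
    m = len(vmap)
    thresh = norm.ppf(maf)
    dosage = np.zeros((n, m))
    for _ in range(2):  # two haplotypes
        z = np.empty((n, m))
        for _, block_idx in vmap.groupby("block").groups.items():
            idx = np.asarray(block_idx)
            k = len(idx)
            e = rng.standard_normal((n, k))
            zb = np.empty((n, k))
            zb[:, 0] = e[:, 0]
            for j in range(1, k):
                zb[:, j] = rho * zb[:, j - 1] + np.sqrt(1 - rho**2) * e[:, j]
            z[:, idx] = zb
        dosage += (z < thresh[None, :]).astype(float)
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples, vmap[["snp_id", "chrom", "pos", "a1", "a2"]], dosage)


@dataclass
class Truth:
    """Ground truth of one simulated cohort, for recovery tests."""

    causal_ids: list[str]
    true_beta: pd.Series           # liability-scale per-allele effects
    major_id: str
    major_beta: float
    e2_id: str
    e2_beta: float
    maf: pd.Series
    h2_polygenic: float
    true_hr: float
    endophenotype_slope: float


def _draw_effects(cfg: SimConfig, vmap: pd.DataFrame, maf: np.ndarray, rng) -> Truth:
    poly = vmap[vmap["chrom"] != APOE_CHROM]
    # one causal SNP per block, spread over the first n_causal blocks
    causal_blocks = sorted(poly["block"].unique())[: cfg.n_causal]
    causal_idx = [poly[poly["block"] == b].index[0] for b in causal_blocks]
    causal_ids = vmap.loc[causal_idx, "snp_id"].tolist()
    # equal-magnitude, random-sign effects: every causal SNP is individually
    # detectable in the discovery scan, so the causal set occupies a
    # well-defined band of the p_T grid
    raw = rng.choice([-1.0, 1.0], size=len(causal_idx))
    p = maf[causal_idx]
    var_unit = np.sum(raw**2 * 2 * p * (1 - p))
    beta = raw * np.sqrt(cfg.h2_polygenic / var_unit)
    major_pos = vmap.index[vmap["snp_id"] == f"rs19_{cfg.block_size // 2:02d}"][0]
    e2_pos = vmap.index[vmap["snp_id"] == "rs19_00"][0]
    return Truth(
        causal_ids=causal_ids,
        true_beta=pd.Series(beta, index=causal_ids),
        major_id=vmap.loc[major_pos, "snp_id"],
        major_beta=float(np.log(cfg.major_locus_or) / _LOGIT_TO_PROBIT),
        e2_id=vmap.loc[e2_pos, "snp_id"],
        e2_beta=float(np.log(0.6) / _LOGIT_TO_PROBIT),
        maf=pd.Series(maf, index=vmap["snp_id"].to_numpy()),
        h2_polygenic=cfg.h2_polygenic,
        true_hr=cfg.hr_high_vs_low,
        endophenotype_slope=cfg.endophenotype_slope,
    )


def _liability(g: GenotypeMatrix, truth: Truth, rng) -> tuple[np.ndarray, np.ndarray]:
    """Liability and the centered true polygenic score (major locus excluded)."""
    ids = list(g.variants["snp_id"])
    lookup = {s: i for i, s in enumerate(ids)}
    x_causal = g.dosage[:, [lookup[s] for s in truth.causal_ids]]
    p = truth.maf[truth.causal_ids].to_numpy()
    g_poly = (x_causal - 2 * p) @ truth.true_beta.to_numpy()
    x_major = g.dosage[:, lookup[truth.major_id]]
    x_e2 = g.dosage[:, lookup[truth.e2_id]]
    p_major = truth.maf[truth.major_id]
    p_e2 = truth.maf[truth.e2_id]
    fixed = (
        truth.major_beta * (x_major - 2 * p_major)
        + truth.e2_beta * (x_e2 - 2 * p_e2)
    )
    var_fixed = (
        truth.major_beta**2 * 2 * p_major * (1 - p_major)
        + truth.e2_beta**2 * 2 * p_e2 * (1 - p_e2)
    )
    resid_var = max(1.0 - truth.h2_polygenic - var_fixed, 0.05)
    liab = g_poly + fixed + rng.standard_normal(len(g_poly)) * np.sqrt(resid_var)
    return liab, g_poly


def _marginal_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 25) -> tuple[float, float]:
    """Newton-fitted single-SNP logistic (intercept + dosage): beta, Wald p."""
    X = np.column_stack([np.ones_like(x), x])
    b = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return 0.0, 1.0
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    se = np.sqrt(np.linalg.inv(hess)[1, 1])
    z = b[1] / se if se > 0 else 0.0
    p = 2 * norm.sf(abs(z))
    return float(b[1]), float(max(p, 5e-324))


def simulate_discovery_gwas(
    cfg: SimConfig, rng: np.random.Generator, vmap: pd.DataFrame,
    maf: np.ndarray, truth: Truth,
) -> SummaryStats:
    """Marginal per-SNP association scan in a simulated discovery sample."""
    g = simulate_genotypes(cfg, cfg.n_discovery, rng, vmap, maf)
    liab, _ = _liability(g, truth, rng)
    cases = liab > np.quantile(liab, 1 - cfg.prevalence)
    y = cases.astype(float)
    betas, pvals = np.empty(g.n_variants), np.empty(g.n_variants)
    for j in range(g.n_variants):
        betas[j], pvals[j] = _marginal_logistic(g.dosage[:, j], y)
    v = g.variants
    return SummaryStats(
        pd.DataFrame(
            {"snp_id": v["snp_id"], "chrom": v["chrom"], "pos": v["pos"],
             "effect_allele": v["a1"], "other_allele": v["a2"],
             "beta": betas, "pvalue": pvals}
        )
    )


def designed_sumstats(
    cfg: SimConfig,
    vmap: pd.DataFrame,
    maf: np.ndarray,
    truth: Truth,
    rng: np.random.Generator,
    causal_p_range: tuple[float, float] = (1.2e-6, 1e-5),
    null_p_range: tuple[float, float] = (2e-4, 1.0),
    null_discovery_n: int = 2000,
) -> SummaryStats:
    """Discovery statistics with a fixed p-value layout.

    Causal SNPs carry their true (logit-scale) effects with p-values
    log-uniform in ``causal_p_range``; every other SNP gets a
    noise-scale beta and a p-value log-uniform in ``null_p_range``.
    Used for threshold-scan experiments where the p_T band occupied by
    the causal set must be known by construction: in a marginal scan the
    weakest causal SNP's realized p is an extreme-value statistic, so
    the band is otherwise not controllable.

    ``null_discovery_n`` sets the sampling-noise scale of the null
    betas.  It is deliberately smaller than a realistic discovery size:
    with only a few hundred desk-scale null SNPs, a larger per-SNP noise
    reproduces the aggregate score-noise dilution that tens of thousands
    of null SNPs exert at permissive thresholds in a full-size scan.
    """
    m = len(vmap)
    p_out = 10 ** rng.uniform(
        np.log10(null_p_range[0]), np.log10(null_p_range[1]), size=m
    )
    prev = cfg.prevalence
    se = 1.0 / np.sqrt(null_discovery_n * 2 * maf * (1 - maf) * prev * (1 - prev))
    beta_out = rng.normal(0.0, se)
    snp_pos = {s: i for i, s in enumerate(vmap["snp_id"])}
    for sid in truth.causal_ids:
        j = snp_pos[sid]
        beta_out[j] = truth.true_beta[sid] * _LOGIT_TO_PROBIT
        p_out[j] = 10 ** rng.uniform(
            np.log10(causal_p_range[0]), np.log10(causal_p_range[1])
        )
    j_major = snp_pos[truth.major_id]
    beta_out[j_major] = truth.major_beta * _LOGIT_TO_PROBIT
    p_out[j_major] = 1e-40
    return SummaryStats(
        pd.DataFrame(
            {"snp_id": vmap["snp_id"], "chrom": vmap["chrom"], "pos": vmap["pos"],
             "effect_allele": vmap["a1"], "other_allele": vmap["a2"],
             "beta": beta_out, "pvalue": np.minimum(p_out, 1.0)}
        )
    )


def reference_ld_table(g: GenotypeMatrix, vmap: pd.DataFrame) -> pd.DataFrame:
    """Pairwise within-block r² from a reference sample (external-LD style)."""
    rows = []
    blocks = vmap["block"].to_numpy()
    d = g.dosage
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        sub = d[:, idx]
        sd = sub.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        c = np.corrcoef(sub[:, ok].T) ** 2
        live = idx[ok]
        for a in range(len(live)):
            for bb in range(a + 1, len(live)):
                rows.append(
                    {"snp_a": g.variants["snp_id"].iloc[live[a]],
                     "snp_b": g.variants["snp_id"].iloc[live[bb]],
                     "r2": float(c[a, bb])}
                )
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def simulate_phenotypes(
    cfg: SimConfig, g: GenotypeMatrix, truth: Truth, rng: np.random.Generator
) -> tuple[PhenoTable, np.ndarray]:
    """Diagnosis by liability rank plus demographics and APOE doses.

    The highest-liability samples become ADD, the next block MCI, the
    rest CU, reproducing the configured group sizes exactly.  Age and
    education are drawn with the observed direction of group differences
    (ADD older, less educated); APOE ε4/ε2 doses are the major-locus and
    ε2-locus genotypes.  Returns the table and the true polygenic score.
    """
    liab, g_poly = _liability(g, truth, rng)
    n_cu, n_mci, n_add = cfg.group_sizes
    order = np.argsort(liab)
    diagnosis = np.empty(len(liab), dtype=object)
    diagnosis[order[:n_cu]] = "CU"
    diagnosis[order[n_cu:n_cu + n_mci]] = "MCI"
    diagnosis[order[n_cu + n_mci:]] = "ADD"

    age_mu = {"CU": 67.8, "MCI": 72.8, "ADD": 73.8}
    age_sd = {"CU": 5.7, "MCI": 5.9, "ADD": 6.6}
    edu_mu = {"CU": 13.8, "MCI": 13.0, "ADD": 12.5}
    age = np.array([rng.normal(age_mu[d], age_sd[d]) for d in diagnosis])
    education = np.array([max(6.0, rng.normal(edu_mu[d], 2.8)) for d in diagnosis])
    sex = rng.choice(["M", "F"], size=len(liab))

    lookup = {s: i for i, s in enumerate(g.variants["snp_id"])}
    e4 = g.dosage[:, lookup[truth.major_id]].astype(int)
    e2 = g.dosage[:, lookup[truth.e2_id]].astype(int)
    table = pd.DataFrame(
        {"sample_id": g.samples, "diagnosis": diagnosis, "age": np.round(age, 1),
         "sex": sex, "education": np.round(education, 1),
         "apoe_e4_dose": e4, "apoe_e2_dose": e2}
    )
    return PhenoTable(table), g_poly


def simulate_conversion(
    cfg: SimConfig, pheno: PhenoTable, prs_group: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Censored MCI→AD conversion times.

    Exponential event times; the hazard is multiplied by
    ``hr_high_vs_low`` for the high-PRS group (within ε4 noncarriers
    only when ``hr_noncarriers_only``).  Drop-out is exponential,
    administrative censoring at ``censor_months``; observed times are
    rounded up to the visit grid when ``visit_months`` is set.
    """
    t = pheno.table
    mci = t[t["diagnosis"] == "MCI"]
    if mci.empty:
        raise ValueError("no MCI participants to follow")
    base_rate = -np.log(1 - cfg.baseline_36m_conversion) / cfg.censor_months
    group = prs_group.reindex(mci["sample_id"]).fillna("mid").to_numpy()
    boosted = group == "high"
    if cfg.hr_noncarriers_only:
        boosted &= mci["apoe_e4_dose"].to_numpy() == 0
    rate = base_rate * np.where(boosted, cfg.hr_high_vs_low, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_drop = (
        rng.exponential(1.0 / cfg.dropout_rate, size=len(rate))
        if cfg.dropout_rate > 0 else np.full(len(rate), np.inf)
    )
    t_cens = np.minimum(t_drop, cfg.censor_months)
    observed = np.minimum(t_event, t_cens)
    converted = (t_event <= t_cens).astype(int)
    if cfg.visit_months:
        observed = np.ceil(observed / cfg.visit_months) * cfg.visit_months
        observed = np.clip(observed, cfg.visit_months, cfg.censor_months)
    return pd.DataFrame(
        {"sample_id": mci["sample_id"].to_numpy(),
         "followup_months": observed, "converted": converted}
    )


def simulate_endophenotypes(
    cfg: SimConfig, pheno: PhenoTable, true_prs: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """CSF tau/Aβ42-ratio-like outcomes linear in the true PRS.

    The slope applies only within the MCI stratum by default (plateau in
    CU/ADD); both outcomes share the slope but have independent noise.
    """
    t = pheno.table
    sd = true_prs.std(ddof=1)
    z = (true_prs - true_prs.mean()) / sd if sd > 0 else np.zeros_like(true_prs)
    in_scope = (
        (t["diagnosis"] == "MCI").to_numpy()
        if cfg.endophenotype_mci_only else np.ones(len(t), bool)
    )
    slope_term = np.where(in_scope, cfg.endophenotype_slope * z, 0.0)
    base = 0.01 * (t["age"].to_numpy() - 72.0) + 0.2 * t["apoe_e4_dose"].to_numpy()
    out = {}
    for name in ("csf_ttau_ab42", "csf_ptau_ab42"):
        out[name] = slope_term + base + rng.standard_normal(len(t))
    return pd.DataFrame({"sample_id": t["sample_id"].to_numpy(), **out})


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    sumstats: SummaryStats
    pheno: PhenoTable
    ld_table: pd.DataFrame
    truth: Truth
    true_prs: np.ndarray


def simulate_cohort(cfg: SimConfig | None = None) -> SimulatedCohort:
    """Generate a complete synthetic study: target genotypes, discovery
    summary statistics, reference LD table, phenotypes with conversion
    records and endophenotypes, and the ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    vmap = _variant_map(cfg)
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=len(vmap))
    # APOE-like haplotype frequencies: ε4-tagging ~0.15, ε2-tagging ~0.05
    maf[vmap.index[vmap["snp_id"] == f"rs19_{cfg.block_size // 2:02d}"][0]] = 0.15
    maf[vmap.index[vmap["snp_id"] == "rs19_00"][0]] = 0.05
    truth = _draw_effects(cfg, vmap, maf, rng)

    sumstats = simulate_discovery_gwas(cfg, rng, vmap, maf, truth)
    g_ref = simulate_genotypes(cfg, 2000, rng, vmap, maf)
    ld_table = reference_ld_table(g_ref, vmap)

    g = simulate_genotypes(cfg, cfg.n_target, rng, vmap, maf)
    pheno, g_poly = simulate_phenotypes(cfg, g, truth, rng)

    comps = ancestry_components(g, 2)
    table = pheno.table.copy()
    table["pc1"], table["pc2"] = comps[:, 0], comps[:, 1]

    # PRS tertiles on the true polygenic score drive the conversion design
    z = pd.Series(g_poly, index=pd.Index(g.samples, name="sample_id"))
    q1, q2 = z.quantile([1 / 3, 2 / 3])
    group = pd.Series(
        np.where(z <= q1, "low", np.where(z <= q2, "mid", "high")), index=z.index
    )
    conv = simulate_conversion(cfg, pheno, group, rng)
    table = table.merge(conv, on="sample_id", how="left")
    endo = simulate_endophenotypes(cfg, pheno, g_poly, rng)
    table = table.merge(endo, on="sample_id", how="left")
    return SimulatedCohort(g, sumstats, PhenoTable(table), ld_table, truth, g_poly)
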