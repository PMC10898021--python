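"""Genotype, summary-statistic and phenotype containers plus file I/O.

Canonical in-memory representations:

* :class:`GenotypeMatrix` — samples × variants minor-allele dosage matrix
  (float array, ``NaN`` for missing) with per-variant metadata.  The
  ``a1`` column of the variant table is the *counted* allele: a dosage of
  2 means two copies of ``a1``.
* :class:`SummaryStats` — per-SNP discovery effect sizes (log-odds
  ``beta``) and p-values used as PRS weights.
* :class:`PhenoTable` — per-sample diagnosis, covariates, APOE allele
  doses and optional endophenotype / follow-up columns.

PLINK .bed files are parsed directly (SNP-major v1.1 layout, the de facto
standard): two bits per genotype, ``00`` = hom A1, ``01`` = missing,
``10`` = het, ``11`` = hom A2, samples packed low-order bits first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from prspipe.errors import ConfigurationError, EmptyIntersectionError, FormatError

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: columns every variant table carries, in order
VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]

#: complementary bases, used to detect strand-ambiguous SNPs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DIAGNOSIS_LEVELS = ("CU", "MCI", "ADD")


@dataclass(frozen=True)
class VariantMeta:
    """Identity of one biallelic variant; ``effect_allele`` is the counted one."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")


class GenotypeMatrix:
    """Samples × variants dosage matrix in {0, 1, 2, NaN}.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``dosage``.
    variants
        DataFrame with columns ``snp_id, chrom, pos, a1, a2``; ``a1`` is
        the allele the dosage counts.
    dosage
        ``(n_samples, n_variants)`` float array; missing genotypes are NaN.
    """

    def __init__(self, samples: Sequence[str], variants: pd.DataFrame, dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2 or dosage.shape != (len(samples), len(variants)):
            raise FormatError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        finite = dosage[~np.isnan(dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise FormatError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise FormatError(f"variant table lacks columns {missing}")
        if variants["snp_id"].duplicated().any():
            dup = variants.loc[variants["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id {dup!r} in variant table")
        self.samples = list(samples)
        self.variants = variants[VARIANT_COLUMNS].reset_index(drop=True).assign(
            chrom=lambda d: d["chrom"].astype(str), pos=lambda d: d["pos"].astype(int)
        )
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            self.variants.iloc[vi].reset_index(drop=True),
            self.dosage[np.ix_(si, vi)],
        )

    def variant_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Positional indices of ``snp_ids`` in this matrix (order preserved)."""
        lookup = pd.Series(np.arange(self.n_variants), index=self.variants["snp_id"])
        try:
            return lookup.loc[list(snp_ids)].to_numpy()
        except KeyError as exc:
            raise KeyError(f"snp_ids absent from genotype matrix: {exc}") from exc


@dataclass
class SummaryStats:
    """GWAS summary statistics: one row per SNP with beta and p-value.

    ``table`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    beta, pvalue.  ``n_dropped`` counts input rows discarded during
    parsing (non-numeric beta/p or p outside (0, 1]).
    """

    table: pd.DataFrame
    n_dropped: int = 0

    REQUIRED = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "pvalue"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary statistics lack columns {missing}")
        t = self.table
        if len(t):
            if not np.isfinite(t["beta"].to_numpy(dtype=float)).all():
                raise FormatError("non-finite beta in summary statistics")
            p = t["pvalue"].to_numpy(dtype=float)
            if ((p <= 0) | (p > 1)).any():
                raise FormatError("p-values must lie in (0, 1]")
        self.table = t.reset_index(drop=True).assign(
            chrom=lambda d: d["chrom"].astype(str), pos=lambda d: d["pos"].astype(int)
        )

    def __len__(self) -> int:
        return len(self.table)

    def subset_ids(self, snp_ids: Sequence[str]) -> "SummaryStats":
        keep = self.table["snp_id"].isin(set(snp_ids))
        return SummaryStats(self.table.loc[keep].reset_index(drop=True), self.n_dropped)


@dataclass
class PhenoTable:
    """Per-sample phenotypes and covariates.

    Required columns: ``sample_id`` and ``diagnosis`` (CU/MCI/ADD, or
    control/case which are mapped onto CU/ADD).  Recognised optional
    columns: age, sex (M/F), education, apoe_e4_dose, apoe_e2_dose,
    followup_months, converted, plus arbitrary endophenotype columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("sample_id", "diagnosis"):
            if col not in t.columns:
                raise FormatError(f"phenotype table lacks required column {col!r}")
        t["diagnosis"] = (
            t["diagnosis"].astype(str).replace({"control": "CU", "case": "ADD"})
        )
        bad = set(t["diagnosis"]) - set(DIAGNOSIS_LEVELS)
        if bad:
            raise FormatError(f"unknown diagnosis levels: {sorted(bad)}")
        for col in ("apoe_e4_dose", "apoe_e2_dose"):
            if col in t.columns and not t[col].isin((0, 1, 2)).all():
                raise FormatError(f"{col} outside {{0,1,2}}")
        if "followup_months" in t.columns and (t["followup_months"].dropna() < 0).any():
            raise FormatError("negative follow-up time")
        if "converted" in t.columns and not t["converted"].dropna().isin((0, 1)).all():
            raise FormatError("conversion flag must be 0/1")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def case_control(self, case: str = "ADD", control: str = "CU") -> pd.DataFrame:
        """CU/ADD rows with a 0/1 ``y`` column (case=1)."""
        t = self.table[self.table["diagnosis"].isin((case, control))].copy()
        t["y"] = (t["diagnosis"] == case).astype(int)
        return t.reset_index(drop=True)

    def is_control(self) -> pd.Series:
        return self.table["diagnosis"] == "CU"


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def _bed_lut() -> np.ndarray:
    """256 × 4 lookup: byte value → four dosages (NaN = missing)."""
    code_to_dosage = {0: 2.0, 1: np.nan, 2: 1.0, 3: 0.0}
    lut = np.empty((256, 4))
    for byte in range(256):
        for k in range(4):
            lut[byte, k] = code_to_dosage[(byte >> (2 * k)) & 0b11]
    return lut


_LUT = _bed_lut()
_DOSAGE_TO_CODE = {2.0: 0, 1.0: 2, 0.0: 3}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 ``prefix.bed/.bim/.fam`` fileset.

    Dosage counts the .bim A1 allele; missing genotypes become NaN.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1 bed)")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise FormatError(
            f"{prefix}.bed: payload is {len(raw) - 3} bytes, expected "
            f"{bytes_per_variant} x {m} = {expected - 3} for {n} samples"
        )
    if n == 0 or m == 0:
        dosage = np.empty((n, m))
    else:
        payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
        dosage = _LUT[payload].reshape(m, -1)[:, :n].T
    variants = bim[["snp_id", "chrom", "pos", "a1", "a2"]]
    return GenotypeMatrix(fam["iid"].tolist(), variants, dosage)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as a PLINK 1 bed/bim/fam fileset (SNP-major v1.1)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = g.variants
    bim = pd.DataFrame(
        {"chrom": v["chrom"], "snp_id": v["snp_id"], "cm": 0, "pos": v["pos"],
         "a1": v["a1"], "a2": v["a2"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": g.samples, "iid": g.samples, "pid": 0, "mid": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = g.n_samples, g.n_variants
    bytes_per_variant = (n + 3) // 4
    codes = np.full((m, bytes_per_variant * 4), 1, dtype=np.uint8)  # pad = missing code
    if n and m:
        d = g.dosage.T  # (m, n)
        c = np.full(d.shape, 1, dtype=np.uint8)
        for dos, code in _DOSAGE_TO_CODE.items():
            c[d == dos] = code
        codes[:, :n] = c
    codes[:, n:] = 0  # PLINK pads with zero bits
    packed = (
        codes[:, 0::4] | (codes[:, 1::4] << 2) | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF; dosage counts the ALT allele."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        gt = rec.gt_types.astype(float)  # 0/1/2 ALT copies, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(
            {"snp_id": rec.ID or f"{rec.CHROM}:{rec.POS}", "chrom": str(rec.CHROM),
             "pos": rec.POS, "a1": rec.ALT[0], "a2": rec.REF}
        )
        dosages.append(gt)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.array(dosages).T if dosages else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dosage)


# ---------------------------------------------------------------------------
# summary statistics


def read_sumstats(path: str | Path, column_map: Mapping[str, str] | None = None) -> SummaryStats:
    """Read a delimited GWAS summary-statistics file.

    ``column_map`` maps canonical names (``snp_id, chrom, pos,
    effect_allele, other_allele, beta, pvalue``) to the file's header
    names; canonical names present in the header need no entry.  Rows
    with non-numeric beta/p-value or p outside (0, 1] are dropped and
    counted in ``n_dropped``.  Alleles are upper-cased.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for canonical in SummaryStats.REQUIRED:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            raise ConfigurationError(
                f"column {source!r} (for {canonical!r}) absent from {path}; "
                f"header is {list(raw.columns)}"
            )
        rename[source] = canonical
    t = raw.rename(columns=rename)[SummaryStats.REQUIRED].copy()
    n_in = len(t)
    t["beta"] = pd.to_numeric(t["beta"], errors="coerce")
    t["pvalue"] = pd.to_numeric(t["pvalue"], errors="coerce")
    ok = (
        np.isfinite(t["beta"]) & np.isfinite(t["pvalue"])
        & (t["pvalue"] > 0) & (t["pvalue"] <= 1)
    )
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.warning("read_sumstats: dropped %d/%d rows with invalid beta/p", dropped, n_in)
    t = t.loc[ok].copy()
    for col in ("effect_allele", "other_allele"):
        t[col] = t[col].astype(str).str.upper()
    return SummaryStats(t.reset_index(drop=True), n_dropped=dropped)


def is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    """True for strand-ambiguous A/T and C/G SNPs."""
    return a2 == a1.map(_COMPLEMENT)


def harmonize(
    genotypes: GenotypeMatrix, stats: SummaryStats
) -> tuple[GenotypeMatrix, SummaryStats]:
    """Align a genotype matrix with summary statistics on SNP id and allele.

    SNPs are intersected on ``snp_id``; strand-ambiguous (A/T, C/G) SNPs
    and SNPs whose allele pairs do not match in either orientation are
    removed.  Where the genotype-counted allele is the stats *other*
    allele, the dosage is flipped (x → 2−x) so that it counts the effect
    allele — the weights themselves are never modified.  Outputs are
    sorted by genome position and carry identical SNP order.
    """
    if genotypes.n_variants == 0 or len(stats) == 0:
        raise EmptyIntersectionError("harmonize requires non-empty inputs")
    gv = genotypes.variants.copy()
    gv["gidx"] = np.arange(len(gv))
    merged = gv.merge(
        stats.table[["snp_id", "effect_allele", "other_allele", "beta", "pvalue"]],
        on="snp_id", how="inner",
    )
    if merged.empty:
        raise EmptyIntersectionError("no overlapping SNP ids between genotypes and stats")

    pal = is_palindromic(merged["a1"], merged["a2"])
    n_pal = int(pal.sum())
    if n_pal:
        logger.info("harmonize: removed %d strand-ambiguous (A/T, C/G) SNPs", n_pal)
    merged = merged.loc[~pal]

    same = (merged["a1"] == merged["effect_allele"]) & (merged["a2"] == merged["other_allele"])
    swapped = (merged["a1"] == merged["other_allele"]) & (merged["a2"] == merged["effect_allele"])
    mismatch = ~(same | swapped)
    if mismatch.any():
        logger.info("harmonize: removed %d allele-mismatched SNPs", int(mismatch.sum()))
        merged = merged.loc[same | swapped]
        swapped = swapped.loc[merged.index]
    if merged.empty:
        raise EmptyIntersectionError("no SNPs with consistent alleles after harmonization")

    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    swap_mask = (merged["a1"] == merged["other_allele"]).to_numpy()
    dosage = genotypes.dosage[:, merged["gidx"].to_numpy()].copy()
    dosage[:, swap_mask] = 2.0 - dosage[:, swap_mask]
    variants = pd.DataFrame(
        {"snp_id": merged["snp_id"], "chrom": merged["chrom"], "pos": merged["pos"],
         "a1": merged["effect_allele"], "a2": merged["other_allele"]}
    )
    g_out = GenotypeMatrix(genotypes.samples, variants, dosage)
    s_out = SummaryStats(
        pd.DataFrame(
            {"snp_id": merged["snp_id"], "chrom": merged["chrom"], "pos": merged["pos"],
             "effect_allele": merged["effect_allele"], "other_allele": merged["other_allele"],
             "beta": merged["beta"], "pvalue": merged["pvalue"]}
        ),
        stats.n_dropped,
    )
    return g_out, s_out
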