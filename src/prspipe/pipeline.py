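"""Config-driven end-to-end run: qc → score → eval → endo → survive.

Every stage writes TSV outputs into the run directory and registers them
in a JSON manifest carrying the seed, package version and a SHA-256 hash
per artifact, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import prspipe
from prspipe import io_genotype as iog
from prspipe import model_eval, prs, qc, survival
from prspipe import endo as endo_mod
from prspipe.errors import ConfigurationError, DegenerateDataError, PrsPipeError
from prspipe.simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

ENDO_OUTCOMES = ("csf_ttau_ab42", "csf_ptau_ab42")


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-loadable)."""

    out_dir: str = "prspipe_run"
    bfile: str | None = None
    sumstats: str | None = None
    pheno: str | None = None
    ld_table: str | None = None
    simulate: bool = True
    seed: int = 0
    grid: tuple[float, ...] = prs.THRESHOLD_GRID
    clump_window_kb: int = 250
    clump_r2_max: float = 0.1
    apoe_chrom: str = prs.APOE_CHROM
    apoe_center: int = prs.APOE_CENTER_BP
    apoe_flank: int = prs.APOE_FLANK_BP
    adjld_r2_cut: float = 0.5
    n_components: int = 2
    cv_folds: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("bfile", "sumstats", "pheno"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigurationError(f"{name} is required when simulate is off")
                probe = Path(f"{value}.bed") if name == "bfile" else Path(value)
                if not probe.exists():
                    raise ConfigurationError(f"{name} path {probe} does not exist")


class Manifest:
    """Artifact registry written as JSON at the end of a run."""

    def __init__(self, out_dir: Path, seed: int):
        self.out_dir = out_dir
        self.data = {"seed": seed, "version": prspipe.__version__, "artifacts": {}}

    def register(self, stage: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["artifacts"][path.name] = {"stage": stage, "sha256": digest}

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


def _write_tsv(df: pd.DataFrame, path: Path, manifest: Manifest, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.register(stage, path)


def _load_inputs(config: RunConfig, out_dir: Path):
    if config.simulate:
        cohort = simulate_cohort(SimConfig(seed=config.seed))
        return cohort.genotypes, cohort.sumstats, cohort.pheno, cohort.ld_table
    g = iog.read_plink(config.bfile)
    stats = iog.read_sumstats(config.sumstats)
    pheno = iog.PhenoTable(pd.read_csv(config.pheno, sep="\t"))
    ld = pd.read_csv(config.ld_table, sep="\t") if config.ld_table else None
    return g, stats, pheno, ld


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out_dir, config.seed)

    g, stats, pheno, ld_table = _load_inputs(config, out_dir)

    # ---- qc ----------------------------------------------------------
    g, marker_report = qc.marker_qc(g, pheno)
    g, sample_report = qc.sample_qc(g)
    pheno_t = pheno.table[pheno.table["sample_id"].isin(g.samples)].reset_index(drop=True)
    pheno = iog.PhenoTable(pheno_t)
    _write_tsv(
        pd.concat([marker_report.to_frame().assign(kind="marker"),
                   sample_report.to_frame().assign(kind="sample")]),
        out_dir / "qc_report.tsv", manifest, "qc",
    )

    # ---- score -------------------------------------------------------
    g, stats = iog.harmonize(g, stats)
    params = prs.ClumpParams(window_kb=config.clump_window_kb, r2_max=config.clump_r2_max)
    clumped = prs.clump(stats, g, params)
    region = prs.ExclusionRegion(config.apoe_chrom, config.apoe_center, config.apoe_flank)
    stats_no = prs.exclude_region(stats, region)
    no_ids = [s for s in clumped if s in set(stats_no.table["snp_id"])]
    adj_ids = prs.adjust_ld(no_ids, stats, ld_table=ld_table, g=g, r2_cut=config.adjld_r2_cut)

    score_rows = []
    profiles: dict[str, dict[float, prs.PRSProfile]] = {"incAPOE": {}, "noAPOE": {}, "adjLD": {}}
    scores_by_pt: dict[str, dict[float, pd.Series]] = {"incAPOE": {}, "noAPOE": {}, "adjLD": {}}
    nsnps_by_pt: dict[str, dict[float, int]] = {"incAPOE": {}, "noAPOE": {}, "adjLD": {}}
    for flag, ids in (("incAPOE", clumped), ("noAPOE", no_ids), ("adjLD", adj_ids)):
        for pt in config.grid:
            try:
                profile = prs.compute_prs(g, stats, ids, pt, variant_flag=flag)
            except DegenerateDataError:
                continue
            profiles[flag][pt] = profile
            scores_by_pt[flag][pt] = profile.scores
            nsnps_by_pt[flag][pt] = profile.m
            score_rows.append(
                pd.DataFrame(
                    {"sample_id": profile.scores.index, "score": profile.scores.to_numpy(),
                     "p_threshold": pt, "m": profile.m, "variant_flag": flag}
                )
            )
    _write_tsv(pd.concat(score_rows), out_dir / "scores.tsv", manifest, "score")
    retained = pd.DataFrame(
        [{"variant_flag": f, "snp_id": s} for f, ids in
         (("incAPOE", clumped), ("noAPOE", no_ids), ("adjLD", adj_ids)) for s in ids]
    )
    _write_tsv(retained, out_dir / "retained_snps.tsv", manifest, "score")

    # ---- eval --------------------------------------------------------
    comps = qc.ancestry_components(g, config.n_components)
    comp_df = pd.DataFrame(
        comps, columns=[f"pc{i+1}" for i in range(config.n_components)],
        index=pd.Index(g.samples, name="sample_id"),
    )
    cc = pheno.case_control()
    cc_ids = cc["sample_id"]
    grids = []
    best_pt = {}
    for flag in ("incAPOE", "noAPOE", "adjLD"):
        by_pt = {pt: s.loc[cc_ids] for pt, s in scores_by_pt[flag].items()}
        table, best = model_eval.select_threshold(
            config.grid, by_pt, cc["y"], comp_df.loc[cc_ids, ["pc1", "pc2"]].reset_index(drop=True),
            n_snps_by_pt=nsnps_by_pt[flag],
        )
        grids.append(table.assign(variant_flag=flag))
        best_pt[flag] = best
    _write_tsv(pd.concat(grids), out_dir / "threshold_grid.tsv", manifest, "eval")

    # standardized best-threshold scores for downstream stages
    std_scores = {
        flag: prs.standardize(profiles[flag][best_pt[flag]]).scores
        for flag in ("noAPOE", "adjLD")
    }

    auc_rows = []
    covar = pheno_t.set_index("sample_id")
    e4 = covar.loc[cc_ids, "apoe_e4_dose"].to_numpy(dtype=float)
    e2 = covar.loc[cc_ids, "apoe_e2_dose"].to_numpy(dtype=float)
    y = cc["y"].to_numpy()
    model_designs = {
        "APOE_e4": pd.DataFrame({"e4": e4}),
        "APOE_e4_e2": pd.DataFrame({"e4": e4, "e2": e2}),
        "PRS.noAPOE": pd.DataFrame({"prs": std_scores["noAPOE"].loc[cc_ids].to_numpy()}),
        "PRS.adjLD": pd.DataFrame({"prs": std_scores["adjLD"].loc[cc_ids].to_numpy()}),
        "PRS.noAPOE+APOE": pd.DataFrame(
            {"prs": std_scores["noAPOE"].loc[cc_ids].to_numpy(), "e4": e4, "e2": e2}
        ),
        "PRS.adjLD+APOE": pd.DataFrame(
            {"prs": std_scores["adjLD"].loc[cc_ids].to_numpy(), "e4": e4, "e2": e2}
        ),
    }
    for name, X in model_designs.items():
        fit = model_eval.fit_logistic(y, X)
        roc = model_eval.roc_auc_delong(fit.predict_linear(model_eval._design(X)), y)
        cv = model_eval.kfold_cv(y, X, k=config.cv_folds, seed=config.seed)
        auc_rows.append(
            {"model": name, "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
             "cv_mean_auc": cv["mean_auc"], "cv_sd_auc": cv["sd_auc"]}
        )
    _write_tsv(pd.DataFrame(auc_rows), out_dir / "model_auc.tsv", manifest, "eval")

    tukey = model_eval.tukey_hsd(
        std_scores["noAPOE"].loc[pheno_t["sample_id"]].to_numpy(),
        pheno_t["diagnosis"].to_numpy(),
    )
    _write_tsv(tukey, out_dir / "group_comparison.tsv", manifest, "eval")

    # ---- endo --------------------------------------------------------
    pheno_full = pheno_t.drop(
        columns=[c for c in comp_df.columns if c in pheno_t.columns]
    ).merge(comp_df.reset_index(), on="sample_id")
    outcomes = [c for c in ENDO_OUTCOMES if c in pheno_full.columns]
    if outcomes:
        assoc = endo_mod.associate(
            pheno_full, std_scores["noAPOE"], outcomes,
        )
        _write_tsv(assoc, out_dir / "endophenotype_assoc.tsv", manifest, "endo")

    # ---- survive -----------------------------------------------------
    if "followup_months" in pheno_full.columns:
        groups = survival.tertile_groups(
            std_scores["noAPOE"], pheno_full["sample_id"]
        )
        records = survival.prepare_records(pheno_full, groups)
        surv_rows = []
        try:
            fit = survival.cox_fit(records)
            surv_rows.append(fit.summary.assign(stratum="all_mci").reset_index())
        except (DegenerateDataError, PrsPipeError) as exc:
            logger.warning("all-MCI Cox fit failed: %s", exc)
        try:
            strat = survival.stratified_conversion(records)
            for name, entry in strat.items():
                if entry.get("cox") is not None:
                    surv_rows.append(entry["cox"].summary.assign(stratum=name).reset_index())
        except PrsPipeError as exc:
            logger.warning("stratified conversion skipped: %s", exc)
        if surv_rows:
            _write_tsv(pd.concat(surv_rows), out_dir / "conversion_cox.tsv", manifest, "survive")
        hl = records[records["prs_group"].isin(["low", "high"])]
        km_rows = []
        for label, sub in hl.groupby("prs_group"):
            km = survival.km_curve(sub["followup_months"], sub["converted"])
            km_rows.append(km.assign(prs_group=label))
        _write_tsv(pd.concat(km_rows), out_dir / "km_curves.tsv", manifest, "survive")

    path = manifest.write()
    logger.info("pipeline complete: %s", path)
    return manifest.data
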