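"""End-to-end pipeline driver.

Chains the stages in study order — simulate (optional) -> probe weights
-> abundance -> sample QC -> derived phenotypes -> associations /
two-lines -> PheWAS -> variant scan — writing every stage product as
TSV plus a manifest (stage, file, rows, sha256).  Each stage is also
exposed on the command line and re-runnable from the intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, assoc, gwaslite, phenotypes, phewas, sampleqc, synthio
from .io import write_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

ALL_STAGES = ("weights", "abundance", "qc", "pheno", "assoc", "twolines", "phewas", "gwas")


class PipelineError(RuntimeError):
    """Raised with the failing stage named."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES
    weight_alpha: float = 0.05
    qc: sampleqc.QCThresholds = field(default_factory=sampleqc.QCThresholds)
    min_cases: int = 251
    variant_filters: gwaslite.VariantFilters = field(default_factory=gwaslite.VariantFilters)
    abundance_method: str = "weighted"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = raw.get("thresholds", {})
        qc_kwargs = {
            k: thresholds[k]
            for k in ("sdl2r_max", "sdl2r_mode", "baf_concordance_max", "call_rate_min")
            if k in thresholds
        }
        vf_kwargs = {
            k: thresholds[k]
            for k in ("maf_min", "missingness_max", "imputation_r2_min", "hwe_p_min")
            if k in thresholds
        }
        cfg = cls(
            out_dir=Path(raw.get("out_dir", "mitoabund_out")),
            seed=int(raw.get("seed", 0)),
            simulate=bool(raw.get("simulate", {}).get("enabled", True)),
            sim_overrides={
                k: v for k, v in raw.get("simulate", {}).items() if k != "enabled"
            },
            inputs=raw.get("inputs", {}),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            weight_alpha=float(thresholds.get("alpha", 0.05)),
            qc=sampleqc.QCThresholds(**qc_kwargs),
            min_cases=int(thresholds.get("min_cases", 251)),
            variant_filters=gwaslite.VariantFilters(**vf_kwargs),
            abundance_method=raw.get("abundance_method", "weighted"),
        )
        for stage in cfg.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}; valid: {ALL_STAGES}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the configured stages; return the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def emit(stage: str, name: str, df: pd.DataFrame):
        path = write_table(df, out / f"{name}.tsv")
        manifest.append(
            {"stage": stage, "file": path.name, "rows": len(df), "sha256": _sha256(path)}
        )

    # ---- inputs -----------------------------------------------------
    if config.simulate:
        sim_cfg = synthio.SimulationConfig(seed=config.seed, **config.sim_overrides)
        cohort = synthio.simulate_cohort(sim_cfg)
        intensity = cohort.intensity
        coverage = cohort.coverage
        pheno = cohort.phenotypes
        events = cohort.events
        dosages, variants = cohort.dosages, cohort.variants
        phemap = phewas.PhecodeMap(synthio.default_phecode_map())
        for name, df in cohort.tables.items():
            if name == "dosages":
                df = df.reset_index()
            emit("simulate", name, df)
    else:
        from .io import (
            COVERAGE_SCHEMA, EVENTS_SCHEMA, INTENSITY_SCHEMA,
            PHECODE_MAP_SCHEMA, PHENOTYPE_SCHEMA, read_table, read_vcf_dosages,
        )

        intensity = read_table(config.inputs["intensity"], INTENSITY_SCHEMA)
        intensity["l2r"] = intensity["l2r"].astype(float)
        coverage = read_table(config.inputs["coverage"], COVERAGE_SCHEMA)
        pheno = read_table(config.inputs["phenotypes"], PHENOTYPE_SCHEMA)
        events = (
            read_table(config.inputs["events"], EVENTS_SCHEMA)
            if "events" in config.inputs
            else pd.DataFrame(columns=["sample_id", "code", "event_date"])
        )
        phemap = (
            phewas.PhecodeMap(read_table(config.inputs["phecode_map"], PHECODE_MAP_SCHEMA))
            if "phecode_map" in config.inputs
            else None
        )
        if "dosages_vcf" in config.inputs:
            dosages, variants = read_vcf_dosages(config.inputs["dosages_vcf"])
            variants["imputation_r2"] = 1.0
        else:
            dosages = variants = None
    pheno = pheno.copy()

    # ---- weights + abundance ---------------------------------------
    weights = None
    if "weights" in config.stages:
        try:
            weights = abundance.fit_probe_weights(intensity, coverage, alpha=config.weight_alpha)
        except ValueError as err:
            raise PipelineError("weights", str(err)) from err
        emit("weights", "probe_weights", weights.table)

    abund = None
    if "abundance" in config.stages:
        if config.abundance_method == "weighted" and weights is None:
            raise PipelineError("abundance", "weighted abundance needs the weights stage")
        try:
            abund = abundance.abundance_table(
                intensity, weights, pheno[["sample_id", "plate_id"]],
                method=config.abundance_method,
            )
        except ValueError as err:
            raise PipelineError("abundance", str(err)) from err
        emit("abundance", "abundance", abund)

    # ---- sample QC --------------------------------------------------
    retained_ids = pheno["sample_id"]
    if "qc" in config.stages:
        sdl2r = sampleqc.compute_sdl2r(intensity)
        metrics = pd.DataFrame(
            {
                "sample_id": pheno["sample_id"],
                "call_rate": pheno["call_rate"].astype(float)
                if "call_rate" in pheno
                else 1.0,
                "sdl2r": sdl2r.reindex(pheno["sample_id"]).to_numpy(),
            }
        )
        if "baf_concordance" in pheno.columns:
            metrics["baf_concordance"] = pheno["baf_concordance"].astype(float)
        else:
            logger.info("no BAF phase data supplied; concordance check inactive (set to 0.5)")
            metrics["baf_concordance"] = 0.5
        report = sampleqc.apply_exclusions(metrics, config.qc)
        emit("qc", "sample_qc", report)
        retained_ids = report.loc[~report["excluded"], "sample_id"]
        if retained_ids.empty:
            raise PipelineError("qc", "all samples excluded by QC; nothing to analyse downstream")

    analysis = pheno[pheno["sample_id"].isin(retained_ids)].copy()
    if abund is not None:
        analysis = analysis.merge(
            abund[["sample_id", "ml2rmt", "ml2rauto"]], on="sample_id", how="left"
        )
        analysis = analysis[analysis["ml2rmt"].notna()]

    # ---- derived phenotypes ----------------------------------------
    tert_labels = None
    if "pheno" in config.stages:
        fi_cols = sorted(c for c in analysis.columns if c.startswith("fi_item_"))
        if fi_cols:
            analysis["frailty_index"] = phenotypes.frailty_index(
                analysis[fi_cols].to_numpy(), n_items=len(fi_cols),
                min_answered=int(np.ceil(0.8 * len(fi_cols))),
            )
        if "ml2rmt" in analysis.columns:
            try:
                spec, tert_labels = phenotypes.tertile_discretize(analysis["ml2rmt"])
            except ValueError as err:
                raise PipelineError("pheno", str(err)) from err
            tert_labels.index = analysis.index
            analysis["ml2rmt_tertile"] = tert_labels
            logger.info("tertile cutoffs: %.4f / %.4f", spec.lower_cutoff, spec.upper_cutoff)
        emit("pheno", "analysis_phenotypes", analysis)

    covars = [c for c in ("age", "sex", "pc1", "pc2", "call_rate", "batch_id") if c in analysis.columns]

    # ---- associations ----------------------------------------------
    if "assoc" in config.stages:
        if "ml2rmt" not in analysis.columns:
            raise PipelineError("assoc", "association stage needs the abundance stage")
        exposures = [
            c for c in ("age", "bmi", "packyears", "frailty_index", "wbc", "neut_pct",
                        "lymph_pct", "platelet", "survival_time")
            if c in analysis.columns
        ]
        results = []
        for expo in exposures:
            adj = [c for c in covars if c != expo]
            try:
                results += assoc.linear_association(
                    analysis, "ml2rmt", expo, covariates=adj, strata="sex"
                )
            except ValueError as err:
                raise PipelineError("assoc", str(err)) from err
        emit("assoc", "associations", assoc.results_table(results))

    if "twolines" in config.stages:
        if "ml2rmt" not in analysis.columns:
            raise PipelineError("twolines", "two-lines stage needs the abundance stage")
        women = analysis[analysis["sex"] == "F"]
        try:
            tl = assoc.two_lines_test(women["age"], women["ml2rmt"])
        except ValueError as err:
            raise PipelineError("twolines", str(err)) from err
        emit("twolines", "two_lines", pd.DataFrame([dataclasses.asdict(tl)]))

    # ---- PheWAS -----------------------------------------------------
    if "phewas" in config.stages and phemap is not None and tert_labels is not None:
        baseline = analysis.set_index("sample_id")["baseline_date"]
        assignments = {}
        for code in phemap.phecodes:
            assignments[code] = phewas.build_case_control(events, phemap, baseline, code)
        tert = analysis.set_index("sample_id")["ml2rmt_tertile"]
        cov_cols = [
            c for c in ("age", "batch_id", "ml2rauto", "neut_pct", "lymph_pct", "wbc",
                        "sex", "bmi", "packyears", "pc1", "pc2")
            if c in analysis.columns
        ]
        cov = analysis.set_index("sample_id")[cov_cols] if cov_cols else None
        res = phewas.run_phewas(tert, assignments, covariates=cov, min_cases=config.min_cases)
        emit("phewas", "phewas_results", res)

    # ---- variant scan ----------------------------------------------
    if "gwas" in config.stages and dosages is not None:
        dos = dosages.loc[dosages.index.isin(analysis["sample_id"])]
        metrics = gwaslite.variant_metrics(dos).merge(
            variants[["variant_id", "chrom", "pos", "imputation_r2"]], on="variant_id"
        )
        retained, report = gwaslite.filter_variants(metrics, config.variant_filters)
        logger.info("variant filters: %s", report)
        if retained.empty:
            raise PipelineError("gwas", "no variant passed the QC filters")
        outcome = analysis.set_index("sample_id")["ml2rmt"]
        cov_cols = [
            c for c in ("pc1", "pc2", "age", "sex", "batch_id", "call_rate",
                        "neut_pct", "lymph_pct", "wbc")
            if c in analysis.columns
        ]
        cov = analysis.set_index("sample_id")[cov_cols] if cov_cols else None
        summary = gwaslite.gwas_scan(
            dos[retained["variant_id"]], outcome, covariates=cov, variants=retained
        )
        summary.loci = gwaslite.clump_signals(summary.table, dos)
        emit("gwas", "gwas_summary", summary.table.assign(lambda_gc=summary.lambda_gc))
        emit(
            "gwas",
            "gwas_loci",
            pd.DataFrame(
                [
                    {**{k: v for k, v in l.items() if k != "independent_signals"},
                     "independent_signals": ";".join(l["independent_signals"]),
                     "n_independent": len(l["independent_signals"])}
                    for l in summary.loci
                ],
                columns=["lead_variant", "chrom", "pos", "lead_p", "n_members",
                         "independent_signals", "n_independent"],
            ),
        )

    manifest_df = pd.DataFrame(manifest, columns=["stage", "file", "rows", "sha256"])
    write_table(manifest_df, out / "manifest.tsv")
    return manifest_df
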