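"""End-to-end orchestration: simulate → segment → extract → QC → phenotype →
associate → clump → MR, with a cohort flow report.

Each run writes its tables (features, QC, phenotypes, reference values,
association results, MR results) plus a JSON flow report giving per-reason
exclusion counts per trait, the accounting a study-selection flowchart
shows. Runs are deterministic for a fixed seed and the run directory is
content-addressed by a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as apio
from .gwas import associate_all, define_loci, filter_variants, genomic_lambda, greedy_clump, ld_r2_matrix
from .mr import harmonize, instrument_strength, ivw_re, mr_egger, mr_report, steiger_filter, weighted_median, weighted_mode
from .phenotypes import compute_bsa, derive_aao_phenotypes, inverse_normal_transform, reference_table, trait_correlations
from .qc import QCThresholds, analyze_study, participant_qc
from .segment import segment_frame_baseline
from .synth import CohortConfig, MRSimConfig, generate_cine_study, generate_covariates, generate_genotypes, generate_mr_summary_stats

logger = logging.getLogger("aortapipe")

__all__ = ["PipelineConfig", "run_pipeline"]

TRAIT_COLUMNS = {"aao_max": "aao_max_cm2", "aao_min": "aao_min_cm2", "aao_dist": "distensibility"}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "runs"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mask_source: str = "baseline"  # "baseline" | "truth" | path to mask PNG dirs
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    write_images: bool = False
    run_gwas: bool = True
    n_variants: int = 2000
    ld_block_size: int = 10
    within_block_r: float = 0.3
    n_causal_variants: int = 5
    causal_effect_cm2: float = 0.3  # area shift per effect allele
    run_mr: bool = True
    mr_sim: MRSimConfig = field(default_factory=lambda: MRSimConfig(theta=np.log(1.5)))
    instrument_p_threshold: float = 5e-8
    apply_steiger: bool = True

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _participant_stage(config: PipelineConfig, run_dir: Path):
    """Simulate, segment and QC every participant; return per-participant
    feature/QC/phenotype records."""
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    covariates = generate_covariates(cohort_cfg)

    genetic_offsets = pd.Series(0.0, index=covariates.index)
    genotypes = None
    if config.run_gwas:
        genotypes, variant_map = generate_genotypes(
            n=len(covariates),
            m=config.n_variants,
            ld_block_size=config.ld_block_size,
            within_block_r=config.within_block_r,
            seed=config.seed + 1,
        )
        rng = np.random.default_rng(config.seed + 2)
        causal_idx = rng.choice(config.n_variants, size=min(config.n_causal_variants, config.n_variants), replace=False)
        centred = genotypes[:, causal_idx] - genotypes[:, causal_idx].mean(axis=0)
        genetic_offsets = pd.Series(centred.sum(axis=1) * config.causal_effect_cm2, index=covariates.index)
    else:
        variant_map = None

    feature_rows, qc_rows, pheno_rows = [], [], []
    for pid, cov in covariates.iterrows():
        cov = cov.to_dict()
        cov["area_offset_cm2"] = float(genetic_offsets.loc[pid])
        study, truth = generate_cine_study(cohort_cfg, pid, covariates=cov)
        if config.mask_source == "truth":
            masks = truth.masks
        elif config.mask_source == "baseline":
            masks = np.stack([segment_frame_baseline(frame) for frame in study.images])
        else:
            masks = apio.read_masks(Path(config.mask_source) / pid)
        feats = analyze_study(study.images, masks, study.pixel_spacing, config.qc_thresholds)
        report = participant_qc(feats, cov, config.qc_thresholds)
        bsa = compute_bsa(cov.get("height"), cov.get("weight"))
        retained = [f for f, s in zip(feats, report.frame_statuses) if s == "pass"]
        pheno = derive_aao_phenotypes(retained, cov.get("sbp"), cov.get("dbp"), bsa)
        if config.write_images:
            apio.write_study(study, run_dir / "studies" / pid, masks=masks)
        for f in feats:
            feature_rows.append({"participant_id": pid, "frame": f.frame_index,
                                 "area_cm2": f.area_cm2, "perimeter_mm": f.perimeter_mm,
                                 "diameter_mm": f.diameter_mm, "roundness": f.roundness,
                                 "noise_sigma": f.noise_sigma, "qc_status": f.qc_status})
        qc_rows.append({"participant_id": pid,
                        "n_excluded_frames": report.n_excluded_frames,
                        "mean_abs_frame_diff": report.mean_abs_frame_diff,
                        "max_sigma": report.max_sigma,
                        **{f"included_{t}": report.included_for[t] for t in report.included_for},
                        **{f"reasons_{t}": ";".join(r) for t, r in report.exclusion_reasons.items()}})
        row = {"participant_id": pid, **{k: getattr(pheno, k) for k in
               ("aao_max_cm2", "aao_min_cm2", "aao_max_idx", "aao_min_idx",
                "diameter_max_mm", "diameter_min_mm", "distensibility", "pp", "bsa")}}
        for trait in TRAIT_COLUMNS:
            row[f"included_{trait}"] = report.included_for[trait]
        pheno_rows.append(row)
    features = pd.DataFrame(feature_rows)
    qc_table = pd.DataFrame(qc_rows).set_index("participant_id")
    phenotypes = pd.DataFrame(pheno_rows).set_index("participant_id")
    # traits the QC cascade excluded are masked out of downstream analyses
    for trait, col in TRAIT_COLUMNS.items():
        phenotypes.loc[~phenotypes[f"included_{trait}"], col] = np.nan
    return covariates, features, qc_table, phenotypes, genotypes, variant_map


def _flow_report(covariates: pd.DataFrame, qc_table: pd.DataFrame) -> dict:
    report = {"n_cohort": int(len(covariates)), "traits": {}}
    for trait in TRAIT_COLUMNS:
        reasons: dict[str, int] = {}
        excluded = 0
        for r in qc_table[f"reasons_{trait}"]:
            if r:
                excluded += 1
                for item in r.split(";"):
                    reasons[item] = reasons.get(item, 0) + 1
        report["traits"][trait] = {
            "included": int(qc_table[f"included_{trait}"].sum()),
            "excluded": excluded,
            "reason_counts": reasons,
        }
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns a dict of result tables and
    writes them under a content-addressed run directory."""
    run_dir = Path(config.output_dir) / f"run_{config.content_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"run_dir": str(run_dir)}
    timings: dict[str, float] = {}
    errors: dict[str, str] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # recorded; downstream stages may skip
                errors[name] = f"{type(exc).__name__}: {exc}"
                logger.exception("stage %s failed", name)
            timings[name] = round(time.perf_counter() - t0, 3)

        return wrap

    state: dict = {}

    @stage("imaging")
    def _imaging():
        covariates, features, qc_table, phenotypes, genotypes, variant_map = _participant_stage(config, run_dir)
        state.update(covariates=covariates, features=features, qc=qc_table,
                     phenotypes=phenotypes, genotypes=genotypes, variant_map=variant_map)
        features.to_csv(run_dir / "frame_features.tsv", sep="\t", index=False)
        qc_table.to_csv(run_dir / "participant_qc.tsv", sep="\t")
        phenotypes.to_csv(run_dir / "phenotypes.tsv", sep="\t")
        results["phenotypes"] = phenotypes
        results["qc"] = qc_table

    @stage("phenotype_summaries")
    def _summaries():
        if "phenotypes" not in state:
            raise RuntimeError("imaging stage unavailable")
        phen = state["phenotypes"].join(state["covariates"][["age", "sex"]])
        ref = reference_table(phen)
        ref.to_csv(run_dir / "reference_values.tsv", sep="\t", index=False)
        corr = trait_correlations(phen, columns=("aao_max_cm2", "aao_min_cm2", "distensibility"))
        corr.to_csv(run_dir / "trait_correlations.tsv", sep="\t", index=False)
        results["reference_table"] = ref
        results["trait_correlations"] = corr

    if config.run_gwas:
        @stage("gwas")
        def _gwas():
            if state.get("genotypes") is None:
                raise RuntimeError("genotypes unavailable")
            phen = state["phenotypes"]
            cov = state["covariates"]
            covariate_matrix = cov[["age", "sex"]].to_numpy(dtype=float)
            leads_per_trait, assoc_tables = {}, {}
            r2 = ld_r2_matrix(state["genotypes"])
            for trait, col in TRAIT_COLUMNS.items():
                values = phen[col]
                usable = values.notna()
                if usable.sum() < 10 or np.nanstd(values) == 0:
                    continue
                y = inverse_normal_transform(values.to_numpy())
                keep = np.isfinite(y)
                assoc = associate_all(state["genotypes"][keep], y[keep],
                                      covariate_matrix[keep], state["variant_map"])
                assoc = filter_variants(assoc)
                idx = state["variant_map"].set_index("SNP").index
                sub_r2 = r2[np.ix_([idx.get_loc(s) for s in assoc["SNP"]],
                                   [idx.get_loc(s) for s in assoc["SNP"]])]
                leads = greedy_clump(assoc, sub_r2)
                assoc_tables[trait] = assoc
                leads_per_trait[trait] = leads
                apio.write_summary_stats(assoc, run_dir / f"gwas_{trait}.tsv")
                leads.to_csv(run_dir / f"leads_{trait}.tsv", sep="\t", index=False)
            loci = define_loci(leads_per_trait)
            pd.DataFrame(
                [{"lead_snp": l.lead_snp, "chrom": l.chrom, "start": l.start,
                  "end": l.end, "lead_p": l.lead_p, "traits": ",".join(sorted(l.traits))}
                 for l in loci]
            ).to_csv(run_dir / "loci.tsv", sep="\t", index=False)
            lambdas = {t: genomic_lambda(a["P"]) for t, a in assoc_tables.items() if len(a) >= 100}
            results["gwas_leads"] = leads_per_trait
            results["loci"] = loci
            results["genomic_lambda"] = lambdas

    if config.run_mr:
        @stage("mr")
        def _mr():
            sim = dataclasses.replace(config.mr_sim, seed=config.seed + 3)
            exposure, outcome = generate_mr_summary_stats(sim)
            exposure = exposure[exposure["P"] < config.instrument_p_threshold]
            apio.write_summary_stats(exposure, run_dir / "mr_exposure.tsv")
            apio.write_summary_stats(outcome, run_dir / "mr_outcome.tsv")
            iset = instrument_strength(harmonize(exposure, outcome, "aao_trait", "outcome"))
            if config.apply_steiger:
                iset = steiger_filter(iset)
            methods = {"IVW-RE": ivw_re(iset)}
            if iset.k >= 3:
                methods["MR-Egger"] = mr_egger(iset)
                methods["weighted-median"] = weighted_median(iset, seed=config.seed + 4)
                methods["weighted-mode"] = weighted_mode(iset, seed=config.seed + 5)
            table = mr_report({("aao_trait", "outcome"): methods},
                              instrument_p_threshold=config.instrument_p_threshold)
            table.to_csv(run_dir / "mr_results.tsv", sep="\t", index=False)
            results["mr_results"] = table

    flow = _flow_report(state["covariates"], state["qc"]) if "qc" in state else {}
    flow["timings_s"] = timings
    flow["stage_errors"] = errors
    flow["seed"] = config.seed
    (run_dir / "flow_report.json").write_text(json.dumps(flow, indent=2))
    results["flow_report"] = flow
    return results
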