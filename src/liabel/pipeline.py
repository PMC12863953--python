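"""End-to-end evaluation pipeline: ingest/simulate -> QC -> relationship
matrices -> Gibbs fits -> diagnostics -> scale transforms -> comparison.

`run_pipeline` is the library's orchestration entry point; every stage
is also callable on its own. Artifacts are written to the output
directory as plain-text files, each preceded by provenance headers
(config hash, seed, stage), and a JSON manifest records what was run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .compare import concordance, eligible_sires, select_top
from .diagnostics import diagnose_chain
from .mcmc import ModelSpec, build_design, run_gibbs, summarize
from .qc import QCReport, check_connectedness, filter_cgs, genotype_qc
from .relationships import build_A, h_inverse_single_step, truncate_pedigree
from .scales import (
    gebv_threshold_density_adjust,
    gebv_to_probability,
    gebv_var_heritability_adjust,
    h2_observed_to_liability,
)
from .simdata import SimConfig, simulate_population

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; thresholds default to routine
    evaluation practice (CG size 10, HWE 1e-15, call rate 0.90, MAF 0.02,
    3 pedigree generations, G blended 0.95, top 10% selection)."""

    output_dir: str = "liabel_out"
    # either file inputs ...
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    genotypes_path: str | None = None
    trait: str | None = None
    # ... or a simulation
    sim: SimConfig | None = None
    # QC
    cg_min_size: int = 10
    min_links: int = 1
    hwe_p: float = 1e-15
    call_rate: float = 0.90
    maf: float = 0.02
    # relationships
    generations: int = 3
    blend: float = 0.95
    # models
    models: tuple[str, ...] = ("linear", "threshold")
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 50
    # transforms & comparison
    transformation: str = "threshold_density"  # or "variance_heritability"
    selection_fraction: float = 0.10
    min_offspring: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(cfg: PipelineConfig, stage: str) -> str:
    return f"#config={cfg.config_hash()}\n#seed={cfg.seed}\n#stage={stage}\n"


def _write_json(path: Path, payload: dict, cfg: PipelineConfig, stage: str) -> None:
    payload = {"_provenance": {"config": cfg.config_hash(), "seed": cfg.seed, "stage": stage},
               **payload}
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write artifacts; returns paths and summaries.

    Any stage failure is re-raised annotated with the stage name after
    persisting a partial manifest.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages_completed": [],
        "artifacts": {},
    }
    results: dict = {"manifest": manifest}
    stage = "ingest"
    try:
        # --- ingest or simulate ---
        if cfg.sim is not None:
            pop = simulate_population(cfg.sim)
            pedigree, phenotypes, genotypes = pop.pedigree, pop.phenotypes, pop.genotypes
            results["truth"] = pop.true_params
        else:
            if cfg.pedigree_path is None or cfg.phenotypes_path is None:
                raise ValueError("need pedigree_path and phenotypes_path (or a sim config)")
            pedigree = lio.read_pedigree(cfg.pedigree_path)
            phenotypes = lio.read_phenotypes(cfg.phenotypes_path, cfg.trait)
            genotypes = (
                lio.read_genotypes(cfg.genotypes_path) if cfg.genotypes_path else None
            )
        manifest["stages_completed"].append(stage)

        # --- QC ---
        stage = "qc"
        report = QCReport()
        phenotypes, report = filter_cgs(phenotypes, cfg.cg_min_size, report)
        phenotypes, report = check_connectedness(phenotypes, pedigree, cfg.min_links, report)
        if genotypes is not None:
            genotypes, report = genotype_qc(
                genotypes, cfg.hwe_p, cfg.call_rate, cfg.maf, report=report
            )
        _write_json(out / "qc_report.json", report.as_dict(), cfg, stage)
        manifest["artifacts"]["qc_report"] = str(out / "qc_report.json")
        manifest["stages_completed"].append(stage)

        # --- relationship matrices ---
        stage = "relationships"
        anchors = set(phenotypes["animal"])
        if genotypes is not None:
            anchors |= set(genotypes.ids)
        ped_use = truncate_pedigree(pedigree, cfg.generations, anchors)
        A = build_A(ped_use)
        G = None
        if genotypes is not None:
            from .relationships import build_G

            genotyped_in_ped = [a for a in genotypes.ids if a in set(ped_use["animal"])]
            G = build_G(genotypes.subset_animals(genotyped_in_ped))
        hinv = h_inverse_single_step(A, G, cfg.blend)
        manifest["stages_completed"].append(stage)

        # --- model fits ---
        stage = "fit"
        design = build_design(phenotypes, hinv)
        summaries: dict = {}
        chains: dict = {}
        for model in cfg.models:
            spec = ModelSpec(
                model_type=model,
                n_iterations=cfg.n_iterations,
                burn_in=cfg.burn_in,
                thin=cfg.thin,
                seed=cfg.seed + (11 if model == "linear" else 13),
            )
            chain = run_gibbs(design, spec)
            chains[model] = chain
            summaries[model] = summarize(chain)
            lio.write_gebv_table(
                summaries[model].gebv, out / f"gebv_{model}_{summaries[model].gebv.scale}.tsv"
            )
        results["summaries"] = summaries
        _write_json(
            out / "posterior_summary.json",
            {
                m: {
                    "sigma2_a": s.sigma2_a,
                    "sigma2_e": s.sigma2_e,
                    "h2": s.h2,
                    "h2_scale": s.h2_scale,
                    "h2_hpd": list(s.h2_hpd),
                    "n_kept": s.n_kept,
                }
                for m, s in summaries.items()
            },
            cfg,
            stage,
        )
        manifest["artifacts"]["posterior_summary"] = str(out / "posterior_summary.json")
        manifest["stages_completed"].append(stage)

        # --- diagnostics ---
        stage = "diagnostics"
        for model, chain in chains.items():
            rep = diagnose_chain(chain)
            rep.to_json(out / f"diagnostics_{model}.json")
            manifest["artifacts"][f"diagnostics_{model}"] = str(out / f"diagnostics_{model}.json")
        manifest["stages_completed"].append(stage)

        # --- scale transforms ---
        stage = "scales"
        alpha = float(phenotypes["y"].mean())
        gebv_prob: dict = {}
        gebv_liab: dict = {}
        if "threshold" in summaries:
            s = summaries["threshold"]
            gebv_liab["threshold"] = s.gebv
            gebv_prob["threshold"] = gebv_to_probability(s.gebv, alpha)
        if "linear" in summaries:
            s = summaries["linear"]
            h2_o = min(max(s.h2, 1e-6), 0.999)
            h2_l = h2_observed_to_liability(h2_o, alpha)
            if cfg.transformation == "threshold_density":
                liab = gebv_threshold_density_adjust(s.gebv, h2_o, h2_l, alpha)
            else:
                liab = gebv_var_heritability_adjust(s.gebv, s.sigma2_e, h2_o, h2_l)
            gebv_liab["linear"] = liab
            gebv_prob["linear"] = gebv_to_probability(liab, alpha)
        for model, table in gebv_liab.items():
            lio.write_gebv_table(table, out / f"gebv_{model}_liability.tsv")
        for model, table in gebv_prob.items():
            lio.write_gebv_table(table, out / f"gebv_{model}_probability.tsv")
        results["gebv_probability"] = gebv_prob
        manifest["stages_completed"].append(stage)

        # --- comparison ---
        stage = "compare"
        if set(("linear", "threshold")) <= set(summaries):
            sires = eligible_sires(pedigree, phenotypes, cfg.min_offspring)
            if len(sires) >= 3:
                sire_ids = list(sires["sire"])
                lin = gebv_liab["linear"].values
                thr = gebv_liab["threshold"].values
                avail = [s for s in sire_ids if s in lin.index and s in thr.index]
                if len(avail) >= 3:
                    sel_l = select_top(lin[avail], cfg.selection_fraction)
                    sel_t = select_top(thr[avail], cfg.selection_fraction)
                    rep = concordance(sel_l, sel_t, avail, (lin[avail], thr[avail]))
                    _write_json(out / "concordance.json", rep.as_dict(), cfg, stage)
                    manifest["artifacts"]["concordance"] = str(out / "concordance.json")
                    results["concordance"] = rep
        manifest["stages_completed"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["output_dir"] = str(out)
    return results
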