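"""End-to-end orchestration: simulate (optional) -> genotype QC -> expression
prep -> ancestry PCA -> eQTL scan -> conditional signals -> F_ST ->
enrichments -> GWAS overlap, from one config, with per-stage checkpoints and
a machine-readable run report.
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

from . import __version__, enrichment, expression, io, popgen, qc
from .datatypes import CovariateSet
from .eqtl import bh_fdr, conditional_signals, map_eqtl
from .simulate import SimulationConfig, simulate_cohort, simulate_two_panels

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "qc",
    "prep-expression",
    "ancestry",
    "map-eqtl",
    "conditional",
    "fst",
    "enrichment",
    "overlap",
]

DEVIATION_FLAGS = {
    "vst_omitted": "variance-stabilizing transform not applied; log2 + quantile + INT only",
    "empirical_p_tie_rule": "add-one rule (1 + #{null >= obs}) / (N + 1), ties significant",
    "stepwise_threshold": "realized BH cutoff at the chosen FDR level",
}


@dataclass
class RunConfig:
    """All paths, thresholds and the master seed for one pipeline run."""

    out_dir: str = "run_out"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # external inputs, used when simulate = False
    genotypes_path: str | None = None
    expression_path: str | None = None
    detection_path: str | None = None
    annotation_path: str | None = None
    trait_lists_path: str | None = None
    peaks_path: str | None = None

    call_rate: float = 0.95
    maf: float = 0.05
    hwe_tiers: tuple[float, float, float] = (1e-6, 1e-4, 1e-3)
    min_het: int = 6
    info_score: float = 0.5
    window_bp: int = 1_000_000
    fdr_grid: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20)
    conditional_fdr: float = 0.10
    pc_k_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    pc_fdr: float = 0.05
    r2_proxy: float = 0.8
    proxy_window_bp: int = 500_000
    eqtl_p_max: float = 0.001
    fst_threshold_high: float = 0.25
    fst_threshold_trait: float = 0.10
    fst_enrichment_fdr: float = 0.10
    n_sets: int = 1000
    outlier_threshold_sd: float = 3.0

    def validate(self) -> None:
        if list(self.fdr_grid) != sorted(self.fdr_grid):
            raise ValueError("fdr_grid must be sorted ascending")
        for v in (*self.fdr_grid, self.conditional_fdr, self.pc_fdr, self.eqtl_p_max):
            if not (0 < v < 1):
                raise ValueError(f"threshold {v} outside (0, 1)")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        cfg = RunConfig(**{k: _coerce(k, v) for k, v in raw.items()})
        cfg.simulation = SimulationConfig(**sim_raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _coerce(key: str, value):
    if key in ("hwe_tiers", "fdr_grid", "pc_k_grid") and isinstance(value, list):
        return tuple(value)
    return value


def run_pipeline(config: RunConfig, from_stage: str | None = None) -> dict:
    """Execute the pipeline; returns (and writes) the run report dict.

    ``from_stage`` reuses checkpointed outputs of earlier stages from
    ``config.out_dir`` instead of recomputing them.
    """
    config.validate()
    if from_stage is not None and from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; stages: {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start_at = STAGES.index(from_stage) if from_stage else 0

    def fresh(stage: str) -> bool:
        return STAGES.index(stage) >= start_at

    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "deviations": DEVIATION_FLAGS,
        "stages": {},
    }

    try:
        # -------------------------------------------------------- simulate
        sim = None
        if config.simulate:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            sim = simulate_cohort(sim_cfg)
            if fresh("simulate"):
                io.write_genotypes_tsv(sim.genotypes, out / "genotypes.tsv")
                io.write_genotypes_vcf(sim.genotypes, out / "genotypes.vcf")
                io.write_expression(
                    sim.expression, out / "expression.tsv", out / "detection_p.tsv"
                )
                io.write_annotation(sim.annotation, out / "annotation.tsv")
                io.write_trait_lists(sim.traits, out / "trait_lists.tsv")
                for name, ps in sim.peaks.items():
                    io.write_bed(ps, out / f"peaks_{name}.bed")
                sim.truth.planted_effects.to_csv(
                    out / "truth_planted_effects.tsv", sep="\t", index=False
                )
            genotypes = sim.genotypes
            expr = sim.expression
            annotation = sim.annotation
            traits = sim.traits
            peaks = sim.peaks
        else:
            genotypes = io.read_genotypes(config.genotypes_path)
            expr = io.read_expression(config.expression_path, config.detection_path)
            annotation = io.read_annotation(config.annotation_path)
            traits = (
                io.read_trait_lists(config.trait_lists_path, genotypes.snp_ids)
                if config.trait_lists_path
                else {}
            )
            peaks = (
                {"peaks": io.read_bed(config.peaks_path)} if config.peaks_path else {}
            )
        report["stages"]["simulate"] = {"enabled": config.simulate}

        # -------------------------------------------------------------- qc
        thresholds = qc.QcThresholds(
            call_rate=config.call_rate,
            maf=config.maf,
            hwe_tiers=config.hwe_tiers,
            min_het=config.min_het,
            min_hom_minor=config.min_het,
            info_score=config.info_score,
        )
        if fresh("qc"):
            stats = qc.compute_snp_stats(genotypes)
            genotypes, qc_report = qc.apply_genotype_filters(genotypes, stats, thresholds)
            io.write_genotypes_tsv(genotypes, out / "genotypes_qc.tsv")
            qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        else:
            genotypes = io.read_genotypes_tsv(out / "genotypes_qc.tsv")
            qc_report = pd.read_csv(out / "qc_report.tsv", sep="\t")
        report["stages"]["qc"] = {
            "n_snps_kept": genotypes.n_snps,
            "removed": dict(zip(qc_report["step"], qc_report["n_removed"].astype(int))),
        }

        # -------------------------------------------------- prep-expression
        if fresh("prep-expression"):
            expr, probe_report = expression.filter_probes(expr, annotation)
            outliers = expression.flag_outlier_samples(expr, config.outlier_threshold_sd)
            kept_samples = [s for s in expr.sample_ids if not outliers[s]]
            expr = expr.subset_samples(kept_samples)
            expr = expression.normalize_expression(expr, log2=False)
            # a probe occupying the same rank in every sample is constant
            # after quantile normalization and cannot be inverse-normal
            # transformed; drop it with a log
            variable = expr.values.var(axis=1) > 0
            if not variable.all():
                logger.warning(
                    "dropping %d probes constant after normalization",
                    int((~variable).sum()),
                )
                expr = expr.subset_probes(list(expr.values.index[variable]))
            io.write_expression(expr, out / "expression_norm.tsv")
            probe_report.to_csv(out / "probe_report.tsv", sep="\t", index=False)
            (out / "outlier_samples.txt").write_text(
                "\n".join(outliers.index[outliers]) + ("\n" if outliers.any() else "")
            )
        else:
            expr = io.read_expression(out / "expression_norm.tsv")
            probe_report = pd.read_csv(out / "probe_report.tsv", sep="\t")
        samples = expr.sample_ids
        genotypes_s = genotypes
        if set(samples) != set(genotypes.sample_ids):
            genotypes_s = _subset_samples(genotypes, samples)
        report["stages"]["prep-expression"] = {
            "n_probes": len(expr.probe_ids),
            "n_samples": len(samples),
            "probe_filters": dict(
                zip(probe_report["step"], probe_report["n_removed"].astype(int))
            ),
        }

        # ---------------------------------------------------------- ancestry
        if fresh("ancestry"):
            pruned = popgen.ld_prune(genotypes_s)
            pcs = popgen.genotype_pca(genotypes_s.subset_snps(pruned), n_components=2)
            base_cov = CovariateSet(pcs[["PC1"]].loc[samples])
            k, k_table = expression.select_expression_pcs(
                expr,
                genotypes_s,
                annotation,
                base_cov,
                k_grid=config.pc_k_grid,
                fdr=config.pc_fdr,
                window_bp=config.window_bp,
            )
            epcs = expression.expression_pcs(expr.values, k) if k else None
            cov_tab = base_cov.table.copy()
            if epcs is not None:
                cov_tab = cov_tab.join(epcs)
            cov = CovariateSet(cov_tab)
            cov_tab.to_csv(out / "covariates.tsv", sep="\t")
            k_table.to_csv(out / "pc_selection.tsv", sep="\t", index=False)
        else:
            cov_tab = pd.read_csv(out / "covariates.tsv", sep="\t", index_col=0)
            cov = CovariateSet(cov_tab)
            k_table = pd.read_csv(out / "pc_selection.tsv", sep="\t")
            k = cov_tab.shape[1] - 1
        report["stages"]["ancestry"] = {
            "n_expression_pcs": int(k),
            "pc_selection": k_table.to_dict(orient="records"),
        }

        # ---------------------------------------------------------- map-eqtl
        if fresh("map-eqtl"):
            expr_int = expression.inverse_normal_transform_table(expr)
            results = map_eqtl(
                genotypes_s, expr_int, annotation, cov, window_bp=config.window_bp
            )
            results = bh_fdr(results)
            io.write_results(results, out / "results.tsv")
            io.write_expression(expr_int, out / "expression_int.tsv")
        else:
            results = io.read_results(out / "results.tsv")
            expr_int = io.read_expression(out / "expression_int.tsv")

        # -------------------------------------------------------- conditional
        if fresh("conditional"):
            signals = conditional_signals(
                results,
                genotypes_s,
                expr_int,
                annotation,
                cov,
                fdr=config.conditional_fdr,
                window_bp=config.window_bp,
            )
            signals.to_csv(out / "signals.tsv", sep="\t", index=False)
        else:
            signals = pd.read_csv(out / "signals.tsv", sep="\t")
        report["summary_table"] = _table1_summary(results, signals, config)

        # --------------------------------------------------------------- fst
        if fresh("fst"):
            if config.simulate:
                panel_cfg = dataclasses.replace(
                    config.simulation, seed=config.seed, n_individuals=100
                )
                pop1, pop2, _ = simulate_two_panels(panel_cfg)
            else:
                raise NotImplementedError(
                    "external population panels: run the fst CLI command separately"
                )
            fst = popgen.fst_table(pop1, pop2)
            fst.to_csv(out / "fst.tsv", sep="\t")
        else:
            fst = pd.read_csv(out / "fst.tsv", sep="\t", index_col="snp_id")
        fst_report = enrichment.fst_differentiation_report(
            results,
            config.fst_enrichment_fdr,
            fst,
            traits,
            config.fst_threshold_high,
            config.fst_threshold_trait,
        )
        report["stages"]["fst"] = fst_report

        # -------------------------------------------------------- enrichment
        if fresh("enrichment"):
            report["enrichment"] = _run_enrichments(
                config, genotypes_s, annotation, results, traits, peaks, fst
            )
            (out / "enrichment.json").write_text(
                json.dumps(report["enrichment"], indent=2, default=_json_default)
            )
        else:
            report["enrichment"] = json.loads((out / "enrichment.json").read_text())

        # ----------------------------------------------------------- overlap
        if fresh("overlap"):
            targets = [s for tl in traits.values() for s in tl.snp_ids]
            proxies, _ = popgen.find_proxies(
                targets, genotypes_s, config.r2_proxy, config.proxy_window_bp
            )
            overlap = enrichment.gwas_eqtl_overlap(
                traits, results, config.conditional_fdr, proxies
            )
            overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
        else:
            overlap = pd.read_csv(out / "overlap.tsv", sep="\t")
        report["stages"]["overlap"] = {"n_rows": int(len(overlap))}
    except Exception as exc:
        stage = _current_stage(report)
        raise RuntimeError(
            f"pipeline failed in stage {stage!r}; checkpoints up to that stage "
            f"are in {out} and can be resumed with from_stage"
        ) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _current_stage(report: dict) -> str:
    done = list(report.get("stages", {}))
    remaining = [s for s in STAGES if s not in done]
    return remaining[0] if remaining else "overlap"


def _subset_samples(genotypes, samples):
    from .datatypes import GenotypeTable

    return GenotypeTable(genotypes.dosages.loc[list(samples)].copy(), genotypes.snps.copy())


def _table1_summary(results: pd.DataFrame, signals: pd.DataFrame, config: RunConfig) -> list[dict]:
    """SNP-gene pairs, SNPs, genes and independent signals per FDR level."""
    rows = []
    for fdr in config.fdr_grid:
        cis = results[(results["type"] == "cis") & (results["q"] <= fdr)]
        n_signals = (
            int(len(signals))
            if fdr == config.conditional_fdr and len(signals)
            else None
        )
        rows.append(
            {
                "fdr": fdr,
                "n_snp_gene_pairs": int(len(cis)),
                "n_snps": int(cis["snp_id"].nunique()),
                "n_genes": int(cis["gene_id"].nunique()),
                "n_independent_signals": n_signals,
            }
        )
    return rows


def _run_enrichments(config, genotypes, annotation, results, traits, peaks, fst) -> dict:
    universe = pd.Index(genotypes.snp_ids)
    maf = pd.Series(
        np.minimum(
            genotypes.dosages.mean(axis=0) / 2.0, 1 - genotypes.dosages.mean(axis=0) / 2.0
        ),
        index=universe,
    )
    tss_dist = enrichment.tss_distance(genotypes, annotation)
    spec = enrichment.MatchingSpec(n_sets=config.n_sets)
    out: dict = {}

    for name, tl in traits.items():
        restricted, _ = tl.restrict_to_universe(universe)
        if len(restricted) == 0:
            continue
        res = enrichment.trait_enrichment(
            restricted, results, universe, maf, tss_dist, spec, config.seed,
            eqtl_p_max=config.eqtl_p_max,
        )
        out[f"trait:{name}"] = {
            "observed": res.observed,
            "empirical_p": res.empirical_p,
            "n_snps": len(restricted),
        }

    sig = results[(results["type"] == "cis") & (results["q"] <= config.fst_enrichment_fdr)]
    if not sig.empty:
        sets = enrichment.eqtl_one_per_gene_sets(
            results, config.fst_enrichment_fdr, config.n_sets, config.seed
        )
        for name, ps in peaks.items():
            res = enrichment.annotation_overlap_enrichment(
                sets, universe, maf, tss_dist, spec,
                enrichment.peak_annotator(ps, genotypes),
                "two_layer_pairs", config.seed,
            )
            out[f"peaks:{name}"] = {
                "mean_eqtl_count": res.observed,
                "empirical_p": res.empirical_p,
                "below_resolution": bool(res.extra.get("below_resolution", False)),
            }
        if len(fst):
            res = enrichment.annotation_overlap_enrichment(
                sets, universe, maf, tss_dist, spec,
                enrichment.fst_annotator(fst, config.fst_threshold_high),
                "two_layer_mannwhitney", config.seed,
            )
            out["fst_differentiation"] = {
                "mean_eqtl_count": res.observed,
                "mannwhitney_p": res.empirical_p,
            }
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
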