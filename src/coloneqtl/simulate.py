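"""Synthetic cohort generator with known ground truth for every pipeline stage.

The generator emulates a small admixed eQTL cohort:

* genotypes follow the Balding–Nichols model — each SNP has an ancestral
  frequency p ~ U[0.05, 0.95] and two population-specific frequencies drawn
  from Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target F_ST; each individual's
  two alleles come from population 1 with probability equal to that
  individual's ancestry proportion (Beta-distributed across individuals);
* expression carries planted additive cis effects scaled so the genotype term
  explains a chosen fraction of expression variance in expectation, plus
  optional hidden batch factors and Gaussian noise;
* trait SNP lists and histone-peak sets are built to overlap the planted
  eQTL by configurable amounts, with matched "null" counterparts.

All randomness flows from one integer seed through named substreams, so each
stage can be regenerated independently of execution order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable, GeneAnnotation, GenotypeTable, PeakSet, TraitSnpList

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child stream of a master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    """Stated world of the synthetic cohort; defaults mirror a small eQTL study."""

    n_individuals: int = 100
    n_snps: int = 1000
    n_genes: int = 100
    chrom: str = "1"
    chrom_length: int = 50_000_000
    target_fst: float = 0.1
    admixture_alpha: tuple[float, float] = (8.0, 2.0)
    fixed_ancestry: float | None = None  # force every individual's ancestry
    n_planted_cis: int = 50
    snps_per_planted_gene: int = 1
    effect_size_r2: float = 0.3
    n_hidden_factors: int = 0
    hidden_factor_sd: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0  # log2-scale array intensity baseline
    peak_enrichment_fold: float = 5.0
    peak_width: int = 2_000
    peak_background_coverage: float = 0.05
    trait_overlap_fraction: float = 1.0
    n_trait_snps: int = 50
    frac_multi_mapped: float = 0.0
    frac_contains_common_snp: float = 0.0
    detection_p: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_individuals", "n_snps", "n_genes", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.target_fst < 1):
            raise ValueError("target_fst must lie in [0, 1)")
        if not (0 <= self.effect_size_r2 < 1):
            raise ValueError("effect_size_r2 must lie in [0, 1)")
        if self.snps_per_planted_gene * self.effect_size_r2 >= 1:
            raise ValueError("per-gene planted variance shares must sum below 1")
        if self.peak_enrichment_fold < 1:
            raise ValueError("peak_enrichment_fold must be >= 1")
        if not (0 <= self.trait_overlap_fraction <= 1):
            raise ValueError("trait_overlap_fraction must lie in [0, 1]")
        if self.n_planted_cis < 0 or self.n_hidden_factors < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_planted_cis > self.n_genes:
            raise ValueError("n_planted_cis cannot exceed n_genes")
        if self.n_snps > self.chrom_length:
            raise ValueError("more SNPs than base pairs")


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator for downstream verification."""

    ancestry: pd.Series  # per-individual population-1 proportion
    ancestral_freqs: pd.DataFrame  # snp_id x (p_anc, p_pop1, p_pop2)
    gene_annotation: GeneAnnotation
    planted_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "probe_id", "snp_id", "beta"])
    )
    hidden_factors: pd.DataFrame | None = None  # factors x samples
    factor_loadings: pd.DataFrame | None = None  # probes x factors

    @property
    def planted_snp_ids(self) -> list[str]:
        return list(dict.fromkeys(self.planted_effects["snp_id"]))


def _layout_genes(config: SimulationConfig) -> GeneAnnotation:
    """Non-overlapping gene bodies spread sparsely over the chromosome."""
    rng = substream(config.seed, "genes")
    slot = config.chrom_length // config.n_genes
    rows = []
    for i in range(config.n_genes):
        length = int(rng.integers(5_000, min(50_000, max(5_001, slot // 2))))
        offset = int(rng.integers(0, max(1, slot - length)))
        start = i * slot + offset + 1
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, end) if strand == "+" else (end, start)
        rows.append(
            {
                "probe_id": f"probe_{i:04d}",
                "gene_id": f"gene_{i:04d}",
                "chrom": config.chrom,
                "strand": strand,
                "tss": tss,
                "tes": tes,
            }
        )
    table = pd.DataFrame(rows).set_index("probe_id")
    flag_rng = substream(config.seed, "flags")
    table["multi_mapped"] = flag_rng.random(len(table)) < config.frac_multi_mapped
    table["contains_common_snp"] = flag_rng.random(len(table)) < config.frac_contains_common_snp
    return GeneAnnotation(table)


def _population_freqs(config: SimulationConfig, rng: np.random.Generator):
    p_anc = rng.uniform(0.05, 0.95, config.n_snps)
    f = config.target_fst
    if f == 0:
        p1 = p_anc.copy()
        p2 = p_anc.copy()
    else:
        shape = (1 - f) / f
        p1 = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        p2 = rng.beta(p_anc * shape, (1 - p_anc) * shape)
    return p_anc, p1, p2


def _draw_genotypes(
    p1: np.ndarray, p2: np.ndarray, ancestry: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Hard-call dosages: two alleles per individual, each from population 1
    with probability equal to that individual's ancestry proportion."""
    n, m = len(ancestry), len(p1)
    dosage = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):
        from_pop1 = rng.random((n, m)) < ancestry[:, None]
        freq = np.where(from_pop1, p1[None, :], p2[None, :])
        dosage += (rng.random((n, m)) < freq).astype(np.int8)
    return dosage


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeTable, SimulationTruth]:
    """Admixed Balding–Nichols genotypes plus recorded ground truth."""
    config.validate()
    rng = substream(config.seed, "genotypes")
    positions = np.sort(rng.choice(config.chrom_length, size=config.n_snps, replace=False)) + 1
    snp_ids = [f"rs{j:05d}" for j in range(config.n_snps)]
    p_anc, p1, p2 = _population_freqs(config, rng)

    if config.fixed_ancestry is not None:
        ancestry = np.full(config.n_individuals, float(config.fixed_ancestry))
    else:
        a, b = config.admixture_alpha
        ancestry = rng.beta(a, b, config.n_individuals)
    dosage = _draw_genotypes(p1, p2, ancestry, rng)

    sample_ids = [f"S{i:03d}" for i in range(config.n_individuals)]
    dosages = pd.DataFrame(dosage.astype(float), index=sample_ids, columns=snp_ids)
    snps = pd.DataFrame(
        {"chrom": config.chrom, "pos": positions, "ref": "A", "alt": "G"}, index=snp_ids
    )
    snps.index.name = "snp_id"
    genotypes = GenotypeTable(dosages, snps)

    truth = SimulationTruth(
        ancestry=pd.Series(ancestry, index=sample_ids, name="ancestry"),
        ancestral_freqs=pd.DataFrame(
            {"p_anc": p_anc, "p_pop1": p1, "p_pop2": p2}, index=snp_ids
        ),
        gene_annotation=_layout_genes(config),
    )
    return genotypes, truth


def simulate_two_panels(
    config: SimulationConfig,
) -> tuple[GenotypeTable, GenotypeTable, pd.DataFrame]:
    """Two unadmixed population panels sharing one Balding–Nichols frequency
    draw — the input shape the F_ST estimator expects."""
    cfg1 = replace(config, fixed_ancestry=1.0)
    geno1, truth = simulate_genotypes(cfg1)
    rng = substream(config.seed, "panel2")
    p2 = truth.ancestral_freqs["p_pop2"].to_numpy()
    dosage2 = _draw_genotypes(p2, p2, np.ones(config.n_individuals), rng)
    samples2 = [f"T{i:03d}" for i in range(config.n_individuals)]
    geno2 = GenotypeTable(
        pd.DataFrame(dosage2.astype(float), index=samples2, columns=geno1.snp_ids),
        geno1.snps.copy(),
    )
    return geno1, geno2, truth.ancestral_freqs


def _cis_snps(genotypes: GenotypeTable, tss: int, tes: int, chrom: str) -> pd.Index:
    lo = min(tss, tes) - CIS_WINDOW_BP
    hi = max(tss, tes) + CIS_WINDOW_BP
    snps = genotypes.snps
    return snps.index[(snps["chrom"] == chrom) & snps["pos"].between(lo, hi)]


def simulate_expression(
    genotypes: GenotypeTable, truth: SimulationTruth, config: SimulationConfig
) -> ExpressionTable:
    """Expression with planted additive cis effects, hidden factors and noise.

    Each planted SNP's coefficient is scaled so the genotype term explains
    ``effect_size_r2`` of that gene's expression variance in expectation
    (variance accounting uses the realized dosage variance).  Values are on a
    log2-intensity-like scale around ``baseline_mean``.
    """
    config.validate()
    rng = substream(config.seed, "expression")
    annot = truth.gene_annotation.table
    n, n_genes = genotypes.n_samples, len(annot)
    sample_ids = genotypes.sample_ids

    k = config.n_hidden_factors
    loadings = rng.normal(0.0, 1.0, (n_genes, k)) if k else np.zeros((n_genes, 0))
    factors = rng.normal(0.0, config.hidden_factor_sd, (k, n)) if k else np.zeros((0, n))
    var_other = config.noise_sd**2 + (loadings**2 * config.hidden_factor_sd**2).sum(axis=1)

    # eligible planted genes: unflagged, with enough common cis SNPs; a
    # near-monomorphic planted SNP would get a divergent coefficient from the
    # variance scaling, so planting requires realized folded MAF >= 0.05
    freq = genotypes.dosages.to_numpy(float).mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    poly = pd.Series(maf >= 0.05, index=genotypes.snp_ids)
    eligible = []
    for probe_id, row in annot.iterrows():
        if row["multi_mapped"] or row["contains_common_snp"]:
            continue
        cis = _cis_snps(genotypes, row["tss"], row["tes"], row["chrom"])
        if poly[cis].sum() >= config.snps_per_planted_gene:
            eligible.append(probe_id)
    if config.n_planted_cis > len(eligible):
        raise ValueError(
            f"only {len(eligible)} genes eligible for {config.n_planted_cis} planted effects"
        )
    planted_probes = list(rng.choice(eligible, size=config.n_planted_cis, replace=False))

    values = rng.normal(0.0, config.noise_sd, (n_genes, n))
    values += loadings @ factors
    probe_pos = {p: i for i, p in enumerate(annot.index)}

    effects = []
    share = config.effect_size_r2
    m_per_gene = config.snps_per_planted_gene
    used: set[str] = set()
    for probe_id in planted_probes:
        row = annot.loc[probe_id]
        cis = _cis_snps(genotypes, row["tss"], row["tes"], row["chrom"])
        cis = [s for s in cis if poly[s]]
        fresh_cis = [s for s in cis if s not in used]  # distinct SNPs across genes
        pool = fresh_cis if len(fresh_cis) >= m_per_gene else cis
        chosen = _pick_planted_snps(genotypes, pool, m_per_gene, rng)
        used.update(chosen)
        gi = probe_pos[probe_id]
        for snp_id in chosen:
            x = genotypes.dosage_vector(snp_id)
            v = x.var()
            if share > 0 and var_other[gi] > 0:
                beta = np.sqrt(share / (1 - m_per_gene * share) * var_other[gi] / v)
            elif share > 0:
                beta = 1.0  # noiseless limit: scale is arbitrary, R^2 = 1
            else:
                beta = 0.0
            values[gi] += beta * x
            effects.append(
                {
                    "gene_id": row["gene_id"],
                    "probe_id": probe_id,
                    "snp_id": snp_id,
                    "beta": beta,
                }
            )

    values += config.baseline_mean
    truth.planted_effects = pd.DataFrame(
        effects, columns=["gene_id", "probe_id", "snp_id", "beta"]
    )
    truth.hidden_factors = pd.DataFrame(
        factors, index=[f"factor_{j}" for j in range(k)], columns=sample_ids
    )
    truth.factor_loadings = pd.DataFrame(
        loadings, index=annot.index, columns=[f"factor_{j}" for j in range(k)]
    )
    detection = pd.DataFrame(
        np.full((n_genes, n), config.detection_p), index=annot.index, columns=sample_ids
    )
    expr = pd.DataFrame(values, index=annot.index, columns=sample_ids)
    return ExpressionTable(expr, detection)


def _pick_planted_snps(
    genotypes: GenotypeTable, cis_snps, m: int, rng: np.random.Generator, r2_max: float = 0.05
) -> list[str]:
    """Choose m polymorphic cis SNPs, mutually near-independent (r² < r2_max)."""
    cis_snps = list(cis_snps)
    if m == 1:
        return [str(rng.choice(cis_snps))]
    for _ in range(200):
        chosen = list(rng.choice(cis_snps, size=m, replace=False))
        vecs = [genotypes.dosage_vector(s) for s in chosen]
        ok = True
        for i in range(m):
            for j in range(i + 1, m):
                r = np.corrcoef(vecs[i], vecs[j])[0, 1]
                if r * r >= r2_max:
                    ok = False
        if ok:
            return [str(s) for s in chosen]
    logger.warning("could not find %d cis SNPs with pairwise r2 < %.2f; using last draw", m, r2_max)
    return [str(s) for s in chosen]


def simulate_features(
    genotypes: GenotypeTable, truth: SimulationTruth, config: SimulationConfig
) -> tuple[GeneAnnotation, dict[str, PeakSet], dict[str, TraitSnpList]]:
    """Gene annotation plus signal/null trait SNP lists and peak sets.

    The "signal" trait list contains ``trait_overlap_fraction`` planted-eQTL
    SNPs (remainder random non-planted); the "null" list is fully random but
    MAF-matched to the signal list.  The "signal" peak set covers planted
    eQTL positions ``peak_enrichment_fold`` times more densely than the
    uniform background; the "null" peak set is uniform.
    """
    config.validate()
    annotation = truth.gene_annotation
    traits = _simulate_trait_lists(genotypes, truth, config)
    peaks = _simulate_peaks(genotypes, truth, config)
    return annotation, peaks, traits


def _folded_maf(genotypes: GenotypeTable) -> pd.Series:
    freq = genotypes.dosages.mean(axis=0) / 2.0
    return pd.Series(np.minimum(freq, 1 - freq), index=genotypes.snp_ids)


def _simulate_trait_lists(genotypes, truth, config) -> dict[str, TraitSnpList]:
    rng = substream(config.seed, "traits")
    planted = truth.planted_snp_ids
    non_planted = [s for s in genotypes.snp_ids if s not in set(planted)]
    n_signal_planted = int(round(config.trait_overlap_fraction * config.n_trait_snps))
    n_signal_planted = min(n_signal_planted, len(planted))
    sig = list(rng.choice(planted, size=n_signal_planted, replace=False)) if n_signal_planted else []
    n_rest = config.n_trait_snps - n_signal_planted
    if n_rest:
        sig += list(rng.choice(non_planted, size=n_rest, replace=False))

    # null list: MAF-matched draw from non-planted SNPs, disjoint from signal
    maf = _folded_maf(genotypes)
    bins = np.floor(maf / 0.05).clip(upper=9).astype(int)
    pool = [s for s in non_planted if s not in set(sig)]
    by_bin: dict[int, list[str]] = {}
    for s in pool:
        by_bin.setdefault(int(bins[s]), []).append(s)
    null: list[str] = []
    for s in sig:
        b = int(bins[s])
        candidates = by_bin.get(b, [])
        if not candidates:  # widen to nearest occupied bin
            occupied = sorted(by_bin, key=lambda x: (abs(x - b), x))
            candidates = by_bin[occupied[0]] if occupied else []
        if not candidates:
            raise ValueError("universe exhausted while matching the null trait list")
        pick = candidates[int(rng.integers(len(candidates)))]
        candidates.remove(pick)
        null.append(pick)
    return {
        "signal": TraitSnpList("signal_trait", sig, source="synthetic"),
        "null": TraitSnpList("null_trait", null, source="synthetic"),
    }


def _simulate_peaks(genotypes, truth, config) -> dict[str, PeakSet]:
    rng = substream(config.seed, "peaks")
    width = config.peak_width
    n_bg = max(1, int(round(config.peak_background_coverage * config.chrom_length / width)))

    def uniform_peaks(r):
        starts = np.sort(r.integers(0, config.chrom_length - width, n_bg))
        return pd.DataFrame(
            {"chrom": config.chrom, "start": starts, "end": starts + width}
        )

    null_iv = uniform_peaks(rng)
    sig_iv = uniform_peaks(rng)
    extra_prob = config.peak_background_coverage * (config.peak_enrichment_fold - 1)
    planted_pos = genotypes.snps.loc[truth.planted_snp_ids, "pos"].to_numpy()
    extra = []
    for pos in planted_pos:
        if rng.random() < min(extra_prob, 1.0):
            offset = int(rng.integers(0, width))
            start = max(0, int(pos) - 1 - offset)
            extra.append({"chrom": config.chrom, "start": start, "end": start + width})
    if extra:
        sig_iv = pd.concat([sig_iv, pd.DataFrame(extra)], ignore_index=True)
    return {
        "signal": PeakSet("H3K4me1_signal", sig_iv),
        "null": PeakSet("H3K9me3_null", null_iv),
    }


@dataclass
class SimulatedCohort:
    """Everything one seed generates, bundled for convenience."""

    config: SimulationConfig
    genotypes: GenotypeTable
    expression: ExpressionTable
    annotation: GeneAnnotation
    peaks: dict[str, PeakSet]
    traits: dict[str, TraitSnpList]
    truth: SimulationTruth


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run all three generator stages in order and bundle the outputs."""
    genotypes, truth = simulate_genotypes(config)
    expression = simulate_expression(genotypes, truth, config)
    annotation, peaks, traits = simulate_features(genotypes, truth, config)
    return SimulatedCohort(config, genotypes, expression, annotation, peaks, traits, truth)
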