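"""Matched-null resampling and the three enrichment analyses: trait-associated
SNPs, population differentiation (F_ST), and histone-mark peak overlap; plus
the nearest-TSS distance profile and the GWAS–eQTL proxy-overlap report.

The resampling null draws SNP sets from the analysis universe that exactly
match the target set's size and its per-bin occupancy over the active
matching dimensions (folded MAF in 0.05-wide bins; |distance to nearest TSS|
in half-decade log bins plus a zero bin).  Empirical p-values use the
add-one rule (1 + #{null >= observed}) / (N + 1), so they are bounded away
from zero and conservative under ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datatypes import GeneAnnotation, GenotypeTable, PeakSet, TraitSnpList
from .simulate import substream

logger = logging.getLogger(__name__)


def tss_distance(genotypes: GenotypeTable, annotation: GeneAnnotation) -> pd.Series:
    """Signed distance from each SNP to the nearest TSS on its chromosome.

    Positive = downstream of that gene's TSS in the gene's strand
    orientation.  SNPs on chromosomes without genes get NaN (and are excluded
    from distance-matched sampling by the caller, with a logged count).
    """
    snps = genotypes.snps
    out = pd.Series(np.nan, index=snps.index, dtype=float)
    annot = annotation.table
    for chrom, sub in annot.groupby("chrom"):
        sel = snps["chrom"] == chrom
        if not sel.any():
            continue
        tss = sub["tss"].to_numpy(np.int64)
        strand_sign = np.where(sub["strand"].to_numpy() == "+", 1, -1)
        order = np.argsort(tss, kind="stable")
        tss_sorted, sign_sorted = tss[order], strand_sign[order]
        pos = snps.loc[sel, "pos"].to_numpy(np.int64)
        idx = np.searchsorted(tss_sorted, pos)
        left = np.clip(idx - 1, 0, len(tss_sorted) - 1)
        right = np.clip(idx, 0, len(tss_sorted) - 1)
        d_left = np.abs(pos - tss_sorted[left])
        d_right = np.abs(pos - tss_sorted[right])
        use_left = d_left <= d_right
        nearest = np.where(use_left, left, right)
        dist = (pos - tss_sorted[nearest]) * sign_sorted[nearest]
        out.loc[sel] = dist.astype(float)
    n_missing = int(out.isna().sum())
    if n_missing:
        logger.warning("%d SNPs have no gene on their chromosome; excluded from "
                       "distance matching", n_missing)
    return out


# half-decade log bins from 1 bp to 10 Mb, plus a dedicated zero bin
_DISTANCE_EDGES = np.concatenate([[0.0, 1.0], 10 ** np.arange(0.5, 7.5, 0.5)])


@dataclass
class MatchingSpec:
    """How null SNP sets are matched to a target set."""

    maf_bin_width: float = 0.05
    tss_distance_edges: np.ndarray = field(default_factory=lambda: _DISTANCE_EDGES.copy())
    match_on: tuple[str, ...] = ("maf", "tss_distance")
    n_sets: int = 1000
    sample_without_replacement: bool = True

    def validate(self) -> None:
        if self.maf_bin_width <= 0:
            raise ValueError("maf_bin_width must be positive")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        unknown = set(self.match_on) - {"maf", "tss_distance"}
        if unknown:
            raise ValueError(f"unknown matching dimensions: {unknown}")


def matching_bins(
    universe: pd.Index,
    maf: pd.Series,
    tss_dist: pd.Series | None,
    spec: MatchingSpec,
) -> pd.Series:
    """Bin label (tuple over active dimensions) per universe SNP."""
    labels = {}
    if "maf" in spec.match_on:
        labels["maf"] = np.floor(maf.loc[universe] / spec.maf_bin_width).astype(int)
    if "tss_distance" in spec.match_on:
        if tss_dist is None:
            raise ValueError("tss_distance matching requested but no distances given")
        d = tss_dist.loc[universe].abs()
        labels["dist"] = pd.Series(
            np.searchsorted(spec.tss_distance_edges, d.to_numpy(), side="right"),
            index=universe,
        ).where(d.notna(), -1)
    if not labels:
        return pd.Series([()] * len(universe), index=universe)
    frame = pd.DataFrame(labels, index=universe)
    return pd.Series(list(map(tuple, frame.to_numpy())), index=universe)


@dataclass
class MatchedSetCollection:
    """Resampled SNP-ID sets plus the bin bookkeeping used to draw them."""

    sets: list[list[str]]
    target: list[str]
    bins: pd.Series  # bin label per universe SNP
    n_widened: int = 0

    def __len__(self) -> int:
        return len(self.sets)


def sample_matched_sets(
    target,
    universe,
    maf: pd.Series,
    tss_dist: pd.Series | None,
    spec: MatchingSpec,
    seed: int,
) -> MatchedSetCollection:
    """Draw ``spec.n_sets`` SNP sets from ``universe`` matching the target's
    bin histogram exactly; sampling is without replacement within a set and
    independent across sets.  Target SNPs stay in the sampling pool (the
    whole study universe is eligible).  An exhausted bin is widened to its
    nearest nonempty neighbor, with a log."""
    spec.validate()
    target = list(dict.fromkeys(target))
    universe = pd.Index(universe)
    missing = [s for s in target if s not in universe]
    if missing:
        raise KeyError(f"target SNPs outside the universe: {missing[:5]}")
    bins = matching_bins(universe, maf, tss_dist, spec)
    target_bins = bins.loc[target]
    pool_by_bin: dict[tuple, np.ndarray] = {
        b: sub.index.to_numpy(object) for b, sub in bins.groupby(bins)
    }
    need = target_bins.value_counts()
    occupied = list(pool_by_bin)

    def nearest_pool(b: tuple, excluded: set) -> np.ndarray:
        # widen: nearest occupied bin by euclidean distance on bin indices
        cands = [c for c in occupied if c != b and len(pool_by_bin[c])]
        if not cands:
            raise ValueError("universe exhausted: no candidates in any bin")
        arr = np.array([c for c in cands], dtype=float)
        ref = np.array(b, dtype=float)
        d = ((arr - ref) ** 2).sum(axis=1)
        best = cands[int(np.argmin(d))]
        return pool_by_bin[best]

    rng = substream(seed, "matched_sets")
    n_widened = 0
    sets: list[list[str]] = []
    for _ in range(spec.n_sets):
        chosen: list[str] = []
        for b, count in need.items():
            pool = pool_by_bin.get(b, np.empty(0, dtype=object))
            if len(pool) >= count:
                picks = rng.choice(pool, size=count, replace=not spec.sample_without_replacement)
            else:
                picks = list(pool)
                n_widened += 1
                wide = nearest_pool(b, set(picks))
                extra = rng.choice(wide, size=count - len(picks), replace=False)
                picks = np.concatenate([np.asarray(picks, dtype=object), extra])
            chosen.extend(str(s) for s in picks)
        sets.append(chosen)
    if n_widened:
        logger.warning("widened exhausted matching bins %d times", n_widened)
    return MatchedSetCollection(sets, target, bins, n_widened)


@dataclass
class EnrichmentResult:
    """Observed statistic, resampling null, and the empirical p-value."""

    observed: float
    null_statistics: np.ndarray
    empirical_p: float
    method: str
    extra: dict = field(default_factory=dict)


def _empirical_p(observed: float, null: np.ndarray) -> float:
    n = len(null)
    return float((1 + np.sum(null >= observed)) / (n + 1))


def best_cis_p_per_snp(results: pd.DataFrame) -> pd.Series:
    """Minimum cis p-value per SNP; SNPs with no cis pair are absent."""
    cis = results[results["type"] == "cis"]
    return cis.groupby("snp_id")["p"].min()


def trait_enrichment(
    trait: TraitSnpList,
    results: pd.DataFrame,
    universe,
    maf: pd.Series,
    tss_dist: pd.Series | None,
    spec: MatchingSpec,
    seed: int,
    eqtl_p_max: float = 0.001,
) -> EnrichmentResult:
    """Are trait SNPs enriched for cis-eQTL (best cis p < ``eqtl_p_max``)?

    Counts trait SNPs that are cis-eQTL at the relaxed threshold, compares
    against the same count in matched random sets, and reports the add-one
    empirical p-value.
    """
    if len(trait) == 0:
        raise ValueError("trait list is empty after universe restriction")
    best_p = best_cis_p_per_snp(results)

    def count_eqtl(snp_ids) -> int:
        p = best_p.reindex(snp_ids)
        return int((p < eqtl_p_max).sum())

    collection = sample_matched_sets(trait.snp_ids, universe, maf, tss_dist, spec, seed)
    observed = count_eqtl(trait.snp_ids)
    null = np.array([count_eqtl(s) for s in collection.sets])
    return EnrichmentResult(
        observed,
        null,
        _empirical_p(observed, null),
        "single_layer",
        {"trait": trait.trait, "n_snps": len(trait), "eqtl_p_max": eqtl_p_max},
    )


def eqtl_one_per_gene_sets(
    results: pd.DataFrame, fdr: float, n_sets: int, seed: int
) -> list[list[str]]:
    """Random one-SNP-per-significant-gene cis-eQTL sets.

    Each set contains exactly one SNP per gene with a significant cis
    association at ``fdr``, chosen uniformly among that gene's significant
    SNPs, independently across sets.
    """
    sig = results[(results["type"] == "cis") & (results["q"] <= fdr)]
    if sig.empty:
        raise ValueError(f"no significant cis genes at FDR {fdr}")
    by_gene = {g: sub["snp_id"].to_numpy(object) for g, sub in sig.groupby("gene_id")}
    rng = substream(seed, "eqtl_sets")
    genes = sorted(by_gene)
    return [[str(rng.choice(by_gene[g])) for g in genes] for _ in range(n_sets)]


def annotation_overlap_enrichment(
    eqtl_sets: list[list[str]],
    universe,
    maf: pd.Series,
    tss_dist: pd.Series | None,
    spec: MatchingSpec,
    annotator,
    mode: str,
    seed: int,
) -> EnrichmentResult:
    """Two-layer resampling enrichment of a SNP annotation among cis-eQTL.

    ``annotator`` maps a list of snp_ids to a boolean array (e.g. in-peak, or
    F_ST above a threshold).  The matched layer is drawn against one
    representative eQTL set.  ``mode``:

    * ``two_layer_pairs`` — empirical p = #{(i, j): null_j >= eqtl_i} / n²,
      reported as "< 1/n²" via the ``extra`` field when the numerator is 0;
    * ``two_layer_mannwhitney`` — two-sided Mann–Whitney U between the two
      count vectors (normal approximation with tie correction).
    """
    if mode not in ("two_layer_pairs", "two_layer_mannwhitney"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = substream(seed, "overlap_rep")
    representative = eqtl_sets[int(rng.integers(len(eqtl_sets)))]
    rep_spec = MatchingSpec(
        maf_bin_width=spec.maf_bin_width,
        tss_distance_edges=spec.tss_distance_edges,
        match_on=spec.match_on,
        n_sets=len(eqtl_sets),
        sample_without_replacement=spec.sample_without_replacement,
    )
    matched = sample_matched_sets(representative, universe, maf, tss_dist, rep_spec, seed)

    def count(snp_ids) -> int:
        return int(np.asarray(annotator(snp_ids), bool).sum())

    eqtl_counts = np.array([count(s) for s in eqtl_sets])
    null_counts = np.array([count(s) for s in matched.sets])

    extra = {"eqtl_counts": eqtl_counts, "n_sets": len(eqtl_sets)}
    if mode == "two_layer_pairs":
        n_pairs = len(eqtl_counts) * len(null_counts)
        exceed = int((null_counts[None, :] >= eqtl_counts[:, None]).sum())
        p = exceed / n_pairs if exceed else 1.0 / n_pairs
        extra["below_resolution"] = exceed == 0
        return EnrichmentResult(float(eqtl_counts.mean()), null_counts, p, mode, extra)
    stat, p = mannwhitneyu(eqtl_counts, null_counts, alternative="two-sided", method="asymptotic")
    extra["u_statistic"] = float(stat)
    return EnrichmentResult(float(eqtl_counts.mean()), null_counts, float(p), mode, extra)


def peak_annotator(peaks: PeakSet, genotypes: GenotypeTable):
    """SNP -> in-peak boolean annotator (1-based positions vs half-open peaks)."""
    snps = genotypes.snps

    def annotate(snp_ids):
        sub = snps.loc[list(snp_ids)]
        return peaks.contains(sub["chrom"].to_numpy(), sub["pos"].to_numpy())

    return annotate


def fst_annotator(fst: pd.DataFrame, threshold: float):
    """SNP -> (theta_hat > threshold) annotator; missing F_ST counts False."""

    def annotate(snp_ids):
        theta = fst["theta_hat"].reindex(list(snp_ids))
        return (theta > threshold).fillna(False).to_numpy(bool)

    return annotate


def fst_differentiation_report(
    results: pd.DataFrame,
    fdr: float,
    fst: pd.DataFrame,
    trait_lists: dict[str, TraitSnpList] | None = None,
    threshold_high: float = 0.25,
    threshold_trait: float = 0.10,
) -> dict:
    """Population-differentiation summary over significant cis-eQTL.

    Counts significant cis-eQTL SNPs with theta_hat strictly above
    ``threshold_high``; SNPs lacking an F_ST estimate leave the denominator
    (logged).  Also lists trait-overlapping eQTL above ``threshold_trait``.
    """
    sig_snps = results[(results["type"] == "cis") & (results["q"] <= fdr)]["snp_id"].unique()
    theta = fst["theta_hat"].reindex(sig_snps)
    n_missing = int(theta.isna().sum())
    if n_missing:
        logger.info("F_ST unavailable for %d of %d significant SNPs", n_missing, len(sig_snps))
    avail = theta.dropna()
    n_diff = int((avail > threshold_high).sum())
    report = {
        "fdr": fdr,
        "n_significant_snps": int(len(sig_snps)),
        "n_with_fst": int(len(avail)),
        "n_missing_fst": n_missing,
        "n_differentiated": n_diff,
        "fraction_differentiated": n_diff / len(avail) if len(avail) else float("nan"),
        "threshold": threshold_high,
        "trait_differentiated": {},
    }
    if trait_lists:
        for name, tl in trait_lists.items():
            overlap = [s for s in tl.snp_ids if s in set(sig_snps)]
            t = fst["theta_hat"].reindex(overlap).dropna()
            report["trait_differentiated"][name] = sorted(t.index[t > threshold_trait])
    return report


def gwas_eqtl_overlap(
    trait_lists: dict[str, TraitSnpList],
    results: pd.DataFrame,
    fdr: float,
    proxies: pd.DataFrame,
) -> pd.DataFrame:
    """Significant cis-eQTL that are trait SNPs or r²-proxies of trait SNPs.

    ``proxies`` is the (target, proxy, r2, distance_bp) table from
    :func:`coloneqtl.popgen.find_proxies` with trait SNPs as targets.
    Returns one row per (trait, trait SNP, eQTL SNP, gene).
    """
    sig = results[(results["type"] == "cis") & (results["q"] <= fdr)]
    sig_best = sig.loc[sig.groupby(["snp_id", "gene_id"])["p"].idxmin()]
    rows = []
    for name, tl in trait_lists.items():
        for gwas_snp in tl.snp_ids:
            prox = proxies[proxies["target"] == gwas_snp]
            linked = dict(zip(prox["proxy"], prox["r2"]))
            linked.setdefault(gwas_snp, 1.0)
            hits = sig_best[sig_best["snp_id"].isin(linked)]
            for _, h in hits.iterrows():
                rows.append(
                    {
                        "trait": name,
                        "gwas_snp": gwas_snp,
                        "eqtl_snp": h["snp_id"],
                        "gene_id": h["gene_id"],
                        "probe_id": h["probe_id"],
                        "eqtl_p": h["p"],
                        "eqtl_q": h["q"],
                        "r2": linked[h["snp_id"]],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["trait", "gwas_snp", "eqtl_snp", "gene_id", "probe_id", "eqtl_p", "eqtl_q", "r2"],
    )
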