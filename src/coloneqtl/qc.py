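"""Genotype quality control: per-SNP statistics, the exact Hardy–Weinberg
test, and the ordered marker-exclusion filters.

Filter order (each step sees the survivors of the previous one):

1. call rate < 0.95
2. folded MAF < 0.05
3. HWE exact p < 1e-6
4. HWE p < 1e-4 with no heterozygotes or no minor-allele homozygotes
5. HWE p < 1e-3 with < 6 heterozygotes or < 6 minor-allele homozygotes
6. non-autosomal chromosome
7. any SNP sharing (chrom, pos) with another SNP (all collision members drop)
8. imputation info score < 0.5, when the field is present

HWE is evaluated on hard calls (dosages rounded half away from zero); the
test is the exact conditional-on-allele-counts test by default, with a
chi-square option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .datatypes import GenotypeTable, is_autosome


@dataclass
class QcThresholds:
    call_rate: float = 0.95
    maf: float = 0.05
    hwe_tiers: tuple[float, float, float] = (1e-6, 1e-4, 1e-3)
    min_het: int = 6
    min_hom_minor: int = 6
    info_score: float = 0.5
    hwe_method: str = "exact"  # or "chisq"
    autosomes_only: bool = True

    def validate(self) -> None:
        for name in ("call_rate", "maf", "info_score"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for t in self.hwe_tiers:
            if not (0 < t < 1):
                raise ValueError("HWE tier thresholds must lie in (0, 1)")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError("hwe_method must be 'exact' or 'chisq'")


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Sums, over every heterozygote count compatible with the observed allele
    counts, the probability of outcomes no more probable than the observed
    configuration (two-sided by probability ordering).  Monomorphic input
    gives p = 1.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be nonnegative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor_alleles = n_het + 2 * n_hom_minor
    n_major_alleles = n_het + 2 * n_hom_major
    if n_minor_alleles > n_major_alleles:  # fold so "minor" really is minor
        n_minor_alleles, n_major_alleles = n_major_alleles, n_minor_alleles
    if n_minor_alleles == 0:
        return 1.0
    hets = np.arange(n_minor_alleles % 2, n_minor_alleles + 1, 2)
    log_probs = _log_hwe_prob(hets, n_minor_alleles, 2 * n)
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _log_hwe_prob(n_het: np.ndarray, n_minor: int, n_alleles: int) -> np.ndarray:
    """Log conditional probability of n_het heterozygotes given allele counts."""
    n = n_alleles // 2
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n - n_het - n_hom_minor
    return (
        n_het * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(n_hom_major + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_alleles - n_minor + 1)
        - gammaln(n_alleles + 1)
    )


def hwe_chisq_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """One-df chi-square Hardy–Weinberg test (no continuity correction)."""
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (n_het + 2 * n_hom_minor) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int, method: str = "exact") -> float:
    if method == "exact":
        return hwe_exact_p(n_hom_major, n_het, n_hom_minor)
    if method == "chisq":
        return hwe_chisq_p(n_hom_major, n_het, n_hom_minor)
    raise ValueError(f"unknown HWE method {method!r}")


def compute_snp_stats(genotypes: GenotypeTable, hwe_method: str = "exact") -> pd.DataFrame:
    """Per-SNP call rate, folded MAF, genotype-class counts and HWE p.

    MAF comes from the mean dosage (folded to <= 0.5); heterozygote and
    homozygote counts come from hard calls, used only for counting.  SNPs
    with no calls get call_rate 0 and NaN for every other statistic.
    """
    if genotypes.n_samples < 1:
        raise ValueError("need at least one individual")
    dos = genotypes.dosages.to_numpy(float)
    calls = genotypes.hard_calls().to_numpy()
    n_samples = dos.shape[0]
    n_called = np.sum(~np.isnan(dos), axis=0)
    call_rate = n_called / n_samples

    sums = np.nansum(dos, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, sums / np.maximum(n_called, 1) / 2.0, np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)

    n_hom_ref = np.nansum(calls == 0, axis=0).astype(int)
    n_het = np.nansum(calls == 1, axis=0).astype(int)
    n_hom_alt = np.nansum(calls == 2, axis=0).astype(int)
    minor_is_alt = alt_freq <= 0.5
    n_hom_minor = np.where(minor_is_alt, n_hom_alt, n_hom_ref)
    n_hom_major = np.where(minor_is_alt, n_hom_ref, n_hom_alt)

    hwe_p = np.full(dos.shape[1], np.nan)
    for j in range(dos.shape[1]):
        if n_called[j] == 0:
            continue
        hwe_p[j] = hwe_test(int(n_hom_major[j]), int(n_het[j]), int(n_hom_minor[j]), hwe_method)
    maf = np.where(n_called > 0, maf, np.nan)

    stats = pd.DataFrame(
        {
            "call_rate": call_rate,
            "maf": maf,
            "n_het": n_het,
            "n_hom_minor": n_hom_minor,
            "n_hom_major": n_hom_major,
            "hwe_p": hwe_p,
        },
        index=genotypes.snp_ids,
    )
    if "info_score" in genotypes.snps.columns:
        stats["info_score"] = genotypes.snps["info_score"].to_numpy()
    return stats


def apply_genotype_filters(
    genotypes: GenotypeTable,
    stats: pd.DataFrame | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Apply the ordered marker filters; return survivors and a step report.

    The report has one row per filter step, in application order, with the
    number of SNPs removed at that step; the counts sum to input - output.
    """
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    if stats is None:
        stats = compute_snp_stats(genotypes, thresholds.hwe_method)
    stats = stats.loc[genotypes.snp_ids]

    alive = pd.Series(True, index=stats.index)
    report_rows = []

    def step(name: str, drop_mask: pd.Series) -> None:
        drop = alive & drop_mask.fillna(False)
        report_rows.append({"step": name, "n_removed": int(drop.sum())})
        alive[drop] = False

    t = thresholds
    step("call_rate", stats["call_rate"] < t.call_rate)
    step("maf", stats["maf"] < t.maf)
    step("hwe_tier1", stats["hwe_p"] < t.hwe_tiers[0])
    step(
        "hwe_tier2",
        (stats["hwe_p"] < t.hwe_tiers[1])
        & ((stats["n_het"] == 0) | (stats["n_hom_minor"] == 0)),
    )
    step(
        "hwe_tier3",
        (stats["hwe_p"] < t.hwe_tiers[2])
        & ((stats["n_het"] < t.min_het) | (stats["n_hom_minor"] < t.min_hom_minor)),
    )
    if t.autosomes_only:
        autosomal = genotypes.snps["chrom"].map(is_autosome)
        step("non_autosomal", ~autosomal)
    else:
        report_rows.append({"step": "non_autosomal", "n_removed": 0})
    # duplicate positions: all members of a (chrom, pos) collision drop,
    # judged among SNPs still alive at this step
    pos_key = genotypes.snps.loc[alive[alive].index, ["chrom", "pos"]]
    dup = pos_key.duplicated(keep=False)
    dup_ids = pos_key.index[dup]
    step("duplicate_position", pd.Series(stats.index.isin(dup_ids), index=stats.index))
    if "info_score" in stats.columns and stats["info_score"].notna().any():
        step("info_score", stats["info_score"] < t.info_score)
    else:
        report_rows.append({"step": "info_score", "n_removed": 0})

    report = pd.DataFrame(report_rows)
    kept = [s for s in genotypes.snp_ids if alive[s]]
    return genotypes.subset_snps(kept), report
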