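"""Population-genetic utilities: genotype PCA, LD r², proxy search, pruning,
and the Weir–Cockerham fixation index between two population panels.

The F_ST estimator is the two-population unbiased variance-components form:
theta_hat = a / (a + b + c), where ``a`` is the between-population component,
``b`` the between-individual-within-population component and ``c`` the
within-individual (heterozygosity) component.  theta_hat can be negative;
negative values are reported as-is so averages stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable


@dataclass
class FstResult:
    """Per-SNP Weir–Cockerham variance components and theta_hat."""

    snp_id: str
    a: float
    b: float
    c: float
    theta_hat: float  # NaN when a + b + c == 0 (undefined)
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float


def wc_fst(counts1, counts2) -> FstResult:
    """Weir–Cockerham theta_hat from genotype counts of two populations.

    Parameters
    ----------
    counts1, counts2
        Length-3 sequences ``(n_hom_ref, n_het, n_hom_alt)`` for each
        population.  Each population needs >= 2 individuals with calls.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != (3,) or c2.shape != (3,):
        raise ValueError("genotype counts must be length-3 (hom_ref, het, hom_alt)")
    n1, n2 = c1.sum(), c2.sum()
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 individuals with genotype calls")

    r = 2.0
    p1 = (c1[1] + 2 * c1[2]) / (2 * n1)
    p2 = (c2[1] + 2 * c2[2]) / (2 * n2)
    h1 = c1[1] / n1
    h2 = c2[1] / n2

    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (pq - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar))
    c = h_bar / 2

    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return FstResult("", a, b, c, theta, int(n1), int(n2), p1, p2, h1, h2)


def genotype_counts(genotypes: GenotypeTable) -> pd.DataFrame:
    """Per-SNP (n_hom_ref, n_het, n_hom_alt) from rounded hard calls."""
    calls = genotypes.hard_calls().to_numpy()
    out = {}
    for k, name in enumerate(["n_hom_ref", "n_het", "n_hom_alt"]):
        out[name] = np.nansum(calls == k, axis=0)
    return pd.DataFrame(out, index=genotypes.snp_ids)


def fst_table(pop1: GenotypeTable, pop2: GenotypeTable, snp_ids=None) -> pd.DataFrame:
    """Weir–Cockerham theta_hat for every SNP shared by the two panels."""
    shared = [s for s in pop1.snp_ids if s in set(pop2.snp_ids)]
    if snp_ids is not None:
        wanted = set(snp_ids)
        shared = [s for s in shared if s in wanted]
    cnt1 = genotype_counts(pop1.subset_snps(shared))
    cnt2 = genotype_counts(pop2.subset_snps(shared))
    rows = []
    for s in shared:
        res = wc_fst(cnt1.loc[s].to_numpy(), cnt2.loc[s].to_numpy())
        rows.append(
            {
                "snp_id": s,
                "a": res.a,
                "b": res.b,
                "c": res.c,
                "theta_hat": res.theta_hat,
                "n1": res.n1,
                "n2": res.n2,
                "p1": res.p1,
                "p2": res.p2,
            }
        )
    return pd.DataFrame(rows).set_index("snp_id") if rows else pd.DataFrame(
        columns=["a", "b", "c", "theta_hat", "n1", "n2", "p1", "p2"]
    )


def multilocus_fst(table: pd.DataFrame) -> float:
    """Multi-locus Weir–Cockerham theta: ratio of summed variance components
    (sum a) / (sum a + b + c) over SNPs.

    This is the estimator's own prescription for combining loci; averaging
    per-SNP ratios is biased toward zero with few populations because the
    between-population component has a single degree of freedom.
    """
    num = table["a"].sum()
    den = (table["a"] + table["b"] + table["c"]).sum()
    return float(num / den) if den else float("nan")


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages (composite, phase-free LD)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must share samples")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD r2 undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Pairwise r² over SNP columns; NaN rows/cols for constant SNPs."""
    sd = dos.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (dos - dos.mean(axis=0)) / sd
        corr = z.T @ z / dos.shape[0]
    r2 = corr**2
    r2[:, sd == 0] = np.nan
    r2[sd == 0, :] = np.nan
    return r2


def find_proxies(
    targets,
    genotypes: GenotypeTable,
    r2_min: float = 0.8,
    window_bp: int = 500_000,
) -> tuple[pd.DataFrame, list[str]]:
    """All SNPs within ``window_bp`` of each target with r² >= ``r2_min``.

    Returns a table (target, proxy, r2, distance_bp) — each target appears as
    its own proxy with r² = 1 — and the list of targets absent from the panel.
    """
    snps = genotypes.snps
    dosages = genotypes.dosages
    misses = [t for t in targets if t not in snps.index]
    rows = []
    for t in targets:
        if t in misses:
            continue
        chrom, pos = snps.at[t, "chrom"], snps.at[t, "pos"]
        near = snps[(snps["chrom"] == chrom) & (snps["pos"] - pos).abs().le(window_bp)]
        x = dosages[t].to_numpy(float)
        if np.nanstd(x) == 0:
            rows.append({"target": t, "proxy": t, "r2": 1.0, "distance_bp": 0})
            continue
        for q in near.index:
            y = dosages[q].to_numpy(float)
            if q == t:
                r2 = 1.0
            elif np.nanstd(y) == 0:
                continue
            else:
                r2 = ld_r2(x, y)
            if r2 >= r2_min:
                rows.append(
                    {"target": t, "proxy": q, "r2": r2, "distance_bp": int(near.at[q, "pos"] - pos)}
                )
    table = pd.DataFrame(rows, columns=["target", "proxy", "r2", "distance_bp"])
    return table, misses


def ld_prune(
    genotypes: GenotypeTable,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy sliding-window LD pruning; keeps the earlier-positioned SNP of
    any retained pair exceeding ``r2_max``. Deterministic given input order."""
    if not (0 < r2_max < 1):
        raise ValueError("r2_max must lie in (0, 1)")
    if window_snps <= 0 or step_snps <= 0:
        raise ValueError("window and step must be positive")
    snp_ids = np.asarray(genotypes.snp_ids, dtype=object)
    chroms = genotypes.snps["chrom"].to_numpy()
    dos = genotypes.dosages.to_numpy(float)
    keep = np.ones(len(snp_ids), dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window_snps]
            active = win[keep[win]]
            if len(active) > 1:
                r2 = _r2_matrix(dos[:, active])
                changed = True
                while changed:
                    changed = False
                    alive = keep[active]
                    live = np.flatnonzero(alive)
                    for ii in range(len(live)):
                        for jj in range(ii + 1, len(live)):
                            v = r2[live[ii], live[jj]]
                            if np.isfinite(v) and v > r2_max:
                                keep[active[live[jj]]] = False
                                changed = True
                                break
                        if changed:
                            break
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return [s for s, k in zip(snp_ids, keep) if k]


def genotype_pca(genotypes: GenotypeTable, n_components: int = 10) -> pd.DataFrame:
    """PCA of standardized genotypes; rows are samples, columns PC1..PCk.

    Each SNP column is centered by 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)).
    Monomorphic SNPs are dropped before scaling.  The sign of each PC is fixed
    so its largest-magnitude SNP loading is positive.
    """
    if genotypes.n_samples < 2 or genotypes.n_snps < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 SNPs")
    dos = genotypes.dosages.to_numpy(float)
    p_hat = np.nanmean(dos, axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if poly.sum() < n_components:
        raise ValueError(
            f"only {int(poly.sum())} polymorphic SNPs for {n_components} components"
        )
    dos = dos[:, poly]
    p_hat = p_hat[poly]
    z = (dos - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            scores[:, k] *= -1
            loadings[k] *= -1
    return pd.DataFrame(
        scores,
        index=genotypes.sample_ids,
        columns=[f"PC{k+1}" for k in range(n_components)],
    )
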