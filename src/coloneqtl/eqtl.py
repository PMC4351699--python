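"""Additive-model eQTL mapping: cis/trans pair enumeration, per-pair OLS,
Benjamini–Hochberg FDR separately by class, and stepwise conditional
decomposition of cis signals.

The scan residualizes expression and dosage on the covariates (with
intercept) once per dataset and then evaluates the per-pair slope test; by
Frisch–Waugh–Lovell this is numerically identical to the full OLS of
expression on [1, dosage, covariates], with t on n - (k + 2) degrees of
freedom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CovariateSet, ExpressionTable, GeneAnnotation, GenotypeTable

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "snp_id",
    "probe_id",
    "gene_id",
    "beta",
    "se",
    "t",
    "p",
    "q",
    "type",
    "distance_bp",
]


def enumerate_cis_pairs(
    genotypes: GenotypeTable,
    annotation: GeneAnnotation,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Classify every SNP x probe pair as cis or trans.

    A pair is cis iff the SNP lies on the gene's chromosome within
    ``window_bp`` (inclusive) of the gene body [min(tss,tes), max(tss,tes)];
    everything else is trans.  Returns one row per pair with the signed
    TSS distance (positive = downstream in the gene's orientation; NaN for
    trans pairs on another chromosome).
    """
    snps = genotypes.snps
    annot = annotation.table
    known = set(snps["chrom"].unique())
    rows = []
    for probe_id, g in annot.iterrows():
        same = snps["chrom"] == g["chrom"]
        lo = min(g["tss"], g["tes"]) - window_bp
        hi = max(g["tss"], g["tes"]) + window_bp
        in_window = same & snps["pos"].between(lo, hi)
        sign = 1 if g["strand"] == "+" else -1
        dist = np.where(same, sign * (snps["pos"] - g["tss"]), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": snps.index,
                    "probe_id": probe_id,
                    "gene_id": g["gene_id"],
                    "type": np.where(in_window, "cis", "trans"),
                    "distance_bp": dist,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fit_additive_model(
    dosage: np.ndarray, expression: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """Exact OLS of expression on [intercept, dosage, covariates].

    Returns (beta, se, t, p) for the dosage term; t has n - (k + 2) degrees
    of freedom where k is the number of covariates.
    """
    x = np.asarray(dosage, float)
    y = np.asarray(expression, float)
    n = len(y)
    if covariates is None:
        covariates = np.empty((n, 0))
    c = np.asarray(covariates, float)
    if c.ndim == 1:
        c = c[:, None]
    k = c.shape[1]
    if n <= k + 2:
        raise ValueError("too few samples for the model")
    if np.ptp(x) == 0:
        raise ValueError("constant dosage")
    design = np.column_stack([np.ones(n), x, c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design (collinear covariates)")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - (k + 2)
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), dof))
    return beta, se, t, p


def _residualize(mat: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``mat`` on [1, cov] via QR."""
    n = mat.shape[0]
    design = np.column_stack([np.ones(n), cov])
    q, _ = np.linalg.qr(design)
    return mat - q @ (q.T @ mat)


def _scan_block(
    dos_r: np.ndarray, y_r: np.ndarray, dof: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Slope test of one residualized probe against many residualized SNPs."""
    sxx = (dos_r**2).sum(axis=0)
    sxy = dos_r.T @ y_r
    syy = float(y_r @ y_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / dof / sxx)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p


def map_eqtl(
    genotypes: GenotypeTable,
    expression: ExpressionTable,
    annotation: GeneAnnotation,
    covariates: CovariateSet | None = None,
    window_bp: int = 1_000_000,
    include_trans: bool = True,
) -> pd.DataFrame:
    """Scan SNP x probe pairs with the additive linear model.

    Expression is expected to be fully preprocessed (normalized and inverse
    normal transformed).  Constant-dosage SNPs are skipped with a logged
    count.  Returns the association table without q-values (see
    :func:`bh_fdr`).
    """
    samples = expression.sample_ids
    geno = genotypes.dosages.loc[samples]
    cov = (
        covariates.matrix(samples)
        if covariates is not None
        else np.empty((len(samples), 0))
    )
    n, k = len(samples), cov.shape[1]
    dof = n - (k + 2)
    if dof <= 0:
        raise ValueError("model not identifiable: too many covariates")

    pairs = enumerate_cis_pairs(genotypes, annotation, window_bp)
    if not include_trans:
        pairs = pairs[pairs["type"] == "cis"]
    pairs = pairs[pairs["probe_id"].isin(expression.probe_ids)]

    dos = geno.to_numpy(float)
    keep = np.ptp(dos, axis=0) > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.info("skipping %d constant-dosage SNPs", n_const)
    snp_ids = np.asarray(genotypes.snp_ids, dtype=object)[keep]
    dos_r = _residualize(dos[:, keep], cov)
    col_of = {s: i for i, s in enumerate(snp_ids)}

    expr_mat = expression.values.loc[:, samples].to_numpy(float)
    expr_r = _residualize(expr_mat.T, cov)  # samples x probes
    probe_of = {pid: i for i, pid in enumerate(expression.probe_ids)}

    pairs = pairs[pairs["snp_id"].isin(col_of)].reset_index(drop=True)
    out = []
    for probe_id, sub in pairs.groupby("probe_id", sort=False):
        y_r = expr_r[:, probe_of[probe_id]]
        cols = np.array([col_of[s] for s in sub["snp_id"]])
        beta, se, t, p = _scan_block(dos_r[:, cols], y_r, dof)
        block = sub.copy()
        block["beta"], block["se"], block["t"], block["p"] = beta, se, t, p
        out.append(block)
    results = pd.concat(out, ignore_index=True) if out else pairs.iloc[0:0].copy()
    results["q"] = np.nan
    return results[RESULT_COLUMNS]


def bh_fdr(results: pd.DataFrame, group_col: str = "type") -> pd.DataFrame:
    """Benjamini–Hochberg q-values computed separately within each group
    (cis and trans), mapped back to the input row order."""
    out = results.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(group_col).groups.items():
        p = out.loc[idx, "p"].to_numpy(float)
        out.loc[idx, "q"] = bh_qvalues(p)
    return out


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH q-values: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p_values, float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def realized_bh_cutoff(results: pd.DataFrame, fdr: float, eqtl_type: str = "cis") -> float:
    """Largest unconditional p among associations passing BH at ``fdr`` —
    the significance rule carried into the stepwise conditional scan."""
    sub = results[(results["type"] == eqtl_type) & (results["q"] <= fdr)]
    if sub.empty:
        return float("nan")
    return float(sub["p"].max())


def stepwise_conditional(
    probe_id: str,
    genotypes: GenotypeTable,
    expression: ExpressionTable,
    annotation: GeneAnnotation,
    covariates: CovariateSet | None,
    p_threshold: float,
    window_bp: int = 1_000_000,
) -> list[tuple[str, float]]:
    """Forward stepwise decomposition of one probe's cis signal.

    Repeatedly adds the most significant cis SNP's dosage to the covariates
    and rescans the probe's remaining cis SNPs, until no remaining SNP falls
    below ``p_threshold`` or the design runs out of degrees of freedom.
    Returns the discovered (snp_id, conditional p) list in discovery order.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    samples = expression.sample_ids
    g = annotation.table.loc[probe_id]
    snps = genotypes.snps
    lo = min(g["tss"], g["tes"]) - window_bp
    hi = max(g["tss"], g["tes"]) + window_bp
    cis_ids = list(
        snps.index[(snps["chrom"] == g["chrom"]) & snps["pos"].between(lo, hi)]
    )
    y = expression.values.loc[probe_id, samples].to_numpy(float)
    base_cov = (
        covariates.matrix(samples)
        if covariates is not None
        else np.empty((len(samples), 0))
    )
    dos = genotypes.dosages.loc[samples, cis_ids].to_numpy(float)

    discovered: list[tuple[str, float]] = []
    conditioned = np.empty((len(samples), 0))
    remaining = list(range(len(cis_ids)))
    n = len(samples)
    while remaining:
        k_total = base_cov.shape[1] + conditioned.shape[1]
        dof = n - (k_total + 2)
        if dof <= 0:
            logger.info("stepwise stopped for %s: design no longer identifiable", probe_id)
            break
        cov = np.column_stack([base_cov, conditioned]) if k_total else np.empty((n, 0))
        cols = [j for j in remaining if np.ptp(dos[:, j]) > 0]
        if not cols:
            break
        x_r = _residualize(dos[:, cols], cov)
        # drop SNPs fully explained by what is already conditioned on
        norms = (x_r**2).sum(axis=0)
        ok = norms > 1e-10 * (dos[:, cols] ** 2).sum(axis=0).clip(min=1.0)
        if not ok.any():
            break
        cols = [c for c, good in zip(cols, ok) if good]
        y_r = _residualize(y[:, None], cov)[:, 0]
        beta, se, t, p = _scan_block(x_r[:, ok], y_r, dof)
        best = int(np.nanargmin(p))
        # tolerance: the boundary association's p can differ from the scan's
        # by an ulp (different BLAS summation order in the residualization)
        if not (p[best] <= p_threshold * (1 + 1e-9)):
            break
        j = cols[best]
        discovered.append((cis_ids[j], float(p[best])))
        conditioned = np.column_stack([conditioned, dos[:, [j]]])
        remaining = [r for r in remaining if r != j]
    return discovered


def conditional_signals(
    results: pd.DataFrame,
    genotypes: GenotypeTable,
    expression: ExpressionTable,
    annotation: GeneAnnotation,
    covariates: CovariateSet | None,
    fdr: float = 0.10,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Stepwise conditional analysis for every probe with a significant cis
    association at ``fdr``; the stepwise p threshold is the realized BH
    cutoff at that level."""
    cutoff = realized_bh_cutoff(results, fdr)
    rows = []
    if np.isnan(cutoff):
        return pd.DataFrame(columns=["probe_id", "gene_id", "rank", "snp_id", "conditional_p"])
    sig = results[(results["type"] == "cis") & (results["q"] <= fdr)]
    for probe_id, sub in sig.groupby("probe_id"):
        found = stepwise_conditional(
            probe_id, genotypes, expression, annotation, covariates, cutoff, window_bp
        )
        for rank, (snp_id, p) in enumerate(found, start=1):
            rows.append(
                {
                    "probe_id": probe_id,
                    "gene_id": sub["gene_id"].iloc[0],
                    "rank": rank,
                    "snp_id": snp_id,
                    "conditional_p": p,
                }
            )
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "rank", "snp_id", "conditional_p"])
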