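"""Expression preprocessing: probe filters, log2 + quantile normalization,
rank-based inverse normal transform, correlation-based outlier flagging, and
data-driven choice of how many expression PCs to use as covariates.

Ordering contract: probe filters -> outlier removal -> quantile normalization
-> expression PCs (on the normalized matrix) -> per-probe inverse normal
transform as the last step before model fitting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr

from .datatypes import CovariateSet, ExpressionTable, GeneAnnotation, GenotypeTable

logger = logging.getLogger(__name__)


def filter_probes(
    expr: ExpressionTable, annotation: GeneAnnotation, detection_p_max: float = 0.01
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Drop multi-mapping probes, probes containing a common SNP, and probes
    never detected (detection p >= threshold in every sample).

    A probe survives the detection filter if detected in at least one sample.
    Returns the filtered table and a per-filter removal report.
    """
    missing = [p for p in expr.probe_ids if p not in annotation.table.index]
    if missing:
        raise KeyError(f"probes absent from annotation: {missing[:5]}")
    annot = annotation.table.loc[expr.probe_ids]
    alive = pd.Series(True, index=expr.values.index)
    report = []

    def step(name: str, drop: pd.Series) -> None:
        drop = alive & drop
        report.append({"step": name, "n_removed": int(drop.sum())})
        alive[drop] = False

    step("multi_mapped", annot["multi_mapped"])
    step("contains_common_snp", annot["contains_common_snp"])
    if expr.detection_p is not None:
        detected = (expr.detection_p < detection_p_max).any(axis=1)
        step("not_detected", ~detected)
    else:
        report.append({"step": "not_detected", "n_removed": 0})
    kept = list(alive.index[alive])
    return expr.subset_probes(kept), pd.DataFrame(report)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across sample columns.

    Every column's sorted values are replaced by the mean sorted profile;
    ties within a column receive the mean of the reference values across the
    tied ranks, so the result is deterministic.
    """
    mat = values.to_numpy(float)
    n_probes, n_samples = mat.shape
    reference = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(n_samples):
        col = mat[:, j]
        order = np.argsort(col, kind="stable")
        ranked_ref = np.empty(n_probes)
        ranked_ref[order] = reference
        # average reference values over tied input values
        s = pd.Series(ranked_ref).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_expression(expr: ExpressionTable, log2: bool = True) -> ExpressionTable:
    """log2 transform (optional, for raw intensities) then quantile-normalize."""
    values = expr.values
    if log2:
        bad = values <= 0
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"nonpositive expression value at probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}; cannot log2-transform"
            )
        values = np.log2(values)
    return ExpressionTable(quantile_normalize(values), expr.detection_p)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform of one probe's values.

    Rank r (average for ties) maps to Phi^-1((r - c) / (n + 1 - 2c)) with the
    plotting-position offset c = 3/8 for n <= 10 and c = 1/2 otherwise.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("inverse normal transform needs n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("constant vector: ranks undefined for all-tied input")
    c = 0.375 if n <= 10 else 0.5
    ranks = rankdata(x, method="average")
    return norm.ppf((ranks - c) / (n + 1 - 2 * c))


def inverse_normal_transform_table(expr: ExpressionTable) -> ExpressionTable:
    """Apply the inverse normal transform independently to every probe row."""
    mat = np.vstack([inverse_normal_transform(row) for row in expr.values.to_numpy(float)])
    return ExpressionTable(
        pd.DataFrame(mat, index=expr.values.index, columns=expr.values.columns),
        expr.detection_p,
    )


def flag_outlier_samples(
    expr: ExpressionTable, threshold_sd: float = 3.0
) -> pd.Series:
    """Flag samples whose mean Spearman correlation to the others is more than
    ``threshold_sd`` SDs below the across-sample mean; iterate once after
    removing the first round of outliers."""
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if expr.values.shape[1] < 4:
        raise ValueError("outlier flagging needs >= 4 samples")
    flags = pd.Series(False, index=expr.values.columns)
    current = expr.values
    for _ in range(2):  # initial pass + one iteration after removal
        corr, _ = spearmanr(current.to_numpy(float))
        corr = np.atleast_2d(corr)
        np.fill_diagonal(corr, np.nan)
        mean_corr = np.nanmean(corr, axis=1)
        mu, sd = mean_corr.mean(), mean_corr.std(ddof=1)
        if sd == 0:
            break
        bad = mean_corr < mu - threshold_sd * sd
        if not bad.any():
            break
        flags[current.columns[bad]] = True
        current = current.loc[:, ~bad]
        if current.shape[1] < 4:
            break
    return flags


def expression_pcs(values: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k principal components of the probe-centered expression matrix,
    as per-sample coordinates (samples x PCs)."""
    mat = values.to_numpy(float)
    centered = mat - mat.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = (vt[:k].T * s[:k])
    for j in range(min(k, vt.shape[0])):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=values.columns, columns=[f"ePC{j+1}" for j in range(k)]
    )


def select_expression_pcs(
    expr: ExpressionTable,
    genotypes: GenotypeTable,
    annotation: GeneAnnotation,
    covariates_base: CovariateSet,
    k_grid=(0, 1, 2, 3, 4, 5),
    fdr: float = 0.05,
    window_bp: int = 1_000_000,
) -> tuple[int, pd.DataFrame]:
    """Choose the expression-PC count that maximizes cis-eQTL probe yield.

    For each k in ``k_grid`` the full cis scan runs with the base covariates
    plus the first k expression PCs; the count is the number of probes with at
    least one cis association at q <= ``fdr``.  Ties break toward smaller k.
    Returns (chosen k, per-k count table).
    """
    from .eqtl import bh_fdr, map_eqtl  # deferred: eqtl builds on this module's output

    n = len(expr.sample_ids)
    n_base = covariates_base.table.shape[1]
    for k in k_grid:
        if k >= n - (n_base + 2):
            raise ValueError(f"k={k} leaves no residual degrees of freedom at n={n}")
    pcs_all = expression_pcs(expr.values, max(k_grid)) if max(k_grid) else None
    expr_int = inverse_normal_transform_table(expr)
    rows = []
    best_k, best_count = None, -1
    for k in sorted(k_grid):
        cov_tab = covariates_base.table.copy()
        if k:
            cov_tab = cov_tab.join(pcs_all.iloc[:, :k])
        cov = CovariateSet(cov_tab)
        results = map_eqtl(
            genotypes, expr_int, annotation, cov, window_bp=window_bp, include_trans=False
        )
        results = bh_fdr(results)
        sig = results[(results["type"] == "cis") & (results["q"] <= fdr)]
        count = sig["probe_id"].nunique()
        rows.append({"k": k, "n_cis_probes": count})
        if count > best_count:
            best_k, best_count = k, count
    return best_k, pd.DataFrame(rows)
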