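"""Additive-model scan against a closed-form OLS oracle, cis/trans
classification against exhaustive interval checks, BH against the step-up
definition, and stepwise conditioning behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coloneqtl.datatypes import CovariateSet, ExpressionTable
from coloneqtl.eqtl import (
    bh_fdr,
    bh_qvalues,
    enumerate_cis_pairs,
    fit_additive_model,
    map_eqtl,
    realized_bh_cutoff,
    stepwise_conditional,
)

from conftest import make_annotation, make_genotypes


def ols_oracle(x, y, covariates):
    """Naive normal-equations solve for the dosage coefficient."""
    n = len(y)
    design = np.column_stack([np.ones(n), x, covariates])
    k = design.shape[1]
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ coef
    dof = n - k
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    beta, se = coef[1], np.sqrt(cov[1, 1])
    t = beta / se
    p = 2 * sps.t.sf(abs(t), dof)
    return beta, se, t, p


class TestEnumerateCisPairs:
    def _setup(self):
        # gene body 5,000,000..5,020,000 on '+'
        annot = make_annotation([("p0", "g0", "1", "+", 5_000_000, 5_020_000)])
        positions = [
            4_000_000,      # exactly window upstream of min(tss,tes): cis
            3_999_999,      # one bp beyond: trans
            5_010_000,      # inside gene: cis
            6_020_000,      # exactly window downstream of max: cis
            6_020_001,      # one beyond: trans
        ]
        geno = make_genotypes(np.zeros((4, 5)), positions=positions)
        return geno, annot

    def test_inclusive_window_bounds(self):
        geno, annot = self._setup()
        pairs = enumerate_cis_pairs(geno, annot, window_bp=1_000_000)
        cls = pairs.set_index("snp_id")["type"]
        assert cls["s0"] == "cis"
        assert cls["s1"] == "trans"
        assert cls["s2"] == "cis"
        assert cls["s3"] == "cis"
        assert cls["s4"] == "trans"

    def test_other_chromosome_is_trans(self):
        annot = make_annotation([("p0", "g0", "2", "+", 5_000_000, 5_020_000)])
        geno = make_genotypes(np.zeros((4, 1)), positions=[5_000_000], chrom="1")
        pairs = enumerate_cis_pairs(geno, annot)
        assert pairs["type"].iloc[0] == "trans"
        assert np.isnan(pairs["distance_bp"].iloc[0])

    def test_signed_distance_strand_oriented(self):
        annot = make_annotation(
            [
                ("pp", "gp", "1", "+", 5_000_000, 5_020_000),
                ("pm", "gm", "1", "-", 5_020_000, 5_000_000),
            ]
        )
        geno = make_genotypes(np.zeros((4, 1)), positions=[5_010_000])
        pairs = enumerate_cis_pairs(geno, annot).set_index("probe_id")
        assert pairs.loc["pp", "distance_bp"] == 10_000   # downstream of + TSS
        assert pairs.loc["pm", "distance_bp"] == 10_000   # 5,020,000 TSS, - strand

    def test_matches_brute_force(self, rng):
        positions = np.sort(rng.choice(20_000_000, 60, replace=False)) + 1
        geno = make_genotypes(np.zeros((4, 60)), positions=positions)
        rows = []
        for i in range(8):
            tss = int(rng.integers(1, 20_000_000))
            tes = tss + int(rng.integers(1_000, 100_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                tss, tes = tes, tss
            rows.append((f"p{i}", f"g{i}", "1", strand, tss, tes))
        annot = make_annotation(rows)
        pairs = enumerate_cis_pairs(geno, annot, window_bp=1_000_000)
        for _, row in pairs.iterrows():
            g = annot.table.loc[row["probe_id"]]
            pos = geno.snps.at[row["snp_id"], "pos"]
            lo = min(g["tss"], g["tes"]) - 1_000_000
            hi = max(g["tss"], g["tes"]) + 1_000_000
            expected = "cis" if lo <= pos <= hi else "trans"
            assert row["type"] == expected


class TestFitAdditiveModel:
    def test_noiseless_affine(self):
        x = np.arange(10, dtype=float) % 3
        y = 2 * x
        beta, se, t, p = fit_additive_model(x, y)
        assert beta == pytest.approx(2.0)
        assert p < 1e-12

    def test_orthogonal_dosage(self):
        x = np.array([1.0, -1, 1, -1, 1, -1]) + 1
        y = np.array([1.0, 1, -1, -1, 1, -1])  # x'y = 0 and mean-orthogonal
        y = y - y.mean()
        x_c = x - x.mean()
        y = y - (y @ x_c) / (x_c @ x_c) * x_c  # force exact orthogonality
        beta, *_ = fit_additive_model(x, y)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(12, 40))
            x = rng.integers(0, 3, n).astype(float)
            if np.ptp(x) == 0:
                continue
            cov = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            got = fit_additive_model(x, y, cov)
            expected = ols_oracle(x, y, cov)
            np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 30
        x = rng.integers(0, 3, n).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.5 * x + rng.normal(size=n)
        beta, se, t, p = fit_additive_model(x, y, cov)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([x, cov]))).fit()
        assert beta == pytest.approx(fit.params[1], abs=1e-10)
        assert se == pytest.approx(fit.bse[1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError):
            fit_additive_model(np.ones(10), np.arange(10.0))

    def test_rank_deficient_covariates_rejected(self, rng):
        x = rng.integers(0, 3, 20).astype(float)
        cov = np.column_stack([np.ones(20), np.ones(20) * 2])
        with pytest.raises(np.linalg.LinAlgError):
            fit_additive_model(x, rng.normal(size=20), cov)


def bh_brute_force(p):
    """O(m^2) literal evaluation of the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_single_p(self):
        assert bh_qvalues(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_worked_two_values(self):
        np.testing.assert_allclose(bh_qvalues(np.array([0.01, 0.04])), [0.02, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 50)))
        np.testing.assert_allclose(bh_qvalues(p), bh_brute_force(p), atol=1e-12)

    def test_q_monotone_in_p_and_at_least_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_grouped_by_class(self, rng):
        df = pd.DataFrame(
            {
                "p": rng.uniform(size=40),
                "type": ["cis"] * 25 + ["trans"] * 15,
            }
        )
        out = bh_fdr(df)
        for cls in ("cis", "trans"):
            sub = out[out["type"] == cls]
            np.testing.assert_allclose(
                sub["q"].to_numpy(), bh_brute_force(sub["p"].to_numpy()), atol=1e-12
            )

    def test_empty_group(self):
        out = bh_fdr(pd.DataFrame({"p": [], "type": []}))
        assert out.empty


def _scan_setup(rng, n=60, n_snps=30, n_genes=5, beta=0.0):
    positions = np.sort(rng.choice(9_000_000, n_snps, replace=False)) + 1
    dosages = rng.integers(0, 3, size=(n, n_snps)).astype(float)
    geno = make_genotypes(dosages, positions=positions)
    rows = [
        (f"p{i}", f"g{i}", "1", "+", 1_000_000 + i * 1_500_000, 1_010_000 + i * 1_500_000)
        for i in range(n_genes)
    ]
    annot = make_annotation(rows)
    expr_mat = rng.normal(size=(n_genes, n))
    if beta:
        expr_mat[0] += beta * dosages[:, 0]
    expr = ExpressionTable(
        pd.DataFrame(expr_mat, index=[r[0] for r in rows], columns=geno.sample_ids)
    )
    return geno, annot, expr


class TestMapEqtl:
    def test_scan_equals_per_pair_ols(self, rng):
        geno, annot, expr = _scan_setup(rng)
        cov = CovariateSet(
            pd.DataFrame(
                rng.normal(size=(60, 2)), index=geno.sample_ids, columns=["c1", "c2"]
            )
        )
        results = map_eqtl(geno, expr, annot, cov)
        check = results.sample(n=25, random_state=0)
        for _, row in check.iterrows():
            x = geno.dosage_vector(row["snp_id"])
            y = expr.values.loc[row["probe_id"]].to_numpy(float)
            beta, se, t, p = fit_additive_model(x, y, cov.matrix(geno.sample_ids))
            assert row["beta"] == pytest.approx(beta, abs=1e-10)
            assert row["p"] == pytest.approx(p, abs=1e-10)

    def test_probe_subset_reproduces_global_fit(self, rng):
        geno, annot, expr = _scan_setup(rng)
        full = map_eqtl(geno, expr, annot)
        sub_expr = expr.subset_probes(["p1", "p3"])
        sub = map_eqtl(geno, sub_expr, annot)
        merged = sub.merge(full, on=["snp_id", "probe_id"], suffixes=("_sub", "_full"))
        np.testing.assert_allclose(merged["beta_sub"], merged["beta_full"], atol=1e-12)
        np.testing.assert_allclose(merged["p_sub"], merged["p_full"], atol=1e-12)

    def test_constant_snps_skipped(self, rng):
        geno, annot, expr = _scan_setup(rng)
        geno.dosages.iloc[:, 4] = 1.0
        results = map_eqtl(geno, expr, annot)
        assert geno.snp_ids[4] not in set(results["snp_id"])


class TestStepwiseConditional:
    def test_nothing_below_threshold(self, rng):
        geno, annot, expr = _scan_setup(rng)
        found = stepwise_conditional("p0", geno, expr, annot, None, 1e-8)
        assert found == []

    def test_recovers_single_planted_signal(self, rng):
        geno, annot, expr = _scan_setup(rng, beta=1.0)
        found = stepwise_conditional("p0", geno, expr, annot, None, 1e-4)
        assert [s for s, _ in found] == ["s0"]

    def test_perfect_proxy_not_rediscovered(self, rng):
        geno, annot, expr = _scan_setup(rng, beta=1.0)
        # duplicate the causal SNP at a nearby position
        geno.dosages["s1"] = geno.dosages["s0"]
        found = stepwise_conditional("p0", geno, expr, annot, None, 1e-4)
        names = [s for s, _ in found]
        assert len(set(names) & {"s0", "s1"}) == 1

    def test_rejects_bad_threshold(self, rng):
        geno, annot, expr = _scan_setup(rng)
        with pytest.raises(ValueError):
            stepwise_conditional("p0", geno, expr, annot, None, 1.5)

    def test_realized_bh_cutoff(self, rng):
        geno, annot, expr = _scan_setup(rng, beta=2.0)
        results = bh_fdr(map_eqtl(geno, expr, annot))
        cutoff = realized_bh_cutoff(results, 0.10)
        sig = results[(results["type"] == "cis") & (results["q"] <= 0.10)]
        assert cutoff == sig["p"].max()
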