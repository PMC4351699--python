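"""Matched resampling machinery, the three enrichment analyses, nearest-TSS
distances, and the GWAS overlap report."""

import numpy as np
import pandas as pd
import pytest

from coloneqtl.datatypes import PeakSet, TraitSnpList
from coloneqtl.enrichment import (
    MatchingSpec,
    annotation_overlap_enrichment,
    best_cis_p_per_snp,
    eqtl_one_per_gene_sets,
    fst_annotator,
    fst_differentiation_report,
    gwas_eqtl_overlap,
    matching_bins,
    peak_annotator,
    sample_matched_sets,
    trait_enrichment,
    tss_distance,
)

from conftest import make_annotation, make_genotypes


def _universe(rng, n_snps=200, n_samples=40):
    mat = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    positions = np.sort(rng.choice(20_000_000, n_snps, replace=False)) + 1
    geno = make_genotypes(mat, positions=positions)
    freq = geno.dosages.mean(axis=0) / 2
    maf = pd.Series(np.minimum(freq, 1 - freq), index=geno.snp_ids)
    return geno, maf


class TestTssDistance:
    def test_snp_at_tss_zero(self):
        annot = make_annotation([("p0", "g0", "1", "+", 5_000, 9_000)])
        geno = make_genotypes(np.zeros((4, 1)), positions=[5_000])
        assert tss_distance(geno, annot).iloc[0] == 0

    def test_upstream_of_plus_gene_negative(self):
        annot = make_annotation(
            [("p0", "g0", "1", "+", 50_000, 90_000), ("p1", "g1", "1", "+", 500_000, 600_000)]
        )
        geno = make_genotypes(np.zeros((4, 1)), positions=[40_000])
        assert tss_distance(geno, annot).iloc[0] == -10_000

    def test_matches_brute_force(self, rng):
        geno, _ = _universe(rng)
        rows = []
        for i in range(10):
            tss = int(rng.integers(1, 20_000_000))
            strand = "+" if rng.random() < 0.5 else "-"
            tes = tss + 10_000 if strand == "+" else tss - 10_000
            rows.append((f"p{i}", f"g{i}", "1", strand, tss, tes))
        annot = make_annotation(rows)
        dist = tss_distance(geno, annot)
        table = annot.table
        for snp_id in geno.snp_ids:
            pos = geno.snps.at[snp_id, "pos"]
            best = min(table.index, key=lambda p: abs(pos - table.at[p, "tss"]))
            expected_mag = abs(pos - table.at[best, "tss"])
            assert abs(dist[snp_id]) == expected_mag

    def test_no_gene_on_chromosome_nan(self, rng):
        geno, _ = _universe(rng, n_snps=5)
        annot = make_annotation([("p0", "g0", "9", "+", 100, 200)])
        assert tss_distance(geno, annot).isna().all()


class TestSampleMatchedSets:
    def test_histograms_match_exactly(self, rng):
        geno, maf = _universe(rng)
        spec = MatchingSpec(n_sets=50, match_on=("maf",))
        target = list(rng.choice(geno.snp_ids, 20, replace=False))
        coll = sample_matched_sets(target, geno.snp_ids, maf, None, spec, seed=1)
        bins = matching_bins(pd.Index(geno.snp_ids), maf, None, spec)
        want = bins.loc[target].value_counts().sort_index()
        for s in coll.sets:
            assert len(s) == len(target)
            got = bins.loc[s].value_counts().sort_index()
            pd.testing.assert_series_equal(got, want)

    def test_single_target(self, rng):
        geno, maf = _universe(rng)
        spec = MatchingSpec(n_sets=10, match_on=("maf",))
        coll = sample_matched_sets([geno.snp_ids[0]], geno.snp_ids, maf, None, spec, 2)
        bins = matching_bins(pd.Index(geno.snp_ids), maf, None, spec)
        b0 = bins.loc[geno.snp_ids[0]]
        for s in coll.sets:
            assert len(s) == 1 and bins.loc[s[0]] == b0

    def test_degenerate_universe_equals_target(self, rng):
        geno, maf = _universe(rng, n_snps=10)
        target = geno.snp_ids
        spec = MatchingSpec(n_sets=5, match_on=("maf",))
        coll = sample_matched_sets(target, target, maf, None, spec, 3)
        for s in coll.sets:
            assert sorted(s) == sorted(target)

    def test_reproducible_given_seed(self, rng):
        geno, maf = _universe(rng)
        spec = MatchingSpec(n_sets=5, match_on=("maf",))
        target = list(rng.choice(geno.snp_ids, 10, replace=False))
        a = sample_matched_sets(target, geno.snp_ids, maf, None, spec, 7)
        b = sample_matched_sets(target, geno.snp_ids, maf, None, spec, 7)
        assert a.sets == b.sets

    def test_target_outside_universe_rejected(self, rng):
        geno, maf = _universe(rng, n_snps=10)
        with pytest.raises(KeyError):
            sample_matched_sets(
                ["ghost"], geno.snp_ids, maf, None, MatchingSpec(n_sets=2), 1
            )


def _results_frame(snp_ids, p_values, gene="g0", q=None):
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "probe_id": "p0",
            "gene_id": gene,
            "beta": 0.0,
            "se": 1.0,
            "t": 0.0,
            "p": p_values,
            "q": q if q is not None else p_values,
            "type": "cis",
            "distance_bp": 0,
        }
    )


class TestTraitEnrichment:
    def test_all_p_one_gives_p_one(self, rng):
        geno, maf = _universe(rng)
        results = _results_frame(geno.snp_ids, np.ones(len(geno.snp_ids)))
        trait = TraitSnpList("t", list(rng.choice(geno.snp_ids, 10, replace=False)))
        spec = MatchingSpec(n_sets=30, match_on=("maf",))
        res = trait_enrichment(trait, results, pd.Index(geno.snp_ids), maf, None, spec, 1)
        assert res.observed == 0
        assert (res.null_statistics == 0).all()
        assert res.empirical_p == 1.0

    def test_empty_trait_rejected(self, rng):
        geno, maf = _universe(rng)
        results = _results_frame(geno.snp_ids, np.ones(len(geno.snp_ids)))
        with pytest.raises(ValueError):
            trait_enrichment(
                TraitSnpList("t", []), results, pd.Index(geno.snp_ids), maf, None,
                MatchingSpec(n_sets=5), 1,
            )

    def test_best_cis_p_is_min_over_pairs(self):
        results = pd.concat(
            [
                _results_frame(["a", "b"], [0.5, 0.01], gene="g0"),
                _results_frame(["a"], [0.002], gene="g1"),
            ]
        )
        best = best_cis_p_per_snp(results)
        assert best["a"] == 0.002 and best["b"] == 0.01


class TestOnePerGeneSets:
    def _sig_results(self, rng, n_genes=3, snps_per_gene=4):
        frames = []
        for g in range(n_genes):
            ids = [f"g{g}snp{j}" for j in range(snps_per_gene)]
            frames.append(_results_frame(ids, np.full(snps_per_gene, 1e-5), gene=f"g{g}"))
        return pd.concat(frames, ignore_index=True)

    def test_single_snp_genes_identical_sets(self, rng):
        results = self._sig_results(rng, snps_per_gene=1)
        sets = eqtl_one_per_gene_sets(results, 0.05, 20, seed=1)
        assert all(s == sets[0] for s in sets)

    def test_sizes_equal_gene_count(self, rng):
        results = self._sig_results(rng, n_genes=5)
        sets = eqtl_one_per_gene_sets(results, 0.05, 15, seed=1)
        assert all(len(s) == 5 for s in sets)

    def test_per_gene_selection_uniform(self, rng):
        from scipy.stats import chisquare

        results = self._sig_results(rng, n_genes=1, snps_per_gene=4)
        sets = eqtl_one_per_gene_sets(results, 0.05, 10_000, seed=5)
        picks = pd.Series([s[0] for s in sets]).value_counts()
        stat, p = chisquare(picks.to_numpy())
        assert p > 0.001

    def test_no_significant_genes_rejected(self, rng):
        results = _results_frame(["a"], [0.9], q=[0.9])
        with pytest.raises(ValueError):
            eqtl_one_per_gene_sets(results, 0.05, 5, seed=1)


class TestAnnotationOverlap:
    def test_constant_false_annotator(self, rng):
        geno, maf = _universe(rng)
        sets = [list(rng.choice(geno.snp_ids, 10, replace=False)) for _ in range(20)]
        spec = MatchingSpec(n_sets=20, match_on=("maf",))
        res = annotation_overlap_enrichment(
            sets, pd.Index(geno.snp_ids), maf, None, spec,
            lambda ids: np.zeros(len(ids), bool), "two_layer_pairs", 1,
        )
        assert res.observed == 0
        assert res.empirical_p == 1.0  # all ties count as >=

    def test_mannwhitney_matches_brute_force(self, rng):
        geno, maf = _universe(rng)
        # fixed small count vectors via a deterministic annotator over sets
        sets_a = [["s0"], ["s1"], ["s0"], ["s2"]]
        in_peak = {"s0": True, "s1": False, "s2": True}
        annot = lambda ids: np.array([in_peak.get(i, False) for i in ids])
        spec = MatchingSpec(n_sets=4, match_on=("maf",))
        res = annotation_overlap_enrichment(
            sets_a, pd.Index(geno.snp_ids), maf, None, spec, annot,
            "two_layer_mannwhitney", 3,
        )
        eqtl_counts = res.extra["eqtl_counts"]
        u_brute = sum(
            (x > y) + 0.5 * (x == y) for x in eqtl_counts for y in res.null_statistics
        )
        assert res.extra["u_statistic"] == pytest.approx(u_brute)

    def test_unknown_mode_rejected(self, rng):
        geno, maf = _universe(rng)
        with pytest.raises(ValueError):
            annotation_overlap_enrichment(
                [["s0"]], pd.Index(geno.snp_ids), maf, None,
                MatchingSpec(n_sets=1, match_on=("maf",)),
                lambda ids: np.zeros(len(ids), bool), "bogus", 1,
            )

    def test_peak_annotator_interval_lookup(self, rng):
        geno, _ = _universe(rng, n_snps=30)
        pos = geno.snps["pos"].to_numpy()
        iv = pd.DataFrame({"chrom": "1", "start": pos[:10] - 1, "end": pos[:10]})
        peaks = PeakSet("m", iv)
        hits = peak_annotator(peaks, geno)(geno.snp_ids)
        # brute force: 1-based pos inside half-open [start, end)
        expected = []
        for p in pos:
            expected.append(any(s <= p - 1 < e for s, e in zip(iv["start"], iv["end"])))
        assert hits.tolist() == expected
        assert hits[:10].all() and not hits[10:].any()


class TestFstReport:
    def _fst(self, snp_ids, thetas):
        return pd.DataFrame({"theta_hat": thetas}, index=snp_ids)

    def test_zero_theta_zero_fraction(self):
        results = _results_frame(["a", "b"], [1e-6, 1e-6])
        fst = self._fst(["a", "b"], [0.0, 0.0])
        rep = fst_differentiation_report(results, 0.1, fst)
        assert rep["fraction_differentiated"] == 0

    def test_strict_threshold(self):
        results = _results_frame(["a", "b"], [1e-6, 1e-6])
        fst = self._fst(["a", "b"], [0.25, 0.2500001])
        rep = fst_differentiation_report(results, 0.1, fst)
        assert rep["n_differentiated"] == 1  # exactly 0.25 not counted

    def test_tally_matches_brute_force(self, rng):
        snp_ids = [f"s{i}" for i in range(50)]
        results = _results_frame(snp_ids, rng.uniform(0, 0.2, 50))
        thetas = rng.uniform(-0.05, 0.6, 50)
        thetas[:5] = np.nan
        fst = self._fst(snp_ids, thetas)
        rep = fst_differentiation_report(results, 0.1, fst)
        sig = results[results["q"] <= 0.1]["snp_id"]
        t = fst["theta_hat"].reindex(sig).dropna()
        assert rep["n_differentiated"] == int((t > 0.25).sum())
        assert rep["n_with_fst"] == len(t)

    def test_fst_annotator_missing_false(self):
        fst = self._fst(["a"], [0.5])
        ann = fst_annotator(fst, 0.25)
        assert ann(["a", "zz"]).tolist() == [True, False]


class TestGwasOverlap:
    def test_disjoint_no_rows(self):
        results = _results_frame(["a"], [1e-6])
        proxies = pd.DataFrame(columns=["target", "proxy", "r2", "distance_bp"])
        out = gwas_eqtl_overlap({"CD": TraitSnpList("CD", ["zzz"])}, results, 0.1, proxies)
        assert out.empty

    def test_self_hit(self):
        results = _results_frame(["a"], [1e-6])
        proxies = pd.DataFrame(columns=["target", "proxy", "r2", "distance_bp"])
        out = gwas_eqtl_overlap({"CD": TraitSnpList("CD", ["a"])}, results, 0.1, proxies)
        assert len(out) == 1
        assert out["r2"].iloc[0] == 1.0

    def test_matches_set_algebra(self, rng):
        snp_ids = [f"s{i}" for i in range(30)]
        results = _results_frame(snp_ids, rng.uniform(0, 0.3, 30))
        trait = TraitSnpList("CD", ["s1", "s5", "s9"])
        proxies = pd.DataFrame(
            {
                "target": ["s1", "s5"],
                "proxy": ["s2", "s6"],
                "r2": [0.95, 0.85],
                "distance_bp": [100, 200],
            }
        )
        out = gwas_eqtl_overlap({"CD": trait}, results, 0.1, proxies)
        sig = set(results[results["q"] <= 0.1]["snp_id"])
        expected = ( {"s1", "s5", "s9"} | {"s2", "s6"} ) & sig
        assert set(out["eqtl_snp"]) == expected
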