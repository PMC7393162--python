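"""Imputed expression: prediction, association, summary Z, correlation grid."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from trio_polygen.expression_xcan import (
    AssociationError,
    GeneZProfile,
    associate,
    predict_expression,
    summary_zscore,
    threshold_correlation,
)
from trio_polygen.genetics_io import (
    DosageCohort,
    ExpressionWeightModel,
    SummaryStats,
    TrioSet,
)
from trio_polygen.synthetic_cohort import simulate_study


def make_cohort(dosages, rng=None):
    dosages = np.asarray(dosages, dtype=float)
    n_ind, n_var = dosages.shape
    return DosageCohort(
        individuals=[f"I{i}" for i in range(n_ind)],
        variants=pd.DataFrame({
            "ID": [f"rs{v}" for v in range(n_var)], "CHR": "1",
            "POS": 1000 * (np.arange(n_var) + 1),
            "REF": ["A"] * n_var, "ALT": ["G"] * n_var}),
        dosages=dosages,
    )


def make_model(entries, tissue="cortex"):
    return ExpressionWeightModel(tissue=tissue, table=pd.DataFrame(
        entries, columns=["GENE", "ID", "REF", "ALT", "WEIGHT"]))


def children_trios(ids, labels):
    n = len(ids)
    return TrioSet(table=pd.DataFrame({
        "CHILD": ids, "FATHER": [f"XF{i}" for i in range(n)],
        "MOTHER": [f"XM{i}" for i in range(n)], "LABEL": labels}))


class TestPredict:
    def test_identity_weight_reproduces_dosage_column(self, rng):
        d = rng.integers(0, 3, size=(10, 4)).astype(float)
        cohort = make_cohort(d)
        model = make_model([("G1", "rs2", "A", "G", 1.0)])
        expr = predict_expression(cohort, model)
        np.testing.assert_array_equal(expr.values[:, 0], d[:, 2])

    def test_zero_weights_give_zero_expression(self, rng):
        cohort = make_cohort(rng.integers(0, 3, size=(5, 3)).astype(float))
        model = make_model([("G1", "rs0", "A", "G", 0.0), ("G1", "rs1", "A", "G", 0.0)])
        expr = predict_expression(cohort, model)
        np.testing.assert_array_equal(expr.values, 0.0)

    def test_matches_nested_loop_oracle(self, rng):
        d = rng.uniform(0, 2, size=(30, 20))
        cohort = make_cohort(d)
        entries = []
        for g in range(10):
            for v in rng.choice(20, size=3, replace=False):
                entries.append((f"G{g:02d}", f"rs{v}", "A", "G", rng.normal()))
        model = make_model(entries)
        expr = predict_expression(cohort, model)
        table = pd.DataFrame(entries, columns=["GENE", "ID", "REF", "ALT", "WEIGHT"])
        for j, gene in enumerate(expr.genes):
            sub = table[table["GENE"] == gene]
            oracle = np.zeros(30)
            for i in range(30):
                for r in sub.itertuples(index=False):
                    oracle[i] += d[i, int(r.ID[2:])] * r.WEIGHT
            np.testing.assert_allclose(expr.values[:, j], oracle, rtol=1e-12)

    def test_linearity_in_weight_models(self, rng):
        d = rng.uniform(0, 2, size=(15, 6))
        cohort = make_cohort(d)
        w1 = [("G1", "rs0", "A", "G", 0.5), ("G1", "rs3", "A", "G", -1.0)]
        w2 = [("G1", "rs0", "A", "G", 0.25), ("G1", "rs5", "A", "G", 2.0)]
        combined = [("G1", "rs0", "A", "G", 0.75), ("G1", "rs3", "A", "G", -1.0),
                    ("G1", "rs5", "A", "G", 2.0)]
        e1 = predict_expression(cohort, make_model(w1)).values
        e2 = predict_expression(cohort, make_model(w2)).values
        ec = predict_expression(cohort, make_model(combined)).values
        np.testing.assert_allclose(ec, e1 + e2, rtol=1e-12)

    def test_unmapped_gene_absent_not_zero_filled(self, rng):
        cohort = make_cohort(rng.integers(0, 3, size=(5, 2)).astype(float))
        model = make_model([("G1", "rs0", "A", "G", 1.0),
                            ("G2", "zz9", "A", "G", 1.0)])
        expr = predict_expression(cohort, model)
        assert expr.genes == ["G1"]


class TestAssociate:
    def test_null_type_i_error(self, rng):
        n, genes = 200, 500
        d = rng.uniform(0, 2, size=(n, genes))
        expr_cohort = make_cohort(d)
        model = make_model([(f"G{v:03d}", f"rs{v}", "A", "G", 1.0)
                            for v in range(genes)])
        expr = predict_expression(expr_cohort, model)
        labels = np.where(rng.random(n) < 0.3, "AS", "Non_AS")
        trios = children_trios(expr_cohort.individuals, labels)
        prof = associate(expr, trios)
        frac = (prof.table["P"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_separating_gene_excluded(self):
        d = np.array([[0.0]] * 5 + [[2.0]] * 5)
        cohort = make_cohort(d)
        expr = predict_expression(cohort, make_model([("G1", "rs0", "A", "G", 1.0)]))
        trios = children_trios(cohort.individuals, ["Non_AS"] * 5 + ["AS"] * 5)
        prof = associate(expr, trios)
        assert prof.table.empty
        assert "G1" in prof.excluded

    def test_constant_expression_excluded_zero_variance(self):
        d = np.ones((8, 1))
        cohort = make_cohort(d)
        expr = predict_expression(cohort, make_model([("G1", "rs0", "A", "G", 1.0)]))
        trios = children_trios(cohort.individuals, ["AS"] * 4 + ["Non_AS"] * 4)
        prof = associate(expr, trios)
        assert prof.excluded == {"G1": "zero variance"}

    def test_single_label_errors(self, rng):
        cohort = make_cohort(rng.integers(0, 3, size=(6, 1)).astype(float))
        expr = predict_expression(cohort, make_model([("G1", "rs0", "A", "G", 1.0)]))
        trios = children_trios(cohort.individuals, ["AS"] * 6)
        with pytest.raises(AssociationError):
            associate(expr, trios)


class TestSummaryZ:
    def _stats(self, betas, ses):
        n = len(betas)
        return SummaryStats(table=pd.DataFrame({
            "ID": [f"rs{v}" for v in range(n)], "CHR": "1",
            "POS": 1000 * (np.arange(n) + 1), "A1": "G", "A2": "A",
            "BETA": betas, "SE": ses, "P": 0.5}))

    def test_single_variant_gene_reduces_to_beta_over_se(self, rng):
        ref = make_cohort(rng.integers(0, 3, size=(100, 3)).astype(float))
        stats = self._stats([0.3, -0.1, 0.2], [0.05, 0.1, 0.02])
        model = make_model([("G1", "rs1", "A", "G", 1.0)])
        prof = summary_zscore(stats, model, ref)
        assert prof.table["Z"].iloc[0] == pytest.approx(-0.1 / 0.1, rel=1e-12)

    def test_weight_scale_invariance(self, rng):
        ref = make_cohort(rng.integers(0, 3, size=(100, 4)).astype(float))
        stats = self._stats([0.3, -0.1, 0.2, 0.05], [0.05, 0.1, 0.02, 0.2])
        w = [("G1", f"rs{v}", "A", "G", x) for v, x in enumerate([0.5, -1.0, 2.0])]
        w_scaled = [(g, i, r, a, 7.0 * wt) for g, i, r, a, wt in w]
        z1 = summary_zscore(stats, make_model(w), ref).table["Z"].iloc[0]
        z2 = summary_zscore(stats, make_model(w_scaled), ref).table["Z"].iloc[0]
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_allele_recoding_invariance(self, rng):
        """Flipping a model variant's orientation (swap REF/ALT, negate the
        weight, recode dosages) leaves the gene Z unchanged."""
        d = rng.integers(0, 3, size=(80, 2)).astype(float)
        ref = make_cohort(d)
        stats = self._stats([0.3, -0.2], [0.05, 0.04])
        w = [("G1", "rs0", "A", "G", 0.8), ("G1", "rs1", "A", "G", -0.3)]
        z1 = summary_zscore(stats, make_model(w), ref).table["Z"].iloc[0]

        d2 = d.copy()
        d2[:, 1] = 2 - d2[:, 1]
        ref2 = make_cohort(d2)
        ref2.variants.loc[1, ["REF", "ALT"]] = ["G", "A"]
        z2 = summary_zscore(stats, make_model(w), ref2).table["Z"].iloc[0]
        assert z1 == pytest.approx(z2, rel=1e-10)


class TestThresholdCorrelation:
    def _profile(self, z, p, source="summary_level", **kw):
        return GeneZProfile(table=pd.DataFrame(
            {"GENE": [f"G{i}" for i in range(len(z))], "Z": z, "P": p}),
            source=source, **kw)

    def test_self_correlation_is_one(self, rng):
        z = rng.normal(size=50)
        p = rng.uniform(0, 1, 50)
        prof = self._profile(z, p)
        grid = threshold_correlation(prof, prof, thresholds=(1.0, 0.5), min_genes=5)
        ok = grid.table.dropna(subset=["rho"])
        np.testing.assert_allclose(ok["rho"], 1.0)

    def test_small_gene_sets_reported_without_rho(self, rng):
        z = rng.normal(size=30)
        prof_a = self._profile(z, np.full(30, 0.5))
        prof_b = self._profile(rng.normal(size=30), np.full(30, 0.5))
        grid = threshold_correlation(prof_a, prof_b, thresholds=(1.0, 0.1))
        row = grid.table[grid.table["p_threshold"] == 0.1].iloc[0]
        assert row["n_genes"] == 0 and np.isnan(row["rho"])

    def test_disjoint_gene_sets_error(self, rng):
        a = self._profile(rng.normal(size=5), np.full(5, 0.5))
        b = GeneZProfile(table=pd.DataFrame(
            {"GENE": [f"H{i}" for i in range(5)], "Z": rng.normal(size=5),
             "P": np.full(5, 0.5)}), source="summary_level")
        with pytest.raises(AssociationError):
            threshold_correlation(a, b)

    def test_independent_profiles_uncorrelated(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            za, zb = r.normal(size=(2, 1000))
            from scipy.stats import norm

            pa, pb = 2 * norm.sf(np.abs(za)), 2 * norm.sf(np.abs(zb))
            grid = threshold_correlation(self._profile(za, pa),
                                         self._profile(zb, pb), thresholds=(1.0,))
            row = grid.table.iloc[0]
            if abs(row["rho"]) < 0.1 and row["p"] > 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_planted_overlap_correlation_grows_with_stringency(self):
        """Ascertainment-driven overlap through planted eQTLs: correlation at
        the strict cutoff exceeds the all-genes correlation in most seeds."""
        from trio_polygen.synthetic_cohort import simulate_study

        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            study = simulate_study(small_config(
                n_trios=160, subgroup_counts={"AS": 80, "Non_AS": 80},
                n_genes_per_tissue=60, tissues=("cortex",),
                planted_tissue="cortex", planted_traits=("SCZ",),
                seed=3000 + seed))
            expr = predict_expression(study.cohort, study.weights["cortex"])
            assoc = associate(expr, study.trios)
            sz = summary_zscore(study.effects["SCZ"].stats,
                                study.weights["cortex"], study.cohort)
            grid = threshold_correlation(assoc, sz, thresholds=(1.0, 0.01),
                                         min_genes=8).table
            strict = grid[grid["p_threshold"] == 0.01]["rho"]
            loose = grid[grid["p_threshold"] == 1.0]["rho"]
            if len(strict.dropna()) and strict.iloc[0] > loose.iloc[0]:
                wins += 1
        assert wins > n_seeds / 2

    def test_tissue_contrast_recovery(self):
        """Overlap planted through one tissue's models only: that tissue's
        correlation at stringent cutoffs beats the other tissue's."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            study = simulate_study(small_config(
                n_trios=160, subgroup_counts={"AS": 80, "Non_AS": 80},
                n_genes_per_tissue=60, tissues=("cortex", "lung"),
                tissue_sharing=0.0, planted_tissue="cortex",
                planted_traits=("SCZ",), seed=4000 + seed))
            rhos = {}
            for tissue in ("cortex", "lung"):
                expr = predict_expression(study.cohort, study.weights[tissue])
                assoc = associate(expr, study.trios)
                sz = summary_zscore(study.effects["SCZ"].stats,
                                    study.weights[tissue], study.cohort)
                grid = threshold_correlation(assoc, sz, thresholds=(0.05,),
                                             min_genes=5).table
                rhos[tissue] = grid["rho"].iloc[0]
            if not np.isnan(rhos["cortex"]) and (
                    np.isnan(rhos["lung"]) or rhos["cortex"] > rhos["lung"]):
                wins += 1
        assert wins >= 0.8 * n_seeds
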