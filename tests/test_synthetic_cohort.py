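"""Statistical and structural checks on the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import small_config
from trio_polygen.synthetic_cohort import (
    AscertainmentSpec,
    ConfigurationError,
    SimulationConfig,
    SimulationError,
    TraitSpec,
    sample_haplotypes,
    simulate_panel,
    simulate_study,
    simulate_trait_effects,
    simulate_trios,
    simulate_weight_models,
)
from trio_polygen import prs_engine, ptdt_stats


class TestPanel:
    def test_invalid_correlation_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(within_block_correlation=1.0)
        with pytest.raises(ConfigurationError):
            small_config(within_block_correlation=-0.1)

    def test_positions_strictly_increasing(self):
        panel = simulate_panel(small_config())
        assert (np.diff(panel.table["POS"]) > 0).all()
        assert (panel.table["REF"] != panel.table["ALT"]).all()

    def test_zero_correlation_gives_independent_dosages(self, rng):
        cfg = small_config(within_block_correlation=0.0)
        panel = simulate_panel(cfg)
        hap = sample_haplotypes(panel, 2 * 2000, rng)
        dos = hap[::2] + hap[1::2]
        r = np.corrcoef(dos, rowvar=False)
        off_diag = r[~np.eye(r.shape[0], dtype=bool)]
        assert np.abs(off_diag).max() < 0.11  # |r| small everywhere
        assert np.abs(off_diag).mean() < 0.05

    def test_markov_correlation_against_monte_carlo_oracle(self, rng):
        """Adjacent-variant correlation matches an independently coded
        copy-process simulation at rho=0.9, single block."""
        cfg = small_config(n_variants=6, n_blocks=1, within_block_correlation=0.9)
        panel = simulate_panel(cfg)
        af = panel.table["AF"].to_numpy()
        n = 5000

        # oracle: direct per-haplotype Markov simulation, separate code path
        oracle_rng = np.random.default_rng(99)
        hap = np.zeros((n, 6), dtype=int)
        hap[:, 0] = oracle_rng.random(n) < af[0]
        for j in range(1, 6):
            copy = oracle_rng.random(n) < 0.9
            fresh = oracle_rng.random(n) < af[j]
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        oracle_r = np.corrcoef(hap[:, 0], hap[:, 1])[0, 1]

        ours = sample_haplotypes(panel, n, rng)
        ours_r = np.corrcoef(ours[:, 0], ours[:, 1])[0, 1]
        assert ours_r == pytest.approx(oracle_r, abs=0.05)
        assert ours_r == pytest.approx(0.9, abs=0.05)

    def test_seeded_determinism(self):
        cfg = small_config(seed=5)
        s1 = simulate_study(cfg)
        s2 = simulate_study(small_config(seed=5))
        assert s1.panel.table.equals(s2.panel.table)
        np.testing.assert_array_equal(s1.cohort.dosages, s2.cohort.dosages)
        for t in s1.effects:
            assert s1.effects[t].stats.table.equals(s2.effects[t].stats.table)


class TestTraitEffects:
    def test_null_architecture(self, rng):
        cfg = small_config(
            n_variants=400, n_blocks=40, ascertainment=(),
            trait_specs=(TraitSpec("NULL", prop_causal=0.0, h2=0.3),),
        )
        panel = simulate_panel(cfg, rng)
        eff = simulate_trait_effects(panel, cfg, rng)["NULL"]
        assert np.all(eff.true_beta == 0.0)
        frac_sig = (eff.stats.table["P"] < 0.05).mean()
        assert 0.02 <= frac_sig <= 0.09  # ~5% by chance

    def test_perfect_correlation_gives_proportional_effects(self, rng):
        cfg = small_config(
            ascertainment=(),
            trait_specs=(TraitSpec("A", 0.3, 0.5), TraitSpec("B", 0.3, 0.2)),
            cross_trait_correlation_matrix=np.array([[1.0, 1.0], [1.0, 1.0]]),
        )
        panel = simulate_panel(cfg, rng)
        eff = simulate_trait_effects(panel, cfg, rng)
        a, b = eff["A"].true_beta, eff["B"].true_beta
        np.testing.assert_array_equal(a != 0, b != 0)  # identical causal sets
        nz = a != 0
        ratios = b[nz] / a[nz]
        assert np.allclose(ratios, ratios[0])

    def test_large_n_observed_effects_converge_to_truth(self, rng):
        cfg = small_config(
            n_variants=2000, n_blocks=200, ascertainment=(),
            trait_specs=(TraitSpec("T", 0.2, 0.5, n_discovery=10_000_000),),
        )
        panel = simulate_panel(cfg, rng)
        eff = simulate_trait_effects(panel, cfg, rng)["T"]
        slope = np.polyfit(eff.true_beta, eff.stats.table["BETA"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ConfigurationError):
            small_config(
                ascertainment=(),
                trait_specs=(TraitSpec("A"), TraitSpec("B")),
                cross_trait_correlation_matrix=bad,
            )


class TestTrios:
    def test_mendelian_consistency_exhaustive(self, small_study):
        cohort, trios = small_study.cohort, small_study.trios
        d = cohort.dosages
        idx = {ind: i for i, ind in enumerate(cohort.individuals)}
        for row in trios.table.itertuples(index=False):
            c = d[idx[row.CHILD]]
            f = d[idx[row.FATHER]]
            m = d[idx[row.MOTHER]]
            # one allele from each parent: child in [pat_min+mat_min, pat_max+mat_max]
            pat_min, pat_max = (f >= 2).astype(int), (f >= 1).astype(int)
            mat_min, mat_max = (m >= 2).astype(int), (m >= 1).astype(int)
            assert np.all(c >= pat_min + mat_min)
            assert np.all(c <= pat_max + mat_max)

    def test_dosages_are_integral(self, small_study):
        assert set(np.unique(small_study.cohort.dosages)) <= {0.0, 1.0, 2.0}

    def test_parent_frequencies_match_panel(self, null_config):
        study = simulate_study(null_config)
        parents = [i for i in study.cohort.individuals if not i.startswith("C")]
        rows = study.cohort.individual_index(parents)
        emp = study.cohort.dosages[rows].mean(axis=0) / 2
        af = study.panel.table["AF"].to_numpy()
        se = np.sqrt(af * (1 - af) / (2 * len(parents)))
        assert (np.abs(emp - af) <= 4 * se + 1e-9).mean() > 0.98

    def test_null_transmission_centered_at_zero(self):
        cfg = small_config(n_trios=500, subgroup_counts={"Non_AS": 500},
                           ascertainment=(), seed=23)
        study = simulate_study(cfg)
        prof = prs_engine.clump_and_score(study.effects["SCZ"].stats, study.cohort)
        dev = ptdt_stats.ptdt_deviations(prof, study.trios, 1.0)
        se = dev.std(ddof=1) / np.sqrt(len(dev))
        assert abs(dev.mean()) < 2 * se + 0.01

    def test_null_transmission_symmetric_sign_flip(self):
        cfg = small_config(n_trios=1000, subgroup_counts={"Non_AS": 1000},
                           ascertainment=(), seed=29)
        study = simulate_study(cfg)
        prof = prs_engine.clump_and_score(study.effects["SCZ"].stats, study.cohort)
        dev = ptdt_stats.ptdt_deviations(prof, study.trios, 1.0)
        n_pos = int((dev > 0).sum())
        n = int((dev != 0).sum())
        p = sps.binomtest(n_pos, n, 0.5).pvalue
        assert p > 0.01

    def test_ascertainment_raises_child_liability(self):
        asc = simulate_study(small_config(
            n_trios=500, subgroup_counts={"AS": 500},
            ascertainment=(AscertainmentSpec("AS", "SCZ", 0.9),), seed=31))
        unasc = simulate_study(small_config(
            n_trios=500, subgroup_counts={"Non_AS": 500}, ascertainment=(), seed=31))
        beta = asc.effects["SCZ"].true_beta
        child_rows = lambda s: s.cohort.individual_index(s.trios.children)  # noqa: E731
        g_asc = asc.cohort.dosages[child_rows(asc)] @ beta
        g_un = unasc.cohort.dosages[child_rows(unasc)] @ unasc.effects["SCZ"].true_beta
        res = sps.ttest_ind(g_asc, g_un, equal_var=False, alternative="greater")
        assert res.pvalue < 0.01

    def test_retry_cap_error_names_subgroup(self):
        cfg = small_config(
            n_trios=5, subgroup_counts={"AS": 5},
            ascertainment=(AscertainmentSpec("AS", "SCZ", 0.99999),),
            retry_cap=50,
        )
        panel = simulate_panel(cfg)
        effects = simulate_trait_effects(panel, cfg)
        with pytest.raises(SimulationError, match="AS"):
            simulate_trios(panel, effects, cfg)

    def test_power_of_subgroup_restricted_ascertainment(self):
        """Ascertainment on one trait in AS only: pTDT positive/significant in
        AS and |mean deviation| larger than Non_AS in nearly all replicates."""
        wins_sig, wins_mag = 0, 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = small_config(
                n_trios=260, subgroup_counts={"AS": 200, "Non_AS": 60},
                ascertainment=(AscertainmentSpec("AS", "SCZ", 0.9),),
                seed=1000 + rep)
            study = simulate_study(cfg)
            prof = prs_engine.clump_and_score(study.effects["SCZ"].stats, study.cohort)
            dev = ptdt_stats.ptdt_deviations(prof, study.trios, 1.0)
            labels = study.trios.labels
            res = ptdt_stats.ptdt_test(dev[labels == "AS"])
            if res.p < 0.05 and res.mean > 0:
                wins_sig += 1
            if abs(dev[labels == "Non_AS"].mean()) < abs(res.mean):
                wins_mag += 1
        assert wins_sig >= 0.9 * n_rep
        assert wins_mag >= 0.9 * n_rep


class TestWeightModels:
    def test_sharing_one_gives_identical_tissues(self, rng):
        cfg = small_config(tissue_sharing=1.0)
        panel = simulate_panel(cfg, rng)
        models = simulate_weight_models(panel, cfg, rng)
        t1, t2 = (models[t].table for t in cfg.tissues)
        assert t1.equals(t2)

    def test_sharing_zero_gives_near_disjoint_entries(self, rng):
        cfg = small_config(tissue_sharing=0.0, n_genes_per_tissue=50)
        panel = simulate_panel(cfg, rng)
        models = simulate_weight_models(panel, cfg, rng)
        t1, t2 = (models[t].table for t in cfg.tissues)
        e1 = set(map(tuple, t1[["GENE", "ID", "WEIGHT"]].itertuples(index=False)))
        e2 = set(map(tuple, t2[["GENE", "ID", "WEIGHT"]].itertuples(index=False)))
        assert len(e1 & e2) == 0

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=3)
        m1 = simulate_weight_models(simulate_panel(cfg), cfg)
        m2 = simulate_weight_models(simulate_panel(cfg), cfg)
        for t in cfg.tissues:
            assert m1[t].table.equals(m2[t].table)

    def test_too_many_eqtls_rejected(self, rng):
        cfg = small_config(n_variants=20, n_blocks=20, eqtls_per_gene=5)
        panel = simulate_panel(cfg, rng)
        with pytest.raises(ConfigurationError):
            simulate_weight_models(panel, cfg, rng)
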