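"""Pedigree growth, gene dropping, and phenotype generation."""
import numpy as np
import pytest

from pedsur.preprocess import ld_r2
from pedsur.simulate import (
    MAP4_PANEL, FamilyTemplate, SimConfig, drop_genes, gaw_like_scenario,
    simulate_pedigree_structure, simulate_phenotypes,
)


class TestPedigreeStructure:
    def test_minimal_template(self):
        cfg = SimConfig(n_families=1, template=FamilyTemplate((2, 2), 1))
        ped = simulate_pedigree_structure(cfg, seed=0)
        assert ped.n_individuals == 4
        assert ped.n_founders == 2

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_families=5)
        assert simulate_pedigree_structure(cfg, 3) == simulate_pedigree_structure(cfg, 3)
        assert not simulate_pedigree_structure(cfg, 3) == simulate_pedigree_structure(cfg, 4)

    def test_default_template_matches_study_scale(self):
        # 20 multigenerational families; the emulated study averaged 42
        # subjects per family (range 21-75)
        cfg = SimConfig(n_families=20)
        ped = simulate_pedigree_structure(cfg, seed=17)
        total = ped.n_individuals
        assert 20 * 21 <= total <= 20 * 75
        assert 21 <= total / 20 <= 75

    def test_parents_sexes_consistent(self):
        cfg = SimConfig(n_families=3)
        ped = simulate_pedigree_structure(cfg, seed=2)
        tab = ped.table.set_index("individual_id")
        for r in ped.table.itertuples():
            if r.father_id is not None:
                assert tab.loc[r.father_id, "sex"] == 1
                assert tab.loc[r.mother_id, "sex"] == 2


class TestDropGenes:
    def test_mendelian_consistency_exhaustive(self):
        cfg = SimConfig(n_families=10, mafs=np.full(6, 0.4),
                        effects=np.zeros((2, 6)))
        ped = simulate_pedigree_structure(cfg, seed=6)
        geno = drop_genes(ped, cfg.mafs, seed=7)
        idx = {s: i for i, s in enumerate(geno.subject_ids)}
        transmissible = {0.0: {0.0}, 1.0: {0.0, 1.0}, 2.0: {1.0}}
        for r in ped.table.itertuples():
            if r.father_id is None:
                continue
            child = geno.dosages[idx[r.individual_id]]
            dad = geno.dosages[idx[r.father_id]]
            mom = geno.dosages[idx[r.mother_id]]
            for c, f, m in zip(child, dad, mom):
                allowed = {a + b for a in transmissible[f] for b in transmissible[m]}
                assert c in allowed

    def test_homozygous_parents_force_child(self):
        # covered by the exhaustive check; assert the two degenerate cases hit
        transmissible = {0.0: {0.0}, 2.0: {1.0}}
        assert {a + b for a in transmissible[0.0] for b in transmissible[0.0]} == {0.0}
        assert {a + b for a in transmissible[2.0] for b in transmissible[2.0]} == {2.0}

    def test_determinism(self):
        cfg = SimConfig(n_families=3, mafs=np.full(4, 0.3), effects=np.zeros((2, 4)))
        ped = simulate_pedigree_structure(cfg, seed=1)
        g1 = drop_genes(ped, cfg.mafs, seed=5)
        g2 = drop_genes(ped, cfg.mafs, seed=5)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_ld_pair_reaches_target_r2(self):
        cfg = SimConfig(n_families=500, template=FamilyTemplate((2, 2), 0),
                        mafs=np.array([0.3, 0.3]), effects=np.zeros((2, 2)))
        ped = simulate_pedigree_structure(cfg, seed=30)
        geno = drop_genes(ped, cfg.mafs, seed=31, ld_pairs=((0, 1, 0.02),))
        r2 = ld_r2(geno, geno.snv_ids[0], geno.snv_ids[1])
        assert r2 >= 0.8
        assert r2 < 1.0

    def test_ensure_polymorphic_rescues_rare_variants(self):
        cfg = SimConfig(n_families=5, template=FamilyTemplate((2, 2), 1),
                        mafs=np.full(8, 0.002), effects=np.zeros((2, 8)))
        ped = simulate_pedigree_structure(cfg, seed=3)
        geno = drop_genes(ped, cfg.mafs, seed=4, ensure_polymorphic=True)
        assert (geno.dosages.sum(axis=0) >= 1).all()


class TestSimulatePhenotypes:
    def test_noise_free_closed_form(self):
        # all variance components zero: y is exactly intercept + dosage * beta,
        # using an effect pair from the benchmark panel
        G = 3
        effects = np.zeros((2, G))
        effects[:, 0] = (-5.46, -8.70)
        cfg = SimConfig(
            n_families=4, template=FamilyTemplate((2, 3), 1),
            mafs=np.full(G, 0.3), effects=effects,
            sigma_p=(0, 0), sigma_s=(0, 0), sigma_e=(0, 0),
            beta_sex=(0, 0), beta_smoke=(0, 0), beta_age=(0, 0),
        )
        ped = simulate_pedigree_structure(cfg, seed=1)
        geno = drop_genes(ped, cfg.mafs, seed=2)
        pheno, truth = simulate_phenotypes(ped, geno, cfg, seed=3)
        idx = {s: i for i, s in enumerate(geno.subject_ids)}
        for r in pheno.data.itertuples():
            dose = geno.dosages[idx[r.individual_id]]
            expected = np.asarray(cfg.beta0) + effects @ dose
            assert r.dbp == pytest.approx(expected[0], abs=1e-10)
            assert r.sbp == pytest.approx(expected[1], abs=1e-10)
        assert truth.causal_sets[0] == frozenset({geno.snv_ids[0]})

    def test_zero_correlations_give_uncorrelated_traits(self):
        cfg = SimConfig(
            n_families=400, template=FamilyTemplate((2, 3), 1),
            mafs=np.full(2, 0.3), effects=np.zeros((2, 2)),
            rho_p=0.0, rho_s=0.0, rho_e=0.0,
            beta_sex=(0, 0), beta_smoke=(0, 0), beta_age=(0, 0),
        )
        ped = simulate_pedigree_structure(cfg, seed=5)
        geno = drop_genes(ped, cfg.mafs, seed=6)
        pheno, _ = simulate_phenotypes(ped, geno, cfg, seed=7)
        y = pheno.data[["dbp", "sbp"]].to_numpy()
        r = np.corrcoef(y[:, 0], y[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(y))

    @pytest.mark.parametrize("sig", [
        dict(sigma_p=(2.0, 3.0), sigma_s=(3.0, 2.0), sigma_e=(4.0, 4.0)),
        dict(sigma_p=(1.0, 1.0), sigma_s=(5.0, 4.0), sigma_e=(2.0, 3.0)),
        dict(sigma_p=(4.0, 2.0), sigma_s=(1.0, 3.0), sigma_e=(3.0, 2.0)),
    ])
    def test_variance_component_moments(self, sig):
        """Var(y) = sp^2+ss^2+se^2; within-subject cross-visit covariance =
        sp^2+ss^2; within-family cross-subject covariance = sp^2 — each within
        3 family-level standard errors."""
        cfg = SimConfig(
            n_families=400, template=FamilyTemplate((2, 3), 1), n_visits=3,
            mafs=np.full(1, 0.3), effects=np.zeros((2, 1)),
            rho_p=0.3, rho_s=0.3, rho_e=0.3,
            beta_sex=(0, 0), beta_smoke=(0, 0), beta_age=(0, 0), **sig,
        )
        ped = simulate_pedigree_structure(cfg, seed=8)
        geno = drop_genes(ped, cfg.mafs, seed=9)
        pheno, _ = simulate_phenotypes(ped, geno, cfg, seed=10)
        df = pheno.data
        for k, trait in enumerate(("dbp", "sbp")):
            r = (df[trait] - df[trait].mean()).to_numpy()
            fam = df["family_id"].to_numpy()
            subj = df["individual_id"].to_numpy()
            per_fam_var, per_fam_covs, per_fam_covf = [], [], []
            for f in np.unique(fam):
                m = fam == f
                rf, sf = r[m], subj[m]
                per_fam_var.append(np.mean(rf**2))
                same = sf[:, None] == sf[None, :]
                off = ~np.eye(len(rf), dtype=bool)
                prods = rf[:, None] * rf[None, :]
                if (same & off).any():
                    per_fam_covs.append(prods[same & off].mean())
                if (~same).any():
                    per_fam_covf.append(prods[~same].mean())
            sp2 = cfg.sigma_p[k] ** 2
            ss2 = cfg.sigma_s[k] ** 2
            se2 = cfg.sigma_e[k] ** 2
            for est_list, truth in (
                (per_fam_var, sp2 + ss2 + se2),
                (per_fam_covs, sp2 + ss2),
                (per_fam_covf, sp2),
            ):
                est = np.mean(est_list)
                se = np.std(est_list, ddof=1) / np.sqrt(len(est_list))
                assert abs(est - truth) < 3 * se, (est, truth, se)


class TestBenchmarkScenario:
    def test_snv_count_tracks_noise_count(self):
        data, truth = gaw_like_scenario(noise_count=1, seed=1, n_families=4)
        assert data.n_snvs == 16
        assert len(truth.snv_ids) == 16

    def test_null_effect_variant_excluded_from_causal_sets(self):
        _, truth = gaw_like_scenario(noise_count=1, seed=1, n_families=4)
        null_id = "map4_48058037"
        assert null_id in truth.snv_ids
        assert null_id not in truth.causal_sets[0]
        assert null_id not in truth.causal_sets[1]
        assert len(truth.causal_sets[0]) == 14
        assert len(truth.causal_sets[1]) == 14

    def test_panel_effects_enter_truth(self):
        _, truth = gaw_like_scenario(noise_count=1, seed=2, n_families=4)
        g = truth.snv_ids.index("map4_47913455")
        assert truth.effects[0, g] == -5.46
        assert truth.effects[1, g] == -8.70
        assert all(truth.effects[:, 15:].ravel() == 0.0)

    def test_full_panel_has_15_rows(self):
        assert len(MAP4_PANEL) == 15

    def test_determinism(self):
        d1, _ = gaw_like_scenario(noise_count=1, seed=9, n_families=3)
        d2, _ = gaw_like_scenario(noise_count=1, seed=9, n_families=3)
        np.testing.assert_array_equal(d1.y, d2.y)
        np.testing.assert_array_equal(d1.snv, d2.snv)
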