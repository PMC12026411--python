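"""Generator properties: determinism, stepwise model, LD, planted effects."""

import numpy as np
import pytest

from scetr.association import fit_association
from scetr.meta import dl_meta
from scetr.synthetic_data import (
    SimulationConfig,
    SimulationError,
    default_effect_table,
    simulate_cohort,
    simulate_gwas,
    simulate_snv_genotypes,
    simulate_tr_genotypes,
)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(SimulationError):
            SimulationConfig(step_prob=1.5)
        with pytest.raises(SimulationError):
            SimulationConfig(ld_target=-0.1)

    def test_positive_counts_and_modes(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_tr_loci=0)
        with pytest.raises(SimulationError):
            SimulationConfig(mode_alleles=0)


class TestStepwiseModel:
    def test_zero_step_prob_degenerate(self):
        cfg = SimulationConfig(seed=1, n_samples_per_cohort=50, n_cohorts=1,
                               n_tr_loci=3, n_snv_loci=3, step_prob=0.0)
        tr = simulate_tr_genotypes(cfg)
        assert np.all(tr.allele1 == 20) and np.all(tr.allele2 == 20)

    def test_mode_centered_spread(self):
        # >90% of alleles within 10 repeats of the mode at step_prob 0.3
        cfg = SimulationConfig(seed=2, n_samples_per_cohort=1000,
                               n_cohorts=2, n_tr_loci=1, n_snv_loci=1,
                               step_prob=0.3)
        tr = simulate_tr_genotypes(cfg)
        alleles = np.concatenate([tr.allele1, tr.allele2]).ravel()
        assert np.mean(np.abs(alleles - 20) <= 10) > 0.90
        # unimodal around the mode
        vals, counts = np.unique(alleles, return_counts=True)
        assert vals[np.argmax(counts)] == 20

    def test_missingness_rate(self):
        cfg = SimulationConfig(seed=3, n_samples_per_cohort=500, n_cohorts=2,
                               n_tr_loci=10, n_snv_loci=10, missing_rate=0.1)
        tr = simulate_tr_genotypes(cfg)
        frac = np.isnan(tr.allele1).mean()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_minimum_one_repeat(self):
        cfg = SimulationConfig(seed=4, n_samples_per_cohort=500, n_cohorts=2,
                               n_tr_loci=2, n_snv_loci=2, mode_alleles=2,
                               step_prob=0.6)
        tr = simulate_tr_genotypes(cfg)
        assert np.nanmin(tr.allele1) >= 1


class TestDeterminism:
    def test_identical_seed_identical_cohort(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        np.testing.assert_array_equal(a.tr_genotypes.allele1,
                                      b.tr_genotypes.allele1)
        np.testing.assert_array_equal(a.snv_genotypes.dosage,
                                      b.snv_genotypes.dosage)
        key = next(iter(a.expression))
        np.testing.assert_array_equal(a.expression[key].expression.values,
                                      b.expression[key].expression.values)
        np.testing.assert_array_equal(a.methylation.values,
                                      b.methylation.values)

    def test_different_seed_differs(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = simulate_cohort(small_config)
        b = simulate_cohort(other)
        assert not np.array_equal(a.tr_genotypes.allele1,
                                  b.tr_genotypes.allele1)


class TestLdTarget:
    @pytest.mark.parametrize("target", [0.3, 0.5])
    def test_realized_r2_near_target(self, target):
        from scetr.finemap import ld_r2

        cfg = SimulationConfig(seed=6, n_samples_per_cohort=1000,
                               n_cohorts=2, n_tr_loci=3, n_snv_loci=3,
                               ld_target=target)
        tr = simulate_tr_genotypes(cfg)
        snv = simulate_snv_genotypes(cfg, tr)
        for j in range(3):
            assert ld_r2(tr.summed_dosage()[:, j],
                         snv.dosage[:, j]) == pytest.approx(target, abs=0.1)


class TestExpressionPlants:
    def test_null_plants_give_uniform_pvalues(self):
        from scipy import stats as sps

        cfg = SimulationConfig(seed=12, n_samples_per_cohort=100, n_cohorts=1,
                               n_cell_types=1, n_tr_loci=100, n_snv_loci=100,
                               n_genes=100)
        cohort = simulate_cohort(cfg)
        pb = cohort.expression[("cohort0", "CT00")]
        dosage = cohort.tr_genotypes.summed_dosage()
        pvals = []
        W = pb.covariates.to_numpy(float)
        from scetr.association import inverse_normal_transform

        for j, gene in enumerate(pb.genes):
            y = inverse_normal_transform(pb.expression[gene].to_numpy())
            pvals.append(fit_association(y, dosage[:, j], W).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_beta_recovered(self):
        cfg = SimulationConfig(seed=9, n_samples_per_cohort=1000, n_cohorts=1,
                               n_cell_types=1, n_tr_loci=2, n_snv_loci=2,
                               n_genes=2, noise_sd=1.0)
        from scetr.synthetic_data import PlantedEffect

        cfg.effect_table.append(PlantedEffect(0, "GENE0000", {"CT00": 0.5}))
        cohort = simulate_cohort(cfg)
        pb = cohort.expression[("cohort0", "CT00")]
        g = cohort.tr_genotypes.summed_dosage()[:, 0]
        st = fit_association(pb.expression["GENE0000"].to_numpy(), g,
                             pb.covariates.to_numpy(float))
        assert abs(st.beta - 0.5) <= 3 * st.se

    def test_opposite_sign_plant_detected_by_meta(self):
        # +beta in CT00, -beta in CT01: per-cell-type metas are significant
        # with discordant signs
        from scetr.synthetic_data import PlantedEffect

        cfg = SimulationConfig(seed=10, n_samples_per_cohort=500,
                               n_cohorts=2, n_cell_types=2, n_tr_loci=2,
                               n_snv_loci=2, n_genes=2)
        cfg.effect_table.append(
            PlantedEffect(0, "GENE0000", {"CT00": 0.5, "CT01": -0.5})
        )
        cohort = simulate_cohort(cfg)
        g = cohort.tr_genotypes.summed_dosage()[:, 0]
        metas = {}
        for ct in ("CT00", "CT01"):
            per_cohort = []
            for co in ("cohort0", "cohort1"):
                pb = cohort.expression[(co, ct)]
                rows = [cohort.tr_genotypes.samples.index(s) for s in pb.samples]
                st = fit_association(pb.expression["GENE0000"].to_numpy(),
                                     g[rows], pb.covariates.to_numpy(float))
                per_cohort.append(st)
            metas[ct] = dl_meta([s.beta for s in per_cohort],
                                [s.se for s in per_cohort])
        assert metas["CT00"].p < 1e-8 and metas["CT01"].p < 1e-8
        assert np.sign(metas["CT00"].beta) != np.sign(metas["CT01"].beta)


class TestGwasSimulation:
    def test_causal_variant_strongest(self, small_config):
        cohort_tr_id = "chrS:1000000-1000020:A"
        gwas = simulate_gwas(small_config, {cohort_tr_id: 0.4}, n_gwas=1500)
        best = gwas.loc[gwas["p"].idxmin(), "variant"]
        tag = "snv_tag_0000"
        assert best in (cohort_tr_id, tag)
        assert gwas.set_index("variant").loc[cohort_tr_id, "p"] < 5e-8
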