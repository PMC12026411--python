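"""ABFs, single-causal-variant fine-mapping, conditional analysis, LD."""

import numpy as np
import pytest
from scipy import integrate, stats

from scetr.association import CollinearityError
from scetr.catalog import TRLocus
from scetr.finemap import (
    FinemapError,
    call_candidate_causal,
    conditional_association,
    ld_r2,
    log_abf,
    prune_tr_indels,
    single_effect_finemap,
)
from scetr.significance import GeneResult


def abf_by_integration(beta, se, W):
    """Oracle: ratio of the two marginal likelihoods of beta_hat by
    numerical integration over the true effect."""
    V = se**2

    def alt_integrand(b):
        return stats.norm.pdf(beta, b, np.sqrt(V)) * stats.norm.pdf(b, 0, np.sqrt(W))

    alt, _ = integrate.quad(alt_integrand, -2, 2, epsabs=1e-14, epsrel=1e-12)
    null = stats.norm.pdf(beta, 0, np.sqrt(V))
    return alt / null


class TestLogAbf:
    def test_derived_example(self):
        assert np.exp(log_abf(0.5, 0.1, 0.0225)) == pytest.approx(3.2e3, rel=0.01)

    def test_matches_numerical_integration(self, rng):
        for _ in range(20):
            beta = rng.uniform(-0.6, 0.6)
            se = rng.uniform(0.05, 0.3)
            W = rng.uniform(0.005, 0.1)
            assert log_abf(beta, se, W) == pytest.approx(
                np.log(abf_by_integration(beta, se, W)), abs=1e-8
            )

    def test_null_z_negative_log_abf(self):
        assert log_abf(0.0, 0.1, 0.05) < 0

    def test_small_prior_limit(self):
        assert log_abf(0.5, 0.1, 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_abs_z(self):
        ses = 0.1
        zs = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        vals = log_abf(zs * ses, np.full(zs.size, ses), 0.05)
        assert np.all(np.diff(vals) > 0)


class TestSingleEffectFinemap:
    def test_single_variant_pip_one(self):
        fm = single_effect_finemap([0.4], [0.1], ["v"])
        assert fm.pip[0] == pytest.approx(1.0)
        assert fm.credible_set == ["v"]

    def test_symmetric_variants_uniform_pip(self):
        k = 5
        fm = single_effect_finemap([0.3] * k, [0.1] * k, [f"v{i}" for i in range(k)])
        np.testing.assert_allclose(fm.pip, np.full(k, 1 / k), atol=1e-12)

    def test_pips_sum_to_one_and_permutation_invariant(self, rng):
        b = rng.normal(0, 0.3, size=12)
        s = rng.uniform(0.05, 0.2, size=12)
        ids = [f"v{i}" for i in range(12)]
        fm = single_effect_finemap(b, s, ids)
        assert fm.pip.sum() == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(12)
        fm2 = single_effect_finemap(b[perm], s[perm], [ids[i] for i in perm])
        for vid in ids:
            assert fm2.pip_of(vid) == pytest.approx(fm.pip_of(vid), rel=1e-9)

    def test_equals_bruteforce_enumeration(self, rng):
        # explicit posterior over the J single-causal hypotheses
        for _ in range(20):
            J = int(rng.integers(2, 20))
            b = rng.normal(0, 0.3, size=J)
            s = rng.uniform(0.05, 0.2, size=J)
            fm = single_effect_finemap(b, s, [f"v{i}" for i in range(J)])
            abfs = np.exp(log_abf(b, s, fm.W_star))
            posterior = abfs / abfs.sum()
            np.testing.assert_allclose(fm.pip, posterior, atol=1e-10)

    def test_credible_set_minimal(self, rng):
        b = np.array([1.0, 0.1, 0.05, 0.02])
        s = np.full(4, 0.1)
        fm = single_effect_finemap(b, s, list("abcd"))
        assert fm.credible_set[0] == "a"
        in_set = ~fm.pruned
        assert fm.pip[in_set].sum() >= 0.95 - 1e-9

    def test_all_degenerate_rejected(self):
        with pytest.raises(FinemapError):
            single_effect_finemap([np.nan], [np.nan], ["v"])


class TestCandidateCausal:
    def _gr(self, lead, top="tr1"):
        return GeneResult(gene="g", cell_type="A", p_gene=1e-10, top_eTR=top,
                          lead_variant=lead)

    def _fm(self, pip_tr):
        pip = np.array([pip_tr, 1 - pip_tr])
        return type("FM", (), {"variant_ids": ["tr1", "snv1"],
                               "pip_of": lambda self, v: float(
                                   pip[["tr1", "snv1"].index(v)])})()

    def test_lead_tr_high_pip_passes(self):
        call = call_candidate_causal(self._fm(0.75), self._gr("tr1"))
        assert call.passes

    def test_pip_below_threshold_fails(self):
        assert not call_candidate_causal(self._fm(0.5), self._gr("tr1")).passes

    def test_non_lead_fails_despite_pip(self):
        assert not call_candidate_causal(self._fm(0.9), self._gr("snv1")).passes

    def test_boundary_pip(self):
        assert call_candidate_causal(self._fm(0.7), self._gr("tr1")).passes


class TestPruneTrIndels:
    locus = TRLocus("chr1", 1000, 1040, "AT")

    def test_whole_copy_removed_partial_retained(self):
        indels = [
            (1010, "GATAT", "G"),   # whole copies inside -> removed
            (5000, "GATAT", "G"),   # outside any locus -> retained
            (1010, "G", "GATA"),    # partial copies -> retained
            (1012, "G", "GTA"),     # cyclic rotation -> removed
        ]
        keep, counts = prune_tr_indels(indels, [self.locus],
                                       ids=list("abcd"))
        assert keep == ["b", "c"]
        assert counts["n_removed"] == 2


class TestLdR2:
    def test_identical_vectors(self):
        a = np.array([0.0, 1, 2, 0, 1, 2])
        assert ld_r2(a, a) == pytest.approx(1.0)

    def test_perfect_negative(self):
        a = np.array([0.0, 1, 2, 0, 1, 2])
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(FinemapError):
            ld_r2([1, 1, 1, 1], [0, 1, 2, 1])

    def test_simulated_pair_near_target(self):
        from scetr.synthetic_data import (
            SimulationConfig,
            simulate_snv_genotypes,
            simulate_tr_genotypes,
        )

        cfg = SimulationConfig(seed=5, n_samples_per_cohort=1000,
                               n_cohorts=2, n_tr_loci=4, n_snv_loci=4,
                               ld_target=0.5)
        tr = simulate_tr_genotypes(cfg)
        snv = simulate_snv_genotypes(cfg, tr)
        for j in range(4):
            r2 = ld_r2(tr.summed_dosage()[:, j], snv.dosage[:, j])
            assert r2 == pytest.approx(0.5, abs=0.1)


class TestConditionalAssociation:
    def test_orthogonal_conditioning_leaves_beta(self, rng):
        n = 500
        g = rng.integers(0, 5, size=n).astype(float)
        other = rng.integers(0, 3, size=n).astype(float)
        y = 0.4 * g + rng.normal(size=n)
        from scetr.association import fit_association

        st0 = fit_association(y, g)
        st1, _ = conditional_association(y, g, other)
        # conditioning variable nearly orthogonal to g: beta barely moves
        assert st1.beta == pytest.approx(st0.beta, abs=0.05)

    def test_perfect_tag_abolishes_signal(self, rng):
        n = 2000
        causal = rng.integers(0, 5, size=n).astype(float)
        tag = causal.copy()
        flip = rng.random(n) < 0.25  # strong but imperfect tag
        tag[flip] = rng.integers(0, 5, size=int(flip.sum())).astype(float)
        y = 0.5 * (causal - causal.mean()) + rng.normal(size=n)
        # conditioning the tag on the causal abolishes the tag's signal
        tag_given_causal, persists = conditional_association(y, tag, causal)
        assert tag_given_causal.p > 1e-4
        assert not persists
        # reciprocal: causal retains signal given the tag
        causal_given_tag, _ = conditional_association(y, causal, tag)
        assert causal_given_tag.p < 1e-8

    def test_collinear_conditioning_rejected(self, rng):
        g = rng.integers(0, 5, size=100).astype(float)
        y = rng.normal(size=100)
        with pytest.raises(CollinearityError):
            conditional_association(y, g, g)
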