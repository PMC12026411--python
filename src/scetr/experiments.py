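"""Calibration and recovery experiments over the synthetic generator.

These are the package's own power/calibration studies: type-I-error
calibration of the association + meta stack under permutation, confidence-
interval coverage for a planted effect, fine-mapping and colocalization
recovery of planted causal variants, specificity-classifier operating
characteristics, and the genotype-validation round trip.  The analysis
drivers and the acceptance machinery both run these; every number they
report is computed here at run time.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .association import fit_association, inverse_normal_transform, marginal_ols
from .coloc import coloc_abf
from .finemap import single_effect_finemap
from .meta import classify_specificity, dl_meta, permutation_calibration
from .synthetic_data import (
    SimulationConfig,
    _rng,
    _stepwise_alleles,
    simulate_covariates,
    simulate_tr_genotypes,
    simulate_truthset,
)
from .validation import concordance, score_offsets


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0]
               % (2**31))


def _tag_haplotypes(rng, tr_hap: np.ndarray, mode: int, r2: float) -> np.ndarray:
    """Haplotype alleles of a tag SNV at approximately the given dosage r^2
    with the TR (indicator of exceeding the mode, flipped)."""
    from .synthetic_data import _solve_flip_prob

    x = (tr_hap > mode).astype(float)
    f = _solve_flip_prob(tr_hap, x, r2)
    flip = rng.random(x.size) < f
    return np.where(flip, 1 - x, x)


def null_calibration(
    seed: int,
    n_samples_per_cohort: int = 250,
    n_genes: int = 200,
    n_cell_types: int = 2,
    alphas=(0.05, 0.01),
) -> dict:
    """Permutation type-I-error calibration of the assoc + meta stack.

    A null two-cohort cohort (no planted effects) is simulated with one TR
    per gene; genotype sample identifiers are permuted (expression fixed)
    and the full per-cohort association + DerSimonian-Laird meta-analysis is
    re-run, yielding one meta p-value per gene x cell type.  Returns the
    calibration summary from :func:`scetr.meta.permutation_calibration`.
    """
    cfg = SimulationConfig(
        seed=_child_seed(seed, 11),
        n_samples_per_cohort=n_samples_per_cohort,
        n_cohorts=2,
        n_cell_types=n_cell_types,
        n_tr_loci=n_genes,
        n_snv_loci=n_genes,
        n_genes=n_genes,
    )
    tr = simulate_tr_genotypes(cfg)
    covariates = simulate_covariates(cfg)
    W_all = covariates.drop(columns=["cohort"]).to_numpy(dtype=float)
    rng = _rng(cfg, 21)
    n = cfg.n_samples
    # null expression: covariate signal + noise, one matrix per cell type
    alpha_cov = rng.normal(0.0, 0.1, size=(W_all.shape[1], n_genes))
    exprs = [W_all @ alpha_cov + rng.normal(size=(n, n_genes))
             for _ in range(n_cell_types)]
    dosage = tr.summed_dosage()
    cohort_of = cfg.cohort_of_sample()
    masks = [cohort_of == c for c in cfg.cohorts]

    def run(perm: np.ndarray):
        gperm = dosage[perm]
        pvals = []
        for expr in exprs:
            per_cohort = []
            for mask in masks:
                y = np.column_stack(
                    [inverse_normal_transform(expr[mask, j])
                     for j in range(n_genes)]
                )
                betas, ses = np.empty(n_genes), np.empty(n_genes)
                for j in range(n_genes):
                    b, s, _ = marginal_ols(y[:, j], gperm[mask, j][:, None],
                                           W_all[mask])
                    betas[j], ses[j] = b[0], s[0]
                per_cohort.append((betas, ses))
            for j in range(n_genes):
                m = dl_meta([per_cohort[0][0][j], per_cohort[1][0][j]],
                            [per_cohort[0][1][j], per_cohort[1][1][j]])
                pvals.append(m.p)
        return pvals

    return permutation_calibration(run, n, seed=_child_seed(seed, 22),
                                   alphas=alphas)


def beta_recovery(
    seed: int,
    n_replicates: int = 500,
    n: int = 1000,
    beta: float = 0.5,
    noise_sd: float = 1.0,
) -> dict:
    """95% CI coverage for a planted per-dosage effect.

    Each replicate simulates one stepwise TR locus, covariates, and
    y = W a + beta * centered dosage + Normal(0, noise_sd); the OLS fit's
    beta +/- 1.96 se interval is checked against the truth.
    """
    rng = np.random.default_rng(_child_seed(seed, 31))
    covered = 0
    errs = []
    for _ in range(n_replicates):
        a1 = _stepwise_alleles(rng, n, 20, 0.3)
        a2 = _stepwise_alleles(rng, n, 20, 0.3)
        g = a1 + a2
        W = rng.normal(size=(n, 4))
        alpha = rng.normal(0.0, 0.1, size=4)
        y = W @ alpha + beta * (g - g.mean()) + rng.normal(0, noise_sd, n)
        st = fit_association(y, g, W)
        if abs(st.beta - beta) <= 1.96 * st.se:
            covered += 1
        errs.append(st.beta - beta)
    return {
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "mean_bias": float(np.mean(errs)),
    }


def finemap_recovery(
    seed: int,
    n_replicates: int = 200,
    n: int = 1000,
    beta: float = 0.4,
    n_snvs: int = 20,
    max_r2: float = 0.5,
) -> dict:
    """How often the planted causal TR attains the top PIP.

    Each replicate plants one causal TR among LD-linked SNVs (r^2 up to
    ``max_r2``), computes marginal summary statistics, fine-maps the window
    under the single-causal-variant model and records whether the TR ranks
    first.
    """
    rng = np.random.default_rng(_child_seed(seed, 41))
    hits = 0
    for _ in range(n_replicates):
        hap1 = _stepwise_alleles(rng, n, 20, 0.3)
        hap2 = _stepwise_alleles(rng, n, 20, 0.3)
        g_tr = hap1 + hap2
        G = [g_tr]
        for _k in range(n_snvs):
            r2 = rng.uniform(0.1, max_r2)
            y1 = _tag_haplotypes(rng, hap1, 20, r2)
            y2 = _tag_haplotypes(rng, hap2, 20, r2)
            G.append(y1 + y2)
        G = np.column_stack(G)
        y = beta * (g_tr - g_tr.mean()) + rng.normal(size=n)
        b, s, _ = marginal_ols(y, G)
        ids = ["tr"] + [f"snv{k}" for k in range(n_snvs)]
        fm = single_effect_finemap(b, s, ids)
        if fm.variant_ids[int(np.argmax(fm.pip))] == "tr":
            hits += 1
    return {"top_pip_rate": hits / n_replicates, "n_replicates": n_replicates}


def coloc_recovery(
    seed: int,
    n_replicates: int = 100,
    n: int = 1000,
    beta: float = 0.4,
    n_variants: int = 30,
) -> dict:
    """Median PP H4 / H3 for shared- vs distinct-causal study pairs.

    Shared scenario: both studies' traits are driven by the same variant.
    Distinct scenario: the second study's causal variant is an independent
    one (r^2 < 0.1 with the first).  Summary statistics come from marginal
    OLS in two independent sample sets sharing the LD structure.
    """
    rng = np.random.default_rng(_child_seed(seed, 51))
    pph4_shared, pph3_distinct = [], []

    def draw_stats(causal_idx: int):
        hap1 = _stepwise_alleles(rng, n, 20, 0.3)
        hap2 = _stepwise_alleles(rng, n, 20, 0.3)
        g_tr = hap1 + hap2
        cols = [g_tr]
        for k in range(n_variants - 1):
            if k < (n_variants - 1) // 2:
                r2 = rng.uniform(0.2, 0.5)
                cols.append(_tag_haplotypes(rng, hap1, 20, r2)
                            + _tag_haplotypes(rng, hap2, 20, r2))
            else:
                maf = rng.uniform(0.2, 0.5)
                cols.append((rng.random(n) < maf).astype(float)
                            + (rng.random(n) < maf).astype(float))
        G = np.column_stack(cols)
        gc = G[:, causal_idx]
        y = beta * (gc - gc.mean()) + rng.normal(size=n)
        return marginal_ols(y, G)

    for _ in range(n_replicates):
        b1, s1, _ = draw_stats(0)
        b2, s2, _ = draw_stats(0)
        pph4_shared.append(coloc_abf(b1, s1, b2, s2).pp["H4"])
        b1, s1, _ = draw_stats(0)
        # distinct causal: an independent filler variant
        b2, s2, _ = draw_stats(n_variants - 1)
        pph3_distinct.append(coloc_abf(b1, s1, b2, s2).pp["H3"])
    return {
        "median_pp_h4_shared": float(np.median(pph4_shared)),
        "median_pp_h3_distinct": float(np.median(pph3_distinct)),
        "n_replicates": n_replicates,
    }


def specificity_rates(
    seed: int,
    n_replicates: int = 40,
    n_samples_per_cohort: int = 300,
    n_cell_types: int = 4,
    beta: float = 0.5,
) -> dict:
    """Operating characteristics of the pairwise-meta specificity rule.

    Per replicate, one sc-eTR is planted either in every cell type
    (globally shared) or in exactly one; two cohorts are simulated, the
    per-cell-type meta statistics are computed, and the classifier is
    applied.  Returns the fraction of shared plants labeled specific (should
    be small) and of single-cell-type plants labeled specific (should be
    large), plus the shared-detection rate under the p_meta < p_origin rule.
    """
    rng = np.random.default_rng(_child_seed(seed, 61))
    n = n_samples_per_cohort
    spec_when_specific = 0
    spec_when_shared = 0
    shared_flagged = 0
    shared_comparisons = 0
    for _ in range(n_replicates):
        hap = [(_stepwise_alleles(rng, n, 20, 0.3)
                + _stepwise_alleles(rng, n, 20, 0.3)) for _ in range(2)]
        for scenario in ("shared", "specific"):
            stats_by_ct = {}
            for ct in range(n_cell_types):
                b_ct = beta if (scenario == "shared" or ct == 0) else 0.0
                per_cohort = []
                for co in range(2):
                    g = hap[co]
                    y = b_ct * (g - g.mean()) + rng.normal(size=n)
                    st = fit_association(y, g)
                    per_cohort.append(st)
                stats_by_ct[ct] = dl_meta(
                    [s.beta for s in per_cohort], [s.se for s in per_cohort],
                    variant="tr", gene="g", cell_type=str(ct),
                )
            origin = stats_by_ct[0]
            others = {str(ct): stats_by_ct[ct]
                      for ct in range(1, n_cell_types)}
            call = classify_specificity(origin, origin.p, others)
            if scenario == "shared":
                spec_when_shared += call.specific
                shared_flagged += call.n_shared
                shared_comparisons += call.n_comparisons
            else:
                spec_when_specific += call.specific
    return {
        "specific_rate_single_ct_plants": spec_when_specific / n_replicates,
        "specific_rate_shared_plants": spec_when_shared / n_replicates,
        "shared_flag_rate_shared_plants": shared_flagged / max(shared_comparisons, 1),
        "n_replicates": n_replicates,
    }


def truthset_roundtrip(
    seed: int,
    n_samples: int = 60,
    n_loci: int = 6,
    error_rate: float = 0.03,
) -> dict:
    """Offset recovery and concordance on a simulated caller/truth pair.

    Plants constant offsets at half the loci, scores candidate offsets,
    and measures strict / +-1-tolerant concordance before correction.
    """
    cfg = SimulationConfig(seed=_child_seed(seed, 71), n_cohorts=1,
                           n_samples_per_cohort=n_samples, n_tr_loci=n_loci,
                           n_snv_loci=n_loci)
    offsets = {j: (j % 3) - 1 for j in range(n_loci // 2)}  # -1, 0, +1, ...
    offsets = {j: d for j, d in offsets.items() if d != 0}
    offsets[0] = 2
    caller, truth, offset_map = simulate_truthset(cfg, offsets=offsets,
                                                  error_rate=error_rate)
    comparisons = {
        locus: {"caller": [
            ((caller.allele1[i, j], caller.allele2[i, j]),
             (truth.allele1[i, j], truth.allele2[i, j]))
            for i in range(caller.n_samples)
        ]}
        for j, locus in enumerate(caller.variant_ids)
    }
    report = score_offsets(comparisons)
    recovered = sum(
        report.adopted.get(locus, None) == offset_map[locus]
        for locus in caller.variant_ids
    )
    _, agg = concordance(caller, truth)
    return {
        "offset_recovery_rate": recovered / n_loci,
        "strict_concordance": agg["strict_concordance"],
        "tolerant_concordance": agg["tolerant_concordance"],
        "planted_offsets": offset_map,
        "adopted_offsets": dict(report.adopted),
    }
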