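"""Random-effects meta-analysis, permutation calibration and cell-type
specificity classification.

Two cohorts ("batches") are pooled per test with the DerSimonian-Laird
random-effects estimator; the same two-study machinery drives the pairwise
cell-type specificity rule: an association is *shared* with another cell
type if pooling the two cell types' estimates yields a smaller p-value than
the original one, and *cell-type-specific* if pooling makes the p-value
larger in every eligible comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .association import AssocStat


class MetaError(ValueError):
    pass


@dataclass
class MetaStat:
    """DerSimonian-Laird pooled estimate over k studies."""

    beta: float
    se: float
    p: float
    tau2: float
    Q: float
    k: int
    variant: str = ""
    gene: str = ""
    cell_type: str = ""


def dl_meta(betas, ses, variant: str = "", gene: str = "", cell_type: str = "") -> MetaStat:
    """DerSimonian-Laird random-effects pooling of per-study (beta, se).

    Fixed-effect weights w_i = 1/se_i^2 give the heterogeneity statistic
    Q = sum w_i (b_i - b_FE)^2; the moment estimator of the between-study
    variance is tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)).
    Random-effects weights w*_i = 1/(se_i^2 + tau2) give the pooled estimate
    and its standard error (sum w*)^(-1/2); the p-value is two-sided normal.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise MetaError("k = 0 studies")
    if b.shape != s.shape:
        raise MetaError("betas and ses must be aligned")
    if np.any(s <= 0):
        raise MetaError("all standard errors must be positive")
    k = b.size
    if k == 1:
        beta1, se1 = float(b[0]), float(s[0])
        p1 = float(2.0 * stats.norm.sf(abs(beta1 / se1)))
        return MetaStat(beta=beta1, se=se1, p=max(p1, 5e-324), tau2=0.0,
                        Q=0.0, k=1, variant=variant, gene=gene,
                        cell_type=cell_type)
    w = 1.0 / s**2
    beta_fe = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - beta_fe) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    beta_pooled = float(np.sum(w_star * b) / np.sum(w_star))
    se_pooled = float(np.sum(w_star) ** -0.5)
    z = beta_pooled / se_pooled
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaStat(beta=beta_pooled, se=se_pooled, p=max(p, 5e-324), tau2=tau2,
                    Q=Q, k=k, variant=variant, gene=gene, cell_type=cell_type)


def meta_stats(per_cohort: Sequence[AssocStat]) -> MetaStat:
    """Pool per-cohort association statistics for one variant x gene test."""
    first = per_cohort[0]
    return dl_meta(
        [s.beta for s in per_cohort],
        [s.se for s in per_cohort],
        variant=first.variant,
        gene=first.gene,
        cell_type=first.cell_type,
    )


@dataclass
class SpecificityCall:
    """Pairwise-meta specificity classification for one sc-eTR."""

    variant: str
    gene: str
    origin_cell_type: str
    shared_with: dict = field(default_factory=dict)  # cell type -> bool
    specific: bool = False
    n_comparisons: int = 0

    @property
    def n_shared(self) -> int:
        return sum(self.shared_with.values())


def classify_specificity(
    origin: AssocStat | MetaStat,
    p_origin: float,
    others: Mapping[str, AssocStat | MetaStat | None],
) -> SpecificityCall:
    """Classify an sc-eTR as shared or cell-type-specific.

    For each eligible comparison cell type (one where the gene is testable;
    pass None for ineligible ones) a two-study DL meta-analysis pools the
    origin estimate with the comparison estimate.  The sc-eTR is *shared*
    with that cell type iff p_meta < p_origin, and *cell-type-specific* iff
    p_meta > p_origin for every eligible comparison.  Ties
    (p_meta == p_origin) count as neither shared nor in favor of
    specificity.  With no eligible comparison, specificity is undefined and
    reported as not specific with n_comparisons = 0.
    """
    shared_with: dict[str, bool] = {}
    all_higher = True
    n_comparisons = 0
    for ct, other in others.items():
        if other is None:
            continue
        n_comparisons += 1
        pooled = dl_meta([origin.beta, other.beta], [origin.se, other.se])
        shared_with[ct] = bool(pooled.p < p_origin)
        if not (pooled.p > p_origin):
            all_higher = False
    specific = bool(n_comparisons > 0 and all_higher)
    return SpecificityCall(
        variant=origin.variant,
        gene=origin.gene,
        origin_cell_type=origin.cell_type,
        shared_with=shared_with,
        specific=specific,
        n_comparisons=n_comparisons,
    )


def permutation_calibration(
    run_association: Callable[[np.ndarray], Sequence[float]],
    n_samples: int,
    seed: int,
    alphas: Sequence[float] = (0.05, 0.01),
) -> dict:
    """Type-I-error calibration by permuting sample identifiers of genotypes.

    ``run_association`` maps a permutation (index array over samples, applied
    to the genotype side only, expression fixed) to the resulting collection
    of p-values from the full association + meta re-run.  Returns the
    permuted p-values, the empirical rejection rate at each nominal alpha
    with its binomial standard error, and a KS test against uniformity.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    pvals = np.asarray(list(run_association(perm)), dtype=float)
    if pvals.size == 0:
        raise MetaError("association run yielded no p-values")
    out = {"p_values": pvals, "permutation": perm, "n_tests": pvals.size}
    out["empirical_rate"] = {
        float(a): float(np.mean(pvals < a)) for a in alphas
    }
    out["binomial_se"] = {
        float(a): float(np.sqrt(a * (1 - a) / pvals.size)) for a in alphas
    }
    ks = stats.kstest(pvals, "uniform")
    out["ks_stat"], out["ks_p"] = float(ks.statistic), float(ks.pvalue)
    return out


def sign_discordant(stats_by_cell_type: Mapping[str, AssocStat | MetaStat],
                    alpha: float = 0.05) -> bool:
    """Convenience: does any pair of cell types show significant effects of
    opposite sign for the same variant x gene? (Reported descriptively; not
    a formal specificity criterion.)"""
    sig = [s for s in stats_by_cell_type.values() if s.p < alpha]
    signs = {np.sign(s.beta) for s in sig if s.beta != 0}
    return len(signs) > 1
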