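"""Single-causal-variant fine-mapping, conditional analysis and dosage LD.

Fine-mapping works from summary statistics only.  Under the assumption of at
most one causal variant per window, each variant's evidence is its Wakefield
approximate Bayes factor (ABF); with a uniform prior over which variant is
causal, posterior inclusion probabilities are the softmax of the log ABFs.
The normal-effect prior variance W is chosen from a grid by maximizing the
average marginal likelihood over variants.  This deliberately re-implements
the L = 1 special case of sum-of-single-effects regression, which the
single-credible-set restriction reduces to exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .association import (
    AssocStat,
    CollinearityError,
    fit_association,
)
from .catalog import TRLocus, is_tr_representing_indel
from .significance import GeneResult

DEFAULT_W_GRID = (0.001, 0.005, 0.01, 0.0225, 0.05, 0.1, 0.2)
GENOME_WIDE_P = 5e-8


class FinemapError(ValueError):
    pass


def log_abf(beta, se, prior_variance: float) -> np.ndarray:
    """Log Wakefield approximate Bayes factor (alternative over null).

    With V = se^2, z = beta/se and prior effect variance W:
    log ABF = 0.5 log(V / (V + W)) + 0.5 z^2 W / (V + W).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise FinemapError("standard errors must be positive")
    if prior_variance <= 0:
        raise FinemapError("prior variance must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + prior_variance)) + 0.5 * z2 * prior_variance / (
        V + prior_variance
    )


@dataclass
class FinemapResult:
    """Posterior over the single causal variant in one window."""

    variant_ids: list[str]
    pip: np.ndarray
    credible_set: list[str]
    W_star: float
    pruned: np.ndarray  # True for variants outside the credible set
    gene: str = ""
    cell_type: str = ""
    coverage: float = 0.95

    def pip_of(self, variant: str) -> float:
        return float(self.pip[self.variant_ids.index(variant)])


def single_effect_finemap(
    betas,
    ses,
    variant_ids: Sequence[str],
    W_grid: Sequence[float] = DEFAULT_W_GRID,
    coverage: float = 0.95,
    gene: str = "",
    cell_type: str = "",
) -> FinemapResult:
    """Fine-map a window of summary statistics to a single credible set.

    For each prior variance W in the grid, per-variant log ABFs are computed;
    W* maximizes log((1/J) sum_j ABF_j) (the marginal likelihood under a
    uniform prior over the causal variant).  PIPs are the softmax of the log
    ABFs at W*; the credible set is the smallest PIP-ranked set with
    cumulative PIP >= ``coverage``.  Variants outside the set keep their PIP
    but are flagged ``pruned`` (single-credible-set pruning).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ids = list(variant_ids)
    ok = ~(np.isnan(b) | np.isnan(s)) & (s > 0)
    if not np.any(ok):
        raise FinemapError("all variants degenerate: no valid (beta, se)")
    if not np.all(ok):
        b, s = b[ok], s[ok]
        ids = [i for i, keep in zip(ids, ok) if keep]
    J = b.size

    best_W, best_ml = None, -np.inf
    for W in W_grid:
        labf = log_abf(b, s, W)
        ml = logsumexp(labf) - np.log(J)
        if ml > best_ml:
            best_ml, best_W = ml, float(W)
    labf = log_abf(b, s, best_W)
    pip = np.exp(labf - logsumexp(labf))

    order = np.argsort(-pip, kind="mergesort")
    cum = np.cumsum(pip[order])
    n_cs = int(np.searchsorted(cum, coverage) + 1)
    n_cs = min(n_cs, J)
    cs_idx = set(order[:n_cs].tolist())
    pruned = np.array([j not in cs_idx for j in range(J)])
    credible_set = [ids[j] for j in order[:n_cs]]
    return FinemapResult(variant_ids=ids, pip=pip, credible_set=credible_set,
                         W_star=best_W, pruned=pruned, gene=gene,
                         cell_type=cell_type, coverage=coverage)


@dataclass
class CandidateCausalCall:
    """Candidate-causal gate: lead variant of its eGene with PIP >= 0.7."""

    variant: str
    is_lead: bool
    pip: float
    passes: bool = field(init=False)
    pip_threshold: float = 0.7

    def __post_init__(self) -> None:
        self.passes = bool(self.is_lead and self.pip >= self.pip_threshold)


def call_candidate_causal(
    finemap: FinemapResult,
    gene_result: GeneResult,
    variant: str | None = None,
    pip_threshold: float = 0.7,
) -> CandidateCausalCall:
    """Call an sc-eTR candidate causal.

    The call passes iff the sc-eTR is the lead variant (strongest signal in
    the eGene, TRs and SNVs jointly) and its PIP is at least
    ``pip_threshold``.
    """
    variant = variant or gene_result.top_eTR
    if variant is None:
        return CandidateCausalCall(variant="", is_lead=False, pip=0.0,
                                   pip_threshold=pip_threshold)
    is_lead = variant == gene_result.lead_variant
    pip = finemap.pip_of(variant) if variant in finemap.variant_ids else 0.0
    return CandidateCausalCall(variant=variant, is_lead=is_lead, pip=pip,
                               pip_threshold=pip_threshold)


def prune_tr_indels(
    indels: Sequence[tuple[int, str, str]],
    catalog: Sequence[TRLocus],
    ids: Sequence[str] | None = None,
) -> tuple[list, dict]:
    """Remove indels that are alternate encodings of TR alleles.

    An indel is removed iff it lies in a cataloged TR interval and its
    inserted/deleted sequence is a whole number of copies of (a cyclic
    rotation of) that locus motif.  Returns (retained indels or ids, counts).
    """
    keep, removed = [], 0
    labels = list(ids) if ids is not None else list(indels)
    for indel, label in zip(indels, labels):
        if any(is_tr_representing_indel(indel, loc) for loc in catalog
               if loc.start - len(indel[1]) <= indel[0] < loc.end):
            removed += 1
        else:
            keep.append(label)
    return keep, {"n_input": len(list(indels)), "n_removed": removed,
                  "n_retained": len(keep)}


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors (complete cases)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise FinemapError("dosage vectors must be aligned")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise FinemapError("need at least 3 complete-case pairs for LD")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise FinemapError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def conditional_association(
    y,
    g_test,
    g_condition,
    W=None,
    variant: str = "",
    gene: str = "",
    cell_type: str = "",
    genome_wide_p: float = GENOME_WIDE_P,
) -> tuple[AssocStat, bool]:
    """Re-test a variant conditioning on another variant's dosage.

    The conditioning dosage is appended to the covariates; the persistence
    flag reports whether the conditional p-value stays below the genome-wide
    threshold (default 5e-8).  Near-collinear test/conditioning dosages
    (r^2 > 0.999) raise :class:`CollinearityError`.
    """
    g_test = np.asarray(g_test, dtype=float)
    g_condition = np.asarray(g_condition, dtype=float)
    ok = ~(np.isnan(g_test) | np.isnan(g_condition))
    if np.sum(ok) >= 3 and not np.all(g_test[ok] == g_test[ok][0]) and not np.all(
        g_condition[ok] == g_condition[ok][0]
    ):
        if ld_r2(g_test, g_condition) > 0.999:
            raise CollinearityError(
                "conditioning variant nearly collinear with test variant"
            )
    if W is None:
        W_full = g_condition[:, None]
    else:
        W = np.asarray(W, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        W_full = np.column_stack([W, g_condition])
    stat = fit_association(y, g_test, W_full, variant=variant, gene=gene,
                           cell_type=cell_type)
    return stat, bool(stat.p < genome_wide_p)
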