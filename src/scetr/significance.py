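"""Gene-level significance: Cauchy combination (ACAT-V), Storey q-values,
and top/lead variant selection.

ACAT-V aggregates the variant-level p-values of a gene into a single
gene-level p-value via the Cauchy combination, which is robust to arbitrary
correlation between the component tests.  Storey's q-value procedure then
controls the FDR across genes within each cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .association import AssocStat
from .meta import MetaStat


class SignificanceError(ValueError):
    pass


_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16
_SMALL_P = 1e-15


def _stable_cauchy_sf(T: float) -> float:
    """Upper tail of the standard Cauchy at T, stable for large |T|."""
    if T > 1.0:
        return float(np.arctan(1.0 / T) / np.pi)
    if T < -1.0:
        return float(1.0 - np.arctan(-1.0 / T) / np.pi)
    return float(0.5 - np.arctan(T) / np.pi)


def acat_combine(p_values, weights=None) -> float:
    """Combine p-values with the Cauchy combination test (ACAT-V).

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i, and the combined p-value
    is the standard-Cauchy upper tail at T.  For p_i below 1e-15 the summand
    uses the stabilized approximation 1/(p_i pi).  Inputs outside (0, 1) are
    clipped with a warning.  Weights default to equal.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise SignificanceError("no p-values to combine")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values outside (0, 1) clipped for Cauchy combination")
        p = np.clip(p, _P_FLOOR, _P_CEIL)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w < 0) or not np.any(w > 0):
            raise SignificanceError("weights must be nonnegative, not all zero")
    terms = np.empty_like(p)
    small = p < _SMALL_P
    terms[small] = 1.0 / (p[small] * np.pi)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    T = float(np.sum(w * terms) / np.sum(w))
    return min(max(_stable_cauchy_sf(T), 5e-324), 1.0)


def estimate_pi0(p_values, lam: float = 0.5) -> float:
    """Storey's estimate of the null proportion at a single lambda."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    return float(min(1.0, np.sum(p > lam) / (m * (1.0 - lam))))


def storey_qvalues(p_values, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    q_(i) = min over j with p_(j) >= p_(i) of pi0 * m * p_(j) / rank(j);
    with pi0 forced to 1 this reduces exactly to Benjamini-Hochberg adjusted
    p-values.  Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise SignificanceError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise SignificanceError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lam=lam)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1) * pi0
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    return out


@dataclass
class GeneResult:
    """Gene-level result within one cell type."""

    gene: str
    cell_type: str
    p_gene: float
    q: float = np.nan
    top_eTR: str | None = None
    top_eTR_p: float = np.nan
    lead_variant: str | None = None
    lead_p: float = np.nan
    is_significant: bool = False


def _tie_key(stat, coords: dict | None):
    coord = coords.get(stat.variant, 0) if coords else 0
    return (stat.p, coord, stat.variant)


def select_top_and_lead(
    tr_stats: Sequence[AssocStat | MetaStat],
    snv_stats: Sequence[AssocStat | MetaStat] = (),
    gene: str = "",
    cell_type: str = "",
    variant_coords: dict | None = None,
    acat_weights=None,
) -> GeneResult:
    """Gene-level combination and top/lead variant selection.

    The gene-level p-value is the ACAT combination of the TR p-values (TR
    discovery; SNV-level gene tests use the same machinery separately).
    ``top_eTR`` is the TR with the smallest nominal p; ``lead_variant`` is
    the smallest-p variant among TRs and SNVs jointly.  Exact p ties break
    deterministically by smaller coordinate (``variant_coords``: id -> start)
    then lexicographic id.
    """
    tr_stats = list(tr_stats)
    snv_stats = list(snv_stats)
    if not tr_stats and not snv_stats:
        raise SignificanceError("no tested variants for gene")
    if tr_stats:
        gene = gene or tr_stats[0].gene
        cell_type = cell_type or tr_stats[0].cell_type
        p_gene = acat_combine([s.p for s in tr_stats], weights=acat_weights)
        top = min(tr_stats, key=lambda s: _tie_key(s, variant_coords))
        top_id, top_p = top.variant, top.p
    else:
        gene = gene or snv_stats[0].gene
        cell_type = cell_type or snv_stats[0].cell_type
        p_gene = acat_combine([s.p for s in snv_stats], weights=None)
        top_id, top_p = None, np.nan
    lead = min(tr_stats + snv_stats, key=lambda s: _tie_key(s, variant_coords))
    return GeneResult(gene=gene, cell_type=cell_type, p_gene=p_gene,
                      top_eTR=top_id, top_eTR_p=top_p,
                      lead_variant=lead.variant, lead_p=lead.p)


def call_significant(results: Sequence[GeneResult], fdr: float = 0.05,
                     lam: float = 0.5, pi0: float | None = None) -> list[GeneResult]:
    """Assign Storey q-values across genes (within a cell type) and flag
    significance at q < ``fdr``.  Mutates and returns the results."""
    if not results:
        return []
    qs = storey_qvalues([r.p_gene for r in results], lam=lam, pi0=pi0)
    for r, q in zip(results, qs):
        r.q = float(q)
        r.is_significant = bool(q < fdr)
    return list(results)
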