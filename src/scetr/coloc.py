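"""Enumeration-based colocalization of eQTL and trait association signals.

Under a single-causal-variant model per study, every configuration of
(causal variant in study 1, causal variant in study 2) is enumerated with
Wakefield ABFs as the per-variant evidence.  Collapsing configurations gives
the posterior probabilities of the five hypotheses: H0 no association, H1/H2
association in one study only, H3 two distinct causal variants, H4 a shared
causal variant.  All sums are carried in log space.

The gating rule for declaring a TR the likely driver of a trait signal
requires strong colocalization (PP H4), a confident candidate-causal call
(lead variant with high PIP), at least moderate LD between the TR and a
variant cataloged in the GWAS window, and a genome-wide-significant GWAS
signal in the window at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .catalog import TRLocus, canonical_motif
from .finemap import CandidateCausalCall, log_abf

# Default configuration priors (per variant): causal for expression only,
# trait only, or both.  Prior effect sd 0.15 for a quantile-normalized
# quantitative trait (sdY = 1), 0.2 on the log-odds scale for binary traits.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
W_QUANT = 0.15**2
W_BINARY = 0.2**2
GENOME_WIDE_P = 5e-8


class ColocError(ValueError):
    pass


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one gene x trait pair."""

    pp: dict  # {"H0": .., "H1": .., "H2": .., "H3": .., "H4": ..}
    n_variants: int
    gene: str = ""
    cell_type: str = ""
    trait: str = ""
    gating: dict = field(default_factory=dict)

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b == -np.inf:
        return a
    if a - b < 1e-12:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    beta_eqtl,
    se_eqtl,
    beta_gwas,
    se_gwas,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    W_eqtl: float = W_QUANT,
    W_gwas: float = W_QUANT,
    gene: str = "",
    cell_type: str = "",
    trait: str = "",
) -> ColocResult:
    """Colocalization posterior from two sets of summary statistics.

    Inputs must already be harmonized: element j of each array refers to the
    same variant.  Unnormalized hypothesis weights are

        L0 = 1
        L1 = p1 * sum_j ABF1_j
        L2 = p2 * sum_j ABF2_j
        L3 = p1 p2 * (sum_j ABF1_j * sum_j ABF2_j - sum_j ABF1_j ABF2_j)
        L4 = p12 * sum_j ABF1_j ABF2_j

    computed in log space and normalized to the posterior probabilities.
    With a single shared variant the H3 term is exactly zero.
    """
    b1 = np.asarray(beta_eqtl, dtype=float)
    s1 = np.asarray(se_eqtl, dtype=float)
    b2 = np.asarray(beta_gwas, dtype=float)
    s2 = np.asarray(se_gwas, dtype=float)
    if not (b1.shape == s1.shape == b2.shape == s2.shape):
        raise ColocError("summary statistic arrays must be aligned")
    if b1.size == 0:
        raise ColocError("zero shared variants")
    l1 = log_abf(b1, s1, W_eqtl)
    l2 = log_abf(b2, s2, W_gwas)
    logS1 = float(logsumexp(l1))
    logS2 = float(logsumexp(l2))
    logS12 = float(logsumexp(l1 + l2))
    logL = np.array(
        [
            0.0,
            np.log(p1) + logS1,
            np.log(p2) + logS2,
            np.log(p1) + np.log(p2) + _logdiffexp(logS1 + logS2, logS12),
            np.log(p12) + logS12,
        ]
    )
    pp = np.exp(logL - logsumexp(logL))
    keys = ["H0", "H1", "H2", "H3", "H4"]
    return ColocResult(pp=dict(zip(keys, pp.tolist())), n_variants=int(b1.size),
                       gene=gene, cell_type=cell_type, trait=trait)


def harmonize_variants(
    eqtl_trs: Sequence[TRLocus] = (),
    gwas_trs: Sequence[TRLocus] = (),
    eqtl_snvs: pd.DataFrame | None = None,
    gwas_snvs: pd.DataFrame | None = None,
) -> dict:
    """Match variant identifiers across two catalogs.

    TR pairs match iff their intervals intersect and their motif classes
    (cyclic rotation / reverse complement equivalence) are equal.  SNVs match
    on (chrom, pos) with identical allele sets; a ref/alt swap matches with a
    recorded sign flip for the effect.  SNV frames need columns
    chrom, pos, ref, alt, id.  Returns a dict with ``tr_pairs`` (list of
    (eqtl_id, gwas_id)), ``snv_pairs`` (list of (eqtl_id, gwas_id, sign)),
    and unmatched counts.
    """
    tr_pairs = []
    for a in eqtl_trs:
        for b in gwas_trs:
            if a.overlap_bp(b) > 0 and a.motif_class == b.motif_class:
                tr_pairs.append((a.locus_id, b.locus_id))
    snv_pairs = []
    if eqtl_snvs is not None and gwas_snvs is not None:
        gwas_by_pos: dict[tuple, list] = {}
        for row in gwas_snvs.itertuples(index=False):
            gwas_by_pos.setdefault((row.chrom, row.pos), []).append(row)
        for row in eqtl_snvs.itertuples(index=False):
            for other in gwas_by_pos.get((row.chrom, row.pos), []):
                if (row.ref, row.alt) == (other.ref, other.alt):
                    snv_pairs.append((row.id, other.id, +1))
                elif (row.ref, row.alt) == (other.alt, other.ref):
                    snv_pairs.append((row.id, other.id, -1))
    n_eqtl = len(list(eqtl_trs)) + (0 if eqtl_snvs is None else len(eqtl_snvs))
    n_gwas = len(list(gwas_trs)) + (0 if gwas_snvs is None else len(gwas_snvs))
    n_matched = len(tr_pairs) + len(snv_pairs)
    return {
        "tr_pairs": tr_pairs,
        "snv_pairs": snv_pairs,
        "n_unmatched_eqtl": n_eqtl - n_matched,
        "n_unmatched_gwas": n_gwas - n_matched,
    }


def gate_colocalization(
    coloc: ColocResult,
    candidate: CandidateCausalCall,
    gwas_window_p: Sequence[float],
    max_r2_with_gwas: float,
    pp_h4_threshold: float = 0.8,
    r2_threshold: float = 0.5,
    genome_wide_p: float = GENOME_WIDE_P,
) -> tuple[bool, dict]:
    """Apply the gating rules for a TR-driven trait colocalization.

    Passes iff PP H4 >= 0.8, the candidate-causal call passes (lead variant
    with PIP >= 0.7), the maximum LD r^2 between the sc-eTR and any variant
    cataloged in the GWAS window is >= 0.5, and the window contains at least
    one genome-wide significant (P < 5e-8) GWAS signal (eligibility; without
    it the pair is ineligible rather than failed).  Thresholds configurable.
    """
    gwas_p = np.asarray(list(gwas_window_p), dtype=float)
    eligible = bool(gwas_p.size and np.any(gwas_p < genome_wide_p))
    report = {
        "pp_h4": coloc.pp_h4,
        "pp_h4_ok": bool(coloc.pp_h4 >= pp_h4_threshold),
        "candidate_causal_ok": bool(candidate.passes),
        "max_r2": float(max_r2_with_gwas),
        "ld_ok": bool(max_r2_with_gwas >= r2_threshold),
        "gwas_hit_in_window": eligible,
    }
    passes = bool(
        eligible
        and report["pp_h4_ok"]
        and report["candidate_causal_ok"]
        and report["ld_ok"]
    )
    report["passes"] = passes
    coloc.gating = report
    return passes, report
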