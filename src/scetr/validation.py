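"""Genotype-accuracy machinery: fragment-length conversion, systematic
offset scoring, and caller-vs-truth concordance.

Capillary-electrophoresis validation reports fragment sizes in base pairs;
``pcr_to_repeats`` converts these to repeat copies via
c = floor(r + (w - l) / s).  Some loci show a constant repeat-unit offset
between a caller and the fragment-derived truth; ``score_offsets``
implements the credit scheme (1 / 0.5 / 0.25) that identifies such offsets
and adopts one per locus only when every caller agrees on it and the locus
has enough calls.  Concordance is measured on the summed repeat dosage,
strictly and allowing a +/-1 repeat difference.

Offset sign convention: an offset d is the correction *added to the caller
genotype* to recover the truth alleles (d = truth - caller for a pure
systematic shift).  Applying an adopted offset to the truth table subtracts
d, aligning truth with the caller.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeTable


class ValidationError(ValueError):
    pass


MIN_CALLS_FOR_OFFSET = 20


def pcr_to_repeats(w: float, l: float, s: int, r: float) -> int | None:
    """Repeat copies from a PCR fragment length: floor(r + (w - l)/s).

    ``w``: measured fragment length (bp); ``l``: reference amplicon length
    (bp); ``s``: motif length (bp); ``r``: reference repeat count.  Negative
    results are masked (returns None, flagged by the caller).
    """
    if s < 1:
        raise ValidationError("motif length must be >= 1")
    if w < 0 or l < 0:
        raise ValidationError("fragment lengths must be nonnegative")
    c = math.floor(r + (w - l) / s)
    return None if c < 0 else c


def _credit(caller: tuple[float, float], truth: tuple[float, float],
            offset: int) -> float:
    """Credit for one discordant call under a candidate offset.

    Shifting both caller alleles by the offset: recovering both truth
    alleles scores 1; recovering exactly one scores 0.5 if the caller call
    was homozygous and 0.25 if heterozygous.
    """
    shifted = sorted((caller[0] + offset, caller[1] + offset))
    t = sorted(truth)
    if shifted == t:
        return 1.0
    # count recovered alleles as a multiset intersection
    recovered = 0
    pool = list(t)
    for a in shifted:
        if a in pool:
            pool.remove(a)
            recovered += 1
    if recovered == 0:
        return 0.0
    return 0.5 if caller[0] == caller[1] else 0.25


@dataclass
class OffsetScore:
    locus: str
    caller: str
    offset: int
    score_sum: float
    n_calls: int


@dataclass
class OffsetReport:
    per_caller_top: dict  # (locus, caller) -> top offset
    adopted: dict  # locus -> adopted offset (may be 0)
    scores: list[OffsetScore] = field(default_factory=list)


def _rank_key(item: tuple[int, float]) -> tuple:
    offset, score = item
    # max score first; ties toward smaller |offset|, then negative first
    return (-score, abs(offset), offset)


def score_offsets(
    comparisons: Mapping[str, Mapping[str, Sequence[tuple]]],
    candidate_offsets: Iterable[int] = range(-10, 11),
    min_calls: int = MIN_CALLS_FOR_OFFSET,
) -> OffsetReport:
    """Score candidate constant offsets per locus per caller.

    ``comparisons`` maps locus -> caller -> list of
    ((caller_a1, caller_a2), (truth_a1, truth_a2)) genotype pairs (unordered
    within each pair).  For every discordant call and candidate offset the
    1/0.5/0.25 credit scheme accumulates a score; the top-ranking offset per
    caller is the one with the highest score, ties broken toward smaller
    magnitude then negative before positive.  A locus adopts an offset iff
    every caller present ranks it top and the locus has at least
    ``min_calls`` calls (counted per caller, minimum over callers).
    """
    offsets = list(candidate_offsets)
    if 0 not in offsets:
        offsets.append(0)
    per_caller_top: dict[tuple, int] = {}
    adopted: dict[str, int] = {}
    all_scores: list[OffsetScore] = []
    for locus, by_caller in comparisons.items():
        tops = []
        n_calls_per_caller = []
        for caller, calls in by_caller.items():
            totals = defaultdict(float)
            for caller_gt, truth_gt in calls:
                # every call is scored under every candidate offset; a
                # concordant call is full recovery at offset 0, so mostly
                # concordant loci robustly rank offset 0 on top even when a
                # few sporadic errors favor a spurious shift
                for d in offsets:
                    totals[d] += _credit(tuple(caller_gt), tuple(truth_gt), d)
            ranked = sorted(((d, totals.get(d, 0.0)) for d in offsets),
                            key=_rank_key)
            top = ranked[0][0]
            per_caller_top[(locus, caller)] = top
            tops.append(top)
            n_calls_per_caller.append(len(calls))
            all_scores.extend(
                OffsetScore(locus=locus, caller=caller, offset=d,
                            score_sum=sc, n_calls=len(calls))
                for d, sc in sorted(totals.items())
            )
        if tops and len(set(tops)) == 1 and min(n_calls_per_caller) >= min_calls:
            adopted[locus] = tops[0]
    return OffsetReport(per_caller_top=per_caller_top, adopted=adopted,
                        scores=all_scores)


def apply_offsets(truth: GenotypeTable, adopted: Mapping[str, int]) -> GenotypeTable:
    """Apply adopted offsets to the truth table (subtracting each offset so
    corrected truth aligns with the caller)."""
    out = truth.copy()
    for locus, d in adopted.items():
        if d == 0 or locus not in out.variant_ids:
            continue
        j = out.variant_ids.index(locus)
        out.allele1[:, j] -= d
        out.allele2[:, j] -= d
    return out


@dataclass
class TruthComparison:
    locus: str
    n_calls: int
    strict_concordance: float
    tolerant_concordance: float


def concordance(
    caller: GenotypeTable,
    truth: GenotypeTable,
    mode: str = "dosage",
) -> tuple[list[TruthComparison], dict]:
    """Per-locus and aggregate caller-vs-truth genotype concordance.

    ``mode="dosage"`` (default) compares the summed repeat dosage: strict
    requires equality, tolerant allows an absolute difference of at most 1
    repeat unit.  ``mode="pair"`` compares unordered allele pairs: strict
    requires both alleles to match; tolerant allows each allele to be off by
    at most 1 under the best pairing.
    """
    shared_samples = [s for s in caller.samples if s in set(truth.samples)]
    shared_loci = [v for v in caller.variant_ids if v in set(truth.variant_ids)]
    if not shared_samples or not shared_loci:
        raise ValidationError("no shared samples/loci between caller and truth")
    ci = [caller.samples.index(s) for s in shared_samples]
    ti = [truth.samples.index(s) for s in shared_samples]
    per_locus: list[TruthComparison] = []
    n_total = n_strict = n_tol = 0
    for locus in shared_loci:
        jc = caller.variant_ids.index(locus)
        jt = truth.variant_ids.index(locus)
        ca1, ca2 = caller.allele1[ci, jc], caller.allele2[ci, jc]
        ta1, ta2 = truth.allele1[ti, jt], truth.allele2[ti, jt]
        ok = ~(np.isnan(ca1) | np.isnan(ta1))
        n = int(ok.sum())
        if n == 0:
            per_locus.append(TruthComparison(locus, 0, np.nan, np.nan))
            continue
        if mode == "dosage":
            diff = np.abs((ca1 + ca2)[ok] - (ta1 + ta2)[ok])
            strict = diff == 0
            tolerant = diff <= 1
        elif mode == "pair":
            c_lo, c_hi = np.minimum(ca1, ca2)[ok], np.maximum(ca1, ca2)[ok]
            t_lo, t_hi = np.minimum(ta1, ta2)[ok], np.maximum(ta1, ta2)[ok]
            strict = (c_lo == t_lo) & (c_hi == t_hi)
            tolerant = (np.abs(c_lo - t_lo) <= 1) & (np.abs(c_hi - t_hi) <= 1)
        else:
            raise ValidationError(f"unknown concordance mode {mode!r}")
        per_locus.append(
            TruthComparison(locus, n, float(strict.mean()), float(tolerant.mean()))
        )
        n_total += n
        n_strict += int(strict.sum())
        n_tol += int(tolerant.sum())
    if n_total == 0:
        raise ValidationError("no shared non-missing calls")
    aggregate = {
        "n_calls": n_total,
        "strict_concordance": n_strict / n_total,
        "tolerant_concordance": n_tol / n_total,
    }
    return per_locus, aggregate


def concordance_report(per_locus: Sequence[TruthComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in per_locus])
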