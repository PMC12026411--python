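"""Genotype containers and locus/call-level quality control.

TR genotypes are diploid repeat-length pairs; SNV genotypes are
non-reference allele dosages in [0, 2].  Both live in a :class:`GenotypeTable`
backed by numpy arrays with NaN marking missing calls.

The locus filters mirror standard practice for repeat genotyping pipelines:
calls far outside the modal allele are masked as likely genotyping artifacts,
then loci are dropped on call rate, polymorphism (expected heterozygosity,
equivalently non-major allele frequency) and departure from Hardy-Weinberg
equilibrium measured by an exact binomial test on the heterozygote count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Default filter thresholds: call rate >= 90%, expected heterozygosity >=
# 0.00995 (non-major allele frequency >= 0.5%), HWE exact binomial p >= 1e-6,
# masking window mode - 30 .. mode + 20 repeats, SNV MAF >= 1%.
DEFAULT_MIN_CALL_RATE = 0.90
DEFAULT_MIN_HET = 0.00995
DEFAULT_HWE_P = 1e-6
DEFAULT_MASK_BELOW = 30
DEFAULT_MASK_ABOVE = 20
DEFAULT_MIN_MAF = 0.01


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Samples x variants genotype matrix.

    For ``kind="tr"`` the table stores two allele matrices (repeat counts,
    ``allele1``/``allele2``, shape n_samples x n_variants, NaN = missing).
    For ``kind="snv"`` it stores a single ``dosage`` matrix in [0, 2].
    ``variants`` holds the variant objects (``TRLocus`` for TRs; any object
    with an id for SNVs) and ``variant_ids`` their string identifiers.
    """

    samples: list[str]
    variant_ids: list[str]
    kind: str  # "tr" | "snv"
    allele1: np.ndarray | None = None
    allele2: np.ndarray | None = None
    dosage: np.ndarray | None = None
    variants: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("tr", "snv"):
            raise GenotypeError(f"unknown table kind {self.kind!r}")
        n, m = len(self.samples), len(self.variant_ids)
        if self.kind == "tr":
            if self.allele1 is None or self.allele2 is None:
                raise GenotypeError("TR table requires allele1/allele2")
            self.allele1 = np.asarray(self.allele1, dtype=float)
            self.allele2 = np.asarray(self.allele2, dtype=float)
            if self.allele1.shape != (n, m) or self.allele2.shape != (n, m):
                raise GenotypeError("allele matrices must be n_samples x n_variants")
            # one missing allele voids the whole diploid call
            either = np.isnan(self.allele1) | np.isnan(self.allele2)
            self.allele1[either] = np.nan
            self.allele2[either] = np.nan
        else:
            if self.dosage is None:
                raise GenotypeError("SNV table requires dosage")
            self.dosage = np.asarray(self.dosage, dtype=float)
            if self.dosage.shape != (n, m):
                raise GenotypeError("dosage matrix must be n_samples x n_variants")
            with np.errstate(invalid="ignore"):
                if np.nanmin(self.dosage, initial=0) < 0 or np.nanmax(
                    self.dosage, initial=0
                ) > 2:
                    raise GenotypeError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def summed_dosage(self) -> np.ndarray:
        """Per-call dosage matrix: summed repeat length (TR) or allele dosage.

        NaN where either allele is missing.
        """
        if self.kind == "tr":
            return self.allele1 + self.allele2
        return self.dosage.copy()

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeTable":
        keep = list(keep)
        kwargs = dict(
            samples=self.samples,
            variant_ids=[self.variant_ids[i] for i in keep],
            kind=self.kind,
            variants=[self.variants[i] for i in keep] if self.variants else [],
        )
        if self.kind == "tr":
            kwargs["allele1"] = self.allele1[:, keep].copy()
            kwargs["allele2"] = self.allele2[:, keep].copy()
        else:
            kwargs["dosage"] = self.dosage[:, keep].copy()
        return GenotypeTable(**kwargs)

    def copy(self) -> "GenotypeTable":
        return self.subset_variants(range(self.n_variants))


def summed_dosage(call: tuple) -> float:
    """Summed repeat dosage of one diploid call; NaN if any allele missing."""
    a1, a2 = call
    if a1 is None or a2 is None or (isinstance(a1, float) and math.isnan(a1)) or (
        isinstance(a2, float) and math.isnan(a2)
    ):
        return float("nan")
    return float(a1) + float(a2)


def expected_heterozygosity(allele_freqs) -> float:
    """Expected heterozygosity 1 - sum(p_k^2) over allele frequencies.

    The polymorphism filter's threshold of 0.00995 corresponds to a
    non-major allele frequency of 0.5% at a biallelic locus
    (2 * 0.995 * 0.005 = 0.00995).
    """
    if isinstance(allele_freqs, dict):
        freqs = np.asarray(list(allele_freqs.values()), dtype=float)
    else:
        freqs = np.asarray(list(allele_freqs), dtype=float)
    if freqs.size == 0:
        raise GenotypeError("no allele frequencies")
    if np.any(freqs < 0):
        raise GenotypeError("negative allele frequency")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise GenotypeError(f"allele frequencies sum to {freqs.sum()}, not 1")
    return float(1.0 - np.sum(freqs**2))


def _mode_allele(alleles: np.ndarray) -> float:
    """Most frequent allele; ties broken toward the smaller allele."""
    vals, counts = np.unique(alleles[~np.isnan(alleles)], return_counts=True)
    if vals.size == 0:
        raise GenotypeError("mode undefined: no non-missing calls")
    return float(vals[np.argmax(counts)])  # np.unique sorts, argmax takes first max


def mask_outlier_calls(
    table: GenotypeTable,
    below: int = DEFAULT_MASK_BELOW,
    above: int = DEFAULT_MASK_ABOVE,
) -> GenotypeTable:
    """Mask TR calls far outside the modal allele.

    An allele more than ``below`` repeats less or ``above`` repeats greater
    than the locus mode voids the whole diploid call (summed dosage would be
    undefined otherwise).  Returns a new table; the input is not modified.
    """
    if table.kind != "tr":
        raise GenotypeError("masking applies to TR tables")
    out = table.copy()
    for j in range(out.n_variants):
        pooled = np.concatenate([out.allele1[:, j], out.allele2[:, j]])
        if np.all(np.isnan(pooled)):
            continue
        mode = _mode_allele(pooled)
        lo, hi = mode - below, mode + above
        with np.errstate(invalid="ignore"):
            bad = (
                (out.allele1[:, j] < lo)
                | (out.allele1[:, j] > hi)
                | (out.allele2[:, j] < lo)
                | (out.allele2[:, j] > hi)
            )
        out.allele1[bad, j] = np.nan
        out.allele2[bad, j] = np.nan
    return out


def locus_qc_report(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus QC metrics: call rate, heterozygosity, HWE p, mode allele."""
    rows = []
    for j in range(table.n_variants):
        a1, a2 = table.allele1[:, j], table.allele2[:, j]
        called = ~np.isnan(a1)
        n_called = int(called.sum())
        call_rate = n_called / table.n_samples
        if n_called == 0:
            rows.append(
                dict(variant=table.variant_ids[j], call_rate=0.0, het_expected=0.0,
                     het_observed=0.0, hwe_p=1.0, mode_allele=np.nan, n_called=0)
            )
            continue
        pooled = np.concatenate([a1[called], a2[called]])
        vals, counts = np.unique(pooled, return_counts=True)
        freqs = counts / counts.sum()
        het_exp = float(1.0 - np.sum(freqs**2))
        n_het = int(np.sum(a1[called] != a2[called]))
        het_obs = n_het / n_called
        if het_exp <= 0.0:
            hwe_p = 1.0
        else:
            hwe_p = float(stats.binomtest(n_het, n_called, het_exp).pvalue)
        rows.append(
            dict(
                variant=table.variant_ids[j],
                call_rate=call_rate,
                het_expected=het_exp,
                het_observed=het_obs,
                hwe_p=hwe_p,
                mode_allele=_mode_allele(pooled),
                n_called=n_called,
            )
        )
    return pd.DataFrame(rows)


def filter_loci(
    table: GenotypeTable,
    min_call_rate: float = DEFAULT_MIN_CALL_RATE,
    min_het: float = DEFAULT_MIN_HET,
    hwe_p: float = DEFAULT_HWE_P,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop TR loci failing call-rate, polymorphism or HWE filters.

    Masking must already have been applied.  Thresholds are inclusive on the
    passing side: a locus passes with call rate >= ``min_call_rate``,
    expected heterozygosity >= ``min_het`` and exact-binomial HWE p-value
    >= ``hwe_p``.  Returns the filtered table and the per-locus report with a
    ``pass`` column.
    """
    if table.n_variants == 0:
        raise GenotypeError("empty genotype table")
    report = locus_qc_report(table)
    passed = (
        (report["call_rate"] >= min_call_rate)
        & (report["het_expected"] >= min_het)
        & (report["hwe_p"] >= hwe_p)
    )
    report["pass"] = passed
    keep = np.flatnonzero(passed.to_numpy())
    return table.subset_variants(keep), report


def filter_snvs(
    table: GenotypeTable, min_maf: float = DEFAULT_MIN_MAF
) -> GenotypeTable:
    """Retain biallelic SNVs with minor allele frequency >= ``min_maf``."""
    if table.kind != "snv":
        raise GenotypeError("filter_snvs applies to SNV tables")
    with np.errstate(invalid="ignore"):
        af = np.nanmean(table.dosage, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=0.0) >= min_maf)
    return table.subset_variants(keep)
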