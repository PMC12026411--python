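"""Per-cohort, per-cell-type linear association of dosage with expression.

The model is y = W a + g b + e: normalized expression regressed on the
summed TR repeat dosage (or SNV allele dosage, or methylation regressor g)
with covariates W, fit by ordinary least squares with classical
(homoskedastic) standard errors and a two-sided t-test on b.  Expression is
inverse-normal transformed per gene before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats


class AssociationError(ValueError):
    pass


class DegenerateVariantError(AssociationError):
    pass


class CollinearityError(AssociationError):
    pass


@dataclass
class AssocStat:
    """Effect estimate for one variant x phenotype test."""

    variant: str
    gene: str
    cell_type: str = ""
    cohort: str = ""
    beta: float = np.nan
    se: float = np.nan
    p: float = np.nan
    n: int = 0


@dataclass
class PseudobulkMatrix:
    """Per cell type, per cohort pseudobulk expression with covariates.

    ``expression``: samples x genes DataFrame of normalized expression;
    ``expressed_fraction``: per-gene fraction of cells expressing it (drives
    the 1%-of-cells testability filter); ``covariates``: samples x covariate
    DataFrame (sex, age, genotype-PC and expression-PC surrogates).
    """

    cell_type: str
    cohort: str
    expression: pd.DataFrame
    expressed_fraction: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)


def inverse_normal_transform(values, offset: str = "weibull") -> np.ndarray:
    """Rank-based transform of values to standard-normal quantiles.

    Ranks (average rank for ties) are mapped to quantiles rank/(n+1)
    (Weibull plotting position; ``offset="blom"`` uses (rank-3/8)/(n+1/4))
    and passed through the standard-normal quantile function, so the output
    has mean ~0 and sd ~1 and depends on the input only through its ranks.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise AssociationError("expected a 1-d vector")
    if np.any(np.isnan(x)):
        raise AssociationError("missing values must be removed before transforming")
    n = x.size
    if n < 3:
        raise AssociationError("need at least 3 values to transform")
    if np.all(x == x[0]):
        raise AssociationError("all values equal: ranks undefined")
    ranks = stats.rankdata(x, method="average")
    if offset == "weibull":
        q = ranks / (n + 1)
    elif offset == "blom":
        q = (ranks - 0.375) / (n + 0.25)
    else:
        raise AssociationError(f"unknown plotting position {offset!r}")
    return special.ndtri(q)


def fit_association(
    y,
    g,
    W=None,
    variant: str = "",
    gene: str = "",
    cell_type: str = "",
    cohort: str = "",
) -> AssocStat:
    """OLS fit of y = W a + g b + e; returns the estimate of b.

    Samples with missing dosage (or missing y) are dropped per test
    (complete-case).  An intercept is always included.  Classical standard
    error and two-sided t-test p-value.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape:
        raise AssociationError("y and g must be aligned")
    if W is None:
        W = np.empty((y.size, 0))
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if W.shape[0] != y.size:
        raise AssociationError("W must be aligned with y")

    ok = ~(np.isnan(y) | np.isnan(g) | np.isnan(W).any(axis=1))
    y, g, W = y[ok], g[ok], W[ok]
    n = y.size
    k = W.shape[1] + 2  # intercept + covariates + g
    if n < k + 1:
        raise AssociationError(f"too few samples ({n}) for {k} parameters")
    if np.all(g == g[0]):
        raise DegenerateVariantError(f"variant {variant or '<g>'} constant after missingness")

    X = np.column_stack([np.ones(n), W, g])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError("design matrix [1, W, g] is rank deficient")

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    beta = float(coef[-1])
    if se == 0.0:
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return AssocStat(variant=variant, gene=gene, cell_type=cell_type,
                     cohort=cohort, beta=beta, se=se, p=max(p, 5e-324), n=n)


def marginal_ols(y, G, W=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized marginal OLS of y on each column of G with covariates W.

    Equivalent to calling :func:`fit_association` per column (no missing
    data allowed here): y and G are residualized on [1, W]
    (Frisch-Waugh-Lovell), then each variant gets a simple regression with
    the full-model degrees of freedom.  Returns (beta, se, p) arrays.
    """
    y = np.asarray(y, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != y.size:
        G = G.T
    n = y.size
    X = np.ones((n, 1)) if W is None else np.column_stack(
        [np.ones(n), np.asarray(W, dtype=float)]
    )
    Q, _ = np.linalg.qr(X)
    ry = y - Q @ (Q.T @ y)
    RG = G - Q @ (Q.T @ G)
    ss_g = np.einsum("ij,ij->j", RG, RG)
    if np.any(ss_g <= 0):
        raise DegenerateVariantError("constant variant in marginal_ols")
    beta = (RG.T @ ry) / ss_g
    dof = n - X.shape[1] - 1
    rss = ry @ ry - beta**2 * ss_g
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / ss_g)
    t = beta / se
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), dof), 5e-324)
    return beta, se, p


def map_gene(
    gene: str,
    expression,
    dosages,
    variant_ids: Sequence[str],
    covariates=None,
    expressed_fraction: float = 1.0,
    min_expressed_fraction: float = 0.01,
    cell_type: str = "",
    cohort: str = "",
    transform: bool = True,
) -> list[AssocStat]:
    """Test every variant in a gene's cis window against its expression.

    The gene is skipped entirely in a cell type where it is expressed in
    fewer than ``min_expressed_fraction`` of cells (inclusive at the
    boundary).  Degenerate variants (constant dosage) are skipped; every
    testable variant yields one :class:`AssocStat`.
    """
    if expressed_fraction < min_expressed_fraction:
        return []
    y = np.asarray(expression, dtype=float)
    if transform:
        y = inverse_normal_transform(y)
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    if dosages.shape[0] == y.size and dosages.shape[1] == len(variant_ids):
        pass
    elif dosages.shape == (len(variant_ids), y.size):
        dosages = dosages.T
    else:
        raise AssociationError("dosage matrix must be samples x variants")
    out = []
    for j, vid in enumerate(variant_ids):
        try:
            out.append(
                fit_association(y, dosages[:, j], covariates, variant=vid,
                                gene=gene, cell_type=cell_type, cohort=cohort)
            )
        except DegenerateVariantError:
            continue
    return out


def map_methylation(
    cpg_values,
    tr_dosages,
    tr_ids: Sequence[str],
    covariates=None,
    min_sd: float = 0.02,
    cpg_id: str = "",
) -> list[AssocStat]:
    """Associate TR dosage with methylation at one CpG site.

    Sites whose methylation standard deviation is <= ``min_sd`` are excluded
    (returns []).  Retained values are inverse-normal transformed and fit
    with the same OLS model as expression.  Bonferroni correction across all
    TR-CpG pairs is applied by the caller via :func:`bonferroni`.
    """
    vals = np.asarray(cpg_values, dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise AssociationError("methylation values must lie in [0, 1]")
    if float(np.std(vals)) <= min_sd:
        return []
    return map_gene(cpg_id, vals, tr_dosages, tr_ids, covariates=covariates,
                    transform=True)


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = n_tests if n_tests is not None else p.size
    return np.minimum(p * m, 1.0)
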