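"""Synthetic cohort generator with the statistical structure of a two-batch
single-cell eTR study.

The generator emulates the data the analysis assumes, so every downstream
stage is testable without any external download:

* diploid TR repeat lengths under a stepwise mutation model around a modal
  allele (number of +/-1 steps per haplotype is geometric);
* biallelic tag SNVs in tunable LD with each TR, plus independent filler
  SNVs in the same cis windows;
* two cohorts ("batches") of samples with cohort-specific expression
  intercept shifts;
* per-cell-type pseudobulk expression y = W a + g b + e with planted
  shared / cell-type-specific / opposite-sign effects on the centered
  summed repeat dosage, plus covariates (sex, age, genotype-PC and
  expression-PC surrogates);
* CpG methylation probabilities linked to TR length;
* caller-vs-truth genotype pairs with per-locus constant offsets and
  sporadic random errors, for the validation machinery.

All randomness flows from ``SimulationConfig.seed`` through per-operation
child generators, so a fixed seed reproduces every table exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import PseudobulkMatrix
from .catalog import TRLocus
from .genotype_qc import GenotypeTable

_MOTIFS = ("A", "AT", "AC", "AGC", "AAAG", "ATGG", "AAGG")
CHROM = "chrS"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SNV:
    """Biallelic SNV record (0-based position; interval of length 1)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    snv_id: str

    @property
    def start(self) -> int:
        return self.pos

    @property
    def end(self) -> int:
        return self.pos + 1


@dataclass(frozen=True)
class PlantedEffect:
    """One planted eTR effect: TR locus -> gene, with per-cell-type betas.

    ``betas`` maps cell type -> effect per unit centered summed repeat
    dosage; cell types absent from the map have a null effect.
    """

    tr_index: int
    gene: str
    betas: Mapping[str, float]


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Defaults are the study conditions the analysis is exercised under:
    two cohorts, a stepwise mutation model with step probability 0.3 (most
    alleles within a few repeats of the mode, matching the observed
    mode-centered allele distributions), tag-SNV LD r^2 of 0.5 (moderate TR-
    SNV LD), unit residual expression noise on the quantile-normalized
    scale, sex + age + 12 genotype-PC + 6 expression-PC covariate
    surrogates, and genes placed so each cis window is controlled exactly.
    """

    n_samples_per_cohort: int = 400
    n_cohorts: int = 2
    n_cell_types: int = 4
    n_tr_loci: int = 20
    n_snv_loci: int = 60
    n_genes: int = 20
    mode_alleles: int | Sequence[int] = 20
    step_prob: float = 0.3
    ld_target: float = 0.5
    effect_table: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    expressed_fraction: float = 0.2
    missing_rate: float = 0.0
    n_genotype_pcs: int = 12
    n_expression_pcs: int = 6
    locus_spacing: int = 250_000
    n_cpg_sites: int = 0
    meth_effect: float = 0.4
    meth_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_per_cohort", "n_cohorts", "n_cell_types",
                     "n_tr_loci", "n_genes"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        for name in ("step_prob", "ld_target", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        modes = np.atleast_1d(np.asarray(self.mode_alleles))
        if np.any(modes < 1):
            raise SimulationError("mode alleles must be positive repeat counts")

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{i:02d}" for i in range(self.n_cell_types)]

    @property
    def cohorts(self) -> list[str]:
        return [f"cohort{i}" for i in range(self.n_cohorts)]

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_cohort * self.n_cohorts

    def sample_ids(self) -> list[str]:
        return [
            f"{cohort}_S{i:04d}"
            for cohort in self.cohorts
            for i in range(self.n_samples_per_cohort)
        ]

    def cohort_of_sample(self) -> np.ndarray:
        return np.repeat(self.cohorts, self.n_samples_per_cohort)

    def mode_allele_array(self) -> np.ndarray:
        modes = np.atleast_1d(np.asarray(self.mode_alleles, dtype=int))
        if modes.size == 1:
            return np.full(self.n_tr_loci, int(modes[0]))
        if modes.size != self.n_tr_loci:
            raise SimulationError("mode_alleles must be scalar or one per locus")
        return modes

    def tr_loci(self) -> list[TRLocus]:
        """Synthetic loci on one artificial chromosome at fixed spacing."""
        modes = self.mode_allele_array()
        loci = []
        for i in range(self.n_tr_loci):
            motif = _MOTIFS[i % len(_MOTIFS)]
            start = 1_000_000 + i * self.locus_spacing
            end = start + len(motif) * int(modes[i])
            loci.append(TRLocus(CHROM, start, end, motif, ref_repeats=float(modes[i])))
        return loci

    def genes(self) -> dict[str, tuple[int, int]]:
        """Gene TSS/TES placed 1 kb downstream of the paired TR locus, so
        window membership is controlled exactly (gene g pairs with TR
        g mod n_tr_loci)."""
        loci = self.tr_loci()
        out = {}
        for g in range(self.n_genes):
            loc = loci[g % self.n_tr_loci]
            tss = loc.end + 1_000
            out[f"GENE{g:04d}"] = (tss, tss + 2_000)
        return out


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    tr_genotypes: GenotypeTable
    snv_genotypes: GenotypeTable
    expression: dict  # (cohort, cell_type) -> PseudobulkMatrix
    covariates: pd.DataFrame  # all samples x covariates (with cohort column)
    methylation: pd.DataFrame | None
    truth: list[PlantedEffect]
    genes: dict  # gene -> (tss, tes)

    def cohort_samples(self, cohort: str) -> list[str]:
        mask = self.covariates["cohort"] == cohort
        return list(self.covariates.index[mask])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _stepwise_alleles(rng, n: int, mode: int, step_prob: float) -> np.ndarray:
    """Haplotype repeat counts: mode + signed sum of geometric-many +/-1
    steps, truncated at a 1-repeat minimum."""
    if step_prob == 0.0:
        return np.full(n, float(mode))
    n_steps = rng.geometric(1.0 - step_prob, size=n) - 1
    up = rng.binomial(n_steps, 0.5)
    alleles = mode + (2 * up - n_steps)
    return np.maximum(alleles, 1).astype(float)


def simulate_tr_genotypes(config: SimulationConfig) -> GenotypeTable:
    """Diploid TR repeat-length genotypes under the stepwise mutation model.

    Each haplotype draws a geometric number of +/-1 repeat-unit steps away
    from the locus mode (unimodal, mode-centered allele distribution).
    Missingness is injected per diploid call at ``config.missing_rate``.
    """
    rng = _rng(config, 1)
    loci = config.tr_loci()
    modes = config.mode_allele_array()
    n = config.n_samples
    a1 = np.empty((n, config.n_tr_loci))
    a2 = np.empty((n, config.n_tr_loci))
    for j in range(config.n_tr_loci):
        a1[:, j] = _stepwise_alleles(rng, n, int(modes[j]), config.step_prob)
        a2[:, j] = _stepwise_alleles(rng, n, int(modes[j]), config.step_prob)
    if config.missing_rate > 0:
        miss = rng.random((n, config.n_tr_loci)) < config.missing_rate
        a1[miss] = np.nan
        a2[miss] = np.nan
    return GenotypeTable(
        samples=config.sample_ids(),
        variant_ids=[loc.locus_id for loc in loci],
        kind="tr",
        allele1=a1,
        allele2=a2,
        variants=loci,
    )


def _solve_flip_prob(hap_dosage: np.ndarray, indicator: np.ndarray,
                     ld_target: float) -> float:
    """Flip probability f such that corr(TR dosage, flipped indicator)^2
    hits ``ld_target``, solved by bisection; the flip noise enters the
    correlation analytically as a factor (1 - 2f)."""
    pX = indicator.mean()
    if pX in (0.0, 1.0):
        return 0.0
    cov_ax = np.cov(hap_dosage, indicator)[0, 1]
    sd_a = hap_dosage.std()
    if sd_a == 0 or cov_ax == 0:
        return 0.0

    def r2(f: float) -> float:
        pY = pX * (1 - f) + (1 - pX) * f
        sd_y = np.sqrt(pY * (1 - pY))
        if sd_y == 0:
            return 0.0
        r = (1 - 2 * f) * cov_ax / (sd_a * sd_y)
        return r * r

    if r2(0.0) <= ld_target:
        return 0.0
    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if r2(mid) > ld_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_snv_genotypes(
    config: SimulationConfig, tr: GenotypeTable
) -> GenotypeTable:
    """Tag SNVs in tunable LD with each TR, plus independent filler SNVs.

    Each TR locus gets one tag SNV whose haplotype allele is the indicator
    of the TR haplotype exceeding the locus mode, flipped with a
    bisection-tuned probability so the realized dosage r^2 approximates
    ``config.ld_target``.  Because the tag is a binary function of a
    mode-concentrated repeat-length distribution, the achievable dosage r^2
    is capped (around 0.5-0.6 at the default step probability); targets
    above the cap realize the cap (flip probability 0).  Remaining SNVs
    (up to ``n_snv_loci``) are
    independent with MAF drawn uniformly in [0.1, 0.5], placed inside the
    same cis windows.
    """
    rng = _rng(config, 2)
    loci = config.tr_loci()
    modes = config.mode_allele_array()
    n = config.n_samples
    n_tags = min(config.n_tr_loci, config.n_snv_loci)
    n_extra = max(0, config.n_snv_loci - n_tags)
    dosage = np.empty((n, config.n_snv_loci))
    variants: list[SNV] = []
    for j in range(n_tags):
        hap = np.concatenate([tr.allele1[:, j], tr.allele2[:, j]])
        hap = np.where(np.isnan(hap), modes[j], hap)
        x = (hap > modes[j]).astype(float)
        f = _solve_flip_prob(hap, x, config.ld_target)
        flip = rng.random(x.size) < f
        y = np.where(flip, 1 - x, x)
        dosage[:, j] = y[:n] + y[n:]
        pos = loci[j].start - 500
        variants.append(SNV(CHROM, pos, "A", "G", f"snv_tag_{j:04d}"))
    for k in range(n_extra):
        j = n_tags + k
        anchor = loci[k % config.n_tr_loci]
        maf = rng.uniform(0.1, 0.5)
        hap = (rng.random(2 * n) < maf).astype(float)
        dosage[:, j] = hap[:n] + hap[n:]
        pos = anchor.end + 2_000 + 400 * (k // config.n_tr_loci + 1)
        variants.append(SNV(CHROM, pos, "C", "T", f"snv_fill_{k:04d}"))
    return GenotypeTable(
        samples=list(tr.samples),
        variant_ids=[v.snv_id for v in variants],
        kind="snv",
        dosage=dosage,
        variants=variants,
    )


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Sample covariates: sex, age, genotype-PC and expression-PC surrogates.

    Surrogates are drawn directly as standard normals (PCA of the simulated
    genotypes is deliberately not performed; the covariate adjustment, not
    the PCA, is what the analysis model needs)."""
    rng = _rng(config, 3)
    n = config.n_samples
    data = {
        "cohort": config.cohort_of_sample(),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "age": rng.normal(50.0, 12.0, size=n),
    }
    for k in range(config.n_genotype_pcs):
        data[f"gPC{k + 1}"] = rng.normal(size=n)
    for k in range(config.n_expression_pcs):
        data[f"ePC{k + 1}"] = rng.normal(size=n)
    return pd.DataFrame(data, index=config.sample_ids())


def covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric covariate matrix (drops the cohort label column)."""
    cols = [c for c in covariates.columns if c != "cohort"]
    return covariates[cols].to_numpy(dtype=float)


def simulate_expression(
    config: SimulationConfig,
    tr: GenotypeTable,
    snv: GenotypeTable | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Pseudobulk expression per (cohort, cell type) with planted effects.

    y = cohort shift + W a + g b + Normal(0, noise_sd), where g is the
    centered summed repeat dosage of the planted TR and b the planted
    per-cell-type beta.  Covariate effects a are drawn once per gene;
    expressed-cell fractions are emitted per gene x cell type.
    """
    rng = _rng(config, 4)
    if covariates is None:
        covariates = simulate_covariates(config)
    genes = config.genes()
    gene_ids = list(genes)
    tr_dosage = tr.summed_dosage()
    centered = tr_dosage - np.nanmean(tr_dosage, axis=0)
    centered = np.nan_to_num(centered, nan=0.0)

    for eff in config.effect_table:
        if eff.tr_index >= config.n_tr_loci:
            raise SimulationError(f"planted TR index {eff.tr_index} out of range")
        if eff.gene not in genes:
            raise SimulationError(f"planted gene {eff.gene} not simulated")

    W = covariate_matrix(covariates)
    n_cov = W.shape[1]
    alpha = rng.normal(0.0, 0.1, size=(len(gene_ids), n_cov))
    cohort_shift = rng.normal(0.0, 0.5, size=(config.n_cohorts, len(gene_ids)))

    beta = np.zeros((len(gene_ids), config.n_tr_loci, config.n_cell_types))
    ct_index = {ct: i for i, ct in enumerate(config.cell_types)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for eff in config.effect_table:
        if config.expressed_fraction < 0.01:
            warnings.warn(
                f"planted effect on {eff.gene} untestable: expressed fraction "
                "< 1% in all cell types"
            )
        for ct, b in eff.betas.items():
            beta[gene_index[eff.gene], eff.tr_index, ct_index[ct]] = b

    cohort_of = config.cohort_of_sample()
    out = {}
    for ci, cohort in enumerate(config.cohorts):
        mask = cohort_of == cohort
        samples = [s for s, m in zip(config.sample_ids(), mask) if m]
        Wc = W[mask]
        for ct in config.cell_types:
            cti = ct_index[ct]
            signal = Wc @ alpha.T + cohort_shift[ci][None, :]
            signal = signal + centered[mask] @ beta[:, :, cti].T
            noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
            expr = pd.DataFrame(signal + noise, index=samples, columns=gene_ids)
            frac = pd.Series(config.expressed_fraction, index=gene_ids)
            out[(cohort, ct)] = PseudobulkMatrix(
                cell_type=ct,
                cohort=cohort,
                expression=expr,
                expressed_fraction=frac,
                covariates=covariates.loc[samples].drop(columns=["cohort"]),
            )
    return out


def simulate_methylation(
    config: SimulationConfig,
    tr: GenotypeTable,
) -> pd.DataFrame | None:
    """CpG methylation probabilities linked to TR length.

    Site k is anchored within 5 kb of TR (k mod n_tr_loci); even-indexed
    sites carry a logistic-scale effect of the standardized summed repeat
    dosage, odd-indexed sites are null.  Values lie in [0, 1].  The anchor
    TR index and planted effect are encoded in the column metadata frame
    returned via ``df.attrs['sites']``.
    """
    if config.n_cpg_sites == 0:
        return None
    rng = _rng(config, 5)
    dosage = tr.summed_dosage()
    z = dosage - np.nanmean(dosage, axis=0)
    sd = np.nanstd(z, axis=0)
    sd[sd == 0] = 1.0
    z = np.nan_to_num(z / sd, nan=0.0)
    cols, data, meta = [], [], []
    for k in range(config.n_cpg_sites):
        j = k % config.n_tr_loci
        effect = config.meth_effect if k % 2 == 0 else 0.0
        base = rng.normal(0.0, 0.4)
        logit = base + effect * z[:, j] + rng.normal(
            0.0, config.meth_noise_sd, size=config.n_samples
        )
        vals = 1.0 / (1.0 + np.exp(-logit))
        anchor = config.tr_loci()[j]
        pos = anchor.start + int(rng.integers(-4_000, 4_000))
        cols.append(f"cpg_{k:04d}")
        data.append(vals)
        meta.append(dict(site=cols[-1], pos=pos, tr_index=j, effect=effect))
    df = pd.DataFrame(np.column_stack(data), index=config.sample_ids(), columns=cols)
    df.attrs["sites"] = pd.DataFrame(meta)
    return df


def simulate_truthset(
    config: SimulationConfig,
    offsets: Mapping[int, int] | None = None,
    error_rate: float = 0.0,
) -> tuple[GenotypeTable, GenotypeTable, dict]:
    """Caller/truth genotype pair with planted systematic offsets.

    ``offsets`` maps TR locus index -> constant offset d (truth - caller):
    the caller table is the truth shifted by -d, so adding d to a caller
    genotype recovers the truth.  Sporadic errors perturb one caller allele
    by +/-1 or +/-2 with probability ``error_rate`` per call.  Returns
    (caller, truth, offset map keyed by locus id).
    """
    truth = simulate_tr_genotypes(config)
    rng = _rng(config, 6)
    caller = truth.copy()
    offset_map: dict[str, int] = {}
    offsets = offsets or {}
    for j, d in offsets.items():
        caller.allele1[:, j] -= d
        caller.allele2[:, j] -= d
        offset_map[truth.variant_ids[j]] = int(d)
    for j in range(truth.n_variants):
        offset_map.setdefault(truth.variant_ids[j], 0)
    if error_rate > 0:
        err = rng.random((truth.n_samples, truth.n_variants)) < error_rate
        which = rng.integers(0, 2, size=err.shape)
        size = rng.choice([-2, -1, 1, 2], size=err.shape)
        a1_err = err & (which == 0)
        a2_err = err & (which == 1)
        caller.allele1[a1_err] += size[a1_err]
        caller.allele2[a2_err] += size[a2_err]
        np.clip(caller.allele1, 1, None, out=caller.allele1)
        np.clip(caller.allele2, 1, None, out=caller.allele2)
    return caller, truth, offset_map


def simulate_gwas(
    config: SimulationConfig,
    causal_betas: Mapping[str, float],
    n_gwas: int = 2_000,
    noise_sd: float = 1.0,
    gwas_seed_stream: int = 7,
) -> pd.DataFrame:
    """Trait GWAS summary statistics from an independent cohort.

    A fresh cohort with the same generative parameters (hence the same
    TR/SNV LD structure) is drawn; the trait is a linear function of the
    centered dosages named in ``causal_betas`` (variant id -> beta) plus
    Gaussian noise, and each variant gets marginal OLS summary statistics.
    Returns a frame (variant, beta, se, p).
    """
    gcfg = replace(
        config,
        n_samples_per_cohort=n_gwas,
        n_cohorts=1,
        missing_rate=0.0,
        seed=int(np.random.SeedSequence([int(config.seed), gwas_seed_stream])
                 .generate_state(1)[0] % (2**31)),
    )
    tr = simulate_tr_genotypes(gcfg)
    snv = simulate_snv_genotypes(gcfg, tr)
    dos = np.column_stack([tr.summed_dosage(), snv.summed_dosage()])
    ids = tr.variant_ids + snv.variant_ids
    centered = dos - dos.mean(axis=0)
    rng = _rng(gcfg, 8)
    trait = rng.normal(0.0, noise_sd, size=dos.shape[0])
    for vid, b in causal_betas.items():
        if vid not in ids:
            raise SimulationError(f"causal variant {vid} not simulated")
        trait = trait + b * centered[:, ids.index(vid)]
    rows = []
    from scipy import stats as sps

    n = trait.size
    for j, vid in enumerate(ids):
        g = centered[:, j]
        var_g = g @ g
        if var_g == 0:
            continue
        beta = float(g @ (trait - trait.mean()) / var_g)
        resid = trait - trait.mean() - beta * g
        sigma2 = float(resid @ resid) / (n - 2)
        se = float(np.sqrt(sigma2 / var_g))
        p = float(2 * sps.t.sf(abs(beta / se), n - 2))
        rows.append(dict(variant=vid, beta=beta, se=se, p=max(p, 5e-324)))
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (genotypes, expression,
    covariates, methylation, truth)."""
    tr = simulate_tr_genotypes(config)
    snv = simulate_snv_genotypes(config, tr)
    covariates = simulate_covariates(config)
    expression = simulate_expression(config, tr, snv, covariates)
    methylation = simulate_methylation(config, tr)
    return SyntheticCohort(
        config=config,
        tr_genotypes=tr,
        snv_genotypes=snv,
        expression=expression,
        covariates=covariates,
        methylation=methylation,
        truth=list(config.effect_table),
        genes=config.genes(),
    )


def default_effect_table(config: SimulationConfig,
                         beta: float = 0.5) -> list[PlantedEffect]:
    """A standard plant layout: one globally shared effect, one
    cell-type-specific effect, one opposite-sign effect, rest null."""
    cts = config.cell_types
    effects = [
        PlantedEffect(0, "GENE0000", {ct: beta for ct in cts}),
        PlantedEffect(1, "GENE0001", {cts[0]: beta}),
    ]
    if len(cts) >= 2 and config.n_tr_loci >= 3 and config.n_genes >= 3:
        effects.append(
            PlantedEffect(2, "GENE0002", {cts[0]: beta, cts[1]: -beta})
        )
    return effects
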