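#!/usr/bin/env python
"""Simulate the standard two-cohort synthetic study and write its inputs.

Generates 2 x 400 samples, 20 TR loci with tag SNVs at r^2 ~ 0.5, 4 cell
types, one globally shared plant, one cell-type-specific plant and one
opposite-sign plant (beta = 0.5), plus a joint SNV+TR trait GWAS driven by
the shared-plant TR.  Writes genotypes (TSV + VCF), expression, covariates,
GWAS summary statistics and the planted truth under results/data/.
"""
import argparse
from pathlib import Path

from scetr import io
from scetr.synthetic_data import (
    SimulationConfig, default_effect_table, simulate_cohort, simulate_gwas,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = SimulationConfig(seed=args.seed, n_samples_per_cohort=400)
cfg.effect_table.extend(default_effect_table(cfg, beta=0.5))
cohort = simulate_cohort(cfg)
gwas = simulate_gwas(cfg, {cohort.tr_genotypes.variant_ids[0]: 0.4},
                     n_gwas=4000)

args.out.mkdir(parents=True, exist_ok=True)
io.write_tr_tsv(cohort.tr_genotypes, args.out / "tr_genotypes.tsv")
io.write_tr_vcf(cohort.tr_genotypes, args.out / "tr_genotypes.vcf")
io.write_dosage_tsv(cohort.snv_genotypes, args.out / "snv_dosage.tsv")
io.write_matrix_tsv(cohort.covariates, args.out / "covariates.tsv")
for (co, ct), pb in cohort.expression.items():
    io.write_matrix_tsv(pb.expression, args.out / f"expression_{co}_{ct}.tsv")
io.write_gwas_tsv(gwas, args.out / "gwas_trait.tsv")
io.write_truth_yaml(cohort.truth, args.out / "truth.yaml")

print(f"cohort: {cfg.n_samples} samples, {cfg.n_tr_loci} TR loci, "
      f"{cohort.snv_genotypes.n_variants} SNVs, {cfg.n_cell_types} cell types")
print(f"planted effects: {[(e.tr_index, e.gene, dict(e.betas)) for e in cohort.truth]}")
print(f"inputs written to {args.out}")
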