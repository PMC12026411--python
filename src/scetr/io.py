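"""File-format glue: genotype VCF/TSV, expression/covariate TSV, GWAS TSV,
and YAML truth/config round-trips.

TR genotypes are written as VCF with one record per locus: the REF allele
stands for the modal repeat count, each distinct non-modal repeat count gets
a symbolic ALT ``<RL{count}>``, GT carries allele indices, and the INFO
fields MOTIF and RCS (comma-separated repeat counts, REF first) carry the
repeat-length annotation.  Flat TSV (sample, locus, allele1, allele2) is the
interchange format the pipeline stages use.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .catalog import TRLocus
from .genotype_qc import GenotypeTable


# ---------------------------------------------------------------------------
# TR genotypes

def write_tr_tsv(table: GenotypeTable, path) -> None:
    rows = []
    for j, vid in enumerate(table.variant_ids):
        for i, sample in enumerate(table.samples):
            a1, a2 = table.allele1[i, j], table.allele2[i, j]
            rows.append(
                (sample, vid,
                 "" if np.isnan(a1) else int(a1),
                 "" if np.isnan(a2) else int(a2))
            )
    pd.DataFrame(rows, columns=["sample", "locus", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def read_tr_tsv(path, variants: Sequence[TRLocus] = ()) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"allele1": "Float64", "allele2": "Float64"})
    samples = list(dict.fromkeys(df["sample"]))
    loci = list(dict.fromkeys(df["locus"]))
    si = {s: i for i, s in enumerate(samples)}
    vi = {v: j for j, v in enumerate(loci)}
    a1 = np.full((len(samples), len(loci)), np.nan)
    a2 = np.full((len(samples), len(loci)), np.nan)
    for row in df.itertuples(index=False):
        i, j = si[row.sample], vi[row.locus]
        if pd.notna(row.allele1):
            a1[i, j] = float(row.allele1)
        if pd.notna(row.allele2):
            a2[i, j] = float(row.allele2)
    return GenotypeTable(samples=samples, variant_ids=loci, kind="tr",
                         allele1=a1, allele2=a2, variants=list(variants))


def write_tr_vcf(table: GenotypeTable, path) -> None:
    """TR genotypes as VCF (symbolic repeat-count alleles, see module docs)."""
    header = pysam.VariantHeader()
    chroms = sorted({loc.chrom for loc in table.variants}) or ["chrS"]
    for chrom in chroms:
        header.contigs.add(chrom, length=2**29)
    header.info.add("MOTIF", 1, "String", "Repeat motif")
    header.info.add("RCS", ".", "String", "Repeat counts per allele (REF first)")
    header.info.add("END", 1, "Integer", "Locus end (1-based inclusive)")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, loc in enumerate(table.variants):
            a1, a2 = table.allele1[:, j], table.allele2[:, j]
            counts = sorted({int(v) for v in np.concatenate([a1, a2])
                             if not np.isnan(v)})
            mode = int(loc.ref_repeats) if loc.ref_repeats else (
                counts[0] if counts else 0)
            alleles = [mode] + [c for c in counts if c != mode]
            idx = {c: k for k, c in enumerate(alleles)}
            rec = vcf.new_record(
                contig=loc.chrom,
                start=loc.start,
                stop=loc.end,
                alleles=tuple(["N"] + [f"<RL{c}>" for c in alleles[1:]]) or ("N",),
            )
            rec.info["MOTIF"] = loc.motif
            rec.info["RCS"] = [str(c) for c in alleles]
            for i, s in enumerate(table.samples):
                if np.isnan(a1[i]):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (idx[int(a1[i])], idx[int(a2[i])])
            vcf.write(rec)


def read_tr_vcf(path) -> GenotypeTable:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        loci, a1_cols, a2_cols = [], [], []
        for rec in vcf:
            motif = rec.info["MOTIF"]
            rcs = rec.info["RCS"]
            if isinstance(rcs, str):
                rcs = rcs.split(",")
            counts = [int(c) for c in rcs]
            loc = TRLocus(rec.chrom, rec.start, rec.stop, motif,
                          ref_repeats=float(counts[0]))
            loci.append(loc)
            a1 = np.full(len(samples), np.nan)
            a2 = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or gt[0] is None:
                    continue
                a1[i], a2[i] = counts[gt[0]], counts[gt[1]]
            a1_cols.append(a1)
            a2_cols.append(a2)
    return GenotypeTable(
        samples=samples,
        variant_ids=[loc.locus_id for loc in loci],
        kind="tr",
        allele1=np.column_stack(a1_cols) if a1_cols else np.empty((len(samples), 0)),
        allele2=np.column_stack(a2_cols) if a2_cols else np.empty((len(samples), 0)),
        variants=loci,
    )


# ---------------------------------------------------------------------------
# SNV dosages / expression / covariates / GWAS: plain TSV matrices

def write_dosage_tsv(table: GenotypeTable, path) -> None:
    pd.DataFrame(table.dosage, index=table.samples,
                 columns=table.variant_ids).to_csv(path, sep="\t",
                                                   index_label="sample")


def read_dosage_tsv(path, variants: Sequence = ()) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return GenotypeTable(samples=list(df.index), variant_ids=list(df.columns),
                         kind="snv", dosage=df.to_numpy(dtype=float),
                         variants=list(variants))


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "sample") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_gwas_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "beta", "se", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GWAS summary TSV missing columns: {sorted(missing)}")
    return df


def write_gwas_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# YAML truth / config

def write_truth_yaml(effects, path) -> None:
    payload = [
        dict(tr_index=int(e.tr_index), gene=str(e.gene),
             betas={str(k): float(v) for k, v in e.betas.items()})
        for e in effects
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_truth_yaml(path):
    from .synthetic_data import PlantedEffect

    with open(path) as fh:
        payload = yaml.safe_load(fh) or []
    return [PlantedEffect(int(e["tr_index"]), e["gene"], e["betas"])
            for e in payload]
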