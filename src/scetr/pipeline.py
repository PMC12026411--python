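"""End-to-end orchestration: qc -> association per cohort -> meta ->
significance -> specificity -> finemap -> conditional -> colocalization.

Every stage writes a plain TSV under the run directory so each stage is
independently re-runnable and diffable; a manifest records the
configuration hash, seed and per-stage row counts.  Reruns with the same
configuration and inputs reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssocStat, map_gene
from .catalog import assign_window
from .coloc import (
    DEFAULT_P1,
    DEFAULT_P12,
    DEFAULT_P2,
    W_QUANT,
    coloc_abf,
    gate_colocalization,
)
from .finemap import (
    call_candidate_causal,
    conditional_association,
    ld_r2,
    single_effect_finemap,
)
from .genotype_qc import filter_loci, filter_snvs, mask_outlier_calls
from .meta import classify_specificity, meta_stats
from .significance import call_significant, select_top_and_lead
from .synthetic_data import SyntheticCohort

STAGES = (
    "qc",
    "assoc",
    "meta",
    "significance",
    "specificity",
    "finemap",
    "conditional",
    "coloc",
)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their standard defaults.

    window: cis window around the gene body (bp); min_call_rate /
    min_het / hwe_p / mask_below / mask_above: TR locus QC; min_maf: SNV
    retention; min_expressed_fraction: gene testability per cell type;
    fdr: gene-level q-value cutoff; pip_threshold / pp_h4_threshold /
    r2_threshold / genome_wide_p: candidate-causal, colocalization, LD and
    GWAS-eligibility gates.
    """

    window: int = 100_000
    min_call_rate: float = 0.90
    min_het: float = 0.00995
    min_nmaf: float = 0.005
    hwe_p: float = 1e-6
    mask_below: int = 30
    mask_above: int = 20
    min_maf: float = 0.01
    min_expressed_fraction: float = 0.01
    fdr: float = 0.05
    pip_threshold: float = 0.7
    pp_h4_threshold: float = 0.8
    r2_threshold: float = 0.5
    genome_wide_p: float = 5e-8
    credible_coverage: float = 0.95
    coloc_p1: float = DEFAULT_P1
    coloc_p2: float = DEFAULT_P2
    coloc_p12: float = DEFAULT_P12
    coloc_w_eqtl: float = W_QUANT
    coloc_w_gwas: float = W_QUANT
    seed: int = 0
    cell_types: list | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


def _assoc_frame(stats) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(s) for s in stats],
        columns=["variant", "gene", "cell_type", "cohort", "beta", "se", "p", "n"],
    )


def run_pipeline(
    cohort: SyntheticCohort,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    gwas: pd.DataFrame | None = None,
    gwas_trait: str = "trait",
) -> dict:
    """Run all stages on a cohort; returns the manifest dict.

    ``gwas`` is an optional harmonized summary-statistics frame
    (variant, beta, se, p) sharing variant identifiers with the cohort;
    without it the colocalization stage is skipped (recorded in the
    manifest).  Stage outputs land in ``outdir`` when given.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    cfg_cts = config.cell_types or cohort.config.cell_types
    cohorts = cohort.config.cohorts

    # ---- stage 1: QC ------------------------------------------------------
    tr = mask_outlier_calls(cohort.tr_genotypes, below=config.mask_below,
                            above=config.mask_above)
    tr, qc_report = filter_loci(tr, min_call_rate=config.min_call_rate,
                                min_het=config.min_het, hwe_p=config.hwe_p)
    snv = filter_snvs(cohort.snv_genotypes, min_maf=config.min_maf)
    counts["qc"] = int(qc_report["pass"].sum()) + snv.n_variants
    if outdir is not None:
        _write(qc_report, outdir / "qc_report.tsv")

    tr_by_id = dict(zip(tr.variant_ids, tr.variants))
    snv_by_id = dict(zip(snv.variant_ids, snv.variants))
    tr_dosage = tr.summed_dosage()
    snv_dosage = snv.summed_dosage()
    coords = {v.locus_id: v.start for v in tr.variants}
    coords.update({v.snv_id: v.start for v in snv.variants})

    # ---- stage 2: per-cohort association ---------------------------------
    assoc_rows: list[AssocStat] = []
    windows: dict[str, tuple[list[str], list[str]]] = {}
    for gene, (tss, tes) in cohort.genes.items():
        tr_in = [v.locus_id for v in assign_window((tss, tes), tr.variants,
                                                   config.window)]
        snv_in = [v.snv_id for v in assign_window((tss, tes), snv.variants,
                                                  config.window)]
        windows[gene] = (tr_in, snv_in)
    sample_index = {s: i for i, s in enumerate(cohort.tr_genotypes.samples)}
    for co in cohorts:
        for ct in cfg_cts:
            pb = cohort.expression[(co, ct)]
            rows = [sample_index[s] for s in pb.samples]
            W = pb.covariates.to_numpy(dtype=float)
            for gene, (tr_in, snv_in) in windows.items():
                frac = float(pb.expressed_fraction.get(gene, 0.0))
                y = pb.expression[gene].to_numpy(dtype=float)
                for ids, dosage, table in ((tr_in, tr_dosage, tr),
                                           (snv_in, snv_dosage, snv)):
                    if not ids:
                        continue
                    cols = [table.variant_ids.index(v) for v in ids]
                    g = dosage[np.ix_(rows, cols)]
                    assoc_rows.extend(
                        map_gene(gene, y, g, ids, covariates=W,
                                 expressed_fraction=frac,
                                 min_expressed_fraction=config.min_expressed_fraction,
                                 cell_type=ct, cohort=co)
                    )
    assoc_df = _assoc_frame(assoc_rows)
    counts["assoc"] = len(assoc_df)
    if outdir is not None:
        _write(assoc_df, outdir / "assoc.tsv")

    # ---- stage 3: meta-analysis ------------------------------------------
    meta_rows = []
    meta_lookup: dict[tuple, object] = {}
    for (variant, gene, ct), grp in assoc_df.groupby(
        ["variant", "gene", "cell_type"], sort=True
    ):
        stats = [AssocStat(**row) for row in grp.to_dict("records")]
        m = meta_stats(stats)
        meta_lookup[(variant, gene, ct)] = m
        meta_rows.append(
            dict(variant=variant, gene=gene, cell_type=ct, beta=m.beta,
                 se=m.se, p=m.p, tau2=m.tau2, Q=m.Q, k=m.k)
        )
    meta_df = pd.DataFrame(meta_rows)
    counts["meta"] = len(meta_df)
    if outdir is not None:
        _write(meta_df, outdir / "meta.tsv")

    # ---- stage 4: gene-level significance --------------------------------
    gene_results = {}
    for ct in cfg_cts:
        per_ct = []
        for gene, (tr_in, snv_in) in windows.items():
            tr_stats = [meta_lookup[(v, gene, ct)] for v in tr_in
                        if (v, gene, ct) in meta_lookup]
            snv_stats = [meta_lookup[(v, gene, ct)] for v in snv_in
                         if (v, gene, ct) in meta_lookup]
            if not tr_stats and not snv_stats:
                continue
            per_ct.append(
                select_top_and_lead(tr_stats, snv_stats, gene=gene,
                                    cell_type=ct, variant_coords=coords)
            )
        gene_results[ct] = call_significant(per_ct, fdr=config.fdr)
    gene_df = pd.DataFrame(
        [dataclasses.asdict(r) for ct in cfg_cts for r in gene_results[ct]]
    )
    counts["significance"] = int(gene_df["is_significant"].sum()) if len(gene_df) else 0
    if outdir is not None:
        _write(gene_df, outdir / "gene_results.tsv")

    # ---- stage 5: cell-type specificity ----------------------------------
    spec_rows = []
    for ct in cfg_cts:
        for res in gene_results[ct]:
            if not res.is_significant or res.top_eTR is None:
                continue
            key = (res.top_eTR, res.gene, ct)
            if key not in meta_lookup:
                continue
            origin = meta_lookup[key]
            others = {}
            for other_ct in cfg_cts:
                if other_ct == ct:
                    continue
                frac = float(
                    cohort.expression[(cohorts[0], other_ct)]
                    .expressed_fraction.get(res.gene, 0.0)
                )
                eligible = frac >= config.min_expressed_fraction
                stat = meta_lookup.get((res.top_eTR, res.gene, other_ct))
                others[other_ct] = stat if eligible else None
            call = classify_specificity(origin, origin.p, others)
            spec_rows.append(
                dict(variant=res.top_eTR, gene=res.gene, origin_cell_type=ct,
                     n_comparisons=call.n_comparisons, n_shared=call.n_shared,
                     specific=call.specific)
            )
    spec_df = pd.DataFrame(spec_rows)
    counts["specificity"] = len(spec_df)
    if outdir is not None:
        _write(spec_df, outdir / "specificity.tsv")

    # ---- stage 6: fine-mapping + candidate causal ------------------------
    fm_rows, cc_rows = [], []
    candidate_lookup = {}
    finemaps = {}
    for ct in cfg_cts:
        for res in gene_results[ct]:
            if not res.is_significant:
                continue
            tr_in, snv_in = windows[res.gene]
            vids = [v for v in tr_in + snv_in
                    if (v, res.gene, ct) in meta_lookup]
            if not vids:
                continue
            stats = [meta_lookup[(v, res.gene, ct)] for v in vids]
            fm = single_effect_finemap(
                [s.beta for s in stats], [s.se for s in stats], vids,
                coverage=config.credible_coverage, gene=res.gene, cell_type=ct,
            )
            finemaps[(res.gene, ct)] = fm
            for vid, pip, pruned in zip(fm.variant_ids, fm.pip, fm.pruned):
                fm_rows.append(
                    dict(gene=res.gene, cell_type=ct, variant=vid,
                         pip=float(pip), in_credible_set=bool(not pruned),
                         W_star=fm.W_star)
                )
            call = call_candidate_causal(fm, res,
                                         pip_threshold=config.pip_threshold)
            candidate_lookup[(res.gene, ct)] = call
            cc_rows.append(
                dict(gene=res.gene, cell_type=ct, variant=call.variant,
                     is_lead=call.is_lead, pip=call.pip, passes=call.passes)
            )
    fm_df, cc_df = pd.DataFrame(fm_rows), pd.DataFrame(cc_rows)
    counts["finemap"] = int(cc_df["passes"].sum()) if len(cc_df) else 0
    if outdir is not None:
        _write(fm_df, outdir / "finemap.tsv")
        _write(cc_df, outdir / "candidate_causal.tsv")

    # ---- stage 7: conditional analysis -----------------------------------
    cond_rows = []
    for (gene, ct), call in candidate_lookup.items():
        if not call.passes:
            continue
        tr_in, snv_in = windows[gene]
        snv_metas = [(v, meta_lookup[(v, gene, ct)]) for v in snv_in
                     if (v, gene, ct) in meta_lookup]
        if not snv_metas:
            continue
        lead_snv = min(snv_metas, key=lambda t: (t[1].p, coords.get(t[0], 0)))[0]
        jt = tr.variant_ids.index(call.variant)
        js = snv.variant_ids.index(lead_snv)
        per_cohort = []
        for co in cohorts:
            pb = cohort.expression[(co, ct)]
            rows = [sample_index[s] for s in pb.samples]
            y = pb.expression[gene].to_numpy(dtype=float)
            from .association import inverse_normal_transform

            try:
                stat, _ = conditional_association(
                    inverse_normal_transform(y), tr_dosage[rows, jt],
                    snv_dosage[rows, js], pb.covariates.to_numpy(dtype=float),
                    variant=call.variant, gene=gene, cell_type=ct,
                    genome_wide_p=config.genome_wide_p,
                )
            except Exception:
                continue
            stat.cohort = co
            per_cohort.append(stat)
        if not per_cohort:
            continue
        m = meta_stats(per_cohort)
        cond_rows.append(
            dict(gene=gene, cell_type=ct, variant=call.variant,
                 conditioned_on=lead_snv, beta=m.beta, se=m.se, p=m.p,
                 persists=bool(m.p < config.genome_wide_p))
        )
    cond_df = pd.DataFrame(cond_rows)
    counts["conditional"] = len(cond_df)
    if outdir is not None:
        _write(cond_df, outdir / "conditional.tsv")

    # ---- stage 8: colocalization -----------------------------------------
    coloc_rows = []
    if gwas is not None:
        gwas_by_id = gwas.set_index("variant")
        dosage_by_id = {}
        for vid in tr.variant_ids:
            dosage_by_id[vid] = tr_dosage[:, tr.variant_ids.index(vid)]
        for vid in snv.variant_ids:
            dosage_by_id[vid] = snv_dosage[:, snv.variant_ids.index(vid)]
        for (gene, ct), call in candidate_lookup.items():
            tr_in, snv_in = windows[gene]
            shared = [v for v in tr_in + snv_in
                      if v in gwas_by_id.index and (v, gene, ct) in meta_lookup]
            if not shared:
                continue
            b1 = [meta_lookup[(v, gene, ct)].beta for v in shared]
            s1 = [meta_lookup[(v, gene, ct)].se for v in shared]
            b2 = gwas_by_id.loc[shared, "beta"].to_numpy()
            s2 = gwas_by_id.loc[shared, "se"].to_numpy()
            result = coloc_abf(
                b1, s1, b2, s2, p1=config.coloc_p1, p2=config.coloc_p2,
                p12=config.coloc_p12, W_eqtl=config.coloc_w_eqtl,
                W_gwas=config.coloc_w_gwas, gene=gene, cell_type=ct,
                trait=gwas_trait,
            )
            gwas_p = gwas_by_id.loc[shared, "p"].to_numpy()
            # LD of the sc-eTR with any variant cataloged in the GWAS
            # window; a joint SNV+TR catalog contains the TR itself (r^2=1)
            max_r2 = 0.0
            if call.variant in dosage_by_id:
                for v in shared:
                    try:
                        max_r2 = max(max_r2, ld_r2(dosage_by_id[call.variant],
                                                   dosage_by_id[v]))
                    except Exception:
                        continue
            passes, report = gate_colocalization(
                result, call, gwas_p, max_r2,
                pp_h4_threshold=config.pp_h4_threshold,
                r2_threshold=config.r2_threshold,
                genome_wide_p=config.genome_wide_p,
            )
            coloc_rows.append(
                dict(gene=gene, cell_type=ct, trait=gwas_trait,
                     n_variants=result.n_variants,
                     **{f"pp_{k.lower()}": v for k, v in result.pp.items()},
                     max_r2=max_r2, gwas_hit=report["gwas_hit_in_window"],
                     gated=passes)
            )
    coloc_df = pd.DataFrame(coloc_rows)
    counts["coloc"] = int(coloc_df["gated"].sum()) if len(coloc_df) else 0
    if outdir is not None:
        _write(coloc_df, outdir / "coloc.tsv")

    manifest = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": list(STAGES),
        "counts": counts,
        "coloc_run": gwas is not None,
    }
    if outdir is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["tables"] = {
        "qc_report": qc_report, "assoc": assoc_df, "meta": meta_df,
        "gene_results": gene_df, "specificity": spec_df, "finemap": fm_df,
        "candidate_causal": cc_df, "conditional": cond_df, "coloc": coloc_df,
    }
    return manifest
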