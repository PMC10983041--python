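"""End-to-end pipeline on a synthetic cohort.

Runs the full analysis deterministically from a single configuration and
seed: simulate annotation + cohort, merge the two germline caller
replicates with 200 bp slop, summarize the call set, build gene x sample
breakpoint matrices for every window, run covariate-corrected
associations, layer on mechanism enrichment (enhancer duplication, SV
class by direction, cytobands, copy categories), derive the signed
survival signature, score the cohort with the t-score and test outcome
separation.  All outputs are plain TSV/JSON.
"""

from __future__ import annotations

import json
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import feature_enrichment as enrich_mod
from . import survival_signature as surv_mod
from . import sv_io
from .breakpoint_matrix import (BreakpointMatrix, WindowSpec,
                                build_breakpoint_matrix,
                                build_weighted_matrix, write_matrix)
from .synthetic_cohort import (CovariateParams, EffectSpec, GermlineParams,
                               HazardSpec, PlantedEffect, SomaticParams,
                               patient_ids, plant_effects, simulate_expression,
                               simulate_genome, simulate_survival,
                               simulate_sv_cohort)

UNWEIGHTED_WINDOWS = ("gene_body", "up_100kb", "down_100kb", "utr3")
SURVIVAL_WINDOWS = ("gene_body", "up_100kb", "down_100kb",
                    "flank_1mb_weighted")


def default_config() -> dict:
    """The default synthetic study conditions."""
    return {
        "genome": {"n_chroms": 2, "n_genes": 800, "n_enhancers": 150,
                   "bands_per_chrom": 12, "chrom_length": 60_000_000},
        "cohort": {"n_patients": 300, "caller_jitter_bp": 50},
        "tissues": ["breast", "liver", "kidney", "lung"],
        "effects": {
            "n_positive": 20, "n_negative": 10,
            "n_enhancer_dup": 6, "n_utr3": 4,
            "effect_log2": 1.0,
            "noise_sd": 0.5, "tissue_baseline_sd": 0.5,
        },
        "association": {"min_carriers": 3, "q_threshold": 0.10,
                        "models": ["none", "tissue", "full"]},
        "survival": {
            "baseline_hazard": 0.01, "censoring_rate": 0.2,
            "max_followup": 240.0, "n_hazard_genes": 10, "log_hr": 0.5,
        },
    }


def _plan_effects(genome, cfg, rng) -> EffectSpec:
    """Choose effect genes and windows from the genome, deterministically.

    Positive effects are split across gene_body/up_100kb/down_100kb with
    the first ``n_enhancer_dup`` of them planted as enhancer-spanning
    duplications in the upstream flank and ``n_utr3`` planted as 3'UTR
    deletions; negative effects are deletions in the gene body.
    """
    eff_cfg = cfg["effects"]
    genes = list(genome.genes)
    with_utr = [g for g in genes if g.utr3 is not None]
    n_pos = eff_cfg["n_positive"]
    n_neg = eff_cfg["n_negative"]
    n_enh = min(eff_cfg["n_enhancer_dup"], n_pos)
    n_utr = min(eff_cfg["n_utr3"], max(0, n_pos - n_enh))
    chosen_utr = [g.gene_id for g in with_utr[:n_utr]]
    pool = [g.gene_id for g in genes if g.gene_id not in chosen_utr]
    order = rng.permutation(len(pool))
    picks = [pool[i] for i in order]
    effect_genes: dict[str, PlantedEffect] = {}
    amp = eff_cfg["effect_log2"]
    for gene_id in chosen_utr:
        effect_genes[gene_id] = PlantedEffect("utr3", amp, sv_class="DEL")
    cursor = 0
    for _ in range(n_enh):
        effect_genes[picks[cursor]] = PlantedEffect(
            "up_100kb", amp, sv_class="DUP", span_enhancer=True)
        cursor += 1
    plain_windows = ("gene_body", "up_100kb", "down_100kb")
    for i in range(n_pos - n_enh - n_utr):
        effect_genes[picks[cursor]] = PlantedEffect(
            plain_windows[i % 3], amp, sv_class="DEL")
        cursor += 1
    for i in range(n_neg):
        effect_genes[picks[cursor]] = PlantedEffect(
            plain_windows[i % 3], -amp, sv_class="DEL")
        cursor += 1
    return EffectSpec(effect_genes=effect_genes,
                      noise_sd=eff_cfg["noise_sd"],
                      tissue_baseline_sd=eff_cfg["tissue_baseline_sd"])


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None,
                 seed: int = 0) -> dict:
    """Run the whole analysis; returns a results dict and, when ``outdir``
    is given, writes every intermediate table plus ``results.json``."""
    cfg = deepcopy(config) if config else default_config()
    rng = np.random.default_rng(seed)
    out: dict = {"seed": seed}

    # --- simulate -----------------------------------------------------
    genome = simulate_genome(seed=int(rng.integers(2**31)),
                             **cfg["genome"])
    effect_spec = _plan_effects(genome, cfg, rng)
    planted = plant_effects(genome, effect_spec, int(rng.integers(2**31)))
    patients = patient_ids(cfg["cohort"]["n_patients"])
    tissue = pd.Series(
        rng.choice(cfg["tissues"], size=len(patients)), index=patients)
    cohort = simulate_sv_cohort(
        genome, cfg["cohort"]["n_patients"],
        GermlineParams(), SomaticParams(),
        caller_jitter_bp=cfg["cohort"]["caller_jitter_bp"],
        seed=int(rng.integers(2**31)), tissues=tissue, extra_panel=planted)
    covar_params = CovariateParams(tissues=tuple(cfg["tissues"]),
                                   tissue_assignments=tissue)
    expr, cn, covars = simulate_expression(
        genome, cohort, covar_params, effect_spec,
        seed=int(rng.integers(2**31)))
    covar_table = assoc_mod.CovariateTable(samples=covars, copy_number=cn)

    # planted hazards ride on carrier status of the first hazard genes
    surv_cfg = cfg["survival"]
    hazard_genes = sorted(effect_spec.effect_genes)[:surv_cfg["n_hazard_genes"]]
    features = pd.DataFrame(index=patients)
    log_hr = {}
    for g in hazard_genes:
        sv_id = effect_spec.effect_genes[g].sv_id
        features[g] = cohort.truth[sv_id].astype(float)
        log_hr[g] = surv_cfg["log_hr"]
    hazard_spec = HazardSpec(
        baseline_hazard=surv_cfg["baseline_hazard"],
        log_hr_per_feature=log_hr,
        censoring_rate=surv_cfg["censoring_rate"],
        max_followup=surv_cfg["max_followup"])
    surv = simulate_survival(features, hazard_spec, tissue,
                             seed=int(rng.integers(2**31)))

    # --- merge caller replicates -------------------------------------
    merged = []
    n_unmatched = 0
    for p in cohort.patients:
        m = sv_io.merge_callsets(cohort.germline_caller_a[p],
                                 cohort.germline_caller_b[p], slop_bp=200)
        merged.extend(m.records)
        n_unmatched += m.n_unmatched_a
    somatic = cohort.all_somatic()
    summary = sv_io.summarize_svs(merged)
    som_summary = sv_io.summarize_svs(somatic)
    out["sv_summary"] = {
        "n_germline_merged": len(merged),
        "n_unmatched_caller_a": n_unmatched,
        "n_somatic": len(somatic),
        "germline_class_fractions": summary.class_fractions,
        "somatic_class_fractions": som_summary.class_fractions,
        "germline_median_intra_size": summary.median_intra_size,
        "somatic_median_intra_size": som_summary.median_intra_size,
        "germline_recurrence_both": summary.recurrence_fraction_both,
        "somatic_recurrence_both": som_summary.recurrence_fraction_both,
    }

    # --- breakpoint matrices and associations ------------------------
    matrices: dict[str, BreakpointMatrix] = {}
    for label in UNWEIGHTED_WINDOWS:
        matrices[label] = build_breakpoint_matrix(
            merged, genome.genes, WindowSpec.from_label(label),
            samples=patients)
    matrices["flank_1mb_weighted"] = build_weighted_matrix(
        merged, genome.genes, samples=patients)

    assoc_cfg = cfg["association"]
    associations: dict[str, dict[str, list]] = {}
    counts: dict[str, dict[str, tuple[int, int]]] = {}
    for label, matrix in matrices.items():
        associations[label] = {}
        counts[label] = {}
        for model in assoc_cfg["models"]:
            recs = assoc_mod.run_associations(
                matrix, expr, covar_table, model=model,
                min_carriers=assoc_cfg["min_carriers"])
            associations[label][model] = recs
            counts[label][model] = assoc_mod.count_significant(
                recs, q_threshold=assoc_cfg["q_threshold"])
    out["significant_counts"] = {
        label: {model: {"positive": c[0], "negative": c[1]}
                for model, c in by_model.items()}
        for label, by_model in counts.items()}

    # --- mechanism enrichment ----------------------------------------
    full_up100 = associations["up_100kb"]["full"]
    gene_by_id = {g.gene_id: g for g in genome.genes}
    up_window = WindowSpec.from_label("up_100kb")
    gene_classes = enrich_mod.contributing_classes(
        merged, genome.genes, up_window)
    out["class_direction"] = {
        cls: {"chi2": r.chi2, "p": r.p, "enriched": r.enriched}
        for cls, r in enrich_mod.sv_class_direction_enrichment(
            full_up100, gene_classes).items()}

    # enhancer duplication among up-associations
    sig_gene_ids = {r.gene_id for r in full_up100
                    if r.p is not None and r.p < 0.01
                    and r.direction == "positive"}
    tested_genes = [r.gene_id for r in full_up100 if r.p is not None]
    enh_flags = enrich_mod.enhancer_duplication_flags(
        merged, [gene_by_id[g] for g in tested_genes], genome.enhancers)
    member = [enh_flags[g] for g in tested_genes]
    outcome = [g in sig_gene_ids for g in tested_genes]
    if member:
        enh = enrich_mod.enrichment_chisq(member, outcome)
        out["enhancer_dup_enrichment"] = {
            "chi2": enh.chi2, "p": enh.p, "enriched": enh.enriched,
            "counts": enh.counts.tolist()}

    # cytobands and copy categories
    per_patient = {p: enrich_mod.cytoband_enrichment(
        cohort.germline_caller_a[p],
        [(c, s, e, n) for c, s, e, n in genome.cytobands])
        for p in cohort.patients}
    out["cytoband_hits"] = enrich_mod.cohort_cytoband_summary(per_patient)
    som_events = enrich_mod.find_spanning_events(somatic, genome.genes)
    xtab = enrich_mod.copy_category_crosstab(som_events, cn, covars["ploidy"])
    out["copy_crosstab"] = {
        "table": xtab.table.to_dict(),
        "dup_gain_p": xtab.dup_gain.p,
        "del_loss_p": xtab.del_loss.p}

    # --- survival signature ------------------------------------------
    full_any = [r for label in SURVIVAL_WINDOWS
                for r in associations[label]["full"]]
    candidates = sorted({r.gene_id for r in full_any
                         if r.p is not None and r.p < 0.05})
    surv_results = []
    for gid in candidates:
        for label in SURVIVAL_WINDOWS:
            row = matrices[label].values
            if gid not in row.index:
                continue
            surv_results.append(surv_mod.cox_feature_survival(
                row.loc[gid], surv, gene_id=gid, window=label))
    signature = surv_mod.derive_signature(surv_results, full_any)
    out["signature"] = {"n_genes": len(signature.genes),
                        **signature.provenance}

    sig_result = None
    if len(signature.high_genes) >= 2 and len(signature.low_genes) >= 2:
        profiles = surv_mod.center_profiles(expr)
        scores = surv_mod.score_cohort(signature, profiles)
        try:
            res = surv_mod.signature_survival(scores, surv)
            sig_result = {"logrank_p": res.logrank_p, "cox_p": res.cox_p,
                          "cox_coef": res.cox_coef}
        except ValueError as exc:
            sig_result = {"error": str(exc)}
    out["signature_survival"] = sig_result

    # planted-effect recovery bookkeeping (truth is known here)
    planted_genes = set(effect_spec.effect_genes)
    q_hits = {r.gene_id for label in matrices for r in
              associations[label]["full"]
              if r.q is not None and r.q < assoc_cfg["q_threshold"]}
    out["planted_recovery"] = {
        "n_planted": len(planted_genes),
        "n_recovered": len(q_hits & planted_genes),
        "n_false": len(q_hits - planted_genes),
        "sensitivity": len(q_hits & planted_genes) / len(planted_genes)
        if planted_genes else None,
    }

    if outdir is not None:
        _write_outputs(Path(outdir), genome, cohort, merged, somatic, expr,
                       cn, covars, surv, matrices, associations, signature,
                       out)
    return out


def _write_outputs(outdir, genome, cohort, merged, somatic, expr, cn, covars,
                   surv, matrices, associations, signature, out):
    outdir.mkdir(parents=True, exist_ok=True)
    sv_io.write_genes_table(genome.genes, outdir / "genes.tsv")
    sv_io.write_bed(genome.enhancers, outdir / "enhancers.bed")
    sv_io.write_bed([(c, s, e, n) for c, s, e, n in genome.cytobands],
                    outdir / "cytobands.bed")
    sv_io.write_sv_table(cohort.all_germline_a(),
                         outdir / "germline_caller_a.bedpe")
    sv_io.write_sv_table(
        [r for p in cohort.patients for r in cohort.germline_caller_b[p]],
        outdir / "germline_caller_b.bedpe")
    sv_io.write_sv_table(merged, outdir / "germline_merged.bedpe")
    sv_io.write_sv_table(somatic, outdir / "somatic.bedpe")
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
    cn.to_csv(outdir / "copy_number.tsv", sep="\t", index_label="gene_id")
    covars.to_csv(outdir / "covariates.tsv", sep="\t",
                  index_label="patient_id")
    surv.to_csv(outdir / "survival.tsv", sep="\t", index_label="patient_id")
    for label, matrix in matrices.items():
        write_matrix(matrix, outdir / f"bkpt_{label}.tsv",
                     outdir / f"bkpt_{label}.json")
    frames = [assoc_mod.associations_to_frame(recs)
              for by_model in associations.values()
              for recs in by_model.values()]
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "associations.tsv", sep="\t", index=False)
    with open(outdir / "signature.json", "w") as fh:
        json.dump({"genes": signature.genes,
                   "provenance": signature.provenance}, fh, indent=2)
    with open(outdir / "results.json", "w") as fh:
        json.dump(out, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
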