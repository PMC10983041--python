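"""Canned simulation experiments over the synthetic cohort.

Each function wires the generator to one downstream analysis under a
named set of study conditions — planted-effect recovery, null
calibration, tissue confounding, enhancer-duplication enrichment,
survival-coefficient recovery — and returns the measured quantities.
They are used by the validation suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sv_io
from .association import CovariateTable, run_associations
from .breakpoint_matrix import WindowSpec, build_breakpoint_matrix
from .feature_enrichment import (enhancer_duplication_flags,
                                 enrichment_chisq)
from .survival_signature import cox_feature_survival, signature_survival
from .synthetic_cohort import (CovariateParams, EffectSpec, GermlineParams,
                               HazardSpec, PlantedEffect, SomaticParams,
                               build_panel, patient_ids, plant_effects,
                               simulate_expression, simulate_genome,
                               simulate_survival, simulate_sv_cohort)

TISSUES = ("breast", "liver", "kidney", "lung")


def _merge_cohort(cohort, slop_bp=200):
    merged = []
    for p in cohort.patients:
        merged.extend(sv_io.merge_callsets(
            cohort.germline_caller_a[p], cohort.germline_caller_b[p],
            slop_bp=slop_bp).records)
    return merged


def association_experiment(
    seed: int,
    n_patients: int = 400,
    n_genes: int = 1_000,
    n_effects: int = 30,
    effect_log2: float = 1.0,
    noise_sd: float = 0.5,
    freq_range: tuple[float, float] = (0.05, 0.5),
    window: str = "up_100kb",
    models: tuple[str, ...] = ("full",),
    tissue_confound: bool = False,
    somatic_mean: float = 10.0,
):
    """Simulate a cohort with ``n_effects`` planted cis-effects (none when
    0) and run the gene association for the given window and models.

    With ``tissue_confound`` the population panel SVs are each enriched in
    one home tissue while expression keeps strong tissue baselines, with
    no true SV effect — the conditions under which only the
    tissue-corrected models should stay quiet.

    Returns (planted gene set, {model: association records}).
    """
    rng = np.random.default_rng(seed)
    genome = simulate_genome(2, n_genes, 0, 6,
                             seed=int(rng.integers(2**31)),
                             chrom_length=60_000_000)
    gene_ids = [g.gene_id for g in genome.genes]
    effect_genes = {}
    if n_effects:
        chosen = rng.choice(gene_ids, size=n_effects, replace=False)
        effect_genes = {
            g: PlantedEffect(window, effect_log2,
                             frequency=float(rng.uniform(*freq_range)))
            for g in chosen}
    spec = EffectSpec(effect_genes=effect_genes, noise_sd=noise_sd,
                      tissue_baseline_sd=1.0 if tissue_confound else 0.5)
    planted = plant_effects(genome, spec, int(rng.integers(2**31)))
    patients = patient_ids(n_patients)
    tissue = pd.Series(rng.choice(TISSUES, size=n_patients), index=patients)

    germ = GermlineParams()
    extra = list(planted)
    if tissue_confound:
        base = build_panel(genome, germ, int(rng.integers(2**31)))
        for sv in base:
            home = TISSUES[int(rng.integers(len(TISSUES)))]
            sv.tissue_freq = {t: (2.5 if t == home else 0.1)
                              for t in TISSUES}
        extra += base
        germ = GermlineParams(n_panel_svs=0)

    cohort = simulate_sv_cohort(
        genome, n_patients, germ, SomaticParams(mean_svs_per_patient=somatic_mean),
        seed=int(rng.integers(2**31)), tissues=tissue, extra_panel=extra)
    expr, cn, covars = simulate_expression(
        genome, cohort, CovariateParams(tissue_assignments=tissue), spec,
        seed=int(rng.integers(2**31)))
    covar_table = CovariateTable(samples=covars, copy_number=cn)
    merged = _merge_cohort(cohort)
    matrix = build_breakpoint_matrix(merged, genome.genes,
                                     WindowSpec.from_label(window),
                                     samples=patients)
    records = {m: run_associations(matrix, expr, covar_table, model=m)
               for m in models}
    return set(effect_genes), records


def effect_recovery(seed: int, q_threshold: float = 0.10, **kwargs):
    """Sensitivity and false-discovery proportion for planted effects."""
    planted, records = association_experiment(seed, **kwargs)
    hits = {r.gene_id for r in records["full"]
            if r.q is not None and r.q < q_threshold}
    sensitivity = len(hits & planted) / len(planted) if planted else None
    fdp = len(hits - planted) / len(hits) if hits else 0.0
    return sensitivity, fdp, len(hits)


def null_pvalues(seed: int, **kwargs) -> np.ndarray:
    """Association p-values under the global null (no planted effects)."""
    _, records = association_experiment(seed, n_effects=0, **kwargs)
    return np.array([r.p for r in records["full"] if r.p is not None])


def enhancer_dup_experiment(
    seed: int,
    n_patients: int = 200,
    n_genes: int = 400,
    n_planted: int = 8,
    effect_log2: float = 1.0,
):
    """Positive effects planted only at enhancer-spanning duplication
    panel SVs; returns the enrichment of the enhancer-duplication class
    among up-associations (p < 0.01) plus the per-gene flags."""
    rng = np.random.default_rng(seed)
    genome = simulate_genome(2, n_genes, 60, 6,
                             seed=int(rng.integers(2**31)),
                             chrom_length=60_000_000)
    gene_ids = [g.gene_id for g in genome.genes]
    chosen = rng.choice(gene_ids, size=n_planted, replace=False)
    spec = EffectSpec(effect_genes={
        g: PlantedEffect("up_100kb", effect_log2, sv_class="DUP",
                         span_enhancer=True,
                         frequency=float(rng.uniform(0.1, 0.4)))
        for g in chosen}, noise_sd=0.5, tissue_baseline_sd=0.5)
    planted = plant_effects(genome, spec, int(rng.integers(2**31)))
    patients = patient_ids(n_patients)
    tissue = pd.Series(rng.choice(TISSUES, size=n_patients), index=patients)
    cohort = simulate_sv_cohort(
        genome, n_patients, GermlineParams(),
        SomaticParams(mean_svs_per_patient=0),
        seed=int(rng.integers(2**31)), tissues=tissue, extra_panel=planted)
    expr, cn, covars = simulate_expression(
        genome, cohort, CovariateParams(tissue_assignments=tissue), spec,
        seed=int(rng.integers(2**31)))
    merged = _merge_cohort(cohort)
    matrix = build_breakpoint_matrix(merged, genome.genes,
                                     WindowSpec.from_label("up_100kb"),
                                     samples=patients)
    records = run_associations(matrix, expr,
                               CovariateTable(samples=covars,
                                              copy_number=cn),
                               model="full")
    tested = [r.gene_id for r in records if r.p is not None]
    sig_up = {r.gene_id for r in records
              if r.p is not None and r.p < 0.01
              and r.direction == "positive"}
    gene_by_id = {g.gene_id: g for g in genome.genes}
    flags = enhancer_duplication_flags(
        merged, [gene_by_id[g] for g in tested], genome.enhancers)
    member = [flags[g] for g in tested]
    outcome = [g in sig_up for g in tested]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = enrichment_chisq(member, outcome)
    return result, set(chosen), sig_up


def survival_recovery(seed: int, n: int = 400, log_hr: float = 0.5,
                      n_strata: int = 4):
    """Fit a stratified Cox on one planted binary hazard feature."""
    rng = np.random.default_rng(seed)
    idx = patient_ids(n)
    feature = pd.Series(rng.integers(0, 2, size=n).astype(float), index=idx)
    strata = pd.Series([f"t{i % n_strata}" for i in range(n)], index=idx)
    spec = HazardSpec(baseline_hazard=0.02, censoring_rate=0.2,
                      max_followup=240.0,
                      log_hr_per_feature={"f": log_hr},
                      stratum_log_hazard={f"t{i}": 0.3 * i
                                          for i in range(n_strata)})
    surv = simulate_survival(feature.to_frame("f"), spec, strata,
                             seed=int(rng.integers(2**31)))
    return cox_feature_survival(feature, surv)


def tertile_power(seed: int, n: int = 600, log_hr: float = 0.5) -> float:
    """Log-rank p when the signature score truly drives hazard."""
    rng = np.random.default_rng(seed)
    idx = patient_ids(n)
    scores = pd.Series(rng.normal(0, 1, size=n), index=idx)
    strata = pd.Series([f"t{i % 3}" for i in range(n)], index=idx)
    spec = HazardSpec(baseline_hazard=0.02, censoring_rate=0.2,
                      log_hr_per_feature={"score": log_hr})
    surv = simulate_survival(scores.to_frame("score"), spec, strata,
                             seed=int(rng.integers(2**31)))
    return signature_survival(scores, surv).logrank_p
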