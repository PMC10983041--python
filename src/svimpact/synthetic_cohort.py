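"""Self-consistent synthetic cohort generator with known planted effects.

Emulates the data structure of a pan-cancer whole-genome cohort: a small
multi-chromosome genome annotation (genes with strand and optional 3'UTR,
enhancers, cytobands), per-patient germline SV calls from two simulated
"callers" plus a somatic call set, a tissue-structured expression matrix
with planted cis-effects at SV carriers, gene-level copy number, sample
covariates (tissue, ploidy, purity), and exponential survival times with
planted hazards.

Germline SVs are drawn from a shared population panel (recurrent across
patients, mostly deletions, kb-scale sizes — default class fractions
DEL 0.78 / INV 0.125 / DUP 0.093 with a trace of translocations, median
size 2.1 kb).  Somatic SVs are patient-private, much larger and rich in
translocations.  Every generator is deterministic for a fixed seed, and
truth tables of planted carriers are returned for test oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .breakpoint_matrix import GeneModel, WindowSpec, window_interval
from .sv_io import SVRecord

# ---------------------------------------------------------------------------
# Annotation


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel]
    enhancers: list[tuple[str, int, int]]
    cytobands: list[tuple[str, int, int, str]]  # (chrom, start, end, name)
    chrom_lengths: dict[str, int]

    def validate(self) -> None:
        """Cytobands must tile each chromosome; all intervals in bounds."""
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.chrom_lengths[g.chrom]):
                raise ValueError(f"gene {g.gene_id} outside chromosome")
        for chrom, start, end in self.enhancers:
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"enhancer {chrom}:{start}-{end} out of bounds")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.cytobands:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, length in self.chrom_lengths.items():
            bands = sorted(by_chrom.get(chrom, []))
            if not bands or bands[0][0] != 0 or bands[-1][1] != length:
                raise ValueError(f"cytobands do not tile {chrom}")
            for (s0, e0), (s1, e1) in zip(bands, bands[1:]):
                if e0 != s1:
                    raise ValueError(f"cytoband gap/overlap on {chrom} at {e0}")


def simulate_genome(
    n_chroms: int,
    n_genes: int,
    n_enhancers: int,
    bands_per_chrom: int,
    seed: int,
    chrom_length: int = 30_000_000,
    gene_length_range: tuple[int, int] = (5_000, 50_000),
    enhancer_length_range: tuple[int, int] = (500, 2_000),
    utr3_fraction: float = 0.5,
) -> GenomeAnnotation:
    """Random annotation: non-overlapping genes packed per chromosome,
    random-strand, about ``utr3_fraction`` of genes given a 3'UTR at the
    strand-appropriate end; enhancers placed uniformly; cytobands tiling
    each chromosome.  Raises when the genes cannot be packed."""
    if min(n_chroms, n_genes, bands_per_chrom) < 1 or n_enhancers < 0:
        raise ValueError("counts must be >= 1 (enhancers >= 0)")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: chrom_length for c in chroms}

    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    genes: list[GeneModel] = []
    gid = 0
    for chrom, count in zip(chroms, per_chrom):
        if count == 0:
            continue
        lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1,
                               size=count)
        slack = chrom_lengths[chrom] - int(lengths.sum())
        if slack < count:  # no room for even 1 bp gaps
            raise ValueError(
                f"cannot pack {count} genes into {chrom} "
                f"({chrom_lengths[chrom]} bp)")
        gaps = rng.dirichlet(np.ones(count + 1)) * slack
        cursor = 0.0
        for glen, gap in zip(lengths, gaps[:-1]):
            cursor += gap
            start = int(cursor)
            end = start + int(glen)
            cursor = float(end)
            strand = "+" if rng.random() < 0.5 else "-"
            utr3 = None
            if rng.random() < utr3_fraction:
                max_utr = max(200, int(glen) // 3)
                ulen = int(rng.integers(200, max(201, min(2_000, max_utr) + 1)))
                utr3 = (end - ulen, end) if strand == "+" else (start, start + ulen)
            genes.append(GeneModel(f"G{gid:05d}", chrom, start, end, strand,
                                   utr3=utr3))
            gid += 1

    enhancers = []
    for _ in range(n_enhancers):
        chrom = chroms[int(rng.integers(n_chroms))]
        elen = int(rng.integers(enhancer_length_range[0],
                                enhancer_length_range[1] + 1))
        start = int(rng.integers(0, chrom_lengths[chrom] - elen))
        enhancers.append((chrom, start, start + elen))

    cytobands = []
    for chrom in chroms:
        length = chrom_lengths[chrom]
        bounds = np.linspace(0, length, bands_per_chrom + 1)
        if bands_per_chrom > 1:
            jitter = rng.uniform(-0.25, 0.25, size=bands_per_chrom - 1) \
                * (length / bands_per_chrom)
            bounds[1:-1] = bounds[1:-1] + jitter
        bounds = np.round(bounds).astype(int)
        for i in range(bands_per_chrom):
            cytobands.append((chrom, int(bounds[i]), int(bounds[i + 1]),
                              f"{chrom}q{i + 1}"))

    genome = GenomeAnnotation(genes=genes, enhancers=enhancers,
                              cytobands=cytobands, chrom_lengths=chrom_lengths)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# SV cohort


def patient_ids(n_patients: int) -> list[str]:
    """Stable patient identifiers used by every generator."""
    return [f"P{i:04d}" for i in range(n_patients)]


@dataclass
class PanelSV:
    """One population germline SV with a per-patient carrier frequency."""

    sv_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    sv_class: str
    frequency: float
    tissue_freq: Optional[dict[str, float]] = None  # per-tissue multiplier


@dataclass
class GermlineParams:
    n_panel_svs: int = 250
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "DEL": 0.78, "INV": 0.125, "DUP": 0.093, "TRA": 0.002})
    median_size_bp: float = 2_100.0
    size_sigma: float = 1.0
    freq_range: tuple[float, float] = (0.05, 0.5)
    caller_dropout: float = 0.05


@dataclass
class SomaticParams:
    mean_svs_per_patient: float = 30.0
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "DEL": 0.30, "DUP": 0.25, "INV": 0.21, "TRA": 0.24})
    median_size_bp: float = 175_000.0
    size_sigma: float = 1.5


@dataclass
class SVCohort:
    patients: list[str]
    germline_caller_a: dict[str, list[SVRecord]]
    germline_caller_b: dict[str, list[SVRecord]]
    somatic: dict[str, list[SVRecord]]
    panel: list[PanelSV]
    truth: pd.DataFrame  # patients x panel sv_id carrier booleans

    def all_germline_a(self) -> list[SVRecord]:
        return [r for p in self.patients for r in self.germline_caller_a[p]]

    def all_somatic(self) -> list[SVRecord]:
        return [r for p in self.patients for r in self.somatic[p]]


def _check_fractions(fractions: dict[str, float], label: str) -> None:
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{label} class fractions sum to {total}, not 1")
    if any(v < 0 for v in fractions.values()):
        raise ValueError(f"negative {label} class fraction")


def _draw_class(rng, fractions: dict[str, float]) -> str:
    classes = sorted(fractions)
    probs = np.array([fractions[c] for c in classes])
    return classes[int(rng.choice(len(classes), p=probs / probs.sum()))]


def _draw_size(rng, median: float, sigma: float) -> int:
    return max(50, int(rng.lognormal(np.log(median), sigma)))


def _place_intra(rng, genome: GenomeAnnotation, size: int
                 ) -> tuple[str, int, int]:
    chroms = sorted(genome.chrom_lengths)
    chrom = chroms[int(rng.integers(len(chroms)))]
    length = genome.chrom_lengths[chrom]
    size = min(size, length - 2)
    pos_a = int(rng.integers(0, length - size - 1))
    return chrom, pos_a, pos_a + size


def build_panel(
    genome: GenomeAnnotation,
    params: GermlineParams,
    seed: int,
) -> list[PanelSV]:
    """Random population panel of recurrent germline SVs."""
    _check_fractions(params.class_fractions, "germline")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chrom_lengths)
    if params.n_panel_svs > 0 and len(chroms) < 2 \
            and params.class_fractions.get("TRA", 0) > 0:
        raise ValueError("translocations need >= 2 chromosomes")
    panel = []
    for i in range(params.n_panel_svs):
        cls = _draw_class(rng, params.class_fractions)
        freq = float(rng.uniform(*params.freq_range))
        if cls == "TRA":
            ca, cb = rng.choice(len(chroms), size=2, replace=False)
            pa = int(rng.integers(genome.chrom_lengths[chroms[ca]]))
            pb = int(rng.integers(genome.chrom_lengths[chroms[cb]]))
            panel.append(PanelSV(f"pan{i:04d}", chroms[ca], pa,
                                 chroms[cb], pb, cls, freq))
        else:
            size = _draw_size(rng, params.median_size_bp, params.size_sigma)
            chrom, pa, pb = _place_intra(rng, genome, size)
            panel.append(PanelSV(f"pan{i:04d}", chrom, pa, chrom, pb, cls,
                                 freq))
    return panel


def simulate_sv_cohort(
    genome: GenomeAnnotation,
    n_patients: int,
    germline_params: Optional[GermlineParams] = None,
    somatic_params: Optional[SomaticParams] = None,
    caller_jitter_bp: int = 50,
    seed: int = 0,
    tissues: Optional[pd.Series] = None,
    extra_panel: Sequence[PanelSV] = (),
) -> SVCohort:
    """Per-patient SV call sets: two germline caller replicates drawn from
    a shared population panel, plus a private somatic set.

    The second germline replicate equals the first with independent
    uniform jitter on ``[-caller_jitter_bp, +caller_jitter_bp]`` at each
    breakpoint and a per-call dropout.  ``extra_panel`` appends planted
    SVs (e.g. from :func:`plant_effects`).  Panel SVs may carry per-tissue
    frequency multipliers, applied when ``tissues`` is given.
    """
    germline_params = germline_params or GermlineParams()
    somatic_params = somatic_params or SomaticParams()
    _check_fractions(somatic_params.class_fractions, "somatic")
    rng = np.random.default_rng(seed)
    panel = build_panel(genome, germline_params,
                        int(rng.integers(2**31))) + list(extra_panel)
    if not panel and n_patients > 0:
        raise ValueError("empty SV panel with patients requested")
    patients = patient_ids(n_patients)
    if tissues is not None:
        tissues = pd.Series(tissues)

    # carrier truth table
    carrier = np.zeros((n_patients, len(panel)), dtype=bool)
    for j, sv in enumerate(panel):
        p = np.full(n_patients, sv.frequency)
        if sv.tissue_freq and tissues is not None:
            mult = np.array([sv.tissue_freq.get(tissues[pt], 1.0)
                             for pt in patients])
            p = np.clip(p * mult, 0.0, 1.0)
        carrier[:, j] = rng.random(n_patients) < p
    truth = pd.DataFrame(carrier, index=patients,
                         columns=[sv.sv_id for sv in panel])

    germ_a: dict[str, list[SVRecord]] = {p: [] for p in patients}
    germ_b: dict[str, list[SVRecord]] = {p: [] for p in patients}
    for pi, patient in enumerate(patients):
        for j, sv in enumerate(panel):
            if not carrier[pi, j]:
                continue
            rec_a = SVRecord(f"{sv.sv_id}.{patient}.a", patient,
                             sv.chrom_a, sv.pos_a, sv.chrom_b, sv.pos_b,
                             sv.sv_class, "germline")
            germ_a[patient].append(rec_a)
            if rng.random() < germline_params.caller_dropout:
                continue
            ja = int(rng.integers(-caller_jitter_bp, caller_jitter_bp + 1)) \
                if caller_jitter_bp else 0
            jb = int(rng.integers(-caller_jitter_bp, caller_jitter_bp + 1)) \
                if caller_jitter_bp else 0
            germ_b[patient].append(SVRecord(
                f"{sv.sv_id}.{patient}.b", patient,
                sv.chrom_a, max(0, sv.pos_a + ja),
                sv.chrom_b, max(0, sv.pos_b + jb),
                sv.sv_class, "germline"))

    chroms = sorted(genome.chrom_lengths)
    if somatic_params.mean_svs_per_patient > 0 and len(chroms) < 2 \
            and somatic_params.class_fractions.get("TRA", 0) > 0:
        raise ValueError("somatic translocations need >= 2 chromosomes")
    somatic: dict[str, list[SVRecord]] = {p: [] for p in patients}
    for patient in patients:
        count = int(rng.poisson(somatic_params.mean_svs_per_patient))
        for k in range(count):
            cls = _draw_class(rng, somatic_params.class_fractions)
            if cls == "TRA":
                ca, cb = rng.choice(len(chroms), size=2, replace=False)
                pa = int(rng.integers(genome.chrom_lengths[chroms[ca]]))
                pb = int(rng.integers(genome.chrom_lengths[chroms[cb]]))
                somatic[patient].append(SVRecord(
                    f"som.{patient}.{k}", patient, chroms[ca], pa,
                    chroms[cb], pb, cls, "somatic"))
            else:
                size = _draw_size(rng, somatic_params.median_size_bp,
                                  somatic_params.size_sigma)
                chrom, pa, pb = _place_intra(rng, genome, size)
                somatic[patient].append(SVRecord(
                    f"som.{patient}.{k}", patient, chrom, pa, chrom, pb,
                    cls, "somatic"))

    return SVCohort(patients=patients, germline_caller_a=germ_a,
                    germline_caller_b=germ_b, somatic=somatic,
                    panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# Planted effects


@dataclass
class PlantedEffect:
    """A cis-effect planted at carriers of one dedicated panel SV."""

    window: str
    effect_log2: float
    sv_class: str = "DEL"
    frequency: Optional[float] = None
    span_enhancer: bool = False
    tissue_freq: Optional[dict[str, float]] = None
    sv_id: Optional[str] = None  # filled by plant_effects


@dataclass
class EffectSpec:
    """Planted expression-effect structure for the generator.

    ``effect_genes`` maps gene id to a :class:`PlantedEffect`; baselines
    are tissue-structured on the log2 scale with Gaussian residual noise.
    """

    effect_genes: dict[str, PlantedEffect] = field(default_factory=dict)
    noise_sd: float = 0.5
    tissue_baseline_sd: float = 0.5
    base_expr_range: tuple[float, float] = (3.0, 8.0)
    cn_coef: float = 0.3
    tissue_baselines: Optional[dict] = None  # (gene, tissue) -> log2 offset

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for gene, eff in self.effect_genes.items():
            if not np.isfinite(eff.effect_log2):
                raise ValueError(f"non-finite effect for {gene}")
            if eff.frequency is not None and not (0 < eff.frequency < 1):
                raise ValueError(f"frequency for {gene} outside (0, 1)")


def plant_effects(
    genome: GenomeAnnotation,
    effect_spec: EffectSpec,
    seed: int,
    default_freq_range: tuple[float, float] = (0.05, 0.5),
) -> list[PanelSV]:
    """Create one dedicated panel SV per effect gene, with breakpoints in
    the gene's stated window.

    Enhancer-duplication effects get a fresh enhancer placed inside the
    SV span (appended to ``genome.enhancers``).  Fills each effect's
    ``sv_id`` so the expression generator can look up carriers.
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genome.genes}
    planted: list[PanelSV] = []
    for idx, (gene_id, eff) in enumerate(sorted(effect_spec.effect_genes.items())):
        gene = gene_by_id.get(gene_id)
        if gene is None:
            raise ValueError(f"effect gene {gene_id} not in genome")
        freq = eff.frequency if eff.frequency is not None \
            else float(rng.uniform(*default_freq_range))
        sv_id = f"eff{idx:04d}.{gene_id}"
        if eff.span_enhancer:
            if eff.sv_class != "DUP":
                raise ValueError("span_enhancer effects must be DUP")
            spec = WindowSpec.from_label("up_100kb")
            lo, hi = window_interval(gene, spec)
            if hi - lo < 10_000:
                raise ValueError(f"flank of {gene_id} too small to plant in")
            size = int(rng.integers(5_000, min(50_000, hi - lo - 2)))
            pos_a = int(rng.integers(lo, hi - size))
            pos_b = pos_a + size
            e_len = 800
            e_start = pos_a + (size - e_len) // 2
            genome.enhancers.append((gene.chrom, e_start, e_start + e_len))
        elif eff.window == "flank_1mb_weighted":
            offset = int(rng.integers(110_000, 500_000))
            size = _draw_size(rng, 2_100.0, 1.0)
            pos_b = max(size + 1, gene.start - offset)
            pos_a = pos_b - size
        else:
            spec = WindowSpec.from_label(eff.window)
            iv = window_interval(gene, spec)
            if iv is None:
                raise ValueError(f"gene {gene_id} lacks window {eff.window}")
            lo, hi = iv
            if hi - lo < 2:
                raise ValueError(f"window {eff.window} of {gene_id} too small")
            pos_a = int(rng.integers(lo, hi - 1))
            pos_b = int(rng.integers(pos_a + 1, hi))
        planted.append(PanelSV(sv_id, gene.chrom, pos_a, gene.chrom, pos_b,
                               eff.sv_class, freq, tissue_freq=eff.tissue_freq))
        eff.sv_id = sv_id
    return planted


# ---------------------------------------------------------------------------
# Expression, copy number, covariates


@dataclass
class CovariateParams:
    tissues: tuple[str, ...] = ("breast", "liver", "kidney", "lung")
    tissue_assignments: Optional[pd.Series] = None
    ploidy_range: tuple[float, float] = (1.5, 4.5)
    purity_range: tuple[float, float] = (0.3, 1.0)


def simulate_expression(
    genome: GenomeAnnotation,
    cohort: SVCohort,
    covar_params: Optional[CovariateParams] = None,
    effect_spec: Optional[EffectSpec] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression, copy-number and covariate tables for the cohort.

    log2 expression = per-gene baseline + tissue offset + planted effect x
    carrier + ``cn_coef`` x (copies - 2) + Gaussian noise; the expression
    matrix is emitted on the linear (unlogged, non-negative) scale as
    ``2 ** log2``.  Tumor copy number starts diploid and is perturbed by
    somatic gene-spanning DUP/DEL events; germline SVs leave it flat.
    """
    covar_params = covar_params or CovariateParams()
    effect_spec = effect_spec or EffectSpec()
    rng = np.random.default_rng(seed)
    patients = cohort.patients
    n = len(patients)
    if len(covar_params.tissues) < 1:
        raise ValueError("need >= 1 tissue")

    if covar_params.tissue_assignments is not None:
        tissue = pd.Series(covar_params.tissue_assignments).reindex(patients)
        if tissue.isna().any():
            raise ValueError("tissue assignment missing for some patients")
    else:
        tissue = pd.Series(
            rng.choice(list(covar_params.tissues), size=n), index=patients)
    ploidy = pd.Series(rng.uniform(*covar_params.ploidy_range, size=n),
                       index=patients)
    purity = pd.Series(rng.uniform(*covar_params.purity_range, size=n),
                       index=patients)
    covars = pd.DataFrame({"tissue": tissue, "ploidy": ploidy,
                           "purity": purity})

    genes = genome.genes
    gene_ids = [g.gene_id for g in genes]
    tissues = sorted(set(tissue))
    baseline = rng.uniform(*effect_spec.base_expr_range, size=len(genes))
    offsets = rng.normal(0.0, effect_spec.tissue_baseline_sd,
                         size=(len(genes), len(tissues)))
    t_index = {t: i for i, t in enumerate(tissues)}
    if effect_spec.tissue_baselines:
        g_index = {g: i for i, g in enumerate(gene_ids)}
        for (g, t), val in effect_spec.tissue_baselines.items():
            offsets[g_index[g], t_index[t]] = val
    tcol = np.array([t_index[tissue[p]] for p in patients])
    log2_expr = baseline[:, None] + offsets[:, tcol]

    # somatic CN perturbation at gene-spanning DUP/DEL events
    from .feature_enrichment import find_spanning_events

    cn = np.full((len(genes), n), 2.0)
    g_index = {g: i for i, g in enumerate(gene_ids)}
    p_index = {p: i for i, p in enumerate(patients)}
    for gene_id, sample, cls in find_spanning_events(
            cohort.all_somatic(), genes):
        gi, pi = g_index[gene_id], p_index[sample]
        if cls == "DUP":
            cn[gi, pi] += int(rng.integers(1, 5))
        else:
            cn[gi, pi] = max(0.0, cn[gi, pi] - 1.0)
    log2_expr = log2_expr + effect_spec.cn_coef * (cn - 2.0)

    for gene_id, eff in effect_spec.effect_genes.items():
        if eff.sv_id is None:
            raise ValueError(
                f"effect for {gene_id} has no planted SV; run plant_effects")
        carriers = cohort.truth[eff.sv_id].to_numpy()
        if carriers.sum() == 0:
            warnings.warn(f"planted effect at {gene_id} has zero carriers")
        log2_expr[g_index[gene_id]] += eff.effect_log2 * carriers

    if effect_spec.noise_sd > 0:
        log2_expr = log2_expr + rng.normal(0.0, effect_spec.noise_sd,
                                           size=log2_expr.shape)
    expr = pd.DataFrame(np.exp2(log2_expr), index=gene_ids, columns=patients)
    cn_df = pd.DataFrame(cn, index=gene_ids, columns=patients)
    return expr, cn_df, covars


# ---------------------------------------------------------------------------
# Survival


@dataclass
class HazardSpec:
    """Exponential survival model: hazard = baseline x exp(sum of log-HR x
    feature), independent exponential censoring, follow-up cap."""

    baseline_hazard: float = 0.01  # events per month
    log_hr_per_feature: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.2
    max_followup: Optional[float] = 240.0
    stratum_log_hazard: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")


def simulate_survival(
    features: pd.DataFrame,
    hazard_spec: HazardSpec,
    strata: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Survival table (time in months, event flag, stratum) per patient.

    Event times are exponential with per-patient hazard; censoring is an
    independent exponential calibrated so that roughly ``censoring_rate``
    of baseline-hazard patients are censored before their event; times
    are capped at ``max_followup`` with the event flag cleared at the cap.
    """
    rng = np.random.default_rng(seed)
    patients = list(features.index)
    eta = np.zeros(len(patients))
    for feat, log_hr in hazard_spec.log_hr_per_feature.items():
        if feat not in features.columns:
            raise ValueError(f"hazard feature {feat!r} not in feature table")
        eta = eta + log_hr * features[feat].to_numpy(dtype=float)
    strata = pd.Series(strata).reindex(patients)
    if hazard_spec.stratum_log_hazard:
        eta = eta + np.array([hazard_spec.stratum_log_hazard.get(s, 0.0)
                              for s in strata])
    hazard = hazard_spec.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    if hazard_spec.censoring_rate > 0:
        c_rate = hazard_spec.baseline_hazard * hazard_spec.censoring_rate \
            / (1.0 - hazard_spec.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(patients))
    else:
        t_cens = np.full(len(patients), np.inf)
    cap = hazard_spec.max_followup if hazard_spec.max_followup is not None \
        else np.inf
    time = np.minimum(np.minimum(t_event, t_cens), cap)
    event = (t_event <= t_cens) & (t_event <= cap)
    return pd.DataFrame({"time": time, "event": event.astype(int),
                         "stratum": strata.to_numpy()}, index=patients)
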