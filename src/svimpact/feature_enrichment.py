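"""Mechanism and descriptive enrichment layers.

Covers the classification of enhancer-duplication events (duplications in
a gene's flank that contain a whole enhancer without touching the gene),
chi-squared enrichment of 2x2 cross-tabulations, SV-class enrichment by
association direction, per-patient cytoband breakpoint-density tests,
ploidy-corrected copy-number category crosstabs, and crossing association
hits with a CRISPR gene-essentiality matrix.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .breakpoint_matrix import GeneModel, classify_sv_gene_relation
from .sv_io import SVRecord


@dataclass
class EnrichmentResult:
    """2x2 contingency outcome.

    ``counts`` rows are membership (yes/no), columns are outcome (yes/no);
    ``enriched`` flags an observed top-left cell above its expectation.
    ``p`` is absent for degenerate tables (a zero margin).
    """

    counts: np.ndarray
    chi2: Optional[float]
    p: Optional[float]
    enriched: Optional[bool]
    low_expected: bool = False
    note: str = ""


def enrichment_chisq(
    member_flags: Sequence[bool],
    outcome_flags: Sequence[bool],
) -> EnrichmentResult:
    """Pearson chi-squared (no continuity correction) on the 2x2
    cross-tabulation of two boolean vectors over the same items."""
    member = np.asarray(member_flags, dtype=bool)
    outcome = np.asarray(outcome_flags, dtype=bool)
    if member.shape != outcome.shape or member.size == 0:
        raise ValueError("need >= 1 item with aligned flags")
    counts = np.array([
        [np.sum(member & outcome), np.sum(member & ~outcome)],
        [np.sum(~member & outcome), np.sum(~member & ~outcome)],
    ], dtype=np.int64)
    return chisq_from_table(counts)


def chisq_from_table(counts: np.ndarray) -> EnrichmentResult:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.min() < 0:
        raise ValueError("negative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return EnrichmentResult(counts, None, None, None,
                                note="degenerate margin")
    chi2, p, _, expected = stats.chi2_contingency(counts, correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("chi-squared table has expected cell < 5")
    enriched = bool(counts[0, 0] > expected[0, 0])
    return EnrichmentResult(counts, float(chi2), float(p), enriched,
                            low_expected=low)


# ---------------------------------------------------------------------------
# Enhancer duplication


def classify_enhancer_duplication(
    sv: SVRecord,
    gene: GeneModel,
    enhancers: Sequence[tuple],
    flank_bp: int = 100_000,
    whole_enhancer: bool = True,
) -> bool:
    """Is ``sv`` a candidate enhancer-duplication event for ``gene``?

    True iff all of: the SV is a duplication; both breakpoints fall in the
    gene's 100 kb flank (either side) without entering the gene; the SV
    does not span the gene; and the SV interval contains at least one
    enhancer (whole containment by default, any overlap when
    ``whole_enhancer`` is False).
    """
    if not sv.is_intrachromosomal:
        raise ValueError("enhancer-duplication classification needs an "
                         "intrachromosomal SV")
    if sv.sv_class != "DUP" or sv.chrom_a != gene.chrom:
        return False
    rel = classify_sv_gene_relation(sv, gene)
    if rel.spans_gene:
        return False
    flank_lo = max(0, gene.start - flank_bp)
    flank_hi = gene.end + flank_bp
    for pos in (sv.pos_a, sv.pos_b):
        in_flank = (flank_lo <= pos < gene.start) or (gene.end <= pos < flank_hi)
        if not in_flank:
            return False
    for enh in enhancers:
        chrom, e_start, e_end = enh[0], enh[1], enh[2]
        if chrom != sv.chrom_a:
            continue
        if whole_enhancer:
            if sv.pos_a <= e_start and e_end <= sv.pos_b:
                return True
        elif e_start < sv.pos_b and sv.pos_a < e_end:
            return True
    return False


# ---------------------------------------------------------------------------
# SV class vs association direction


def enhancer_duplication_flags(
    records: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    enhancers: Sequence[tuple],
    flank_bp: int = 100_000,
) -> dict[str, bool]:
    """Per gene: does any intrachromosomal SV qualify as an
    enhancer-duplication event for it?  Only SVs with a breakpoint within
    reach of the gene's flanks are considered."""
    out: dict[str, bool] = {}
    reach = flank_bp * 3
    by_chrom: dict[str, list[SVRecord]] = defaultdict(list)
    for r in records:
        if r.is_intrachromosomal:
            by_chrom[r.chrom_a].append(r)
    for gene in genes:
        out[gene.gene_id] = any(
            classify_enhancer_duplication(r, gene, enhancers,
                                          flank_bp=flank_bp)
            for r in by_chrom.get(gene.chrom, ())
            if abs(r.pos_a - gene.start) < reach)
    return out


def sv_class_direction_enrichment(
    records,
    gene_classes: dict[str, Sequence[str]],
    p_threshold: float = 0.01,
) -> dict[str, EnrichmentResult]:
    """Per SV class, enrichment of the class among increased- versus
    decreased-expression associations.

    ``gene_classes`` attributes each gene to every SV class with a
    breakpoint contributing to its window; each (gene, class) attribution
    of a significant association is one item.  Items are cross-tabulated
    as (this class vs other classes) x (increased vs decreased).
    """
    items: list[tuple[str, bool]] = []
    for r in records:
        if r.p is None or r.p >= p_threshold or r.direction is None:
            continue
        for cls in gene_classes.get(r.gene_id, ()):
            items.append((cls, r.direction == "positive"))
    results: dict[str, EnrichmentResult] = {}
    for cls in sorted({c for c, _ in items}):
        member = [c == cls for c, _ in items]
        outcome = [up for _, up in items]
        results[cls] = enrichment_chisq(member, outcome)
    return results


def contributing_classes(
    cohort: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    window,
) -> dict[str, set[str]]:
    """Map gene -> SV classes with a breakpoint in the gene's window."""
    from .breakpoint_matrix import window_interval

    out: dict[str, set[str]] = defaultdict(set)
    by_chrom: dict[str, list] = defaultdict(list)
    for r in cohort:
        by_chrom[r.chrom_a].append((r.pos_a, r.sv_class))
        by_chrom[r.chrom_b].append((r.pos_b, r.sv_class))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for gene in genes:
        iv = window_interval(gene, window)
        if iv is None:
            continue
        pts = by_chrom.get(gene.chrom, [])
        pos = [p for p, _ in pts]
        lo = np.searchsorted(pos, iv[0], side="left")
        hi = np.searchsorted(pos, iv[1], side="left")
        for _, cls in pts[lo:hi]:
            out[gene.gene_id].add(cls)
    return dict(out)


# ---------------------------------------------------------------------------
# Cytoband breakpoint density


def cytoband_enrichment(
    patient_svs: Sequence[SVRecord],
    cytobands: Sequence[tuple],
) -> dict[str, EnrichmentResult]:
    """Per-band breakpoint-density test for one patient.

    For each band, the patient's breakpoint count inside versus outside
    the band is tested (1-df chi-squared goodness of fit) against the
    expectation proportional to the band's share of total genome length.
    A patient with zero SVs yields no tested bands.
    """
    bands = [(str(b[3]) if len(b) > 3 else f"{b[0]}:{b[1]}-{b[2]}",
              str(b[0]), int(b[1]), int(b[2])) for b in cytobands]
    genome_len = sum(e - s for _, _, s, e in bands)
    if genome_len <= 0:
        raise ValueError("cytobands have zero total length")
    breakpoints: list[tuple[str, int]] = []
    for r in patient_svs:
        breakpoints.append((r.chrom_a, r.pos_a))
        breakpoints.append((r.chrom_b, r.pos_b))
    n = len(breakpoints)
    results: dict[str, EnrichmentResult] = {}
    if n == 0:
        return results
    for name, chrom, start, end in bands:
        k = sum(1 for c, p in breakpoints if c == chrom and start <= p < end)
        f = (end - start) / genome_len
        expected = np.array([n * f, n * (1 - f)])
        observed = np.array([k, n - k])
        counts = np.array([[k, n - k],
                           [int(round(expected[0])), int(round(expected[1]))]])
        if expected.min() <= 0:
            results[name] = EnrichmentResult(counts, None, None, None,
                                             note="degenerate expectation")
            continue
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        p = float(stats.chi2.sf(chi2, df=1))
        results[name] = EnrichmentResult(
            counts, chi2, p, enriched=bool(k > expected[0]),
            low_expected=bool(expected.min() < 5))
    return results


def cohort_cytoband_summary(
    per_patient: dict[str, dict[str, EnrichmentResult]],
    p_threshold: float = 1e-4,
    min_patients: int = 20,
) -> list[str]:
    """Bands enriched (p below threshold) in at least ``min_patients``."""
    hits: dict[str, int] = defaultdict(int)
    for results in per_patient.values():
        for band, res in results.items():
            if res.p is not None and res.p < p_threshold and res.enriched:
                hits[band] += 1
    return sorted(b for b, n in hits.items() if n >= min_patients)


# ---------------------------------------------------------------------------
# Copy-number categories


def copy_category(corrected_copies: float) -> str:
    """Diploid-equivalent copy bin: >5 amplification, [3, 5] copy_gain,
    [0, 1] copy_loss, otherwise neutral."""
    if corrected_copies > 5:
        return "amplification"
    if 3 <= corrected_copies <= 5:
        return "copy_gain"
    if 0 <= corrected_copies <= 1:
        return "copy_loss"
    return "neutral"


COPY_CATEGORIES = ("amplification", "copy_gain", "neutral", "copy_loss")


@dataclass
class CopyCategoryCrosstab:
    table: pd.DataFrame
    dup_gain: EnrichmentResult
    del_loss: EnrichmentResult


def find_spanning_events(
    cohort: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    classes: tuple[str, ...] = ("DUP", "DEL"),
) -> list[tuple[str, str, str]]:
    """(gene_id, sample, sv_class) for DUP/DEL SVs spanning whole genes."""
    events = []
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: g.start)
    for r in cohort:
        if r.sv_class not in classes or not r.is_intrachromosomal:
            continue
        for g in by_chrom.get(r.chrom_a, ()):
            if g.start > r.pos_b:
                break
            if r.pos_a <= g.start and r.pos_b >= g.end:
                events.append((g.gene_id, r.patient_id, r.sv_class))
    return sorted(set(events))


def copy_category_crosstab(
    spanning_events: Sequence[tuple[str, str, str]],
    copy_matrix: pd.DataFrame,
    ploidy: pd.Series,
) -> CopyCategoryCrosstab:
    """Cross-tabulate gene-spanning DUP versus DEL events against
    ploidy-corrected copy categories.

    Corrected copies = copies * 2 / ploidy (diploid equivalent).  Also
    tests DUP enrichment in gained/amplified categories and DEL
    enrichment in the lost category.
    """
    rows = []
    for gene, sample, cls in spanning_events:
        if gene not in copy_matrix.index or sample not in copy_matrix.columns:
            continue
        if sample not in ploidy.index:
            raise ValueError(f"no ploidy for sample {sample!r}")
        corrected = copy_matrix.loc[gene, sample] * 2.0 / ploidy[sample]
        rows.append({"sv_class": cls, "category": copy_category(corrected)})
    df = pd.DataFrame(rows, columns=["sv_class", "category"])
    table = pd.crosstab(df["sv_class"], df["category"]) if len(df) else \
        pd.DataFrame()
    table = table.reindex(index=["DUP", "DEL"],
                          columns=list(COPY_CATEGORIES), fill_value=0)
    is_dup = df["sv_class"] == "DUP"
    gained = df["category"].isin(["copy_gain", "amplification"])
    lost = df["category"] == "copy_loss"
    if len(df):
        dup_gain = enrichment_chisq(is_dup.tolist(), gained.tolist())
        del_loss = enrichment_chisq((~is_dup).tolist(), lost.tolist())
    else:
        empty = np.zeros((2, 2), dtype=np.int64)
        dup_gain = EnrichmentResult(empty, None, None, None, note="no events")
        del_loss = EnrichmentResult(empty, None, None, None, note="no events")
    return CopyCategoryCrosstab(table=table, dup_gain=dup_gain,
                                del_loss=del_loss)


# ---------------------------------------------------------------------------
# Essentiality crossing


def cross_essentiality(
    genes_up: Sequence[str],
    ess: pd.DataFrame,
    score_threshold: float = -0.75,
    frac_threshold: float = 0.05,
) -> list[str]:
    """Genes, among ``genes_up``, essential (score below threshold) in
    more than ``frac_threshold`` of cell lines.

    ``ess`` is a gene x cell-line matrix of gene-effect scores (more
    negative = more essential).  Genes absent from the matrix are
    excluded.
    """
    if ess.shape[1] < 1:
        raise ValueError("essentiality matrix has no cell lines")
    out = []
    missing = 0
    for gene in genes_up:
        if gene not in ess.index:
            missing += 1
            continue
        frac = float((ess.loc[gene] < score_threshold).mean())
        if frac > frac_threshold:
            out.append(gene)
    if missing:
        warnings.warn(f"{missing} genes absent from essentiality matrix")
    return sorted(out)
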