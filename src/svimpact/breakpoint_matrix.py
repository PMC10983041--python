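"""Gene x sample breakpoint matrices and SV-gene geometric relations.

The central object of the gene-centric approach: for a chosen genomic
window relative to each gene (gene body, 100 kb up/downstream, 2 kb
upstream, 3'UTR, or a 1 Mb distance-weighted flank), a matrix with one row
per gene and one column per sample whose entry records whether (or, for
the weighted window, how close) any SV breakpoint of that sample falls in
the window.

Intervals are 0-based half-open.  Upstream/downstream are strand-aware:
upstream is 5' of the gene on the gene's strand.  Flank windows exclude
the gene body itself, so a breakpoint inside the gene counts only toward
the gene-body (or 3'UTR) window.  The weighted 1 Mb flank is anchored at
the gene start: the entry is ``1 - d/extent`` for the breakpoint nearest
the gene start within ``extent`` bp, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sv_io import SVRecord

WINDOW_LABELS = (
    "gene_body", "up_100kb", "down_100kb", "up_2kb", "utr3",
    "flank_1mb_weighted",
)

_DEFAULT_EXTENTS = {
    "up_100kb": 100_000,
    "down_100kb": 100_000,
    "up_2kb": 2_000,
    "flank_1mb_weighted": 1_000_000,
}


@dataclass
class GeneModel:
    """Stranded gene interval with an optional 3'UTR sub-interval.

    The 3'UTR, when present, must lie within the gene and abut the
    strand-appropriate 3' end (the right end for '+', the left for '-').
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.utr3 is not None:
            u0, u1 = self.utr3
            if not (self.start <= u0 < u1 <= self.end):
                raise ValueError(f"{self.gene_id}: utr3 outside gene")
            three_prime_ok = (u1 == self.end) if self.strand == "+" \
                else (u0 == self.start)
            if not three_prime_ok:
                raise ValueError(
                    f"{self.gene_id}: utr3 must abut the 3' gene end")


@dataclass
class WindowSpec:
    label: str
    extent: Optional[int] = None
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.label not in WINDOW_LABELS:
            raise ValueError(f"unknown window label {self.label!r}")
        if self.weighted and self.label != "flank_1mb_weighted":
            raise ValueError("only flank_1mb_weighted may be weighted")
        if self.label in _DEFAULT_EXTENTS:
            if self.extent is None:
                self.extent = _DEFAULT_EXTENTS[self.label]
            if self.extent <= 0:
                raise ValueError("extent must be > 0 for flank windows")

    @classmethod
    def from_label(cls, label: str) -> "WindowSpec":
        return cls(label=label, weighted=(label == "flank_1mb_weighted"))


@dataclass
class BreakpointMatrix:
    """Gene x sample matrix for one window spec.

    ``values`` holds 0/1 for unweighted windows and [0, 1] weights for the
    weighted flank.
    """

    window: WindowSpec
    values: pd.DataFrame

    @property
    def carrier_counts(self) -> pd.Series:
        return (self.values != 0).sum(axis=1)


def window_interval(gene: GeneModel, window: WindowSpec
                    ) -> Optional[tuple[int, int]]:
    """Half-open interval of ``window`` relative to ``gene``.

    Returns None when the window does not exist for the gene (no 3'UTR).
    Flank intervals are clamped at 0 on the left.
    """
    label = window.label
    if label == "gene_body":
        return gene.start, gene.end
    if label == "utr3":
        return gene.utr3
    if label in ("up_100kb", "up_2kb"):
        upstream = True
    elif label == "down_100kb":
        upstream = False
    else:
        raise ValueError(f"no fixed interval for window {label!r}")
    left_side = (gene.strand == "+") == upstream
    if left_side:
        return max(0, gene.start - window.extent), gene.start
    return gene.end, gene.end + window.extent


def _breakpoints_by_chrom(cohort: Sequence[SVRecord], sample_index):
    """Sorted (positions, sample-index) arrays per chromosome; both
    breakpoints of every SV contribute independently."""
    acc: dict[str, list[tuple[int, int]]] = {}
    for r in cohort:
        si = sample_index.get(r.patient_id)
        if si is None:
            continue
        acc.setdefault(r.chrom_a, []).append((r.pos_a, si))
        acc.setdefault(r.chrom_b, []).append((r.pos_b, si))
    out = {}
    for chrom, pairs in acc.items():
        pairs.sort()
        out[chrom] = (np.array([p[0] for p in pairs], dtype=np.int64),
                      np.array([p[1] for p in pairs], dtype=np.int64))
    return out


def _resolve_samples(cohort, samples):
    if samples is None:
        samples = sorted({r.patient_id for r in cohort})
    return list(samples), {s: i for i, s in enumerate(samples)}


def build_breakpoint_matrix(
    cohort: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    window: WindowSpec,
    samples: Optional[Sequence[str]] = None,
) -> BreakpointMatrix:
    """Binary matrix: entry (g, s) = 1 iff any breakpoint of any SV of
    sample ``s`` lies in ``window`` of gene ``g``.

    Genes lacking a 3'UTR are skipped for the utr3 window; genes on
    chromosomes without any breakpoint keep all-zero rows.
    """
    if window.weighted:
        raise ValueError("use build_weighted_matrix for weighted windows")
    samples, sample_index = _resolve_samples(cohort, samples)
    by_chrom = _breakpoints_by_chrom(cohort, sample_index)
    if window.label == "utr3":
        genes = [g for g in genes if g.utr3 is not None]
    mat = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for gi, gene in enumerate(genes):
        iv = window_interval(gene, window)
        if iv is None:
            continue
        entry = by_chrom.get(gene.chrom)
        if entry is None:
            continue
        pos, sidx = entry
        lo = np.searchsorted(pos, iv[0], side="left")
        hi = np.searchsorted(pos, iv[1], side="left")
        if hi > lo:
            mat[gi, np.unique(sidx[lo:hi])] = 1
    values = pd.DataFrame(mat, index=[g.gene_id for g in genes],
                          columns=samples)
    return BreakpointMatrix(window=window, values=values)


def build_weighted_matrix(
    cohort: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    extent_bp: int = 1_000_000,
    samples: Optional[Sequence[str]] = None,
) -> BreakpointMatrix:
    """Relative-distance-weighted flank matrix.

    For each (gene, sample) let ``d`` be the minimum distance between the
    gene start and any breakpoint of the sample on the gene's chromosome
    with ``d <= extent_bp``; the entry is ``1 - d/extent_bp`` (linear
    decay), or 0 when no such breakpoint exists.
    """
    if extent_bp <= 0:
        raise ValueError("extent_bp must be > 0")
    samples, sample_index = _resolve_samples(cohort, samples)
    by_chrom = _breakpoints_by_chrom(cohort, sample_index)
    mat = np.zeros((len(genes), len(samples)), dtype=float)
    for gi, gene in enumerate(genes):
        entry = by_chrom.get(gene.chrom)
        if entry is None:
            continue
        pos, sidx = entry
        lo = np.searchsorted(pos, gene.start - extent_bp, side="left")
        hi = np.searchsorted(pos, gene.start + extent_bp, side="right")
        if hi <= lo:
            continue
        d = np.abs(pos[lo:hi] - gene.start)
        keep = d <= extent_bp
        if not np.any(keep):
            continue
        dmin = np.full(len(samples), np.iinfo(np.int64).max, dtype=np.int64)
        np.minimum.at(dmin, sidx[lo:hi][keep], d[keep])
        hit = dmin <= extent_bp
        mat[gi, hit] = 1.0 - dmin[hit] / extent_bp
    values = pd.DataFrame(mat, index=[g.gene_id for g in genes],
                          columns=samples)
    spec = WindowSpec("flank_1mb_weighted", extent=extent_bp, weighted=True)
    return BreakpointMatrix(window=spec, values=values)


# ---------------------------------------------------------------------------
# Geometric relation of one SV to one gene


@dataclass
class SVGeneRelation:
    """Per-breakpoint relation labels plus a per-SV span flag."""

    relation_a: str
    relation_b: str
    spans_gene: bool
    distance_to_gene_start: Optional[int]


def _breakpoint_relation(chrom: str, pos: int, gene: GeneModel) -> str:
    if chrom != gene.chrom:
        return "none"
    if gene.utr3 is not None and gene.utr3[0] <= pos < gene.utr3[1]:
        return "in_utr3"
    if gene.start <= pos < gene.end:
        return "breakpoint_in_gene"
    left_of_gene = pos < gene.start
    if (gene.strand == "+") == left_of_gene:
        return "upstream"
    return "downstream"


def classify_sv_gene_relation(sv: SVRecord, gene: GeneModel) -> SVGeneRelation:
    """Classify each breakpoint of ``sv`` relative to ``gene``.

    ``spans_gene`` is true only for intrachromosomal SVs whose breakpoint
    interval contains the whole gene.  The reported distance is the
    smallest |breakpoint - gene start| over breakpoints on the gene's
    chromosome (absent when neither breakpoint is on it).
    """
    rel_a = _breakpoint_relation(sv.chrom_a, sv.pos_a, gene)
    rel_b = _breakpoint_relation(sv.chrom_b, sv.pos_b, gene)
    spans = (sv.is_intrachromosomal and sv.chrom_a == gene.chrom
             and sv.pos_a <= gene.start and sv.pos_b >= gene.end)
    dists = [abs(pos - gene.start)
             for chrom, pos in ((sv.chrom_a, sv.pos_a), (sv.chrom_b, sv.pos_b))
             if chrom == gene.chrom]
    return SVGeneRelation(
        relation_a=rel_a, relation_b=rel_b, spans_gene=spans,
        distance_to_gene_start=min(dists) if dists else None,
    )


# ---------------------------------------------------------------------------
# Matrix I/O


def write_matrix(matrix: BreakpointMatrix, path, sidecar_path=None) -> None:
    """TSV (genes x samples) plus a JSON sidecar recording the window."""
    import json

    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"label": matrix.window.label,
                       "extent": matrix.window.extent,
                       "weighted": matrix.window.weighted}, fh, indent=2)


def read_matrix(path, sidecar_path=None) -> BreakpointMatrix:
    import json

    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        spec = WindowSpec(meta["label"], extent=meta["extent"],
                          weighted=meta["weighted"])
    else:
        spec = WindowSpec.from_label("gene_body")
    return BreakpointMatrix(window=spec, values=values)
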