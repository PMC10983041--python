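"""Reading, writing and harmonizing structural-variant (SV) call sets.

An SV is represented as a pair of genomic breakpoints plus a class label
(DEL, DUP, INV, TRA).  This module covers the plumbing around call sets:
tab-separated BEDPE-like tables, consensus merging of two caller replicates
with positional slop, breakpoint recurrence across patients, overlap with a
known-SV catalog, and descriptive summaries (class fractions, sizes,
per-patient counts).

Coordinates are 0-based throughout; intrachromosomal records are stored in
canonical order with ``pos_a <= pos_b``.  All slop comparisons are
inclusive (``<=``).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SV_CLASSES = ("DEL", "DUP", "INV", "TRA")
ORIGINS = ("germline", "somatic")

#: Column order of the on-disk BEDPE-like SV table.
SV_TABLE_COLUMNS = (
    "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
    "sv_id", "sv_class", "patient_id", "origin",
)


@dataclass
class SVRecord:
    """One breakpoint pair.

    Intrachromosomal records are canonicalized so that ``pos_a <= pos_b``;
    the class must be TRA exactly when the two breakpoints sit on different
    chromosomes.
    """

    sv_id: str
    patient_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    sv_class: str
    origin: str

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown sv_class {self.sv_class!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError(
                f"negative breakpoint position in {self.sv_id!r}: "
                f"{self.pos_a}, {self.pos_b}"
            )
        inter = self.chrom_a != self.chrom_b
        if inter != (self.sv_class == "TRA"):
            raise ValueError(
                f"class/geometry mismatch in {self.sv_id!r}: class "
                f"{self.sv_class} with chromosomes {self.chrom_a}/{self.chrom_b}"
            )
        if not inter and self.pos_a > self.pos_b:
            self.pos_a, self.pos_b = self.pos_b, self.pos_a

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def span(self) -> int | None:
        """Distance between breakpoints, or None for translocations."""
        if not self.is_intrachromosomal:
            return None
        return self.pos_b - self.pos_a


@dataclass
class MergedCallset:
    """Consensus of two caller replicates; coordinates come from set ``a``."""

    records: list[SVRecord]
    provenance: list[tuple[str, str]]
    n_unmatched_a: int = 0
    n_unmatched_b: int = 0


@dataclass
class RecurrenceFlags:
    both_shared: bool
    either_shared: bool


@dataclass
class SVSummary:
    class_fractions: dict[str, float]
    median_intra_size: float | None
    recurrence_fraction_both: float
    recurrence_fraction_either: float
    per_patient_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Table I/O


def read_sv_table(path: str | Path, origin: str) -> list[SVRecord]:
    """Read a BEDPE-like SV table (tab-separated, 0-based starts).

    Breakpoint positions are taken from ``start_a``/``start_b``.  All
    malformed rows are collected and reported together with their 1-based
    row numbers; any malformed row aborts the read.
    """
    if origin not in ORIGINS:
        raise ValueError(f"unknown origin {origin!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chrom_a", "start_a", "chrom_b", "start_b", "sv_id", "sv_class",
                "patient_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[SVRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(SVRecord(
                sv_id=str(row.sv_id),
                patient_id=str(row.patient_id),
                chrom_a=str(row.chrom_a),
                pos_a=int(row.start_a),
                chrom_b=str(row.chrom_b),
                pos_b=int(row.start_b),
                sv_class=str(row.sv_class),
                origin=origin,
            ))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValueError(f"{path}: {len(problems)} malformed rows — "
                         + "; ".join(problems[:10]))
    return records


def write_sv_table(records: Iterable[SVRecord], path: str | Path) -> None:
    """Write records as a BEDPE-like table (``end = start + 1``)."""
    rows = [
        {
            "chrom_a": r.chrom_a, "start_a": r.pos_a, "end_a": r.pos_a + 1,
            "chrom_b": r.chrom_b, "start_b": r.pos_b, "end_b": r.pos_b + 1,
            "sv_id": r.sv_id, "sv_class": r.sv_class,
            "patient_id": r.patient_id, "origin": r.origin,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SV_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Two-caller consensus merge


def merge_callsets(
    a: Sequence[SVRecord],
    b: Sequence[SVRecord],
    slop_bp: int = 200,
    require_class_match: bool = False,
) -> MergedCallset:
    """One-to-one consensus of two call sets for the same patient/origin.

    A record of ``a`` is emitted iff some record of ``b`` shares its
    chromosome pair and both breakpoints agree within ``slop_bp``
    (inclusive).  Matching is one-to-one, greedy by ascending total
    breakpoint distance with ties broken by input order, and emitted
    coordinates are those of ``a``.  Unmatched records on either side are
    dropped (counted, logged).
    """
    candidates: list[tuple[int, int, int]] = []
    by_pair: dict[tuple, list[int]] = defaultdict(list)
    for j, rb in enumerate(b):
        by_pair[(rb.chrom_a, rb.chrom_b)].append(j)
    for i, ra in enumerate(a):
        for j in by_pair.get((ra.chrom_a, ra.chrom_b), ()):
            rb = b[j]
            if require_class_match and ra.sv_class != rb.sv_class:
                continue
            da = abs(ra.pos_a - rb.pos_a)
            db = abs(ra.pos_b - rb.pos_b)
            if da <= slop_bp and db <= slop_bp:
                candidates.append((da + db, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    matches.sort()
    merged = MergedCallset(
        records=[a[i] for i, _ in matches],
        provenance=[(a[i].sv_id, b[j].sv_id) for i, j in matches],
        n_unmatched_a=len(a) - len(matches),
        n_unmatched_b=len(b) - len(matches),
    )
    if merged.n_unmatched_a or merged.n_unmatched_b:
        logger.info("merge_callsets: dropped %d/%d unmatched records (a/b)",
                    merged.n_unmatched_a, merged.n_unmatched_b)
    return merged


# ---------------------------------------------------------------------------
# Cross-patient recurrence and catalog overlap


def _unique_key_groups(records, require_class_match):
    """Group records by chromosome pair (and optionally class) into unique
    coordinate keys, each with its patient set and member record indices."""
    groups: dict[tuple, dict[tuple[int, int], dict]] = defaultdict(dict)
    for idx, r in enumerate(records):
        gkey = (r.chrom_a, r.chrom_b) + (
            (r.sv_class,) if require_class_match else ())
        entry = groups[gkey].setdefault(
            (r.pos_a, r.pos_b), {"patients": set(), "members": []})
        entry["patients"].add(r.patient_id)
        entry["members"].append(idx)
    return groups


def compute_recurrence(
    records: Sequence[SVRecord],
    slop_bp: int = 10,
    require_class_match: bool = False,
) -> list[RecurrenceFlags]:
    """Flag, per record, whether another patient carries a matching SV.

    Breakpoints correspond positionally after canonical ordering (A to A,
    B to B; never cross-matched) and must share the chromosome pair.
    ``both_shared`` needs both breakpoints within ``slop_bp`` of another
    patient's SV; ``either_shared`` needs at least one.  A patient's own
    other SVs never count.

    Recurrent call sets collapse onto few unique coordinate pairs, so
    matching is done between unique keys with a sliding window on the
    sorted first-breakpoint positions.
    """
    flags = [RecurrenceFlags(False, False) for _ in records]
    for keyed in _unique_key_groups(records, require_class_match).values():
        keys = sorted(keyed)
        pa = np.array([k[0] for k in keys])
        pb = np.array([k[1] for k in keys])
        patients = [keyed[k]["patients"] for k in keys]
        n = len(keys)
        order_b = np.argsort(pb, kind="stable")
        pb_sorted = pb[order_b]
        for i in range(n):
            lo = np.searchsorted(pa, pa[i] - slop_bp, side="left")
            hi = np.searchsorted(pa, pa[i] + slop_bp, side="right")
            a_window = np.arange(lo, hi)
            both_idx = a_window[np.abs(pb[a_window] - pb[i]) <= slop_bp]
            lo_b = np.searchsorted(pb_sorted, pb[i] - slop_bp, side="left")
            hi_b = np.searchsorted(pb_sorted, pb[i] + slop_bp, side="right")
            b_window = order_b[lo_b:hi_b]
            both_patients: set[str] = set()
            for j in both_idx:
                both_patients |= patients[j]
            either_patients = set(both_patients)
            for j in a_window:
                either_patients |= patients[j]
            for j in b_window:
                either_patients |= patients[j]
            for ridx in keyed[keys[i]]["members"]:
                me = records[ridx].patient_id
                flags[ridx].both_shared = bool(both_patients - {me})
                flags[ridx].either_shared = bool(either_patients - {me})
    return flags


def annotate_known(
    records: Sequence[SVRecord],
    catalog: Sequence[SVRecord],
    slop_bp: int = 10,
) -> list[bool]:
    """Flag records whose both breakpoints match a catalog entry within slop.

    The catalog plays the role of a known-variant database (DGV-like);
    matching follows the same corresponding-breakpoint rule as
    :func:`compute_recurrence`.
    """
    if not catalog:
        raise ValueError("annotate_known: catalog is empty")
    by_pair: dict[tuple, list[tuple[int, int]]] = defaultdict(list)
    for c in catalog:
        by_pair[(c.chrom_a, c.chrom_b)].append((c.pos_a, c.pos_b))
    sorted_pairs = {}
    for key, pairs in by_pair.items():
        pairs.sort()
        sorted_pairs[key] = (np.array([p[0] for p in pairs]),
                             np.array([p[1] for p in pairs]))
    out = []
    for r in records:
        hit = False
        entry = sorted_pairs.get((r.chrom_a, r.chrom_b))
        if entry is not None:
            pa, pb = entry
            lo = np.searchsorted(pa, r.pos_a - slop_bp, side="left")
            hi = np.searchsorted(pa, r.pos_a + slop_bp, side="right")
            hit = bool(np.any(np.abs(pb[lo:hi] - r.pos_b) <= slop_bp))
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# Descriptive summary


def summarize_svs(
    records: Sequence[SVRecord],
    recurrence_slop_bp: int = 10,
) -> SVSummary:
    """Class fractions, median intrachromosomal size, recurrence, counts."""
    n = len(records)
    class_fractions: dict[str, float] = {}
    per_patient: dict[str, int] = defaultdict(int)
    spans: list[int] = []
    for r in records:
        class_fractions[r.sv_class] = class_fractions.get(r.sv_class, 0) + 1
        per_patient[r.patient_id] += 1
        if r.is_intrachromosomal:
            spans.append(r.span)
    if n:
        class_fractions = {k: v / n for k, v in class_fractions.items()}
    median_size = float(np.median(spans)) if spans else None
    if n:
        flags = compute_recurrence(records, slop_bp=recurrence_slop_bp)
        frac_both = sum(f.both_shared for f in flags) / n
        frac_either = sum(f.either_shared for f in flags) / n
    else:
        frac_both = frac_either = 0.0
    return SVSummary(
        class_fractions=class_fractions,
        median_intra_size=median_size,
        recurrence_fraction_both=frac_both,
        recurrence_fraction_either=frac_either,
        per_patient_counts=dict(per_patient),
    )


# ---------------------------------------------------------------------------
# Annotation tables (genes, plain BED)


def write_genes_table(genes, path: str | Path) -> None:
    """Write gene models as BED6+2 (utr3 columns '.' when absent)."""
    rows = []
    for g in genes:
        utr = g.utr3 if g.utr3 is not None else (".", ".")
        rows.append({
            "chrom": g.chrom, "start": g.start, "end": g.end,
            "gene_id": g.gene_id, "score": 0, "strand": g.strand,
            "utr3_start": utr[0], "utr3_end": utr[1],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes_table(path: str | Path):
    """Read gene models written by :func:`write_genes_table`."""
    from .breakpoint_matrix import GeneModel

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        utr = None
        if str(row.utr3_start) != "." and not pd.isna(row.utr3_start):
            utr = (int(float(row.utr3_start)), int(float(row.utr3_end)))
        genes.append(GeneModel(
            gene_id=str(row.gene_id), chrom=str(row.chrom),
            start=int(row.start), end=int(row.end),
            strand=str(row.strand), utr3=utr,
        ))
    return genes


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED."""
    rows = []
    for iv in intervals:
        row = {"chrom": iv[0], "start": iv[1], "end": iv[2]}
        if len(iv) > 3:
            row["name"] = iv[3]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, named: bool = False) -> list[tuple]:
    cols = ["chrom", "start", "end"] + (["name"] if named else [])
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     usecols=range(len(cols)), dtype={0: str})
    if named:
        return [(str(r.chrom), int(r.start), int(r.end), str(r.name))
                for r in df.itertuples(index=False)]
    return [(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)]
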