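"""Per-gene association of expression with breakpoint patterns.

For each gene, the log2-transformed expression (``log2(x + 1)``) is
regressed on the gene's breakpoint value (0/1 for unweighted windows,
[0, 1] weights for the distance-weighted flank) under one of three
covariate models:

``none``
    intercept only;
``tissue``
    adds tumor tissue-of-origin indicator contrasts (reference = most
    frequent tissue);
``full``
    adds tissue, per-gene copy number, tumor ploidy and tumor purity.

Genes with fewer carriers than ``min_carriers`` are excluded before
Benjamini-Hochberg FDR adjustment, which is applied within the tested
gene set of one (window, model) run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .breakpoint_matrix import BreakpointMatrix

logger = logging.getLogger(__name__)

MODELS = ("none", "tissue", "full")


@dataclass
class CovariateTable:
    """Sample covariates (tissue, ploidy, purity) plus a gene x sample
    copy-number matrix for the full model."""

    samples: pd.DataFrame
    copy_number: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for col in ("tissue", "ploidy", "purity"):
            if col not in self.samples.columns:
                raise ValueError(f"covariates missing column {col!r}")
        if self.samples["tissue"].isna().any():
            raise ValueError("missing tissue labels")
        purity = self.samples["purity"]
        if ((purity < 0) | (purity > 1)).any():
            raise ValueError("purity outside [0, 1]")
        if (self.samples["ploidy"] <= 0).any():
            raise ValueError("non-positive ploidy")


@dataclass
class AssociationRecord:
    gene_id: str
    window: str
    model: str
    beta: Optional[float]
    t_stat: Optional[float]
    p: Optional[float]
    q: Optional[float]
    n_carriers: int
    direction: Optional[str]
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.p is not None


def log2p1(x):
    """log2(x + 1), the fixed transform applied to expression values."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def _tissue_dummies(tissue: pd.Series) -> pd.DataFrame:
    """Full-rank indicator contrasts, reference = most frequent tissue."""
    counts = tissue.value_counts()
    if len(counts) < 2:
        warnings.warn("single tissue in cohort; tissue term dropped")
        return pd.DataFrame(index=tissue.index)
    reference = counts.index[0]
    dummies = pd.get_dummies(tissue, prefix="tissue", dtype=float)
    return dummies.drop(columns=f"tissue_{reference}")


def fit_gene_association(
    expr: pd.Series,
    bkpt: pd.Series,
    covars: Optional[CovariateTable] = None,
    model: str = "none",
    gene_id: str = "",
    window: str = "",
    copy_number: Optional[pd.Series] = None,
) -> AssociationRecord:
    """Linear-model association of one gene's expression with its
    breakpoint values.

    ``expr`` is on the linear (unlogged) scale; the response is
    ``log2(expr + 1)``.  Returns the two-sided p for the breakpoint
    coefficient.  Degenerate designs (constant expression, constant
    breakpoint, rank deficiency) yield an untestable record with ``p``
    absent rather than an exception.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    y = pd.Series(log2p1(expr), index=expr.index)
    bkpt = bkpt.astype(float)
    n_carriers = int((bkpt != 0).sum())
    X = pd.DataFrame({"bkpt": bkpt})
    if model in ("tissue", "full"):
        if covars is None:
            raise ValueError(f"model {model!r} requires covariates")
        X = X.join(_tissue_dummies(covars.samples.loc[X.index, "tissue"]))
    if model == "full":
        if copy_number is not None:
            X["copy_number"] = copy_number.astype(float)
        X["ploidy"] = covars.samples.loc[X.index, "ploidy"].astype(float)
        X["purity"] = covars.samples.loc[X.index, "purity"].astype(float)
    keep = ~(X.isna().any(axis=1) | y.isna())
    if (~keep).any():
        logger.info("%s: dropped %d samples with missing covariates",
                    gene_id, int((~keep).sum()))
        X, y = X[keep], y[keep]

    def untestable(note):
        return AssociationRecord(gene_id, window, model, None, None, None,
                                 None, n_carriers, None, note=note)

    if X["bkpt"].nunique() < 2:
        return untestable("constant breakpoint values")
    if y.nunique() < 2:
        return untestable("constant expression")
    # constant covariates (e.g. a flat copy-number profile) carry no
    # information and would only render the design rank-deficient
    constant = [c for c in X.columns
                if c != "bkpt" and X[c].nunique() < 2]
    if constant:
        X = X.drop(columns=constant)
    design = sm.add_constant(X, has_constant="add")
    if len(y) <= design.shape[1]:
        return untestable("more parameters than samples")
    res = sm.OLS(y, design).fit()
    if res.df_resid <= 0 or np.linalg.matrix_rank(design.values) < design.shape[1]:
        return untestable("rank-deficient design")
    beta = float(res.params["bkpt"])
    t = float(res.tvalues["bkpt"])
    p = float(res.pvalues["bkpt"])
    if not np.isfinite(p):
        return untestable("non-finite test statistic")
    direction = "positive" if beta > 0 else "negative"
    return AssociationRecord(gene_id, window, model, beta, t, p, None,
                             n_carriers, direction)


def run_associations(
    M: BreakpointMatrix,
    expr_matrix: pd.DataFrame,
    covars: CovariateTable,
    model: str = "full",
    min_carriers: int = 3,
) -> list[AssociationRecord]:
    """Fit every gene shared by the breakpoint matrix and the expression
    matrix, with the carrier filter applied before FDR.

    Expression is on the linear scale (genes x samples).  Sample columns
    must agree across all inputs; BH q-values are computed within the
    tested gene set and results are sorted by p (untestable genes last).
    """
    m_samples = set(M.values.columns)
    e_samples = set(expr_matrix.columns)
    c_samples = set(covars.samples.index)
    if not (m_samples == e_samples == c_samples):
        offending = sorted((m_samples ^ e_samples) | (m_samples ^ c_samples))
        raise ValueError(f"sample-column mismatch: {offending[:20]}")
    samples = list(M.values.columns)
    expr_matrix = expr_matrix[samples]
    genes = [g for g in M.values.index if g in expr_matrix.index]

    records: list[AssociationRecord] = []
    carrier_counts = (M.values != 0).sum(axis=1)
    for gene in genes:
        if carrier_counts[gene] < min_carriers:
            continue
        cn = None
        if model == "full" and covars.copy_number is not None \
                and gene in covars.copy_number.index:
            cn = covars.copy_number.loc[gene, samples]
        rec = fit_gene_association(
            expr_matrix.loc[gene], M.values.loc[gene], covars, model,
            gene_id=gene, window=M.window.label, copy_number=cn)
        records.append(rec)

    apply_bh(records)
    records.sort(key=lambda r: (not r.testable, r.p if r.testable else 1.0))
    return records


def apply_bh(records: Sequence[AssociationRecord]) -> None:
    """Benjamini-Hochberg q-values in place over the testable records."""
    tested = [r for r in records if r.testable]
    if tested:
        _, qvals, _, _ = multipletests([r.p for r in tested],
                                       method="fdr_bh")
        for r, q in zip(tested, qvals):
            r.q = float(q)


def count_significant(
    records: Sequence[AssociationRecord],
    q_threshold: float = 0.10,
) -> tuple[int, int]:
    """(n_positive, n_negative) at q below threshold."""
    pos = sum(1 for r in records
              if r.q is not None and r.q < q_threshold
              and r.direction == "positive")
    neg = sum(1 for r in records
              if r.q is not None and r.q < q_threshold
              and r.direction == "negative")
    return pos, neg


def overlap_germline_somatic(
    germline_records: Sequence[AssociationRecord],
    somatic_records: Sequence[AssociationRecord],
    p_threshold: float = 0.01,
) -> list[tuple[str, str, str]]:
    """Genes significant in both origins, same window, same direction.

    Returns (gene_id, window, direction) triples; both inputs should come
    from the covariate-corrected (full) model.
    """
    def keyed(records):
        out = {}
        for r in records:
            if r.testable and r.p < p_threshold:
                out[(r.gene_id, r.window)] = r.direction
        return out

    germ = keyed(germline_records)
    som = keyed(somatic_records)
    shared = []
    for key, direction in germ.items():
        if som.get(key) == direction:
            shared.append((key[0], key[1], direction))
    shared.sort()
    return shared


def associations_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Stable-column table for TSV export."""
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "window": r.window, "model": r.model,
          "beta": r.beta, "t": r.t_stat, "p": r.p, "q": r.q,
          "n_carriers": r.n_carriers, "direction": r.direction,
          "note": r.note}
         for r in records],
        columns=["gene_id", "window", "model", "beta", "t", "p", "q",
                 "n_carriers", "direction", "note"],
    )
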