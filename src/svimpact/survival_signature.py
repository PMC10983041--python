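"""Survival association and signed gene-signature scoring.

Breakpoint patterns (and expression) are associated with overall survival
by Cox proportional-hazards regression stratified on cancer type (Breslow
tie handling).  Genes whose breakpoint pattern positively associates with
worse survival (one-sided p) and whose expression associates with nearby
breakpoints (two-sided p) form a signed signature; external expression
profiles are then scored by the "t-score" — the pooled-variance
two-sample t statistic comparing a sample's values over signature-high
genes with its values over signature-low genes — and score tertiles are
tested against outcome by stratified log-rank plus a stratified Cox on
the continuous score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats


@dataclass
class CoxResult:
    gene_id: str
    feature: str  # "breakpoint" or "expression" (or free-form)
    window: str = ""
    coef: Optional[float] = None
    p_two_sided: Optional[float] = None
    p_one_sided_positive: Optional[float] = None
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.p_two_sided is not None


@dataclass
class SignedSignature:
    """Gene set with +/-1 directions plus the thresholds that derived it."""

    genes: dict[str, int]
    provenance: dict = field(default_factory=dict)

    @property
    def high_genes(self) -> list[str]:
        return sorted(g for g, d in self.genes.items() if d > 0)

    @property
    def low_genes(self) -> list[str]:
        return sorted(g for g, d in self.genes.items() if d < 0)


def cap_survival(surv: pd.DataFrame, cap_months: float) -> pd.DataFrame:
    """Truncate follow-up at ``cap_months``; events beyond the cap become
    censored at the cap."""
    capped = surv.copy()
    over = capped["time"] > cap_months
    capped.loc[over, "time"] = cap_months
    capped.loc[over, "event"] = 0
    return capped


def one_sided_positive(coef: float, p_two_sided: float) -> float:
    """One-sided p for a positive (hazard-increasing) coefficient."""
    return p_two_sided / 2 if coef > 0 else 1 - p_two_sided / 2


def cox_feature_survival(
    feature: pd.Series,
    surv: pd.DataFrame,
    strata: Optional[pd.Series] = None,
    cap_months: Optional[float] = None,
    gene_id: str = "",
    feature_name: str = "breakpoint",
    window: str = "",
) -> CoxResult:
    """Stratified Cox of one per-patient feature against overall survival.

    ``surv`` needs ``time`` and ``event`` columns indexed by patient; the
    strata default to a ``stratum`` column when present.  Constant
    features, too few events, or a failed fit return an untestable result
    (p absent) rather than raising.
    """
    df = surv[["time", "event"]].copy()
    df["x"] = feature.reindex(df.index).astype(float)
    if strata is not None:
        df["stratum"] = strata.reindex(df.index)
    elif "stratum" in surv.columns:
        df["stratum"] = surv["stratum"]
    df = df.dropna()
    if cap_months is not None:
        df = cap_survival(df, cap_months)

    def untestable(note):
        return CoxResult(gene_id, feature_name, window, note=note)

    if df["x"].nunique() < 2:
        return untestable("constant feature")
    if int(df["event"].sum()) < 2:
        return untestable("fewer than 2 events")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event",
                       strata=["stratum"] if "stratum" in df.columns else None,
                       show_progress=False)
    except Exception as exc:  # noqa: BLE001 - any fit failure is untestable
        return untestable(f"fit failed: {type(exc).__name__}")
    coef = float(fitter.params_["x"])
    p2 = float(fitter.summary.loc["x", "p"])
    return CoxResult(gene_id, feature_name, window, coef=coef,
                     p_two_sided=p2,
                     p_one_sided_positive=one_sided_positive(coef, p2))


def derive_signature(
    surv_results: Sequence[CoxResult],
    assoc_results,
    surv_p: float = 0.05,
    assoc_p: float = 0.05,
) -> SignedSignature:
    """Signed signature from joint survival + expression criteria.

    A gene enters iff, for some window, its breakpoint pattern has a
    positive survival association (one-sided p below ``surv_p``) and, for
    some (possibly different) window, its breakpoint-expression
    association has two-sided p below ``assoc_p``.  The direction is the
    sign of the most significant qualifying expression association (ties
    broken by larger |beta|).
    """
    surv_pass: set[str] = set()
    for r in surv_results:
        if r.testable and r.coef is not None and r.coef > 0 \
                and r.p_one_sided_positive < surv_p:
            surv_pass.add(r.gene_id)
    best: dict[str, tuple[float, float, int]] = {}
    for a in assoc_results:
        if a.p is None or a.p >= assoc_p or a.beta is None:
            continue
        cand = (a.p, -abs(a.beta), 1 if a.beta > 0 else -1)
        if a.gene_id not in best or cand < best[a.gene_id]:
            best[a.gene_id] = cand
    genes = {g: best[g][2] for g in surv_pass if g in best}
    if not genes:
        warnings.warn("derived signature is empty")
    return SignedSignature(
        genes=genes,
        provenance={"surv_p": surv_p, "assoc_p": assoc_p,
                    "n_positive": sum(1 for d in genes.values() if d > 0),
                    "n_negative": sum(1 for d in genes.values() if d < 0)},
    )


# ---------------------------------------------------------------------------
# t-score


def center_profiles(expr_matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) expression centered per gene on the cohort mean,
    producing the differential profiles the t-score expects."""
    logged = np.log2(expr_matrix.astype(float) + 1.0)
    return logged.sub(logged.mean(axis=1), axis=0)


def tscore(signature: SignedSignature, profile: pd.Series) -> float:
    """Pooled-variance two-sample t statistic of a sample's
    signature-high values versus its signature-low values.

    Genes missing from the profile are dropped; fewer than two genes
    remaining on either side is an error.  Zero pooled variance yields
    0.0 when the group means agree and NaN (flagged by a warning)
    otherwise.
    """
    high = [g for g in signature.high_genes if g in profile.index]
    low = [g for g in signature.low_genes if g in profile.index]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"need >= 2 signature genes per side in the profile "
            f"(high={len(high)}, low={len(low)})")
    hv = profile[high].astype(float).to_numpy()
    lv = profile[low].astype(float).to_numpy()
    sp2 = (np.sum((hv - hv.mean()) ** 2) + np.sum((lv - lv.mean()) ** 2)) \
        / (len(hv) + len(lv) - 2)
    denom = np.sqrt(sp2 * (1 / len(hv) + 1 / len(lv)))
    diff = hv.mean() - lv.mean()
    if denom == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means")
        return float("nan")
    return float(diff / denom)


def score_cohort(signature: SignedSignature,
                 profiles: pd.DataFrame) -> pd.Series:
    """t-score every column (sample) of a centered profile matrix."""
    return pd.Series({s: tscore(signature, profiles[s])
                      for s in profiles.columns}, name="tscore")


# ---------------------------------------------------------------------------
# Stratified log-rank (k groups)


def stratified_logrank(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    strata: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Stratified k-sample log-rank test.

    Observed-minus-expected event counts and their covariance are
    accumulated per stratum at each distinct event time and summed; the
    statistic is the quadratic form over the first k-1 groups, chi-squared
    with k-1 degrees of freedom.  With one stratum this is the ordinary
    multivariate log-rank test.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.unique(group)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    gidx = np.searchsorted(groups, group)
    if strata is None:
        strata = np.zeros(len(time), dtype=int)
    omE = np.zeros(k)
    V = np.zeros((k, k))
    for s in np.unique(strata):
        sel = strata == s
        t, e, g = time[sel], event[sel], gidx[sel]
        for tt in np.unique(t[e == 1]):
            at_risk = t >= tt
            n = at_risk.sum()
            d = int(((t == tt) & (e == 1)).sum())
            if n <= 1 or d == 0:
                continue
            n_j = np.bincount(g[at_risk], minlength=k).astype(float)
            d_j = np.bincount(g[(t == tt) & (e == 1)], minlength=k)
            frac = n_j / n
            omE += d_j - d * frac
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    sub = slice(0, k - 1)
    try:
        chi2 = float(omE[sub] @ np.linalg.solve(V[sub, sub], omE[sub]))
    except np.linalg.LinAlgError:
        chi2 = float(omE[sub] @ np.linalg.pinv(V[sub, sub]) @ omE[sub])
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


@dataclass
class SignatureSurvivalResult:
    logrank_chi2: float
    logrank_p: float
    cox_coef: Optional[float]
    cox_p: Optional[float]
    tertiles: pd.Series


def signature_survival(
    scores: pd.Series,
    surv: pd.DataFrame,
    strata: Optional[pd.Series] = None,
    cap_months: Optional[float] = None,
) -> SignatureSurvivalResult:
    """Outcome separation by signature score.

    Patients are split at the empirical 1/3 and 2/3 score quantiles into
    low/intermediate/high groups, tested by stratified log-rank; a
    stratified Cox on the continuous score is fitted alongside.  Tied
    scores that collapse a tertile boundary are an error.
    """
    scores = scores.reindex(surv.index).dropna()
    surv = surv.loc[scores.index]
    if strata is not None:
        strata = strata.reindex(scores.index)
    elif "stratum" in surv.columns:
        strata = surv["stratum"]
    if cap_months is not None:
        surv = cap_survival(surv, cap_months)
    q1, q2 = scores.quantile([1 / 3, 2 / 3])
    if q1 == q2:
        raise ValueError(
            f"tied scores collapse the tertile boundaries (1/3 and 2/3 "
            f"quantiles both {q1!r})")
    groups = pd.cut(scores, bins=[-np.inf, q1, q2, np.inf],
                    labels=["low", "intermediate", "high"])
    sizes = groups.value_counts()
    if (sizes < 3).any():
        raise ValueError(f"tertile group with < 3 patients: {dict(sizes)}")
    chi2, logrank_p = stratified_logrank(
        surv["time"].to_numpy(), surv["event"].to_numpy(),
        groups.to_numpy(),
        strata.to_numpy() if strata is not None else None)
    cox = cox_feature_survival(scores, surv, strata=strata,
                               feature_name="signature_score")
    return SignatureSurvivalResult(
        logrank_chi2=chi2, logrank_p=logrank_p,
        cox_coef=cox.coef, cox_p=cox.p_two_sided,
        tertiles=groups,
    )
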