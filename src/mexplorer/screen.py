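"""Genome-wide TF screening: per-TF LR tests, BY-FDR, ranking and scores.

Every TF with at least one non-baseline evidence level is tested
independently against the shared intercept-only null fit; raw LR p-values are
corrected with the Benjamini-Yekutieli step-up (valid under arbitrary
dependence among the tests) and TFs are ranked by ascending p with
lexicographic tie-breaking on the TF identifier.

Coefficient-derived summaries accompany each result: per-response-class
shares of positive coefficient mass (process/phase specificity) and the
symmetric per-evidence-level shares (which kind of evidence carried the
signal).  Composite scores combine two or more independent screens by
min-max-scaling -log10 p within each run to [0, 1] and summing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mnlogit import (
    LRTestResult,
    MultinomialFit,
    encode_predictor,
    fit_alternative,
    fit_null,
    lr_test,
)
from .regdata import ProcessResponse, RegulatoryMatrix

logger = logging.getLogger(__name__)

#: Floor applied to p-values before log-transformation in composite scoring.
P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} p_(j) * m * c(m) / j with the harmonic factor
    c(m) = sum_{u=1}^m 1/u, clamped to one; monotone in the input order
    statistics and valid under arbitrary dependence.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    cm = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m * cm / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (c(m) = 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Coefficient-derived summaries
# ---------------------------------------------------------------------------


def phase_specificity(fit: MultinomialFit) -> dict[str, float]:
    """Unit-scaled positive coefficient mass per response class.

    s_c = sum_k max(beta_{k,c}, 0) over slope rows; shares are s_c normalized
    to sum to one (all-zero if no coefficient is positive).  Positive slopes
    mark evidence levels over-represented in the class relative to baseline
    genes, so the shares read as the TF's relative activity across
    sub-processes.
    """
    slopes = fit.coef[1:, :]  # drop intercept row
    pos = np.clip(slopes, 0.0, None)
    s = pos.sum(axis=0)
    total = s.sum()
    shares = s / total if total > 0 else np.zeros_like(s)
    return dict(zip(fit.classes[:-1], shares.tolist()))


def evidence_contribution(fit: MultinomialFit) -> dict[str, float]:
    """Unit-scaled positive coefficient mass per evidence level (the
    transpose of :func:`phase_specificity`: s_k = sum_c max(beta_{k,c}, 0))."""
    slopes = fit.coef[1:, :]
    pos = np.clip(slopes, 0.0, None)
    s = pos.sum(axis=1)
    total = s.sum()
    shares = s / total if total > 0 else np.zeros_like(s)
    return dict(zip(fit.levels, shares.tolist()))


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


@dataclass
class TFTestResult:
    """Screening outcome for one TF."""

    tf: str
    K: int
    test: LRTestResult | None
    q: float | None = None
    rank: int | None = None
    significant: bool = False
    class_shares: dict[str, float] = field(default_factory=dict)
    evidence_shares: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def p(self) -> float | None:
        return self.test.p if self.test is not None else None

    @property
    def tested(self) -> bool:
        return self.test is not None


def run_screen(
    matrix: RegulatoryMatrix,
    response: ProcessResponse,
    alpha: float = 0.05,
    fit_method: str = "auto",
) -> list[TFTestResult]:
    """Screen every TF of the matrix against the process response.

    For each TF with K >= 1 evidence levels: encode the predictor, fit the
    alternative model, and LR-test it against the shared null fit (computed
    once — it depends only on the response).  BY correction runs over the
    tested TFs only; untested (K = 0) TFs are reported with a ``skipped-K0``
    flag and no p-value.  Results are sorted by ascending p then TF id, with
    untested TFs last, and ranks run 1..T.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    genes = response.genes
    if set(genes) != set(matrix.genes):
        raise ValueError("matrix and response must share a gene universe")

    null_fit = fit_null(response)
    results: list[TFTestResult] = []
    for tf in matrix.tfs:
        enc = encode_predictor(matrix, tf, genes)
        if enc.K == 0:
            results.append(TFTestResult(tf=tf, K=0, test=None, flags=["skipped-K0"]))
            continue
        alt = fit_alternative(response, enc, method=fit_method)
        test = lr_test(null_fit, alt)
        flags = []
        if alt.separated_levels:
            flags.append("separation:" + ",".join(alt.separated_levels))
        if not alt.converged:
            flags.append("non-convergence")
        results.append(
            TFTestResult(
                tf=tf,
                K=enc.K,
                test=test,
                class_shares=phase_specificity(alt),
                evidence_shares=evidence_contribution(alt),
                flags=flags,
            )
        )

    tested = [r for r in results if r.tested]
    untested = [r for r in results if not r.tested]
    if not tested:
        logger.warning("no testable TF in the matrix (all K=0)")
    else:
        qvals = by_adjust([r.test.p for r in tested])
        for r, q in zip(tested, qvals):
            r.q = float(q)
            r.significant = bool(q <= alpha)
    tested.sort(key=lambda r: (r.test.p, r.tf))
    untested.sort(key=lambda r: r.tf)
    ordered = tested + untested
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def screen_to_frame(results: list[TFTestResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per TF) for TSV serialization."""
    class_names: list[str] = []
    level_names: list[str] = []
    for r in results:
        for c in r.class_shares:
            if c not in class_names:
                class_names.append(c)
        for l in r.evidence_shares:
            if l not in level_names:
                level_names.append(l)
    rows = []
    for r in results:
        row: dict[str, object] = {
            "tf": r.tf,
            "rank": r.rank,
            "K": r.K,
            "statistic": r.test.statistic if r.tested else np.nan,
            "df": r.test.df if r.tested else np.nan,
            "p": r.test.p if r.tested else np.nan,
            "q": r.q if r.q is not None else np.nan,
            "significant": r.significant,
            "flags": ";".join(r.flags),
        }
        for c in class_names:
            row[f"share_class:{c}"] = r.class_shares.get(c, np.nan)
        for l in level_names:
            row[f"share_evidence:{l}"] = r.evidence_shares.get(l, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Composite scoring across runs
# ---------------------------------------------------------------------------


@dataclass
class CompositeScore:
    """Per-TF composite of unit-scaled -log10 p over several screens."""

    tf: str
    run_scores: list[float]
    composite: float


def _unit_scale_run(results: list[TFTestResult], scaling: str) -> dict[str, float]:
    tested = [r for r in results if r.tested]
    if not tested:
        return {}
    logs = {r.tf: -np.log10(max(r.test.p, P_FLOOR)) for r in tested}
    vals = np.array(list(logs.values()))
    lo, hi = vals.min(), vals.max()
    if len(tested) == 1:
        logger.warning("composite run with a single TF: score set to 1")
        return {tested[0].tf: 1.0}
    if scaling == "minmax":
        if hi == lo:
            return {tf: 1.0 for tf in logs}
        return {tf: (v - lo) / (hi - lo) for tf, v in logs.items()}
    if scaling == "maxdiv":
        if hi == 0:
            return {tf: 0.0 for tf in logs}
        return {tf: v / hi for tf, v in logs.items()}
    raise ValueError(f"unknown scaling {scaling!r}")


def composite_score(
    runs: list[list[TFTestResult]], scaling: str = "minmax"
) -> list[CompositeScore]:
    """Combine two or more independent screens into composite TF scores.

    Within each run, -log10 p (p floored at 1e-300) is scaled to [0, 1] over
    the TFs tested in that run; a TF absent from (or untested in) a run scores
    0 there.  The composite is the sum across runs, so it lies in [0, #runs].
    Output is sorted by descending composite, ties broken by TF id.
    """
    if len(runs) < 2:
        raise ValueError("composite scoring requires at least two runs")
    if any(not run for run in runs):
        raise ValueError("each run must be non-empty")
    per_run = [_unit_scale_run(run, scaling) for run in runs]
    tfs = sorted({tf for scores in per_run for tf in scores})
    out = []
    for tf in tfs:
        scores = [scores_r.get(tf, 0.0) for scores_r in per_run]
        out.append(CompositeScore(tf=tf, run_scores=scores, composite=sum(scores)))
    out.sort(key=lambda s: (-s.composite, s.tf))
    return out


def composite_to_frame(scores: list[CompositeScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"tf": s.tf}
        for i, v in enumerate(s.run_scores, start=1):
            row[f"score_run{i}"] = v
        row["composite"] = s.composite
        rows.append(row)
    return pd.DataFrame(rows)
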