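"""Evaluation protocol: AUC scoring, subsampling robustness, a Fisher's-test
baseline screen, and the shuffled-response false-positive check.

Rankings from the multinomial screen (and from the Fisher baseline, a
drop-in comparator on the same inputs) are scored against a gold-standard
set of positive TFs with the rank-based AUC: the probability that a positive
outranks a negative, with midranks for ties and untested TFs placed
tied-last so methods stay comparable on identical TF universes.  Robustness
repeats the screen on random gene subsets (e.g. 30/50/70/90% of the
universe) and reports mean AUC with a percentile confidence interval per
fraction.  The shuffle check permutes the response over genes (class sizes
preserved) and counts significant calls, which under a well-calibrated
screen should be near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import collapse_to_2x2, fisher_overlap
from .regdata import ProcessResponse, RegulatoryMatrix
from .screen import TFTestResult, by_adjust, run_screen
from .synthdata import GoldStandard

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def auc_from_scores(scores: dict[str, float], gold: GoldStandard) -> float:
    """Rank-based AUC of scores (higher = better) against the gold standard.

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg, with
    midranks for ties.  TFs of the gold universe missing from ``scores`` are
    assigned -inf (tied last).
    """
    universe = gold.universe
    positives = gold.positives
    n_pos = len(positives)
    n_neg = len(universe) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gold standard must have both positives and negatives")
    vals = np.array([scores.get(tf, -np.inf) for tf in universe])
    ranks = stats.rankdata(vals)  # ascending, midranks for ties
    is_pos = np.array([tf in positives for tf in universe])
    r_pos = ranks[is_pos].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc(ranking, gold: GoldStandard) -> float:
    """AUC of a ranking (best-first sequence of TF ids, or {tf: score} with
    higher = better) against the gold standard."""
    if isinstance(ranking, dict):
        return auc_from_scores(ranking, gold)
    ranking = list(ranking)
    scores = {tf: -i for i, tf in enumerate(ranking)}
    return auc_from_scores(scores, gold)


def screen_scores(results: list[TFTestResult]) -> dict[str, float]:
    """Convert screen results to AUC-ready scores: -log p for tested TFs;
    untested TFs omitted (ranked tied-last by :func:`auc_from_scores`)."""
    out = {}
    for r in results:
        if r.tested:
            out[r.tf] = -np.log(max(r.test.p, 1e-300))
    return out


# ---------------------------------------------------------------------------
# Fisher baseline screen
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    tf: str
    table_counts: tuple[int, int, int, int]
    p: float
    q: float | None = None
    rank: int | None = None
    significant: bool = False


def fisher_baseline_screen(
    matrix: RegulatoryMatrix,
    response: ProcessResponse,
    alpha: float = 0.05,
) -> list[FisherResult]:
    """Per-TF one-sided Fisher's exact test on the 2x2 collapse, BY-adjusted.

    The standard frequency-table comparator: all evidence levels merge into
    'target', all process classes into 'process'.  TFs with no targets are
    untested (no p), mirroring the multinomial screen's K=0 handling.
    """
    results: list[FisherResult] = []
    untested: list[FisherResult] = []
    for tf in matrix.tfs:
        table = collapse_to_2x2(matrix, tf, response)
        counts = (table.g_CT, table.g_Ct, table.g_cT, table.g_ct)
        if table.g_CT + table.g_cT == 0:  # no targets at all
            untested.append(FisherResult(tf=tf, table_counts=counts, p=np.nan))
            continue
        p = fisher_overlap(table, sided="greater")
        results.append(FisherResult(tf=tf, table_counts=counts, p=p))
    if results:
        qvals = by_adjust([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
            r.significant = bool(q <= alpha)
    results.sort(key=lambda r: (r.p, r.tf))
    untested.sort(key=lambda r: r.tf)
    ordered = results + untested
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def fisher_scores(results: list[FisherResult]) -> dict[str, float]:
    return {
        r.tf: -np.log(max(r.p, 1e-300)) for r in results if np.isfinite(r.p)
    }


# ---------------------------------------------------------------------------
# Subsampling robustness
# ---------------------------------------------------------------------------


@dataclass
class RobustnessCurve:
    """Mean AUC and percentile 95% CI per retained-gene fraction."""

    fractions: list[float]
    mean_auc: list[float]
    ci_low: list[float]
    ci_high: list[float]
    reps: int
    aucs: dict[float, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "mean_auc": self.mean_auc,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "reps": self.reps,
            }
        )


def _subsample_genes(
    rng: np.random.Generator,
    response: ProcessResponse,
    n_keep: int,
    max_attempts: int = 100,
) -> list[str]:
    """Random gene subset keeping every response class non-empty."""
    genes = response.genes
    for _ in range(max_attempts):
        idx = rng.choice(len(genes), size=n_keep, replace=False)
        subset = [genes[i] for i in idx]
        counts = response.assignment.loc[subset].value_counts()
        if all(counts.get(cls, 0) > 0 for cls in response.classes):
            return subset
    raise RuntimeError(
        f"could not draw a subset of {n_keep} genes covering all response "
        f"classes in {max_attempts} attempts"
    )


def robustness(
    matrix: RegulatoryMatrix,
    response: ProcessResponse,
    gold: GoldStandard,
    fractions=(0.3, 0.5, 0.7, 0.9),
    reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> RobustnessCurve:
    """Gene-subsampling robustness curve of the multinomial screen.

    Per fraction, draws ``reps`` gene subsets without replacement (resampling
    subsets that empty a response class), reruns the screen on each, and
    scores the resulting ranking against the gold standard.  Fraction 1.0 is
    deterministic (no subsampling).
    """
    if reps < 2:
        raise ValueError("need at least two replicates per fraction")
    rng = np.random.default_rng(seed)
    genes = response.genes
    fractions = sorted(fractions)
    aucs: dict[float, np.ndarray] = {}
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"fraction {frac} outside (0, 1]")
        vals = np.empty(reps)
        for rep in range(reps):
            if frac == 1.0:
                subset = genes
            else:
                n_keep = max(len(response.classes), int(round(frac * len(genes))))
                subset = _subsample_genes(rng, response, n_keep)
            sub_matrix = matrix.subset_genes(subset)
            sub_response = response.subset_genes(subset)
            results = run_screen(sub_matrix, sub_response, alpha=alpha)
            vals[rep] = auc_from_scores(screen_scores(results), gold)
        aucs[frac] = vals
    mean = [float(aucs[f].mean()) for f in fractions]
    lo = [float(np.percentile(aucs[f], 2.5)) for f in fractions]
    hi = [float(np.percentile(aucs[f], 97.5)) for f in fractions]
    return RobustnessCurve(
        fractions=list(fractions), mean_auc=mean, ci_low=lo, ci_high=hi,
        reps=reps, aucs=aucs,
    )


# ---------------------------------------------------------------------------
# Shuffled-response false-positive check
# ---------------------------------------------------------------------------


def shuffle_fp(
    matrix: RegulatoryMatrix,
    response: ProcessResponse,
    reps: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permute the response over genes and count significant calls.

    Class sizes are preserved under every permutation.  Returns one row per
    replicate with the number of q <= alpha calls from the multinomial screen
    and from the Fisher baseline on the same shuffled response.
    """
    rng = np.random.default_rng(seed)
    genes = response.genes
    values = response.assignment.to_numpy()
    rows = []
    for rep in range(reps):
        shuffled = pd.Series(rng.permutation(values), index=genes)
        sh_response = ProcessResponse(
            list(response.classes), shuffled, response.baseline
        )
        mn = run_screen(matrix, sh_response, alpha=alpha)
        fb = fisher_baseline_screen(matrix, sh_response, alpha=alpha)
        rows.append(
            {
                "replicate": rep,
                "fp_mexplorer": sum(r.significant for r in mn),
                "fp_fisher": sum(r.significant for r in fb),
            }
        )
    return pd.DataFrame(rows)
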