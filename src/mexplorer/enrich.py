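"""Overlap and functional-enrichment statistics.

Three companion statistics used around the TF screen:

* Fisher's exact test on 2x2 collapses of the regulatory matrix and the
  process response — one-sided (enrichment) by default, reading the upper
  hypergeometric tail at fixed margins.
* Ordered (ranked-list) hypergeometric enrichment: for a list ranked
  strongest-first, each functional category is tested at every prefix length
  and the minimum upper-tail hypergeometric p over prefixes is reported, with
  redundancy pruning of categories that are subsets of other categories.
  The prefix scan is not corrected for internally, so the reported minimum is
  anti-conservative by construction; BH-FDR runs across categories.
* Direction counting of up-/down-regulated (gene, strain) pairs per category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regdata import BASELINE_LABEL, ProcessResponse, RegulatoryMatrix
from .screen import bh_adjust, by_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher's exact overlap test
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """2x2 gene counts: rows process membership (C/c), columns TF-target
    status (T/t); n = g_CT + g_Ct + g_cT + g_ct genes in total."""

    g_CT: int
    g_Ct: int
    g_cT: int
    g_ct: int

    def __post_init__(self) -> None:
        for v in (self.g_CT, self.g_Ct, self.g_cT, self.g_ct):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.g_CT + self.g_Ct + self.g_cT + self.g_ct


def fisher_overlap(table: ContingencyTable, sided: str = "greater") -> float:
    """Fisher's exact test of a 2x2 overlap.

    With margins fixed, the count in the top-left cell is hypergeometric;
    ``sided='greater'`` (default, enrichment) returns the upper tail
    P(X >= g_CT).  ``sided='two-sided'`` sums all configurations at least as
    improbable as the observed one.
    """
    a, b, c, d = table.g_CT, table.g_Ct, table.g_cT, table.g_ct
    if sided == "greater":
        # upper tail of Hypergeom(N=n, K=row1 total, n=col1 total) at a
        return float(stats.hypergeom.sf(a - 1, table.n, a + b, a + c))
    if sided == "two-sided":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(p)
    raise ValueError(f"unknown sidedness {sided!r}")


def collapse_to_2x2(
    matrix: RegulatoryMatrix, tf: str, response: ProcessResponse
) -> ContingencyTable:
    """Collapse a TF column and the response to a 2x2 table.

    Rows: gene in any process class vs baseline; columns: any-evidence TF
    target vs ``not_regulated``.  All multi-level structure is merged, which
    is what makes a plain Fisher's test applicable.
    """
    col = matrix.column(tf).loc[response.genes]
    is_target = (col != BASELINE_LABEL).to_numpy()
    in_process = (response.assignment != response.baseline).to_numpy()
    g_CT = int(np.sum(in_process & is_target))
    g_Ct = int(np.sum(in_process & ~is_target))
    g_cT = int(np.sum(~in_process & is_target))
    g_ct = int(np.sum(~in_process & ~is_target))
    return ContingencyTable(g_CT, g_Ct, g_cT, g_ct)


# ---------------------------------------------------------------------------
# Ordered hypergeometric enrichment
# ---------------------------------------------------------------------------


@dataclass
class RankedGeneList:
    """Genes ordered strongest-signal-first.

    ``scores`` are the per-gene ordering scores (e.g. products of
    differential-expression p-values): smaller = stronger, so they are
    non-decreasing along the list.  Ties are broken lexicographically.
    """

    genes: list[str]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if self.scores is not None:
            if len(self.scores) != len(self.genes):
                raise ValueError("scores and genes differ in length")
            arr = np.asarray(self.scores, dtype=float)
            if np.any(np.diff(arr) < 0):
                raise ValueError("scores must be non-decreasing in rank order")

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedGeneList":
        """Rank genes ascending by score (smallest = strongest = first),
        ties broken lexicographically."""
        items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
        return cls([g for g, _ in items], [s for _, s in items])


@dataclass
class CategoryResult:
    """Ordered-enrichment outcome for one functional category."""

    category: str
    best_prefix: int
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float | None = None
    significant: bool = False
    n_up: int = 0
    n_down: int = 0


def _min_prefix_p(hits: np.ndarray, N: int, K: int) -> tuple[float, int, int]:
    """Minimum over prefix lengths n of P(X >= k_n), X ~ Hypergeom(N, K, n).

    Returns (p, best n, hits in best prefix); among ties the shortest prefix
    wins.
    """
    L = hits.size
    k_cum = np.cumsum(hits)
    ns = np.arange(1, L + 1)
    pvals = stats.hypergeom.sf(k_cum - 1, N, K, ns)
    best = int(np.argmin(pvals))
    return float(pvals[best]), int(ns[best]), int(k_cum[best])


def ordered_enrichment(
    ranked: RankedGeneList,
    categories: Mapping[str, Iterable[str]],
    universe_size: int,
    alpha: float = 0.05,
    fdr: str = "bh",
    prune: bool = True,
    direction_calls: Mapping[str, Mapping[str, str]] | None = None,
) -> list[CategoryResult]:
    """Ordered hypergeometric enrichment of categories in a ranked list.

    For each category (intersected with the implicit universe of size
    ``universe_size``), the upper-tail hypergeometric p-value is evaluated at
    every prefix of the ranked list and the minimum is reported together with
    the prefix at which it is attained.  Categories with zero universe
    overlap are skipped with a note.  BH-FDR (or BY via ``fdr='by'``) is
    applied across categories; redundant categories whose gene set is a
    subset of another category's are pruned before correction.
    """
    N = int(universe_size)
    if N < len(ranked.genes):
        raise ValueError("universe smaller than the ranked list")
    listed = ranked.genes
    cat_sets = {name: set(members) for name, members in categories.items()}
    if prune:
        cat_sets = prune_redundant_sets(cat_sets)
    results: list[CategoryResult] = []
    for name in sorted(cat_sets):
        members = cat_sets[name]
        K = len(members)
        if K == 0:
            logger.info("category %s has zero universe overlap; skipped", name)
            continue
        hits = np.fromiter((g in members for g in listed), dtype=bool, count=len(listed))
        p, best_n, k = _min_prefix_p(hits.astype(np.int64), N, K)
        n_up = n_down = 0
        if direction_calls is not None:
            n_up, n_down = direction_counts(members, direction_calls)
        results.append(
            CategoryResult(
                category=name, best_prefix=best_n, k=k, K=K, n=best_n, N=N,
                p=p, n_up=n_up, n_down=n_down,
            )
        )
    if results:
        adjust = bh_adjust if fdr == "bh" else by_adjust
        qvals = adjust([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
            r.significant = bool(q <= alpha)
    results.sort(key=lambda r: (r.p, r.category))
    return results


def prune_redundant_sets(
    categories: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Drop categories whose gene set is a subset of another category's.

    Among identical sets the lexicographically smaller id is kept.  The
    retained collection is an antichain: no kept set is a subset of another
    kept set.
    """
    order = sorted(categories, key=lambda name: (-len(categories[name]), name))
    kept: dict[str, set[str]] = {}
    for name in order:
        s = categories[name]
        if any(s <= other for other in kept.values()):
            continue
        kept[name] = s
    return kept


def prune_redundant(
    results: Sequence[CategoryResult], categories: Mapping[str, Iterable[str]]
) -> list[CategoryResult]:
    """Filter a result list to the non-redundant categories (see
    :func:`prune_redundant_sets`)."""
    kept = prune_redundant_sets(
        {r.category: set(categories[r.category]) for r in results}
    )
    return [r for r in results if r.category in kept]


def direction_counts(
    category_genes: Iterable[str],
    calls: Mapping[str, Mapping[str, str]],
) -> tuple[int, int]:
    """Count up-/down-regulated (gene, strain) pairs within a category.

    ``calls`` maps strain -> gene -> {'up', 'down'}; a gene with no call in a
    strain contributes nothing.
    """
    members = set(category_genes)
    n_up = n_down = 0
    for strain_calls in calls.values():
        for gene, call in strain_calls.items():
            if gene not in members:
                continue
            if call == "up":
                n_up += 1
            elif call == "down":
                n_down += 1
    return n_up, n_down


def enrichment_to_frame(results: Sequence[CategoryResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "best_prefix": r.best_prefix,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
                "n_up": r.n_up,
                "n_down": r.n_down,
            }
            for r in results
        ]
    )
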