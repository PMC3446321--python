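"""Synthetic regulatory matrices, process lists and viability tables.

The generator emulates the structure of the compiled yeast regulator dataset:
a sparse gene x TF grid where roughly 7% of cells carry non-baseline
evidence, evidence-class mass dominated by expression-only calls (84%) with
composite expression+binding classes rare (1.5%) and the remainder
binding-only; a multi-class process response shaped like the six cell-cycle
phase/checkpoint lists over a genome-scale universe; and a planted subset of
TFs whose targets are enriched inside designated process classes by a known
odds multiplier.  Planted TFs are the ground truth for benchmarking the
screen.

Viability tables mirror the quiescence time-course design: eight time-points,
triplicate measurements, two independent batches with tested strains split
between batches and wildtype/negative-control strains covered in both,
log-normal noise around a declining batch-specific wildtype trajectory, and
optional planted fold changes per strain and time-point.

All draws flow from a single integer seed through one generator, so every
fixture is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regdata import (
    BASELINE_CLASS,
    BASELINE_LABEL,
    EVIDENCE_CLASSES,
    ProcessResponse,
    RegulatoryMatrix,
)

logger = logging.getLogger(__name__)

#: Evidence-class mixture over the eight non-baseline classes, proportioned
#: to the yeast dataset: 84% expression-only mass (split evenly up/down),
#: 1.5% composite evidence, the remaining 14.5% binding-only.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "up": 0.42,
    "down": 0.42,
    "TFBS": 0.085,
    "NDTFBS": 0.06,
    "up+TFBS": 0.00375,
    "down+TFBS": 0.00375,
    "up+NDTFBS": 0.00375,
    "down+NDTFBS": 0.00375,
}

#: Process-class sizes for the default benchmark: six cell-cycle-like
#: phase/checkpoint classes, ~9.6% of a 2000-gene universe in total
#: (the yeast analysis assigns 600 of 6253 genes to six classes of 41-257).
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "G1": 82,
    "S": 30,
    "G2": 13,
    "G2/M": 19,
    "M": 30,
    "M/G1": 18,
}


@dataclass
class GeneratorSpec:
    """Parameters of the planted-TF benchmark generator."""

    n_genes: int = 2000
    n_tfs: int = 100
    n_planted: int = 5
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    sparsity: float = 0.07
    odds: float = 8.0
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    seed: int = 42

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_tfs < 1:
            raise ValueError("n_genes and n_tfs must be positive")
        if not (0 <= self.n_planted <= self.n_tfs):
            raise ValueError("n_planted must lie in [0, n_tfs]")
        total = sum(self.class_sizes.values())
        if total >= self.n_genes:
            raise ValueError(
                f"process class sizes sum to {total} >= n_genes {self.n_genes}: "
                "baseline class would be empty"
            )
        if any(s < 1 for s in self.class_sizes.values()):
            raise ValueError("every process class needs at least one gene")
        if not (0.0 < self.sparsity < 1.0):
            raise ValueError("sparsity must lie in (0, 1)")
        if self.odds < 1.0:
            raise ValueError("enrichment odds multiplier must be >= 1")
        w = np.array(list(self.class_weights.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("class weights must be non-negative and sum to 1")
        unknown = set(self.class_weights) - set(EVIDENCE_CLASSES[1:])
        if unknown:
            raise ValueError(f"unknown evidence class in weights: {sorted(unknown)}")
        if self.sparsity * self.odds >= 1.0:
            raise ValueError("sparsity * odds must stay below 1")


@dataclass
class GoldStandard:
    """Positive TF set against which rankings are scored."""

    positives: set[str]
    universe: list[str]

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValueError("gold standard needs at least one positive")
        if not self.positives < set(self.universe):
            raise ValueError("positives must be a proper subset of the TF universe")


def gen_benchmark(
    spec: GeneratorSpec | None = None,
) -> tuple[RegulatoryMatrix, ProcessResponse, GoldStandard]:
    """Generate a planted-TF benchmark instance.

    Background TFs draw non-baseline targets uniformly at random at the
    spec's sparsity; planted TFs multiply that probability by the enrichment
    odds inside their designated process classes (classes assigned round-robin,
    two per planted TF).  The evidence class of each non-baseline cell is an
    independent draw from the class-weight mixture.  Fully determined by the
    spec seed.
    """
    spec = spec or GeneratorSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    tfs = [f"tf{i:03d}" for i in range(spec.n_tfs)]
    planted = sorted(rng.choice(spec.n_tfs, size=spec.n_planted, replace=False))
    planted_tfs = [tfs[i] for i in planted]

    # response: contiguous blocks over a shuffled gene order
    perm = rng.permutation(spec.n_genes)
    assignment = pd.Series(BASELINE_CLASS, index=genes, dtype=object)
    class_names = list(spec.class_sizes)
    pos = 0
    class_members: dict[str, np.ndarray] = {}
    for cls in class_names:
        size = spec.class_sizes[cls]
        idx = perm[pos : pos + size]
        class_members[cls] = idx
        assignment.iloc[idx] = cls
        pos += size
    response = ProcessResponse(class_names + [BASELINE_CLASS], assignment)

    class_codes = assignment.map(
        {cls: i for i, cls in enumerate(class_names + [BASELINE_CLASS])}
    ).to_numpy()

    labels = np.array(list(spec.class_weights), dtype=object)
    weights = np.array(list(spec.class_weights.values()), dtype=float)
    weights = weights / weights.sum()

    n_classes = len(class_names)
    cells = np.full((spec.n_genes, spec.n_tfs), BASELINE_LABEL, dtype=object)
    for j, tf in enumerate(tfs):
        prob = np.full(spec.n_genes, spec.sparsity)
        if tf in planted_tfs:
            rank = planted_tfs.index(tf)
            target_classes = {
                (2 * rank) % n_classes,
                (2 * rank + 1) % n_classes,
            }
            in_target = np.isin(class_codes, list(target_classes))
            prob[in_target] = np.minimum(spec.sparsity * spec.odds, 0.99)
        hit = rng.random(spec.n_genes) < prob
        n_hit = int(hit.sum())
        if n_hit:
            cells[hit, j] = rng.choice(labels, size=n_hit, p=weights)

    matrix = RegulatoryMatrix(pd.DataFrame(cells, index=genes, columns=tfs))
    gold = GoldStandard(set(planted_tfs), tfs)
    return matrix, response, gold


# ---------------------------------------------------------------------------
# Viability tables
# ---------------------------------------------------------------------------

#: Quiescence time-course sampling days: 7 h and 48 h after inoculation,
#: then six weekly measurements.
DEFAULT_DAYS: tuple[float, ...] = (0.3, 2.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0)


def gen_viability(
    n_tested: int = 13,
    n_wildtype: int = 2,
    n_controls: int = 2,
    days: Sequence[float] = DEFAULT_DAYS,
    replicates: int = 3,
    batches: int = 2,
    planted: Mapping[str, Mapping[float, float]] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic strain-viability time-course table.

    Viability declines along a batch-specific wildtype trajectory (starting
    near 0.9 in exponential growth and decaying through the time-course) with
    log-normal replicate noise of the given log-scale SD (0.2 ~ 20% of the
    mean).  Tested strains are split between batches; wildtype and
    negative-control strains appear in every batch.  ``planted`` maps strain
    -> day -> fold change multiplied onto that strain's mean viability.
    """
    if replicates < 2:
        raise ValueError("need at least two replicates")
    if batches < 1:
        raise ValueError("need at least one batch")
    rng = np.random.default_rng(seed)
    planted = planted or {}

    strains = (
        [(f"strain{i:02d}", "tested") for i in range(1, n_tested + 1)]
        + [(f"wt{i}", "wildtype") for i in range(1, n_wildtype + 1)]
        + [(f"ctrl{i}", "negative_control") for i in range(1, n_controls + 1)]
    )
    days = list(days)
    # declining trajectory on [0, max(day)]; half-life ~3 weeks in G0
    base = {d: 0.9 * np.exp(-max(d - 2.0, 0.0) / 25.0) for d in days}
    batch_shift = rng.normal(0.0, 0.1, size=batches)  # batch effect on log scale

    rows = []
    for s_idx, (strain, role) in enumerate(strains):
        if role == "tested":
            strain_batches = [s_idx % batches + 1]
        else:
            strain_batches = list(range(1, batches + 1))
        for b in strain_batches:
            for d in days:
                mean = base[d]
                fold = planted.get(strain, {}).get(d, 1.0)
                log_mean = np.log(mean * fold) + batch_shift[b - 1]
                noise = rng.normal(0.0, noise_sd, size=replicates)
                for r in range(1, replicates + 1):
                    rows.append(
                        {
                            "strain": strain,
                            "role": role,
                            "batch": b,
                            "replicate": r,
                            "day": d,
                            "viability": float(np.exp(log_mean + noise[r - 1])),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Functional categories
# ---------------------------------------------------------------------------


def gen_categories(
    universe: Sequence[str],
    n_categories: int = 20,
    size_range: tuple[int, int] = (10, 60),
    ranked_head: Sequence[str] | None = None,
    planted_overlap: float = 0.8,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Generate random functional gene sets, optionally with one planted
    top-heavy category.

    Random categories draw members uniformly from the universe.  If
    ``ranked_head`` is given, category ``planted`` draws ``planted_overlap``
    of its members from that head (the top of a ranked list) and the rest at
    random, so ordered enrichment should flag it.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size range")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    cats: dict[str, list[str]] = {}
    for i in range(1, n_categories + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        cats[f"cat{i:03d}"] = sorted(universe[j] for j in members)
    if ranked_head is not None:
        head = list(ranked_head)
        size = min(max(lo, len(head)), hi)
        n_head = max(1, int(round(planted_overlap * size)))
        n_head = min(n_head, len(head))
        picked = list(rng.choice(head, size=n_head, replace=False))
        rest_pool = [g for g in universe if g not in set(picked)]
        n_rest = size - n_head
        if n_rest > 0:
            picked += list(rng.choice(rest_pool, size=n_rest, replace=False))
        cats["planted"] = sorted(picked)
    return cats
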