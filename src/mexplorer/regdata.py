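"""Discretized regulatory-evidence matrices and multi-class process responses.

A regulatory matrix records, for every (gene, TF) pair, one of nine categorical
evidence classes describing how the TF is thought to regulate the gene:
expression response in the TF deletion strain (``up`` / ``down``), a binding
site in the gene's promoter (``TFBS``), a binding site in nucleosome-depleted
open chromatin (``NDTFBS``), the four pairwise combinations of an expression
call with a binding call, or the baseline ``not_regulated``.

The process response partitions the gene universe into named sub-process
classes (for example cell-cycle phases) plus a baseline class of all remaining
genes.  Both structures feed the multinomial regression screen in
:mod:`mexplorer.mnlogit` and :mod:`mexplorer.screen`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Evidence vocabulary
# ---------------------------------------------------------------------------

BASELINE_LABEL = "not_regulated"

#: Closed vocabulary of evidence classes; downstream code indexes this tuple
#: rather than parsing label strings.
EVIDENCE_CLASSES: tuple[str, ...] = (
    BASELINE_LABEL,
    "up",
    "down",
    "TFBS",
    "NDTFBS",
    "up+TFBS",
    "down+TFBS",
    "up+NDTFBS",
    "down+NDTFBS",
)

_EVIDENCE_SET = frozenset(EVIDENCE_CLASSES)

#: Default name of the response baseline class (genes in no process list).
BASELINE_CLASS = "baseline"


def validate_evidence_label(label: str) -> str:
    """Return *label* if it belongs to the closed evidence vocabulary."""
    if label not in _EVIDENCE_SET:
        raise ValueError(
            f"unknown evidence class {label!r}; admissible labels are "
            f"{sorted(_EVIDENCE_SET)}"
        )
    return label


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryMatrix:
    """Gene x TF grid of categorical evidence classes.

    Stored as a :class:`pandas.DataFrame` with gene identifiers as the index,
    TF identifiers as columns and evidence-class labels as cell values.  The
    matrix is logically complete: every cell carries exactly one label, and an
    absent cell in serialized form means ``not_regulated``.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.cells
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate TF identifier {dup!r}")
        for tf in df.columns:
            bad = set(df[tf].unique()) - _EVIDENCE_SET
            if bad:
                raise ValueError(
                    f"unknown evidence class {sorted(bad)[0]!r} in column {tf!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def tfs(self) -> list[str]:
        return list(self.cells.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def column(self, tf: str) -> pd.Series:
        if tf not in self.cells.columns:
            raise KeyError(f"TF {tf!r} not in matrix")
        return self.cells[tf]

    def sparsity(self) -> float:
        """Fraction of cells that carry non-baseline evidence."""
        total = self.cells.size
        nonbase = int((self.cells.to_numpy() != BASELINE_LABEL).sum())
        return nonbase / total if total else 0.0

    def subset_genes(self, genes: Sequence[str]) -> "RegulatoryMatrix":
        return RegulatoryMatrix(self.cells.loc[list(genes)])


@dataclass
class ProcessResponse:
    """Per-gene process class labels with an explicit baseline class.

    ``classes`` lists the sub-process names followed by the baseline class;
    ``assignment`` maps every gene of the universe to exactly one class.
    """

    classes: list[str]
    assignment: pd.Series
    baseline: str = BASELINE_CLASS

    def __post_init__(self) -> None:
        if self.baseline not in self.classes:
            raise ValueError("baseline class missing from class list")
        counts = self.assignment.value_counts()
        for cls in self.classes:
            if counts.get(cls, 0) == 0:
                raise ValueError(f"response class {cls!r} is empty")
        extra = set(self.assignment.unique()) - set(self.classes)
        if extra:
            raise ValueError(f"assignment uses undeclared class {sorted(extra)[0]!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.assignment.index)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_counts(self) -> pd.Series:
        return self.assignment.value_counts().reindex(self.classes)

    def codes(self) -> np.ndarray:
        """Integer codes 0..C-1 in class order (baseline last if declared last)."""
        mapping = {cls: i for i, cls in enumerate(self.classes)}
        return self.assignment.map(mapping).to_numpy(dtype=np.int64)

    def subset_genes(self, genes: Sequence[str]) -> "ProcessResponse":
        sub = self.assignment.loc[list(genes)]
        return ProcessResponse(list(self.classes), sub, self.baseline)


@dataclass
class OccupancyProfile:
    """Normalized nucleosome-occupancy observations at one (gene, TF) site set."""

    gene: str
    tf: str
    occupancy: np.ndarray
    genome_mean: float

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if not np.all(np.isfinite(self.occupancy)):
            raise ValueError(
                f"non-finite occupancy for site ({self.gene}, {self.tf})"
            )
        if not np.isfinite(self.genome_mean):
            raise ValueError("genome_mean must be finite")


@dataclass
class DepletionCall:
    """Outcome of the nucleosome-depletion test for one site."""

    gene: str
    tf: str
    depleted: bool
    p: float
    q: float
    warning: str | None = None


# ---------------------------------------------------------------------------
# Nucleosome-depletion classification
# ---------------------------------------------------------------------------


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def _lower_tail_t_p(obs: np.ndarray, genome_mean: float) -> float:
    """One-sided (lower-tail) one-sample t-test p-value of obs against genome_mean."""
    obs = np.asarray(obs, dtype=float)
    sd = obs.std(ddof=1)
    if sd == 0.0:
        mean = obs.mean()
        if mean == genome_mean:
            return 0.5
        return 0.0 if mean < genome_mean else 1.0
    res = stats.ttest_1samp(obs, genome_mean, alternative="less")
    return float(res.pvalue)


def classify_ndtfbs(
    sites: Sequence[OccupancyProfile], alpha: float = 0.05
) -> dict[tuple[str, str], DepletionCall]:
    """Classify binding sites as nucleosome-depleted (NDTFBS) or not.

    Each site's occupancy observations are tested against the genome-wide
    average with a one-sided lower-tail one-sample t-test; p-values are
    FDR-adjusted (Benjamini-Hochberg) across all testable sites, and a site is
    called depleted when its adjusted p-value is at most ``alpha``.

    Sites with fewer than two observations cannot be tested; they are returned
    ``not_depleted`` with a warning record rather than raising.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    testable: list[OccupancyProfile] = []
    calls: dict[tuple[str, str], DepletionCall] = {}
    for site in sites:
        key = (site.gene, site.tf)
        if site.occupancy.size < 2:
            msg = f"site {key} has <2 occupancy observations; left not_depleted"
            logger.warning(msg)
            calls[key] = DepletionCall(site.gene, site.tf, False, np.nan, np.nan, msg)
        else:
            testable.append(site)
    if testable:
        pvals = np.array(
            [_lower_tail_t_p(s.occupancy, s.genome_mean) for s in testable]
        )
        qvals = _bh_adjust(pvals)
        for site, p, q in zip(testable, pvals, qvals):
            calls[(site.gene, site.tf)] = DepletionCall(
                site.gene, site.tf, bool(q <= alpha), float(p), float(q)
            )
    return calls


# ---------------------------------------------------------------------------
# Evidence merging
# ---------------------------------------------------------------------------


def merge_evidence(
    genes: Sequence[str],
    up: Mapping[str, Iterable[str]],
    down: Mapping[str, Iterable[str]],
    bound: Mapping[str, Iterable[str]],
    depleted: Mapping[str, Iterable[str]] | None = None,
) -> RegulatoryMatrix:
    """Merge per-TF expression, binding and depletion calls into a matrix.

    Parameters
    ----------
    genes:
        Ordered gene universe (matrix rows).
    up, down:
        Per-TF sets of genes with significant up-/down-regulation in the TF
        deletion strain.
    bound:
        Per-TF sets of genes whose promoter carries at least one binding site.
    depleted:
        Per-TF sets of bound genes whose sites are nucleosome-depleted; must
        be a subset of ``bound`` for each TF.

    The cell class is the exact cross-product of the three calls, e.g.
    (up, bound, depleted) -> ``up+NDTFBS`` and (none, none, none) ->
    ``not_regulated``.  A gene called both up and down for one TF is a
    contradictory input and is rejected.
    """
    depleted = depleted or {}
    tfs = sorted(set(up) | set(down) | set(bound) | set(depleted))
    universe = list(genes)
    gene_set = set(universe)
    if len(gene_set) != len(universe):
        raise ValueError("duplicate gene identifiers in universe")

    data: dict[str, pd.Series] = {}
    for tf in tfs:
        up_g = set(up.get(tf, ()))
        down_g = set(down.get(tf, ()))
        bound_g = set(bound.get(tf, ()))
        depl_g = set(depleted.get(tf, ()))
        clash = up_g & down_g
        if clash:
            raise ValueError(
                f"gene {sorted(clash)[0]!r} called both up and down for TF {tf!r}"
            )
        stray = depl_g - bound_g
        if stray:
            raise ValueError(
                f"gene {sorted(stray)[0]!r} depleted but not bound for TF {tf!r}"
            )
        for name, group in (("up", up_g), ("down", down_g), ("bound", bound_g)):
            outside = group - gene_set
            if outside:
                raise ValueError(
                    f"{name} gene {sorted(outside)[0]!r} for TF {tf!r} "
                    "absent from universe"
                )
        col = pd.Series(BASELINE_LABEL, index=universe, dtype=object)
        for g in bound_g:
            col[g] = "NDTFBS" if g in depl_g else "TFBS"
        for g in up_g:
            if g in bound_g:
                col[g] = "up+NDTFBS" if g in depl_g else "up+TFBS"
            else:
                col[g] = "up"
        for g in down_g:
            if g in bound_g:
                col[g] = "down+NDTFBS" if g in depl_g else "down+TFBS"
            else:
                col[g] = "down"
        data[tf] = col
    frame = pd.DataFrame(data, index=universe)
    return RegulatoryMatrix(frame)


# ---------------------------------------------------------------------------
# Process response construction
# ---------------------------------------------------------------------------


def build_response(
    lists: Mapping[str, Iterable[str]],
    universe: Sequence[str],
    overlap_policy: str = "error",
    baseline: str = BASELINE_CLASS,
) -> ProcessResponse:
    """Assemble a multi-class process response over a gene universe.

    Genes in exactly one named list receive that class; genes in no list fall
    into the baseline class; genes present in several lists are rejected
    (``overlap_policy='error'``) or assigned to the first-declared class
    (``overlap_policy='priority_order'``).  Listed genes absent from the
    universe are dropped with a logged count — the model cannot use genes that
    have no evidence row.
    """
    if overlap_policy not in ("error", "priority_order"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    if not lists:
        raise ValueError("at least one process gene list is required")
    if baseline in lists:
        raise ValueError(f"class name {baseline!r} is reserved for the baseline")
    universe = list(universe)
    gene_set = set(universe)

    assignment = pd.Series(baseline, index=universe, dtype=object)
    seen: dict[str, str] = {}
    dropped = 0
    for cls, members in lists.items():
        members = list(members)
        inside = [g for g in members if g in gene_set]
        dropped += len(members) - len(inside)
        if not inside:
            raise ValueError(
                f"process class {cls!r} is empty after intersection with the universe"
            )
        for g in inside:
            if g in seen:
                if overlap_policy == "error":
                    raise ValueError(
                        f"gene {g!r} appears in classes {seen[g]!r} and {cls!r}"
                    )
                continue  # priority_order: first-declared class wins
            seen[g] = cls
            assignment[g] = cls
    if dropped:
        logger.info("dropped %d listed genes absent from the matrix universe", dropped)
    if (assignment == baseline).sum() == 0:
        raise ValueError("baseline class is empty: process lists cover the universe")
    classes = list(lists.keys()) + [baseline]
    return ProcessResponse(classes, assignment, baseline)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> RegulatoryMatrix:
    """Read a regulatory matrix from TSV.

    Expected layout: header row of TF identifiers, first column gene
    identifiers, cells drawn from the nine-label vocabulary; empty cells mean
    ``not_regulated``.  Unknown labels are rejected with the offending row and
    column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df = df.replace("", BASELINE_LABEL)
    for tf in df.columns:
        bad = set(df[tf].unique()) - _EVIDENCE_SET
        if bad:
            label = sorted(bad)[0]
            row = df.index[df[tf] == label][0]
            raise ValueError(
                f"unknown evidence class {label!r} at gene {row!r}, TF {tf!r} "
                f"in {path}"
            )
    return RegulatoryMatrix(df)


def write_matrix(matrix: RegulatoryMatrix, path: str | Path, sort: bool = True) -> None:
    """Write a regulatory matrix as TSV (inverse of :func:`read_matrix`)."""
    df = matrix.cells
    if sort:
        df = df.sort_index().sort_index(axis=1)
    df.to_csv(path, sep="\t", index_label="gene")


def read_gene_lists(path: str | Path) -> dict[str, list[str]]:
    """Read named gene lists from a GMT-like file or a two-column TSV.

    GMT rows are ``name <tab> description <tab> gene1 <tab> gene2 ...``; a row
    with no genes is rejected.  Two-column TSV rows are ``gene <tab> class``.
    A ``.gmt`` suffix forces GMT parsing; otherwise the format is sniffed
    from the row widths.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"{path}: no gene lists found")
    is_gmt = path.suffix == ".gmt" or any(len(r) != 2 for r in rows)
    lists: dict[str, list[str]] = {}
    if is_gmt:
        for r in rows:
            if len(r) < 3 or not any(g.strip() for g in r[2:]):
                raise ValueError(f"{path}: GMT row {r[0]!r} has no genes")
            name = r[0]
            if name in lists:
                raise ValueError(f"{path}: duplicate list name {name!r}")
            lists[name] = [g for g in r[2:] if g.strip()]
    else:
        for r in rows:
            gene, cls = r[0], r[1]
            lists.setdefault(cls, []).append(gene)
        for cls, members in lists.items():
            if not members:
                raise ValueError(f"{path}: class {cls!r} has no genes")
    return lists


def write_gene_lists(lists: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write named gene lists in GMT format."""
    with open(path, "wt", encoding="utf-8") as fh:
        for name, members in lists.items():
            members = list(members)
            if not members:
                raise ValueError(f"refusing to write empty gene list {name!r}")
            fh.write("\t".join([name, "."] + members) + "\n")


def read_occupancy_table(
    path: str | Path, genome_mean: float
) -> list[OccupancyProfile]:
    """Read an occupancy TSV (gene, TF, value; one row per observation)."""
    df = pd.read_csv(
        path, sep="\t", header=0, names=["gene", "tf", "value"], dtype={"value": float}
    )
    profiles = []
    for (gene, tf), grp in df.groupby(["gene", "tf"], sort=True):
        profiles.append(
            OccupancyProfile(str(gene), str(tf), grp["value"].to_numpy(), genome_mean)
        )
    return profiles
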