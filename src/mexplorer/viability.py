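"""Nested linear error model for strain-viability time-courses.

Culture viability (CFU/ml divided by total cells/ml) is measured for deletion
strains, wildtype and negative-control strains across a time-course run in
independent batches.  For each (tested strain, time-point) the cross-section
of that time-point is fit with two nested Gaussian linear models on
log-viability:

    H1:  v ~ i + c + b + m        H0:  v ~ i + c + b

where i is the global intercept, c an indicator for negative-control rows,
b the batch indicator(s), and m the tested-strain indicator.  With Gaussian
log-likelihoods at the MLE variance the LR statistic reduces to the closed
form N * log(RSS_0 / RSS_1), referred to chi-square with one degree of
freedom.  exp(m-hat) is the viability fold change of the strain against the
background prediction.  The grid of (strain, time-point) p-values is BH-FDR
corrected, and strains with raw viability below 0.005 are flagged inviable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust, by_adjust

logger = logging.getLogger(__name__)

#: Raw-viability threshold below which a strain is flagged inviable.
INVIABILITY_THRESHOLD = 0.005

REQUIRED_COLUMNS = ("strain", "role", "batch", "replicate", "day", "viability")
ROLES = ("tested", "wildtype", "negative_control")


# ---------------------------------------------------------------------------
# Table handling
# ---------------------------------------------------------------------------


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a viability table and floor zero measurements.

    Requires the canonical columns, non-negative viability, known roles, and
    wildtype plus negative-control coverage in every batch.  Zero viabilities
    (below plating detection) are floored at half the smallest positive
    observed value so the log transform is defined; floored rows are logged.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"viability table missing columns {missing}")
    bad_roles = set(table["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown strain role {sorted(bad_roles)[0]!r}")
    v = table["viability"].to_numpy(dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("viability must be finite and non-negative")
    for batch, grp in table.groupby("batch"):
        roles = set(grp["role"])
        if "wildtype" not in roles or "negative_control" not in roles:
            raise ValueError(
                f"batch {batch!r} lacks wildtype or negative-control rows"
            )
    table = table.copy()
    zeros = v == 0
    if zeros.any():
        positive = v[v > 0]
        if positive.size == 0:
            raise ValueError("all viability values are zero")
        floor = positive.min() / 2.0
        table.loc[zeros, "viability"] = floor
        logger.warning("floored %d zero viability values at %g", zeros.sum(), floor)
    return table


def read_viability_table(path) -> pd.DataFrame:
    """Read and validate a viability TSV (strain, role, batch, replicate,
    day, viability)."""
    df = pd.read_csv(path, sep="\t")
    return validate_table(df)


# ---------------------------------------------------------------------------
# Per-strain LR test
# ---------------------------------------------------------------------------


@dataclass
class StrainTest:
    """Viability deviation test for one (strain, time-point)."""

    strain: str
    day: float
    log_fold_change: float
    fold_change: float
    statistic: float
    df: int
    p: float
    q: float | None = None
    significant: bool = False
    inviable: bool = False
    flags: tuple[str, ...] = ()


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least-squares fit; returns (coefficients, RSS, design rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def gaussian_lr_stat(rss0: float, rss1: float, n: int, scale: float = 1.0) -> float:
    """LR statistic for nested Gaussian linear models at the MLE variance:
    N * log(RSS_0 / RSS_1), clamped at zero.

    If the null model already fits to numerical precision (RSS_0 below
    round-off at the response's scale) there is no evidence left for the
    extra term and the statistic is zero.
    """
    eps = 1e-12 * max(scale, 1.0)
    if rss0 <= eps:
        return 0.0
    if rss1 <= eps:
        rss1 = eps
    return max(0.0, n * float(np.log(rss0 / rss1)))


def test_strain(
    table: pd.DataFrame, strain: str, day: float, validate: bool = True
) -> StrainTest:
    """Test one tested strain's viability deviation at one time-point.

    Fits H0 and H1 (module docstring) on all rows of the time-point; the
    response is log viability.  Requires at least two replicates of the
    strain and wildtype rows at the time-point.  With a single batch the
    batch term is dropped (flagged) and degrees of freedom bookkeeping stays
    consistent because the LR df is the single ``m`` indicator either way.
    """
    if validate:
        table = validate_table(table)
    cross = table[table["day"] == day]
    if cross.empty:
        raise ValueError(f"no rows at time-point {day}")
    strain_rows = cross[cross["strain"] == strain]
    if len(strain_rows) < 2:
        raise ValueError(
            f"strain {strain!r} has {len(strain_rows)} replicate(s) at day {day}; "
            "need at least 2"
        )
    if not (cross["role"] == "wildtype").any():
        raise ValueError(f"no wildtype rows at time-point {day}")

    y = np.log(cross["viability"].to_numpy(dtype=float))
    n = y.size
    flags: list[str] = []

    control = (cross["role"] == "negative_control").to_numpy(dtype=float)
    batches = sorted(cross["batch"].unique())
    batch_cols = []
    if len(batches) >= 2:
        for b in batches[1:]:
            batch_cols.append((cross["batch"] == b).to_numpy(dtype=float))
    else:
        flags.append("single-batch:batch-term-dropped")
    m = (cross["strain"] == strain).to_numpy(dtype=float)

    X0 = np.column_stack([np.ones(n), control] + batch_cols)
    X1 = np.column_stack([X0, m])
    beta0, rss0, _ = _ols_rss(X0, y)
    beta1, rss1, rank1 = _ols_rss(X1, y)
    if rank1 < X1.shape[1]:
        flags.append("singular-design")
    stat = gaussian_lr_stat(rss0, rss1, n, scale=float(y @ y))
    p = float(stats.chi2.sf(stat, 1))
    m_hat = float(beta1[-1])
    inviable = bool(strain_rows["viability"].mean() < INVIABILITY_THRESHOLD)
    return StrainTest(
        strain=strain,
        day=float(day),
        log_fold_change=m_hat,
        fold_change=float(np.exp(m_hat)),
        statistic=stat,
        df=1,
        p=p,
        inviable=inviable,
        flags=tuple(flags),
    )


def test_all_strains(
    table: pd.DataFrame, alpha: float = 0.05, fdr: str = "bh"
) -> list[StrainTest]:
    """Run :func:`test_strain` over every (tested strain, time-point) with at
    least two replicates, then FDR-correct the grid."""
    table = validate_table(table)
    tests: list[StrainTest] = []
    tested_strains = sorted(table.loc[table["role"] == "tested", "strain"].unique())
    for strain in tested_strains:
        days = sorted(table.loc[table["strain"] == strain, "day"].unique())
        for day in days:
            n_rep = ((table["strain"] == strain) & (table["day"] == day)).sum()
            if n_rep < 2:
                logger.warning(
                    "skipping %s day %s: %d replicate(s)", strain, day, n_rep
                )
                continue
            tests.append(test_strain(table, strain, day, validate=False))
    return fdr_grid(tests, alpha=alpha, fdr=fdr)


def fdr_grid(
    tests: list[StrainTest], alpha: float = 0.05, fdr: str = "bh"
) -> list[StrainTest]:
    """FDR-correct a grid of strain x time-point tests (BH by default,
    BY via ``fdr='by'``)."""
    if not tests:
        return tests
    adjust = bh_adjust if fdr == "bh" else by_adjust
    qvals = adjust([t.p for t in tests])
    for t, q in zip(tests, qvals):
        t.q = float(q)
        t.significant = bool(q <= alpha)
    return tests


def tests_to_frame(tests: list[StrainTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": t.strain,
                "day": t.day,
                "log_fold_change": t.log_fold_change,
                "fold_change": t.fold_change,
                "statistic": t.statistic,
                "df": t.df,
                "p": t.p,
                "q": t.q,
                "significant": t.significant,
                "inviable": t.inviable,
                "flags": ";".join(t.flags),
            }
            for t in tests
        ]
    )
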