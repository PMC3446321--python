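"""Baseline-category multinomial logistic regression and the LR test.

The screen asks, per transcription factor, whether the TF's categorical
evidence classes predict the process class of genes better than class
frequencies alone.  Formally, with response classes c = 1..C (class C the
baseline) and K dummy-coded evidence levels, the alternative model is

    log(p_ic / p_iC) = beta_{0,c} + sum_k beta_{k,c} x_{i,k}

and the null model keeps only the intercepts.  Both are fit by maximum
likelihood on the standard multinomial log-likelihood
l = sum_i sum_c y_{i,c} log p_{i,c}, and compared with the chi-square
likelihood-ratio statistic -2(l0 - l1) on (C-1)K degrees of freedom.

Because the single predictor is categorical, the alternative model is exactly
saturated in the evidence-level dimension: its maximized likelihood equals the
log-likelihood of the observed (level x class) cross-tabulation frequencies,
sum_{l,c} n_{lc} log(n_{lc} / n_{l.}).  That closed form is the supremum of
the likelihood even when some cells are empty (coefficients then diverge and
are capped for reporting), so it is used directly; an iterative Newton fitter
is provided as an alternative method and for verification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regdata import BASELINE_LABEL, ProcessResponse, RegulatoryMatrix

logger = logging.getLogger(__name__)

#: Reported coefficients are clamped to this magnitude under quasi-separation.
COEF_CAP = 30.0
#: Absolute tolerance for all log-likelihood comparisons.
LOGLIK_TOL = 1e-6
#: Newton solver: stop when the log-likelihood improves by less than this.
NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 500


# ---------------------------------------------------------------------------
# Predictor encoding
# ---------------------------------------------------------------------------


@dataclass
class PredictorEncoding:
    """Dummy coding of one TF's evidence column.

    ``levels`` lists the non-baseline evidence classes actually present for
    the TF (size K, in vocabulary order); ``level_codes`` assigns each gene an
    integer in 0..K where 0 is ``not_regulated`` and code k corresponds to
    ``levels[k-1]``.  Each gene's indicator vector has at most one nonzero
    entry because evidence classes are mutually exclusive.
    """

    tf: str
    levels: list[str]
    level_codes: np.ndarray
    dropped_levels: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.levels)


def encode_predictor(
    matrix: RegulatoryMatrix, tf: str, genes: list[str] | None = None
) -> PredictorEncoding:
    """Dummy-code a TF's evidence column with ``not_regulated`` as reference.

    Evidence levels with zero genes are dropped (and recorded so the degrees
    of freedom stay reproducible); K = 0 means the TF has no non-baseline
    target in the universe and cannot be tested.
    """
    col = matrix.column(tf)
    if genes is not None:
        col = col.loc[list(genes)]
    values = col.to_numpy()
    from .regdata import EVIDENCE_CLASSES

    present = [
        lab for lab in EVIDENCE_CLASSES[1:] if (values == lab).any()
    ]
    dropped = [lab for lab in EVIDENCE_CLASSES[1:] if lab not in present]
    code_of = {lab: i + 1 for i, lab in enumerate(present)}
    codes = np.zeros(values.shape[0], dtype=np.int64)
    for lab, code in code_of.items():
        codes[values == lab] = code
    return PredictorEncoding(tf, present, codes, dropped)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


@dataclass
class MultinomialFit:
    """A fitted baseline-category multinomial model.

    ``coef`` has shape (K+1, C-1): row 0 holds the intercepts beta_{0,c},
    row k the slopes beta_{k,c}; the response baseline class contributes no
    column.  ``loglik`` is the maximized log-likelihood; ``n_params`` is
    (C-1)(K+1).
    """

    classes: list[str]
    levels: list[str]
    coef: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    class_counts: np.ndarray
    converged: bool = True
    iterations: int = 0
    separated_levels: list[str] = field(default_factory=list)

    @property
    def C(self) -> int:
        return len(self.classes)

    @property
    def K(self) -> int:
        return len(self.levels)

    def predict_proba(self, level_codes: np.ndarray) -> np.ndarray:
        """Fitted class probabilities (columns ordered as ``classes``).

        Computed from the (possibly capped) coefficients, so probabilities are
        strictly inside (0, 1) and rows sum to one.
        """
        design = np.zeros((len(level_codes), self.K + 1))
        design[:, 0] = 1.0
        for k in range(1, self.K + 1):
            design[level_codes == k, k] = 1.0
        eta = design @ self.coef  # (n, C-1)
        logits = np.concatenate([eta, np.zeros((eta.shape[0], 1))], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p


def _xlogy_sum(n: np.ndarray, p: np.ndarray) -> float:
    """sum n * log(p) with the 0*log(0) = 0 convention."""
    from scipy.special import xlogy

    return float(xlogy(n, p).sum())


def fit_null(response: ProcessResponse) -> MultinomialFit:
    """Intercept-only fit: every gene's class probabilities are the observed
    class frequencies n_c / N; in closed form l0 = sum_c n_c log(n_c / N) and
    beta_{0,c} = log(n_c / n_C)."""
    counts = response.class_counts().to_numpy(dtype=float)
    N = counts.sum()
    C = len(counts)
    if C < 2:
        raise ValueError("response must have at least two classes")
    if (counts == 0).any():
        raise ValueError("empty response class")
    loglik = _xlogy_sum(counts, counts / N)
    intercepts = np.log(counts[:-1] / counts[-1])
    coef = intercepts.reshape(1, C - 1)
    return MultinomialFit(
        classes=list(response.classes),
        levels=[],
        coef=coef,
        loglik=loglik,
        n_params=C - 1,
        n_obs=int(N),
        class_counts=counts,
    )


def crosstab_counts(
    response: ProcessResponse, pred: PredictorEncoding
) -> np.ndarray:
    """(K+1) x C table of gene counts by evidence level and response class."""
    y = response.codes()
    C = response.n_classes
    K = pred.K
    flat = pred.level_codes * C + y
    return np.bincount(flat, minlength=(K + 1) * C).reshape(K + 1, C).astype(float)


def saturated_loglik(table: np.ndarray) -> float:
    """Log-likelihood of the saturated level x class cross-tabulation:
    sum_{l,c} n_lc log(n_lc / n_l.)."""
    row_tot = table.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(row_tot > 0, table / np.where(row_tot > 0, row_tot, 1.0), 0.0)
    return _xlogy_sum(table, np.where(p > 0, p, 1.0))


def _coef_from_table(table: np.ndarray, cap: float) -> tuple[np.ndarray, list[int]]:
    """Closed-form coefficients from the cross-tab; empty cells drive
    coefficients to +/-inf, which are capped at +/-cap and flagged."""
    K1, C = table.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        logodds = np.log(table[:, :-1]) - np.log(table[:, -1:])
        coef = np.empty((K1, C - 1))
        coef[0] = logodds[0]
        coef[1:] = logodds[1:] - logodds[0]
    separated_rows: list[int] = []
    bad = ~np.isfinite(coef)
    if bad.any():
        for row in range(K1):
            if bad[row].any():
                separated_rows.append(row)
        coef = np.nan_to_num(coef, nan=0.0, posinf=cap, neginf=-cap)
        coef = np.clip(coef, -cap, cap)
    return coef, separated_rows


def fit_alternative(
    response: ProcessResponse,
    pred: PredictorEncoding,
    method: str = "auto",
    cap: float = COEF_CAP,
    tol: float = NEWTON_TOL,
    max_iter: int = NEWTON_MAX_ITER,
) -> MultinomialFit:
    """Univariate alternative fit of the multinomial model for one TF.

    ``method='auto'`` uses the exact saturated cross-tab solution (see module
    docstring); ``method='newton'`` runs the iterative Newton solver on the
    aggregated counts.  Both maximize the same standard multinomial
    log-likelihood.
    """
    if pred.K == 0:
        raise ValueError(
            f"TF {pred.tf!r} has no non-baseline evidence (K=0); use fit_null"
        )
    if len(pred.level_codes) != len(response.assignment):
        raise ValueError("predictor and response cover different gene universes")
    table = crosstab_counts(response, pred)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("predictor has an empty level after drop; re-encode")
    C = response.n_classes
    K = pred.K
    n_params = (C - 1) * (K + 1)

    if method == "auto":
        loglik = saturated_loglik(table)
        coef, sep_rows = _coef_from_table(table, cap)
        labels = [BASELINE_LABEL] + pred.levels
        separated = [labels[r] for r in sep_rows]
        if separated:
            logger.debug(
                "TF %s: quasi-separation in levels %s; coefficients capped",
                pred.tf,
                separated,
            )
        return MultinomialFit(
            classes=list(response.classes),
            levels=list(pred.levels),
            coef=coef,
            loglik=loglik,
            n_params=n_params,
            n_obs=int(table.sum()),
            class_counts=table.sum(axis=0),
            converged=True,
            iterations=0,
            separated_levels=separated,
        )
    if method == "newton":
        return _fit_newton(response, pred, table, cap, tol, max_iter)
    raise ValueError(f"unknown method {method!r}")


def _fit_newton(
    response: ProcessResponse,
    pred: PredictorEncoding,
    table: np.ndarray,
    cap: float,
    tol: float,
    max_iter: int,
) -> MultinomialFit:
    """Newton-Raphson on the aggregated (level x class) counts.

    The design collapses to K+1 unique rows (intercept plus one indicator),
    so the Hessian is a small ((K+1)(C-1))^2 matrix regardless of N.
    """
    K1, C = table.shape
    Cm1 = C - 1
    X = np.zeros((K1, K1))
    X[:, 0] = 1.0
    for k in range(1, K1):
        X[k, k] = 1.0
    n_l = table.sum(axis=1)  # row totals
    Y = table[:, :Cm1]

    B = np.zeros((K1, Cm1))

    def loglik_of(Bm: np.ndarray) -> float:
        eta = X @ Bm
        logits = np.concatenate([eta, np.zeros((K1, 1))], axis=1)
        m = logits.max(axis=1, keepdims=True)
        logZ = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
        logp = logits - logZ[:, None]
        return _xlogy_sum(table, np.exp(logp))

    ll = loglik_of(B)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ B
        logits = np.concatenate([eta, np.zeros((K1, 1))], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        Pn = P[:, :Cm1]
        grad = X.T @ (Y - n_l[:, None] * Pn)  # (K1, Cm1)
        g = grad.ravel(order="F")
        H = np.zeros((K1 * Cm1, K1 * Cm1))
        for c in range(Cm1):
            for d in range(Cm1):
                w = n_l * Pn[:, c] * ((1.0 if c == d else 0.0) - Pn[:, d])
                H[c * K1:(c + 1) * K1, d * K1:(d + 1) * K1] = X.T @ (w[:, None] * X)
        H_reg = H + 1e-10 * np.eye(H.shape[0])
        try:
            step = np.linalg.solve(H_reg, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H_reg, g, rcond=None)[0]
        step_mat = step.reshape((K1, Cm1), order="F")
        new_B = B + step_mat
        new_ll = loglik_of(new_B)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step_mat *= 0.5
            new_B = B + step_mat
            new_ll = loglik_of(new_B)
            halvings += 1
        improvement = new_ll - ll
        B, ll = new_B, new_ll
        if abs(improvement) < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "TF %s: Newton fit did not converge in %d iterations", pred.tf, max_iter
        )
    separated = []
    if np.abs(B).max() > cap:
        labels = [BASELINE_LABEL] + pred.levels
        for row in range(K1):
            if np.abs(B[row]).max() > cap:
                separated.append(labels[row])
        B = np.clip(B, -cap, cap)
    return MultinomialFit(
        classes=list(response.classes),
        levels=list(pred.levels),
        coef=B,
        loglik=ll,
        n_params=(C - 1) * K1,
        n_obs=int(table.sum()),
        class_counts=table.sum(axis=0),
        converged=converged,
        iterations=it,
        separated_levels=separated,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass
class LRTestResult:
    """Chi-square likelihood-ratio comparison of nested multinomial fits."""

    statistic: float
    df: int
    p: float


def lr_test(null: MultinomialFit, alt: MultinomialFit) -> LRTestResult:
    """LR test of the univariate alternative against the intercept-only null.

    statistic = -2 (l0 - l1), clamped at zero against round-off; p is the
    chi-square upper-tail probability on df = params(alt) - params(null).
    """
    if null.n_obs != alt.n_obs:
        raise ValueError("fits cover different numbers of genes")
    if null.classes != alt.classes:
        raise ValueError("fits use different response class sets")
    if not np.allclose(null.class_counts, alt.class_counts):
        raise ValueError("fits disagree on response class counts")
    df = alt.n_params - null.n_params
    if df <= 0:
        raise ValueError("alternative model must have more parameters than null")
    stat = -2.0 * (null.loglik - alt.loglik)
    if stat < -LOGLIK_TOL:
        raise ValueError(
            f"alternative log-likelihood below null by {-stat/2:.3g}: fits invalid"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return LRTestResult(statistic=stat, df=df, p=p)
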