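"""From-formula statistics used by the screen.

Everything here is implemented directly from its defining formula — Pearson
chi-squared on 2x2 tables, the two-sample Kolmogorov–Smirnov test with the
asymptotic Kolmogorov p-value, Bonferroni family-wise correction, and
maximum-likelihood logistic regression by iteratively reweighted least
squares (IRLS). Only the chi-squared survival function is taken from scipy.

These are the screen's hypothesis-testing and propensity primitives; keeping
them explicit makes every exclusion rule and p-value auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2 as _chi2_dist

from .errors import DegenerateTableError, ValidationError

__all__ = [
    "Table2x2",
    "TestResult",
    "LogisticModel",
    "chi2_2x2",
    "ks_two_sample",
    "bonferroni",
    "fit_logistic",
    "predict_probability",
]


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table: rows exposed/unexposed, columns success/failure.

    ``a`` = exposed successes, ``b`` = exposed failures,
    ``c`` = unexposed successes, ``d`` = unexposed failures.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"cell {name} must be a non-negative count, got {v!r}")
        if self.total == 0:
            raise ValidationError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int
    method: str


@dataclass
class LogisticModel:
    """Fitted logistic regression: P(y=1|x) = expit(intercept + x @ coefficients)."""

    coefficients: np.ndarray
    intercept: float
    converged: bool
    n_iterations: int
    final_deviance: float
    deviance_path: list = field(default_factory=list, repr=False)


def chi2_2x2(table: Table2x2, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table, df=1.

    The statistic is ``sum (O-E)^2 / E`` over the four cells, with expected
    counts from the margins. With the Yates continuity correction each
    ``|O-E|`` is reduced by 0.5 (clipped at zero) before squaring.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError(
            f"degenerate table: zero margin in {table!r}; the statistic is undefined"
        )
    expected = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.clip(dev - 0.5, 0.0, None)
    stat = float(np.sum(dev**2 / expected))
    p = float(_chi2_dist.sf(stat, df=1))
    method = "pearson-chi2" + ("-yates" if continuity_correction else "")
    return TestResult(statistic=stat, p_value=p, df=1, method=method)


def _kolmogorov_sf(lam: float, max_terms: int = 100, tol: float = 1e-10) -> float:
    """Asymptotic Kolmogorov survival function Q(lam) = 2 sum (-1)^{k-1} exp(-2 k^2 lam^2)."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, max_terms + 1):
        term = 2.0 * (-1.0) ** (k - 1) * np.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < tol:
            break
    return float(min(1.0, max(0.0, total)))


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup |Fx - Fy| over the pooled support, computed exactly on the sorted
    pooled values (ties handled by evaluating both empirical CDFs at every
    pooled point). The p-value uses the asymptotic Kolmogorov distribution
    with effective sample size n = nx*ny/(nx+ny).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("ks_two_sample requires two non-empty samples")
    xs = np.sort(x)
    ys = np.sort(y)
    pooled = np.concatenate([xs, ys])
    pooled.sort(kind="mergesort")
    fx = np.searchsorted(xs, pooled, side="right") / xs.size
    fy = np.searchsorted(ys, pooled, side="right") / ys.size
    d = float(np.max(np.abs(fx - fy)))
    n_eff = xs.size * ys.size / (xs.size + ys.size)
    p = _kolmogorov_sf(np.sqrt(n_eff) * d)
    return TestResult(statistic=d, p_value=p, df=0, method="ks-two-sample")


def bonferroni(p_values) -> list:
    """Bonferroni family-wise correction: each p becomes min(1, m*p), m = len(p_values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    return [float(min(1.0, m * v)) for v in p]


def _logistic_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 log-likelihood, computed stably from the linear predictor
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    tolerance: float = 1e-8,
    max_iterations: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS with step-halving.

    An intercept is always included; ``features`` holds the non-constant
    columns. Convergence is declared when the score (gradient) max-norm drops
    below ``tolerance``. Step-halving guarantees the deviance never increases
    between iterations. Perfect or quasi-perfect separation is reported as
    ``converged=False`` (coefficients diverge; the fit at the last stable
    iterate is returned) rather than raised.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("features must be a 2-D array with one row per label")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValidationError("labels must be binary 0/1")
    if uniq.size < 2:
        raise ValidationError("no variation in outcome: labels are all identical")

    design = np.column_stack([np.ones(y.size), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR: columns pivoted beyond the rank are linear combinations
        # of earlier ones
        from scipy.linalg import qr

        _, _, piv = qr(design, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        names = ["intercept" if j == 0 else f"feature {j - 1}" for j in bad]
        raise ValidationError(f"rank-deficient design: collinear columns {names}")

    beta = np.zeros(design.shape[1])
    eta = design @ beta
    deviance = _logistic_deviance(y, eta)
    path = [deviance]
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        mu = expit(eta)
        grad = design.T @ (y - mu)
        if np.max(np.abs(grad)) < tolerance:
            converged = True
            break
        w = mu * (1.0 - mu)
        # guard against exactly-saturated weights under separation
        w = np.clip(w, 1e-12, None)
        XtWX = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            trial_dev = _logistic_deviance(y, design @ trial)
            if trial_dev <= deviance + 1e-12:
                break
            scale /= 2.0
        else:
            break
        beta = beta + scale * step
        eta = design @ beta
        deviance = _logistic_deviance(y, eta)
        path.append(deviance)
    else:
        it = max_iterations

    mu = expit(eta)
    grad = design.T @ (y - mu)
    if np.max(np.abs(grad)) < tolerance:
        converged = True
    # separation: every fitted probability saturated means the MLE is at
    # infinity and the returned coefficients are a truncation of it
    saturated = np.all((mu < 1e-6) | (mu > 1.0 - 1e-6))
    if saturated or np.max(np.abs(beta)) > 1e3:
        converged = False
    return LogisticModel(
        coefficients=beta[1:].copy(),
        intercept=float(beta[0]),
        converged=converged,
        n_iterations=it,
        final_deviance=deviance,
        deviance_path=path,
    )


def predict_probability(model: LogisticModel, features) -> np.ndarray | float:
    """Inverse-logit of the model's linear predictor; always in (0, 1).

    Accepts a single feature vector or a 2-D matrix (one row per observation).
    """
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.coefficients.size:
        raise ValidationError(
            f"feature length {x.shape[1]} does not match model "
            f"({model.coefficients.size} coefficients)"
        )
    eta = model.intercept + x @ model.coefficients
    p = expit(eta)
    return float(p[0]) if single else p
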