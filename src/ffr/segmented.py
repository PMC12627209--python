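"""Two-segment (broken-line) regression with break-point estimation.

The model is y = b0 + b1*x + (b2 - b1)*(x - psi)_+ + e: a line with
slope ``b1`` up to the break point ``psi`` and slope ``b2`` beyond it.
``psi`` enters non-linearly; it is estimated by iterative linearization:
given a working break point, the model is refit with the hinge covariate
(x - psi)_+ and the gap indicator -1(x > psi), and the break point is
updated by the ratio of the gap coefficient to the slope change until
the update vanishes.  Standard errors for psi come from the same
linearization (delta method); slope CIs are Wald intervals.

Because the break point is only identified when the slope actually
changes, "is there a break at all?" needs care: the test statistic's
null distribution is that of the supremum of a correlated process over
candidate break points.  ``davies_test`` evaluates the Wald statistic of
the slope change on a grid of candidate break points and applies the
classical upper bound for the tail of the supremum of such a process,
yielding a conservative adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BrokenLineFit",
    "SlopePair",
    "SlopeTestResult",
    "SegmentedError",
    "BreakpointUnidentifiedError",
    "fit_broken_line",
    "davies_test",
    "slopes_at_fixed_break",
    "group_slope_test",
]


class SegmentedError(RuntimeError):
    """Segmented regression failed (degenerate data or non-convergence)."""

    def __init__(self, message: str, last_fit: Optional["BrokenLineFit"] = None):
        super().__init__(message)
        self.last_fit = last_fit


class BreakpointUnidentifiedError(SegmentedError):
    """No detectable slope change: the break point is not identified."""


@dataclass(frozen=True)
class BrokenLineFit:
    """Estimates from a two-segment regression."""

    psi: float
    ci_psi: Tuple[float, float]
    b1: float
    b2: float
    intercept: float
    ci_b1: Tuple[float, float]
    ci_b2: Tuple[float, float]
    davies_p: Optional[float]
    n: int
    n_iter: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "ci_psi": list(self.ci_psi),
            "b1": self.b1,
            "b2": self.b2,
            "intercept": self.intercept,
            "ci_b1": list(self.ci_b1),
            "ci_b2": list(self.ci_b2),
            "davies_p": self.davies_p,
            "n": self.n,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class SlopePair:
    """Per-observer slopes at a fixed, externally supplied break point."""

    observer_id: str
    condition: str
    b1: float
    b2: float


@dataclass(frozen=True)
class SlopeTestResult:
    """One-sample t-test of a set of slopes against zero."""

    t: float
    df: int
    p: float
    cohens_d: float
    zero_variance: bool = False


def _check_xy(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SegmentedError("x and y must be 1-D arrays of equal length")
    if np.unique(x).size < 5:
        raise SegmentedError("need >= 5 distinct x values for a two-segment fit")
    return x, y


def _hinge(x: np.ndarray, psi: float) -> np.ndarray:
    return np.where(x > psi, x - psi, 0.0)


def _admissible(x: np.ndarray, psi: float) -> bool:
    # at least one distinct x strictly on each side keeps the design full rank
    return (np.unique(x[x <= psi]).size >= 1) and (np.unique(x[x > psi]).size >= 1)


def _rss3(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    X = np.column_stack([np.ones_like(x), x, _hinge(x, psi)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_broken_line(
    x: Sequence[float],
    y: Sequence[float],
    psi0: Optional[float] = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    davies_k: Optional[int] = 10,
    alpha: float = 0.05,
) -> BrokenLineFit:
    """Fit the two-segment model, estimating the break point.

    Starts from the midpoint of the x range (or ``psi0``), with restarts
    from the 25% and 75% quantiles on non-convergence.  ``davies_k``
    candidate points feed the Davies break-existence test (skipped if
    None).  Raises ``BreakpointUnidentifiedError`` when the data carry no
    detectable slope change, ``SegmentedError`` (with the last iterate
    attached) on non-convergence.
    """
    x, y = _check_xy(x, y)
    x_lo, x_hi = x.min(), x.max()
    x_range = x_hi - x_lo
    starts = [psi0] if psi0 is not None else []
    starts += [
        0.5 * (x_lo + x_hi),
        float(np.quantile(x, 0.25)),
        float(np.quantile(x, 0.75)),
    ]

    # Identifiability guard: residual variation around a single line.
    ols_lin = sm.OLS(y, sm.add_constant(x)).fit()
    scale = max(float(np.std(y)), 1e-12)
    if np.sqrt(ols_lin.ssr / len(y)) < 1e-9 * scale + 1e-30:
        raise BreakpointUnidentifiedError(
            "data are exactly linear: the break point is not identified"
        )

    last_error = None
    last_fit = None
    best = None  # (rss, psi, n_iter) over converged starts
    lo = x_lo + 1e-6 * x_range
    hi = x_hi - 1e-6 * x_range
    for start in starts:
        psi = float(np.clip(start, lo, hi))
        converged = False
        for it in range(1, max_iter + 1):
            U = _hinge(x, psi)
            V = -(x > psi).astype(float)
            X = np.column_stack([np.ones_like(x), x, U, V])
            fit = sm.OLS(y, X).fit()
            beta2 = fit.params[2]
            gamma = fit.params[3]
            if abs(beta2) < 1e-12 * scale / max(x_range, 1e-12):
                last_error = BreakpointUnidentifiedError(
                    "slope change estimate is numerically zero"
                )
                break
            # step halving keeps the working-model RSS from increasing,
            # which stabilizes the linearization on noisy data
            step = gamma / beta2
            rss_here = _rss3(x, y, psi)
            psi_new = None
            for _ in range(12):
                cand = float(np.clip(psi + step, lo, hi))
                if _admissible(x, cand) and _rss3(x, y, cand) <= rss_here + 1e-12:
                    psi_new = cand
                    break
                step *= 0.5
            if psi_new is None:
                converged = True  # no improving update: local optimum
                break
            moved = abs(psi_new - psi)
            psi = psi_new
            if moved <= tol * max(x_range, 1.0):
                converged = True
                break
        if converged:
            rss = _rss3(x, y, psi)
            if best is None or rss < best[0]:
                best = (rss, psi, it)
        elif last_error is None:
            last_error = SegmentedError(
                f"no convergence after {max_iter} iterations from start {start:.4g}"
            )
            last_fit = _summarize(x, y, psi, max_iter, converged=False, alpha=alpha)
    if best is not None:
        _, psi, n_iter = best
        result = _summarize(x, y, psi, n_iter, converged=True, alpha=alpha)
        if davies_k is not None:
            result = _with_davies(result, x, y, davies_k)
        return result
    if isinstance(last_error, BreakpointUnidentifiedError):
        raise last_error
    raise SegmentedError(str(last_error), last_fit=last_fit)


def _summarize(
    x: np.ndarray, y: np.ndarray, psi: float, n_iter: int, converged: bool, alpha: float
) -> BrokenLineFit:
    U = _hinge(x, psi)
    V = -(x > psi).astype(float)
    X = np.column_stack([np.ones_like(x), x, U, V])
    fit = sm.OLS(y, X).fit()
    b0, b1, beta2, gamma = fit.params
    cov = np.asarray(fit.cov_params())
    tcrit = stats.t.ppf(1 - alpha / 2, df=max(len(x) - X.shape[1], 1))

    se_b1 = np.sqrt(cov[1, 1])
    se_b2 = np.sqrt(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2])
    se_psi = np.sqrt(cov[3, 3]) / abs(beta2) if abs(beta2) > 0 else np.inf
    b2 = b1 + beta2
    return BrokenLineFit(
        psi=float(psi),
        ci_psi=(float(psi - tcrit * se_psi), float(psi + tcrit * se_psi)),
        b1=float(b1),
        b2=float(b2),
        intercept=float(b0),
        ci_b1=(float(b1 - tcrit * se_b1), float(b1 + tcrit * se_b1)),
        ci_b2=(float(b2 - tcrit * se_b2), float(b2 + tcrit * se_b2)),
        davies_p=None,
        n=len(x),
        n_iter=n_iter,
        converged=converged,
    )


def _with_davies(result: BrokenLineFit, x, y, k: int) -> BrokenLineFit:
    from dataclasses import replace

    return replace(result, davies_p=davies_test(x, y, k))


def davies_test(x: Sequence[float], y: Sequence[float], k: int = 10) -> float:
    """Adjusted p-value for the existence of a slope change.

    The Wald statistic of the hinge coefficient is evaluated at ``k``
    evenly spaced interior candidate break points; the maximum absolute
    statistic M and the total variation V of the statistic sequence give
    the upper bound  p <= 2 * [Phi(-M) + V * exp(-M^2/2) / sqrt(8*pi)]
    for the two-sided supremum test.  Conservative by construction.
    """
    if k < 2:
        raise SegmentedError(f"need k >= 2 candidate break points, got {k}")
    x, y = _check_xy(x, y)
    candidates = np.linspace(x.min(), x.max(), k + 2)[1:-1]
    t_stats = []
    for psi in candidates:
        X = np.column_stack([np.ones_like(x), x, _hinge(x, psi)])
        fit = sm.OLS(y, X).fit()
        se = np.sqrt(np.asarray(fit.cov_params())[2, 2])
        t_stats.append(fit.params[2] / se if se > 0 else 0.0)
    t_stats = np.asarray(t_stats)
    m_stat = float(np.max(np.abs(t_stats)))
    total_var = float(np.sum(np.abs(np.diff(t_stats))))
    p = 2.0 * (
        stats.norm.sf(m_stat) + total_var * np.exp(-0.5 * m_stat**2) / np.sqrt(8 * np.pi)
    )
    return float(min(p, 1.0))


def slopes_at_fixed_break(
    x: Sequence[float], y: Sequence[float], psi: float
) -> Tuple[float, float]:
    """OLS slopes before/after a break point supplied from outside.

    Used for per-observer analyses where ``psi`` comes from a segmented
    fit to the aggregated data and is *not* re-estimated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.min() < psi < x.max()):
        raise SegmentedError(
            f"psi={psi} must lie strictly inside the x range [{x.min()}, {x.max()}]"
        )
    X = np.column_stack([np.ones_like(x), x, _hinge(x, psi)])
    fit = sm.OLS(y, X).fit()
    b1 = float(fit.params[1])
    return b1, float(b1 + fit.params[2])


def group_slope_test(slopes: Sequence[float]) -> SlopeTestResult:
    """One-sample t-test of per-observer slopes against zero.

    Cohen's d = |mean| / sd.  Zero-variance input is flagged, not tested.
    """
    slopes = np.asarray(slopes, dtype=float)
    if slopes.size < 2:
        raise SegmentedError("need >= 2 slopes")
    df = slopes.size - 1
    sd = slopes.std(ddof=1)
    if sd == 0:
        return SlopeTestResult(np.nan, df, np.nan, np.nan, True)
    t, p = stats.ttest_1samp(slopes, 0.0)
    return SlopeTestResult(float(t), df, float(p), float(abs(slopes.mean()) / sd))
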