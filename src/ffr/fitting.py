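"""Exact likelihood and maximum-likelihood fitting of the sub-sampling observer.

The sub-sampling observer (see :mod:`ffr.observers`) has two free
parameters: attended sample size N and perceptual noise sigma.  Given a
trial, disk i sits at circular distance d_i JND from the probed hue and
matches it (after noise and rounding to the wheel) with probability
p_i = match_probability(d_i, sigma), independently across disks.  The
number of matches K in a uniformly random size-N subset then follows a
mixture of Poisson-binomial distributions over subsets; its exact pmf is
computed by dynamic programming over disks with state (disks selected,
matches so far), which sums Poisson-binomial mass over all C(36, N)
subsets in O(36 * N * K) time.  The response pmf follows by mixing K
over the uniform extrapolation multiplier m in {1, ..., floor(36/N)} and
clipping m*K to the 0-8 slider.

Fitting is exact-likelihood: for each candidate N in {1, ..., 36} the
noise sigma is optimized by bounded scalar search, and the global
minimum of the negative log-likelihood over the (N, sigma) profile is
returned.  Because the pmf depends on the trial only through the
multiset of disk distances from the probe, trials collapse into at most
24 (condition x |offset|) groups, and one DP sweep per sigma yields the
likelihood for every N simultaneously, which keeps the exhaustive
profile cheap.

``parameter_recovery`` closes the loop: simulate sessions at known
(N, sigma) pairs, refit each, and correlate true with fitted values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .observers import (
    SLIDER_MAX,
    SubsamplingParams,
    match_probability,
    multiplier_max,
    simulate_dataset,
)
from .stimuli import (
    ColorWheel,
    DISPLAY_SIZE,
    Session,
    Trial,
    WHEEL48,
    generate_session,
    get_spec,
    signed_offset,
)

__all__ = [
    "ResponsePMF",
    "FitResult",
    "RecoveryResult",
    "FitError",
    "subset_match_count_distribution",
    "match_count_distribution",
    "mix_multiplier",
    "response_pmf",
    "negative_log_likelihood",
    "simulated_negative_log_likelihood",
    "fit_mle",
    "parameter_recovery",
]

N_RESPONSES = SLIDER_MAX + 1

#: Floor added inside the log to guard responses the model deems
#: impossible (e.g. lapses in human data); configurable in the fitters.
DEFAULT_LOG_FLOOR = 1e-12

DEFAULT_SIGMA_BOUNDS = (0.05, 20.0)
DEFAULT_SIGMA_XATOL = 1e-3


class FitError(RuntimeError):
    """Likelihood or fitting failure."""


@dataclass(frozen=True)
class ResponsePMF:
    """Predicted response distribution (0-8) for one trial."""

    trial: Trial
    params: SubsamplingParams
    pmf: np.ndarray

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        if pmf.shape != (N_RESPONSES,):
            raise FitError(f"pmf must have length {N_RESPONSES}")
        if np.any(pmf < -1e-12) or abs(pmf.sum() - 1.0) > 1e-9:
            raise FitError("pmf must be non-negative and sum to 1")
        object.__setattr__(self, "pmf", pmf)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimate with the per-N profile behind it."""

    params_hat: SubsamplingParams
    nll: float
    profile: pd.DataFrame  # columns: N, sigma, nll

    def to_dict(self) -> dict:
        return {
            "N": int(self.params_hat.N),
            "sigma": float(self.params_hat.sigma),
            "nll": float(self.nll),
            "profile": self.profile.to_dict(orient="list"),
        }


@dataclass(frozen=True)
class RecoveryResult:
    """Parameter-recovery study output: per-run table and correlations."""

    table: pd.DataFrame  # run, true_N, true_sigma, fit_N, fit_sigma
    r_N: float
    r_sigma: float
    r_cross: float
    p_N: float
    p_sigma: float
    p_cross: float
    n_runs: int

    def summary(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "r_N": self.r_N,
            "r_sigma": self.r_sigma,
            "r_cross": self.r_cross,
            "p_N": self.p_N,
            "p_sigma": self.p_sigma,
            "p_cross": self.p_cross,
        }


def subset_match_count_distribution(
    match_probs: Sequence[float], n_select: int
) -> np.ndarray:
    """Exact pmf of the match count in a random size-``n_select`` subset.

    ``match_probs[i]`` is disk i's independent match probability.  The
    DP accumulates, over subsets S of the first i disks with |S| = s,
    the Poisson-binomial probability of k matches within S; dividing by
    C(n, n_select) averages uniformly over subsets.
    """
    p = np.asarray(match_probs, dtype=float)
    n = p.size
    if not 1 <= n_select <= n:
        raise FitError(f"n_select must be in [1, {n}], got {n_select}")
    if np.any((p < 0) | (p > 1)):
        raise FitError("match probabilities must lie in [0, 1]")
    # A[s, k] = sum over size-s subsets of P(k matches | subset)
    A = np.zeros((n + 1, n + 1))
    A[0, 0] = 1.0
    for i, pi in enumerate(p):
        sel = np.zeros_like(A)
        sel[:, 1:] = pi * A[:, :-1]
        sel[:, :] += (1.0 - pi) * A
        A[1:, :] += sel[:-1, :]
    return A[n_select, : n_select + 1] / math.comb(n, n_select)


def _disk_distances(trial: Trial, wheel: ColorWheel) -> np.ndarray:
    return np.array(
        [signed_offset(trial.test_hue, h, wheel) for h in trial.disk_hues], dtype=float
    )


def match_count_distribution(
    trial: Trial, params: SubsamplingParams, wheel: ColorWheel = WHEEL48
) -> np.ndarray:
    """Exact pmf over k = 0..N of matches to the probed hue in ``trial``."""
    d = _disk_distances(trial, wheel)
    p = match_probability(d, params.sigma, wheel)
    return subset_match_count_distribution(p, params.N)


def mix_multiplier(match_pmf: Sequence[float], n_sampled: int) -> np.ndarray:
    """Response pmf: mix the match count over the extrapolation multiplier.

    The multiplier is uniform on {1, ..., floor(36/N)} (identically 1 for
    N >= 19); each product k*m is clipped to the 0-8 slider and its mass
    aggregated.
    """
    match_pmf = np.asarray(match_pmf, dtype=float)
    m_max = multiplier_max(n_sampled)
    out = np.zeros(N_RESPONSES)
    for m in range(1, m_max + 1):
        for k, mass in enumerate(match_pmf):
            out[min(k * m, SLIDER_MAX)] += mass / m_max
    return out


def response_pmf(
    trial: Trial, params: SubsamplingParams, wheel: ColorWheel = WHEEL48
) -> ResponsePMF:
    """Exact predicted response distribution for one trial."""
    return ResponsePMF(
        trial, params, mix_multiplier(match_count_distribution(trial, params, wheel), params.N)
    )


# ---------------------------------------------------------------------------
# Fast grouped likelihood
# ---------------------------------------------------------------------------

def _group_distances(condition: str, abs_offset: int, wheel: ColorWheel) -> np.ndarray:
    """Distances of the 36 disks from a probe ``abs_offset`` JND off the mean.

    All trials sharing (condition, |offset|) have the same distance
    multiset: the display counts are fixed and symmetric, so the mirror
    probe -|offset| yields the mirrored (hence equivalent) multiset.
    """
    spec = get_spec(condition)
    mean_hue = 0
    probe = wheel.steps(abs_offset) % wheel.n_hues
    d = []
    for k in sorted(spec.counts):
        hue = wheel.steps(k) % wheel.n_hues
        d.extend([signed_offset(probe, hue, wheel)] * spec.counts[k])
    assert len(d) == DISPLAY_SIZE
    return np.array(d, dtype=float)


# Response mapping tensors: T[N-1][k_bucket, r] sends bucketed match counts
# (bucket 8 pools k >= 8, which always responds 8) to responses for each N.
def _multiplier_tensors() -> np.ndarray:
    T = np.zeros((DISPLAY_SIZE, N_RESPONSES, N_RESPONSES))
    for N in range(1, DISPLAY_SIZE + 1):
        m_max = multiplier_max(N)
        for m in range(1, m_max + 1):
            for k in range(N_RESPONSES):
                T[N - 1, k, min(k * m, SLIDER_MAX)] += 1.0 / m_max
    return T


_T_MULT = _multiplier_tensors()
_LOG_COMB = np.array(
    [math.lgamma(DISPLAY_SIZE + 1) - math.lgamma(N + 1) - math.lgamma(DISPLAY_SIZE - N + 1)
     for N in range(1, DISPLAY_SIZE + 1)]
)


class SessionLikelihood:
    """Grouped exact likelihood of a filled session, profiled over all N.

    Trials are grouped by (condition, |test offset|); the group's
    response histogram and disk-distance vector are precomputed.  One
    bucketed DP sweep per sigma (match counts >= 8 pooled, since they
    respond 8 regardless of the multiplier) yields the negative
    log-likelihood for every N in {1, ..., 36} at once.
    """

    def __init__(
        self,
        session: Session,
        wheel: ColorWheel = WHEEL48,
        log_floor: float = DEFAULT_LOG_FLOOR,
    ):
        if len(session) == 0:
            raise FitError("empty session")
        if not session.has_responses:
            raise FitError("session has trials without responses")
        self.wheel = wheel
        self.log_floor = float(log_floor)
        counts: Dict[Tuple[str, int], np.ndarray] = {}
        for t in session.trials:
            key = (t.condition, abs(t.test_offset))
            hist = counts.setdefault(key, np.zeros(N_RESPONSES))
            hist[int(t.response)] += 1
        self._keys = sorted(counts)
        self._counts = np.stack([counts[k] for k in self._keys])  # (G, 9)
        self._dists = np.stack(
            [_group_distances(cond, off, wheel) for cond, off in self._keys]
        )  # (G, 36)
        self._cache: Dict[float, np.ndarray] = {}

    def _bucketed_dp(self, probs: np.ndarray) -> np.ndarray:
        """DP over disks for all groups; returns (G, 37, 9) subset-weighted pmf."""
        G = probs.shape[0]
        A = np.zeros((G, DISPLAY_SIZE + 1, N_RESPONSES))
        A[:, 0, 0] = 1.0
        for i in range(DISPLAY_SIZE):
            pi = probs[:, i][:, None, None]
            shifted = np.zeros_like(A)
            shifted[:, :, 1:] = A[:, :, :-1]
            shifted[:, :, SLIDER_MAX] += A[:, :, SLIDER_MAX]  # bucket k >= 8
            sel = pi * shifted + (1.0 - pi) * A
            A[:, 1:, :] += sel[:, :-1, :]
        return A

    def nll_profile(self, sigma: float) -> np.ndarray:
        """Negative log-likelihood for every N in {1..36} at this sigma."""
        key = round(float(sigma), 12)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        probs = match_probability(self._dists, sigma, self.wheel)
        A = self._bucketed_dp(probs)
        # (G, 36, 9): match-count pmf per N, normalized by C(36, N)
        match = A[:, 1:, :] / np.exp(_LOG_COMB)[None, :, None]
        resp = np.einsum("gnk,nkr->gnr", match, _T_MULT)
        log_resp = np.log(resp + self.log_floor)
        profile = -np.einsum("gr,gnr->n", self._counts, log_resp)
        self._cache[key] = profile
        return profile

    def nll(self, params: SubsamplingParams) -> float:
        return float(self.nll_profile(params.sigma)[params.N - 1])


def negative_log_likelihood(
    session: Session,
    params: SubsamplingParams,
    wheel: ColorWheel = WHEEL48,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> float:
    """Exact negative log-likelihood of a filled session under ``params``."""
    return SessionLikelihood(session, wheel, log_floor).nll(params)


def simulated_negative_log_likelihood(
    session: Session,
    params: SubsamplingParams,
    n_sims: int = 2000,
    seed: Optional[int] = None,
    smoothing: float = 0.5,
    wheel: ColorWheel = WHEEL48,
) -> float:
    """Simulation-based likelihood, for fidelity comparisons with the exact DP.

    Estimates each trial's response pmf from ``n_sims`` forward
    simulations of the generative observer with additive smoothing
    (``smoothing`` pseudo-counts per response value).  Stochastic but
    reproducible from ``seed``; the exact DP likelihood is the default
    everywhere else.
    """
    from .observers import simulate_subsampling_response

    if len(session) == 0:
        raise FitError("empty session")
    if not session.has_responses:
        raise FitError("session has trials without responses")
    rng = np.random.default_rng(seed)
    # one smoothed pmf per (condition, |offset|) group, like the exact path
    groups: Dict[Tuple[str, int], list] = {}
    for t in session.trials:
        groups.setdefault((t.condition, abs(t.test_offset)), []).append(t)
    nll = 0.0
    for trials in groups.values():
        rep = trials[0]
        sims = np.array(
            [simulate_subsampling_response(rep, params, rng, wheel) for _ in range(n_sims)]
        )
        pmf = (np.bincount(sims, minlength=N_RESPONSES) + smoothing) / (
            n_sims + smoothing * N_RESPONSES
        )
        for t in trials:
            nll -= float(np.log(pmf[int(t.response)]))
    return nll


def fit_mle(
    session: Session,
    wheel: ColorWheel = WHEEL48,
    sigma_bounds: Tuple[float, float] = DEFAULT_SIGMA_BOUNDS,
    sigma_xatol: float = DEFAULT_SIGMA_XATOL,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> FitResult:
    """Maximum-likelihood fit of (N, sigma) to one observer's session.

    Exhaustive over N in {1, ..., 36}; for each N, bounded scalar
    minimization of the profiled negative log-likelihood over sigma.
    Deterministic given the data; exact ties across N break toward the
    smaller N.
    """
    like = SessionLikelihood(session, wheel, log_floor)
    rows = []
    failures = []
    for N in range(1, DISPLAY_SIZE + 1):
        try:
            res = optimize.minimize_scalar(
                lambda s, n=N: float(like.nll_profile(s)[n - 1]),
                bounds=sigma_bounds,
                method="bounded",
                options={"xatol": sigma_xatol},
            )
            rows.append((N, float(res.x), float(res.fun)))
        except Exception as err:  # pragma: no cover - optimizer robustness
            failures.append((N, str(err)))
            rows.append((N, np.nan, np.inf))
    if len(failures) == DISPLAY_SIZE:
        raise FitError(f"sigma optimization failed for every N: {failures[:3]}...")
    profile = pd.DataFrame(rows, columns=["N", "sigma", "nll"])
    best = profile.sort_values(["nll", "N"]).iloc[0]
    if not np.isfinite(best["nll"]):
        raise FitError("no finite likelihood found")
    return FitResult(
        SubsamplingParams(int(best["N"]), float(best["sigma"])),
        float(best["nll"]),
        profile,
    )


def parameter_recovery(
    n_runs: int,
    trials_per_run: int = 450,
    n_range: Tuple[int, int] = (1, DISPLAY_SIZE),
    sigma_range: Tuple[float, float] = (0.5, 10.0),
    seed: Optional[int] = None,
    wheel: ColorWheel = WHEEL48,
    progress: Optional[callable] = None,
    **fit_kwargs,
) -> RecoveryResult:
    """Simulate-and-refit study of the (N, sigma) estimator.

    Each run draws N uniformly on the integer range and sigma uniformly
    on its range, simulates a fresh session of ``trials_per_run`` trials
    from the sub-sampling observer, refits by :func:`fit_mle`, and
    records true vs fitted values.  Pearson correlations quantify
    recovery; ``r_cross`` correlates the two *fitted* parameters with
    each other (near zero when the estimator does not trade them off).
    """
    if n_runs < 2:
        raise FitError(f"n_runs must be >= 2, got {n_runs}")
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        true_n = int(rng.integers(n_range[0], n_range[1] + 1))
        true_sigma = float(rng.uniform(*sigma_range))
        session_seed = int(rng.integers(2**31))
        response_seed = int(rng.integers(2**31))
        session = generate_session(
            trials_per_run, observer_id=f"recovery-{run}", seed=session_seed, wheel=wheel
        )
        filled = simulate_dataset(
            session, SubsamplingParams(true_n, true_sigma), seed=response_seed, wheel=wheel
        )
        fit = fit_mle(filled, wheel=wheel, **fit_kwargs)
        rows.append(
            (run, true_n, true_sigma, fit.params_hat.N, fit.params_hat.sigma, fit.nll)
        )
        if progress is not None:
            progress(run + 1, n_runs)
    table = pd.DataFrame(
        rows, columns=["run", "true_N", "true_sigma", "fit_N", "fit_sigma", "nll"]
    )
    r_N, p_N = stats.pearsonr(table["true_N"], table["fit_N"])
    r_sigma, p_sigma = stats.pearsonr(table["true_sigma"], table["fit_sigma"])
    r_cross, p_cross = stats.pearsonr(table["fit_N"], table["fit_sigma"])
    return RecoveryResult(
        table,
        float(r_N),
        float(r_sigma),
        float(r_cross),
        float(p_N),
        float(p_sigma),
        float(p_cross),
        n_runs,
    )
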