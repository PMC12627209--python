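"""Synthetic observers for FFR sessions.

Two generative response models:

* **Sub-sampling observer** — perceives each of the 36 disk hues with
  independent Gaussian perceptual noise (SD ``sigma`` JND, applied on
  the hue circle), attends to ``N`` disks chosen uniformly without
  replacement, counts how many of those noisy hues round to the probed
  hue, and extrapolates to the full display by multiplying the count by
  a uniform random integer in [1, floor(36/N)].  The product, clipped to
  the 0-8 slider, is the response.  This is the working-memory-sampling
  account that the model-fitting stage is designed to test.

* **Veridical-noisy observer** — reports the true disk count at the
  probed hue plus additive Gaussian response noise, rounded and clipped.
  A transparent fixture: with zero noise its folded response curve is
  exactly the ground-truth distribution shape, which pins down the
  descriptive analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.stats import norm

from .stimuli import ColorWheel, DISPLAY_SIZE, Session, Trial, WHEEL48

__all__ = [
    "SubsamplingParams",
    "VeridicalParams",
    "ObserverError",
    "SLIDER_MAX",
    "match_probability",
    "multiplier_max",
    "simulate_subsampling_response",
    "simulate_veridical_response",
    "simulate_dataset",
]

#: Upper end of the response slider.
SLIDER_MAX = 8


class ObserverError(ValueError):
    """Invalid observer parameters or session state."""


@dataclass(frozen=True)
class SubsamplingParams:
    """Free parameters of the sub-sampling observer.

    N : attended sample size, integer in [1, 36].
    sigma : perceptual noise SD in JND, > 0.
    """

    N: int
    sigma: float

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and 1 <= self.N <= DISPLAY_SIZE):
            raise ObserverError(f"N must be an integer in [1, {DISPLAY_SIZE}], got {self.N}")
        if not self.sigma > 0:
            raise ObserverError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class VeridicalParams:
    """Additive response noise SD (slider units) of the veridical observer."""

    response_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.response_noise_sd < 0:
            raise ObserverError("response_noise_sd must be >= 0")


def multiplier_max(n_sampled: int) -> int:
    """Largest extrapolation multiplier, floor(36 / N); 1 for N >= 19."""
    return DISPLAY_SIZE // int(n_sampled)


def match_probability(d, sigma: float, wheel: ColorWheel = WHEEL48):
    """Probability that a disk ``d`` JND from the probed hue matches it.

    The disk's hue is perturbed by circular Gaussian noise (SD ``sigma``)
    and then rounded to the nearest wheel hue; a match means it rounds to
    the probed hue.  Wrap-around is summed explicitly, so the per-hue
    match probabilities over the whole wheel sum to 1.  Accepts scalars
    or arrays of ``d``.
    """
    if not sigma > 0:
        raise ObserverError(f"sigma must be > 0, got {sigma}")
    d_arr = np.asarray(d, dtype=float)
    period = wheel.period_jnd
    half = 0.5 * wheel.jnd_per_step
    n_wraps = int(np.ceil((6.0 * sigma + period / 2) / period))
    wraps = np.arange(-n_wraps, n_wraps + 1) * period
    z = -d_arr[..., None] + wraps
    p = norm.cdf((z + half) / sigma) - norm.cdf((z - half) / sigma)
    p = p.sum(axis=-1)
    return float(p) if np.isscalar(d) or d_arr.ndim == 0 else p


def simulate_subsampling_response(
    trial: Trial,
    params: SubsamplingParams,
    rng: np.random.Generator,
    wheel: ColorWheel = WHEEL48,
) -> int:
    """One stochastic response of the sub-sampling observer to ``trial``."""
    hues = np.asarray(trial.disk_hues, dtype=float)
    noised = hues + rng.normal(0.0, params.sigma / wheel.jnd_per_step, size=hues.shape)
    rounded = np.round(noised).astype(int) % wheel.n_hues
    sampled = rng.choice(hues.shape[0], size=params.N, replace=False)
    matches = int(np.sum(rounded[sampled] == trial.test_hue))
    m_max = multiplier_max(params.N)
    multiplier = int(rng.integers(1, m_max + 1)) if m_max > 1 else 1
    return min(matches * multiplier, SLIDER_MAX)


def simulate_veridical_response(
    trial: Trial,
    params: VeridicalParams,
    rng: np.random.Generator,
) -> int:
    """True count at the probed hue plus rounded Gaussian response noise."""
    count = sum(h == trial.test_hue for h in trial.disk_hues)
    if params.response_noise_sd > 0:
        count = round(count + rng.normal(0.0, params.response_noise_sd))
    return int(min(max(count, 0), SLIDER_MAX))


def simulate_dataset(
    session: Session,
    model: Union[SubsamplingParams, VeridicalParams],
    seed=None,
    wheel: ColorWheel = WHEEL48,
) -> Session:
    """Fill every trial of ``session`` with a simulated response.

    Returns a new Session; the input must not already carry responses.
    Reproducible from ``seed``.
    """
    if any(t.response is not None for t in session.trials):
        raise ObserverError("session already has responses; refusing to overwrite")
    rng = np.random.default_rng(seed)
    if isinstance(model, SubsamplingParams):
        responses = [
            simulate_subsampling_response(t, model, rng, wheel) for t in session.trials
        ]
    elif isinstance(model, VeridicalParams):
        responses = [simulate_veridical_response(t, model, rng) for t in session.trials]
    else:
        raise ObserverError(f"unknown observer model {model!r}")
    out = session.with_responses(responses)
    out.seed = seed if seed is not None else session.seed
    return out
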