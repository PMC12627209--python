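"""Stimulus generation for Feature Frequency Report (FFR) sessions.

An FFR trial shows 36 colored disks drawn from one of three fixed,
symmetric hue distributions (gaussian, uniform, bimodal) centered on a
random mean hue of a circular color wheel whose neighboring hues are
~1 JND apart.  A single hue is then probed and the observer reports how
many disks had that hue on a 0-8 slider.  The probed hue sits at a
signed offset from the mean in {0, +/-3, ..., +/-21} JND, i.e. inside or
up to 9 JND outside the presented +/-12 JND range.

Displays are represented as multisets of hue indices: the frequency
report depends only on how many disks of each hue were shown, not on
where they were.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ColorWheel",
    "DistributionSpec",
    "Trial",
    "Session",
    "StimulusError",
    "WHEEL48",
    "DISPLAY_SIZE",
    "CONDITIONS",
    "TEST_OFFSETS",
    "get_spec",
    "signed_offset",
    "build_display",
    "sample_test_offset",
    "make_trial",
    "generate_session",
]


class StimulusError(ValueError):
    """Invalid stimulus parameter (hue index, offset, distribution...)."""


#: Number of disks in every display.
DISPLAY_SIZE = 36

#: The three distribution conditions, in canonical order.
CONDITIONS = ("gaussian", "uniform", "bimodal")

#: Signed probe offsets (JND): every presented value plus three values
#: beyond each edge of the +/-12 JND range.
TEST_OFFSETS = tuple(
    sorted({0} | {s * k for s in (-1, 1) for k in (3, 6, 9, 12, 15, 18, 21)})
)


@dataclass(frozen=True)
class ColorWheel:
    """Circular hue space with ``n_hues`` equally spaced hues.

    Neighboring hues are ``jnd_per_step`` JND apart; all offsets and
    noise magnitudes elsewhere in the package are expressed in JND.
    """

    n_hues: int = 48
    jnd_per_step: float = 1.0

    def __post_init__(self) -> None:
        if self.n_hues < 2 or self.n_hues % 2 != 0:
            raise StimulusError(f"n_hues must be even and >= 2, got {self.n_hues}")
        if not self.jnd_per_step > 0:
            raise StimulusError(f"jnd_per_step must be > 0, got {self.jnd_per_step}")

    @property
    def period_jnd(self) -> float:
        """Circumference of the wheel in JND."""
        return self.n_hues * self.jnd_per_step

    def check_hue(self, hue: int) -> int:
        hue = int(hue)
        if not 0 <= hue < self.n_hues:
            raise StimulusError(f"hue index {hue} outside [0, {self.n_hues})")
        return hue

    def steps(self, offset_jnd: float) -> int:
        """Convert a JND offset to an integer number of wheel steps."""
        steps = offset_jnd / self.jnd_per_step
        rounded = int(round(steps))
        if abs(steps - rounded) > 1e-9:
            raise StimulusError(
                f"offset {offset_jnd} JND is not a whole number of wheel steps"
            )
        return rounded


WHEEL48 = ColorWheel()


def signed_offset(hue_a: int, hue_b: int, wheel: ColorWheel = WHEEL48) -> float:
    """Signed shortest circular displacement from ``hue_a`` to ``hue_b`` in JND.

    The result lies in ``(-period/2, +period/2]``; the antipodal tie is
    resolved to the positive direction.
    """
    a = wheel.check_hue(hue_a)
    b = wheel.check_hue(hue_b)
    d = (b - a) % wheel.n_hues
    if d > wheel.n_hues // 2:
        d -= wheel.n_hues
    return d * wheel.jnd_per_step


@dataclass(frozen=True)
class DistributionSpec:
    """A fixed, symmetric mapping from signed JND offset to disk count.

    The three canonical shapes share total count (36), range (+/-12 JND)
    and mean offset 0, so they are matched on the summary statistics the
    frequency report is meant to go beyond.
    """

    name: str
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        allowed = {0, 3, -3, 6, -6, 9, -9, 12, -12}
        if not set(counts) <= allowed:
            raise StimulusError(
                f"{self.name}: offsets {sorted(set(counts) - allowed)} outside "
                "the +/-12 JND grid"
            )
        for k, c in counts.items():
            if c < 0:
                raise StimulusError(f"{self.name}: negative count at offset {k}")
            if counts.get(-k, 0) != c:
                raise StimulusError(f"{self.name}: counts not symmetric at +/-{abs(k)}")
        if sum(counts.values()) != DISPLAY_SIZE:
            raise StimulusError(
                f"{self.name}: counts sum to {sum(counts.values())}, "
                f"expected {DISPLAY_SIZE}"
            )
        object.__setattr__(self, "counts", counts)

    def count_at(self, signed_offset_jnd: int) -> int:
        """Disk count at one signed offset (0 outside the spec's support)."""
        return self.counts.get(int(signed_offset_jnd), 0)


def _symmetric(center: int, per_side: Mapping[int, int]) -> dict:
    counts = {0: center}
    for k, c in per_side.items():
        counts[k] = c
        counts[-k] = c
    return counts


_SPECS = {
    "gaussian": DistributionSpec(
        "gaussian", _symmetric(8, {3: 7, 6: 4, 9: 2, 12: 1})
    ),
    "uniform": DistributionSpec(
        "uniform", _symmetric(4, {3: 4, 6: 4, 9: 4, 12: 4})
    ),
    "bimodal": DistributionSpec(
        "bimodal", _symmetric(0, {3: 2, 6: 3, 9: 6, 12: 7})
    ),
}


def get_spec(name: str) -> DistributionSpec:
    """Look up one of the three canonical distribution shapes by name."""
    try:
        return _SPECS[name]
    except KeyError:
        raise StimulusError(
            f"unknown distribution {name!r}; expected one of {CONDITIONS}"
        ) from None


@dataclass(frozen=True)
class Trial:
    """One display plus its probe; ``response`` is filled by an observer."""

    condition: str
    mean_hue: int
    disk_hues: tuple
    test_offset: int
    test_hue: int
    response: Optional[int] = None


@dataclass
class Session:
    """An ordered list of trials for one observer, with the seed that made it."""

    observer_id: str
    trials: list
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def has_responses(self) -> bool:
        return all(t.response is not None for t in self.trials)

    def with_responses(self, responses: Sequence[int]) -> "Session":
        if len(responses) != len(self.trials):
            raise StimulusError("response count does not match trial count")
        trials = [replace(t, response=int(r)) for t, r in zip(self.trials, responses)]
        return Session(self.observer_id, trials, self.seed)


def build_display(
    spec: DistributionSpec, mean_hue: int, wheel: ColorWheel = WHEEL48
) -> list:
    """Hue indices of the 36 disks realizing ``spec`` around ``mean_hue``.

    Deterministic given (spec, mean_hue); order follows ascending offset.
    """
    mean_hue = wheel.check_hue(mean_hue)
    hues = []
    for k in sorted(spec.counts):
        hue = (mean_hue + wheel.steps(k)) % wheel.n_hues
        hues.extend([hue] * spec.counts[k])
    return hues


def sample_test_offset(
    rng: np.random.Generator, probabilities: Optional[Sequence[float]] = None
) -> int:
    """Draw a signed probe offset; uniform over the 15 values by default."""
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (len(TEST_OFFSETS),):
            raise StimulusError(
                f"offset probabilities must have length {len(TEST_OFFSETS)}"
            )
        if np.any(probabilities < 0) or not np.isclose(probabilities.sum(), 1.0):
            raise StimulusError("offset probabilities must be >= 0 and sum to 1")
    return int(rng.choice(TEST_OFFSETS, p=probabilities))


def make_trial(
    condition: str,
    mean_hue: int,
    test_offset: int,
    wheel: ColorWheel = WHEEL48,
) -> Trial:
    """Assemble a Trial: display around ``mean_hue`` and probe at ``test_offset``."""
    spec = get_spec(condition)
    if test_offset not in TEST_OFFSETS:
        raise StimulusError(
            f"test offset {test_offset} not in the probed set {TEST_OFFSETS}"
        )
    disk_hues = tuple(build_display(spec, mean_hue, wheel))
    test_hue = (mean_hue + wheel.steps(test_offset)) % wheel.n_hues
    return Trial(condition, mean_hue, disk_hues, int(test_offset), test_hue)


def generate_session(
    n_trials: int,
    observer_id: str = "sim",
    seed: Optional[int] = None,
    wheel: ColorWheel = WHEEL48,
    offset_probabilities: Optional[Sequence[float]] = None,
) -> Session:
    """Generate an FFR session with conditions intermixed trial by trial.

    Conditions are balanced within consecutive blocks of three trials
    (a random permutation of the three shapes per block), the mean hue
    is uniform over the wheel, and the probe offset is drawn per trial.
    Fully reproducible from ``seed``.
    """
    if n_trials < 1:
        raise StimulusError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    conditions: list = []
    while len(conditions) < n_trials:
        conditions.extend(rng.permutation(CONDITIONS))
    trials = []
    for i in range(n_trials):
        mean_hue = int(rng.integers(wheel.n_hues))
        offset = sample_test_offset(rng, offset_probabilities)
        trials.append(make_trial(conditions[i], mean_hue, offset, wheel))
    return Session(observer_id, trials, seed)
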