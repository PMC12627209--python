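"""Descriptive analysis of FFR responses.

All three stimulus distributions are symmetric around the mean hue, so
responses at +k and -k JND are averaged ("folding"), giving one mean
response per absolute probe offset in {0, 3, ..., 21} JND per observer
and condition.  Folded curves are aggregated across observers with SEM
error bars, and the summary-statistics account is probed by paired
t-tests of the mean-offset response against every other offset: if
observers only knew the mean and variance, the probe at the mean should
always get the highest rating, whatever the distribution's shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import DistributionSpec, Session

__all__ = [
    "FOLDED_OFFSETS",
    "FoldedCurve",
    "PairedTestResult",
    "CurveError",
    "true_count",
    "fold_and_average",
    "aggregate_curves",
    "compare_mean_vs_offsets",
    "curves_to_frame",
]

#: Absolute probe offsets after folding, in JND.
FOLDED_OFFSETS = (0, 3, 6, 9, 12, 15, 18, 21)


class CurveError(ValueError):
    """Invalid or incomplete response-curve input."""


@dataclass(frozen=True)
class FoldedCurve:
    """Per-observer, per-condition mean response at each folded offset."""

    observer_id: str
    condition: str
    mean_response: Mapping[int, float]
    n_trials: Mapping[int, int]

    def values(self) -> np.ndarray:
        return np.array([self.mean_response[k] for k in FOLDED_OFFSETS])


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test of response(0) - response(offset) across observers."""

    offset: int
    t: float
    df: int
    p: float
    cohens_d: float
    zero_variance: bool = False


def true_count(spec: DistributionSpec, abs_offset: int) -> int:
    """Presented disk count at one signed offset ``abs_offset`` JND from the mean.

    Zero beyond the +/-12 JND range; this is the ground-truth curve that a
    noiseless veridical observer reproduces exactly.
    """
    if abs_offset not in FOLDED_OFFSETS:
        raise CurveError(
            f"abs_offset must be one of {FOLDED_OFFSETS}, got {abs_offset}"
        )
    return spec.count_at(abs_offset)


def _sessions_frame(sessions: Union[Session, Iterable[Session]]) -> pd.DataFrame:
    if isinstance(sessions, Session):
        sessions = [sessions]
    rows = []
    for s in sessions:
        for t in s.trials:
            if t.response is None:
                raise CurveError(
                    f"observer {s.observer_id!r} has trials without responses"
                )
            rows.append((s.observer_id, t.condition, abs(t.test_offset), t.response))
    if not rows:
        raise CurveError("no trials supplied")
    return pd.DataFrame(rows, columns=["observer_id", "condition", "abs_offset", "response"])


def fold_and_average(sessions: Union[Session, Iterable[Session]]) -> List[FoldedCurve]:
    """Fold signed offsets to |offset| and average per observer x condition.

    Responses at +k and -k are pooled (offset 0 uses only its own trials).
    Every (observer, condition) cell must cover all folded offsets;
    otherwise the empty cells are listed in the error.
    """
    frame = _sessions_frame(sessions)
    grouped = frame.groupby(["observer_id", "condition", "abs_offset"])["response"]
    means = grouped.mean()
    counts = grouped.size()
    curves = []
    missing = []
    for (obs, cond), _ in frame.groupby(["observer_id", "condition"], sort=False):
        mean_response, n_trials = {}, {}
        for k in FOLDED_OFFSETS:
            key = (obs, cond, k)
            if key not in means.index:
                missing.append(key)
                continue
            mean_response[k] = float(means[key])
            n_trials[k] = int(counts[key])
        curves.append(FoldedCurve(obs, cond, mean_response, n_trials))
    if missing:
        raise CurveError(
            "no trials at (observer, condition, |offset|) cells: "
            + ", ".join(map(str, missing))
        )
    return curves


def curves_to_frame(curves: Iterable[FoldedCurve]) -> pd.DataFrame:
    """Tidy table of folded curves (one row per observer x condition x offset)."""
    rows = [
        (c.observer_id, c.condition, k, c.mean_response[k], c.n_trials[k])
        for c in curves
        for k in FOLDED_OFFSETS
    ]
    return pd.DataFrame(
        rows, columns=["observer_id", "condition", "abs_offset", "mean_response", "n_trials"]
    )


def aggregate_curves(curves: Iterable[FoldedCurve]) -> pd.DataFrame:
    """Across-observer mean curve with SEM per condition and offset.

    SEM = sd / sqrt(n_observers), with sd the ddof=1 standard deviation;
    at least two observers per condition are required.
    """
    curves = list(curves)
    frame = curves_to_frame(curves)
    out_rows = []
    for cond, group in frame.groupby("condition", sort=False):
        n_obs = group["observer_id"].nunique()
        if n_obs < 2:
            raise CurveError(
                f"condition {cond!r} has {n_obs} observer(s); >= 2 required for SEM"
            )
        for k, cell in group.groupby("abs_offset"):
            vals = cell["mean_response"].to_numpy(dtype=float)
            out_rows.append(
                (cond, int(k), vals.mean(), vals.std(ddof=1) / np.sqrt(n_obs), n_obs)
            )
    return pd.DataFrame(
        out_rows, columns=["condition", "abs_offset", "mean_response", "sem", "n_observers"]
    )


def compare_mean_vs_offsets(
    curves: Iterable[FoldedCurve], condition: str, tail: str = "two-sided"
) -> List[PairedTestResult]:
    """Paired t-tests of response(0) - response(k) for every offset k > 0.

    Cohen's d is the mean paired difference over its SD.  Cells with zero
    variance (t undefined) are returned flagged rather than silently
    dropped.
    """
    selected = sorted(
        (c for c in curves if c.condition == condition), key=lambda c: c.observer_id
    )
    if len(selected) < 2:
        raise CurveError(f"need >= 2 observers for condition {condition!r}")
    results = []
    for k in FOLDED_OFFSETS[1:]:
        diffs = np.array([c.mean_response[0] - c.mean_response[k] for c in selected])
        df = len(diffs) - 1
        sd = diffs.std(ddof=1)
        if sd == 0:
            results.append(PairedTestResult(k, np.nan, df, np.nan, np.nan, True))
            continue
        t, p = stats.ttest_1samp(diffs, 0.0, alternative=tail)
        results.append(
            PairedTestResult(k, float(t), df, float(p), float(diffs.mean() / sd))
        )
    return results
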