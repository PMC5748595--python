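"""Assay stability QC: score range, SD/range criterion, borderline region.

The attainable score range of the signature is estimated from a cohort
as the symmetric interval [-max|score|, +max|score|]; its width is
2 * max|score|.  Technical stability of the assay is the sample
standard deviation of repeated control measurements divided by this
range width, with an empirical pass criterion of 10%.  The borderline
region around the decision threshold — within which calls are too
uncertain for concordance assessment — is threshold +/- 1.96 * SD,
using the larger control SD as a conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ScoreDistribution",
    "StabilityReport",
    "BorderlineRegion",
    "estimate_range",
    "assess_control",
    "borderline_region",
    "SD_OVER_RANGE_CRITERION",
]

SD_OVER_RANGE_CRITERION = 0.10


@dataclass(frozen=True)
class ScoreDistribution:
    """Cohort scores and the symmetric range estimated from them."""

    scores: tuple[float, ...]
    range_low: float
    range_high: float
    range_width: float
    conservative: bool  # True when estimated from fewer than 302 samples


@dataclass(frozen=True)
class StabilityReport:
    """SD/range QC verdict for one technical control sample."""

    control_id: str
    n_reps: int
    sd: float
    sd_over_range: float
    passed: bool
    all_calls_consistent: bool


@dataclass(frozen=True)
class BorderlineRegion:
    """Uncertainty zone around the decision threshold."""

    threshold: float
    sd: float
    low: float
    high: float

    def contains(self, score: float | np.ndarray) -> np.ndarray | bool:
        """Inclusive membership test (edge scores count as borderline)."""
        return (score >= self.low) & (score <= self.high)


def estimate_range(scores: Sequence[float], reference_n: int = 302) -> ScoreDistribution:
    """Symmetric score range from a cohort: [-max|s|, +max|s|].

    The result is flagged ``conservative`` when fewer than
    ``reference_n`` scores were supplied — the attainable range can only
    grow with more samples.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValidationError("at least one score is required to estimate the range")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("scores must be finite")
    m = float(np.max(np.abs(arr)))
    return ScoreDistribution(
        scores=tuple(float(s) for s in arr),
        range_low=-m,
        range_high=m,
        range_width=2.0 * m,
        conservative=arr.size < reference_n,
    )


def assess_control(
    scores: Sequence[float],
    range_width: float,
    true_class: str,
    threshold: float,
    control_id: str = "control",
) -> StabilityReport:
    """SD/range stability assessment of one control's replicate scores.

    ``sd`` uses the sample (n-1) formula; ``passed`` requires
    sd / range_width <= 10%.  ``all_calls_consistent`` additionally
    checks that every replicate is called as the control's known class
    under the strict-greater rule.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValidationError("at least 2 replicate scores are required")
    if range_width <= 0:
        raise ValidationError("range_width must be positive")
    if true_class not in ("mutation_like", "wildtype_like"):
        raise ValidationError(f"unknown true_class {true_class!r}")
    sd = float(np.std(arr, ddof=1))
    ratio = sd / range_width
    calls_mut = arr > threshold
    consistent = bool(np.all(calls_mut)) if true_class == "mutation_like" else bool(
        np.all(~calls_mut)
    )
    return StabilityReport(
        control_id=control_id,
        n_reps=int(arr.size),
        sd=sd,
        sd_over_range=ratio,
        passed=ratio <= SD_OVER_RANGE_CRITERION,
        all_calls_consistent=consistent,
    )


def borderline_region(threshold: float, sds: Sequence[float]) -> BorderlineRegion:
    """Borderline zone threshold +/- 1.96 * max(control SDs)."""
    arr = np.asarray(sds, dtype=float)
    if arr.size == 0:
        raise ValidationError("at least one control SD is required")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("control SDs must be finite and >= 0")
    sd = float(np.max(arr))
    half = 1.96 * sd
    return BorderlineRegion(
        threshold=float(threshold), sd=sd, low=float(threshold - half), high=float(threshold + half)
    )
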