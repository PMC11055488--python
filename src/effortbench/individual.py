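"""Intra-individual detectability of an SNR-condition difference.

A condition difference within one participant is called significant when it
exceeds the test-retest variability of the measure.  The threshold is
derived by fitting a normal distribution (maximum likelihood) to the mean
test-retest differences per participant and taking the mean of the absolute
values of its 5th and 95th percentiles; the direction of the test-retest
difference is irrelevant, so a difference this large has only a 5% chance
of arising from session-to-session noise alone.

Because the threshold shrinks as test-retest data accumulate, the
proportion of participants whose condition difference merely has the
expected sign (better in the easier condition) is also reported as the
maximum detection rate of the measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ThresholdResult", "participant_condition_diffs",
           "participant_testretest_diffs", "testretest_threshold",
           "count_detections"]

_Z95 = float(stats.norm.ppf(0.95))  # 1.6449...


@dataclass
class ThresholdResult:
    """Test-retest normal fit, derived threshold, detection counts."""

    testretest_diffs: dict = field(default_factory=dict)
    mu: float = np.nan
    sigma: float = np.nan
    threshold: float = np.nan
    condition_diffs: dict = field(default_factory=dict)
    n_participants: int = 0
    n_significant: int = 0
    n_correct_direction: int = 0
    max_detection_rate: float = np.nan


def participant_condition_diffs(trials: pd.DataFrame, value_col: str,
                                direction: str = "higher_better",
                                hard: str = "+4", easy: str = "+8",
                                condition_col: str = "snr_condition",
                                ) -> pd.Series:
    """Per-participant signed condition differences, pooled over sessions.

    The sign convention is positive = performed better in the easier (+8)
    condition: for ``direction='higher_better'`` (proportions correct) the
    difference is mean(+8) - mean(+4); for ``direction='lower_better'``
    (reaction times) it is mean(+4) - mean(+8), i.e. positive when faster
    at +8.  Reaction times should be learning-corrected first.  Participants
    missing a condition are excluded with a warning.
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    vals = pd.to_numeric(trials[value_col], errors="coerce")
    df = trials.assign(_v=vals).dropna(subset=["_v"])
    means = df.groupby(["participant_id", condition_col])["_v"].mean().unstack()
    for col in (hard, easy):
        if col not in means.columns:
            means[col] = np.nan
    incomplete = means[means[[hard, easy]].isna().any(axis=1)].index
    if len(incomplete):
        warnings.warn(f"participants missing a condition excluded: "
                      f"{sorted(incomplete)}")
    means = means.dropna(subset=[hard, easy])
    if direction == "higher_better":
        return means[easy] - means[hard]
    return means[hard] - means[easy]


def participant_testretest_diffs(trials: pd.DataFrame, value_col: str,
                                 session_col: str = "session") -> pd.Series:
    """Per-participant mean test-minus-retest differences of a measure."""
    vals = pd.to_numeric(trials[value_col], errors="coerce")
    df = trials.assign(_v=vals).dropna(subset=["_v"])
    means = df.groupby(["participant_id", session_col])["_v"].mean().unstack()
    means = means.dropna(subset=["test", "retest"])
    return means["test"] - means["retest"]


def testretest_threshold(diffs: pd.Series | np.ndarray) -> ThresholdResult:
    """Fit a normal to test-retest differences and derive the 5%-risk threshold.

    Maximum-likelihood fit (sd with divisor n); the threshold is the mean of
    the absolute 5th and 95th percentiles of the fitted normal,
    ``(|mu - 1.645 sigma| + |mu + 1.645 sigma|) / 2``, which reduces to
    ``max(1.645 sigma, |mu|)`` and is invariant to the sign of every input.
    """
    values = np.asarray(pd.Series(diffs).to_numpy(), dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 3:
        raise ValueError(f"need >= 3 participants to fit the test-retest "
                         f"normal, got {len(values)}")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma == 0:
        warnings.warn("degenerate test-retest fit (sigma = 0); threshold "
                      "equals |mu|")
    q05 = mu - _Z95 * sigma
    q95 = mu + _Z95 * sigma
    threshold = 0.5 * (abs(q05) + abs(q95))
    result = ThresholdResult(mu=mu, sigma=sigma, threshold=float(threshold))
    if isinstance(diffs, pd.Series):
        result.testretest_diffs = {k: float(v) for k, v in diffs.items()}
    return result


def count_detections(condition_diffs: pd.Series | np.ndarray,
                     threshold_result: ThresholdResult | float,
                     ) -> ThresholdResult:
    """Count participants beyond the threshold and in the expected direction.

    ``n_significant`` counts condition differences larger than the threshold
    in the correct direction only; ``n_correct_direction`` counts positive
    differences regardless of size, and their proportion is the maximum
    detection rate.
    """
    if isinstance(threshold_result, ThresholdResult):
        result = threshold_result
    else:
        result = ThresholdResult(threshold=float(threshold_result))
    if result.threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {result.threshold}")
    diffs = pd.Series(condition_diffs).astype(float)
    result.condition_diffs = {k: float(v) for k, v in diffs.items()}
    result.n_participants = int(diffs.notna().sum())
    result.n_significant = int((diffs > result.threshold).sum())
    result.n_correct_direction = int((diffs > 0).sum())
    result.max_detection_rate = (result.n_correct_direction
                                 / result.n_participants
                                 if result.n_participants else np.nan)
    return result
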