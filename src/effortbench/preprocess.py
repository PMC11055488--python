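"""Data conditioning ahead of model fitting.

Four steps, applied to tidy trial tables:

1. response-validity filtering for the sentence verification test (SVT):
   a response counts only when given between 0.8 s before and 3.0 s after
   the end of the sentence (inclusive);
2. shifting raw reaction times by +0.8 s so the earliest valid response maps
   to 0 s and a Gamma law applies;
3. item/list outlier detection: fit a pooled distribution (binomial for
   binary outcomes, Gamma for reaction times) to all trials in the most
   difficult condition and flag units whose mean is in the two-sided 1% tail
   of its sampling distribution under the pooled fit;
4. learning-effect correction for SVT reaction times: a linear model of
   per-participant retest means on test means provides an individual
   correction factor that is added to every retest trial.

None of the steps deletes rows; trials are flagged or get adjusted columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import RT_SHIFT_S, RT_WINDOW_S

__all__ = ["OutlierReport", "LearningModel", "validate_svt_responses",
           "shift_rt", "detect_item_outliers", "correct_learning_effect"]

#: Two-sided tail probability below which an item/list is called an outlier.
OUTLIER_ALPHA = 0.01


@dataclass(frozen=True)
class OutlierReport:
    """Outlier assessment for one item or list."""

    unit_id: object
    n_trials: int
    unit_mean: float
    pooled_fit: dict
    tail_probability: float
    flagged: bool


@dataclass(frozen=True)
class LearningModel:
    """Linear relation between per-participant test and retest mean RTs.

    ``retest_mean = intercept_s + slope * test_mean``; the individual
    correction factor ``test_mean_i - (intercept_s + slope * test_mean_i)``
    is added to each retest trial so the corrected retest data sit at the
    test session's expected level.
    """

    intercept_s: float
    slope: float
    r_squared: float
    correction_per_participant: dict = field(default_factory=dict)


def validate_svt_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Recompute validity flags; invalid trials get a missing outcome.

    A trial is valid iff a response is present and its raw RT lies in the
    inclusive window [-0.8 s, 3.0 s] relative to sentence end.  Invalid
    trials are retained with ``response='missing'`` and null outcome columns.
    """
    out = trials.copy()
    rt = out["rt_raw_s"].to_numpy(dtype=float)
    has_response = out["response"].notna() & (out["response"] != "missing")
    in_window = (rt >= RT_WINDOW_S[0]) & (rt <= RT_WINDOW_S[1])
    valid = has_response & np.nan_to_num(in_window, nan=False)
    out["valid"] = valid
    out.loc[~valid, "response"] = "missing"
    if "answer_correct" in out:
        out["answer_correct"] = out["answer_correct"].astype("boolean")
        out.loc[~valid, "answer_correct"] = pd.NA
    return out


def shift_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``rt_shifted_s = rt_raw_s + 0.8`` for valid trials.

    After the shift, 0 s corresponds to the earliest response that counts and
    0.8 s to the end of the sentence.  A valid trial with a raw RT below
    -0.8 s is an internal inconsistency and raises.
    """
    out = trials.copy()
    rt = out["rt_raw_s"].to_numpy(dtype=float)
    valid = out["valid"].to_numpy(dtype=bool)
    if np.any(valid & (rt < RT_WINDOW_S[0])):
        raise ValueError("valid trial with rt_raw_s below the window start; "
                         "run validate_svt_responses first")
    out["rt_shifted_s"] = np.where(valid, rt + RT_SHIFT_S, np.nan)
    return out


def detect_item_outliers(trials: pd.DataFrame, variable: str,
                         value_col: str, unit_col: str,
                         condition_col: str = "snr_condition",
                         hardest: str = "+4",
                         alpha: float = OUTLIER_ALPHA) -> list[OutlierReport]:
    """Flag items/lists whose mean score is extreme under the pooled fit.

    Only trials from the most difficult condition are pooled.  For
    ``variable='binary'`` the pooled fit is a binomial success probability
    (maximum likelihood = pooled proportion) and each unit's tail probability
    is the two-sided exact binomial tail of a count at least as extreme as
    observed given the unit's own trial count.  For ``variable='rt'`` the
    pooled fit is a Gamma distribution (MLE, location 0) and the unit's mean
    of n trials is referred to the Gamma(n*shape, scale/n) distribution of a
    mean of n iid draws.  Units with a two-sided tail probability < ``alpha``
    are flagged.
    """
    if variable not in ("binary", "rt"):
        raise ValueError(f"variable must be 'binary' or 'rt', got {variable!r}")
    pool = trials[trials[condition_col] == hardest]
    values = pd.to_numeric(pool[value_col], errors="coerce")
    pool = pool.assign(_value=values).dropna(subset=["_value"])
    units = pool.groupby(unit_col, sort=True)["_value"]
    if units.ngroups < 2:
        raise ValueError("outlier detection needs at least 2 units")

    counts = units.count()
    sums = units.sum()
    ids = counts.index.to_numpy()
    n_arr = counts.to_numpy(dtype=float)
    if variable == "binary":
        p_hat = float(pool["_value"].mean())
        fit = {"family": "binomial", "p": p_hat}
        x_arr = sums.to_numpy(dtype=float)
        lo = stats.binom.cdf(x_arr, n_arr, p_hat)
        hi = stats.binom.sf(x_arr - 1, n_arr, p_hat)
        means = x_arr / n_arr
    else:
        rts = pool["_value"].to_numpy(dtype=float)
        if np.any(rts <= 0):
            raise ValueError("Gamma outlier fit requires strictly positive "
                             "(shifted) reaction times")
        shape, _, scale = stats.gamma.fit(rts, floc=0)
        fit = {"family": "gamma", "shape": float(shape), "scale": float(scale)}
        means = sums.to_numpy(dtype=float) / n_arr
        # mean of n iid Gamma(k, theta) draws ~ Gamma(n*k, theta/n)
        lo = stats.gamma.cdf(means, n_arr * shape, scale=scale / n_arr)
        hi = stats.gamma.sf(means, n_arr * shape, scale=scale / n_arr)
    tails = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
    return [OutlierReport(uid, int(n), float(m), fit, float(t), bool(t < alpha))
            for uid, n, m, t in zip(ids, n_arr, means, tails)]


def outlier_flags(reports: list[OutlierReport]) -> set:
    """Unit ids flagged as outliers."""
    return {r.unit_id for r in reports if r.flagged}


def correct_learning_effect(trials: pd.DataFrame,
                            rt_col: str = "rt_shifted_s",
                            ) -> tuple[pd.DataFrame, LearningModel]:
    """Correct retest reaction times for the between-session learning effect.

    Per-participant mean RTs are computed for each session, collapsed across
    SNR conditions and condition order; retest means are regressed on test
    means by least squares and each participant's residual-based correction
    (``test_mean - fitted_retest_mean``) is added to all of their retest
    trials.  Test-session trials are unchanged.  Participants missing a
    session are excluded from the fit (with a warning) and left uncorrected.
    """
    valid = trials[trials["valid"].astype(bool) & trials[rt_col].notna()]
    means = (valid.groupby(["participant_id", "session"])[rt_col]
             .mean().unstack("session"))
    complete = means.dropna(subset=["test", "retest"]) if {
        "test", "retest"}.issubset(means.columns) else means.iloc[0:0]
    skipped = set(means.index) - set(complete.index)
    if skipped:
        warnings.warn(f"participants missing a session excluded from the "
                      f"learning fit: {sorted(skipped)}")
    if len(complete) < 2:
        raise ValueError("learning correction needs >= 2 participants with "
                         "both sessions")

    x = complete["test"].to_numpy(dtype=float)
    y = complete["retest"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    corrections = dict(zip(complete.index, x - fitted))

    out = trials.copy()
    corr = out["participant_id"].map(corrections).fillna(0.0)
    is_retest = (out["session"] == "retest").to_numpy()
    out[rt_col] = out[rt_col] + np.where(is_retest, corr, 0.0)
    if rt_col == "rt_shifted_s" and "rt_raw_s" in out:
        out["rt_raw_s"] = out["rt_shifted_s"] - RT_SHIFT_S
    model = LearningModel(float(intercept), float(slope), float(r2),
                          {k: float(v) for k, v in corrections.items()})
    return out, model
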