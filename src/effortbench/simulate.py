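"""Synthetic cohorts and trial-level data for two behavioral listening-effort tests.

The generator emulates the data-generating structure assumed by the analysis
pipeline: each virtual cochlear-implant (CI) listener carries a psychometric
function for speech-in-noise word recognition (variable 50% speech reception
threshold, sub-100% asymptote), and produces

* SVT trials — sentence verification (true/false categorization) with reaction
  times that follow a shifted-Gamma law relative to sentence end, window
  censoring that yields missing responses, and a guess bias toward "false"
  when the sentence was not understood;
* SWIRT trials — per-sentence final-word repetition driven by the psychometric
  function, and end-of-list recall with strong list-position effects.

Both tests are measured at two SNR conditions placed relative to the
listener's own threshold (SRT50 + 4 dB and SRT50 + 8 dB), in a test and a
retest session, with a multiplicative between-session learning effect on
reaction time.

Trial tables are returned as tidy :class:`pandas.DataFrame` objects, one row
per trial, suitable for direct CSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache as _lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PsychometricListener",
    "CohortConfig",
    "SVT_COLUMNS",
    "SWIRT_COLUMNS",
    "make_cohort",
    "p_correct",
    "simulate_word_score",
    "simulate_svt_session",
    "simulate_swirt_session",
    "simulate_experiment",
]

#: Offset (seconds) added to raw reaction times (measured from sentence end)
#: so that the earliest valid response maps to 0 s and a Gamma law applies.
RT_SHIFT_S = 0.8

#: Valid-response window relative to sentence end, inclusive, in seconds.
RT_WINDOW_S = (-0.8, 3.0)

SVT_COLUMNS = [
    "participant_id", "session", "order", "snr_condition", "item_id",
    "item_truth", "response", "answer_correct", "rt_raw_s", "rt_shifted_s",
    "valid",
]

SWIRT_COLUMNS = [
    "participant_id", "session", "order", "snr_condition", "list_id",
    "list_length", "position_in_list", "position_category", "word_type",
    "repeated_correct", "recalled_correct",
]

_WORD_TYPES = ("noun", "verb", "adjective", "other")
_WORD_TYPE_PROBS = (0.50, 0.22, 0.16, 0.12)

# Substream tags: every random draw runs on a named substream spawned from
# (seed, participant_index, tag, ...) so that adding participants or sessions
# never perturbs draws made for existing ones.
_TAG_COHORT = 1
_TAG_SVT = 2
_TAG_SWIRT = 3
_TAG_ITEMS = 4
_TAG_TRAINING = 5
_TAG_WORDSCORE = 6

_SESSION_CODE = {"test": 0, "retest": 1}
_CONDITION_CODE = {"+4": 0, "+8": 1}
_ORDER_CODE = {"hard_first": 0, "easy_first": 1}


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


@dataclass(frozen=True)
class PsychometricListener:
    """A virtual participant: intelligibility curve plus response parameters.

    The intelligibility curve is a four-parameter logistic re-anchored so the
    50% word-score point sits exactly at ``srt50_db``::

        p(snr) = guess + (p_max - guess) / (1 + A * exp(-growth * (snr - srt50)))

    with ``A = (p_max - guess) / (0.5 - guess) - 1`` so ``p(srt50) = 0.5``.
    """

    participant_id: int
    srt50_db: float
    growth_rate: float = 0.5
    p_max: float = 0.95
    guess_rate: float = 0.0
    rt_base_log: float = 0.30
    learning_gain: float = 0.93
    recall_ability: float = 0.0
    session_noise_sd: float = 0.06
    word_score_quiet: float = 0.95
    training_recall: int = 3
    repeat_shift_db: float = 0.0
    svt_accuracy_shift_db: float = 0.0

    def __post_init__(self) -> None:
        if not (self.guess_rate < 0.5 < self.p_max):
            raise ValueError(
                f"listener requires guess_rate < 0.5 < p_max, got "
                f"guess_rate={self.guess_rate}, p_max={self.p_max}"
            )
        if self.growth_rate <= 0:
            raise ValueError(f"growth_rate must be positive, got {self.growth_rate}")
        if not 0 <= self.training_recall <= 5:
            raise ValueError(f"training_recall must be in 0..5, got {self.training_recall}")

    @property
    def list_length(self) -> int:
        """SWIRT list length: 5 sentences unless all 5 training words recalled."""
        return 7 if self.training_recall == 5 else 5


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic CI cohort.

    Defaults are calibrated so that, at large simulated n, the group
    descriptives match the observed study values: SRT50 of 3.1 +/- 2.9 dB,
    ~2.2% missing SVT responses, SVT accuracy 93.1% (false) vs 86.8% (true)
    sentences, SWIRT recall by list position 92.2/64.4/57.0% (last/first/
    middle), a per-participant repeat-proportion condition difference of
    11.6 percentage points and a recall difference of 3.8 points.
    """

    n_participants: int = 18
    seed: int = 0

    # population intelligibility
    srt50_mean_db: float = 3.1
    srt50_sd_db: float = 2.9
    growth_rate: float = 0.5
    p_max_low: float = 0.88
    p_max_high: float = 0.99
    guess_rate: float = 0.0
    quiet_n_words: int = 78  # 13 training sentences, median 6 words

    # SVT accuracy: lapse when understood, biased guess otherwise
    svt_lapse_rate: float = 0.043
    false_guess_bias: float = 0.748
    svt_item_sd_db: float = 1.0

    # SVT reaction time (shifted-Gamma on log-mean scale)
    rt_base_log_mean: float = 0.482
    rt_participant_sd: float = 0.25
    rt_shape: float = 4.0
    rt_condition_effect: float = 0.05   # log-RT increase in the harder (+4) condition
    rt_order_effect: float = 0.03      # log-RT offset when the hard condition came first
    rt_answer_effect: float = -0.12    # log-RT offset for correct answers
    rt_truth_effect: float = -0.04     # log-RT offset for false sentences
    rt_item_sd: float = 0.05
    session_noise_sd: float = 0.06
    learning_gain_mean: float = 0.93   # multiplicative per-session RT reduction
    learning_gain_sd_log: float = 0.05

    # SWIRT repetition: psychometric function at a difficulty-shifted SNR
    repeat_shift_db: float = 0.72      # final words harder than running words
    repeat_participant_sd_db: float = 0.75
    repeat_item_sd_db: float = 0.5
    repeat_session_shift_db: float = 0.247  # intelligibility learning, retest easier

    # SWIRT recall: logistic on position / condition / session / participant
    recall_intercept_first: float = 0.423
    recall_intercept_middle: float = -0.039
    recall_intercept_last: float = 2.465
    recall_condition_effect: float = 0.205  # logit boost in the easier (+8) condition
    recall_session_effect: float = 0.140    # logit boost at retest
    recall_participant_sd: float = 0.80
    recall_list_sd: float = 0.30
    recall_word_type_effects: tuple[float, ...] = (0.18, 0.10, 0.0, -0.05)
    recall_training_logit: float = 1.2

    # item/list pools
    n_svt_items: int = 190
    n_swirt_lists: int = 34

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"n_participants must be >= 1, got {self.n_participants}")
        for name in ("srt50_sd_db", "rt_participant_sd", "session_noise_sd",
                     "recall_participant_sd", "recall_list_sd", "svt_item_sd_db",
                     "repeat_participant_sd_db", "repeat_item_sd_db", "rt_item_sd",
                     "learning_gain_sd_log"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("svt_lapse_rate", "false_guess_bias", "guess_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if not 0.5 < self.p_max_low <= self.p_max_high <= 1.0:
            raise ValueError(
                f"p_max range must satisfy 0.5 < low <= high <= 1, got "
                f"[{self.p_max_low}, {self.p_max_high}]"
            )
        if self.rt_shape <= 0:
            raise ValueError(f"rt_shape must be positive, got {self.rt_shape}")


def make_cohort(config: CohortConfig) -> list[PsychometricListener]:
    """Draw a cohort of virtual listeners from the configured population.

    Deterministic given ``config.seed``; each participant runs on its own
    random substream, so growing ``n_participants`` extends the cohort
    without changing earlier listeners.
    """
    listeners = []
    for i in range(config.n_participants):
        rng = _rng(config.seed, i, _TAG_COHORT)
        srt50 = config.srt50_mean_db + config.srt50_sd_db * rng.standard_normal()
        p_max = rng.uniform(config.p_max_low, config.p_max_high)
        quiet_score = rng.binomial(config.quiet_n_words, p_max) / config.quiet_n_words
        ability = config.recall_participant_sd * rng.standard_normal()
        gain = config.learning_gain_mean * np.exp(
            config.learning_gain_sd_log * rng.standard_normal())
        listener = PsychometricListener(
            participant_id=i,
            srt50_db=float(srt50),
            growth_rate=config.growth_rate,
            p_max=float(p_max),
            guess_rate=config.guess_rate,
            rt_base_log=float(config.rt_base_log_mean
                              + config.rt_participant_sd * rng.standard_normal()),
            learning_gain=float(gain),
            recall_ability=float(ability),
            session_noise_sd=config.session_noise_sd,
            word_score_quiet=float(quiet_score),
            training_recall=_simulate_training_recall(ability, config, rng),
            repeat_shift_db=float(config.repeat_participant_sd_db
                                  * rng.standard_normal()),
        )
        listeners.append(listener)
    return listeners


def _simulate_training_recall(ability: float, config: CohortConfig,
                              rng: np.random.Generator) -> int:
    """Recall count for the 5-sentence training list in quiet (sets list length)."""
    p = _expit(config.recall_training_logit + ability)
    return int(rng.binomial(5, p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def p_correct(listener: PsychometricListener, snr_db) -> float | np.ndarray:
    """Word-score probability at a given SNR (dB).

    Four-parameter logistic anchored so ``p_correct(srt50_db) == 0.5``.
    Strictly increasing in SNR whenever ``guess_rate < p_max``; bounded in
    ``[guess_rate, p_max]``.
    """
    snr = np.asarray(snr_db, dtype=float)
    g, pm = listener.guess_rate, listener.p_max
    a = (pm - g) / (0.5 - g) - 1.0  # anchors the 50% point at srt50_db
    with np.errstate(over="ignore"):
        p = g + (pm - g) / (1.0 + a * np.exp(-listener.growth_rate
                                             * (snr - listener.srt50_db)))
    return float(p) if np.isscalar(snr_db) else p


def simulate_word_score(listener: PsychometricListener, snr_db: float,
                        n_words: int | None = None,
                        rng: np.random.Generator | int | None = None) -> float:
    """Proportion of words repeated correctly for one sentence at ``snr_db``.

    When ``n_words`` is not given the sentence length is sampled uniformly
    from 5..9 words (median 6), matching the sentence material.
    """
    rng = np.random.default_rng(rng)
    if n_words is None:
        n_words = int(rng.integers(5, 10))
    if n_words < 1:
        raise ValueError(f"n_words must be >= 1, got {n_words}")
    p = p_correct(listener, snr_db)
    return float(rng.binomial(n_words, p) / n_words)


# ---------------------------------------------------------------------------
# item / list property tables (deterministic per config seed)

def svt_item_table(config: CohortConfig) -> pd.DataFrame:
    """Per-item truth value and difficulty/RT offsets, fixed per config seed."""
    return _svt_item_table_cached(config).copy()


@_lru_cache(maxsize=8)
def _svt_item_table_cached(config: CohortConfig) -> pd.DataFrame:
    rng = _rng(config.seed, 0, _TAG_ITEMS, 1)
    n = config.n_svt_items
    return pd.DataFrame({
        "item_id": np.arange(n),
        # half true, half false (true/false sentence pairs)
        "item_truth": np.arange(n) % 2 == 0,
        "item_shift_db": config.svt_item_sd_db * rng.standard_normal(n),
        "item_rt_offset": config.rt_item_sd * rng.standard_normal(n),
    })


def swirt_list_table(config: CohortConfig) -> pd.DataFrame:
    """Per-list recall offset and per-position word properties."""
    return _swirt_list_table_cached(config).copy()


@_lru_cache(maxsize=8)
def _swirt_list_table_cached(config: CohortConfig) -> pd.DataFrame:
    rng = _rng(config.seed, 0, _TAG_ITEMS, 2)
    rows = []
    for list_id in range(config.n_swirt_lists):
        list_offset = config.recall_list_sd * rng.standard_normal()
        word_types = rng.choice(_WORD_TYPES, size=7, p=_WORD_TYPE_PROBS)
        word_shifts = config.repeat_item_sd_db * rng.standard_normal(7)
        for pos in range(1, 8):
            rows.append((list_id, pos, word_types[pos - 1],
                         float(word_shifts[pos - 1]), float(list_offset)))
    return pd.DataFrame(rows, columns=[
        "list_id", "position_in_list", "word_type", "word_shift_db",
        "list_offset"])


# ---------------------------------------------------------------------------
# SVT

def simulate_svt_session(listener: PsychometricListener, session: str,
                         order: str, snr_condition: str, n_items: int = 30,
                         seed: int | None = None,
                         config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate one SVT block: ``n_items`` true/false sentences in one SNR condition.

    Half the items are true, half false.  Correct categorization follows a
    two-stage process: with probability given by the psychometric function the
    sentence is understood and answered correctly up to a small lapse rate;
    otherwise the listener guesses, with a bias toward answering "false".
    Shifted reaction times follow a Gamma law whose log-mean carries
    condition, session (learning), order, correctness and truth-type terms;
    responses drawn beyond the 3.0 s window become missing.
    """
    config = config if config is not None else CohortConfig()
    if n_items % 2 != 0:
        raise ValueError(f"n_items must be even (half true, half false), got {n_items}")
    _check_labels(session, order, snr_condition)
    seed = config.seed if seed is None else seed

    items = svt_item_table(config)
    rng = _rng(seed, listener.participant_id, _TAG_SVT,
               _SESSION_CODE[session], _CONDITION_CODE[snr_condition])

    # sample items: n/2 true, n/2 false, without replacement within the block
    true_pool = items.loc[items.item_truth, "item_id"].to_numpy()
    false_pool = items.loc[~items.item_truth, "item_id"].to_numpy()
    chosen = np.concatenate([rng.choice(true_pool, n_items // 2, replace=False),
                             rng.choice(false_pool, n_items // 2, replace=False)])
    rng.shuffle(chosen)
    block = items.set_index("item_id").loc[chosen].reset_index()

    snr = listener.srt50_db + (4.0 if snr_condition == "+4" else 8.0)
    u = p_correct_at(listener, snr + block.item_shift_db.to_numpy()
                     + listener.svt_accuracy_shift_db)
    understood = rng.random(n_items) < u
    lapse = rng.random(n_items) < config.svt_lapse_rate
    guess_false = rng.random(n_items) < config.false_guess_bias

    truth = block.item_truth.to_numpy()
    # understood -> truthful answer unless lapse flips it; else biased guess
    resp_false = np.where(understood, np.where(lapse, truth, ~truth), guess_false)
    response_is_true = ~resp_false
    correct = response_is_true == truth

    session_shift = (listener.session_noise_sd
                     * _rng(seed, listener.participant_id, _TAG_SVT, 9,
                            _SESSION_CODE[session]).standard_normal())
    log_mu = (listener.rt_base_log
              + config.rt_condition_effect * (snr_condition == "+4")
              + np.log(listener.learning_gain) * (session == "retest")
              + config.rt_order_effect * (order == "hard_first")
              + config.rt_answer_effect * correct
              + config.rt_truth_effect * (~truth)
              + block.item_rt_offset.to_numpy()
              + session_shift)
    mu = np.exp(log_mu)
    k = config.rt_shape
    rt_shifted = rng.gamma(k, mu / k)
    rt_raw = rt_shifted - RT_SHIFT_S

    missing = rt_raw > RT_WINDOW_S[1]  # no response within the window
    response = np.where(missing, "missing",
                        np.where(response_is_true, "true", "false"))
    out = pd.DataFrame({
        "participant_id": listener.participant_id,
        "session": session,
        "order": order,
        "snr_condition": snr_condition,
        "item_id": block.item_id.to_numpy(),
        "item_truth": truth,
        "response": response,
        "answer_correct": pd.array(np.where(missing, pd.NA, correct),
                                   dtype="boolean"),
        "rt_raw_s": np.where(missing, np.nan, rt_raw),
        "rt_shifted_s": np.where(missing, np.nan, rt_shifted),
        "valid": ~missing,
    })
    return out[SVT_COLUMNS]


def p_correct_at(listener: PsychometricListener, snr_db) -> np.ndarray:
    """Vectorized :func:`p_correct` over an array of SNRs."""
    return np.asarray(p_correct(listener, np.asarray(snr_db, dtype=float)))


# ---------------------------------------------------------------------------
# SWIRT

def simulate_swirt_session(listener: PsychometricListener, session: str,
                           order: str, snr_condition: str, n_lists: int = 5,
                           training_recall: int | None = None,
                           seed: int | None = None,
                           config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate one SWIRT block: ``n_lists`` sentence lists in one SNR condition.

    List length is 5 sentences when 0-4 training words were recalled and 7
    when all 5 were (ceiling avoidance).  Final-word repetition is Bernoulli
    with probability from the psychometric function at the condition SNR
    shifted by a final-word difficulty offset; end-of-list recall is Bernoulli
    on a logit scale with position (large last-item boost), condition,
    session, word-type, list and participant terms.  A final word that was
    misheard but whose substituted token is reproduced at recall counts as a
    correct recall, so recall success is modelled independently of repetition
    success.
    """
    config = config if config is not None else CohortConfig()
    _check_labels(session, order, snr_condition)
    if n_lists < 1:
        raise ValueError(f"n_lists must be >= 1, got {n_lists}")
    if training_recall is None:
        training_recall = listener.training_recall
    if not 0 <= training_recall <= 5:
        raise ValueError(f"training_recall must be in 0..5, got {training_recall}")
    seed = config.seed if seed is None else seed

    list_length = 7 if training_recall == 5 else 5
    lists = swirt_list_table(config)
    rng = _rng(seed, listener.participant_id, _TAG_SWIRT,
               _SESSION_CODE[session], _CONDITION_CODE[snr_condition])
    chosen = rng.choice(config.n_swirt_lists, n_lists, replace=False)

    snr = listener.srt50_db + (4.0 if snr_condition == "+4" else 8.0)
    wt_effect = dict(zip(_WORD_TYPES, config.recall_word_type_effects))

    frames = []
    for list_id in chosen:
        sub = lists[(lists.list_id == list_id)
                    & (lists.position_in_list <= list_length)]
        pos = sub.position_in_list.to_numpy()
        pos_cat = np.where(pos == 1, "first",
                           np.where(pos == list_length, "last", "middle"))
        p_rep = p_correct_at(
            listener,
            snr - config.repeat_shift_db - listener.repeat_shift_db
            - sub.word_shift_db.to_numpy()
            + config.repeat_session_shift_db * (session == "retest"))
        repeated = rng.random(list_length) < p_rep

        intercept = np.select(
            [pos_cat == "first", pos_cat == "last"],
            [config.recall_intercept_first, config.recall_intercept_last],
            default=config.recall_intercept_middle)
        logit = (intercept
                 + config.recall_condition_effect * (snr_condition == "+8")
                 + config.recall_session_effect * (session == "retest")
                 + listener.recall_ability
                 + sub.list_offset.to_numpy()
                 + np.array([wt_effect[w] for w in sub.word_type]))
        recalled = rng.random(list_length) < _expit(logit)

        frames.append(pd.DataFrame({
            "participant_id": listener.participant_id,
            "session": session,
            "order": order,
            "snr_condition": snr_condition,
            "list_id": list_id,
            "list_length": list_length,
            "position_in_list": pos,
            "position_category": pos_cat,
            "word_type": sub.word_type.to_numpy(),
            "repeated_correct": repeated,
            "recalled_correct": recalled,
        }))
    return pd.concat(frames, ignore_index=True)[SWIRT_COLUMNS]


def _check_labels(session: str, order: str, snr_condition: str) -> None:
    if session not in _SESSION_CODE:
        raise ValueError(f"session must be 'test' or 'retest', got {session!r}")
    if order not in _ORDER_CODE:
        raise ValueError(f"order must be 'hard_first' or 'easy_first', got {order!r}")
    if snr_condition not in _CONDITION_CODE:
        raise ValueError(f"snr_condition must be '+4' or '+8', got {snr_condition!r}")


# ---------------------------------------------------------------------------
# whole-experiment convenience

def simulate_experiment(config: CohortConfig, n_svt_items: int = 30,
                        n_swirt_lists: int = 5,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, list[PsychometricListener]]:
    """Simulate the full test-retest design for a cohort.

    Each participant is measured in both SNR conditions in both sessions;
    the order of SNR conditions alternates across participants
    (counterbalancing).  Returns ``(svt_trials, swirt_trials, cohort)``.
    """
    cohort = make_cohort(config)
    svt_frames, swirt_frames = [], []
    for listener in cohort:
        order = "hard_first" if listener.participant_id % 2 == 0 else "easy_first"
        for session in ("test", "retest"):
            for cond in ("+4", "+8"):
                svt_frames.append(simulate_svt_session(
                    listener, session, order, cond, n_items=n_svt_items,
                    config=config))
                swirt_frames.append(simulate_swirt_session(
                    listener, session, order, cond, n_lists=n_swirt_lists,
                    config=config))
    return (pd.concat(svt_frames, ignore_index=True),
            pd.concat(swirt_frames, ignore_index=True),
            cohort)
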