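"""Stochastic-approximation adaptive procedure for the 50% speech reception threshold.

The SRT50 is the SNR at which a listener repeats 50% of the words of a
sentence correctly.  It is measured adaptively: the first sentence is
presented at +2 dB SNR, and after each sentence the SNR moves by
``4 * (0.5 - word_score)`` dB, so the step shrinks as the word score
approaches the 50% target and is bounded in [-2, +2] dB.  A track presents
26 sentences; the 27th SNR is computed from the 26th sentence's score but
never presented.  The SRT50 estimate is the arithmetic mean of SNRs 5
through 27 (1-based), discarding the early burn-in of the staircase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["AdaptiveTrack", "next_snr", "run_track", "estimate_srt50",
           "INITIAL_SNR_DB", "N_SENTENCES", "listener_responder"]

INITIAL_SNR_DB = 2.0
N_SENTENCES = 26
#: First SNR index (1-based) included in the SRT50 average.
_FIRST_AVERAGED = 5


@dataclass(frozen=True)
class AdaptiveTrack:
    """One adaptive run: 27 presented/computed SNRs, 26 word scores, estimate."""

    snr_sequence_db: tuple[float, ...]
    word_scores: tuple[float, ...]
    srt50_db: float

    def __post_init__(self) -> None:
        if len(self.snr_sequence_db) != len(self.word_scores) + 1:
            raise ValueError("snr sequence must be one longer than the word scores")


def next_snr(current_snr_db: float, prev_word_score: float) -> float:
    """SNR for the next sentence: ``current + 4 * (0.5 - prev_word_score)`` dB.

    The step is bounded in [-2, +2] dB since word scores are proportions.
    """
    if not 0.0 <= prev_word_score <= 1.0:
        raise ValueError(
            f"word score must be a proportion in [0, 1], got {prev_word_score}")
    return current_snr_db + 4.0 * (0.5 - prev_word_score)


def run_track(responder: Callable[[float], float],
              n_sentences: int = N_SENTENCES,
              start_snr_db: float = INITIAL_SNR_DB) -> AdaptiveTrack:
    """Run one adaptive track against a responder.

    ``responder(snr_db)`` must return the word-score proportion for a sentence
    presented at that SNR (e.g. a closure over
    :func:`effortbench.simulate.simulate_word_score`).  The returned track has
    ``n_sentences + 1`` SNRs: the last one is computed from the final score
    but never presented.
    """
    if n_sentences < _FIRST_AVERAGED:
        raise ValueError(
            f"need at least {_FIRST_AVERAGED} sentences, got {n_sentences}")
    snrs = [float(start_snr_db)]
    scores: list[float] = []
    for i in range(n_sentences):
        try:
            score = float(responder(snrs[-1]))
        except Exception as exc:
            raise RuntimeError(f"responder failed at sentence {i + 1}") from exc
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"responder returned {score} at sentence {i + 1}; "
                "word scores must lie in [0, 1]")
        scores.append(score)
        snrs.append(next_snr(snrs[-1], score))
    track = AdaptiveTrack(tuple(snrs), tuple(scores), float("nan"))
    return AdaptiveTrack(track.snr_sequence_db, track.word_scores,
                         estimate_srt50(track))


def estimate_srt50(track: AdaptiveTrack) -> float:
    """SRT50 estimate: mean of SNRs 5 through the end of the sequence (1-based)."""
    seq = np.asarray(track.snr_sequence_db, dtype=float)
    if len(seq) < _FIRST_AVERAGED + 1:
        raise ValueError(f"track too short to estimate SRT50 (length {len(seq)})")
    return float(seq[_FIRST_AVERAGED - 1:].mean())


def listener_responder(listener, rng: np.random.Generator | int | None = None,
                       n_words: int | None = None) -> Callable[[float], float]:
    """Responder closure over a simulated listener's word scores.

    Sentence length is resampled per sentence (uniform 5..9 words) when
    ``n_words`` is not fixed.
    """
    from .simulate import simulate_word_score

    rng = np.random.default_rng(rng)
    return lambda snr_db: simulate_word_score(listener, snr_db,
                                              n_words=n_words, rng=rng)
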