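"""The nine per-participant linguistic measures.

Four dimensions are covered: lexical richness (type-token ratio, mean
lexical frequency), fluency (mean length of utterance, mean gap duration,
mean silent-and-filled pause duration, pause-to-word ratio), frequency of
personal pronouns, and the psychological lexicon (affective words, words
expressing cognitive mechanisms).

Conventions baked in here:

* a silent pause is a within-turn silence *strictly longer* than 200 ms;
* a gap is the latency between the interviewer's turn end and the
  participant's turn start — overlapping starts produce no gap, and gaps
  are never counted as pauses;
* fillers (uhm, ehm, ...) are filled pauses, excluded from every
  word-denominated count;
* types are unique normalized surface forms;
* the mean lexical frequency is a token-wise mean over in-lexicon tokens,
  with out-of-vocabulary tokens excluded and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .corpus_io import FEATURE_COLUMNS, Interview, Token
from .lexicon import (
    CAT_AFFECTIVE,
    CAT_COGMECH,
    CAT_PRONOUNS,
    CategoryDictionary,
    FrequencyLexicon,
    match_categories,
)

logger = logging.getLogger(__name__)

#: A within-turn silence must exceed this to count as a silent pause.
DEFAULT_SILENT_PAUSE_THRESHOLD_MS = 200


class FeatureError(ValueError):
    """Interview cannot support a measure (no timing, no words, ...)."""


@dataclass(frozen=True)
class PauseInventory:
    """Silent pauses, filled pauses, and turn-initial gaps of one interview."""

    silent_pauses_ms: tuple[int, ...]
    filled_pauses_ms: tuple[int, ...]
    gaps_ms: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.filled_pauses_ms + self.gaps_ms):
            raise FeatureError("negative pause/gap duration")

    @property
    def n_pauses(self) -> int:
        return len(self.silent_pauses_ms) + len(self.filled_pauses_ms)

    @property
    def total_pause_ms(self) -> int:
        return sum(self.silent_pauses_ms) + sum(self.filled_pauses_ms)


@dataclass(frozen=True)
class FeatureVector:
    """The nine measures for one participant (NaN marks a missing value)."""

    ttr: float
    mean_lex_freq: float
    mlu_words: float
    mean_gap_ms: float
    mean_pause_ms: float
    pause_word_ratio: float
    pct_pronouns: float
    pct_affective: float
    pct_cogmech: float

    def __post_init__(self) -> None:
        if not (0 < self.ttr <= 1):
            raise FeatureError(f"ttr {self.ttr} outside (0, 1]")
        for name in ("pct_pronouns", "pct_affective", "pct_cogmech"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise FeatureError(f"{name} {v} outside [0, 100]")
        for name in ("mean_gap_ms", "mean_pause_ms", "pause_word_ratio"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise FeatureError(f"{name} negative")
        if self.mlu_words < 1:
            raise FeatureError("mlu_words < 1 (an utterance has at least one word)")

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS}


# ---------------------------------------------------------------------------
# Pause and gap detection
# ---------------------------------------------------------------------------

def detect_pauses_and_gaps(
    interview: Interview,
    silent_threshold_ms: int = DEFAULT_SILENT_PAUSE_THRESHOLD_MS,
) -> PauseInventory:
    """Build the pause inventory from turn timing.

    Within each participant turn, silences between consecutive tokens (and
    between consecutive utterances) that are strictly longer than
    ``silent_threshold_ms`` become silent pauses; filler token spans become
    filled pauses.  Turn-initial latencies after interviewer turns are
    gaps; an overlapping start (negative latency) is not a silence and
    records no gap.
    """
    silent: list[int] = []
    filled: list[int] = []
    gaps: list[int] = []
    any_timed = False
    for turn in interview.turns:
        if turn.speaker != "participant":
            continue
        if turn.gap_before_ms is not None:
            gaps.append(turn.gap_before_ms)
        tokens: list[Token] = [t for u in turn.utterances for t in u.tokens]
        for tok in tokens:
            if tok.kind == "filler" and tok.duration_ms is not None:
                filled.append(tok.duration_ms)
        for prev, nxt in zip(tokens, tokens[1:]):
            if prev.offset_ms is None or nxt.onset_ms is None:
                continue
            any_timed = True
            silence = nxt.onset_ms - prev.offset_ms
            if silence > silent_threshold_ms:  # strict: exactly 200 ms is not a pause
                silent.append(silence)
    if not any_timed and not gaps and not filled:
        raise FeatureError(
            f"{interview.participant_id}: interview carries no timing information"
        )
    return PauseInventory(
        silent_pauses_ms=tuple(silent),
        filled_pauses_ms=tuple(filled),
        gaps_ms=tuple(gaps),
    )


# ---------------------------------------------------------------------------
# Lexical measures
# ---------------------------------------------------------------------------

def lexical_measures(
    words: tuple[Token, ...] | list[Token],
    lex: FrequencyLexicon,
) -> tuple[float, float, int]:
    """Type-token ratio, token-wise mean lexical frequency, and OOV count.

    TTR is unique normalized surfaces over total word tokens.  The mean
    frequency averages the lexicon value of every token occurrence (repeats
    counted each time); out-of-vocabulary tokens are excluded from the mean
    and tallied.  With every token out of vocabulary the mean is NaN.
    """
    surfaces = [t.surface for t in words if t.kind == "word"]
    if not surfaces:
        raise FeatureError("no word tokens")
    ttr = len(set(surfaces)) / len(surfaces)
    freqs = []
    oov = 0
    for s in surfaces:
        f = lex.lookup(s)
        if f is None:
            oov += 1
        else:
            freqs.append(f)
    mean_freq = sum(freqs) / len(freqs) if freqs else float("nan")
    return ttr, mean_freq, oov


# ---------------------------------------------------------------------------
# Fluency measures
# ---------------------------------------------------------------------------

def fluency_measures(
    interview: Interview,
    inv: PauseInventory,
) -> tuple[float, float, float, float]:
    """Mean length of utterance, mean gap, mean pause, pause-to-word ratio.

    MLU counts words (not fillers) over participant utterances; the mean
    pause pools silent and filled pauses; the pause-to-word ratio divides
    the pooled pause count by the word count.  An interview without gaps
    (or without pauses) yields NaN for the corresponding mean.
    """
    utterances = [u for t in interview.participant_turns() for u in t.utterances]
    n_utt = len(utterances)
    n_words = len(interview.participant_words())
    if n_utt == 0:
        raise FeatureError("zero utterances")
    if n_words == 0:
        raise FeatureError("zero words")
    mlu = n_words / n_utt
    mean_gap = sum(inv.gaps_ms) / len(inv.gaps_ms) if inv.gaps_ms else float("nan")
    mean_pause = inv.total_pause_ms / inv.n_pauses if inv.n_pauses else float("nan")
    ratio = inv.n_pauses / n_words
    return mlu, mean_gap, mean_pause, ratio


# ---------------------------------------------------------------------------
# Category percentages
# ---------------------------------------------------------------------------

def category_percentages(
    words: tuple[Token, ...] | list[Token],
    dictionary: CategoryDictionary,
) -> tuple[float, float, float]:
    """Percentage of pronoun / affective / cognitive-mechanism tokens.

    Each percentage is 100 × matched word tokens over total word tokens; a
    token belonging to several categories contributes to each of them.
    Fillers are never matched — they are pauses, not words.
    """
    surfaces = [t.surface for t in words if t.kind == "word"]
    if not surfaces:
        raise FeatureError("no word tokens")
    counts = {CAT_PRONOUNS: 0, CAT_AFFECTIVE: 0, CAT_COGMECH: 0}
    for s in surfaces:
        for cat in match_categories(s, dictionary):
            if cat in counts:
                counts[cat] += 1
    n = len(surfaces)
    return (
        100.0 * counts[CAT_PRONOUNS] / n,
        100.0 * counts[CAT_AFFECTIVE] / n,
        100.0 * counts[CAT_COGMECH] / n,
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def compute_features(
    interview: Interview,
    lex: FrequencyLexicon,
    dictionary: CategoryDictionary,
    silent_threshold_ms: int = DEFAULT_SILENT_PAUSE_THRESHOLD_MS,
) -> FeatureVector:
    """All nine measures for one interview."""
    inv = detect_pauses_and_gaps(interview, silent_threshold_ms)
    words = interview.participant_words()
    ttr, mean_freq, oov = lexical_measures(words, lex)
    mlu, mean_gap, mean_pause, ratio = fluency_measures(interview, inv)
    pct_pro, pct_aff, pct_cog = category_percentages(words, dictionary)
    logger.info(
        "%s: words=%d oov=%d silent=%d filled=%d gaps=%d",
        interview.participant_id, len(words), oov,
        len(inv.silent_pauses_ms), len(inv.filled_pauses_ms), len(inv.gaps_ms),
    )
    return FeatureVector(
        ttr=ttr,
        mean_lex_freq=mean_freq,
        mlu_words=mlu,
        mean_gap_ms=mean_gap,
        mean_pause_ms=mean_pause,
        pause_word_ratio=ratio,
        pct_pronouns=pct_pro,
        pct_affective=pct_aff,
        pct_cogmech=pct_cog,
    )


def compute_feature_matrix(
    interviews,
    lex: FrequencyLexicon,
    dictionary: CategoryDictionary,
    silent_threshold_ms: int = DEFAULT_SILENT_PAUSE_THRESHOLD_MS,
) -> pd.DataFrame:
    """Participant × nine-measure table (deterministic; NaN marks missing)."""
    rows: dict[str, dict[str, float]] = {}
    for interview in interviews:
        pid = interview.participant_id
        if pid in rows:
            raise FeatureError(f"duplicate participant id {pid!r}")
        try:
            rows[pid] = compute_features(
                interview, lex, dictionary, silent_threshold_ms
            ).as_dict()
        except FeatureError as exc:
            raise FeatureError(f"{pid}: {exc}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_COLUMNS))
    df.index.name = "participant_id"
    return df
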