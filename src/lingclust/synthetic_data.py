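"""Synthetic interview cohorts with two latent linguistic profiles.

The generator emulates the input side of the pipeline: per-participant
timed transcripts of a semi-structured interview (interviewer question
turns, participant answer turns with word and filler tokens, silent
pauses, utterance boundaries) plus a clinical covariate table, with a
known two-profile ground truth.

Profile 1 is the fluent/repetitive profile: longer utterances, shorter
and rarer pauses and gaps, more personal pronouns and psychological
lexicon, but a more concentrated vocabulary (lower type-token ratio,
higher mean lexical frequency).  Profile 2 reverses every direction.

Words are drawn from a Zipfian master vocabulary whose sub-lists are
tagged with the category dictionary's classes, so lexical richness, mean
frequency, and category percentages are all controllable.  Pause and gap
durations are log-normal (positive, right-skewed); silent-pause draws are
truncated above the 200 ms rule so every generated pause is detectable.
Clinical covariates are truncated Gaussians, independent of the
linguistic stream given the cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import (
    INTERVIEWER,
    PARTICIPANT,
    Interview,
    Token,
    Turn,
    Utterance,
)
from .group_stats import DISORGANIZATION_ITEMS
from .lexicon import (
    CAT_AFFECTIVE,
    CAT_COGMECH,
    CAT_PRONOUNS,
    CategoryDictionary,
    FrequencyLexicon,
)


class SyntheticError(ValueError):
    """Inconsistent generator parameters."""


# ---------------------------------------------------------------------------
# Fixture vocabulary and lexical resources
# ---------------------------------------------------------------------------

PRONOUNS = (
    "io", "tu", "lui", "lei", "noi", "voi", "loro",
    "mi", "ti", "si", "ci", "vi", "me", "te",
)

AFFECTIVE = (
    "felice", "triste", "paura", "amore", "gioia", "rabbia", "contento",
    "sereno", "ansia", "dolore", "allegro", "nervoso", "tranquillo",
    "preoccupato", "emozione", "piacere", "odio", "sofferenza", "speranza",
    "malinconia",
)

COGMECH = (
    "penso", "pensare", "credo", "credere", "perché", "quindi", "forse",
    "sapere", "capire", "ragione", "causa", "dubbio", "certo", "sicuro",
    "decidere", "ricordo", "immagino", "considerare", "escludere", "motivo",
)

_COMMON = (
    "la", "il", "di", "che", "non", "un", "una", "per", "con", "sono",
    "casa", "giorno", "lavoro", "tempo", "famiglia", "mattina", "sera",
    "cosa", "fare", "andare", "vedere", "mangiare", "parlare", "gente",
)

#: Number of generic (non-category) words in the master vocabulary.
GENERIC_VOCAB_SIZE = 600

#: Fillers emitted as filled pauses (a subset of the reader's inventory).
FILLERS = ("uhm", "ehm", "mh")

_ZIPF_LEXICON_EXPONENT = 1.1
_TOP_FREQ_PER_MILLION = 30000.0


def _generic_vocab() -> tuple[str, ...]:
    extra = tuple(f"parola{i:03d}" for i in range(GENERIC_VOCAB_SIZE - len(_COMMON)))
    return _COMMON + extra


def _master_rank_order() -> tuple[str, ...]:
    """Global frequency ranking: common words and pronouns at the top,
    psychological lexicon mid-table, the generic tail below."""
    generic = _generic_vocab()
    head: list[str] = []
    # interleave the closed-class pronouns with the commonest generic words
    for common, pron in zip(generic[: len(PRONOUNS)], PRONOUNS):
        head += [common, pron]
    mid = list(generic[len(PRONOUNS) : 40]) + list(COGMECH) + list(AFFECTIVE)
    tail = list(generic[40:])
    return tuple(head + mid + tail)


def fixture_frequency_lexicon() -> FrequencyLexicon:
    """Zipf-shaped per-million frequencies over the master vocabulary."""
    ranked = _master_rank_order()
    entries = {
        w: _TOP_FREQ_PER_MILLION / (r + 1) ** _ZIPF_LEXICON_EXPONENT
        for r, w in enumerate(ranked)
    }
    return FrequencyLexicon(entries=entries)


def write_fixture_lexicon(path: str | Path) -> None:
    ranked = _master_rank_order()
    lines = [
        f"{w}\t{_TOP_FREQ_PER_MILLION / (r + 1) ** _ZIPF_LEXICON_EXPONENT:.6g}"
        for r, w in enumerate(ranked)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def fixture_category_dictionary() -> CategoryDictionary:
    literals: dict[str, frozenset[str]] = {}
    for w in PRONOUNS:
        literals[w] = frozenset({CAT_PRONOUNS})
    for w in AFFECTIVE:
        literals[w] = frozenset({CAT_AFFECTIVE})
    for w in COGMECH:
        literals[w] = frozenset({CAT_COGMECH})
    # a couple of wildcard stems exercise the stem-matching path
    stems = {
        "pens": frozenset({CAT_COGMECH}),
        "cred": frozenset({CAT_COGMECH}),
        "felic": frozenset({CAT_AFFECTIVE}),
    }
    return CategoryDictionary(
        categories=frozenset({CAT_PRONOUNS, CAT_AFFECTIVE, CAT_COGMECH}),
        literals=literals,
        stems=stems,
    )


def write_fixture_dictionary(path: str | Path) -> None:
    lines = ["%", f"1\t{CAT_PRONOUNS}", f"2\t{CAT_AFFECTIVE}", f"3\t{CAT_COGMECH}", "%"]
    lines += [f"{w}\t1" for w in PRONOUNS]
    lines += [f"{w}\t2" for w in AFFECTIVE]
    lines += [f"{w}\t3" for w in COGMECH]
    lines += ["pens*\t3", "cred*\t3", "felic*\t2"]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Profile and cohort parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileParams:
    """Generative knobs for one latent linguistic profile.

    Rates are per word token; durations are log-normal parameters on the
    millisecond scale; category probabilities are per-token emission
    probabilities; ``zipf_exponent`` and ``vocab_size`` control how
    concentrated the generic vocabulary is.
    """

    utterance_length_mean: float  # words per utterance (shifted Poisson, >= 1)
    silent_pause_rate: float      # within-utterance silent pauses per word
    pause_log_mu: float           # log-ms, truncated > 200 ms on draw
    pause_log_sigma: float
    filler_rate: float            # filled pauses per word
    filler_log_mu: float
    filler_log_sigma: float
    gap_log_mu: float             # turn-initial latency, log-ms
    gap_log_sigma: float
    pronoun_prob: float
    affective_prob: float
    cogmech_prob: float
    zipf_exponent: float
    vocab_size: int
    oov_rate: float = 0.01        # out-of-lexicon neologisms per word

    def __post_init__(self) -> None:
        for name in ("pronoun_prob", "affective_prob", "cogmech_prob", "oov_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SyntheticError(f"{name}={v} outside [0, 1]")
        if self.pronoun_prob + self.affective_prob + self.cogmech_prob + self.oov_rate > 1:
            raise SyntheticError("category emission probabilities sum above 1")
        for name in ("silent_pause_rate", "filler_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SyntheticError(f"{name}={v} outside [0, 1]")
        if self.utterance_length_mean < 1:
            raise SyntheticError("utterance_length_mean < 1")
        if self.vocab_size < 50:
            raise SyntheticError("vocab_size < 50")
        if self.vocab_size > GENERIC_VOCAB_SIZE:
            raise SyntheticError(f"vocab_size > {GENERIC_VOCAB_SIZE}")


def fluent_profile() -> ProfileParams:
    """Profile 1: fluent, pronoun- and psych-lexicon-rich, lexically repetitive."""
    return ProfileParams(
        utterance_length_mean=10.0,
        silent_pause_rate=0.025,
        pause_log_mu=math.log(380.0),
        pause_log_sigma=0.45,
        filler_rate=0.018,
        filler_log_mu=math.log(350.0),
        filler_log_sigma=0.35,
        gap_log_mu=math.log(500.0),
        gap_log_sigma=0.40,
        pronoun_prob=0.15,
        affective_prob=0.065,
        cogmech_prob=0.085,
        zipf_exponent=1.35,
        vocab_size=220,
    )


def dysfluent_profile() -> ProfileParams:
    """Profile 2: short utterances, long/frequent pauses, lexically varied."""
    return ProfileParams(
        utterance_length_mean=4.0,
        silent_pause_rate=0.100,
        pause_log_mu=math.log(950.0),
        pause_log_sigma=0.50,
        filler_rate=0.055,
        filler_log_mu=math.log(450.0),
        filler_log_sigma=0.35,
        gap_log_mu=math.log(1500.0),
        gap_log_sigma=0.45,
        pronoun_prob=0.050,
        affective_prob=0.022,
        cogmech_prob=0.030,
        zipf_exponent=0.85,
        vocab_size=520,
    )


#: Clinical moments per cluster: variable -> ((mean1, sd1), (mean2, sd2), (lo, hi)).
DEFAULT_CLINICAL_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "age": ((40.62, 10.99), (37.70, 11.16), (18, 70)),
    "education": ((11.87, 2.82), (12.10, 2.53), (5, 25)),
    "illness_duration": ((15.91, 10.67), (14.85, 11.00), (0.5, 50)),
    "age_of_onset": ((24.68, 6.54), (23.35, 5.98), (12, 60)),
    "cpz_dose": ((414.79, 187.64), (502.55, 220.93), (50, 1500)),
    "bacs_total": ((1.57, 0.87), (1.52, 0.99), (0, 4)),
    "qls_ire": ((20.91, 6.08), (14.40, 5.83), (0, 48)),
    "qls_iro": ((4.83, 5.45), (2.85, 4.94), (0, 24)),
    "qls_pa": ((28.96, 7.04), (18.80, 8.01), (0, 48)),
    "panss_positive": ((16.23, 3.76), (18.70, 4.52), (7, 49)),
    "panss_negative": ((19.72, 4.71), (23.50, 3.95), (7, 49)),
    "panss_general": ((37.15, 6.62), (41.55, 4.94), (16, 112)),
    "panss_disorganization": ((20.23, 5.10), (23.45, 4.19), (8, 56)),
    "bacs_verbal_memory": ((45.79, 10.10), (41.90, 11.32), (0, 75)),
    "bacs_digit_sequencing": ((17.97, 4.49), (17.09, 5.82), (0, 28)),
    "bacs_token_task": ((33.74, 9.37), (35.20, 7.24), (0, 100)),
    "bacs_semantic_fluency": ((23.76, 16.34), (19.63, 17.45), (0, 100)),
    "bacs_symbol_coding": ((40.71, 12.06), (40.16, 14.29), (0, 110)),
    "bacs_tower_of_london": ((14.60, 3.64), (13.85, 4.54), (0, 22)),
    "tom_sequencing": ((27.63, 7.72), (27.00, 9.04), (0, 44)),
    "tom_questionnaire": ((17.30, 4.62), (17.53, 4.43), (0, 26)),
}

#: Probability of atypical (vs typical) antipsychotic treatment per cluster.
DEFAULT_ATYPICAL_PROB = (42 / 47, 19 / 20)


@dataclass(frozen=True)
class CohortParams:
    n_per_cluster: tuple[int, int] = (47, 20)
    profiles: tuple[ProfileParams, ProfileParams] = field(
        default_factory=lambda: (fluent_profile(), dysfluent_profile())
    )
    words_per_interview: int = 420
    seed: int = 0
    clinical_moments: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_MOMENTS))
    atypical_prob: tuple[float, float] = DEFAULT_ATYPICAL_PROB
    #: scale of the four within-cluster latent traits (1.0 = default spread)
    jitter: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_per_cluster) < 2:
            raise SyntheticError("each cluster needs n >= 2")
        if self.words_per_interview < 20:
            raise SyntheticError("words_per_interview < 20")


@dataclass(frozen=True)
class SyntheticCohort:
    interviews: tuple[Interview, ...]
    clinical: pd.DataFrame
    true_labels: pd.Series
    params: CohortParams

    def __post_init__(self) -> None:
        ids = [iv.participant_id for iv in self.interviews]
        if list(self.clinical.index) != ids or list(self.true_labels.index) != ids:
            raise SyntheticError("participant ids inconsistent across cohort members")


# ---------------------------------------------------------------------------
# Interview generation
# ---------------------------------------------------------------------------

def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lower: float
) -> float:
    for _ in range(1000):
        v = rng.lognormal(mu, sigma)
        if v > lower:
            return v
    return lower + 1.0  # pragma: no cover - pathological parameters


class _WordSampler:
    """Per-profile word source: category pools with mildly Zipfian use,
    a Zipf(zipf_exponent) generic vocabulary, and rare out-of-lexicon
    neologisms."""

    def __init__(self, profile: ProfileParams) -> None:
        self.profile = profile
        self.generic = _generic_vocab()[: profile.vocab_size]
        w = np.arange(1, len(self.generic) + 1, dtype=float) ** (-profile.zipf_exponent)
        self.generic_p = w / w.sum()
        self.pools = {}
        for name, pool in (("pro", PRONOUNS), ("aff", AFFECTIVE), ("cog", COGMECH)):
            pw = np.arange(1, len(pool) + 1, dtype=float) ** -0.8
            self.pools[name] = (pool, pw / pw.sum())
        self.n_oov = 0

    def draw(self, rng: np.random.Generator) -> str:
        pr = self.profile
        u = rng.random()
        if u < pr.pronoun_prob:
            pool, p = self.pools["pro"]
        elif u < pr.pronoun_prob + pr.affective_prob:
            pool, p = self.pools["aff"]
        elif u < pr.pronoun_prob + pr.affective_prob + pr.cogmech_prob:
            pool, p = self.pools["cog"]
        elif u < pr.pronoun_prob + pr.affective_prob + pr.cogmech_prob + pr.oov_rate:
            self.n_oov += 1
            return f"neologismo{self.n_oov:03d}"  # out of lexicon by construction
        else:
            return self.generic[rng.choice(len(self.generic), p=self.generic_p)]
        return pool[rng.choice(len(pool), p=p)]


def _word_duration_ms(word: str, rng: np.random.Generator) -> int:
    return max(80, int(round(180 + 28 * len(word) + rng.normal(0, 20))))


def generate_interview(
    profile: ProfileParams,
    n_words: int,
    seed: int,
    participant_id: str = "SYN",
) -> Interview:
    """One fully timed synthetic interview (pure function of its arguments).

    Interviewer question turns alternate with participant answer turns on
    a global millisecond clock; the participant stream carries utterance
    structure (boundary silences of one second or longer), within-utterance
    silent pauses truncated above 200 ms, fillers, and category-tagged
    words.
    """
    if n_words < 20:
        raise SyntheticError("n_words < 20")
    rng = np.random.default_rng(seed)
    sampler = _WordSampler(profile)
    clock = 0
    turns: list[Turn] = []
    words_left = n_words
    while words_left > 0:
        # interviewer question: a short untimed-content turn on the clock
        q_words = rng.integers(3, 9)
        q_tokens = []
        for _ in range(q_words):
            w = sampler.draw(rng)
            d = _word_duration_ms(w, rng)
            q_tokens.append(
                Token(surface=w, speaker=INTERVIEWER, onset_ms=clock, offset_ms=clock + d)
            )
            clock += d + int(rng.integers(10, 60))
        turns.append(
            Turn(speaker=INTERVIEWER, utterances=(Utterance(tokens=tuple(q_tokens)),))
        )
        # turn-initial gap before the participant answers
        gap = int(round(rng.lognormal(profile.gap_log_mu, profile.gap_log_sigma)))
        clock += max(gap, 1)

        # participant turn: a handful of utterances
        n_utt = 1 + rng.poisson(2.0)
        utterances: list[Utterance] = []
        for ui in range(n_utt):
            if words_left <= 0:
                break
            length = 1 + rng.poisson(max(profile.utterance_length_mean - 1, 0.0))
            length = int(min(length, words_left))
            tokens: list[Token] = []
            for wi in range(length):
                w = sampler.draw(rng)
                d = _word_duration_ms(w, rng)
                tokens.append(
                    Token(surface=w, speaker=PARTICIPANT, onset_ms=clock, offset_ms=clock + d)
                )
                clock += d
                words_left -= 1
                if wi < length - 1:
                    if rng.random() < profile.silent_pause_rate:
                        clock += int(round(_truncated_lognormal(
                            rng, profile.pause_log_mu, profile.pause_log_sigma, 200.0
                        )))
                    else:
                        clock += int(rng.integers(20, 120))  # articulation gap, not a pause
                    if rng.random() < profile.filler_rate:
                        f = FILLERS[rng.integers(0, len(FILLERS))]
                        fd = int(round(rng.lognormal(profile.filler_log_mu, profile.filler_log_sigma)))
                        tokens.append(
                            Token(
                                surface=f, speaker=PARTICIPANT,
                                onset_ms=clock, offset_ms=clock + fd, kind="filler",
                            )
                        )
                        clock += fd + int(rng.integers(20, 120))
            utterances.append(Utterance(tokens=tuple(tokens)))
            if ui < n_utt - 1 and words_left > 0:
                # utterance boundary: silence of at least one second
                clock += int(round(_truncated_lognormal(rng, math.log(1400.0), 0.25, 1000.0)))
        if utterances:
            turns.append(Turn(speaker=PARTICIPANT, utterances=tuple(utterances)))
        clock += int(rng.integers(200, 800))  # interviewer re-takes the floor

    from .corpus_io import _assemble_turns  # reuse gap attachment

    flat_utts = [u for t in turns for u in t.utterances]
    assembled = _assemble_turns(flat_utts)
    floor = sum(
        u.offset_ms - u.onset_ms
        for t in assembled
        if t.speaker == PARTICIPANT
        for u in t.utterances
    )
    return Interview(
        participant_id=participant_id,
        turns=assembled,
        total_duration_ms=clock,
        floor_time_ms=floor,
        n_excluded=0,
    )


def _jittered(profile: ProfileParams, rng: np.random.Generator, jitter: float) -> ProfileParams:
    """Per-participant individual variation around the cluster profile.

    Four independent latent traits — fluency, lexical richness, pronoun
    use, psychological-lexicon use — each modulate their own block of
    generator parameters, so the nine measures vary along four
    semi-independent dimensions within a cluster rather than a single
    severity axis.  ``jitter`` scales the trait standard deviations.
    """
    if jitter == 0:
        return profile
    z_flu, z_lex, z_pro, z_psy = rng.normal(0.0, jitter, 4)
    eps = rng.normal(0.0, 0.05 * jitter, 5)  # small block-internal decorrelation
    clip01 = lambda v: float(min(max(v, 0.0), 0.45))
    return replace(
        profile,
        utterance_length_mean=max(1.5, profile.utterance_length_mean * math.exp(0.18 * z_flu + eps[0])),
        silent_pause_rate=clip01(profile.silent_pause_rate * math.exp(-0.30 * z_flu + eps[1])),
        filler_rate=clip01(profile.filler_rate * math.exp(-0.30 * z_flu + eps[2])),
        pause_log_mu=profile.pause_log_mu - 0.16 * z_flu + eps[3],
        gap_log_mu=profile.gap_log_mu - 0.22 * z_flu + eps[4],
        pronoun_prob=clip01(profile.pronoun_prob * math.exp(0.25 * z_pro)),
        affective_prob=clip01(profile.affective_prob * math.exp(0.25 * z_psy)),
        cogmech_prob=clip01(profile.cogmech_prob * math.exp(0.25 * z_psy)),
        zipf_exponent=max(0.5, profile.zipf_exponent - 0.08 * z_lex),
    )


# ---------------------------------------------------------------------------
# Clinical table generation
# ---------------------------------------------------------------------------

def _disorganization_items(
    target: float, rng: np.random.Generator
) -> dict[str, int]:
    """Eight PANSS items in [1, 7] whose sum approximates the composite target."""
    total = int(round(min(max(target, 8.0), 56.0)))
    items = {name: 1 for name in DISORGANIZATION_ITEMS}
    for _ in range(total - 8):
        open_items = [k for k, v in items.items() if v < 7]
        items[open_items[rng.integers(0, len(open_items))]] += 1
    return items


def generate_clinical(
    labels,
    seed: int,
    moments: dict | None = None,
    atypical_prob: tuple[float, float] = DEFAULT_ATYPICAL_PROB,
    participant_ids=None,
) -> pd.DataFrame:
    """Clinical covariate table with cluster-conditional truncated Gaussians.

    ``labels`` holds 1/2 cluster memberships.  The PANSS disorganization
    composite is realized as eight items in [1, 7] summing to the drawn
    composite; the QLS total is the sum of its three subscales and the ToM
    total the sum of its two subscores.
    """
    y = np.asarray(labels)
    if not set(np.unique(y)) <= {1, 2}:
        raise SyntheticError("labels must be 1 or 2")
    moments = dict(DEFAULT_CLINICAL_MOMENTS if moments is None else moments)
    for var, (m1, m2, _b) in moments.items():
        if m1[1] <= 0 or m2[1] <= 0:
            raise SyntheticError(f"{var}: sd must be positive")
    rng = np.random.default_rng(seed)
    n = len(y)
    if participant_ids is None:
        participant_ids = [f"P{i + 1:03d}" for i in range(n)]
    rows: list[dict] = []
    for i in range(n):
        cl = int(y[i]) - 1
        rec: dict[str, float | str] = {}
        for var, (mo1, mo2, (lo, hi)) in moments.items():
            mean, sd = (mo1, mo2)[cl]
            if var == "panss_disorganization":
                continue  # realized from items below
            rec[var] = float(np.clip(rng.normal(mean, sd), lo, hi))
        dis_mean, dis_sd = moments["panss_disorganization"][cl]
        items = _disorganization_items(rng.normal(dis_mean, dis_sd), rng)
        rec.update(items)
        rec["panss_disorganization"] = float(sum(items.values()))
        rec["qls_total"] = rec["qls_ire"] + rec["qls_iro"] + rec["qls_pa"]
        rec["tom_total"] = rec["tom_sequencing"] + rec["tom_questionnaire"]
        rec["treatment"] = (
            "atypical" if rng.random() < atypical_prob[cl] else "typical"
        )
        rows.append(rec)
    df = pd.DataFrame(rows, index=pd.Index(participant_ids, name="participant_id"))
    return df


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(params: CohortParams | None = None) -> SyntheticCohort:
    """Complete synthetic cohort: interviews, clinical table, true labels."""
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    n1, n2 = params.n_per_cluster
    labels = np.array([1] * n1 + [2] * n2)
    ids = [f"P{i + 1:03d}" for i in range(n1 + n2)]
    interviews: list[Interview] = []
    for i, (pid, cl) in enumerate(zip(ids, labels)):
        profile = _jittered(params.profiles[cl - 1], rng, params.jitter)
        n_words = max(
            60,
            int(round(params.words_per_interview * rng.lognormal(0.0, 0.20))),
        )
        iv_seed = int(rng.integers(0, 2**31 - 1))
        interviews.append(
            generate_interview(profile, n_words, seed=iv_seed, participant_id=pid)
        )
    clinical_seed = int(rng.integers(0, 2**31 - 1))
    clinical = generate_clinical(
        labels,
        seed=clinical_seed,
        moments=params.clinical_moments,
        atypical_prob=params.atypical_prob,
        participant_ids=ids,
    )
    return SyntheticCohort(
        interviews=tuple(interviews),
        clinical=clinical,
        true_labels=pd.Series(labels, index=pd.Index(ids, name="participant_id"), name="cluster"),
        params=params,
    )
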