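import numpy as np
import pandas as pd
import pytest

from lingclust.corpus_io import (
    PARTICIPANT,
    INTERVIEWER,
    Interview,
    Token,
    Turn,
    Utterance,
)
from lingclust.features import compute_feature_matrix
from lingclust.reduction import fit_pca_varimax
from lingclust.synthetic_data import (
    CohortParams,
    fixture_category_dictionary,
    fixture_frequency_lexicon,
    generate_cohort,
)


@pytest.fixture(scope="session")
def lexicon():
    return fixture_frequency_lexicon()


@pytest.fixture(scope="session")
def dictionary():
    return fixture_category_dictionary()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 1 (shared, treat as read-only)."""
    return generate_cohort(CohortParams(seed=1))


@pytest.fixture(scope="session")
def pipeline(cohort, lexicon, dictionary):
    """Features, fitted reduction, and scores for the shared cohort."""
    features = compute_feature_matrix(cohort.interviews, lexicon, dictionary)
    model, scores = fit_pca_varimax(features)
    return {"features": features, "model": model, "scores": scores}


def make_utterance(words, speaker=PARTICIPANT, start=0, dur=300, gap=50, kinds=None):
    """Contiguously timed utterance from a list of surfaces."""
    tokens = []
    t = start
    for i, w in enumerate(words):
        kind = kinds[i] if kinds else "word"
        tokens.append(
            Token(surface=w, speaker=speaker, onset_ms=t, offset_ms=t + dur, kind=kind)
        )
        t += dur + gap
    return Utterance(tokens=tuple(tokens))


def make_interview(turn_specs, participant_id="T01"):
    """Interview from [(speaker, [utterance, ...], gap_before_ms), ...]."""
    turns = tuple(
        Turn(speaker=spk, utterances=tuple(utts), gap_before_ms=gap)
        for spk, utts, gap in turn_specs
    )
    offsets = [t.offset_ms for t in turns if t.offset_ms is not None]
    floor = sum(
        u.offset_ms - u.onset_ms
        for t in turns
        if t.speaker == PARTICIPANT
        for u in t.utterances
    )
    return Interview(
        participant_id=participant_id,
        turns=turns,
        total_duration_ms=max(max(offsets, default=0), floor),
        floor_time_ms=floor,
    )


@pytest.fixture
def simple_interview():
    """One interviewer question, one participant turn of two utterances."""
    q = make_utterance(["come", "va"], speaker=INTERVIEWER, start=0)
    u1 = make_utterance(["bene", "grazie", "penso"], start=1500)
    u2 = make_utterance(["io", "lavoro", "molto", "felice"], start=4000)
    # gap = participant onset (1500) − interviewer offset (650)
    return make_interview(
        [
            (INTERVIEWER, [q], None),
            (PARTICIPANT, [u1, u2], 850),
        ]
    )
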