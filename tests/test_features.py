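import math

import pytest
from hypothesis import given, settings, strategies as st

from lingclust.corpus_io import INTERVIEWER, PARTICIPANT, Token
from lingclust.features import (
    FeatureError,
    PauseInventory,
    category_percentages,
    compute_feature_matrix,
    detect_pauses_and_gaps,
    fluency_measures,
    lexical_measures,
)
from lingclust.lexicon import FrequencyLexicon

from conftest import make_interview, make_utterance


def _tokens(surfaces):
    return [Token(surface=s, speaker=PARTICIPANT) for s in surfaces]


# ---------------------------------------------------------------------------
# pause and gap detection
# ---------------------------------------------------------------------------

def _interview_with_silences(silences, gap=800):
    """Participant turn whose inter-token silences are as given."""
    toks = []
    t = 2000
    for i in range(len(silences) + 1):
        toks.append(Token(surface=f"w{i}", speaker=PARTICIPANT, onset_ms=t, offset_ms=t + 200))
        t += 200 + (silences[i] if i < len(silences) else 0)
    q = make_utterance(["come", "va"], speaker=INTERVIEWER, start=0, dur=500, gap=100)
    from lingclust.corpus_io import Utterance

    return make_interview(
        [(INTERVIEWER, [q], None), (PARTICIPANT, [Utterance(tokens=tuple(toks))], gap)]
    )


def test_silent_pause_rule_is_strictly_greater_than_200ms():
    iv = _interview_with_silences([150, 200, 250, 1200])
    inv = detect_pauses_and_gaps(iv)
    assert inv.silent_pauses_ms == (250, 1200)  # 150 and exactly-200 excluded


def test_gap_between_interviewer_and_participant():
    iv = _interview_with_silences([300], gap=800)
    assert detect_pauses_and_gaps(iv).gaps_ms == (800,)


def test_overlapping_start_records_no_gap():
    iv = _interview_with_silences([300], gap=None)  # overlap → reader stores None
    assert detect_pauses_and_gaps(iv).gaps_ms == ()


def test_filler_spans_become_filled_pauses(simple_interview):
    from lingclust.corpus_io import Utterance

    toks = (
        Token(surface="bene", speaker=PARTICIPANT, onset_ms=0, offset_ms=300),
        Token(surface="ehm", speaker=PARTICIPANT, onset_ms=350, offset_ms=750, kind="filler"),
        Token(surface="sì", speaker=PARTICIPANT, onset_ms=800, offset_ms=1100),
    )
    iv = make_interview([(PARTICIPANT, [Utterance(tokens=toks)], None)])
    inv = detect_pauses_and_gaps(iv)
    assert inv.filled_pauses_ms == (400,)
    assert inv.silent_pauses_ms == ()  # 50 ms articulation gaps are not pauses


# ---------------------------------------------------------------------------
# lexical measures
# ---------------------------------------------------------------------------

def test_ttr_by_definition():
    ttr, _, _ = lexical_measures(
        _tokens(["il", "cane", "vede", "il", "gatto"]),
        FrequencyLexicon(entries={"il": 1.0}),
    )
    assert ttr == pytest.approx(4 / 5)


def test_mean_lexical_frequency_is_tokenwise():
    lex = FrequencyLexicon(entries={"il": 1000, "cane": 50, "vede": 20, "gatto": 40})
    _, mean_freq, oov = lexical_measures(
        _tokens(["il", "cane", "vede", "il", "gatto"]), lex
    )
    assert mean_freq == pytest.approx((1000 + 50 + 20 + 1000 + 40) / 5)
    assert oov == 0


def test_oov_tokens_excluded_from_mean_and_counted():
    lex = FrequencyLexicon(entries={"il": 1000, "cane": 50, "vede": 20, "gatto": 40})
    _, mean_freq, oov = lexical_measures(
        _tokens(["il", "cane", "vede", "gatto", "zzz"]), lex
    )
    assert oov == 1
    assert mean_freq == pytest.approx((1000 + 50 + 20 + 40) / 4)


def test_all_oov_yields_missing_mean():
    _, mean_freq, oov = lexical_measures(
        _tokens(["xx", "yy"]), FrequencyLexicon(entries={"il": 1.0})
    )
    assert oov == 2 and math.isnan(mean_freq)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.sampled_from("abcdefg"), min_size=1, max_size=30), st.data())
def test_ttr_weakly_decreases_under_repetition(words, data):
    """Appending an already-seen word can only lower the type-token ratio."""
    lex = FrequencyLexicon(entries={"a": 1.0})
    ttr0, _, _ = lexical_measures(_tokens(words), lex)
    repeat = data.draw(st.sampled_from(words))
    ttr1, _, _ = lexical_measures(_tokens(words + [repeat]), lex)
    assert ttr1 <= ttr0 + 1e-12
    assert (ttr0 == 1.0) == (len(set(words)) == len(words))


# ---------------------------------------------------------------------------
# fluency measures
# ---------------------------------------------------------------------------

def _mlu_interview(lengths):
    utts = [
        make_utterance([f"w{i}{j}" for j in range(n)], start=5000 * i)
        for i, n in enumerate(lengths)
    ]
    return make_interview([(PARTICIPANT, utts, None)])


def test_mlu_words_per_utterance():
    iv = _mlu_interview([4, 5, 6])
    inv = PauseInventory(silent_pauses_ms=(), filled_pauses_ms=(), gaps_ms=())
    mlu, mean_gap, mean_pause, _ = fluency_measures(iv, inv)
    assert mlu == pytest.approx(5.0)
    assert math.isnan(mean_gap) and math.isnan(mean_pause)


def test_mean_pause_pools_silent_and_filled():
    iv = _mlu_interview([3])
    inv = PauseInventory(silent_pauses_ms=(300, 500), filled_pauses_ms=(200,), gaps_ms=())
    _, _, mean_pause, ratio = fluency_measures(iv, inv)
    assert mean_pause == pytest.approx(1000 / 3)
    assert ratio == pytest.approx(3 / 3)


def test_pause_word_ratio():
    iv = _mlu_interview([30, 30])
    inv = PauseInventory(silent_pauses_ms=(300, 400), filled_pauses_ms=(250,), gaps_ms=())
    assert fluency_measures(iv, inv)[3] == pytest.approx(3 / 60)


def test_doubling_pause_durations_doubles_mean_not_ratio():
    iv = _mlu_interview([10])
    inv1 = PauseInventory(silent_pauses_ms=(300, 500), filled_pauses_ms=(220,), gaps_ms=())
    inv2 = PauseInventory(silent_pauses_ms=(600, 1000), filled_pauses_ms=(440,), gaps_ms=())
    _, _, mp1, r1 = fluency_measures(iv, inv1)
    _, _, mp2, r2 = fluency_measures(iv, inv2)
    assert mp2 == pytest.approx(2 * mp1)
    assert r2 == r1


# ---------------------------------------------------------------------------
# category percentages
# ---------------------------------------------------------------------------

def test_category_percentages(dictionary):
    words = _tokens(["io", "mi"] + [f"parola{i:03d}" for i in range(8)])
    pro, aff, cog = category_percentages(words, dictionary)
    assert pro == pytest.approx(20.0)
    assert aff == 0.0 and cog == 0.0


def test_multi_category_token_counts_in_both():
    from lingclust.lexicon import CategoryDictionary

    d = CategoryDictionary(
        categories=frozenset({"pronouns_personal", "affective", "cognitive_mechanisms"}),
        literals={"perché": frozenset({"affective", "cognitive_mechanisms"})},
        stems={},
    )
    _, aff, cog = category_percentages(_tokens(["perché", "casa"]), d)
    assert aff == pytest.approx(50.0) and cog == pytest.approx(50.0)


def test_category_percentages_permutation_invariant(dictionary):
    words = ["io", "felice", "penso", "casa", "giorno", "mi"]
    base = category_percentages(_tokens(words), dictionary)
    assert category_percentages(_tokens(words[::-1]), dictionary) == base


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on small interviews
# ---------------------------------------------------------------------------

def test_measures_match_naive_recomputation(cohort, lexicon, dictionary):
    """Each measure equals an independent from-scratch recomputation."""
    iv = cohort.interviews[0]
    fm = compute_feature_matrix([iv], lexicon, dictionary)
    row = fm.iloc[0]

    words = [t.surface for t in iv.participant_words()]
    assert row.ttr == pytest.approx(len(set(words)) / len(words))

    freqs = [lexicon.lookup(w) for w in words if lexicon.lookup(w) is not None]
    assert row.mean_lex_freq == pytest.approx(sum(freqs) / len(freqs))

    utts = [u for t in iv.participant_turns() for u in t.utterances]
    assert row.mlu_words == pytest.approx(len(words) / len(utts))

    gaps = [t.gap_before_ms for t in iv.participant_turns() if t.gap_before_ms is not None]
    assert row.mean_gap_ms == pytest.approx(sum(gaps) / len(gaps))

    silent, filled = [], []
    for turn in iv.participant_turns():
        toks = [tk for u in turn.utterances for tk in u.tokens]
        filled += [tk.offset_ms - tk.onset_ms for tk in toks if tk.kind == "filler"]
        for a, b in zip(toks, toks[1:]):
            if b.onset_ms - a.offset_ms > 200:
                silent.append(b.onset_ms - a.offset_ms)
    assert row.mean_pause_ms == pytest.approx(
        (sum(silent) + sum(filled)) / (len(silent) + len(filled))
    )
    assert row.pause_word_ratio == pytest.approx((len(silent) + len(filled)) / len(words))

    from lingclust.lexicon import match_categories

    for col, cat in [
        ("pct_pronouns", "pronouns_personal"),
        ("pct_affective", "affective"),
        ("pct_cogmech", "cognitive_mechanisms"),
    ]:
        n = sum(1 for w in words if cat in match_categories(w, dictionary))
        assert row[col] == pytest.approx(100 * n / len(words))


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def test_feature_matrix_shape_and_determinism(cohort, lexicon, dictionary):
    sub = cohort.interviews[:2]
    m1 = compute_feature_matrix(sub, lexicon, dictionary)
    m2 = compute_feature_matrix(sub, lexicon, dictionary)
    assert m1.shape == (2, 9)
    assert m1.equals(m2)
    assert not m1.isna().any().any()


def test_interview_without_gaps_yields_missing_mean_gap(lexicon, dictionary):
    iv = _mlu_interview([5, 5])
    fm = compute_feature_matrix([iv], lexicon, dictionary)
    assert math.isnan(fm.iloc[0]["mean_gap_ms"])
    assert fm.drop(columns=["mean_gap_ms", "mean_lex_freq"]).notna().all().all()


def test_zero_words_rejected(lexicon, dictionary):
    with pytest.raises(FeatureError):
        lexical_measures([], lexicon)
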