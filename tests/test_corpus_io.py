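import json

import pytest

from lingclust.corpus_io import (
    INTERVIEWER,
    PARTICIPANT,
    TextGridParseError,
    TimingAnnotation,
    Token,
    TranscriptError,
    normalize_token,
    read_feature_table,
    read_textgrid,
    read_transcript,
    segment_utterances,
    write_feature_table,
    write_textgrid,
    write_transcript_jsonl,
)

# ---------------------------------------------------------------------------
# token normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Ciao,", "ciao"),
        ("«perché»", "perché"),
        ("l'ho", "l'ho"),  # internal apostrophe kept (clitic)
        ("CASA!", "casa"),
    ],
)
def test_normalize_token(raw, expected):
    assert normalize_token(raw) == expected


# ---------------------------------------------------------------------------
# TextGrid
# ---------------------------------------------------------------------------

def _textgrid_text(intervals, tier="participant"):
    body = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {max(e for _s, e, _l in intervals)}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier}"',
        "        xmin = 0",
        f"        xmax = {max(e for _s, e, _l in intervals)}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (s, e, label) in enumerate(intervals, 1):
        body += [
            f"        intervals [{i}]:",
            f"            xmin = {s}",
            f"            xmax = {e}",
            f'            text = "{label}"',
        ]
    return "\n".join(body) + "\n"


def test_read_textgrid_converts_seconds_to_ms(tmp_path):
    p = tmp_path / "a.TextGrid"
    p.write_text(_textgrid_text([(0.0, 1.5, "ciao")]))
    ann = read_textgrid(p)
    assert ann.tiers["participant"] == ((0, 1500, "ciao"),)


def test_read_textgrid_keeps_empty_labels_as_silence_candidates(tmp_path):
    p = tmp_path / "a.TextGrid"
    p.write_text(_textgrid_text([(0.0, 1.5, "ciao"), (1.5, 1.8, "")]))
    ann = read_textgrid(p)
    assert ann.tiers["participant"][1] == (1500, 1800, "")


def test_read_textgrid_rejects_overlapping_intervals(tmp_path):
    p = tmp_path / "a.TextGrid"
    p.write_text(_textgrid_text([(0, 2, "a"), (1, 3, "b")]))
    with pytest.raises(TextGridParseError, match="participant"):
        read_textgrid(p)


def test_read_textgrid_rejects_non_textgrid(tmp_path):
    p = tmp_path / "a.TextGrid"
    p.write_text("not a grid\n")
    with pytest.raises(TextGridParseError):
        read_textgrid(p)


def test_textgrid_roundtrip_fixed_point(tmp_path):
    p1, p2 = tmp_path / "a.TextGrid", tmp_path / "b.TextGrid"
    p1.write_text(
        _textgrid_text([(0.0, 1.234, "ciao"), (1.234, 2.0, ""), (2.0, 3.5, "bene")])
    )
    ann1 = read_textgrid(p1)
    write_textgrid(ann1, p2)
    assert read_textgrid(p2) == ann1


def test_timing_annotation_validates_interval_order():
    with pytest.raises(TextGridParseError):
        TimingAnnotation(tiers={"t": ((0, 0, "x"),)})


# ---------------------------------------------------------------------------
# utterance segmentation
# ---------------------------------------------------------------------------

def _timed_tokens(silences, dur=200):
    """Same-speaker token chain with the given inter-token silences."""
    toks = []
    t = 0
    for i in range(len(silences) + 1):
        toks.append(
            Token(surface=f"w{i}", speaker=PARTICIPANT, onset_ms=t, offset_ms=t + dur)
        )
        t += dur + (silences[i] if i < len(silences) else 0)
    return toks


def test_segmentation_splits_at_long_silence():
    utts = segment_utterances(_timed_tokens([300, 1200, 400]))
    assert [u.n_words for u in utts] == [2, 2]


def test_segmentation_threshold_is_inclusive_at_one_second():
    utts = segment_utterances(_timed_tokens([1000]))
    assert len(utts) == 2


def test_segmentation_no_split_below_threshold():
    utts = segment_utterances(_timed_tokens([999, 300]))
    assert len(utts) == 1


def test_segmentation_preserves_tokens_and_is_idempotent():
    toks = _timed_tokens([100, 1500, 100, 2000, 50])
    utts = segment_utterances(toks)
    flat = [t for u in utts for t in u.tokens]
    assert flat == toks  # boundaries never drop tokens
    again = [u for u0 in utts for u in segment_utterances(u0.tokens)]
    assert [u.tokens for u in again] == [u.tokens for u in utts]


def test_segmentation_honors_preset_boundaries():
    utts = segment_utterances(_timed_tokens([100, 100]), preset_boundaries=[0])
    assert [u.n_words for u in utts] == [1, 2]


def test_segmentation_requires_timestamps_without_annotation():
    toks = [Token(surface="a", speaker=PARTICIPANT), Token(surface="b", speaker=PARTICIPANT)]
    with pytest.raises(TranscriptError):
        segment_utterances(toks)


# ---------------------------------------------------------------------------
# transcript dialects
# ---------------------------------------------------------------------------

def _write_jsonl(path, utterances):
    path.write_text("\n".join(json.dumps(u) for u in utterances) + "\n")


def _utt(speaker, words, start, kind=None):
    toks = []
    t = start
    for w in words:
        toks.append({"surface": w, "onset_ms": t, "offset_ms": t + 300, "kind": kind})
        t += 350
    return {"speaker": speaker, "tokens": toks, "onset_ms": start, "offset_ms": t - 50}


def test_read_jsonl_counts_word_tokens(tmp_path):
    p = tmp_path / "P01.jsonl"
    _write_jsonl(
        p,
        [
            _utt("interviewer", ["come", "va"], 0),
            _utt("participant", ["bene", "molto", "bene"], 1000),
            _utt("participant", ["oggi", "sono", "stanco", "davvero"], 3000),
        ],
    )
    iv = read_transcript(p, dialect="jsonl")
    assert iv.participant_id == "P01"
    assert len(iv.participant_words()) == 7


def test_read_jsonl_tags_fillers_from_inventory(tmp_path):
    p = tmp_path / "P01.jsonl"
    _write_jsonl(p, [_utt("participant", ["ehm", "bene"], 0)])
    iv = read_transcript(p, dialect="jsonl")
    kinds = [t.kind for t in iv.participant_tokens()]
    assert kinds == ["filler", "word"]


def test_read_jsonl_rejects_interviewer_only(tmp_path):
    p = tmp_path / "P01.jsonl"
    _write_jsonl(p, [_utt("interviewer", ["come", "va"], 0)])
    with pytest.raises(TranscriptError, match="no participant speech"):
        read_transcript(p, dialect="jsonl")


def test_read_jsonl_rejects_unknown_speaker(tmp_path):
    p = tmp_path / "P01.jsonl"
    _write_jsonl(p, [_utt("nurse", ["ciao"], 0)])
    with pytest.raises(TranscriptError, match="unknown speaker"):
        read_transcript(p, dialect="jsonl")


def test_jsonl_roundtrip(tmp_path, simple_interview):
    p = tmp_path / "T01.jsonl"
    write_transcript_jsonl(simple_interview, p)
    iv = read_transcript(p, dialect="jsonl")
    assert [t.surface for t in iv.participant_tokens()] == [
        t.surface for t in simple_interview.participant_tokens()
    ]
    assert iv.turns[1].gap_before_ms == simple_interview.turns[1].gap_before_ms


CHAT = """\
@Begin
@Participants: PAR Participant, INT Investigator
*INT:\tcome va oggi ?
%tim:\t0_2000
*PAR:\tbene &-uhm penso di sì
%tim:\t2600_6900
*PAR:\tieri [//] oggi &=laughs lavoro
%tim:\t8100_10500
@End
"""


def test_read_chat_min(tmp_path):
    p = tmp_path / "P02.cha"
    p.write_text(CHAT)
    iv = read_transcript(p, dialect="chat_min")
    words = [t.surface for t in iv.participant_words()]
    # "&-uhm" is a filler, "ieri [//]" a false start, "&=laughs" non-verbal
    assert words == ["bene", "penso", "di", "sì", "oggi", "lavoro"]
    fillers = [t.surface for t in iv.participant_tokens() if t.kind == "filler"]
    assert fillers == ["uhm"]
    assert iv.n_excluded == 2
    # gap between interviewer turn end (2000) and participant onset (2600)
    assert iv.turns[1].gap_before_ms == 600


def test_read_chat_min_rejects_unknown_code(tmp_path):
    p = tmp_path / "P02.cha"
    p.write_text("*DOC:\tciao bene\n%tim:\t0_1000\n")
    with pytest.raises(TranscriptError, match="unknown speaker"):
        read_transcript(p, dialect="chat_min")


def test_read_chat_min_requires_tim(tmp_path):
    p = tmp_path / "P02.cha"
    p.write_text("*PAR:\tciao bene\n")
    with pytest.raises(TranscriptError, match="%tim"):
        read_transcript(p, dialect="chat_min")


# ---------------------------------------------------------------------------
# feature table round-trip
# ---------------------------------------------------------------------------

def test_feature_table_roundtrip(tmp_path, pipeline):
    path = tmp_path / "features.csv"
    write_feature_table(pipeline["features"], path)
    back = read_feature_table(path)
    assert back.shape == pipeline["features"].shape
    assert (back - pipeline["features"]).abs().max().max() < 1e-9


def test_feature_table_rejects_duplicate_ids(tmp_path, pipeline):
    dup = pipeline["features"].iloc[[0, 0]]
    with pytest.raises(ValueError, match="duplicate"):
        write_feature_table(dup, tmp_path / "x.csv")
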