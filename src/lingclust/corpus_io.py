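"""Transcript and timing I/O.

Reads interview transcripts (a minimal CHAT-like dialect and a JSON-lines
dialect) together with Praat TextGrid timing annotations, and assembles
timed, speaker-attributed token streams with utterance segmentation.

Time is integer milliseconds everywhere; TextGrid seconds are converted on
read.  Speakers are ``"participant"`` and ``"interviewer"``; interviewer
material is retained only as time boundaries for gap (turn-initial latency)
computation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

PARTICIPANT = "participant"
INTERVIEWER = "interviewer"

#: Filler vocalizations treated as filled pauses rather than words.
DEFAULT_FILLER_INVENTORY = frozenset({"uhm", "ehm", "mh", "eh"})

#: Silence at or above this duration starts a new utterance (CLAN criterion:
#: a pause of one second or longer delimits utterances).
DEFAULT_SEGMENT_THRESHOLD_MS = 1000

_PUNCT_STRIP = "\"'`.,;:!?()[]{}<>«»“”‘’-–—…/\\"


class TranscriptError(ValueError):
    """Malformed or semantically invalid transcript input."""


class TextGridParseError(ValueError):
    """Malformed TextGrid file; message names the tier/line where possible."""


def normalize_token(surface: str) -> str:
    """Lowercase and strip surrounding punctuation, keeping internal
    apostrophes (Italian clitics like ``l'ho`` stay intact)."""
    return surface.lower().strip(_PUNCT_STRIP)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    surface: str
    speaker: str
    onset_ms: int | None = None
    offset_ms: int | None = None
    kind: str = "word"  # "word" | "filler"

    def __post_init__(self) -> None:
        if not self.surface:
            raise TranscriptError("token surface empty after normalization")
        if self.speaker not in (PARTICIPANT, INTERVIEWER):
            raise TranscriptError(f"unknown speaker {self.speaker!r}")
        if self.kind not in ("word", "filler"):
            raise TranscriptError(f"unknown token kind {self.kind!r}")
        if (
            self.onset_ms is not None
            and self.offset_ms is not None
            and self.offset_ms < self.onset_ms
        ):
            raise TranscriptError(
                f"token {self.surface!r}: offset {self.offset_ms} < onset {self.onset_ms}"
            )

    @property
    def duration_ms(self) -> int | None:
        if self.onset_ms is None or self.offset_ms is None:
            return None
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class Utterance:
    """A same-speaker word string delimited by pauses or annotated boundaries."""

    tokens: tuple[Token, ...]
    onset_ms: int | None = None
    offset_ms: int | None = None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise TranscriptError("utterance with no tokens")
        speakers = {t.speaker for t in self.tokens}
        if len(speakers) > 1:
            raise TranscriptError("utterance mixes speakers")
        onsets = [t.onset_ms for t in self.tokens if t.onset_ms is not None]
        if onsets != sorted(onsets):
            raise TranscriptError("utterance tokens not time-ordered")
        if self.onset_ms is None and onsets:
            object.__setattr__(self, "onset_ms", onsets[0])
        offsets = [t.offset_ms for t in self.tokens if t.offset_ms is not None]
        if self.offset_ms is None and offsets:
            object.__setattr__(self, "offset_ms", offsets[-1])

    @property
    def speaker(self) -> str:
        return self.tokens[0].speaker

    @property
    def n_words(self) -> int:
        return sum(1 for t in self.tokens if t.kind == "word")


@dataclass(frozen=True)
class Turn:
    """A maximal run of same-speaker utterances.

    ``gap_before_ms`` is the turn-initial latency and is defined only for
    participant turns that follow an interviewer turn without overlap.
    """

    speaker: str
    utterances: tuple[Utterance, ...]
    gap_before_ms: int | None = None

    def __post_init__(self) -> None:
        if not self.utterances:
            raise TranscriptError("turn with no utterances")
        if any(u.speaker != self.speaker for u in self.utterances):
            raise TranscriptError("turn mixes speakers")
        if self.gap_before_ms is not None and self.gap_before_ms < 0:
            raise TranscriptError("negative gap_before_ms")

    @property
    def onset_ms(self) -> int | None:
        return self.utterances[0].onset_ms

    @property
    def offset_ms(self) -> int | None:
        return self.utterances[-1].offset_ms


@dataclass(frozen=True)
class TimingAnnotation:
    """Interval tiers (name -> sorted, non-overlapping (start_ms, end_ms, label))."""

    tiers: dict[str, tuple[tuple[int, int, str], ...]]

    def __post_init__(self) -> None:
        for name, intervals in self.tiers.items():
            prev_end = None
            for start, end, _label in intervals:
                if end <= start:
                    raise TextGridParseError(
                        f"tier {name!r}: interval ({start}, {end}) has end <= start"
                    )
                if prev_end is not None and start < prev_end:
                    raise TextGridParseError(
                        f"tier {name!r}: overlapping intervals at {start} ms"
                    )
                prev_end = end


@dataclass(frozen=True)
class Interview:
    """One participant's interview: time-ordered turns plus summary timing."""

    participant_id: str
    turns: tuple[Turn, ...]
    total_duration_ms: int
    floor_time_ms: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not any(t.speaker == PARTICIPANT for t in self.turns):
            raise TranscriptError(
                f"{self.participant_id}: interview contains no participant speech"
            )
        if self.floor_time_ms > self.total_duration_ms:
            raise TranscriptError(
                f"{self.participant_id}: floor time exceeds total duration"
            )

    def participant_turns(self) -> tuple[Turn, ...]:
        return tuple(t for t in self.turns if t.speaker == PARTICIPANT)

    def participant_tokens(self) -> tuple[Token, ...]:
        return tuple(
            tok
            for turn in self.participant_turns()
            for utt in turn.utterances
            for tok in utt.tokens
        )

    def participant_words(self) -> tuple[Token, ...]:
        return tuple(t for t in self.participant_tokens() if t.kind == "word")


# ---------------------------------------------------------------------------
# TextGrid (Praat long text form)
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"=\s*([-\d.eE+]+)")
_TEXT_RE = re.compile(r'=\s*"(.*)"\s*$')


def _sec_to_ms(s: float) -> int:
    return int(round(s * 1000.0))


def read_textgrid(path: str | Path) -> TimingAnnotation:
    """Parse a long-form text TextGrid into millisecond interval tiers.

    Labels (including empty silence candidates) are preserved verbatim.
    """
    path = Path(path)
    raw = path.read_bytes()
    for enc in ("utf-8", "utf-16"):
        try:
            text = raw.decode(enc)
            break
        except UnicodeDecodeError:
            continue
    else:
        raise TextGridParseError(f"{path}: unknown encoding")

    lines = text.splitlines()
    if not any("TextGrid" in ln for ln in lines[:3]):
        raise TextGridParseError(f"{path}: malformed header (not a TextGrid)")

    tiers: dict[str, list[tuple[int, int, str]]] = {}
    cur_tier: str | None = None
    cur_class: str | None = None
    in_interval = False  # tier-level xmin/xmax lines precede any "intervals [n]:"
    pending: dict[str, float | str] = {}

    def flush_interval(lineno: int) -> None:
        if not pending:
            return
        if not {"xmin", "xmax", "text"} <= pending.keys():
            raise TextGridParseError(
                f"{path}:{lineno}: incomplete interval in tier {cur_tier!r}"
            )
        start = _sec_to_ms(float(pending["xmin"]))
        end = _sec_to_ms(float(pending["xmax"]))
        tiers[cur_tier].append((start, end, str(pending["text"])))
        pending.clear()

    for lineno, ln in enumerate(lines, 1):
        s = ln.strip()
        if s.startswith("item ["):
            flush_interval(lineno)
            cur_tier, cur_class, in_interval = None, None, False
        elif s.startswith("class"):
            m = _TEXT_RE.search(s)
            cur_class = m.group(1) if m else None
        elif s.startswith("name"):
            m = _TEXT_RE.search(s)
            if m is None:
                raise TextGridParseError(f"{path}:{lineno}: unreadable tier name")
            if cur_class != "IntervalTier":
                cur_tier = None  # point tiers are skipped
                continue
            cur_tier = m.group(1)
            tiers[cur_tier] = []
            in_interval = False
        elif cur_tier is not None and s.startswith("intervals ["):
            flush_interval(lineno)
            in_interval = True
        elif cur_tier is not None and in_interval and s.startswith(("xmin", "xmax")):
            m = _NUM_RE.search(s)
            if m is None:
                raise TextGridParseError(
                    f"{path}:{lineno}: unreadable boundary in tier {cur_tier!r}"
                )
            pending["xmin" if s.startswith("xmin") else "xmax"] = float(m.group(1))
        elif cur_tier is not None and in_interval and s.startswith("text"):
            m = _TEXT_RE.search(s)
            if m is None:
                raise TextGridParseError(
                    f"{path}:{lineno}: unreadable interval text in tier {cur_tier!r}"
                )
            pending["text"] = m.group(1)

    if cur_tier is not None:
        flush_interval(len(lines))
    if not tiers:
        raise TextGridParseError(f"{path}: no interval tiers found")
    return TimingAnnotation(tiers={k: tuple(v) for k, v in tiers.items()})


def write_textgrid(ann: TimingAnnotation, path: str | Path) -> None:
    """Serialize to the long text TextGrid form (read→write→read fixed point)."""
    path = Path(path)
    xmin = min((iv[0] for t in ann.tiers.values() for iv in t), default=0) / 1000.0
    xmax = max((iv[1] for t in ann.tiers.values() for iv in t), default=0) / 1000.0
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin}",
        f"xmax = {xmax}",
        "tiers? <exists>",
        f"size = {len(ann.tiers)}",
        "item []:",
    ]
    for ti, (name, intervals) in enumerate(ann.tiers.items(), 1):
        t_xmin = (intervals[0][0] / 1000.0) if intervals else xmin
        t_xmax = (intervals[-1][1] / 1000.0) if intervals else xmax
        out += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {t_xmin}",
            f"        xmax = {t_xmax}",
            f"        intervals: size = {len(intervals)}",
        ]
        for ii, (start, end, label) in enumerate(intervals, 1):
            out += [
                f"        intervals [{ii}]:",
                f"            xmin = {start / 1000.0}",
                f"            xmax = {end / 1000.0}",
                f'            text = "{label}"',
            ]
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Utterance segmentation
# ---------------------------------------------------------------------------

def segment_utterances(
    tokens: Sequence[Token],
    pause_threshold_ms: int = DEFAULT_SEGMENT_THRESHOLD_MS,
    preset_boundaries: Iterable[int] = (),
) -> tuple[Utterance, ...]:
    """Split a same-speaker, time-ordered token stream into utterances.

    A boundary is inserted after token ``i`` wherever the silence between
    token ``i`` and token ``i+1`` is at least ``pause_threshold_ms`` (the
    one-second-or-longer rule).  ``preset_boundaries`` are indices after
    which an annotated boundary (terminal intonation / grammatical
    completeness) already exists; these are always honored and never
    removed.
    """
    if not tokens:
        return ()
    speakers = {t.speaker for t in tokens}
    if len(speakers) > 1:
        raise TranscriptError("segment_utterances requires same-speaker tokens")
    preset = set(preset_boundaries)
    missing_time = any(t.onset_ms is None or t.offset_ms is None for t in tokens)
    if missing_time and not preset:
        raise TranscriptError(
            "tokens lack timestamps and no pre-annotated boundaries exist"
        )

    boundaries: set[int] = set(preset)
    if not missing_time:
        for i in range(len(tokens) - 1):
            silence = tokens[i + 1].onset_ms - tokens[i].offset_ms
            if silence >= pause_threshold_ms:
                boundaries.add(i)

    utterances: list[Utterance] = []
    start = 0
    for i in range(len(tokens)):
        if i in boundaries or i == len(tokens) - 1:
            utterances.append(Utterance(tokens=tuple(tokens[start : i + 1])))
            start = i + 1
    return tuple(utterances)


# ---------------------------------------------------------------------------
# Transcript readers
# ---------------------------------------------------------------------------

def _assemble_turns(utterances: Sequence[Utterance]) -> tuple[Turn, ...]:
    """Group consecutive same-speaker utterances into turns and attach
    turn-initial latencies (gaps) to participant turns following
    interviewer turns; overlapping starts get no gap."""
    turns: list[Turn] = []
    group: list[Utterance] = []
    for utt in utterances:
        if group and utt.speaker != group[-1].speaker:
            turns.append(Turn(speaker=group[0].speaker, utterances=tuple(group)))
            group = []
        group.append(utt)
    if group:
        turns.append(Turn(speaker=group[0].speaker, utterances=tuple(group)))

    with_gaps: list[Turn] = []
    for i, turn in enumerate(turns):
        gap = None
        if (
            turn.speaker == PARTICIPANT
            and i > 0
            and turns[i - 1].speaker == INTERVIEWER
            and turn.onset_ms is not None
            and turns[i - 1].offset_ms is not None
        ):
            latency = turn.onset_ms - turns[i - 1].offset_ms
            if latency >= 0:  # an overlap is not a silence
                gap = latency
        with_gaps.append(replace(turn, gap_before_ms=gap))
    return tuple(with_gaps)


def _finish_interview(
    participant_id: str,
    utterances: list[Utterance],
    n_excluded: int,
    total_duration_ms: int | None = None,
) -> Interview:
    turns = _assemble_turns(utterances)
    offsets = [t.offset_ms for t in turns if t.offset_ms is not None]
    total = total_duration_ms if total_duration_ms is not None else (max(offsets) if offsets else 0)
    floor = sum(
        (u.offset_ms - u.onset_ms)
        for t in turns
        if t.speaker == PARTICIPANT
        for u in t.utterances
        if u.onset_ms is not None and u.offset_ms is not None
    )
    return Interview(
        participant_id=participant_id,
        turns=turns,
        total_duration_ms=max(total, floor),
        floor_time_ms=floor,
        n_excluded=n_excluded,
    )


def _read_jsonl(path: Path, filler_inventory: frozenset[str]) -> Interview:
    utterances: list[Utterance] = []
    n_excluded = 0
    participant_id = path.stem
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        obj = json.loads(line)
        if "participant_id" in obj and len(obj) <= 2:
            participant_id = obj["participant_id"]
            continue
        speaker = obj.get("speaker")
        if speaker not in (PARTICIPANT, INTERVIEWER):
            raise TranscriptError(f"{path}:{lineno}: unknown speaker code {speaker!r}")
        if obj.get("excluded"):
            n_excluded += len(obj.get("tokens", ())) or 1
            continue
        tokens: list[Token] = []
        for td in obj["tokens"]:
            surface = normalize_token(td["surface"])
            if not surface:
                continue
            kind = td.get("kind") or (
                "filler" if surface in filler_inventory else "word"
            )
            tokens.append(
                Token(
                    surface=surface,
                    speaker=speaker,
                    onset_ms=td.get("onset_ms"),
                    offset_ms=td.get("offset_ms"),
                    kind=kind,
                )
            )
        if tokens:
            utterances.append(
                Utterance(
                    tokens=tuple(tokens),
                    onset_ms=obj.get("onset_ms"),
                    offset_ms=obj.get("offset_ms"),
                )
            )
    return _finish_interview(participant_id, utterances, n_excluded)


_CHAT_SPEAKERS = {"*PAR": PARTICIPANT, "*INT": INTERVIEWER}
_TIM_RE = re.compile(r"(\d+)\s*[_\-]\s*(\d+)")


def _chat_tokens(
    text: str, speaker: str, filler_inventory: frozenset[str]
) -> tuple[list[tuple[str, str]], int]:
    """Tokenize one CHAT-min utterance line.

    ``&-word`` is a filled pause, ``&=event`` a non-verbal vocalization
    (excluded), ``xxx`` unintelligible (excluded), and ``[//]`` marks the
    preceding token as a false start (excluded).  Returns (surface, kind)
    pairs plus the excluded count.
    """
    out: list[tuple[str, str]] = []
    n_excluded = 0
    for piece in text.split():
        if piece == "[//]":
            if out:
                out.pop()
                n_excluded += 1
            continue
        if piece.startswith("&="):
            n_excluded += 1
            continue
        if piece.startswith("&-"):
            surf = normalize_token(piece[2:])
            if surf:
                out.append((surf, "filler"))
            continue
        surf = normalize_token(piece)
        if not surf:
            continue
        if surf == "xxx":
            n_excluded += 1
            continue
        kind = "filler" if surf in filler_inventory else "word"
        out.append((surf, kind))
    return out, n_excluded


def _read_chat_min(path: Path, filler_inventory: frozenset[str]) -> Interview:
    participant_id = path.stem
    utterances: list[Utterance] = []
    n_excluded = 0
    pending: tuple[str, list[tuple[str, str]]] | None = None  # (speaker, tokens)

    def flush(tim: tuple[int, int] | None) -> None:
        nonlocal pending
        if pending is None:
            return
        speaker, toks = pending
        pending = None
        if not toks:
            return
        if tim is None:
            raise TranscriptError(
                f"{path}: utterance without %tim line (token outside any turn)"
            )
        onset, offset = tim
        # Tokens are laid out contiguously across the utterance span: the
        # dialect carries no word-level timing, so no intra-utterance
        # silence is fabricated.
        span = max(offset - onset, len(toks))
        edges = [onset + round(span * i / len(toks)) for i in range(len(toks) + 1)]
        tokens = tuple(
            Token(surface=s, speaker=speaker, onset_ms=edges[i], offset_ms=edges[i + 1], kind=k)
            for i, (s, k) in enumerate(toks)
        )
        utterances.append(Utterance(tokens=tokens, onset_ms=onset, offset_ms=offset))

    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip()
        if not line or line.startswith("@"):
            continue
        if line.startswith("*"):
            if pending is not None:
                raise TranscriptError(
                    f"{path}:{lineno}: utterance without %tim timing line"
                )
            code, _, text = line.partition(":")
            if code not in _CHAT_SPEAKERS:
                raise TranscriptError(f"{path}:{lineno}: unknown speaker code {code!r}")
            if "[+ exc]" in text:  # line marked excluded (false start / non-verbal)
                n_excluded += len(text.replace("[+ exc]", "").split())
                continue
            toks, n_exc = _chat_tokens(text, _CHAT_SPEAKERS[code], filler_inventory)
            n_excluded += n_exc
            pending = (_CHAT_SPEAKERS[code], toks)
        elif line.startswith("%tim"):
            m = _TIM_RE.search(line)
            if m is None:
                raise TranscriptError(f"{path}:{lineno}: unreadable %tim line")
            flush((int(m.group(1)), int(m.group(2))))
        # other dependent tiers ignored
    if pending is not None:
        raise TranscriptError(f"{path}: trailing utterance without %tim line")
    return _finish_interview(participant_id, utterances, n_excluded)


def read_transcript(
    path: str | Path,
    dialect: str = "jsonl",
    filler_inventory: Iterable[str] = DEFAULT_FILLER_INVENTORY,
) -> Interview:
    """Read one participant's transcript into an :class:`Interview`.

    ``dialect`` is ``"jsonl"`` (one JSON object per utterance with per-token
    timing) or ``"chat_min"`` (``*PAR:``/``*INT:`` speaker lines followed by
    ``%tim:`` start-end lines in milliseconds).
    """
    path = Path(path)
    inventory = frozenset(normalize_token(w) for w in filler_inventory)
    if dialect == "jsonl":
        return _read_jsonl(path, inventory)
    if dialect == "chat_min":
        return _read_chat_min(path, inventory)
    raise ValueError(f"unknown transcript dialect {dialect!r}")


def write_transcript_jsonl(interview: Interview, path: str | Path) -> None:
    """Serialize an interview in the JSONL dialect (round-trip safe)."""
    path = Path(path)
    lines = [json.dumps({"participant_id": interview.participant_id})]
    for turn in interview.turns:
        for utt in turn.utterances:
            lines.append(
                json.dumps(
                    {
                        "speaker": turn.speaker,
                        "onset_ms": utt.onset_ms,
                        "offset_ms": utt.offset_ms,
                        "tokens": [
                            {
                                "surface": t.surface,
                                "onset_ms": t.onset_ms,
                                "offset_ms": t.offset_ms,
                                "kind": t.kind,
                            }
                            for t in utt.tokens
                        ],
                    },
                    ensure_ascii=False,
                )
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

#: Fixed column order of the nine linguistic measures.
FEATURE_COLUMNS = (
    "ttr",
    "mean_lex_freq",
    "mlu_words",
    "mean_gap_ms",
    "mean_pause_ms",
    "pause_word_ratio",
    "pct_pronouns",
    "pct_affective",
    "pct_cogmech",
)


def write_feature_table(matrix, path: str | Path) -> None:
    """Write the participant × nine-measure table as CSV (lossless round-trip)."""
    import pandas as pd

    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("feature matrix must be a pandas DataFrame")
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate participant ids: {dupes}")
    missing = [c for c in FEATURE_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    out = matrix.loc[:, list(FEATURE_COLUMNS)]
    out.rename_axis("participant_id").to_csv(path)


def read_feature_table(path: str | Path):
    import pandas as pd

    df = pd.read_csv(path, index_col="participant_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate participant ids: {dupes}")
    return df.loc[:, list(FEATURE_COLUMNS)]
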