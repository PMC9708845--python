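"""Word-frequency lookup and category-dictionary matching.

Two lexical resources drive the lexical measures: a word-frequency lexicon
(TSV: word, occurrences per million — the interface a written-Italian
frequency corpus such as CoLFIS exposes) and a category dictionary in the
classic word-count ``.dic`` dialect (numeric category ids declared between
``%`` lines, then entry lines mapping literal words or wildcard stems like
``pens*`` to one or more ids).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .corpus_io import normalize_token

#: Canonical category names used by the feature layer.
CAT_PRONOUNS = "pronouns_personal"
CAT_AFFECTIVE = "affective"
CAT_COGMECH = "cognitive_mechanisms"


class LexiconError(ValueError):
    """Malformed lexicon or dictionary resource."""


@dataclass(frozen=True)
class FrequencyLexicon:
    """Case-normalized word → occurrences-per-million lookup."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        bad = {w: f for w, f in self.entries.items() if not f > 0}
        if bad:
            raise LexiconError(f"non-positive frequencies: {sorted(bad)[:5]}")

    def lookup(self, word: str) -> float | None:
        return self.entries.get(normalize_token(word))

    def __contains__(self, word: str) -> bool:
        return normalize_token(word) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CategoryDictionary:
    """Literal and wildcard-stem entries mapped to named categories."""

    categories: frozenset[str]
    literals: dict[str, frozenset[str]]
    stems: dict[str, frozenset[str]]  # stem without the trailing '*'

    def __post_init__(self) -> None:
        for entry, cats in list(self.literals.items()) + list(self.stems.items()):
            if not cats:
                raise LexiconError(f"entry {entry!r} maps to no category")
            unknown = cats - self.categories
            if unknown:
                raise LexiconError(f"entry {entry!r} uses undeclared categories {sorted(unknown)}")
        if "" in self.stems:
            raise LexiconError("empty stem before wildcard")


def load_frequency_lexicon(path: str | Path) -> FrequencyLexicon:
    """Load a two-column TSV (word, per-million frequency).

    Lookup is case-insensitive; duplicate words are collapsed by summing
    their frequencies (surface variants of one headword).
    """
    path = Path(path)
    entries: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated columns")
        word = normalize_token(parts[0])
        try:
            freq = float(parts[1])
        except ValueError as exc:
            raise LexiconError(f"{path}:{lineno}: non-numeric frequency {parts[1]!r}") from exc
        if freq <= 0:
            raise LexiconError(f"{path}:{lineno}: non-positive frequency for {word!r}")
        entries[word] = entries.get(word, 0.0) + freq
    if not entries:
        raise LexiconError(f"{path}: empty lexicon")
    return FrequencyLexicon(entries=entries)


def load_category_dictionary(path: str | Path) -> CategoryDictionary:
    """Load a ``.dic``-dialect category dictionary.

    Format::

        %
        1   pronouns_personal
        31  cognitive_mechanisms
        %
        io      1
        pens*   31

    Wildcard entries are stored as stems; literals exactly.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    id_to_name: dict[str, str] = {}
    literals: dict[str, set[str]] = {}
    stems: dict[str, set[str]] = {}
    in_header = False
    header_done = False
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line:
            continue
        if line == "%":
            if not header_done and not in_header:
                in_header = True
            elif in_header:
                in_header, header_done = False, True
            continue
        parts = line.split()
        if in_header:
            if len(parts) < 2 or not parts[0].isdigit():
                raise LexiconError(f"{path}:{lineno}: malformed header line {line!r}")
            id_to_name[parts[0]] = parts[1]
        else:
            if not header_done:
                raise LexiconError(f"{path}:{lineno}: entry before '%' header")
            if len(parts) < 2:
                raise LexiconError(f"{path}:{lineno}: entry without category ids")
            entry, ids = parts[0], parts[1:]
            cats: set[str] = set()
            for cid in ids:
                if cid not in id_to_name:
                    raise LexiconError(
                        f"{path}:{lineno}: entry {entry!r} references undeclared id {cid}"
                    )
                cats.add(id_to_name[cid])
            if entry.endswith("*"):
                stem = normalize_token(entry[:-1])
                if not stem:
                    raise LexiconError(f"{path}:{lineno}: empty stem before wildcard")
                stems.setdefault(stem, set()).update(cats)
            else:
                word = normalize_token(entry)
                literals.setdefault(word, set()).update(cats)
    if not id_to_name:
        raise LexiconError(f"{path}: no category header found")
    return CategoryDictionary(
        categories=frozenset(id_to_name.values()),
        literals={w: frozenset(c) for w, c in literals.items()},
        stems={s: frozenset(c) for s, c in stems.items()},
    )


def match_categories(token: str, dictionary: CategoryDictionary) -> frozenset[str]:
    """Categories a normalized word token belongs to.

    An exact literal match wins outright; otherwise the longest wildcard
    stem that prefixes the token matches.  A token may belong to several
    categories; no match yields the empty set.  The result depends only on
    the dictionary contents, never on file line order.
    """
    if token in dictionary.literals:
        return dictionary.literals[token]
    best: str | None = None
    for stem in dictionary.stems:
        if token.startswith(stem) and (best is None or len(stem) > len(best)):
            best = stem
    if best is not None:
        return dictionary.stems[best]
    return frozenset()
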