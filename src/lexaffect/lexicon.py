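"""Word-list dictionaries and dictionary-based match counting.

A lexicon maps affect dimensions (``positive_affect``, ``joy``, ...) to word
lists, following the LIWC family of instruments: entries are literal words,
multiword phrases, or stems with a single trailing ``*`` wildcard meaning
prefix match.  Matching is case-insensitive after unicode NFC normalization.

Two match modes are provided.  *Token* mode assumes the text has been
segmented into tokens (whitespace corpora, or Chinese text run through a
segmenter) and counts tokens that equal a literal entry or start with a
wildcard stem.  *Substring* mode works on the raw, unsegmented string and
counts non-overlapping occurrences scanned left-to-right, preferring the
longest entry at each position — the deterministic analogue of
maximum-forward-matching used for unsegmented CJK text.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

WILDCARD = "*"

#: Dimension names the analysis pipeline knows about.  A Lexicon may declare
#: any dimensions; these are the ones the scoring composites expect.
CORE_DIMENSIONS = (
    "positive_affect",
    "negative_affect",
    "joy",
    "sadness",
    "anger",
    "fear",
    "disgust",
    "sexual",
    "health",
)


class LexiconError(ValueError):
    """Malformed or invalid lexicon file."""


def _normalize(word: str) -> str:
    return unicodedata.normalize("NFC", word).casefold()


def _normalize_dimension(name: str) -> str:
    name = _normalize(name.strip())
    name = re.sub(r"[\s\-]+", "_", name)
    return name


@dataclass(frozen=True)
class Entry:
    """One lexicon entry: a literal word/phrase or a prefix stem."""

    text: str
    is_wildcard: bool = False

    @classmethod
    def parse(cls, raw: str) -> "Entry":
        raw = _normalize(raw.strip())
        if raw.endswith(WILDCARD):
            stem = raw[:-1]
            if not stem:
                raise LexiconError("bare wildcard '*' is not a valid entry")
            return cls(stem, True)
        if not raw:
            raise LexiconError("empty string is not a valid entry")
        return cls(raw, False)

    def matches_token(self, token: str) -> bool:
        if self.is_wildcard:
            return token.startswith(self.text)
        return token == self.text


@dataclass
class Lexicon:
    """Mapping from dimension name to an ordered set of entries.

    Dimensions may share entries: the instruments this emulates overlap, and a
    token matching k dimensions increments all k counts.
    """

    dimensions: dict[str, tuple[Entry, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validated: dict[str, tuple[Entry, ...]] = {}
        for name, entries in self.dimensions.items():
            norm = _normalize_dimension(name)
            uniq: dict[Entry, None] = {}
            for e in entries:
                if e in uniq:
                    logger.warning("duplicate entry %r in dimension %r collapsed", e.text, norm)
                uniq[e] = None
            if not uniq:
                raise LexiconError(f"dimension {norm!r} has no entries")
            validated[norm] = tuple(uniq)
        self.dimensions = validated

    @classmethod
    def from_words(cls, dims: Mapping[str, Iterable[str]]) -> "Lexicon":
        return cls({name: tuple(Entry.parse(w) for w in words) for name, words in dims.items()})

    @property
    def dimension_names(self) -> tuple[str, ...]:
        return tuple(self.dimensions)

    def __contains__(self, dimension: str) -> bool:
        return _normalize_dimension(dimension) in self.dimensions

    def entries(self, dimension: str) -> tuple[Entry, ...]:
        norm = _normalize_dimension(dimension)
        if norm not in self.dimensions:
            raise KeyError(
                f"unknown dimension {dimension!r}; available: {sorted(self.dimensions)}"
            )
        return self.dimensions[norm]

    # Reverse index used by the scoring hot path: literal word -> dimensions.
    def literal_index(self) -> dict[str, tuple[str, ...]]:
        index: dict[str, list[str]] = {}
        for dim, entries in self.dimensions.items():
            for e in entries:
                if not e.is_wildcard:
                    index.setdefault(e.text, []).append(dim)
        return {w: tuple(d) for w, d in index.items()}

    def wildcard_entries(self) -> dict[str, tuple[Entry, ...]]:
        return {
            dim: tuple(e for e in entries if e.is_wildcard)
            for dim, entries in self.dimensions.items()
        }


def load_lexicon(path: str | Path, dialect: str = "tsv") -> Lexicon:
    """Load a lexicon file.

    Dialects: ``tsv`` (``dimension<TAB>word`` rows), ``json`` (object mapping
    dimension to array of words), ``liwc_dic`` (``%``-delimited category
    header block of ``id<TAB>name`` lines, then ``word<TAB>catid...`` lines).
    All files are UTF-8; a trailing ``*`` marks a prefix stem in any dialect.
    """
    path = Path(path)
    if dialect == "tsv":
        return _load_tsv(path)
    if dialect == "json":
        return _load_json(path)
    if dialect == "liwc_dic":
        return _load_liwc_dic(path)
    raise ValueError(f"unknown lexicon dialect {dialect!r} (tsv, json, liwc_dic)")


def _load_tsv(path: Path) -> Lexicon:
    dims: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0].strip():
            raise LexiconError(f"{path}:{lineno}: expected 'dimension<TAB>word', got {line!r}")
        dims.setdefault(parts[0], []).append(parts[1])
    if not dims:
        raise LexiconError(f"{path}: no entries found")
    return Lexicon.from_words(dims)


def _load_json(path: Path) -> Lexicon:
    try:
        obj = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise LexiconError(f"{path}:{exc.lineno}: {exc.msg}") from exc
    if not isinstance(obj, dict) or not all(isinstance(v, list) for v in obj.values()):
        raise LexiconError(f"{path}: expected a JSON object mapping dimension -> array of words")
    return Lexicon.from_words(obj)


def _load_liwc_dic(path: Path) -> Lexicon:
    """Parse the LIWC ``.dic`` dialect.

    Layout: a header block delimited by lines containing only ``%``, holding
    ``catid<TAB>catname`` pairs, followed by ``word<TAB>catid[<TAB>catid...]``
    body lines.
    """
    lines = path.read_text(encoding="utf-8").splitlines()
    try:
        first = next(i for i, l in enumerate(lines) if l.strip() == "%")
        second = next(i for i, l in enumerate(lines[first + 1 :], first + 1) if l.strip() == "%")
    except StopIteration:
        raise LexiconError(f"{path}: missing %%-delimited category header block") from None

    categories: dict[str, str] = {}
    for lineno, line in enumerate(lines[first + 1 : second], first + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 'catid<TAB>name', got {line!r}")
        categories[parts[0].strip()] = parts[1]

    dims: dict[str, list[str]] = {name: [] for name in categories.values()}
    for lineno, line in enumerate(lines[second + 1 :], second + 2):
        if not line.strip():
            continue
        parts = [p for p in line.split("\t") if p.strip()]
        if len(parts) < 2:
            raise LexiconError(f"{path}:{lineno}: expected 'word<TAB>catid...', got {line!r}")
        word, cat_ids = parts[0], parts[1:]
        for cid in cat_ids:
            if cid.strip() not in categories:
                raise LexiconError(f"{path}:{lineno}: unknown category id {cid!r}")
            dims[categories[cid.strip()]].append(word)
    empty = [d for d, words in dims.items() if not words]
    if empty:
        raise LexiconError(f"{path}: dimensions with no entries: {sorted(empty)}")
    return Lexicon.from_words(dims)


# ---------------------------------------------------------------------------
# Tokenization

_PUNCT_ONLY = re.compile(r"^[\W_]+$", re.UNICODE)
_WORD_RUN = re.compile(r"\w+", re.UNICODE)

Segmenter = Callable[[str], Sequence[str]]


def tokenize(
    text: str,
    mode: str = "whitespace",
    segmenter: Segmenter | None = None,
) -> list[str]:
    """Split text into normalized tokens.

    ``whitespace`` mode splits on runs of whitespace, then on punctuation runs
    within each chunk, so punctuation-only tokens vanish and ``"a,b!!"``
    yields two tokens.  ``segmenter`` mode delegates to a user-supplied
    callable (e.g. ``jieba.lcut``); the callable must be deterministic for a
    fixed input.  Empty or degenerate text yields an empty list.
    """
    if not text:
        return []
    if mode == "whitespace":
        tokens = []
        for chunk in text.split():
            for tok in _WORD_RUN.findall(chunk):
                tokens.append(_normalize(tok))
        return tokens
    if mode == "segmenter":
        if segmenter is None:
            raise ValueError(
                "segmenter mode requires a segmenter callable (e.g. jieba.lcut); "
                "none is bundled with this package"
            )
        return [_normalize(t) for t in segmenter(text) if t.strip() and not _PUNCT_ONLY.match(t)]
    raise ValueError(f"unknown tokenize mode {mode!r} (whitespace, segmenter)")


# ---------------------------------------------------------------------------
# Match counting

def count_matches(
    tokens_or_text: Sequence[str] | str,
    lexicon: Lexicon,
    dimension: str,
    match_mode: str = "token",
) -> int:
    """Count lexicon hits for one dimension in a posting.

    Token mode takes a token list; a token matches if it equals a literal
    entry or starts with a wildcard entry's stem, contributing at most 1 per
    dimension.  Substring mode takes the raw string and counts non-overlapping
    occurrences, scanning left-to-right and preferring the longest entry at
    each position (ties impossible: equal-length distinct entries cannot both
    match the same position).
    """
    entries = lexicon.entries(dimension)
    if match_mode == "token":
        if isinstance(tokens_or_text, str):
            raise TypeError("token mode expects a token list; pass the output of tokenize()")
        return sum(1 for tok in tokens_or_text if any(e.matches_token(tok) for e in entries))
    if match_mode == "substring":
        if not isinstance(tokens_or_text, str):
            tokens_or_text = " ".join(tokens_or_text)
        return _count_substring(_normalize(tokens_or_text), entries)
    raise ValueError(f"unknown match mode {match_mode!r} (token, substring)")


def _count_substring(text: str, entries: Sequence[Entry]) -> int:
    # Wildcards degenerate to their stem for substring scanning: a prefix
    # match inside running text is exactly an occurrence of the stem.
    patterns = sorted({e.text for e in entries}, key=len, reverse=True)
    count = 0
    i, n = 0, len(text)
    while i < n:
        for pat in patterns:
            if text.startswith(pat, i):
                count += 1
                i += len(pat)
                break
        else:
            i += 1
    return count
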