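"""Offset-preserving tokenization and sentence splitting for clinical notes.

Clinical text is annotated with character offsets, so every token and
sentence carries its exact character span back into the source string.
Both routines are rule based: a regex tokenizer that detaches punctuation,
and a sentence splitter that breaks on ``. ! ?`` followed by whitespace and
a capital, with an exception list of common clinical abbreviations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List

_TOKEN_RE = re.compile(r"\w+(?:[/'-]\w+)*|[^\w\s]")

# Abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "st", "vs", "etc", "e.g", "i.e",
        "pt", "hx", "dx", "sx", "rx", "fx", "tab", "qd", "bid", "tid",
        "p.o", "b.i.d", "t.i.d", "prn",
    }
)

_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9])|[.!?]+$")


@dataclass(frozen=True)
class Token:
    """A token with its half-open character span in the source text."""

    text: str
    start: int
    end: int


def tokenize(text: str) -> List[Token]:
    """Split ``text`` into word and punctuation tokens with exact offsets.

    Words keep internal hyphens, slashes and apostrophes (``son-in-law``,
    ``130/80``, ``pt's``); every other non-space character becomes its own
    token.  ``text[t.start:t.end] == t.text`` holds for every token.
    """
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def sentence_spans(text: str) -> List[tuple]:
    """Return half-open character spans of sentences in ``text``.

    A boundary is a run of ``. ! ?`` followed by whitespace and an
    upper-case letter or digit, unless the preceding word is a known
    clinical abbreviation.  The trailing fragment (if any) is always a
    sentence, so the spans cover all non-space text.
    """
    boundaries = []
    for m in _SENT_BOUNDARY_RE.finditer(text):
        prev = text[: m.start()]
        w = re.search(r"([A-Za-z][A-Za-z.]*)$", prev)
        if w and w.group(1).lower().rstrip(".") in _ABBREVIATIONS:
            continue
        boundaries.append(m.end())
    spans = []
    start = 0
    for b in boundaries:
        if b > start:
            spans.append((start, b))
            start = b
    if start < len(text) and text[start:].strip():
        spans.append((start, len(text)))
    if not spans and text.strip():
        spans.append((0, len(text)))
    return spans


def sentence_index(text: str) -> List[int]:
    """Per-character sentence ids (characters outside any sentence get the
    id of the following sentence; trailing ones the last)."""
    spans = sentence_spans(text)
    idx = [0] * len(text)
    for i, (s, e) in enumerate(spans):
        for c in range(s, min(e, len(text))):
            idx[c] = i
    return idx
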