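"""Text canonicalization and light sentence segmentation.

Phrase matching runs over a *normalized* view of each section: lowercased
(optionally), whitespace runs collapsed to single spaces, and typographic
quote/dash variants unified. Every normalized character remembers where it
came from, so match offsets always map back to the original text.

Sentence boundaries are computed on the *original* text (``.``, ``;``, ``!``,
``?`` and newline terminate a sentence, with a guard so decimal points inside
numbers do not split). This keeps exclusion-cue scoping deterministic and easy
to reproduce by hand, which is the point: the phenotype is a fixed term list,
not a negation grammar.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass

__all__ = [
    "NormalizedText",
    "normalize_text",
    "sentence_spans",
    "sentence_index_of",
    "token_spans",
]

_QUOTE_MAP = {
    "‘": "'",
    "’": "'",
    "‚": "'",
    "‛": "'",
    "“": '"',
    "”": '"',
    "„": '"',
    "′": "'",
}
_DASH_MAP = {
    "‐": "-",
    "‑": "-",
    "‒": "-",
    "–": "-",
    "—": "-",
    "―": "-",
    "−": "-",
}
_CHAR_MAP = {**_QUOTE_MAP, **_DASH_MAP}

_SENTENCE_BREAK = ".;!?\n"


@dataclass(frozen=True)
class NormalizedText:
    """A normalized string plus per-character maps back to the original.

    ``starts[i]``/``ends[i]`` give the half-open original span that produced
    normalized character ``i`` (a collapsed whitespace run maps to the whole
    run it replaced).
    """

    original: str
    text: str
    starts: tuple[int, ...]
    ends: tuple[int, ...]

    def to_original(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open span in normalized space back to original offsets."""
        if not (0 <= start <= end <= len(self.text)):
            raise ValueError(f"span [{start}, {end}) out of bounds")
        if start == end:
            pos = self.starts[start] if start < len(self.text) else len(self.original)
            return pos, pos
        return self.starts[start], self.ends[end - 1]


def normalize(text: str, case_insensitive: bool = True) -> NormalizedText:
    """Normalize ``text`` keeping an offset map to the original."""
    out: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            j = i
            while j < n and text[j].isspace():
                j += 1
            # leading/trailing runs still emit one space: offsets stay simple
            out.append(" ")
            starts.append(i)
            ends.append(j)
            i = j
            continue
        ch = _CHAR_MAP.get(ch, ch)
        if case_insensitive:
            ch = ch.lower()
        for piece in ch:  # casefolding may expand (rare); same origin char
            out.append(piece)
            starts.append(i)
            ends.append(i + 1)
        i += 1
    return NormalizedText(
        original=text, text="".join(out), starts=tuple(starts), ends=tuple(ends)
    )


def normalize_text(text: str, case_insensitive: bool = True) -> str:
    """Normalized string only (see :func:`normalize` for the offset map).

    Unlike :func:`normalize`, which preserves offsets, the convenience form
    strips the leading/trailing collapsed space so phrases compare cleanly.
    """
    return normalize(text, case_insensitive=case_insensitive).text.strip()


def _is_decimal_point(text: str, i: int) -> bool:
    return (
        text[i] == "."
        and 0 < i < len(text) - 1
        and text[i - 1].isdigit()
        and text[i + 1].isdigit()
    )


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open spans of sentences in ``text``, boundaries included in the
    preceding sentence. Empty sentences (e.g. between ``.\\n``) are dropped."""
    spans: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in _SENTENCE_BREAK and not _is_decimal_point(text, i):
            if text[start : i + 1].strip():
                spans.append((start, i + 1))
            start = i + 1
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


def sentence_index_of(spans: list[tuple[int, int]], offset: int) -> int:
    """Index of the sentence containing ``offset`` (nearest if in a gap)."""
    if not spans:
        return 0
    starts = [s for s, _ in spans]
    idx = bisect.bisect_right(starts, offset) - 1
    return max(idx, 0)


_TOKEN_RE = re.compile(r"\S+")


def token_spans(text: str) -> list[tuple[int, int]]:
    """Half-open spans of whitespace-delimited tokens."""
    return [m.span() for m in _TOKEN_RE.finditer(text)]
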