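"""Clinical-note section segmentation.

Hospital notes arrive as flat text with header lines ("Principal Diagnosis:",
"Brief Hospital Course:", ...). The phenotype is restricted to a handful of
sections, so segmentation maps header lines to canonical snake_case names and
carves the note into half-open character spans. Header labels differ across
EHRs; the pattern table is configurable and the shipped defaults cover the
usual hospital-summary labels.
"""

from __future__ import annotations

import re
from collections.abc import Sequence

from .records import NoteSection

__all__ = [
    "SectionPattern",
    "DEFAULT_SECTION_PATTERNS",
    "CANONICAL_SECTIONS",
    "segment_note",
]


class SectionPattern:
    """Maps a header line to a canonical section name.

    ``pattern`` is matched case-insensitively at the start of a line; an
    optional trailing colon is tolerated.
    """

    def __init__(self, name: str, pattern: str):
        self.name = name
        self.pattern = pattern
        self.regex = re.compile(
            rf"^[ \t]*(?:{pattern})[ \t]*:?[ \t]*$|^[ \t]*(?:{pattern})[ \t]*:",
            re.IGNORECASE,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"SectionPattern({self.name!r}, {self.pattern!r})"


DEFAULT_SECTION_PATTERNS: tuple[SectionPattern, ...] = (
    SectionPattern("principal_diagnosis", r"(?:diagnosis[ \t]*-[ \t]*)?principal\s+diagnosis"),
    SectionPattern("secondary_diagnoses", r"secondary\s+diagnos[ie]s"),
    SectionPattern("chief_complaint", r"chief\s+complaint(?:\s*/\s*reason\s+for\s+visit)?"),
    SectionPattern("brief_hospital_course", r"brief\s+hospital\s+course"),
    SectionPattern("family_history", r"family\s+history"),
    SectionPattern("medications", r"medications?(?:\s+on\s+(?:admission|discharge))?"),
    SectionPattern("other", r"(?:past\s+medical\s+history|social\s+history|allergies)"),
)

CANONICAL_SECTIONS: tuple[str, ...] = (
    "preamble",
    "principal_diagnosis",
    "secondary_diagnoses",
    "chief_complaint",
    "brief_hospital_course",
    "family_history",
    "medications",
    "other",
)


def segment_note(
    raw_text: str,
    section_patterns: Sequence[SectionPattern] = DEFAULT_SECTION_PATTERNS,
) -> list[NoteSection]:
    """Split ``raw_text`` into named sections.

    Each line matching a header pattern opens a section extending to the next
    header (or end of text); the header line itself belongs to its section.
    Text before the first header becomes a ``preamble`` section. An empty
    note yields no sections; a note with no recognized header yields a single
    preamble spanning the whole text.
    """
    if not section_patterns:
        raise ValueError("section_patterns must be non-empty")
    if raw_text == "":
        return []

    # line start offsets
    headers: list[tuple[int, str]] = []  # (line start offset, canonical name)
    pos = 0
    for line in raw_text.splitlines(keepends=True):
        stripped = line.rstrip("\n")
        for pat in section_patterns:
            if pat.regex.match(stripped):
                headers.append((pos, pat.name))
                break
        pos += len(line)

    sections: list[NoteSection] = []
    if not headers or headers[0][0] > 0:
        end = headers[0][0] if headers else len(raw_text)
        sections.append(
            NoteSection("preamble", raw_text[0:end], 0, end)
        )
    for i, (start, name) in enumerate(headers):
        end = headers[i + 1][0] if i + 1 < len(headers) else len(raw_text)
        sections.append(NoteSection(name, raw_text[start:end], start, end))
    return sections
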