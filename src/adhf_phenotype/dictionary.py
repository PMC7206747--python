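"""The computable phenotype's definition: the term dictionary.

A :class:`TermDictionary` is the whole executable definition of the
phenotype — inclusion phrases (the surface forms of ADHF clinicians write),
exclusion phrases (cues like "rule out" whose proximity suppresses a hit),
the note sections the search is restricted to, and matching options. The
shipped defaults reconstruct a clinically standard ADHF term list; anything
can be overridden from a YAML/JSON file, and tests that need exactness build
their own dictionaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "MatchOptions",
    "TermDictionary",
    "DEFAULT_INCLUSION_TERMS",
    "DEFAULT_EXCLUSION_TERMS",
    "DEFAULT_SCOPED_SECTIONS",
    "default_dictionary",
    "load_term_dictionary",
    "save_term_dictionary",
]

# ADHF surface forms: synonyms, abbreviations and acronyms a hospital note
# would carry. Configurable; these defaults favour recall.
DEFAULT_INCLUSION_TERMS: tuple[str, ...] = (
    "acute decompensated heart failure",
    "acute on chronic heart failure",
    "decompensated heart failure",
    "decompensated chf",
    "acute chf",
    "acute heart failure",
    "heart failure exacerbation",
    "chf exacerbation",
    "acute systolic heart failure",
    "acute diastolic heart failure",
    "acute on chronic systolic heart failure",
    "acute on chronic diastolic heart failure",
    "adhf",
)

# The first three cues are the core exclusion vocabulary; the rest are
# common variants kept configurable.
DEFAULT_EXCLUSION_TERMS: tuple[str, ...] = (
    "prior",
    "rule out",
    "negative for",
    "history of",
    "no evidence of",
    "resolved",
    "ruled out",
    "r/o",
)

DEFAULT_SCOPED_SECTIONS: frozenset[str] = frozenset(
    {
        "principal_diagnosis",
        "secondary_diagnoses",
        "chief_complaint",
        "brief_hospital_course",
    }
)


@dataclass(frozen=True)
class MatchOptions:
    """How phrases are matched and how far an exclusion cue reaches.

    ``exclusion_scope='sentence'`` suppresses a hit when a cue occurs anywhere
    in the same sentence; ``'window'`` when a cue ends within
    ``window_tokens`` tokens before the hit.
    """

    case_insensitive: bool = True
    word_boundary: bool = True
    exclusion_scope: str = "sentence"
    window_tokens: int = 5

    def __post_init__(self) -> None:
        if self.exclusion_scope not in ("sentence", "window"):
            raise ValueError(
                f"exclusion_scope must be 'sentence' or 'window', got "
                f"{self.exclusion_scope!r}"
            )
        if self.exclusion_scope == "window" and self.window_tokens < 1:
            raise ValueError("window_tokens must be >= 1 under window scoping")


@dataclass(frozen=True)
class TermDictionary:
    inclusion_terms: tuple[str, ...]
    exclusion_terms: tuple[str, ...] = ()
    scoped_sections: frozenset[str] = DEFAULT_SCOPED_SECTIONS
    match_options: MatchOptions = field(default_factory=MatchOptions)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inclusion_terms", tuple(self.inclusion_terms))
        object.__setattr__(self, "exclusion_terms", tuple(self.exclusion_terms))
        object.__setattr__(self, "scoped_sections", frozenset(self.scoped_sections))
        if not self.inclusion_terms:
            raise ValueError("inclusion_terms must be non-empty")
        if any(not t.strip() for t in self.inclusion_terms + self.exclusion_terms):
            raise ValueError("terms must be non-empty strings")
        both = set(self.inclusion_terms) & set(self.exclusion_terms)
        if both:
            raise ValueError(f"terms in both inclusion and exclusion lists: {sorted(both)}")

    def with_terms(
        self,
        add_inclusion: tuple[str, ...] | list[str] = (),
        add_exclusion: tuple[str, ...] | list[str] = (),
    ) -> "TermDictionary":
        """A copy with extra terms appended (duplicates dropped, order kept)."""

        def extend(base: tuple[str, ...], extra) -> tuple[str, ...]:
            seen = set(base)
            return base + tuple(t for t in extra if not (t in seen or seen.add(t)))

        return replace(
            self,
            inclusion_terms=extend(self.inclusion_terms, add_inclusion),
            exclusion_terms=extend(self.exclusion_terms, add_exclusion),
        )


def default_dictionary() -> TermDictionary:
    """The shipped ADHF dictionary."""
    return TermDictionary(
        inclusion_terms=DEFAULT_INCLUSION_TERMS,
        exclusion_terms=DEFAULT_EXCLUSION_TERMS,
        scoped_sections=DEFAULT_SCOPED_SECTIONS,
    )


def _to_mapping(dictionary: TermDictionary) -> dict:
    return {
        "inclusion_terms": list(dictionary.inclusion_terms),
        "exclusion_terms": list(dictionary.exclusion_terms),
        "scoped_sections": sorted(dictionary.scoped_sections),
        "match_options": {
            "case_insensitive": dictionary.match_options.case_insensitive,
            "word_boundary": dictionary.match_options.word_boundary,
            "exclusion_scope": dictionary.match_options.exclusion_scope,
            "window_tokens": dictionary.match_options.window_tokens,
        },
    }


def _from_mapping(data: dict) -> TermDictionary:
    if "inclusion_terms" not in data:
        raise ValueError("dictionary file lacks required key 'inclusion_terms'")
    opts = data.get("match_options", {})
    return TermDictionary(
        inclusion_terms=tuple(data["inclusion_terms"]),
        exclusion_terms=tuple(data.get("exclusion_terms", ())),
        scoped_sections=frozenset(data.get("scoped_sections", DEFAULT_SCOPED_SECTIONS)),
        match_options=MatchOptions(**opts),
    )


def load_term_dictionary(path: str | Path) -> TermDictionary:
    """Load a dictionary from a YAML or JSON file (sniffed by suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: dictionary file must contain a mapping")
    return _from_mapping(data)


def save_term_dictionary(dictionary: TermDictionary, path: str | Path) -> None:
    path = Path(path)
    data = _to_mapping(dictionary)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
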