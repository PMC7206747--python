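"""The computable phenotype engine.

The phenotype is a Boolean free-text search over the scoped sections of an
admission's notes: find occurrences of any inclusion phrase (longest match
first, whole tokens only), suppress a hit when an exclusion cue occurs within
its scope (same sentence by default), and call the admission positive iff at
least one hit survives anywhere across its notes. Every verdict carries its
evidence trail — the kept and the suppressed matches — because the
derivation protocol works by reviewing mismatches against chart review and
editing the term lists.

The classifier is deliberately dumb: no stemming, no spelling correction, no
general negation grammar. A fixed term list is the method; the engine just
executes it deterministically.

:class:`PhenotypeClassifier` wraps the pipeline as a scikit-learn estimator
(rows are admissions — a :class:`~adhf_phenotype.records.ClinicalNote` or an
iterable of them — and ``predict`` returns the boolean ADHF call), so the
phenotype drops into sklearn model-selection tooling. The module-level
functions are thin wrappers over it.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .dictionary import (
    DEFAULT_EXCLUSION_TERMS,
    DEFAULT_INCLUSION_TERMS,
    DEFAULT_SCOPED_SECTIONS,
    MatchOptions,
    TermDictionary,
)
from .records import ClinicalNote, NoteSection
from .text import (
    NormalizedText,
    normalize,
    normalize_text,
    sentence_index_of,
    sentence_spans,
    token_spans,
)

__all__ = [
    "TermMatch",
    "PhenotypeVerdict",
    "PhenotypeClassifier",
    "find_inclusion_matches",
    "apply_exclusions",
    "classify_admission",
    "run_phenotype",
]


@dataclass(frozen=True)
class TermMatch:
    """One phrase hit, with offsets into the *original* section text."""

    term: str
    section_name: str
    start: int
    end: int
    sentence_index: int
    suppressed_by: str | None = None
    note_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"match span [{self.start}, {self.end}) is empty")

    @property
    def suppressed(self) -> bool:
        return self.suppressed_by is not None


@dataclass(frozen=True)
class PhenotypeVerdict:
    """Admission-level call plus the evidence that produced it."""

    admission_id: str
    adhf: bool
    kept_matches: tuple[TermMatch, ...] = ()
    suppressed_matches: tuple[TermMatch, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "kept_matches", tuple(self.kept_matches))
        object.__setattr__(self, "suppressed_matches", tuple(self.suppressed_matches))
        if self.adhf != bool(self.kept_matches):
            raise ValueError("adhf must be true iff kept_matches is non-empty")
        if any(m.suppressed for m in self.kept_matches):
            raise ValueError("kept matches must not carry suppressed_by")
        if any(not m.suppressed for m in self.suppressed_matches):
            raise ValueError("suppressed matches must name a suppressing phrase")


def _phrase_pattern(term_norm: str, word_boundary: bool) -> str:
    body = re.escape(term_norm)
    return rf"\b{body}\b" if word_boundary else body


class _CompiledDictionary:
    """Term lists compiled to regexes over normalized text."""

    def __init__(self, dictionary: TermDictionary):
        self.dictionary = dictionary
        opts = dictionary.match_options
        self._norm_inclusion = {
            normalize_text(t, opts.case_insensitive): t for t in dictionary.inclusion_terms
        }
        self._norm_exclusion = {
            normalize_text(t, opts.case_insensitive): t for t in dictionary.exclusion_terms
        }
        # longest-first alternation: leftmost position wins, and at a given
        # position the longest phrase wins because re tries alternatives in order
        self._inc_re = self._compile(self._norm_inclusion, opts)
        self._exc_re = self._compile(self._norm_exclusion, opts)

    @staticmethod
    def _compile(norm_terms: dict[str, str], opts: MatchOptions) -> re.Pattern | None:
        if not norm_terms:
            return None
        alts = sorted(norm_terms, key=len, reverse=True)
        return re.compile("|".join(_phrase_pattern(t, opts.word_boundary) for t in alts))

    def _scan(self, pattern: re.Pattern | None, norm: NormalizedText, norm_terms):
        """Yield (original term, original-start, original-end, norm-start)."""
        if pattern is None:
            return
        for m in pattern.finditer(norm.text):
            start, end = norm.to_original(m.start(), m.end())
            yield norm_terms[m.group(0)], start, end, m.start()

    def match_section(
        self, section: NoteSection, note_id: str | None = None
    ) -> list[TermMatch]:
        """All matches in a section, exclusion scoping already applied."""
        opts = self.dictionary.match_options
        norm = normalize(section.text, opts.case_insensitive)
        sents = sentence_spans(section.text)

        inc = list(self._scan(self._inc_re, norm, self._norm_inclusion))
        if not inc:
            return []
        exc = list(self._scan(self._exc_re, norm, self._norm_exclusion))

        matches: list[TermMatch] = []
        if opts.exclusion_scope == "sentence":
            cues_by_sentence: dict[int, str] = {}
            for term, start, _end, _ns in exc:
                idx = sentence_index_of(sents, start)
                cues_by_sentence.setdefault(idx, term)
            for term, start, end, _ns in inc:
                idx = sentence_index_of(sents, start)
                matches.append(
                    TermMatch(
                        term=term,
                        section_name=section.name,
                        start=start,
                        end=end,
                        sentence_index=idx,
                        suppressed_by=cues_by_sentence.get(idx),
                        note_id=note_id,
                    )
                )
        else:  # window scope: cue ends within window_tokens tokens before the hit
            toks = token_spans(norm.text)
            tok_starts = [s for s, _ in toks]
            import bisect

            def tok_index(norm_pos: int) -> int:
                return bisect.bisect_right(tok_starts, norm_pos) - 1

            for term, start, end, ns in inc:
                idx = sentence_index_of(sents, start)
                match_tok = tok_index(ns)
                suppressor = None
                for exc_term, _es, _ee, ens in exc:
                    cue_tok = tok_index(ens)
                    gap = match_tok - cue_tok
                    if 0 < gap <= self.dictionary.match_options.window_tokens:
                        suppressor = exc_term
                        break
                matches.append(
                    TermMatch(
                        term=term,
                        section_name=section.name,
                        start=start,
                        end=end,
                        sentence_index=idx,
                        suppressed_by=suppressor,
                        note_id=note_id,
                    )
                )
        return matches


def find_inclusion_matches(
    section: NoteSection, dictionary: TermDictionary
) -> list[TermMatch]:
    """Non-overlapping inclusion hits in one section (no exclusion filtering).

    Longest phrase wins at each position; scanning resumes after the match.
    The caller is responsible for section scoping.
    """
    compiled = _CompiledDictionary(replace(dictionary, exclusion_terms=()))
    return compiled.match_section(section)


def apply_exclusions(
    matches: Sequence[TermMatch], section: NoteSection, dictionary: TermDictionary
) -> list[TermMatch]:
    """Re-evaluate ``matches`` from this section against the exclusion cues.

    Surviving matches are returned unmodified; suppressed ones carry the
    cue in ``suppressed_by``.
    """
    compiled = _CompiledDictionary(dictionary)
    note_id = matches[0].note_id if matches else None
    full = {
        (m.start, m.end): m for m in compiled.match_section(section, note_id=note_id)
    }
    out: list[TermMatch] = []
    for m in matches:
        hit = full.get((m.start, m.end))
        out.append(replace(m, suppressed_by=hit.suppressed_by) if hit else m)
    return out


def _iter_notes(admission) -> list[ClinicalNote]:
    if isinstance(admission, ClinicalNote):
        return [admission]
    return list(admission)


class PhenotypeClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based ADHF classifier over admissions of sectioned clinical notes.

    Parameters mirror the term dictionary; ``None`` means the shipped default
    list. ``fit`` validates and compiles the dictionary (there is nothing to
    estimate — the rules *are* the model); ``predict`` takes a sequence whose
    rows are admissions, each a :class:`ClinicalNote` or an iterable of notes
    sharing one admission id, and returns a boolean array.

    Examples
    --------
    >>> clf = PhenotypeClassifier().fit()
    >>> clf.predict([note])          # doctest: +SKIP
    array([ True])
    """

    def __init__(
        self,
        inclusion_terms: Sequence[str] | None = None,
        exclusion_terms: Sequence[str] | None = None,
        scoped_sections: Iterable[str] | None = None,
        case_insensitive: bool = True,
        word_boundary: bool = True,
        exclusion_scope: str = "sentence",
        window_tokens: int = 5,
    ):
        self.inclusion_terms = inclusion_terms
        self.exclusion_terms = exclusion_terms
        self.scoped_sections = scoped_sections
        self.case_insensitive = case_insensitive
        self.word_boundary = word_boundary
        self.exclusion_scope = exclusion_scope
        self.window_tokens = window_tokens

    @classmethod
    def from_dictionary(cls, dictionary: TermDictionary) -> "PhenotypeClassifier":
        opts = dictionary.match_options
        return cls(
            inclusion_terms=dictionary.inclusion_terms,
            exclusion_terms=dictionary.exclusion_terms,
            scoped_sections=dictionary.scoped_sections,
            case_insensitive=opts.case_insensitive,
            word_boundary=opts.word_boundary,
            exclusion_scope=opts.exclusion_scope,
            window_tokens=opts.window_tokens,
        )

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X=None, y=None) -> "PhenotypeClassifier":
        """Validate and compile the term dictionary. ``X``/``y`` are ignored."""
        inc = (
            tuple(self.inclusion_terms)
            if self.inclusion_terms is not None
            else DEFAULT_INCLUSION_TERMS
        )
        exc = (
            tuple(self.exclusion_terms)
            if self.exclusion_terms is not None
            else DEFAULT_EXCLUSION_TERMS
        )
        scoped = (
            frozenset(self.scoped_sections)
            if self.scoped_sections is not None
            else DEFAULT_SCOPED_SECTIONS
        )
        self.dictionary_ = TermDictionary(
            inclusion_terms=inc,
            exclusion_terms=exc,
            scoped_sections=scoped,
            match_options=MatchOptions(
                case_insensitive=self.case_insensitive,
                word_boundary=self.word_boundary,
                exclusion_scope=self.exclusion_scope,
                window_tokens=self.window_tokens,
            ),
        )
        self.compiled_ = _CompiledDictionary(self.dictionary_)
        self.classes_ = np.array([False, True])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "compiled_"):
            raise AttributeError(
                "PhenotypeClassifier is not fitted; call .fit() first"
            )

    def predict(self, X: Sequence) -> np.ndarray:
        """Boolean ADHF call per admission row."""
        return np.array([v.adhf for v in self.predict_verdicts(X)], dtype=bool)

    def predict_verdicts(self, X: Sequence) -> list[PhenotypeVerdict]:
        """Full verdicts (call plus evidence) per admission row."""
        self._check_fitted()
        return [self._classify(_iter_notes(row)) for row in X]

    # -- pipeline ------------------------------------------------------------

    def _classify(
        self, notes: list[ClinicalNote], admission_id: str | None = None
    ) -> PhenotypeVerdict:
        if notes:
            ids = {n.admission_id for n in notes}
            if len(ids) > 1:
                raise ValueError(
                    f"notes span multiple admissions: {sorted(ids)}"
                )
            admission_id = ids.pop()
        kept: list[TermMatch] = []
        suppressed: list[TermMatch] = []
        # sort for evidence order independent of input iteration order
        for note in sorted(notes, key=lambda n: (n.timestamp, n.note_id)):
            for section in note.sections:
                if section.name not in self.dictionary_.scoped_sections:
                    continue
                for m in self.compiled_.match_section(section, note_id=note.note_id):
                    (suppressed if m.suppressed else kept).append(m)
        return PhenotypeVerdict(
            admission_id=admission_id or "",
            adhf=bool(kept),
            kept_matches=tuple(kept),
            suppressed_matches=tuple(suppressed),
        )


def classify_admission(
    notes: Iterable[ClinicalNote],
    dictionary: TermDictionary,
    admission_id: str | None = None,
) -> PhenotypeVerdict:
    """Run the phenotype on all notes of one admission.

    An empty note collection yields a negative verdict with empty evidence
    (pass ``admission_id`` to label it).
    """
    clf = PhenotypeClassifier.from_dictionary(dictionary).fit()
    return clf._classify(list(notes), admission_id=admission_id)


def run_phenotype(
    corpus: Iterable[ClinicalNote], dictionary: TermDictionary
) -> dict[str, PhenotypeVerdict]:
    """Group a corpus by admission and classify each one.

    Returns a mapping ordered by admission id; the verdicts do not depend on
    the iteration order of ``corpus``.
    """
    clf = PhenotypeClassifier.from_dictionary(dictionary).fit()
    groups: dict[str, list[ClinicalNote]] = {}
    for note in corpus:
        groups.setdefault(note.admission_id, []).append(note)
    return {
        adm_id: clf._classify(notes, admission_id=adm_id)
        for adm_id, notes in sorted(groups.items())
    }


def verdicts_to_predictions(
    verdicts: Mapping[str, PhenotypeVerdict]
) -> dict[str, bool]:
    """Collapse verdicts to the plain admission_id -> bool mapping used by
    the evaluation layer."""
    return {adm_id: v.adhf for adm_id, v in verdicts.items()}
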