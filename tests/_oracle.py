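"""Independent brute-force scanner used to cross-check the engine.

Deliberately written from scratch against the stated classification rule —
split each scoped section into sentences, check word-boundary phrase
containment per sentence, suppress a sentence that also contains an
exclusion cue — without sharing any code with the engine's matcher.
"""

from __future__ import annotations

import re


def _squash(text: str) -> str:
    return " ".join(text.lower().split())


def split_sentences(text: str) -> list[str]:
    # protect decimal points, then split on terminators
    protected = re.sub(r"(\d)\.(\d)", r"\1<DOT>\2", text)
    parts = re.split(r"[.;!?\n]", protected)
    return [p.replace("<DOT>", ".") for p in parts if p.strip()]


def contains_phrase(sentence: str, phrase: str) -> bool:
    pat = rf"(?<!\w){re.escape(_squash(phrase))}(?!\w)"
    return re.search(pat, sentence) is not None


def sentence_positive(sentence, inclusion_terms, exclusion_terms) -> bool:
    s = _squash(sentence)
    if not any(contains_phrase(s, t) for t in inclusion_terms):
        return False
    return not any(contains_phrase(s, e) for e in exclusion_terms)


def oracle_classify_admission(notes, inclusion_terms, exclusion_terms, scoped_sections) -> bool:
    """True iff any scoped-section sentence affirms an inclusion phrase."""
    for note in notes:
        for sec in note.sections:
            if sec.name not in scoped_sections:
                continue
            for sentence in split_sentences(sec.text):
                if sentence_positive(sentence, inclusion_terms, exclusion_terms):
                    return True
    return False


def oracle_run(corpus, inclusion_terms, exclusion_terms, scoped_sections) -> dict[str, bool]:
    groups: dict[str, list] = {}
    for note in corpus:
        groups.setdefault(note.admission_id, []).append(note)
    return {
        adm: oracle_classify_admission(ns, inclusion_terms, exclusion_terms, scoped_sections)
        for adm, ns in groups.items()
    }
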