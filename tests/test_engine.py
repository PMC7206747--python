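import random

import numpy as np
import pytest
from sklearn.base import clone

from adhf_phenotype import (
    MatchOptions,
    PhenotypeClassifier,
    TermDictionary,
    apply_exclusions,
    classify_admission,
    find_inclusion_matches,
    run_phenotype,
)
from adhf_phenotype.simulate import SyntheticCohortSpec, generate_cohort, matched_dictionary

from conftest import SCOPED, make_note, make_section


class TestInclusionMatching:
    def test_single_phrase_hit(self, basic_dictionary):
        sec = make_section("acute decompensated heart failure with edema")
        matches = find_inclusion_matches(sec, basic_dictionary)
        assert len(matches) == 1
        assert matches[0].term == "acute decompensated heart failure"

    def test_word_boundary_blocks_substring(self, basic_dictionary):
        sec = make_section("BADHFX noted")
        assert find_inclusion_matches(sec, basic_dictionary) == []

    def test_repeated_term_counted_twice(self, basic_dictionary):
        sec = make_section("adhf. adhf.")
        assert len(find_inclusion_matches(sec, basic_dictionary)) == 2

    def test_longest_match_wins_and_scan_resumes(self):
        d = TermDictionary(
            inclusion_terms=("heart failure", "acute decompensated heart failure"),
            scoped_sections=SCOPED,
        )
        sec = make_section("acute decompensated heart failure")
        matches = find_inclusion_matches(sec, d)
        assert [m.term for m in matches] == ["acute decompensated heart failure"]

    def test_case_and_whitespace_insensitive(self, basic_dictionary):
        sec = make_section("Acute  Decompensated\nHeart Failure")
        matches = find_inclusion_matches(sec, basic_dictionary)
        assert len(matches) == 1
        # offsets index the original section text
        assert "Decompensated" in sec.text[matches[0].start : matches[0].end]

    def test_match_order_follows_section(self, basic_dictionary):
        sec = make_section("acute chf first, then adhf")
        terms = [m.term for m in find_inclusion_matches(sec, basic_dictionary)]
        assert terms == ["acute chf", "adhf"]


class TestExclusionScoping:
    def test_rule_out_suppresses(self, basic_dictionary):
        sec = make_section("rule out ADHF")
        matches = find_inclusion_matches(sec, basic_dictionary)
        out = apply_exclusions(matches, sec, basic_dictionary)
        assert out[0].suppressed_by == "rule out"

    def test_suppression_is_sentence_local(self, basic_dictionary):
        sec = make_section("negative for ADHF. Admitted for ADHF exacerbation.")
        out = apply_exclusions(
            find_inclusion_matches(sec, basic_dictionary), sec, basic_dictionary
        )
        assert out[0].suppressed_by == "negative for"
        assert out[1].suppressed_by is None

    def test_no_cues_is_identity(self, basic_dictionary):
        sec = make_section("Patient has adhf today.")
        matches = find_inclusion_matches(sec, basic_dictionary)
        assert apply_exclusions(matches, sec, basic_dictionary) == matches

    @pytest.mark.parametrize("cue", ["prior", "rule out", "negative for"])
    def test_each_printed_cue_suppresses(self, cue, basic_dictionary):
        sec = make_section(f"{cue} adhf")
        out = apply_exclusions(
            find_inclusion_matches(sec, basic_dictionary), sec, basic_dictionary
        )
        assert out[0].suppressed_by == cue

    def test_window_scope_respects_token_distance(self):
        d = TermDictionary(
            inclusion_terms=("adhf",),
            exclusion_terms=("rule out",),
            scoped_sections=SCOPED,
            match_options=MatchOptions(exclusion_scope="window", window_tokens=3),
        )
        near = make_section("rule out possible adhf")
        far = make_section("rule out pneumonia, sepsis, and delirium adhf")
        assert apply_exclusions(find_inclusion_matches(near, d), near, d)[0].suppressed
        assert not apply_exclusions(find_inclusion_matches(far, d), far, d)[0].suppressed


class TestClassifyAdmission:
    def test_scoped_mention_is_positive(self, basic_dictionary):
        note = make_note("Principal Diagnosis: Acute decompensated heart failure\n")
        verdict = classify_admission([note], basic_dictionary)
        assert verdict.adhf
        assert verdict.kept_matches[0].section_name == "principal_diagnosis"

    def test_out_of_scope_mention_is_negative(self, basic_dictionary):
        note = make_note("Family History: mother had adhf\n")
        verdict = classify_admission([note], basic_dictionary)
        assert not verdict.adhf
        assert verdict.kept_matches == ()

    def test_prior_mention_only_is_negative(self, basic_dictionary):
        note = make_note("Principal Diagnosis: prior ADHF\n")
        verdict = classify_admission([note], basic_dictionary)
        assert not verdict.adhf
        assert verdict.suppressed_matches[0].suppressed_by == "prior"

    def test_empty_note_collection_is_negative(self, basic_dictionary):
        verdict = classify_admission([], basic_dictionary, admission_id="A9")
        assert verdict.admission_id == "A9"
        assert not verdict.adhf and verdict.kept_matches == ()

    def test_notes_from_mixed_admissions_rejected(self, basic_dictionary):
        notes = [make_note("x", admission_id="A1"), make_note("y", "N2", "A2")]
        with pytest.raises(ValueError, match="multiple admissions"):
            classify_admission(notes, basic_dictionary)

    def test_any_note_of_admission_can_decide(self, basic_dictionary):
        notes = [
            make_note("Chief Complaint: dyspnea\n", "N1", hour=8),
            make_note("Brief Hospital Course: treated for adhf\n", "N2", hour=9),
        ]
        assert classify_admission(notes, basic_dictionary).adhf


class TestRunPhenotype:
    def test_one_verdict_per_admission(self, basic_dictionary):
        corpus = [make_note("x", f"N{i}", f"A{i % 5}") for i in range(10)]
        verdicts = run_phenotype(corpus, basic_dictionary)
        assert len(verdicts) == 5

    def test_empty_corpus(self, basic_dictionary):
        assert run_phenotype([], basic_dictionary) == {}

    def test_verdicts_independent_of_note_order(self, basic_dictionary):
        cohort = generate_cohort(SyntheticCohortSpec(n_patients=30, seed=11))
        notes = list(cohort.notes)
        v1 = run_phenotype(notes, basic_dictionary)
        random.Random(0).shuffle(notes)
        v2 = run_phenotype(notes, basic_dictionary)
        assert v1 == v2

    def test_adding_inclusion_term_is_monotone(self):
        cohort = generate_cohort(SyntheticCohortSpec(n_patients=60, seed=3))
        d0 = matched_dictionary(drop_forms=2)
        d1 = d0.with_terms(add_inclusion=["heart failure exacerbation"])
        v0 = run_phenotype(cohort.notes, d0)
        v1 = run_phenotype(cohort.notes, d1)
        for adm, verdict in v0.items():
            if verdict.adhf:
                assert v1[adm].adhf  # never flips positive -> negative

    def test_adding_exclusion_term_is_antitone(self):
        cohort = generate_cohort(
            SyntheticCohortSpec(n_patients=60, seed=4, p_negated_mention=0.4)
        )
        d0 = matched_dictionary(include_cues=False)
        d1 = d0.with_terms(add_exclusion=["rule out", "negative for", "prior"])
        v0 = run_phenotype(cohort.notes, d0)
        v1 = run_phenotype(cohort.notes, d1)
        for adm, verdict in v0.items():
            if not verdict.adhf:
                assert not v1[adm].adhf  # never flips negative -> positive

    def test_offset_fidelity_of_evidence(self):
        from adhf_phenotype.text import normalize_text

        cohort = generate_cohort(SyntheticCohortSpec(n_patients=40, seed=5))
        d = matched_dictionary()
        by_note = {n.note_id: n for n in cohort.notes}
        for verdict in run_phenotype(cohort.notes, d).values():
            for m in verdict.kept_matches + verdict.suppressed_matches:
                note = by_note[m.note_id]
                sec = next(s for s in note.sections if s.name == m.section_name)
                assert normalize_text(sec.text[m.start : m.end]) == m.term


class TestSklearnInterface:
    def test_fit_predict_over_admission_rows(self, basic_dictionary):
        clf = PhenotypeClassifier.from_dictionary(basic_dictionary).fit()
        X = [
            make_note("Principal Diagnosis: adhf\n"),
            [make_note("Chief Complaint: cough\n", "N2", "A2")],
        ]
        pred = clf.predict(X)
        assert pred.dtype == bool
        assert pred.tolist() == [True, False]
        assert list(clf.classes_) == [False, True]

    def test_params_round_trip_through_clone(self):
        clf = PhenotypeClassifier(inclusion_terms=("adhf",), window_tokens=7)
        cloned = clone(clf)
        assert cloned.get_params()["window_tokens"] == 7
        assert cloned.get_params()["inclusion_terms"] == ("adhf",)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            PhenotypeClassifier().predict([])

    def test_verdict_invariant_enforced(self, basic_dictionary):
        clf = PhenotypeClassifier.from_dictionary(basic_dictionary).fit()
        verdicts = clf.predict_verdicts([make_note("Chief Complaint: rule out adhf\n")])
        v = verdicts[0]
        assert not v.adhf and all(m.suppressed for m in v.suppressed_matches)

    def test_predictions_match_run_phenotype(self, basic_dictionary):
        cohort = generate_cohort(SyntheticCohortSpec(n_patients=25, seed=9))
        verdicts = run_phenotype(cohort.notes, basic_dictionary)
        clf = PhenotypeClassifier.from_dictionary(basic_dictionary).fit()
        by_adm = {}
        for n in cohort.notes:
            by_adm.setdefault(n.admission_id, []).append(n)
        rows = [by_adm[a] for a in sorted(by_adm)]
        np.testing.assert_array_equal(
            clf.predict(rows), [verdicts[a].adhf for a in sorted(by_adm)]
        )
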