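# Methods

## The phenotype

The target condition is acute decompensated heart failure (ADHF): new or
worsening heart-failure signs/symptoms requiring unplanned hospital care.
The computable phenotype is a deterministic rule system over the clinical
notes of one hospital admission:

- **Scope.** Only sections whose canonical names are in the dictionary's
  `scoped_sections` are searched. Default scope: `principal_diagnosis`,
  `secondary_diagnoses`, `chief_complaint`, `brief_hospital_course`.
  Restricting the search to diagnosis-bearing sections is what keeps
  specificity high: a mention in a family-history or medication list is not
  evidence of an acute admission diagnosis.
- **Inclusion matching.** Section text is normalized (lowercased, whitespace
  runs collapsed, typographic quotes/dashes unified) with a per-character
  offset map back to the original text. Inclusion phrases are matched on the
  normalized view as whole tokens (`\b` boundaries), non-overlapping, with
  the longest phrase winning at each position and scanning resuming after a
  match. There is no stemming, spelling correction, or general negation
  grammar: the fixed term list *is* the method, and everything else is kept
  deterministic so a verdict can be reproduced by hand.
- **Exclusion scoping.** A hit is suppressed when an exclusion cue occurs in
  the same sentence (default), or — in window mode — when a cue ends within
  `window_tokens` (default 5) tokens before the hit. Sentences are split on
  `.;!?` and newline, with a guard so decimal points inside numbers do not
  split; there is no abbreviation lexicon, again for hand-reproducibility.
  Sentence-level scope is the design choice for "words associated with" a
  diagnosis; window mode is provided for sensitivity analyses.
- **Aggregation.** An admission is positive iff at least one unsuppressed
  hit exists across all of its notes. Verdicts carry both kept and
  suppressed matches, with section names, character offsets into the
  original section text, sentence indices and the suppressing cue — the
  evidence a reviewer needs to decide whether to edit the term lists.

Default term lists: the inclusion list covers the standard ADHF surface
forms ("acute decompensated heart failure", "acute on chronic heart
failure", "decompensated chf", "acute chf", "heart failure exacerbation",
"adhf", ...); the exclusion list is the core cue triple "prior", "rule out",
"negative for" plus common variants ("history of", "no evidence of",
"resolved", "ruled out", "r/o"). Both are configuration, not code: any
deployment should expect to refine them against local chart review, which is
what the discordance report is for.

## ICD-9 comparators

Two admission-level code strategies serve as benchmarks. The *acute HF* set
contains the six ICD-9-CM fifth-digit acute and acute-on-chronic
systolic/diastolic/combined codes {428.21, 428.23, 428.31, 428.33, 428.41,
428.43}; the *all HF* set matches any 428.x code by hierarchical prefix.
Exact-code matching is string-exact after trimming/uppercasing — "428.0" and
"428.00" are distinct ICD-9-CM entities. Hypertensive-heart-disease codes
(402.x1, 404.x1/x3) are deliberately not in the default all-HF set, which is
defined as the 428 family; a custom code-set CSV can add them. Code position
(principal vs secondary) is not weighted.

## Accuracy evaluation

2×2 tables are counted with the reference standard as column truth.
Sensitivity and specificity are the only default metrics; their 95% CIs are
exact Clopper–Pearson bounds computed from beta quantiles
(`Beta(α/2; k, n−k+1)` and `Beta(1−α/2; k+1, n−k)`, with the k=0 lower and
k=n upper bounds pinned to 0 and 1). Predictive values are available behind
an explicit call because they depend on cohort prevalence and do not
transport between settings. Reference admissions without a prediction are an
error; predictions outside the reference cohort are logged and ignored.
Report percentages are rendered to one decimal.

## Eligibility flow

Patients are filtered before evaluation: excluded first if younger than 18
(completed years at the first admission — the reference date is a
configurable rule, since eligibility snapshots differ between registries),
then if research authorization is absent, so the two exclusion counts
partition the excluded set and `eligible = total − age-excluded −
auth-excluded` holds exactly. A patient with no admissions has no reference
date and is rejected rather than silently classified. Authorization is
modelled per patient, not per admission.

## Synthetic cohort generator

The generator emulates the data regime the phenotype assumes, with ground
truth drawn *before* any text is rendered:

| parameter | default | meaning |
|---|---|---|
| `prevalence` | 0.40 | P(admission is a true ADHF case) |
| `p_document` | 0.98 | P(case documented with an in-scope surface form) |
| `p_negated_mention` | 0.15 | P(control carries a negated/historical mention) |
| `p_out_of_scope_mention` | 0.05 | P(undocumented case mentioned only out of scope) |
| `p_acute_code_given_case` | 0.475 | P(acute 428.x1/x3 code billed for a case) |
| `p_anyhf_code_given_case` | 0.96 | P(any 428 code billed for a case) |
| `p_anyhf_code_given_control` | 0.13 | P(any 428 code billed for a control) |
| `minor_fraction` / `unauthorized_fraction` | 0.14 / 0.05 | eligibility-flow arms |

The defaults describe a cohort where documentation sensitivity is high,
acute-specific coding captures roughly half of true cases, and the broad HF
code family is sensitive but unspecific — the regime in which a text search
outperforms billing codes. The two coding arms share one uniform draw, so an
acute code implies an all-HF code and both marginal rates equal their
parameters exactly (hence the validation `p_acute ≤ p_anyhf`). Controls
never receive acute codes under the three-parameter coding model; acute-code
specificity against truth is therefore 1.0 in simulation, slightly cleaner
than real coding noise.

Notes are templated: six headed sections (four in scope, family history and
medications as distractors) with at least three filler templates per
section, and mention sentences of the form "Patient admitted with *form*."
or "*Cue* *form*." The templates contain no surface form and no cue except
where planted, which is what makes truth labels exact. Deliberately **not**
modelled: realistic clinical discourse, misspellings, copy-forward text,
inter-reviewer disagreement, multi-note admissions by default (a
multi-admission mode exists but the evaluation is admission-level). Passing
tests on this corpus therefore demonstrate the engine's rule semantics and
the evaluation arithmetic — not performance on real notes, which depends
entirely on local term-list refinement.

The generator publishes a manifest (surface forms, cues, section layout) so
tests and the refinement demonstration can build matched or deliberately
impoverished dictionaries without copying string literals.

## Numerical and design choices

- Offsets are 0-based half-open everywhere; timestamps ISO-8601.
- Normalization tracks per-character origin spans, so a match over collapsed
  whitespace still slices correctly out of the original section text.
- Tie-break: at equal start positions the longest inclusion phrase wins;
  overlapping later candidates are skipped (scan resumes at match end).
- A cue and a hit interact only within one section; sections are independent.
- CI method is fixed to Clopper–Pearson ("exact"); mid-p alternatives were
  considered and rejected as the default because exactness (guaranteed
  coverage) is the conventional choice for validation studies.
- Problem sizes in the test-suite and acceptance script (200–5000 synthetic
  admissions, 100 oracle-equivalence corpora of ≤50 notes) were chosen so
  binomial noise is small relative to the margins being checked while the
  whole suite stays interactive.

## Known limitations

- The engine matches phrases across line breaks (whitespace is normalized),
  but the sentence splitter treats a newline as a boundary; a phrase
  wrapped mid-line is matched yet attributed to the sentence containing its
  first character. Templated corpora never wrap phrases.
- Exclusion cues act at sentence (or token-window) granularity; discourse-level
  negation ("the following were ruled out: ... ADHF") is out of scope.
- ICD-9 only; no ICD-10 mapping.
- The section segmenter is header-line based; prose notes without headers
  fall into a single `preamble` section, which is out of scope by default.
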