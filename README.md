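# adhf-phenotype

A computable phenotype for **acute decompensated heart failure (ADHF)** in
hospitalized patients, for clinical-informatics researchers who need to find
ADHF admissions in an EHR without reviewing every chart by hand.

The phenotype (*eADHF*) is a rule-based Boolean free-text search over
sectioned clinical notes:

1. **Section scoping** — only designated note sections are searched
   (principal diagnosis, secondary diagnoses, chief complaint / reason for
   visit, brief hospital course).
2. **Inclusion terms** — ADHF synonyms, abbreviations and acronyms
   ("acute decompensated heart failure", "acute chf", "adhf", ...) matched
   case-insensitively on whole tokens, longest phrase first.
3. **Exclusion-cue scoping** — a hit is suppressed when a cue such as
   *prior*, *rule out* or *negative for* occurs in the same sentence.
4. **Admission-level aggregation** — an admission is called positive iff at
   least one hit survives across all of its notes, and every verdict carries
   its evidence trail (kept and suppressed matches).

The package also provides the two ICD-9 comparator strategies the phenotype
is benchmarked against (an *acute HF* code set — 428.21/.23/.31/.33/.41/.43 —
and an *all HF* set, every 428.x code), the diagnostic-accuracy layer
(2×2 tables; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), with exact
Clopper–Pearson 95% CIs from beta quantiles), the patient-eligibility flow
(adults with research authorization), and a synthetic EHR generator with
known ground truth so the whole derivation/validation workflow runs end to
end with no external data.

The two classifiers are scikit-learn estimators (`PhenotypeClassifier`,
`ICD9CodeClassifier`): rows are admissions, `predict` returns the boolean
call, and the usual `get_params`/`clone` machinery works.

## Worked example

```python
from adhf_phenotype import (
    PhenotypeClassifier, confusion_matrix, sensitivity, specificity,
    run_phenotype, verdicts_to_predictions,
)
from adhf_phenotype.simulate import SyntheticCohortSpec, generate_cohort, matched_dictionary

cohort = generate_cohort(SyntheticCohortSpec(n_patients=50, seed=1))
verdicts = run_phenotype(cohort.notes, matched_dictionary())
tt = confusion_matrix(verdicts_to_predictions(verdicts), cohort.truth_labels)
print(tt)
print(sensitivity(tt).format(), specificity(tt).format())
```

prints

```
TwoByTwo(tp=22, fp=0, fn=0, tn=28)
100.0% (95% CI 84.6-100.0) 100.0% (95% CI 87.7-100.0)
```

i.e. on this 50-admission synthetic cohort (22 true ADHF cases, all
documented) the text search recovers every case and raises no false
positives; the CIs are the exact binomial intervals at those denominators.

The same workflow is available from the shell:

```bash
phenotype simulate --seed 1 --n-patients 200 --out-dir sim/
phenotype run --notes sim/notes.jsonl --out verdicts.csv --evidence ev.jsonl
phenotype icd9 --admissions sim/codes.csv --codeset acute_hf --out icd9.csv
phenotype evaluate --predictions verdicts.csv --reference sim/truth.csv
phenotype protocol --notes sim/notes.jsonl --admissions sim/admissions.csv \
    --codes sim/codes.csv --patients sim/patients.csv \
    --reference sim/truth.csv --out-dir report/
```

`protocol` writes the full report bundle: the strategies-vs-reference
comparison table, the code-sets-vs-eADHF table, a discordance file listing
every mismatching admission with its evidence (the input to the iterative
term-list refinement loop), the cohort-flow counts and a provenance record.

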