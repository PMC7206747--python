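"""End-to-end study protocol: cohort filter -> text phenotype -> ICD-9
comparators -> accuracy report -> discordance file.

One call (or ``phenotype protocol`` on the command line) reproduces the
whole comparison workflow on any corpus laid out in the package's
interchange formats, and writes a provenance record (hashes of config and
dictionary) sufficient to reproduce the report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as _io
from .cohort import filter_eligible
from .dictionary import TermDictionary, default_dictionary, load_term_dictionary
from .engine import run_phenotype, verdicts_to_predictions
from .evaluation import (
    compare_strategies,
    comparison_to_frame,
    discordance_report,
    render_comparison_markdown,
)
from .icd9 import ACUTE_HF_CODE_SET, ALL_HF_CODE_SET, classify_by_codes

__all__ = ["RunConfig", "ProtocolError", "run_full_protocol"]

logger = logging.getLogger(__name__)


class ProtocolError(RuntimeError):
    """A protocol stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    notes_path: Path
    admissions_path: Path
    codes_path: Path
    patients_path: Path
    reference_path: Path
    out_dir: Path
    dictionary_path: Path | None = None
    alpha: float = 0.05
    cohort_label: str = "cohort"
    min_age_years: float = 18
    require_authorization: bool = True

    def validate(self) -> None:
        for name in ("notes_path", "admissions_path", "codes_path",
                     "patients_path", "reference_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.dictionary_path is not None and not Path(self.dictionary_path).exists():
            raise FileNotFoundError(f"dictionary_path: {self.dictionary_path} does not exist")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full_protocol(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle into ``out_dir``.

    Outputs: ``cohort_flow.json``, ``verdicts_eadhf.csv`` (+ evidence),
    ``verdicts_icd9_{acute,all}.csv``, ``comparison_vs_reference.csv/.md``
    (the strategies-vs-reference table), ``comparison_vs_eadhf.csv/.md``
    (code sets judged against the text phenotype), ``discordances.jsonl``
    and ``provenance.json``. Any stage failure removes partial outputs and
    re-raises with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    stage = "config"
    try:
        config.validate()

        stage = "load"
        patients = _io.read_patients(config.patients_path)
        admissions = _io.read_admissions(config.admissions_path, config.codes_path)
        notes = _io.read_note_corpus(config.notes_path)
        labels = _io.labels_to_mapping(_io.read_labels(config.reference_path))
        dictionary: TermDictionary = (
            load_term_dictionary(config.dictionary_path)
            if config.dictionary_path is not None
            else default_dictionary()
        )

        stage = "cohort"
        eligible, flow = filter_eligible(
            patients,
            admissions,
            min_age_years=config.min_age_years,
            require_authorization=config.require_authorization,
        )
        with emit("cohort_flow.json").open("w") as fh:
            json.dump(dataclasses.asdict(flow), fh, indent=2)
        eligible_admissions = [a for a in admissions if a.patient_id in eligible]
        eligible_ids = {a.admission_id for a in eligible_admissions}
        notes = [n for n in notes if n.admission_id in eligible_ids]
        labels = {k: v for k, v in labels.items() if k in eligible_ids}
        if not labels:
            raise ValueError("no reference-labelled admissions in the eligible cohort")

        stage = "phenotype"
        verdicts = run_phenotype(notes, dictionary)
        # admissions without any note are negative by construction
        for adm in eligible_admissions:
            if adm.admission_id not in verdicts:
                from .engine import PhenotypeVerdict

                verdicts[adm.admission_id] = PhenotypeVerdict(
                    admission_id=adm.admission_id, adhf=False
                )
        eadhf = verdicts_to_predictions(verdicts)
        _io.write_verdicts(verdicts, emit("verdicts_eadhf.csv"))
        _io.write_evidence(verdicts, emit("evidence_eadhf.jsonl"))

        stage = "icd9"
        icd9_acute = {
            a.admission_id: classify_by_codes(a, ACUTE_HF_CODE_SET)
            for a in eligible_admissions
        }
        icd9_all = {
            a.admission_id: classify_by_codes(a, ALL_HF_CODE_SET)
            for a in eligible_admissions
        }
        for name, preds in (("acute", icd9_acute), ("all", icd9_all)):
            import pandas as pd

            pd.DataFrame(
                [{"admission_id": k, "adhf": int(v)} for k, v in preds.items()]
            ).to_csv(emit(f"verdicts_icd9_{name}.csv"), index=False)

        stage = "evaluate"
        strategies = {
            "eADHF": eadhf,
            "ICD-9 (acute HF)": icd9_acute,
            "ICD-9 (all HF)": icd9_all,
        }
        vs_reference = compare_strategies(
            labels, strategies, cohort_label=config.cohort_label, alpha=config.alpha
        )
        vs_eadhf = compare_strategies(
            {k: eadhf[k] for k in labels},
            {"ICD-9 (acute HF)": icd9_acute, "ICD-9 (all HF)": icd9_all},
            cohort_label=config.cohort_label,
            reference_name="eADHF",
            alpha=config.alpha,
        )
        comparison_to_frame(vs_reference).to_csv(
            emit("comparison_vs_reference.csv"), index=False
        )
        comparison_to_frame(vs_eadhf).to_csv(emit("comparison_vs_eadhf.csv"), index=False)
        report_md = render_comparison_markdown(
            vs_reference, title="Strategies vs reference standard"
        ) + "\n" + render_comparison_markdown(
            vs_eadhf, title="ICD-9 code sets vs text phenotype (eADHF)"
        )
        emit("report.md").write_text(report_md)

        stage = "discordance"
        discords = discordance_report(eadhf, labels, evidence_store=verdicts)
        _io.write_discordances(discords, emit("discordances.jsonl"))

        stage = "provenance"
        provenance = {
            "config": {
                k: str(v) for k, v in dataclasses.asdict(config).items()
            },
            "input_hashes": {
                "notes": _hash_file(Path(config.notes_path)),
                "admissions": _hash_file(Path(config.admissions_path)),
                "codes": _hash_file(Path(config.codes_path)),
                "patients": _hash_file(Path(config.patients_path)),
                "reference": _hash_file(Path(config.reference_path)),
            },
            "dictionary_sha": hashlib.sha256(
                json.dumps(
                    {
                        "inclusion": list(dictionary.inclusion_terms),
                        "exclusion": list(dictionary.exclusion_terms),
                        "sections": sorted(dictionary.scoped_sections),
                    },
                    sort_keys=True,
                ).encode()
            ).hexdigest()[:16],
        }
        with emit("provenance.json").open("w") as fh:
            json.dump(provenance, fh, indent=2)

    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, ProtocolError):
            raise
        raise ProtocolError(stage, exc) from exc

    return {
        "flow": flow,
        "vs_reference": vs_reference,
        "vs_eadhf": vs_eadhf,
        "discordances": discords,
        "out_dir": out_dir,
    }
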