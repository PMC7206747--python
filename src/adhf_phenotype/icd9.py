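"""ICD-9 code-set comparators.

The phenotype is benchmarked against two billing-code strategies applied per
admission: an *acute HF* set (the ICD-9-CM 428.x fifth-digit "acute" and
"acute on chronic" systolic/diastolic/combined codes) and an *all HF* set
(every 428 code, matched hierarchically by prefix). Matching on exact codes
is string-exact after normalization — "428.0" and "428.00" are distinct
codes in ICD-9-CM and stay distinct here.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import HospitalAdmission, is_valid_icd9

__all__ = [
    "CodeSet",
    "ACUTE_HF_CODE_SET",
    "ALL_HF_CODE_SET",
    "ICD9CodeClassifier",
    "classify_by_codes",
    "load_code_set",
    "save_code_set",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodeSet:
    """A named set of exact ICD-9 codes and hierarchical prefixes."""

    name: str
    codes: frozenset[str] = frozenset()
    prefixes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(_norm(c) for c in self.codes))
        object.__setattr__(self, "prefixes", frozenset(_norm(p) for p in self.prefixes))
        if not self.codes and not self.prefixes:
            raise ValueError(f"code set {self.name!r} is empty")
        for c in self.codes | self.prefixes:
            if not is_valid_icd9(c):
                raise ValueError(f"code set {self.name!r}: invalid ICD-9 code {c!r}")

    def matches(self, code: str) -> bool:
        """True if ``code`` is in the set or extends one of its prefixes."""
        code = _norm(code)
        if code in self.codes:
            return True
        bare = code.replace(".", "")
        return any(bare.startswith(p.replace(".", "")) for p in self.prefixes)

    def issubset(self, other: "CodeSet") -> bool:
        """True if every code this set can match, the other can too (checked
        symbolically: exact codes and prefixes must be covered)."""
        return all(other.matches(c) for c in self.codes) and all(
            other.matches(p) or any(p.replace(".", "").startswith(q.replace(".", ""))
                                    for q in other.prefixes)
            for p in self.prefixes
        )


def _norm(code: str) -> str:
    return code.strip().upper()


# Fifth-digit acute + acute-on-chronic systolic/diastolic/combined HF codes.
ACUTE_HF_CODE_SET = CodeSet(
    name="acute_hf",
    codes=frozenset({"428.21", "428.23", "428.31", "428.33", "428.41", "428.43"}),
)

# Every heart-failure code in the 428 family, matched hierarchically.
ALL_HF_CODE_SET = CodeSet(name="all_hf", prefixes=frozenset({"428"}))

_BUILTIN = {"acute_hf": ACUTE_HF_CODE_SET, "all_hf": ALL_HF_CODE_SET}


def classify_by_codes(
    admission: HospitalAdmission | Iterable[str], code_set: CodeSet
) -> bool:
    """True iff any of the admission's codes falls in ``code_set``.

    Syntactically invalid codes are skipped with a logged warning rather than
    failing the admission.
    """
    codes = (
        admission.icd9_codes
        if isinstance(admission, HospitalAdmission)
        else tuple(admission)
    )
    result = False
    for code in codes:
        if not is_valid_icd9(code):
            logger.warning("skipping invalid ICD-9 code %r", code)
            continue
        if code_set.matches(code):
            result = True
    return result


def resolve_code_set(spec: str | Path | CodeSet) -> CodeSet:
    """Accept a built-in name ('acute_hf', 'all_hf'), a CSV path, or a CodeSet."""
    if isinstance(spec, CodeSet):
        return spec
    if isinstance(spec, str) and spec in _BUILTIN:
        return _BUILTIN[spec]
    return load_code_set(spec)


def load_code_set(path: str | Path, name: str | None = None) -> CodeSet:
    """Read a code set from CSV with columns ``code`` and ``kind``
    (``exact`` | ``prefix``); duplicates collapse."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"code", "kind"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    codes, prefixes = set(), set()
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        code, kind = _norm(str(row.code)), str(row.kind).strip().lower()
        if not is_valid_icd9(code):
            raise ValueError(f"{path} row {row_num}: invalid ICD-9 code {code!r}")
        if kind == "exact":
            codes.add(code)
        elif kind == "prefix":
            prefixes.add(code)
        else:
            raise ValueError(f"{path} row {row_num}: kind must be exact|prefix, got {kind!r}")
    return CodeSet(name=name or path.stem, codes=frozenset(codes), prefixes=frozenset(prefixes))


def save_code_set(code_set: CodeSet, path: str | Path) -> None:
    rows = [{"code": c, "kind": "exact"} for c in sorted(code_set.codes)]
    rows += [{"code": p, "kind": "prefix"} for p in sorted(code_set.prefixes)]
    pd.DataFrame(rows, columns=["code", "kind"]).to_csv(path, index=False)


class ICD9CodeClassifier(ClassifierMixin, BaseEstimator):
    """Admission classifier by ICD-9 code-set membership.

    ``code_set`` may be a built-in name (``"acute_hf"``, ``"all_hf"``), a CSV
    path, or a :class:`CodeSet`. Rows of ``X`` are
    :class:`HospitalAdmission` objects or iterables of code strings.
    """

    def __init__(self, code_set: str | Path | CodeSet = "acute_hf"):
        self.code_set = code_set

    def fit(self, X=None, y=None) -> "ICD9CodeClassifier":
        self.code_set_ = resolve_code_set(self.code_set)
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "code_set_"):
            raise AttributeError("ICD9CodeClassifier is not fitted; call .fit() first")
        return np.array([classify_by_codes(row, self.code_set_) for row in X], dtype=bool)
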