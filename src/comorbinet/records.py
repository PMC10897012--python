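"""Patient-record ingest, ICD-10 code validation, stratification and incidence matrices.

One record is one hospitalization case: demographics (age, sex, binarized
socioeconomic status) plus a set of 1-6 ICD-10 diagnosis codes (one principal
diagnosis and up to five comorbidities). Rows with missing demographics or
no valid diagnosis code are excluded, mirroring the usual EHR cleaning step,
and the exclusions are accounted for by reason.

Strata are age-bracket x sex x SES cells. The default scheme uses the five
brackets 0-20, 21-40, 41-60, 61-80 and 81+, with inclusive integer bounds.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "SES_LEVELS",
    "DEFAULT_AGE_BRACKETS",
    "PatientRecord",
    "StratumSpec",
    "SchemeError",
    "IncidenceMatrix",
    "CodeCheck",
    "ExclusionReport",
    "validate_code",
    "load_records",
    "default_scheme",
    "stratify",
    "build_incidence",
    "stratum_report",
]

SEXES = ("man", "woman")
SES_LEVELS = ("low", "high")

#: Inclusive age brackets; ``None`` upper bound means open-ended.
DEFAULT_AGE_BRACKETS = ((0, 20), (21, 40), (41, 60), (61, 80), (81, None))

# One uppercase letter, two digits, optionally '.' plus 1-2 alphanumerics
# (covers 3-character categories like I25 and subdivisions like I25.8, M32.14).
_CODE_RE = re.compile(r"[A-Z][0-9]{2}(?:\.[A-Z0-9]{1,2})?")


class SchemeError(ValueError):
    """Stratification scheme is overlapping or does not cover [0, inf)."""


@dataclass(frozen=True)
class PatientRecord:
    """One hospitalization case.

    ``codes`` is a set (duplicate diagnoses collapse); it is guaranteed
    non-empty only after ingest validation — the synthetic generator may
    emit empty-code cases, which ingest then excludes.
    """

    case_id: str
    age: int
    sex: str
    ses: str
    codes: frozenset[str]


@dataclass(frozen=True)
class StratumSpec:
    """One age-bracket x sex x SES cell. Bounds are inclusive; ``age_hi=None`` is open."""

    label: str
    age_lo: int
    age_hi: int | None
    sex: str
    ses: str

    def contains(self, record: PatientRecord) -> bool:
        if record.sex != self.sex or record.ses != self.ses:
            return False
        if record.age < self.age_lo:
            return False
        return self.age_hi is None or record.age <= self.age_hi


class CodeCheck(NamedTuple):
    """Outcome of ICD-10 code validation; rejection is a state, not an exception."""

    ok: bool
    code: str | None
    reason: str | None


def validate_code(code: str) -> CodeCheck:
    """Normalize and validate an ICD-10 code string.

    Accepts one uppercase letter, two digits, and optionally a dot followed
    by one or two alphanumerics (e.g. ``I25.8``, ``Q24.8``, ``M32.14``).
    Input is trimmed and upper-cased before matching.

    Returns
    -------
    CodeCheck
        ``(True, normalized, None)`` on acceptance,
        ``(False, None, reason)`` on rejection with reason in
        ``{"empty", "malformed"}``.
    """
    if code is None:
        return CodeCheck(False, None, "empty")
    norm = str(code).strip().upper()
    if not norm:
        return CodeCheck(False, None, "empty")
    if not _CODE_RE.fullmatch(norm):
        return CodeCheck(False, None, "malformed")
    return CodeCheck(True, norm, None)


@dataclass
class ExclusionReport:
    """Accounting of rows and codes dropped during ingest."""

    n_rows: int = 0
    n_loaded: int = 0
    row_exclusions: Counter = field(default_factory=Counter)
    invalid_codes: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.row_exclusions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.row_exclusions.items())
        rows.append(("invalid_code", self.invalid_codes))
        return pd.DataFrame(rows, columns=["reason", "count"])


_DX_RE = re.compile(r"dx\d+")


def load_records(source) -> tuple[list[PatientRecord], ExclusionReport]:
    """Read patient records from the record CSV dialect.

    Expected header: ``case_id,age,sex,ses,dx1..dxK`` (K diagnosis columns,
    trailing cells may be empty). Rows with missing/invalid age, sex or SES
    are excluded with reason ``"incomplete"``; rows whose diagnosis cells
    yield no valid ICD-10 code are excluded with reason ``"no_valid_codes"``.
    Individual malformed codes within otherwise valid rows are dropped and
    counted in the report.

    Parameters
    ----------
    source : path or file-like
        CSV input.

    Returns
    -------
    (records, report)
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = ["case_id", "age", "sex", "ses"]
    missing = [c for c in required if c not in df.columns]
    dx_cols = sorted(
        (c for c in df.columns if _DX_RE.fullmatch(c)), key=lambda c: int(c[2:])
    )
    if missing or not dx_cols:
        raise ValueError(
            f"malformed record CSV header: missing {missing or 'dx columns'}"
        )

    report = ExclusionReport(n_rows=len(df))
    records: list[PatientRecord] = []
    for row in df.itertuples(index=False):
        age_raw = getattr(row, "age").strip()
        sex = getattr(row, "sex").strip().lower()
        ses = getattr(row, "ses").strip().lower()
        try:
            age = int(age_raw)
        except ValueError:
            age = -1
        if age < 0 or sex not in SEXES or ses not in SES_LEVELS:
            report.row_exclusions["incomplete"] += 1
            continue
        codes: set[str] = set()
        for col in dx_cols:
            cell = getattr(row, col)
            if not str(cell).strip():
                continue
            ok, norm, _reason = validate_code(cell)
            if ok:
                codes.add(norm)
            else:
                report.invalid_codes += 1
        if not codes:
            report.row_exclusions["no_valid_codes"] += 1
            continue
        records.append(
            PatientRecord(
                case_id=getattr(row, "case_id"),
                age=age,
                sex=sex,
                ses=ses,
                codes=frozenset(codes),
            )
        )
    report.n_loaded = len(records)
    return records, report


def default_scheme(
    brackets: Sequence[tuple[int, int | None]] = DEFAULT_AGE_BRACKETS,
) -> list[StratumSpec]:
    """Full age x sex x SES stratification scheme (5 x 2 x 2 = 20 cells by default)."""
    scheme = []
    for sex in SEXES:
        for ses in SES_LEVELS:
            for lo, hi in brackets:
                tail = f"{lo}-{hi}" if hi is not None else f"{lo}plus"
                scheme.append(
                    StratumSpec(
                        label=f"{sex}-{ses}-{tail}", age_lo=lo, age_hi=hi, sex=sex, ses=ses
                    )
                )
    return scheme


def validate_scheme(scheme: Sequence[StratumSpec]) -> None:
    """Check that per-(sex, SES) age brackets are disjoint and cover [0, inf)."""
    if not scheme:
        raise SchemeError("empty stratification scheme")
    labels = [s.label for s in scheme]
    if len(set(labels)) != len(labels):
        raise SchemeError("duplicate stratum labels")
    groups: dict[tuple[str, str], list[StratumSpec]] = {}
    for s in scheme:
        if s.sex not in SEXES or s.ses not in SES_LEVELS:
            raise SchemeError(f"stratum {s.label!r}: unknown sex/ses {s.sex!r}/{s.ses!r}")
        if s.age_hi is not None and s.age_lo > s.age_hi:
            raise SchemeError(f"stratum {s.label!r}: age_lo > age_hi")
        groups.setdefault((s.sex, s.ses), []).append(s)
    expected = {(sex, ses) for sex in SEXES for ses in SES_LEVELS}
    if set(groups) != expected:
        raise SchemeError(f"scheme must cover all sex x SES cells; has {sorted(groups)}")
    for key, cells in groups.items():
        cells = sorted(cells, key=lambda s: s.age_lo)
        if cells[0].age_lo != 0:
            raise SchemeError(f"{key}: brackets do not start at age 0")
        for prev, nxt in zip(cells, cells[1:]):
            if prev.age_hi is None:
                raise SchemeError(f"{key}: open-ended bracket before {nxt.label!r}")
            if nxt.age_lo != prev.age_hi + 1:
                raise SchemeError(
                    f"{key}: brackets {prev.label!r} and {nxt.label!r} overlap or leave a gap"
                )
        if cells[-1].age_hi is not None:
            raise SchemeError(f"{key}: brackets do not cover ages above {cells[-1].age_hi}")


def stratify(
    records: Iterable[PatientRecord], scheme: Sequence[StratumSpec] | None = None
) -> dict[StratumSpec, list[PatientRecord]]:
    """Assign every record to exactly one stratum of the scheme.

    The returned mapping contains every stratum of the scheme, including
    empty ones, in scheme order.
    """
    if scheme is None:
        scheme = default_scheme()
    validate_scheme(scheme)
    out: dict[StratumSpec, list[PatientRecord]] = {s: [] for s in scheme}
    for rec in records:
        for s in scheme:
            if s.contains(rec):
                out[s].append(rec)
                break
        else:  # unreachable with a validated covering scheme
            raise RuntimeError(f"record {rec.case_id!r} matched no stratum")
    return out


@dataclass
class IncidenceMatrix:
    """Binary patient x disease occurrence structure for one stratum.

    Diseases are ordered lexicographically and every retained disease occurs
    in at least one patient; ``marginals`` are the per-disease case counts
    n_X used by the co-occurrence test.
    """

    patients: list[str]
    diseases: list[str]
    matrix: np.ndarray  # bool, shape (N, D)
    stratum: StratumSpec | None = None

    @property
    def N(self) -> int:
        return len(self.patients)

    @property
    def marginals(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(int)

    @property
    def is_empty(self) -> bool:
        return self.N == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.astype(int), index=self.patients, columns=self.diseases
        )


def build_incidence(
    records: Sequence[PatientRecord], stratum: StratumSpec | None = None
) -> IncidenceMatrix:
    """Build the binary incidence matrix for one stratum's records.

    Diseases never observed are absent; an empty record list yields a valid
    empty matrix (``is_empty`` true).
    """
    records = list(records)
    diseases = sorted(set().union(*(r.codes for r in records))) if records else []
    idx = {c: j for j, c in enumerate(diseases)}
    matrix = np.zeros((len(records), len(diseases)), dtype=bool)
    for i, rec in enumerate(records):
        for c in rec.codes:
            matrix[i, idx[c]] = True
    return IncidenceMatrix(
        patients=[r.case_id for r in records],
        diseases=diseases,
        matrix=matrix,
        stratum=stratum,
    )


def stratum_report(
    strata: Mapping[StratumSpec | str, Sequence[PatientRecord] | int],
) -> pd.DataFrame:
    """Per-stratum counts, sex split and percentage of the grand total.

    Values of the mapping may be record lists or plain counts (in which case
    the sex split is left missing). Percentages are computed against the sum
    of all stratum counts and rounded to 2 decimals.
    """
    rows = []
    for key, val in strata.items():
        label = key.label if isinstance(key, StratumSpec) else str(key)
        if isinstance(val, (int, np.integer)):
            n, n_women, n_men = int(val), pd.NA, pd.NA
        else:
            n = len(val)
            n_women = sum(1 for r in val if r.sex == "woman")
            n_men = n - n_women
        rows.append((label, n, n_women, n_men))
    total = sum(r[1] for r in rows)
    df = pd.DataFrame(rows, columns=["stratum", "n", "n_women", "n_men"])
    df["percent"] = [round(100.0 * n / total, 2) if total else 0.0 for n in df["n"]]
    return df
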