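"""Domain types and tabular I/O for a longitudinal elderly MRI cohort.

The cohort follows the design of population-based ageing studies: a baseline
examination with structural MRI (regional white-matter-lesion volumes, brain
volumetrics) and standardized follow-up visits at roughly 2, 4 and 7 years,
each with a short cognitive battery and a clinical diagnosis of normal
cognition, mild cognitive impairment (MCI) or dementia.

Two plain-text tables represent a cohort on disk:

* a baseline table, one row per subject (volumes, covariates, censoring times);
* a long-format visit table (subject_id, time, complaint, four test scores,
  diagnosis).

All floats are written with ``repr`` so that write → read is an exact
round trip; missing optional values are empty fields.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ADDITIVITY_TOL",
    "AGE_BANDS",
    "BASELINE_COLUMNS",
    "COGNITIVE_TESTS",
    "EDUCATION_LEVELS",
    "VISIT_COLUMNS",
    "CohortParseError",
    "CohortSchemaError",
    "CohortValidationError",
    "PercentileNorms",
    "RegionalVolumes",
    "Subject",
    "Visit",
    "age_band",
    "mci_r_diagnosis",
    "read_cohort",
    "read_norms",
    "write_cohort",
    "write_norms",
]

#: Tolerance for the additivity invariant total == frontal+parietal+temporal+occipital.
ADDITIVITY_TOL = 1e-9

COGNITIVE_TESTS = ("benton", "isaacs", "five_word_immediate", "five_word_delayed")
EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")
SEXES = ("female", "male")
DIAGNOSES = ("normal", "mci", "dementia")

#: 5-year age bands covering the recruitment window [65, 80).
AGE_BANDS = ("65-69", "70-74", "75-79")


class CohortSchemaError(ValueError):
    """A mandatory column is missing from a cohort file."""


class CohortParseError(ValueError):
    """A cohort file row could not be parsed; the message names the line."""


class CohortValidationError(ValueError):
    """A constructed object violates a domain invariant."""


def age_band(age: float) -> str:
    """Map a baseline age in [65, 80) to its 5-year band label."""
    if 65 <= age < 70:
        return "65-69"
    if 70 <= age < 75:
        return "70-74"
    if 75 <= age < 80:
        return "75-79"
    raise CohortValidationError(f"age {age!r} outside the recruitment window [65, 80)")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionalVolumes:
    """Lobar white-matter-lesion volumes in ml; total is the sum of the four regions."""

    frontal: float
    parietal: float
    temporal: float
    occipital: float
    total: float

    def __post_init__(self) -> None:
        for name in ("frontal", "parietal", "temporal", "occipital", "total"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise CohortValidationError(f"{name} WML volume must be finite and >= 0, got {v!r}")
        s = self.frontal + self.parietal + self.temporal + self.occipital
        if abs(s - self.total) > ADDITIVITY_TOL:
            raise CohortValidationError(
                f"regional WML volumes sum to {s!r} but total is {self.total!r} "
                f"(additivity tolerance {ADDITIVITY_TOL})"
            )

    @classmethod
    def from_regions(
        cls, frontal: float, parietal: float, temporal: float, occipital: float
    ) -> "RegionalVolumes":
        """Build with the total computed as the sum, guaranteeing additivity."""
        return cls(frontal, parietal, temporal, occipital, frontal + parietal + temporal + occipital)


@dataclass(frozen=True)
class Visit:
    """One scheduled follow-up examination.

    ``time`` is in years since baseline (0 for the baseline visit).  The
    diagnosis recorded here is the clinical consensus diagnosis; for event
    definition only the *first* visit with an mci/dementia diagnosis counts.
    """

    time: float
    cognitive_complaint: bool
    test_scores: Mapping[str, float]
    diagnosis: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise CohortValidationError(f"unknown diagnosis {self.diagnosis!r}")
        if self.time < 0:
            raise CohortValidationError(f"visit time must be >= 0, got {self.time!r}")
        missing = [t for t in COGNITIVE_TESTS if t not in self.test_scores]
        if missing:
            raise CohortValidationError(f"visit at t={self.time} missing test scores {missing}")


@dataclass
class Subject:
    """One participant: baseline measurements, covariates and visit history."""

    subject_id: str
    age_baseline: float
    sex: str
    education: str
    hypertension: bool
    vascular_history: bool
    apoe4: bool
    depressive_symptomatology: bool
    total_brain_volume: float
    brain_atrophy: float
    wml: RegionalVolumes
    visits: Sequence[Visit] = field(default_factory=list)
    hippocampal_volume: Optional[float] = None
    silent_brain_infarcts: Optional[bool] = None
    death_time: Optional[float] = None
    dropout_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not (65 <= self.age_baseline < 80):
            raise CohortValidationError(
                f"subject {self.subject_id}: age_baseline {self.age_baseline!r} outside [65, 80)"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(f"subject {self.subject_id}: unknown sex {self.sex!r}")
        if self.education not in EDUCATION_LEVELS:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown education {self.education!r}"
            )
        if self.death_time is not None and self.dropout_time is not None:
            raise CohortValidationError(
                f"subject {self.subject_id}: at most one of death_time/dropout_time may end the record"
            )
        times = [v.time for v in self.visits]
        if times:
            if times[0] != 0:
                raise CohortValidationError(
                    f"subject {self.subject_id}: first visit must be at time 0, got {times[0]!r}"
                )
            for a, b in zip(times, times[1:]):
                if not b > a:
                    raise CohortValidationError(
                        f"subject {self.subject_id}: visit times not strictly increasing ({a!r} -> {b!r})"
                    )
        end = self.death_time if self.death_time is not None else self.dropout_time
        if end is not None and times and times[-1] > end:
            raise CohortValidationError(
                f"subject {self.subject_id}: visit at {times[-1]!r} after record end at {end!r}"
            )

    # -- event extraction ---------------------------------------------------

    def first_event(self) -> Optional[tuple[float, float, str]]:
        """First mci/dementia visit, as (last_normal_time, event_visit_time, diagnosis).

        Returns None for subjects who remained cognitively normal at every
        attended visit.  Later visits never reset an event: the first
        impaired visit defines it.
        """
        last_normal = None
        for v in self.visits:
            if v.diagnosis == "normal":
                last_normal = v.time
            else:
                if last_normal is None:
                    raise CohortValidationError(
                        f"subject {self.subject_id}: impaired at baseline; cohort must be "
                        "cognitively healthy at entry"
                    )
                return (last_normal, v.time, v.diagnosis)
        return None

    def followup_visits(self) -> list[Visit]:
        return [v for v in self.visits if v.time > 0]


@dataclass(frozen=True)
class PercentileNorms:
    """20th-percentile cutoffs per (test, age band, education band).

    A score at or below the cutoff for the subject's band counts as impaired
    on that test ("within the 20th percentile", boundary inclusive).
    """

    cutoffs: Mapping[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        for test in COGNITIVE_TESTS:
            for ab in AGE_BANDS:
                for eb in EDUCATION_LEVELS:
                    key = (test, ab, eb)
                    if key not in self.cutoffs:
                        raise CohortValidationError(f"norms missing cutoff for {key}")
                    if not math.isfinite(self.cutoffs[key]):
                        raise CohortValidationError(f"non-finite cutoff for {key}")

    def cutoff(self, test: str, age_band_label: str, education_band: str) -> float:
        try:
            return self.cutoffs[(test, age_band_label, education_band)]
        except KeyError:
            raise CohortValidationError(
                f"no normative cutoff for test={test!r}, age_band={age_band_label!r}, "
                f"education={education_band!r}"
            ) from None


def mci_r_diagnosis(
    complaint: bool,
    scores: Mapping[str, float],
    norms: PercentileNorms,
    age_band_label: str,
    education_band: str,
    *,
    inclusive: bool = True,
) -> str:
    """Revised-criteria MCI algorithm on one visit's cognitive battery.

    Returns ``"mci"`` iff a cognitive complaint is present AND at least one of
    the four test scores falls within the 20th percentile of the subject's
    age/education-matched normative group; otherwise ``"normal"``.

    Percentile membership is boundary-inclusive by default (score <= cutoff);
    set ``inclusive=False`` for a strict comparison.  Missing scores or bands
    raise rather than being silently imputed.
    """
    missing = [t for t in COGNITIVE_TESTS if t not in scores or scores[t] is None]
    if missing:
        raise CohortValidationError(f"missing test scores {missing}; all four tests are required")
    if not complaint:
        return "normal"
    for test in COGNITIVE_TESTS:
        c = norms.cutoff(test, age_band_label, education_band)
        s = float(scores[test])
        if (s <= c) if inclusive else (s < c):
            return "mci"
    return "normal"


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

BASELINE_COLUMNS = (
    "subject_id",
    "age_baseline",
    "sex",
    "education",
    "hypertension",
    "vascular_history",
    "apoe4",
    "depressive_symptomatology",
    "total_brain_volume",
    "brain_atrophy",
    "hippocampal_volume",
    "silent_brain_infarcts",
    "wml_frontal",
    "wml_parietal",
    "wml_temporal",
    "wml_occipital",
    "wml_total",
    "death_time",
    "dropout_time",
)

VISIT_COLUMNS = (
    "subject_id",
    "time",
    "cognitive_complaint",
    "benton",
    "isaacs",
    "five_word_immediate",
    "five_word_delayed",
    "diagnosis",
)


def _fmt_float(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def _fmt_bool(x: Optional[bool]) -> str:
    return "" if x is None else ("1" if x else "0")


def _parse_float(s: str, line: int, col: str, *, optional: bool = False) -> Optional[float]:
    if s == "":
        if optional:
            return None
        raise CohortParseError(f"line {line}: mandatory numeric column {col!r} is empty")
    try:
        return float(s)
    except ValueError:
        raise CohortParseError(f"line {line}: cannot parse {col!r} value {s!r} as a number") from None


def _parse_bool(s: str, line: int, col: str, *, optional: bool = False) -> Optional[bool]:
    if s == "":
        if optional:
            return None
        raise CohortParseError(f"line {line}: mandatory boolean column {col!r} is empty")
    if s in ("1", "true", "True"):
        return True
    if s in ("0", "false", "False"):
        return False
    raise CohortParseError(f"line {line}: cannot parse {col!r} value {s!r} as a boolean")


def default_visits_path(baseline_path: Path | str) -> Path:
    p = Path(baseline_path)
    return p.with_name(p.stem + "_visits" + (p.suffix or ".csv"))


def write_cohort(
    subjects: Iterable[Subject],
    baseline_path: Path | str,
    visits_path: Optional[Path | str] = None,
    *,
    delimiter: str = ",",
) -> tuple[Path, Path]:
    """Write a cohort as a baseline table plus a long-format visit table.

    Column order is fixed and the output is byte-stable for a given cohort.
    Returns the two paths written.
    """
    baseline_path = Path(baseline_path)
    visits_path = Path(visits_path) if visits_path is not None else default_visits_path(baseline_path)

    brows, vrows = [], []
    for s in subjects:
        brows.append(
            [
                s.subject_id,
                _fmt_float(s.age_baseline),
                s.sex,
                s.education,
                _fmt_bool(s.hypertension),
                _fmt_bool(s.vascular_history),
                _fmt_bool(s.apoe4),
                _fmt_bool(s.depressive_symptomatology),
                _fmt_float(s.total_brain_volume),
                _fmt_float(s.brain_atrophy),
                _fmt_float(s.hippocampal_volume),
                _fmt_bool(s.silent_brain_infarcts),
                _fmt_float(s.wml.frontal),
                _fmt_float(s.wml.parietal),
                _fmt_float(s.wml.temporal),
                _fmt_float(s.wml.occipital),
                _fmt_float(s.wml.total),
                _fmt_float(s.death_time),
                _fmt_float(s.dropout_time),
            ]
        )
        for v in s.visits:
            vrows.append(
                [
                    s.subject_id,
                    _fmt_float(v.time),
                    _fmt_bool(v.cognitive_complaint),
                    _fmt_float(v.test_scores["benton"]),
                    _fmt_float(v.test_scores["isaacs"]),
                    _fmt_float(v.test_scores["five_word_immediate"]),
                    _fmt_float(v.test_scores["five_word_delayed"]),
                    v.diagnosis,
                ]
            )

    for path, cols, rows in (
        (baseline_path, BASELINE_COLUMNS, brows),
        (visits_path, VISIT_COLUMNS, vrows),
    ):
        buf = io.StringIO()
        buf.write(delimiter.join(cols) + "\n")
        for row in rows:
            buf.write(delimiter.join(row) + "\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
    return baseline_path, visits_path


def _read_table(path: Path, delimiter: Optional[str]) -> pd.DataFrame:
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def read_cohort(
    baseline_path: Path | str,
    visits_path: Optional[Path | str] = None,
    *,
    delimiter: Optional[str] = None,
    on_error: str = "raise",
):
    """Read and validate a cohort written by :func:`write_cohort`.

    The delimiter is sniffed from the header (comma or tab) unless given.
    With ``on_error="raise"`` (default) the first invalid row aborts with a
    diagnostic naming the line; with ``on_error="collect"`` invalid subjects
    are dropped and ``(subjects, diagnostics)`` is returned, one message per
    rejected subject.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    baseline_path = Path(baseline_path)
    visits_path = Path(visits_path) if visits_path is not None else default_visits_path(baseline_path)
    if not baseline_path.exists():
        raise FileNotFoundError(baseline_path)

    bdf = _read_table(baseline_path, delimiter)
    missing = [c for c in BASELINE_COLUMNS if c not in bdf.columns]
    if missing:
        raise CohortSchemaError(f"{baseline_path}: missing mandatory columns {missing}")
    vdf = _read_table(visits_path, delimiter) if visits_path.exists() else pd.DataFrame(
        columns=list(VISIT_COLUMNS)
    )
    missing = [c for c in VISIT_COLUMNS if c not in vdf.columns]
    if missing:
        raise CohortSchemaError(f"{visits_path}: missing mandatory columns {missing}")

    visits_by_subject: dict[str, list[tuple[int, Visit]]] = {}
    verrors: dict[str, str] = {}
    for i, row in enumerate(vdf.itertuples(index=False)):
        line = i + 2
        sid = row.subject_id
        try:
            scores = {
                t: _parse_float(getattr(row, t), line, t) for t in COGNITIVE_TESTS
            }
            diag = row.diagnosis
            if diag not in DIAGNOSES:
                raise CohortParseError(f"line {line}: unknown diagnosis {diag!r}")
            v = Visit(
                time=_parse_float(row.time, line, "time"),
                cognitive_complaint=_parse_bool(row.cognitive_complaint, line, "cognitive_complaint"),
                test_scores=scores,
                diagnosis=diag,
            )
        except (CohortParseError, CohortValidationError) as e:
            if on_error == "raise":
                raise CohortParseError(f"{visits_path}: {e}") from None
            verrors.setdefault(sid, str(e))
            continue
        visits_by_subject.setdefault(sid, []).append((line, v))

    subjects: list[Subject] = []
    diagnostics: list[str] = []
    for i, row in enumerate(bdf.itertuples(index=False)):
        line = i + 2
        sid = row.subject_id
        try:
            if sid in verrors:
                raise CohortParseError(f"invalid visit row for subject {sid}: {verrors[sid]}")
            wml = RegionalVolumes(
                frontal=_parse_float(row.wml_frontal, line, "wml_frontal"),
                parietal=_parse_float(row.wml_parietal, line, "wml_parietal"),
                temporal=_parse_float(row.wml_temporal, line, "wml_temporal"),
                occipital=_parse_float(row.wml_occipital, line, "wml_occipital"),
                total=_parse_float(row.wml_total, line, "wml_total"),
            )
            subject = Subject(
                subject_id=sid,
                age_baseline=_parse_float(row.age_baseline, line, "age_baseline"),
                sex=row.sex,
                education=row.education,
                hypertension=_parse_bool(row.hypertension, line, "hypertension"),
                vascular_history=_parse_bool(row.vascular_history, line, "vascular_history"),
                apoe4=_parse_bool(row.apoe4, line, "apoe4"),
                depressive_symptomatology=_parse_bool(
                    row.depressive_symptomatology, line, "depressive_symptomatology"
                ),
                total_brain_volume=_parse_float(row.total_brain_volume, line, "total_brain_volume"),
                brain_atrophy=_parse_float(row.brain_atrophy, line, "brain_atrophy"),
                hippocampal_volume=_parse_float(
                    row.hippocampal_volume, line, "hippocampal_volume", optional=True
                ),
                silent_brain_infarcts=_parse_bool(
                    row.silent_brain_infarcts, line, "silent_brain_infarcts", optional=True
                ),
                wml=wml,
                visits=[v for _, v in sorted(visits_by_subject.get(sid, []), key=lambda lv: lv[1].time)],
                death_time=_parse_float(row.death_time, line, "death_time", optional=True),
                dropout_time=_parse_float(row.dropout_time, line, "dropout_time", optional=True),
            )
        except (CohortParseError, CohortValidationError) as e:
            msg = f"{baseline_path} line {line} (subject {sid!r}): {e}"
            if on_error == "raise":
                raise type(e)(msg) from None
            diagnostics.append(msg)
            continue
        subjects.append(subject)

    if on_error == "collect":
        return subjects, diagnostics
    return subjects


# -- normative tables -------------------------------------------------------


def write_norms(norms: PercentileNorms, path: Path | str) -> Path:
    path = Path(path)
    rows = ["test,age_band,education,cutoff"]
    for test in COGNITIVE_TESTS:
        for ab in AGE_BANDS:
            for eb in EDUCATION_LEVELS:
                rows.append(f"{test},{ab},{eb},{repr(float(norms.cutoffs[(test, ab, eb)]))}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


def read_norms(path: Path | str) -> PercentileNorms:
    df = pd.read_csv(path, dtype={"test": str, "age_band": str, "education": str, "cutoff": float})
    cutoffs = {
        (r.test, r.age_band, r.education): float(r.cutoff) for r in df.itertuples(index=False)
    }
    return PercentileNorms(cutoffs)
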