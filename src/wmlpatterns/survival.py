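"""Onset dating, censoring, person-years and delayed-entry Cox models.

Time runs on the *age* scale with birth as the origin: a subject enters the
risk set at their baseline age (left truncation / delayed entry) and leaves
at their exit age.  Exit is determined by, in order of precedence:

* incident MCI/dementia — the onset is dated halfway between the last visit
  at which the subject was cognitively normal and the diagnosing visit
  (midpoint rule for interval-censored, visit-detected onsets);
* death without a prior event — censored at the age of death;
* otherwise — censored at the last attended visit; a subject who attended no
  post-baseline visit at all contributes zero exposure and is flagged.

Hazard-ratio models follow a fixed ladder of adjustment sets (1-5), from
demographics only up to the fully adjusted model including brain volumetrics
and silent brain infarcts; the fully adjusted model drops subjects with a
missing hippocampal volume or SBI rating.  Age is the timescale, never a
covariate.  Fitting is by maximum partial likelihood with Efron tie handling
(lifelines ``CoxPHFitter`` with an entry column).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import EDUCATION_LEVELS, Subject

__all__ = [
    "CoxFit",
    "MODEL_COVARIATES",
    "SurvivalRecord",
    "build_survival_records",
    "cox_delayed_entry",
    "incidence_rate",
    "onset_time",
    "person_years",
    "rate_per_1000",
    "records_frame",
    "write_records",
    "read_records",
]


def onset_time(last_normal_visit: float, diagnosis_visit: float) -> float:
    """Midpoint onset dating for a visit-detected event: halfway between the
    last cognitively normal visit and the diagnosing visit (years since
    baseline)."""
    if last_normal_visit < 0:
        raise ValueError("visit times must be >= 0")
    if not diagnosis_visit > last_normal_visit:
        raise ValueError(
            f"diagnosis visit ({diagnosis_visit}) must be strictly after the last "
            f"normal visit ({last_normal_visit})"
        )
    return (last_normal_visit + diagnosis_visit) / 2.0


@dataclass
class SurvivalRecord:
    """One subject's contribution to the age-scale risk set."""

    subject_id: str
    entry_age: float
    exit_age: float
    event: bool
    event_type: Optional[str] = None  # "mci" | "dementia" when event
    pattern: Optional[int] = None
    covariates: dict[str, Optional[float]] = field(default_factory=dict)
    zero_exposure: bool = False

    def __post_init__(self) -> None:
        if self.exit_age < self.entry_age:
            raise ValueError(
                f"{self.subject_id}: exit_age {self.exit_age} before entry_age {self.entry_age}"
            )


def _covariates(s: Subject) -> dict[str, Optional[float]]:
    return {
        "sex_male": 1.0 if s.sex == "male" else 0.0,
        "education": float(EDUCATION_LEVELS.index(s.education)),
        "hypertension": float(s.hypertension),
        "vascular_history": float(s.vascular_history),
        "apoe4": float(s.apoe4),
        "depressive_symptomatology": float(s.depressive_symptomatology),
        "total_brain_volume": float(s.total_brain_volume),
        "brain_atrophy": float(s.brain_atrophy),
        "hippocampal_volume": None if s.hippocampal_volume is None else float(s.hippocampal_volume),
        "silent_brain_infarcts": None
        if s.silent_brain_infarcts is None
        else float(s.silent_brain_infarcts),
    }


def build_survival_records(
    subjects: Sequence[Subject], patterns: Mapping[str, int]
) -> list[SurvivalRecord]:
    """Turn the visit histories into delayed-entry records on the age scale.

    ``patterns`` maps subject_id to the assigned lesion pattern (1/2/3).
    """
    records = []
    for s in subjects:
        entry = s.age_baseline
        ev = s.first_event()
        if ev is not None:
            last_normal, tvisit, kind = ev
            exit_age = entry + onset_time(last_normal, tvisit)
            rec = SurvivalRecord(
                s.subject_id, entry, exit_age, True, event_type=kind
            )
        elif s.death_time is not None:
            rec = SurvivalRecord(s.subject_id, entry, entry + s.death_time, False)
        else:
            followups = s.followup_visits()
            if followups:
                rec = SurvivalRecord(s.subject_id, entry, entry + followups[-1].time, False)
            else:
                # attended no post-baseline visit: zero exposure, flagged
                rec = SurvivalRecord(s.subject_id, entry, entry, False, zero_exposure=True)
        rec.pattern = int(patterns[s.subject_id])
        rec.covariates = _covariates(s)
        records.append(rec)
    return records


def person_years(records: Iterable[SurvivalRecord]) -> float:
    """Total exposure: sum of (exit_age - entry_age) over all records."""
    return float(sum(r.exit_age - r.entry_age for r in records))


def rate_per_1000(n_events: int, total_person_years: float) -> float:
    """Incidence rate from aggregate counts: 1000 * events / person-years."""
    if total_person_years <= 0:
        raise ValueError("total person-years must be > 0")
    if n_events < 0:
        raise ValueError("event count must be >= 0")
    return 1000.0 * n_events / total_person_years


def incidence_rate(records: Iterable[SurvivalRecord], event_type: Optional[str] = None) -> float:
    """Events per 1000 person-years; ``event_type`` restricts the numerator to
    "mci" or "dementia" events while keeping the full person-year denominator."""
    records = list(records)
    py = person_years(records)
    if py <= 0:
        raise ValueError("total person-years must be > 0")
    n_events = sum(
        1 for r in records if r.event and (event_type is None or r.event_type == event_type)
    )
    return 1000.0 * n_events / py


def records_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "entry_age": r.entry_age,
                "exit_age": r.exit_age,
                "event": int(r.event),
                "event_type": r.event_type or "",
                "pattern": r.pattern,
                "zero_exposure": int(r.zero_exposure),
                **r.covariates,
            }
        )
    return pd.DataFrame(rows)


def write_records(records: Iterable[SurvivalRecord], path: Path | str) -> Path:
    path = Path(path)
    records_frame(records).to_csv(path, index=False)
    return path


def read_records(path: Path | str) -> list[SurvivalRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str, "event_type": str}, keep_default_na=False)
    covariate_cols = [
        c
        for c in df.columns
        if c
        not in ("subject_id", "entry_age", "exit_age", "event", "event_type", "pattern", "zero_exposure")
    ]
    out = []
    for row in df.itertuples(index=False):
        cov = {}
        for c in covariate_cols:
            v = getattr(row, c)
            cov[c] = None if v == "" or (isinstance(v, float) and math.isnan(v)) else float(v)
        out.append(
            SurvivalRecord(
                subject_id=row.subject_id,
                entry_age=float(row.entry_age),
                exit_age=float(row.exit_age),
                event=bool(int(row.event)),
                event_type=row.event_type or None,
                pattern=int(row.pattern),
                covariates=cov,
                zero_exposure=bool(int(row.zero_exposure)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

#: Adjustment ladder.  Age is absorbed by the delayed-entry age timescale.
MODEL_COVARIATES: dict[int, tuple[str, ...]] = {
    1: ("sex_male", "education"),
    2: ("sex_male", "education", "vascular_history", "hypertension"),
    3: (
        "sex_male",
        "education",
        "vascular_history",
        "hypertension",
        "apoe4",
        "depressive_symptomatology",
    ),
    4: (
        "sex_male",
        "education",
        "vascular_history",
        "hypertension",
        "apoe4",
        "depressive_symptomatology",
        "total_brain_volume",
    ),
    5: (
        "sex_male",
        "education",
        "vascular_history",
        "hypertension",
        "apoe4",
        "depressive_symptomatology",
        "total_brain_volume",
        "hippocampal_volume",
        "brain_atrophy",
        "silent_brain_infarcts",
    ),
}


@dataclass
class CoxFit:
    """A fitted delayed-entry Cox model: one row per covariate with log HR,
    SE, HR and Wald 95% CI/p-value."""

    model: int
    reference_pattern: int
    n: int
    n_events: int
    summary: pd.DataFrame  # index: covariate; columns: coef, se, hr, ci_low, ci_high, p

    def hr(self, covariate: str) -> tuple[float, float, float]:
        """(HR, CI low, CI high) for one covariate."""
        row = self.summary.loc[covariate]
        return float(row["hr"]), float(row["ci_low"]), float(row["ci_high"])

    def coef(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "coef"])

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "reference_pattern": self.reference_pattern,
            "n": self.n,
            "n_events": self.n_events,
            "covariates": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in self.summary.iterrows()
            },
        }

    def save(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
        return path


def _model_frame(
    records: Sequence[SurvivalRecord], covariate_names: Sequence[str], reference_pattern: int
) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.zero_exposure:
            continue  # no time at risk: cannot enter the partial likelihood
        row = {
            "entry_age": r.entry_age,
            "exit_age": r.exit_age,
            "event": int(r.event),
        }
        for p in (1, 2, 3):
            if p != reference_pattern:
                row[f"pattern_{p}"] = 1.0 if r.pattern == p else 0.0
        ok = True
        for c in covariate_names:
            v = r.covariates.get(c)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                ok = False
                break
            row[c] = v
        if ok:
            rows.append(row)
    df = pd.DataFrame(rows)
    # an unrepresented pattern leaves an all-zero indicator: unidentifiable,
    # so it is dropped rather than fed to the optimizer
    for c in [c for c in df.columns if c.startswith("pattern_")]:
        if df[c].nunique() <= 1:
            df = df.drop(columns=c)
    return df


def cox_delayed_entry(
    records: Sequence[SurvivalRecord],
    model: int = 5,
    *,
    reference_pattern: int = 1,
    covariates: Optional[Sequence[str]] = None,
) -> CoxFit:
    """Fit the left-truncated Cox model for one adjustment set.

    The risk set at an event age t contains the records with
    entry_age < t <= exit_age.  Pattern membership enters as two indicators
    against ``reference_pattern``, so all three pairwise contrasts are
    available by switching the reference.  Subjects with a missing covariate
    in the requested set are dropped (the fully adjusted model mirrors the
    reduced n from missing hippocampal volume / SBI ratings).
    """
    if covariates is None:
        if model not in MODEL_COVARIATES:
            raise ValueError(f"model must be one of {sorted(MODEL_COVARIATES)}")
        covariates = MODEL_COVARIATES[model]
    if reference_pattern not in (1, 2, 3):
        raise ValueError("reference_pattern must be 1, 2 or 3")
    df = _model_frame(records, covariates, reference_pattern)
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")

    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(
        df,
        duration_col="exit_age",
        event_col="event",
        entry_col="entry_age",
        show_progress=False,
        fit_options={"precision": 1e-12, "max_steps": 500},
    )
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(
        model=model,
        reference_pattern=reference_pattern,
        n=int(len(df)),
        n_events=n_events,
        summary=summary,
    )
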