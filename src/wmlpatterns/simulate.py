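"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the analysis assumes, so that the whole
pipeline — descriptors, consensus tree, pattern assignment, delayed-entry Cox
models — is exercisable end to end without any real imaging data:

* baseline regional white-matter-lesion volumes drawn from zero-inflated
  log-normal distributions calibrated in closed form to published cohort
  marginals (means/SDs per lobe; the temporal and occipital lobes carry a
  point mass at zero, matching mean << SD);
* a latent three-pattern geography: pattern 1 below a planted total-volume
  threshold (default 1.587 ml); above it, patterns 2 and 3 separated by a
  planted relative temporal volume threshold (default 0.65%);
* MCI/dementia onset from a (piecewise-)constant hazard on the age timescale,
  multiplied by exp(log HR) for true pattern-3 subjects (default ln 2.28);
  onset is only *observed* at the first scheduled visit after it, which
  reproduces the interval censoring the midpoint dating rule handles;
* independent exponential death and loss-to-follow-up processes that censor;
* visit-level cognitive scores generated *consistently* with the recorded
  diagnosis under the MCI-R rule (complaint + >=1 score at or below the 20th
  percentile of the age/education band).

The latent truth (true pattern, latent onset time) is returned alongside the
cohort for oracle-based testing and is written to a separate truth file that
downstream stages never read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .cohort import (
    AGE_BANDS,
    COGNITIVE_TESTS,
    EDUCATION_LEVELS,
    PercentileNorms,
    RegionalVolumes,
    Subject,
    Visit,
    age_band,
)

__all__ = [
    "GeneratorConfig",
    "RegionModel",
    "ScoreModel",
    "SyntheticCohort",
    "generate_cohort",
    "generate_norms",
    "sample_regional_volumes",
    "write_truth",
    "read_truth",
]

REGIONS = ("frontal", "parietal", "temporal", "occipital")


@dataclass(frozen=True)
class RegionModel:
    """Marginal model for one lobe: overall mean/SD targets (ml) plus a zero
    mass.  The conditional log-normal parameters are solved in closed form so
    the *overall* mean and SD equal the targets exactly.  ``loading`` is the
    correlation of the lobe's underlying normal with a shared severity factor
    (a Gaussian copula: lobar volumes are positively correlated in elderly
    cohorts while each marginal stays on target)."""

    mean: float
    sd: float
    zero_mass: float = 0.0
    loading: float = 0.0

    def lognormal_params(self) -> tuple[float, float]:
        p = 1.0 - self.zero_mass
        if not (0 < p <= 1):
            raise ValueError(f"zero_mass must be in [0, 1), got {self.zero_mass}")
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("region mean and sd must be > 0")
        m1 = self.mean / p  # conditional mean given non-zero
        m2 = (self.sd**2 + self.mean**2) / p  # conditional second moment
        sigma2 = math.log(m2 / m1**2)
        if sigma2 <= 0:
            raise ValueError(
                f"infeasible region model (mean={self.mean}, sd={self.sd}, "
                f"zero_mass={self.zero_mass}): conditional variance non-positive"
            )
        mu = math.log(m1) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class ScoreModel:
    """Normative model for one cognitive test: band mean = base - age_step *
    age_band_index + edu_step * education_index, constant SD."""

    base: float
    sd: float
    age_step: float
    edu_step: float

    def mean(self, age_idx: int, edu_idx: int) -> float:
        return self.base - self.age_step * age_idx + self.edu_step * edu_idx


def _default_regions() -> dict[str, RegionModel]:
    # Mean (SD) targets per lobe; zero masses reflect that many elderly
    # subjects have no measurable temporal/occipital lesion load; loadings
    # give the antero-posterior severity gradient its shared component.
    return {
        "frontal": RegionModel(1.15, 2.31, 0.0, loading=0.9),
        "parietal": RegionModel(0.56, 1.37, 0.05, loading=0.9),
        "temporal": RegionModel(0.05, 0.13, 0.10, loading=0.5),
        "occipital": RegionModel(0.03, 0.10, 0.40, loading=0.6),
    }


def _default_scores() -> dict[str, ScoreModel]:
    return {
        "benton": ScoreModel(11.5, 2.0, 0.6, 0.5),
        "isaacs": ScoreModel(32.0, 5.0, 1.0, 1.5),
        "five_word_immediate": ScoreModel(4.6, 0.5, 0.08, 0.05),
        "five_word_delayed": ScoreModel(4.2, 0.8, 0.12, 0.1),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All the dials of the synthetic cohort; defaults are the study
    conditions the downstream analysis is validated under."""

    n_subjects: int = 426
    seed: int = 0

    # lesion geography
    regions: dict[str, RegionModel] = field(default_factory=_default_regions)
    true_total_threshold: float = 1.587  # ml
    true_temporal_wmlr_threshold: float = 0.65  # % of total WML volume

    #: Common age->lesion-load coupling: every lobe is scaled by the same
    #: log-normal factor exp(s*a - s^2/2) (a = standardized age), so lesion
    #: load rises with age while the relative regional volumes are untouched
    #: and each lobar marginal stays exactly on target (the base log-SD is
    #: shrunk to compensate).
    age_wml_coupling: float = 0.45

    # outcome process (age timescale; rate rises with age as cognitive
    # decline incidence does in elderly cohorts)
    baseline_hazard: float = 0.022  # events / person-year, patterns 1-2, youngest band
    log_hazard_pattern3: float = math.log(2.28)
    hazard_breaks: tuple[float, ...] = (70.0, 75.0)  # ages where the baseline rate changes
    hazard_multipliers: tuple[float, ...] = (1.0, 1.6, 2.56)  # len(breaks)+1 multipliers
    dementia_fraction: float = 0.1  # share of incident events that are dementia

    # follow-up design and censoring
    visit_times: tuple[float, ...] = (0.0, 2.0, 4.0, 7.0)
    death_rate: float = 0.006  # per person-year
    dropout_rate: float = 0.032  # per person-year

    # demographics and covariates
    age_mean: float = 71.1
    age_sd: float = 4.0
    age_range: tuple[float, float] = (65.0, 80.0)
    female_fraction: float = 0.55
    education_probs: tuple[float, ...] = (0.15, 0.35, 0.35, 0.15)
    hypertension_prevalence: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.65, 3: 0.65}
    )
    vascular_prevalence: dict[int, float] = field(
        default_factory=lambda: {1: 0.12, 2: 0.20, 3: 0.20}
    )
    depression_prevalence: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.25, 3: 0.12}
    )
    apoe4_prevalence: float = 0.20
    sbi_prevalence: dict[int, float] = field(default_factory=lambda: {1: 0.07, 2: 0.15, 3: 0.15})
    total_brain_volume: tuple[float, float] = (1017.0, 101.0)  # ml, mean/SD
    brain_atrophy: tuple[float, float] = (15.2, 2.4)  # % of ICV, mean/SD
    hippocampal_volume: tuple[float, float] = (5.8, 0.8)  # ml, mean/SD
    p_hippocampus_missing: float = 2 / 426
    p_sbi_missing: float = 8 / 426

    # cognitive battery
    scores: dict[str, ScoreModel] = field(default_factory=_default_scores)
    complaint_prevalence: float = 0.30  # among cognitively normal visits

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for r in REGIONS:
            if r not in self.regions:
                raise ValueError(f"missing region model for {r!r}")
            self.regions[r].lognormal_params()  # raises if degenerate
        for rate in (self.baseline_hazard, self.death_rate, self.dropout_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.true_total_threshold <= 0 or self.true_temporal_wmlr_threshold <= 0:
            raise ValueError("planted thresholds must be > 0")
        vt = self.visit_times
        if len(vt) < 2 or vt[0] != 0 or any(b <= a for a, b in zip(vt, vt[1:])):
            raise ValueError("visit_times must start at 0 and be strictly increasing")
        if self.hazard_breaks:
            if len(self.hazard_multipliers) != len(self.hazard_breaks) + 1:
                raise ValueError("need len(hazard_breaks)+1 hazard_multipliers")
            if any(m < 0 for m in self.hazard_multipliers):
                raise ValueError("hazard multipliers must be >= 0")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education_probs must sum to 1")
        for t in COGNITIVE_TESTS:
            if t not in self.scores or self.scores[t].sd <= 0:
                raise ValueError(f"invalid score model for {t!r}")


class SyntheticCohort(NamedTuple):
    subjects: list[Subject]
    truth: pd.DataFrame  # subject_id, true_pattern, onset_time (latent; NaN if never)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def sample_regional_volumes(
    config: GeneratorConfig,
    n: int,
    rng: np.random.Generator,
    ages: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw an (n, 4) array of lobar volumes (frontal, parietal, temporal,
    occipital): zero-inflated log-normals whose overall mean/SD equal the
    configured targets exactly, correlated across lobes through a shared
    Gaussian severity factor weighted by each region's loading, and scaled
    jointly by the age coupling (which cancels in relative volumes).

    When ``ages`` is omitted, baseline ages are drawn internally from the
    configured truncated normal (consuming the rng in the same order as
    :func:`generate_cohort`)."""
    if ages is None:
        ages = _sample_truncated_normal(
            rng, config.age_mean, config.age_sd, config.age_range[0], config.age_range[1], n
        )
    s = config.age_wml_coupling
    a = (np.asarray(ages, dtype=float) - config.age_mean) / config.age_sd
    # Exact first/second moments of exp(s*a) for the truncated standard
    # normal a, so the age multiplier has mean 1 and a known variance that the
    # base log-SD absorbs: every lobar marginal stays on target exactly.
    alpha = (config.age_range[0] - config.age_mean) / config.age_sd
    beta = (config.age_range[1] - config.age_mean) / config.age_sd
    denom = ndtr(beta) - ndtr(alpha)

    def trunc_mgf(t: float) -> float:
        return math.exp(t * t / 2.0) * (ndtr(beta - t) - ndtr(alpha - t)) / denom

    c1 = trunc_mgf(s)
    log_c2_over_c1sq = math.log(trunc_mgf(2 * s)) - 2 * math.log(c1)
    age_term = s * a - math.log(c1)  # multiplier exp(age_term) has mean exactly 1
    z = rng.standard_normal(n)
    out = np.empty((n, len(REGIONS)))
    for j, r in enumerate(REGIONS):
        model = config.regions[r]
        mu, sigma = model.lognormal_params()
        resid_var = sigma * sigma - log_c2_over_c1sq
        if resid_var <= 0:
            raise ValueError(f"age_wml_coupling {s} exceeds the log-scale SD of region {r!r}")
        resid = math.sqrt(resid_var)
        mu_base = math.log(model.mean / (1.0 - model.zero_mass)) - resid_var / 2.0
        lam = model.loading
        if not -1.0 <= lam <= 1.0:
            raise ValueError(f"region loading must be in [-1, 1], got {lam}")
        e = rng.standard_normal(n)
        x = np.exp(mu_base + age_term + resid * (lam * z + math.sqrt(1.0 - lam * lam) * e))
        if model.zero_mass > 0:
            x[rng.random(n) < model.zero_mass] = 0.0
        out[:, j] = x
    return out


def _sample_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    return mean + sd * ndtri(a + (b - a) * rng.random(n))


def _cumulative_hazard(config: GeneratorConfig, a0: float, t: float, rate: float) -> float:
    """Integrated hazard over ages [a0, a0+t] for a subject with multiplier-free
    rate ``rate`` and the configured piecewise age profile."""
    if not config.hazard_breaks:
        return rate * t
    edges = (-math.inf,) + tuple(config.hazard_breaks) + (math.inf,)
    total = 0.0
    for m, (lo, hi) in zip(config.hazard_multipliers, zip(edges, edges[1:])):
        seg = max(0.0, min(a0 + t, hi) - max(a0, lo))
        total += rate * m * seg
    return total


def _sample_onset(config: GeneratorConfig, a0: float, rate: float, u: float) -> float:
    """Invert the cumulative hazard on the age timescale: the latent onset time
    (years after entry at age a0) solving Lambda(t) = -log(u)."""
    if rate <= 0:
        return math.inf
    target = -math.log(u)
    if not config.hazard_breaks:
        return target / rate
    # piecewise-constant: walk the age segments
    edges = list(config.hazard_breaks) + [math.inf]
    t = 0.0
    acc = 0.0
    age = a0
    for m, hi in zip(
        list(config.hazard_multipliers)[_segment_index(config, a0):], edges[_segment_index(config, a0):]
    ):
        seg_rate = rate * m
        width = hi - age
        seg_haz = seg_rate * width
        if acc + seg_haz >= target or math.isinf(width):
            if seg_rate <= 0:
                return math.inf
            return t + (target - acc) / seg_rate
        acc += seg_haz
        t += width
        age = hi
    return math.inf


def _segment_index(config: GeneratorConfig, age: float) -> int:
    i = 0
    for b in config.hazard_breaks:
        if age >= b:
            i += 1
    return i


# ---------------------------------------------------------------------------
# Normative tables
# ---------------------------------------------------------------------------


def generate_norms(config: GeneratorConfig) -> PercentileNorms:
    """20th-percentile cutoffs of the generator's own per-band score
    distributions (normal, so the percentile is available in closed form)."""
    config.validate()
    z20 = float(ndtri(0.2))
    cutoffs = {}
    for test in COGNITIVE_TESTS:
        model = config.scores[test]
        for ai, ab in enumerate(AGE_BANDS):
            for ei, eb in enumerate(EDUCATION_LEVELS):
                cutoffs[(test, ab, eb)] = model.mean(ai, ei) + model.sd * z20
    return PercentileNorms(cutoffs)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_scores_normal(
    rng: np.random.Generator,
    config: GeneratorConfig,
    ai: int,
    ei: int,
    complaint: bool,
    cutoffs: dict,
    ab: str,
    eb: str,
) -> dict[str, float]:
    """Scores for a cognitively normal visit.  With a complaint present, every
    score is drawn truncated *above* its band cutoff so the MCI-R rule still
    returns normal; without a complaint scores are unconstrained."""
    scores = {}
    for test in COGNITIVE_TESTS:
        m = config.scores[test]
        mu = m.mean(ai, ei)
        if complaint:
            c = cutoffs[(test, ab, eb)]
            lo = float(ndtr((c - mu) / m.sd))
            u = lo + (1.0 - lo) * rng.random()
            # guard against u == lo landing exactly on the cutoff
            scores[test] = float(mu + m.sd * ndtri(min(max(u, lo + 1e-12), 1 - 1e-12)))
        else:
            scores[test] = float(mu + m.sd * rng.standard_normal())
    return scores


def _draw_scores_impaired(
    rng: np.random.Generator,
    config: GeneratorConfig,
    ai: int,
    ei: int,
    cutoffs: dict,
    ab: str,
    eb: str,
    severe: bool,
) -> dict[str, float]:
    """Scores for an MCI (or dementia, ``severe``) visit: one randomly chosen
    test is placed at or below its band cutoff; the rest are unconstrained
    (extra impaired tests only reinforce the diagnosis)."""
    impaired = COGNITIVE_TESTS[rng.integers(len(COGNITIVE_TESTS))]
    scores = {}
    for test in COGNITIVE_TESTS:
        m = config.scores[test]
        mu = m.mean(ai, ei)
        if test == impaired:
            c = cutoffs[(test, ab, eb)]
            drop = abs(rng.standard_normal()) * 0.4 * m.sd + (0.5 * m.sd if severe else 0.0)
            scores[test] = float(c - drop)
        else:
            shift = 0.5 * m.sd if severe else 0.0
            scores[test] = float(mu - shift + m.sd * rng.standard_normal())
    return scores


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given config and seed.

    Returns the subjects plus a latent-truth table (true pattern from the
    planted thresholds, latent onset time) meant for oracle tests only.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_subjects

    ages = _sample_truncated_normal(
        rng, config.age_mean, config.age_sd, config.age_range[0], config.age_range[1], n
    )
    regions = sample_regional_volumes(config, n, rng, ages)
    totals = regions.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tshare = np.where(totals > 0, 100.0 * regions[:, 2] / totals, 0.0)
    pattern = np.where(
        totals < config.true_total_threshold,
        1,
        np.where(tshare < config.true_temporal_wmlr_threshold, 2, 3),
    )

    female = rng.random(n) < config.female_fraction
    education_idx = rng.choice(len(EDUCATION_LEVELS), size=n, p=np.asarray(config.education_probs))
    u_cov = rng.random((n, 4))
    hypertension = u_cov[:, 0] < np.vectorize(config.hypertension_prevalence.get)(pattern)
    vascular = u_cov[:, 1] < np.vectorize(config.vascular_prevalence.get)(pattern)
    depression = u_cov[:, 2] < np.vectorize(config.depression_prevalence.get)(pattern)
    sbi = u_cov[:, 3] < np.vectorize(config.sbi_prevalence.get)(pattern)
    apoe4 = rng.random(n) < config.apoe4_prevalence
    tbv = config.total_brain_volume[0] + config.total_brain_volume[1] * rng.standard_normal(n)
    atrophy = config.brain_atrophy[0] + config.brain_atrophy[1] * rng.standard_normal(n)
    hippo = config.hippocampal_volume[0] + config.hippocampal_volume[1] * rng.standard_normal(n)
    hippo_missing = rng.random(n) < config.p_hippocampus_missing
    sbi_missing = rng.random(n) < config.p_sbi_missing

    rates = config.baseline_hazard * np.exp(config.log_hazard_pattern3 * (pattern == 3))
    u_onset = rng.random(n)
    onset = np.array(
        [_sample_onset(config, float(ages[i]), float(rates[i]), float(u_onset[i])) for i in range(n)]
    )
    death = (
        rng.exponential(1.0 / config.death_rate, size=n)
        if config.death_rate > 0
        else np.full(n, math.inf)
    )
    dropout = (
        rng.exponential(1.0 / config.dropout_rate, size=n)
        if config.dropout_rate > 0
        else np.full(n, math.inf)
    )
    is_dementia = rng.random(n) < config.dementia_fraction

    cutoffs = dict(generate_norms(config).cutoffs)
    last_visit = config.visit_times[-1]
    subjects: list[Subject] = []
    width = len(str(n))
    for i in range(n):
        end = min(death[i], dropout[i])
        attended = [t for t in config.visit_times if t < end]
        ab = age_band(float(ages[i]))
        ai = AGE_BANDS.index(ab)
        ei = int(education_idx[i])
        eb = EDUCATION_LEVELS[ei]

        visits: list[Visit] = []
        event_seen = False
        for t in attended:
            if not event_seen and t > onset[i]:
                severe = bool(is_dementia[i])
                scores = _draw_scores_impaired(rng, config, ai, ei, cutoffs, ab, eb, severe)
                visits.append(
                    Visit(
                        time=float(t),
                        cognitive_complaint=True,
                        test_scores=scores,
                        diagnosis="dementia" if severe else "mci",
                    )
                )
                event_seen = True
                break  # follow-up ends at the diagnosing visit
            complaint = bool(rng.random() < config.complaint_prevalence)
            scores = _draw_scores_normal(rng, config, ai, ei, complaint, cutoffs, ab, eb)
            visits.append(
                Visit(
                    time=float(t),
                    cognitive_complaint=complaint,
                    test_scores=scores,
                    diagnosis="normal",
                )
            )

        death_time = dropout_time = None
        if not event_seen:
            if death[i] <= dropout[i] and death[i] <= last_visit:
                death_time = float(death[i])
            elif dropout[i] < death[i] and dropout[i] <= last_visit:
                dropout_time = float(dropout[i])

        subjects.append(
            Subject(
                subject_id=f"S{i + 1:0{width}d}",
                age_baseline=float(ages[i]),
                sex="female" if female[i] else "male",
                education=eb,
                hypertension=bool(hypertension[i]),
                vascular_history=bool(vascular[i]),
                apoe4=bool(apoe4[i]),
                depressive_symptomatology=bool(depression[i]),
                total_brain_volume=float(tbv[i]),
                brain_atrophy=float(atrophy[i]),
                hippocampal_volume=None if hippo_missing[i] else float(hippo[i]),
                silent_brain_infarcts=None if sbi_missing[i] else bool(sbi[i]),
                wml=RegionalVolumes.from_regions(*[float(v) for v in regions[i]]),
                visits=visits,
                death_time=death_time,
                dropout_time=dropout_time,
            )
        )

    truth = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "true_pattern": pattern.astype(int),
            "onset_time": [float(t) if math.isfinite(t) else math.nan for t in onset],
        }
    )
    return SyntheticCohort(subjects, truth)


def write_truth(truth: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    truth.to_csv(path, index=False)
    return path


def read_truth(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "true_pattern": int})
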